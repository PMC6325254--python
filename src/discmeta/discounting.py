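"""Hyperbolic discounting of delayed, uncertain, and effortful rewards.

Choices between a smaller reward at a lower cost and a larger reward at a
higher cost are modeled with the hyperbolic subjective-value function
SV = R / (1 + k*C), where R is the monetary magnitude, k >= 0 the discount
rate, and C the transformed cost: delay in days (time), odds against winning
(1 - p)/p (probability), or the proportion of the maximum finger-press rate
(effort).  Choice is stochastic through a softmax (logistic) function of the
subjective-value difference with a single slope (inverse temperature).  Both
parameters are estimated per subject by maximum likelihood; because k is
strongly right-skewed across people, Ln(k + 1) is also reported, together
with the model-free proportion of smaller-reward choices.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, log_expit

logger = logging.getLogger(__name__)

__all__ = [
    "Domain",
    "Choice",
    "ChoiceTrial",
    "ChoiceDataset",
    "DiscountFit",
    "cost_transform",
    "subjective_value",
    "choice_probability",
    "fit_discount_model",
    "summarize_choices",
    "load_choice_log",
]


class Domain(str, enum.Enum):
    TIME = "time"
    PROBABILITY = "probability"
    EFFORT = "effort"


class Choice(str, enum.Enum):
    SMALLER = "smaller_cost_option"
    LARGER = "larger_cost_option"


def cost_transform(raw: float, domain: Domain | str) -> float:
    """Map a raw option cost to the cost scale entering the hyperbola.

    time: delay in days (identity); probability: odds against winning
    (1 - p)/p; effort: proportion of maximum press rate (identity).
    """
    domain = Domain(domain)
    if domain == Domain.TIME:
        if raw < 0:
            raise ValueError(f"delay must be >= 0 days, got {raw}")
        return float(raw)
    if domain == Domain.PROBABILITY:
        if not 0 < raw <= 1:
            raise ValueError(f"win probability must be in (0, 1], got {raw}")
        return (1.0 - raw) / raw
    if not 0 < raw <= 1:
        raise ValueError(f"effort proportion must be in (0, 1], got {raw}")
    return float(raw)


def subjective_value(R: float, C: float, k: float) -> float:
    """Hyperbolically discounted value R / (1 + k*C)."""
    if R < 0 or C < 0 or k < 0:
        raise ValueError("R, C and k must all be non-negative")
    return R / (1.0 + k * C)


@dataclass(frozen=True)
class ChoiceTrial:
    """One two-option trial: a smaller reward at a lower cost vs a larger
    reward at a higher cost."""

    r_small: float
    r_large: float
    cost_small: float
    cost_large: float
    domain: Domain
    choice: Choice | None = None

    def __post_init__(self):
        if not self.r_small < self.r_large:
            raise ValueError(
                f"smaller-cost option must have the smaller magnitude "
                f"({self.r_small} vs {self.r_large})"
            )
        c_s = cost_transform(self.cost_small, self.domain)
        c_l = cost_transform(self.cost_large, self.domain)
        if not c_s < c_l:
            raise ValueError(
                f"transformed cost of the smaller option must be strictly lower "
                f"({c_s} vs {c_l})"
            )

    @property
    def transformed_costs(self) -> tuple[float, float]:
        return (
            cost_transform(self.cost_small, self.domain),
            cost_transform(self.cost_large, self.domain),
        )


@dataclass
class ChoiceDataset:
    """Trial-level choices of one subject in one cost domain."""

    trials: list[ChoiceTrial]
    subject_id: str = ""

    def __post_init__(self):
        if not self.trials:
            raise ValueError("dataset must contain at least one trial")
        domains = {t.domain for t in self.trials}
        if len(domains) > 1:
            raise ValueError(f"dataset mixes domains: {sorted(d.value for d in domains)}")

    @property
    def domain(self) -> Domain:
        return self.trials[0].domain

    def arrays(self):
        """(r_small, r_large, C_small, C_large, chose_smaller) as ndarrays."""
        rs = np.array([t.r_small for t in self.trials])
        rl = np.array([t.r_large for t in self.trials])
        cs = np.array([t.transformed_costs[0] for t in self.trials])
        cl = np.array([t.transformed_costs[1] for t in self.trials])
        y = np.array(
            [np.nan if t.choice is None else float(t.choice == Choice.SMALLER)
             for t in self.trials]
        )
        return rs, rl, cs, cl, y


def choice_probability(trial: ChoiceTrial, k: float, slope: float) -> float:
    """Softmax probability of choosing the smaller-cost option."""
    if slope < 0:
        raise ValueError(f"softmax slope must be >= 0, got {slope}")
    c_s, c_l = trial.transformed_costs
    dv = subjective_value(trial.r_small, c_s, k) - subjective_value(trial.r_large, c_l, k)
    return float(expit(slope * dv))


@dataclass(frozen=True)
class DiscountFit:
    """Per-subject maximum-likelihood discounting estimate."""

    k: float
    slope: float
    loglik: float
    ln_k_plus_1: float
    prop_smaller: float
    boundary: bool
    subject_id: str = ""
    domain: Domain | None = None

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "domain": None if self.domain is None else self.domain.value,
            "k": self.k,
            "slope": self.slope,
            "loglik": self.loglik,
            "ln_k_plus_1": self.ln_k_plus_1,
            "prop_smaller": self.prop_smaller,
            "boundary": self.boundary,
        }


#: optimization box for (k, slope); k on the transformed-cost scale
K_BOUNDS = (0.0, 5.0)
SLOPE_BOUNDS = (0.0, 50.0)
#: fixed log-spaced multistart grid (deterministic)
_K_STARTS = np.geomspace(1e-4, K_BOUNDS[1], 8)
_SLOPE_STARTS = np.geomspace(1e-3, SLOPE_BOUNDS[1], 8)
#: number of best start points from which a local optimization is launched
_N_LOCAL = 8


def _negloglik(params, rs, rl, cs, cl, y):
    k, slope = params
    dv = rs / (1.0 + k * cs) - rl / (1.0 + k * cl)
    x = slope * dv
    # Bernoulli log-likelihood, numerically stable via log_expit
    return -float(np.sum(y * log_expit(x) + (1.0 - y) * log_expit(-x)))


def fit_discount_model(data: ChoiceDataset) -> DiscountFit:
    """Estimate (k, slope) by maximum likelihood for one subject.

    Deterministic multistart scheme: the likelihood is evaluated on a fixed
    8x8 log-spaced grid of start values inside the box k in [0, 5],
    slope in [0, 50]; bounded local optimizations (L-BFGS-B) are launched
    from the best grid points and the best converged optimum is returned.
    Solutions at the box edge, or datasets in which every choice is the same,
    are flagged as boundary fits.
    """
    rs, rl, cs, cl, y = data.arrays()
    if np.any(np.isnan(y)):
        raise ValueError("cannot fit a dataset with missing choices")
    prop = float(np.mean(y))

    # vectorized grid evaluation over the start lattice
    kk, ss = np.meshgrid(_K_STARTS, _SLOPE_STARTS, indexing="ij")
    dv = rs / (1.0 + kk[..., None] * cs) - rl / (1.0 + kk[..., None] * cl)
    x = ss[..., None] * dv
    grid_nll = -np.sum(y * log_expit(x) + (1.0 - y) * log_expit(-x), axis=-1)
    order = np.argsort(grid_nll, axis=None, kind="stable")[:_N_LOCAL]

    best = None
    for idx in order:
        i, j = np.unravel_index(idx, grid_nll.shape)
        res = optimize.minimize(
            _negloglik,
            x0=[_K_STARTS[i], _SLOPE_STARTS[j]],
            args=(rs, rl, cs, cl, y),
            method="L-BFGS-B",
            bounds=[K_BOUNDS, SLOPE_BOUNDS],
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    k_hat, slope_hat = float(best.x[0]), float(best.x[1])

    edge_tol = 1e-6
    # a fit no better than random responding (slope = 0, p = 0.5 everywhere)
    # by the joint 95% likelihood-ratio bound has a likelihood essentially
    # flat in k and is unidentifiable
    nll_flat = len(y) * math.log(2.0)
    flat = 2.0 * (nll_flat - best.fun) < stats.chi2.ppf(0.95, df=2)
    boundary = (
        prop in (0.0, 1.0)
        or flat
        or k_hat <= K_BOUNDS[0] + edge_tol
        or k_hat >= K_BOUNDS[1] - edge_tol
        or slope_hat <= SLOPE_BOUNDS[0] + edge_tol
        or slope_hat >= SLOPE_BOUNDS[1] - edge_tol
    )
    if boundary:
        logger.warning(
            "%s/%s: boundary fit (k=%.4g, slope=%.4g, prop_smaller=%.3f)",
            data.subject_id, data.domain.value, k_hat, slope_hat, prop,
        )
    return DiscountFit(
        k=k_hat,
        slope=slope_hat,
        loglik=-float(best.fun),
        ln_k_plus_1=math.log1p(k_hat),
        prop_smaller=prop,
        boundary=boundary,
        subject_id=data.subject_id,
        domain=data.domain,
    )


def summarize_choices(data: ChoiceDataset) -> float:
    """Model-free summary: fraction of trials choosing the smaller-cost option."""
    _, _, _, _, y = data.arrays()
    if np.any(np.isnan(y)):
        raise ValueError("dataset contains trials without an observed choice")
    return float(np.mean(y))


def load_choice_log(path: str | Path) -> list[ChoiceDataset]:
    """Read a trial-level choice CSV into one dataset per subject/domain.

    Columns: subject_id, domain, r_small, r_large, cost_small, cost_large,
    choice (``smaller_cost_option`` / ``larger_cost_option``, may be blank).
    """
    df = pd.read_csv(path)
    required = {"subject_id", "domain", "r_small", "r_large", "cost_small",
                "cost_large", "choice"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for (subj, dom), grp in df.groupby(["subject_id", "domain"], sort=False):
        trials = [
            ChoiceTrial(
                r_small=row.r_small,
                r_large=row.r_large,
                cost_small=row.cost_small,
                cost_large=row.cost_large,
                domain=Domain(dom),
                choice=None if pd.isna(row.choice) else Choice(row.choice),
            )
            for row in grp.itertuples()
        ]
        out.append(ChoiceDataset(trials=trials, subject_id=str(subj)))
    return out
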