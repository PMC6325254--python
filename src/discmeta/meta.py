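"""Random-effects meta-regression by restricted maximum likelihood.

Model: each harmonized effect z_i is Normal(x_i' beta, se_i^2 + tau^2), with
tau^2 the between-effect variance shared across effects.  tau^2 is estimated
by maximizing the restricted (residual) log-likelihood profiled in tau^2;
beta is the weighted least-squares solution at the optimum.  Heterogeneity is
summarized by Cochran's residual Q (QE), the omnibus Wald statistic of the
moderator coefficients (QM), and I^2 computed with the generalized
"typical within-effect variance" convention so that it is defined for
moderated models as well.  Conventions (restricted-likelihood constants,
AIC = -2*loglik + 2*(p+1) counting tau^2, Wald z inference, I^2 from the
hat-matrix trace) follow standard meta-analytic practice so fits are directly
comparable with mainstream meta-analysis software.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .effects import Design, EffectTable, FORMULAS, Group

logger = logging.getLogger(__name__)

__all__ = [
    "RandomEffectsFit",
    "GroupPrediction",
    "reml_fit",
    "compare_models",
    "predict_group",
    "i_squared",
    "restricted_loglik",
]

#: two-sided 95% normal critical value
CI_Z = 1.959964


class ConvergenceError(RuntimeError):
    pass


def _wls(X: np.ndarray, z: np.ndarray, w: np.ndarray):
    """Weighted least squares; returns (beta, (X'WX)^-1)."""
    XtW = X.T * w
    xtwx_inv = np.linalg.inv(XtW @ X)
    return xtwx_inv @ (XtW @ z), xtwx_inv


def restricted_loglik(tau2: float, z: np.ndarray, v: np.ndarray, X: np.ndarray) -> float:
    """Restricted log-likelihood of the model profiled in tau^2.

    Includes all constants — the (k-p)/2 log(2*pi) term, +1/2 log|X'X| and
    -1/2 log|X'WX| — so that AIC values follow the comparable convention.
    """
    k, p = X.shape
    w = 1.0 / (v + tau2)
    beta, _ = _wls(X, z, w)
    resid = z - X @ beta
    _, ld_xtx = np.linalg.slogdet(X.T @ X)
    _, ld_xtwx = np.linalg.slogdet((X.T * w) @ X)
    return float(
        -0.5 * (k - p) * math.log(2 * math.pi)
        + 0.5 * ld_xtx
        + 0.5 * np.sum(np.log(w))
        - 0.5 * ld_xtwx
        - 0.5 * np.sum(w * resid**2)
    )


@dataclass
class RandomEffectsFit:
    """A fitted random-effects meta-regression."""

    formula: str
    coef_names: tuple[str, ...]
    coefficients: np.ndarray
    coef_se: np.ndarray
    coef_cov: np.ndarray
    tau2: float
    QE: float
    QM: float
    QM_df: int
    I2: float
    loglik_reml: float
    aic: float
    k_effects: int
    p_fixed: int
    dropped: tuple[str, ...] = ()
    converged: bool = True
    table_fingerprint: bytes = b""
    design: Design | None = field(default=None, repr=False)

    @property
    def zvals(self) -> np.ndarray:
        return self.coefficients / self.coef_se

    @property
    def pvals(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.zvals))

    def to_dict(self) -> dict:
        """JSON-serializable report of the fit."""
        return {
            "formula": self.formula,
            "coefficients": [
                {
                    "name": n,
                    "estimate": float(b),
                    "se": float(s),
                    "z": float(zv),
                    "p": float(pv),
                    "ci_low": float(b - CI_Z * s),
                    "ci_high": float(b + CI_Z * s),
                }
                for n, b, s, zv, pv in zip(
                    self.coef_names, self.coefficients, self.coef_se, self.zvals, self.pvals
                )
            ],
            "tau2": float(self.tau2),
            "QE": float(self.QE),
            "QM": float(self.QM),
            "QM_df": int(self.QM_df),
            "I2": float(self.I2),
            "loglik_reml": float(self.loglik_reml),
            "aic": float(self.aic),
            "k_effects": int(self.k_effects),
            "p_fixed": int(self.p_fixed),
            "dropped_columns": list(self.dropped),
            "converged": bool(self.converged),
        }


def _fit_arrays(
    z: np.ndarray,
    v: np.ndarray,
    design: Design,
    formula: str,
    fingerprint: bytes = b"",
    tol: float = 1e-8,
    maxiter: int = 1000,
) -> RandomEffectsFit:
    X = design.matrix
    k, p = X.shape
    if k < p:
        raise ValueError(f"need at least as many effects as coefficients ({p}), got {k}")
    if np.any(v <= 0):
        raise ValueError("all standard errors must be positive")
    if k < p + 2:
        logger.warning(
            "only %d effects for %d coefficients; tau^2 is weakly identified", k, p
        )

    # profile REML in tau^2 by bounded scalar maximization; the upper bound
    # comfortably exceeds any plausible between-effect variance of Fisher-z
    # correlations
    hi = max(10.0 * float(np.var(z)), 1.0)
    res = optimize.minimize_scalar(
        lambda t2: -restricted_loglik(t2, z, v, X),
        bounds=(0.0, hi),
        method="bounded",
        options={"xatol": tol * 1e-2, "maxiter": maxiter},
    )
    if not res.success:
        raise ConvergenceError(f"REML optimization failed: {res.message}")
    tau2 = float(res.x)
    # the bounded optimizer cannot land exactly on the boundary; accept 0 if
    # it is at least as good (up to floating-point noise in a flat profile)
    if restricted_loglik(0.0, z, v, X) >= -res.fun - 1e-10:
        tau2 = 0.0
    ll = restricted_loglik(tau2, z, v, X)

    w = 1.0 / (v + tau2)
    beta, cov = _wls(X, z, w)
    se = np.sqrt(np.diag(cov))

    # residual heterogeneity at fixed-effect (tau^2 = 0) weights
    wfe = 1.0 / v
    beta_fe, _ = _wls(X, z, wfe)
    QE = float(np.sum(wfe * (z - X @ beta_fe) ** 2))

    # omnibus Wald test of the moderators (of the intercept if there are none)
    btt = [i for i, n in enumerate(design.names) if n != "intercept"] or [0]
    sub = np.ix_(btt, btt)
    QM = float(beta[btt] @ np.linalg.solve(cov[sub], beta[btt]))

    I2 = _i_squared(tau2, v, X)
    aic = -2.0 * ll + 2.0 * (p + 1)

    return RandomEffectsFit(
        formula=formula,
        coef_names=design.names,
        coefficients=beta,
        coef_se=se,
        coef_cov=cov,
        tau2=tau2,
        QE=QE,
        QM=QM,
        QM_df=len(btt),
        I2=I2,
        loglik_reml=ll,
        aic=aic,
        k_effects=k,
        p_fixed=p,
        dropped=design.dropped,
        table_fingerprint=fingerprint,
        design=design,
    )


def _i_squared(tau2: float, v: np.ndarray, X: np.ndarray) -> float:
    """I^2 (%) with the generalized typical-variance s^2 = (k-p)/tr(P).

    P = W - W X (X'WX)^-1 X'W with fixed-effect weights W = diag(1/v); this
    reduces to the usual Higgins-Thompson form for an intercept-only model
    and remains defined when moderators are present.
    """
    k, p = X.shape
    if tau2 == 0.0 or k == p:
        return 0.0
    w = 1.0 / v
    XtW = X.T * w
    # diag(P) = w_i - w_i^2 * x_i' (X'WX)^-1 x_i
    P_diag = w - w**2 * np.einsum("ij,jk,ik->i", X, np.linalg.inv(XtW @ X), X)
    s2 = (k - p) / float(np.sum(P_diag))
    return 100.0 * tau2 / (tau2 + s2)


def reml_fit(table: EffectTable, formula: str = "intercept", **kwargs) -> RandomEffectsFit:
    """Fit a random-effects meta-regression to a harmonized effect table.

    ``formula`` selects the moderator structure: ``"intercept"`` (common
    correlation), ``"group"`` (clinical group dummies, healthy reference),
    ``"tracer"`` (radiotracer-target dummies, D2 receptor reference), or
    ``"group_x_tracer"`` (both sets plus their estimable interactions).
    """
    if formula not in FORMULAS:
        raise ValueError(f"formula must be one of {FORMULAS}, got {formula!r}")
    design = table.design(formula)
    return _fit_arrays(
        table.z, table.se**2, design, formula, fingerprint=table.fingerprint(), **kwargs
    )


@dataclass(frozen=True)
class GroupPrediction:
    """Model-implied effect for one clinical group, on both z and r scales."""

    group: Group
    z_hat: float
    z_ci: tuple[float, float]
    r_hat: float
    r_ci: tuple[float, float]


def predict_group(fit: RandomEffectsFit, group: Group | str) -> GroupPrediction:
    """Predicted group effect with Wald 95% CI, back-transformed to r via tanh."""
    group = Group(group)
    if not all(
        n == "intercept" or (n.startswith("group[") and ":" not in n) for n in fit.coef_names
    ):
        raise ValueError(
            f"design of formula {fit.formula!r} contains non-group moderators; "
            "a pure group prediction is ambiguous"
        )
    if (
        group != Group.HEALTHY
        and fit.formula != "intercept"
        and f"group[{group.value}]" not in fit.coef_names
    ):
        raise ValueError(f"group {group.value!r} absent from design")
    x = np.array(
        [
            1.0 if n in ("intercept", f"group[{group.value}]") else 0.0
            for n in fit.coef_names
        ]
    )
    z_hat = float(x @ fit.coefficients)
    half = CI_Z * math.sqrt(float(x @ fit.coef_cov @ x))
    z_lo, z_hi = z_hat - half, z_hat + half
    return GroupPrediction(
        group=group,
        z_hat=z_hat,
        z_ci=(z_lo, z_hi),
        r_hat=math.tanh(z_hat),
        r_ci=(math.tanh(z_lo), math.tanh(z_hi)),
    )


def i_squared(fit: RandomEffectsFit) -> float:
    """Percent of total variance due to between-effect heterogeneity."""
    return fit.I2


def compare_models(fits: list[RandomEffectsFit]) -> list[dict]:
    """Rank fits of the same effect table by ascending AIC.

    Returns one record per fit with its AIC and the difference from the best
    model.  REML likelihoods of models with different fixed-effect structures
    are not strictly comparable; a warning is logged and flagged.
    """
    if len(fits) < 2:
        raise ValueError("model comparison needs at least two fits")
    fps = {f.table_fingerprint for f in fits}
    if len(fps) != 1:
        raise ValueError("all fits must be computed on the same effect table")
    differing = len({f.formula for f in fits}) > 1
    if differing:
        logger.warning(
            "comparing REML AICs across different fixed-effect structures; "
            "REML likelihoods are not strictly comparable between such models"
        )
    ranked = sorted(fits, key=lambda f: f.aic)
    best = ranked[0].aic
    return [
        {
            "formula": f.formula,
            "aic": float(f.aic),
            "delta_aic": float(f.aic - best),
            "reml_caveat": differing,
        }
        for f in ranked
    ]
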