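"""Synthetic data: choice datasets from known discounting parameters on the
study task grids, and effect-size collections with known meta-analytic truth.

The choice generators reproduce the factorial structure of the three
two-alternative tasks: temporal discounting with fixed delay menus (younger
adult grid: today/2 weeks/1 month vs 2 weeks/1 month/6 weeks over 84 trials;
life-span grid: today/2 months/4 months vs 2 months/4 months/6 months over
82 trials), probability discounting with the higher win probability at
50/75/100% and the lower one 25 or 50 points below, and effort discounting
with the lower requirement at 35/55/75% of the maximum press rate and the
higher one 20 or 40 points above.  The smaller-cost option's magnitude is
drawn 1-50% below the larger reward.  Choices are Bernoulli draws from the
softmax model, so recovery of (k, slope) by the fitting routines can be
tested against ground truth.

The effect-collection generator mirrors the random-effects model assumed in
the meta-analysis: each effect's true Fisher z is its group mean plus
Normal(0, tau^2) heterogeneity, and the observed z adds Normal(0, 1/(n-3))
sampling noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .discounting import Choice, ChoiceDataset, ChoiceTrial, Domain, choice_probability
from .effects import (
    DiscountIndex,
    EffectTable,
    Group,
    StudyEffect,
    TracerTarget,
    fisher_z_se,
)

__all__ = [
    "TaskGrid",
    "EffectSimSpec",
    "time_grid",
    "probability_grid",
    "effort_grid",
    "generate_choice_dataset",
    "generate_effect_collection",
]

# calendar conventions for delay menus given in weeks/months
_WEEK = 7.0
_MONTH = 30.0


@dataclass(frozen=True)
class TaskGrid:
    """Factorial cost structure of one discounting task.

    ``cost_pairs`` lists the admissible (cost_small, cost_large) raw-cost
    combinations; each trial samples one pair uniformly.  Magnitudes: the
    larger reward is uniform on ``magnitude_range`` and the smaller one is
    1-50% lower (``magnitude_discount_range``).
    """

    domain: Domain
    cost_pairs: tuple[tuple[float, float], ...]
    n_trials: int
    magnitude_range: tuple[float, float] = (10.0, 50.0)
    magnitude_discount_range: tuple[float, float] = (0.01, 0.50)


def time_grid(sample: int = 2) -> TaskGrid:
    """Temporal task grid; ``sample=1`` is the 84-trial younger-adult menu
    (today/2wk/1mo vs 2wk/1mo/6wk), ``sample=2`` the 82-trial life-span menu
    (today/2mo/4mo vs 2mo/4mo/6mo)."""
    if sample == 1:
        small = (0.0, 2 * _WEEK, 1 * _MONTH)
        large = (2 * _WEEK, 1 * _MONTH, 6 * _WEEK)
        n = 84
    elif sample in (2, 3):
        small = (0.0, 2 * _MONTH, 4 * _MONTH)
        large = (2 * _MONTH, 4 * _MONTH, 6 * _MONTH)
        n = 82
    else:
        raise ValueError(f"sample must be 1, 2 or 3, got {sample}")
    pairs = tuple((s, l) for s in small for l in large if s < l)
    return TaskGrid(domain=Domain.TIME, cost_pairs=pairs, n_trials=n)


def probability_grid() -> TaskGrid:
    """Probabilistic task grid: higher probability 50/75/100%, lower one 25 or
    50 points below (82 trials).  The higher-probability option is the
    smaller-cost option (lower odds against)."""
    pairs = []
    for p_high in (0.50, 0.75, 1.00):
        for drop in (0.25, 0.50):
            p_low = round(p_high - drop, 2)
            if p_low > 0:
                pairs.append((p_high, p_low))
    return TaskGrid(domain=Domain.PROBABILITY, cost_pairs=tuple(pairs), n_trials=82)


def effort_grid() -> TaskGrid:
    """Effort task grid: lower requirement 35/55/75% of the maximum press
    rate, higher one 20 or 40 points above, capped at 95% (82 trials)."""
    pairs = []
    for e_low in (0.35, 0.55, 0.75):
        for step in (0.20, 0.40):
            e_high = round(e_low + step, 2)
            if e_high <= 0.95:
                pairs.append((e_low, e_high))
    return TaskGrid(domain=Domain.EFFORT, cost_pairs=tuple(pairs), n_trials=82)


def generate_choice_dataset(
    grid: TaskGrid,
    k: float,
    slope: float,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
) -> ChoiceDataset:
    """Simulate one subject's choices from known (k, slope) on a task grid."""
    if k < 0 or slope < 0:
        raise ValueError("k and slope must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    trials = []
    for _ in range(grid.n_trials):
        c_small, c_large = grid.cost_pairs[rng.integers(len(grid.cost_pairs))]
        r_large = rng.uniform(*grid.magnitude_range)
        frac = rng.uniform(*grid.magnitude_discount_range)
        trial = ChoiceTrial(
            r_small=r_large * (1.0 - frac),
            r_large=r_large,
            cost_small=c_small,
            cost_large=c_large,
            domain=grid.domain,
        )
        p_small = choice_probability(trial, k, slope)
        chosen = Choice.SMALLER if rng.random() < p_small else Choice.LARGER
        trials.append(
            ChoiceTrial(
                r_small=trial.r_small,
                r_large=trial.r_large,
                cost_small=trial.cost_small,
                cost_large=trial.cost_large,
                domain=trial.domain,
                choice=chosen,
            )
        )
    return ChoiceDataset(trials=trials, subject_id=subject_id)


@dataclass(frozen=True)
class EffectSimSpec:
    """Specification of a simulated effect-size collection.

    ``true_betas`` are the group-level mean Fisher-z effects in the order
    (healthy, addiction, other_psychopathology); ``group_props`` the mixing
    proportions over those groups; ``tau2_true`` the between-effect variance;
    ``n_range`` the inclusive interval from which per-effect sample sizes are
    drawn uniformly.  Defaults mirror the structure of the published
    collection: 14 effects in roughly 7/4/3 group proportions, small-study
    sample sizes, and group means implied by the fitted group model.
    ``noise_scale`` multiplies the sampling SD (0 yields noise-free effects,
    useful for degenerate-case checks).
    """

    n_effects: int = 14
    group_props: tuple[float, float, float] = (0.5, 0.29, 0.21)
    true_betas: tuple[float, float, float] = (-0.138, -0.754, 0.655)
    tau2_true: float = 0.05
    n_range: tuple[int, int] = (10, 30)
    seed: int = 0
    noise_scale: float = 1.0

    def __post_init__(self):
        if abs(sum(self.group_props) - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        if self.tau2_true < 0:
            raise ValueError("tau2_true must be >= 0")
        if self.n_range[0] < 4:
            raise ValueError("per-effect sample sizes must be >= 4")


_GROUPS = (Group.HEALTHY, Group.ADDICTION, Group.OTHER_PSYCHOPATHOLOGY)


def generate_effect_collection(spec: EffectSimSpec) -> EffectTable:
    """Draw an effect collection with known group means and heterogeneity.

    Per effect: group label from ``group_props``, sample size uniform on
    ``n_range``, true z = group beta + Normal(0, tau2), observed
    z = true z + Normal(0, 1/(n-3)).  The observed z is stored as a
    harmonized effect (the equivalent correlation is tanh(z)); deterministic
    given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    groups = rng.choice(len(_GROUPS), size=spec.n_effects, p=spec.group_props)
    effects = []
    for i, gi in enumerate(groups):
        n = int(rng.integers(spec.n_range[0], spec.n_range[1] + 1))
        true_z = spec.true_betas[gi] + spec.noise_scale * rng.normal(
            0.0, np.sqrt(spec.tau2_true)
        )
        se = fisher_z_se(n)
        obs_z = true_z + spec.noise_scale * rng.normal(0.0, se)
        effects.append(
            StudyEffect(
                study_id=f"sim{i:03d}",
                group=_GROUPS[gi],
                tracer_target=TracerTarget.D2_RECEPTOR,
                region="whole striatum",
                index=DiscountIndex.K,
                n=n,
                r=float(np.tanh(obs_z)),
                z=float(obs_z),
                se=se,
                note="simulated",
            )
        )
    return EffectTable(effects)
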