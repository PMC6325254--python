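"""Publication-bias diagnostics: Egger-type regression test and funnel data.

The asymmetry test follows the moderated-model convention: the effect
standard error is added to the meta-regression design as one more fixed
effect, the random-effects model is refit by REML, and the Wald z of the
standard-error coefficient is the test statistic.  A significant negative z
indicates that less precise studies report systematically more negative
harmonized effects (small-study asymmetry).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .effects import Design, EffectTable
from .meta import RandomEffectsFit, _fit_arrays

__all__ = ["EggerResult", "FunnelDatum", "egger_test", "funnel_data", "funnel_plot"]

#: two-sided pseudo-confidence levels shown as funnel shading bands
FUNNEL_LEVELS = (0.90, 0.95, 0.99)


@dataclass(frozen=True)
class EggerResult:
    """Result of the regression test for funnel-plot asymmetry."""

    z: float
    p: float
    slope: float
    slope_se: float
    fit: RandomEffectsFit

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"Egger's regression test: Z = {self.z:.3f}, p = {self.p:.4f}"


def egger_test(table: EffectTable, formula: str = "intercept") -> EggerResult:
    """Small-study asymmetry test on a (possibly moderated) random-effects model."""
    se = table.se
    if np.ptp(se) == 0:
        raise ValueError("all effects have identical standard errors; the "
                         "precision moderator is collinear with the intercept")
    base = table.design(formula)
    design = Design(base.names + ("se",), np.column_stack([base.matrix, se]), base.dropped)
    fit = _fit_arrays(
        table.z, se**2, design, f"{formula}+se", fingerprint=table.fingerprint()
    )
    i = design.names.index("se")
    slope = float(fit.coefficients[i])
    slope_se = float(fit.coef_se[i])
    z = slope / slope_se
    return EggerResult(z=z, p=float(2 * stats.norm.sf(abs(z))), slope=slope,
                       slope_se=slope_se, fit=fit)


@dataclass(frozen=True)
class FunnelDatum:
    """One point of a residual funnel plot."""

    effect_id: str
    residual: float
    se: float


def funnel_data(fit: RandomEffectsFit, table: EffectTable):
    """Residual funnel-plot data for a fitted model.

    Returns ``(data, bands)`` where ``data`` is one :class:`FunnelDatum` per
    effect (residual = observed z minus model prediction) and ``bands`` maps
    each two-sided level in :data:`FUNNEL_LEVELS` to ``(se_grid, half_width)``
    with half-width = z_crit * sqrt(se^2 + tau^2): residuals outside a band
    are more extreme than that level's p-value under the fitted model.
    """
    if fit.table_fingerprint != table.fingerprint():
        raise ValueError("fit was not produced from this effect table")
    X = fit.design.matrix if fit.design is not None else table.design(fit.formula).matrix
    resid = table.z - X @ fit.coefficients
    data = [
        FunnelDatum(effect_id=e.study_id, residual=float(r), se=float(e.se))
        for e, r in zip(table.effects, resid)
    ]
    se_grid = np.linspace(0.0, float(table.se.max()) * 1.05, 200)
    bands = {
        level: (se_grid, stats.norm.ppf(0.5 + level / 2) * np.sqrt(se_grid**2 + fit.tau2))
        for level in FUNNEL_LEVELS
    }
    return data, bands


def funnel_plot(fit: RandomEffectsFit, table: EffectTable, path: str):
    """Render the residual funnel plot (shaded pseudo-confidence bands) to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data, bands = funnel_data(fit, table)
    fig, ax = plt.subplots(figsize=(5, 5))
    shades = {0.90: "0.85", 0.95: "0.70", 0.99: "0.55"}
    for level in sorted(bands, reverse=True):
        grid, half = bands[level]
        ax.fill_betweenx(grid, -half, half, color=shades.get(level, "0.8"),
                         label=f"p < {1 - level:.2f}")
    ax.scatter([d.residual for d in data], [d.se for d in data],
               marker="D", color="black", zorder=3)
    ax.invert_yaxis()
    ax.set_xlabel("residual (Fisher z)")
    ax.set_ylabel("standard error")
    ax.legend(loc="lower left", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
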