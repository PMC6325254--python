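"""Harmonization of published correlation effects onto a signed Fisher-z scale.

Published PET studies of reward discounting report their behavior-binding
associations in heterogeneous forms: Pearson or partial correlations,
t statistics with degrees of freedom, and a variety of discounting indices
(hyperbolic k, Ln(k), area under the discounting curve, proportions of
smaller-reward choices, occupancy correlates).  Before meta-analysis every
effect is expressed as a Fisher z value whose *sign* is aligned so that more
positive values mean greater discounting, with standard error 1/sqrt(n - 3).
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Group",
    "TracerTarget",
    "DiscountIndex",
    "StudyEffect",
    "EffectTable",
    "Design",
    "SchemaError",
    "correlation_from_t",
    "fisher_z",
    "fisher_z_se",
    "sign_align",
    "pool_subcondition_effects",
    "partial_correlation",
    "load_effect_table",
    "load_bundled_effects",
]


class SchemaError(ValueError):
    """Raised when an effect table fails validation; carries offending rows."""

    def __init__(self, message: str, rows: Sequence[int] = ()):
        super().__init__(message)
        self.rows = list(rows)


class Group(str, enum.Enum):
    HEALTHY = "healthy"
    ADDICTION = "addiction"
    OTHER_PSYCHOPATHOLOGY = "other_psychopathology"


class TracerTarget(str, enum.Enum):
    D2_RECEPTOR = "d2_receptor"
    DA_SYNTHESIS = "da_synthesis"
    DAT = "dat"


class DiscountIndex(str, enum.Enum):
    """Behavioral index a study correlated with its dopamine measure.

    The index determines the harmonization sign: k, Ln(k) and the proportion
    of smaller (sooner / more certain / less effortful) choices all increase
    with discounting and keep their sign; AUC and the proportion of larger
    (high-effort) choices decrease with discounting and are flipped; an
    occupancy correlate is inversely related to the underlying availability
    measure and is likewise flipped.
    """

    K = "k"
    LN_K = "ln_k"
    AUC = "auc"
    PROPORTION_SMALLER = "proportion_smaller"
    PROPORTION_LARGER = "proportion_larger"
    OCCUPANCY_CORRELATE = "occupancy_correlate"


# Indices for which the reported correlation sign must be inverted so that
# positive harmonized z means "more dopamine measure, more discounting".
_FLIP_INDICES = frozenset(
    {DiscountIndex.AUC, DiscountIndex.PROPORTION_LARGER, DiscountIndex.OCCUPANCY_CORRELATE}
)


def correlation_from_t(t: float, df: float) -> float:
    """Convert a t statistic with df degrees of freedom to a correlation.

    r = sign(t) * sqrt(t^2 / (t^2 + df)).
    """
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    t = float(t)
    return math.copysign(math.sqrt(t * t / (t * t + df)), t) if t != 0 else 0.0


def fisher_z(r: float) -> float:
    """Fisher r-to-z (variance stabilizing) transform, arctanh(r)."""
    if abs(r) >= 1:
        raise ValueError(f"|r| must be < 1, got {r}")
    return math.atanh(r)


def fisher_z_se(n: float) -> float:
    """Standard error of a Fisher z value from a sample of n participants."""
    if n < 4:
        raise ValueError(f"sample size must be >= 4 for a finite SE, got {n}")
    return 1.0 / math.sqrt(n - 3)


def sign_align(z_raw: float, index: DiscountIndex | str) -> float:
    """Align the sign of a Fisher z so positive means greater discounting."""
    index = DiscountIndex(index)
    return -z_raw if index in _FLIP_INDICES else z_raw


def index_direction(index: DiscountIndex | str) -> int:
    """+1 if the index increases with discounting, -1 if it decreases."""
    return -1 if DiscountIndex(index) in _FLIP_INDICES else 1


def pool_subcondition_effects(rs: Iterable[float]) -> float:
    """Average sub-condition correlations on the Fisher-z scale.

    Used when a study reports one correlation per within-task condition and
    only their common effect is wanted: each r is z-transformed and the z
    values are averaged arithmetically.
    """
    rs = list(rs)
    if not rs:
        raise ValueError("cannot pool an empty list of correlations")
    return float(np.mean([fisher_z(r) for r in rs]))


def partial_correlation(
    x: Sequence[float], y: Sequence[float], covariates: Sequence[Sequence[float]] | None = None
) -> float:
    """Pearson correlation of x and y after partialling out covariates.

    Both variables are residualized against the covariate columns plus an
    intercept by least squares; with no covariates this reduces to the plain
    Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if covariates is None or np.size(covariates) == 0:
        C = np.ones((x.size, 1))
    else:
        C = np.column_stack([np.ones(x.size), np.asarray(covariates, dtype=float)])
    if x.size < C.shape[1] + 2:
        raise ValueError("too few observations for the requested adjustment")
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    proj = C @ np.linalg.lstsq(C, np.column_stack([x, y]), rcond=None)[0]
    rx, ry = (np.column_stack([x, y]) - proj).T
    return float(np.corrcoef(rx, ry)[0, 1])


@dataclass(frozen=True)
class StudyEffect:
    """One published effect, harmonized onto the signed Fisher-z scale."""

    study_id: str
    group: Group
    tracer_target: TracerTarget
    region: str
    index: DiscountIndex
    n: int
    r: float
    z: float
    se: float
    note: str = ""

    @classmethod
    def from_reported(
        cls,
        study_id: str,
        group: Group | str,
        tracer_target: TracerTarget | str,
        region: str,
        index: DiscountIndex | str,
        n: int,
        r: float | None = None,
        t: float | None = None,
        df: float | None = None,
        note: str = "",
    ) -> "StudyEffect":
        """Build a harmonized effect from the statistics a study reported.

        Exactly one of ``r`` or ``(t, df)`` must be supplied; if both are
        present the correlation wins and a warning is logged.
        """
        if r is None and (t is None or df is None):
            raise ValueError(f"{study_id}: supply either r or both t and df")
        if r is not None and t is not None:
            logger.warning("%s: both r and t supplied; using r", study_id)
        if r is None:
            r = correlation_from_t(t, df)
        index = DiscountIndex(index)
        z = sign_align(fisher_z(r), index)
        return cls(
            study_id=study_id,
            group=Group(group),
            tracer_target=TracerTarget(tracer_target),
            region=str(region),
            index=index,
            n=int(n),
            r=float(r),
            z=z,
            se=fisher_z_se(n),
            note=note,
        )

    @property
    def index_direction(self) -> int:
        return index_direction(self.index)


#: moderator formulas understood by :meth:`EffectTable.design`
FORMULAS = ("intercept", "group", "tracer", "group_x_tracer")

_REFERENCE_LEVELS = {"group": Group.HEALTHY, "tracer": TracerTarget.D2_RECEPTOR}


@dataclass(frozen=True)
class Design:
    """Dummy-coded moderator matrix with named columns.

    ``dropped`` lists columns removed because they were empty or linearly
    dependent on earlier columns (possible in the group-by-tracer interaction,
    where some group/tracer cells are unobserved); they are surfaced rather
    than silently discarded.
    """

    names: tuple[str, ...]
    matrix: np.ndarray
    dropped: tuple[str, ...] = ()


@dataclass
class EffectTable:
    """Ordered collection of harmonized study effects."""

    effects: list[StudyEffect] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.effects)

    @property
    def z(self) -> np.ndarray:
        return np.array([e.z for e in self.effects])

    @property
    def se(self) -> np.ndarray:
        return np.array([e.se for e in self.effects])

    def fingerprint(self) -> bytes:
        """Stable identity of the (z, se) data, used to match fits to tables."""
        return np.round(np.concatenate([self.z, self.se]), 12).tobytes()

    def design(self, formula: str = "intercept") -> Design:
        """Build the dummy-coded moderator matrix for one of the named models.

        Reference levels (no column): healthy group, D2-receptor target.
        """
        if formula not in FORMULAS:
            raise ValueError(f"formula must be one of {FORMULAS}, got {formula!r}")
        k = len(self.effects)
        cols: list[tuple[str, np.ndarray]] = [("intercept", np.ones(k))]
        g_levels = [Group.ADDICTION, Group.OTHER_PSYCHOPATHOLOGY]
        t_levels = [TracerTarget.DA_SYNTHESIS, TracerTarget.DAT]
        gdum = {
            g: np.array([1.0 if e.group == g else 0.0 for e in self.effects]) for g in g_levels
        }
        tdum = {
            t: np.array([1.0 if e.tracer_target == t else 0.0 for e in self.effects])
            for t in t_levels
        }
        if formula in ("group", "group_x_tracer"):
            cols += [(f"group[{g.value}]", gdum[g]) for g in g_levels]
        if formula in ("tracer", "group_x_tracer"):
            cols += [(f"tracer[{t.value}]", tdum[t]) for t in t_levels]
        if formula == "group_x_tracer":
            cols += [
                (f"group[{g.value}]:tracer[{t.value}]", gdum[g] * tdum[t])
                for g in g_levels
                for t in t_levels
            ]
        names, mat, dropped = [], [], []
        for name, col in cols:
            if not np.any(col):
                dropped.append(name)
                continue
            cand = np.column_stack(mat + [col]) if mat else col[:, None]
            if np.linalg.matrix_rank(cand) < cand.shape[1]:
                dropped.append(name)
                continue
            names.append(name)
            mat.append(col)
        if dropped:
            logger.warning(
                "design %r: dropped empty or collinear columns: %s", formula, ", ".join(dropped)
            )
        return Design(tuple(names), np.column_stack(mat), tuple(dropped))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "study_id": [e.study_id for e in self.effects],
                "group": [e.group.value for e in self.effects],
                "tracer_target": [e.tracer_target.value for e in self.effects],
                "region": [e.region for e in self.effects],
                "index": [e.index.value for e in self.effects],
                "n": [e.n for e in self.effects],
                "r": [e.r for e in self.effects],
                "z": [e.z for e in self.effects],
                "se": [e.se for e in self.effects],
            }
        )


_REQUIRED_COLUMNS = ("study_id", "group", "tracer_target", "region", "index", "n")


def load_effect_table(path: str | Path, sep: str | None = None) -> EffectTable:
    """Read a CSV/TSV effect table and return the harmonized ``EffectTable``.

    Expected columns: study_id, group, tracer_target, region, index, r, t,
    df, n, exclude, note (r or t/df may be blank row-wise, but one of the two
    must be present on every non-excluded row).  Rows with a truthy
    ``exclude`` flag are dropped with a log message; row order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    effects: list[StudyEffect] = []
    bad: list[tuple[int, str]] = []
    for i, row in df.iterrows():
        excl = row.get("exclude") if "exclude" in df.columns else None
        if excl is not None and pd.notna(excl):
            try:
                flagged = float(excl) != 0
            except (TypeError, ValueError):
                flagged = str(excl).strip().lower() in ("true", "yes", "y")
            if flagged:
                logger.info("row %d (%s): excluded by flag", i, row["study_id"])
                continue
        r = row.get("r")
        t = row.get("t")
        dfree = row.get("df")
        kwargs = dict(
            r=None if pd.isna(r) else float(r),
            t=None if pd.isna(t) else float(t),
            df=None if pd.isna(dfree) else float(dfree),
        )
        try:
            effects.append(
                StudyEffect.from_reported(
                    study_id=str(row["study_id"]),
                    group=str(row["group"]),
                    tracer_target=str(row["tracer_target"]),
                    region=str(row["region"]),
                    index=str(row["index"]),
                    n=int(row["n"]),
                    note="" if pd.isna(row.get("note")) else str(row.get("note")),
                    **kwargs,
                )
            )
        except (ValueError, KeyError) as exc:
            bad.append((i, str(exc)))
    if bad:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad)
        raise SchemaError(f"{path}: invalid rows — {detail}", rows=[i for i, _ in bad])
    if not effects:
        raise SchemaError(f"{path}: no usable effect rows")
    return EffectTable(effects)


def bundled_effects_path() -> Path:
    """Path of the packaged table of published time-discounting effects."""
    return Path(resources.files("discmeta").joinpath("data/table1_time_effects.csv"))


def load_bundled_effects() -> EffectTable:
    """Load the 14 published time-discounting PET effects shipped with the package."""
    return load_effect_table(bundled_effects_path())
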