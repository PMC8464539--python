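"""Life tables and synthetic inputs.

Background mortality of the general population enters the lifetime model as a
life table: annual death probability ``qx`` per integer age.  Real tables are
read from a two-column CSV (``age,qx``).  Because national life tables are not
redistributable here, the module also generates parametric Gompertz-Makeham
tables; the repository bundles one such synthetic table calibrated to UK-like
adult mortality for reproduction runs.

``random_params`` produces jittered parameter sets around the base case for
property testing of the full pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .params import (
    AnalysisSettings,
    ClinicalParams,
    CostParams,
    ModelParams,
    MrsDistribution,
    UtilityParams,
)

__all__ = [
    "MortalityTable",
    "gompertz_life_table",
    "uk_like_life_table",
    "read_life_table",
    "write_life_table",
    "random_params",
]


@dataclass(frozen=True)
class MortalityTable:
    """Annual death probability per integer age.

    Ages must be contiguous and ascending.  Lookups beyond the last
    tabulated age return the last qx (plateau extrapolation), so a cohort
    can always be propagated past the table end; lookups below the first
    age are an error.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        if ages.ndim != 1 or ages.shape != qx.shape or ages.size == 0:
            raise ValueError("ages and qx must be equal-length non-empty 1-d arrays")
        if not np.all(np.diff(ages) == 1):
            raise ValueError("ages must be contiguous ascending integers with no gaps")
        if np.any(qx < 0) or np.any(qx > 1):
            raise ValueError("qx values must lie in [0, 1]")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)

    def qx_at(self, age: int) -> float:
        """Annual death probability at ``age`` (plateau beyond the table end)."""
        first = int(self.ages[0])
        if age < first:
            raise ValueError(f"age {age} below table start {first}")
        idx = min(age - first, self.qx.size - 1)
        return float(self.qx[idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MortalityTable)
            and np.array_equal(self.ages, other.ages)
            and np.array_equal(self.qx, other.qx)
        )


def gompertz_life_table(
    a: float = 3.5e-5,
    b: float = 0.094,
    c: float = 4e-4,
    max_age: int = 110,
) -> MortalityTable:
    """Synthetic Gompertz-Makeham life table.

    qx(age) = min(1, c + a * exp(b * age)) for age 0..max_age: ``a`` scales
    the age-dependent (Gompertz) hazard, ``b`` is its log-slope per year of
    age (b = 0.094 doubles adult mortality roughly every 7.4 years), and
    ``c`` is the age-independent (Makeham) hazard floor.
    """
    if a < 0 or b < 0 or c < 0:
        raise ValueError("Gompertz-Makeham parameters must be non-negative")
    if max_age < 1:
        raise ValueError("max_age must be >= 1")
    ages = np.arange(0, max_age + 1)
    qx = np.minimum(1.0, c + a * np.exp(b * ages))
    return MortalityTable(ages, qx)


def uk_like_life_table(max_age: int = 100) -> MortalityTable:
    """Synthetic life table calibrated to UK 2017-2019 unisex adult mortality.

    Gompertz-Makeham parameters are fitted to widely published national
    life-table magnitudes (annual death probability about 1.2% at age 66 and
    about 4.7% at age 80), giving a remaining life expectancy at 66 of about
    18.5 years.  This is a synthetic stand-in, not the national table itself.
    """
    return gompertz_life_table(a=1.93e-5, b=0.0975, c=2e-4, max_age=max_age)


def read_life_table(path) -> MortalityTable:
    """Read a CSV life table with header ``age,qx``, one row per integer age."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV
        raise ValueError(f"cannot parse life table {path}: {exc}") from exc
    if list(df.columns[:2]) != ["age", "qx"]:
        raise ValueError(f"life table {path} must have columns 'age,qx', got {list(df.columns)}")
    ages_raw = df["age"].to_numpy()
    if not np.all(ages_raw == ages_raw.astype(int)):
        bad = int(np.argmax(ages_raw != ages_raw.astype(int))) + 2
        raise ValueError(f"life table {path}: non-integer age at row {bad}")
    ages = ages_raw.astype(int)
    if np.unique(ages).size != ages.size:
        raise ValueError(f"life table {path}: duplicate ages")
    try:
        return MortalityTable(ages, df["qx"].to_numpy(dtype=float))
    except ValueError as exc:
        raise ValueError(f"life table {path}: {exc}") from exc


def write_life_table(table: MortalityTable, path) -> None:
    """Write a life table as the canonical ``age,qx`` CSV (round-trips)."""
    pd.DataFrame({"age": table.ages, "qx": table.qx}).to_csv(
        path, index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Random parameter sets for property testing


def _jitter_vec(rng: np.random.Generator, vec, jitter: float) -> np.ndarray:
    v = np.asarray(vec, dtype=float)
    return v * rng.uniform(1 - jitter, 1 + jitter, size=v.shape)


def _jitter_dist(rng: np.random.Generator, dist: MrsDistribution, jitter: float) -> MrsDistribution:
    p = _jitter_vec(rng, dist.as_array(), jitter)
    return MrsDistribution(p / p.sum())


def random_params(seed: int, jitter: float = 0.2) -> ModelParams:
    """Base-case parameters with every scalar multiplied by an independent
    uniform factor in [1 - jitter, 1 + jitter].

    Probabilities are clamped to [0, 1], mRS distributions renormalized,
    utilities kept non-increasing, so the result is always valid.  Identical
    seeds give identical parameter sets; jitter 0 returns the exact defaults.
    """
    if not 0.0 <= jitter <= 0.5:
        raise ValueError("jitter must lie in [0, 0.5]")
    rng = np.random.default_rng(seed)
    base = ModelParams.defaults()

    def jp(x):  # jittered probability
        return float(np.clip(x * rng.uniform(1 - jitter, 1 + jitter), 0.0, 1.0))

    def js(x):  # jittered non-negative scalar
        return float(x * rng.uniform(1 - jitter, 1 + jitter))

    c = base.clinical
    clinical = ClinicalParams(
        p_lvo=jp(c.p_lvo),
        p_eligible=jp(c.p_eligible),
        p_missed=jp(c.p_missed),
        reduction=jp(c.reduction),
        p_recurrent=jp(c.p_recurrent),
        age0=max(18, int(round(js(c.age0)))),
        cohort_n=c.cohort_n,
        mrs_iat=_jitter_dist(rng, c.mrs_iat, jitter),
        mrs_no_iat=_jitter_dist(rng, c.mrs_no_iat, jitter),
    )
    k = base.costs
    costs = CostParams(
        acute_by_state=tuple(_jitter_vec(rng, k.acute_by_state, jitter)),
        longterm_by_state=tuple(_jitter_vec(rng, k.longterm_by_state, jitter)),
        tx_iat=js(k.tx_iat),
        tx_no_iat=js(k.tx_no_iat),
        ai_per_analysis=js(k.ai_per_analysis),
        discount_costs=float(np.clip(js(k.discount_costs), 0.0, 0.2)),
    )
    u = base.utilities
    uvec = np.clip(_jitter_vec(rng, u.utility_by_state, jitter), 0.0, 1.0)
    uvec = np.minimum.accumulate(uvec)  # keep utilities non-increasing in mRS
    utilities = UtilityParams(
        utility_by_state=tuple(uvec),
        discount_utilities=float(np.clip(js(u.discount_utilities), 0.0, 0.2)),
    )
    settings = replace(base.settings, seed=int(seed))
    return ModelParams(clinical=clinical, costs=costs, utilities=utilities, settings=settings)
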