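"""Seeded generator of cancer-registry-like case tables.

The generator emulates the record schema of a pathology registry — patient
age and sex, examination year, organ, T/N/M staging, grading, receptor
state, disease-free and overall survival, and a mortality flag — with the
conditional structure that makes the glyph views informative:

* sex-skewed organs (lung male-skewed, thyroid female-skewed),
* mortality and survival times conditioned on T stage,
* a per-sex missing-T-staging bias (male-biased, as seen in registry data
  where colon tissue arrives as a secondary finding of a prostate biopsy),
* rare age-entry errors pinned at exactly 0 and 100 years.

Distributional forms (truncated-normal age, exponential survival) are the
simplest ones producing the right phenomenology — a pyramid-shaped age
profile and cap-color gradients — not epidemiological estimates.  All
sampling flows through one ``numpy`` Generator, so a seed fully determines
the dataset, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .data_model import MISSING, CaseRecord, Dataset, infer_variable_meta

__all__ = [
    "CohortConfig",
    "ConfigError",
    "PRESETS",
    "generate_cases",
    "generate_preset",
    "make_comparison_cohorts",
    "concat_datasets",
    "SCHEMA",
]

T_STAGES = ("T1", "T2", "T3", "T4")
FOLLOW_UP_MONTHS = 120  # truncation horizon for survival columns

#: Declared scale (and ordinal order) per generated column, used to build
#: VariableMeta and written to the sidecar by the CLI.
SCHEMA: Mapping[str, dict] = {
    "organ": {"scale": "nominal"},
    "sex": {"scale": "nominal"},
    "age": {"scale": "continuous"},
    "exam_year": {"scale": "interval"},
    "t_stage": {"scale": "ordinal", "order": list(T_STAGES)},
    "n_stage": {"scale": "ordinal", "order": ["N0", "N1", "N2"]},
    "m_stage": {"scale": "ordinal", "order": ["M0", "M1"]},
    "grading": {"scale": "ordinal", "order": ["G1", "G2", "G3"]},
    "receptor_state": {"scale": "nominal"},
    "dfs_months": {"scale": "continuous"},
    "os_months": {"scale": "continuous"},
    "deceased": {"scale": "nominal"},
}


class ConfigError(ValueError):
    """Invalid cohort configuration (checked before any sampling)."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    ``missing_t_rate`` is either a single probability or a ``(male, female)``
    pair; the pair form reproduces the male-biased missing-staging anomaly.
    ``mortality_by_t`` / ``dfs_mean_by_t`` are per-T-class vectors aligned
    with T1..T4.  ``year_trend`` skews the examination-year distribution
    linearly (0 = uniform, 1 = strongly increasing caseload).
    """

    n: int
    organ: str
    male_fraction: float
    age_mean: float
    age_sd: float
    year_range: tuple = (1984, 2004)
    t_stage_probs: tuple = (0.3, 0.3, 0.25, 0.15)
    missing_t_rate: float | tuple = 0.05
    mortality_by_t: tuple = (0.05, 0.15, 0.35, 0.6)
    dfs_mean_by_t: tuple = (90.0, 60.0, 36.0, 18.0)
    outlier_rate: float = 0.0
    year_trend: float = 0.0
    receptor_missing_rate: float = 0.1

    def validate(self) -> None:
        if self.n < 0:
            raise ConfigError(f"n must be >= 0, got {self.n}")
        probs = list(self.t_stage_probs)
        if len(probs) != len(T_STAGES):
            raise ConfigError("t_stage_probs must have one entry per T class")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigError(f"t_stage_probs sum to {sum(probs)!r}, expected 1")
        singles = [self.male_fraction, self.outlier_rate, self.receptor_missing_rate]
        singles += list(probs) + list(self.mortality_by_t)
        singles += list(self._missing_t_pair())
        for p in singles:
            if not (0.0 <= p <= 1.0):
                raise ConfigError(f"probability {p!r} outside [0, 1]")
        if self.age_sd <= 0:
            raise ConfigError("age_sd must be positive")
        if any(m <= 0 for m in self.dfs_mean_by_t):
            raise ConfigError("dfs_mean_by_t entries must be positive")
        if self.year_range[0] > self.year_range[1]:
            raise ConfigError("year_range start must not exceed end")

    def _missing_t_pair(self) -> tuple:
        if isinstance(self.missing_t_rate, (tuple, list)):
            if len(self.missing_t_rate) != 2:
                raise ConfigError("missing_t_rate pair must be (male, female)")
            return tuple(self.missing_t_rate)
        return (self.missing_t_rate, self.missing_t_rate)


# Conditional N-stage distribution per T class: nodal involvement rises
# with tumor size.
_N_PROBS_BY_T = {
    "T1": (0.85, 0.12, 0.03),
    "T2": (0.7, 0.22, 0.08),
    "T3": (0.5, 0.32, 0.18),
    "T4": (0.3, 0.4, 0.3),
}
_M1_PROB_BY_T = {"T1": 0.01, "T2": 0.04, "T3": 0.12, "T4": 0.3}
_GRADING_PROBS = (0.3, 0.5, 0.2)


def generate_cases(config: CohortConfig, seed: int) -> Dataset:
    """Sample a cohort; the same (config, seed) yields an identical Dataset."""
    config.validate()
    rng = np.random.default_rng(seed)
    n = config.n

    male = rng.random(n) < config.male_fraction
    sex = np.where(male, "M", "F")

    lo, hi = 0.0, 100.0
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )
    age = np.clip(np.rint(age), 0, 100).astype(int)

    y0, y1 = config.year_range
    years = np.arange(y0, y1 + 1)
    w = 1.0 + config.year_trend * np.linspace(0.0, 4.0, len(years))
    exam_year = rng.choice(years, size=n, p=w / w.sum())

    t_idx = rng.choice(len(T_STAGES), size=n, p=list(config.t_stage_probs))
    t_stage = np.array(T_STAGES)[t_idx]

    m_rate, f_rate = config._missing_t_pair()
    miss_t = rng.random(n) < np.where(male, m_rate, f_rate)

    n_stage = np.empty(n, dtype=object)
    m_stage = np.empty(n, dtype=object)
    deceased = np.empty(n, dtype=bool)
    dfs = np.empty(n)
    mortality = dict(zip(T_STAGES, config.mortality_by_t))
    dfs_mean = dict(zip(T_STAGES, config.dfs_mean_by_t))
    u_n = rng.random(n)
    u_m = rng.random(n)
    u_d = rng.random(n)
    u_dfs = rng.exponential(1.0, size=n)
    for i in range(n):
        t = t_stage[i]
        cum = np.cumsum(_N_PROBS_BY_T[t])
        n_stage[i] = ("N0", "N1", "N2")[int(np.searchsorted(cum, u_n[i]))]
        m_stage[i] = "M1" if u_m[i] < _M1_PROB_BY_T[t] else "M0"
        deceased[i] = u_d[i] < mortality[t]
        dfs[i] = min(u_dfs[i] * dfs_mean[t], FOLLOW_UP_MONTHS)

    grading_idx = rng.choice(3, size=n, p=_GRADING_PROBS)
    grading = np.array(["G1", "G2", "G3"])[grading_idx]

    receptor = np.where(rng.random(n) < 0.5, "pos", "neg").astype(object)
    receptor[rng.random(n) < config.receptor_missing_rate] = None

    os_extra = rng.exponential(12.0, size=n)
    os_months = np.minimum(dfs + os_extra, FOLLOW_UP_MONTHS)

    # data-entry errors: age keyed as 0 or 100
    outlier = rng.random(n) < config.outlier_rate
    outlier_val = np.where(rng.random(n) < 0.5, 0, 100)
    age = np.where(outlier, outlier_val, age)

    records = []
    for i in range(n):
        records.append(CaseRecord({
            "organ": config.organ,
            "sex": str(sex[i]),
            "age": int(age[i]),
            "exam_year": int(exam_year[i]),
            "t_stage": MISSING if miss_t[i] else str(t_stage[i]),
            "n_stage": MISSING if miss_t[i] else str(n_stage[i]),
            "m_stage": MISSING if miss_t[i] else str(m_stage[i]),
            "grading": str(grading[i]),
            "receptor_state": MISSING if receptor[i] is None else str(receptor[i]),
            "dfs_months": round(float(dfs[i]), 1),
            "os_months": round(float(os_months[i]), 1),
            "deceased": "yes" if deceased[i] else "no",
        }))
    return _build_dataset(records, provenance=f"synthetic:{config.organ}:seed={seed}")


def _build_dataset(records, provenance: str) -> Dataset:
    names = list(SCHEMA)
    ds = Dataset(records=records, variables=[], provenance=provenance)
    from .data_model import VariableMeta

    ds.variables = [VariableMeta(nm, "nominal", [], 0) for nm in names]
    metas = []
    for nm in names:
        spec = SCHEMA[nm]
        metas.append(
            infer_variable_meta(
                ds, nm,
                declared_scale=spec["scale"],
                declared_order=spec.get("order"),
            )
        )
    ds.variables = metas
    return ds


def concat_datasets(*datasets: Dataset, provenance: str = "") -> Dataset:
    """Concatenate cohorts sharing the registry schema; metadata is rebuilt."""
    records = [rec for ds in datasets for rec in ds.records]
    return _build_dataset(records, provenance or "+".join(d.provenance for d in datasets))


# ---------------------------------------------------------------------------
# presets

PRESETS: Mapping[str, CohortConfig] = {
    # female-skewed, young-ish, low mortality; T1 mortality 0 gives the
    # caps-without-death subgroup; visible age-entry outliers at 0/100
    "thyroid": CohortConfig(
        n=2109, organ="thyroid", male_fraction=0.25,
        age_mean=48.0, age_sd=16.0,
        t_stage_probs=(0.5, 0.28, 0.15, 0.07),
        mortality_by_t=(0.0, 0.05, 0.15, 0.35),
        dfs_mean_by_t=(110.0, 90.0, 60.0, 30.0),
        missing_t_rate=0.03, outlier_rate=0.004,
    ),
    # male-skewed, older, high mortality
    "lung": CohortConfig(
        n=1782, organ="lung", male_fraction=0.68,
        age_mean=66.0, age_sd=10.0,
        t_stage_probs=(0.15, 0.25, 0.35, 0.25),
        mortality_by_t=(0.3, 0.5, 0.7, 0.85),
        dfs_mean_by_t=(60.0, 36.0, 18.0, 8.0),
        missing_t_rate=0.04,
    ),
    # 1984-2004 caseload growth, male-biased missing T staging
    "colon": CohortConfig(
        n=11000, organ="colon", male_fraction=0.55,
        age_mean=68.0, age_sd=12.0,
        year_range=(1984, 2004), year_trend=1.0,
        t_stage_probs=(0.2, 0.3, 0.3, 0.2),
        mortality_by_t=(0.1, 0.25, 0.45, 0.65),
        dfs_mean_by_t=(100.0, 70.0, 40.0, 20.0),
        missing_t_rate=(0.15, 0.05),
    ),
}


def generate_preset(name: str, seed: int, n: int | None = None) -> Dataset:
    """Generate a named preset cohort; ``mixed`` is the two-organ comparison."""
    if name == "mixed":
        if n is not None:
            raise ConfigError("the mixed preset has fixed cohort sizes")
        return make_comparison_cohorts(seed)
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from "
                          f"{sorted(PRESETS)} or 'mixed'")
    config = PRESETS[name]
    if n is not None:
        config = replace(config, n=n)
    return generate_cases(config, seed)


def make_comparison_cohorts(seed: int) -> Dataset:
    """Thyroid (n=2109) plus lung (n=1782) cohorts, tagged by organ.

    The two cohorts back the side-by-side age-pyramid comparison: 3891
    records total, female-skewed low-mortality thyroid against male-skewed
    high-mortality lung.
    """
    thyroid = generate_cases(PRESETS["thyroid"], seed % (2**31 - 1))
    lung = generate_cases(PRESETS["lung"], (seed + 1_000_003) % (2**31 - 1))
    return concat_datasets(thyroid, lung, provenance=f"synthetic:mixed:seed={seed}")
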