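"""Synthetic paired postmortem cohort generator.

Emulates the structure of a two-time-point femoral-blood study: each case
contributes a sample at mortuary admission (t1) and one at autopsy (t2),
both measured in the same batch; each batch carries pooled-QC injections
and three isotope-labelled internal standards.  Collection times follow
log-normal laws truncated to the study's observed ranges (median t1 = 8 h
in 1.3-290 h, median delta-t = 71 h in 6.4-434 h).

Peak areas follow a fully multiplicative model,

    area = exp(N(mu_a, sigma_inter)) * f_a(t) * batch(b, a)
           * prep(sample) * exp(N(0, sigma_intra)),

where f_a(t) is one of four temporal drift patterns (steady increase,
lag-then-increase, exponential decrease with a positivity floor, stable)
and the batch, preparation and measurement factors are log-normal.
Multiplicativity makes the ratio-based corrections downstream (pool batch
correction, IS division, PQN) exact in the noise-free limit, so every
pipeline stage has a recoverable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import AnalyteSpec, load_panel

__all__ = [
    "PATTERNS",
    "IS_NAMES",
    "KineticModel",
    "CohortConfig",
    "SampleRecord",
    "CasePair",
    "Cohort",
    "generate_cohort",
    "impute_tod",
    "default_panel_kinetics",
    "well_separated_kinetics",
    "stable_kinetics",
]

PATTERNS = ("steady_increase", "lag_then_increase", "decrease", "stable")

#: The three spiked isotope-labelled internal standards.
IS_NAMES = ("creatinine-d3", "arginine-13C6", "phenylalanine-d1")

#: Floor for the decrease pattern, as a fraction of baseline: areas must
#: stay positive and detectable.
DECREASE_FLOOR = 0.05


@dataclass(frozen=True)
class KineticModel:
    """Temporal drift law of one analyte.

    ``rate`` is the per-hour drift magnitude: slope of the linear rise for
    the increase patterns, exponential decay constant for ``decrease``;
    ``lag_h`` is the flat-window length of ``lag_then_increase``.
    ``sigma_inter`` and ``sigma_intra`` are the between-case and
    measurement log-normal standard deviations.
    """

    pattern: str
    baseline_log_mean: float = 12.0
    sigma_inter: float = 0.6
    sigma_intra: float = 0.15
    rate: float = 0.0
    lag_h: float = 36.0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.sigma_inter < 0 or self.sigma_intra < 0:
            raise ValueError("sigmas must be >= 0")
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.pattern == "stable" and self.rate != 0:
            raise ValueError("stable pattern requires rate = 0")

    def f(self, t_h: np.ndarray | float) -> np.ndarray:
        """Drift factor f(t) at time-since-death t (hours); f >= floor > 0."""
        t = np.asarray(t_h, dtype=float)
        if self.pattern == "steady_increase":
            out = 1.0 + self.rate * t
        elif self.pattern == "lag_then_increase":
            out = np.where(t < self.lag_h, 1.0, 1.0 + self.rate * (t - self.lag_h))
        elif self.pattern == "decrease":
            out = np.maximum(np.exp(-self.rate * t), DECREASE_FLOOR)
        else:  # stable
            out = np.ones_like(t)
        return out


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic cohort.

    Defaults reproduce the study conditions: 427 cases in 17 batches with 5
    pooled-QC injections each, log-median t1 of 8 h (range 1.3-290 h),
    log-median delta-t of 71 h (range 6.4-434 h), and 163/427 cases whose
    time of death is known only to the day.
    """

    n_cases: int = 427
    n_batches: int = 17
    pools_per_batch: int = 5
    t1_log_median_h: float = 8.0
    t1_log_sigma: float = 1.0
    t1_range_h: tuple[float, float] = (1.3, 290.0)
    dt_log_median_h: float = 71.0
    dt_log_sigma: float = 0.8
    dt_range_h: tuple[float, float] = (6.4, 434.0)
    sigma_batch: float = 0.15
    sigma_prep: float = 0.10
    frac_tod_unknown: float = 163.0 / 427.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_batches < 1 or self.pools_per_batch < 0:
            raise ValueError("counts must be positive")
        for lo, hi in (self.t1_range_h, self.dt_range_h):
            if not (0 < lo < hi):
                raise ValueError("ranges must be positive and ordered")
        if not 0.0 <= self.frac_tod_unknown <= 1.0:
            raise ValueError("frac_tod_unknown must lie in [0, 1]")
        if self.sigma_batch < 0 or self.sigma_prep < 0:
            raise ValueError("sigmas must be >= 0")


@dataclass(frozen=True)
class SampleRecord:
    """One measured sample (study t1/t2 or pooled QC) with its peak areas."""

    sample_id: str
    case_id: str | None
    timepoint_label: str  # t1 | t2 | pool
    sample_type: str  # study | pool
    batch_id: str
    time_since_death_h: float | None
    areas: Mapping[str, float]
    is_areas: Mapping[str, float]
    true_prep_factor: float = 1.0
    tod_known_exact: bool = True


@dataclass(frozen=True)
class CasePair:
    """The t1/t2 sample pair of one case; both share the measurement batch."""

    case_id: str
    t1_record: SampleRecord
    t2_record: SampleRecord
    delta_t_h: float

    def __post_init__(self) -> None:
        if self.delta_t_h <= 0:
            raise ValueError("delta_t_h must be > 0")
        if self.t1_record.batch_id != self.t2_record.batch_id:
            raise ValueError("t1 and t2 of one case must share a batch")


@dataclass
class Cohort:
    """Generated cohort: records, pairs, and the ground-truth tables."""

    samples: list[SampleRecord]
    pairs: list[CasePair]
    truth: dict[str, pd.DataFrame]
    analytes: list[str]
    config: CohortConfig
    _areas_cache: pd.DataFrame | None = field(default=None, repr=False)

    def areas_table(self) -> pd.DataFrame:
        """Long-format table: one row per (sample, analyte)."""
        if self._areas_cache is None:
            rows = []
            for rec in self.samples:
                for analyte in self.analytes:
                    rows.append(
                        (
                            rec.sample_id,
                            rec.case_id if rec.case_id is not None else "",
                            rec.timepoint_label,
                            rec.sample_type,
                            rec.batch_id,
                            rec.time_since_death_h,
                            analyte,
                            rec.areas[analyte],
                        )
                    )
            self._areas_cache = pd.DataFrame(
                rows,
                columns=[
                    "sample_id",
                    "case_id",
                    "timepoint_label",
                    "sample_type",
                    "batch_id",
                    "time_since_death_h",
                    "analyte",
                    "peak_area",
                ],
            )
        return self._areas_cache.copy()

    def samples_table(self) -> pd.DataFrame:
        """One row per sample with metadata and the three IS areas."""
        rows = []
        for rec in self.samples:
            row = {
                "sample_id": rec.sample_id,
                "case_id": rec.case_id if rec.case_id is not None else "",
                "timepoint_label": rec.timepoint_label,
                "sample_type": rec.sample_type,
                "batch_id": rec.batch_id,
                "time_since_death_h": rec.time_since_death_h,
                "tod_known_exact": rec.tod_known_exact,
            }
            for is_name in IS_NAMES:
                row[f"is_{is_name}"] = rec.is_areas[is_name]
            rows.append(row)
        return pd.DataFrame(rows)

    def wide(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(metadata indexed by sample_id, sample x analyte area matrix)."""
        meta = self.samples_table().set_index("sample_id")
        areas = np.array(
            [[rec.areas[a] for a in self.analytes] for rec in self.samples]
        )
        wide = pd.DataFrame(
            areas, index=meta.index, columns=list(self.analytes)
        )
        return meta, wide

    def pairs_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_id": [p.case_id for p in self.pairs],
                "t1_sample_id": [p.t1_record.sample_id for p in self.pairs],
                "t2_sample_id": [p.t2_record.sample_id for p in self.pairs],
                "delta_t_h": [p.delta_t_h for p in self.pairs],
            }
        )


def _truncated_lognormal(
    rng: np.random.Generator,
    n: int,
    log_median: float,
    sigma: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    """Log-normal sampler truncated to ``bounds`` by resampling."""
    out = np.empty(n)
    remaining = np.arange(n)
    mu = np.log(log_median)
    for _ in range(1000):
        draw = np.exp(rng.normal(mu, sigma, size=len(remaining)))
        ok = (draw >= bounds[0]) & (draw <= bounds[1])
        out[remaining[ok]] = draw[ok]
        remaining = remaining[~ok]
        if len(remaining) == 0:
            return out
    raise RuntimeError("truncated sampler failed to converge")


def generate_cohort(
    config: CohortConfig,
    kinetics: Mapping[str, KineticModel],
    seed: int | None = None,
) -> Cohort:
    """Generate a paired cohort under the multiplicative area model.

    Study samples get per-case baselines, drift factors evaluated at their
    time since death, batch x analyte instrument factors, per-sample
    preparation factors, and measurement noise.  Pool records carry the
    batch factor and measurement noise only.  IS areas are nominal areas
    under the same batch/preparation/noise factors (no drift: the standards
    are spiked at fixed concentration).  Identical config and seed yield
    identical output.
    """
    if not kinetics:
        raise ValueError("need at least one analyte")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    analytes = list(kinetics.keys())
    n = config.n_cases
    n_an = len(analytes)

    t1 = _truncated_lognormal(
        rng, n, config.t1_log_median_h, config.t1_log_sigma, config.t1_range_h
    )
    dt = _truncated_lognormal(
        rng, n, config.dt_log_median_h, config.dt_log_sigma, config.dt_range_h
    )
    t2 = t1 + dt
    batch_of_case = rng.integers(0, config.n_batches, size=n)
    tod_unknown = rng.random(n) < config.frac_tod_unknown

    # ground-truth multiplicative factors
    baseline = np.exp(
        np.array(
            [
                rng.normal(kinetics[a].baseline_log_mean, kinetics[a].sigma_inter, n)
                for a in analytes
            ]
        ).T
    )  # cases x analytes
    batch_factor = np.exp(
        rng.normal(0.0, config.sigma_batch, size=(config.n_batches, n_an))
    )
    batch_factor_is = np.exp(
        rng.normal(0.0, config.sigma_batch, size=(config.n_batches, len(IS_NAMES)))
    )
    prep = {
        "t1": np.exp(rng.normal(0.0, config.sigma_prep, n)),
        "t2": np.exp(rng.normal(0.0, config.sigma_prep, n)),
    }
    sigma_intra = np.array([kinetics[a].sigma_intra for a in analytes])
    drift = {
        "t1": np.array([kinetics[a].f(t1) for a in analytes]).T,
        "t2": np.array([kinetics[a].f(t2) for a in analytes]).T,
    }
    is_nominal = np.array([1.0e6, 1.2e6, 1.5e6])
    is_sigma_intra = 0.05  # injection repeatability of the spiked standards

    samples: list[SampleRecord] = []
    per_tp_records: dict[str, list[SampleRecord]] = {}
    for tp, t_vals in (("t1", t1), ("t2", t2)):
        noise = np.exp(rng.normal(0.0, 1.0, size=(n, n_an)) * sigma_intra)
        is_noise = np.exp(rng.normal(0.0, is_sigma_intra, size=(n, len(IS_NAMES))))
        areas_mat = (
            baseline
            * drift[tp]
            * batch_factor[batch_of_case]
            * prep[tp][:, None]
            * noise
        )
        is_mat = (
            is_nominal[None, :]
            * batch_factor_is[batch_of_case]
            * prep[tp][:, None]
            * is_noise
        )
        recs = []
        for i in range(n):
            recs.append(
                SampleRecord(
                    sample_id=f"case{i:04d}_{tp}",
                    case_id=f"case{i:04d}",
                    timepoint_label=tp,
                    sample_type="study",
                    batch_id=f"B{batch_of_case[i] + 1:02d}",
                    time_since_death_h=float(t_vals[i]),
                    areas=dict(zip(analytes, areas_mat[i])),
                    is_areas=dict(zip(IS_NAMES, is_mat[i])),
                    true_prep_factor=float(prep[tp][i]),
                    tod_known_exact=not bool(tod_unknown[i]),
                )
            )
        per_tp_records[tp] = recs
        samples.extend(recs)

    # pooled-QC injections: one shared pool matrix, batch factor + noise only
    pool_base = np.exp(np.array([kinetics[a].baseline_log_mean for a in analytes]))
    for b in range(config.n_batches):
        for j in range(config.pools_per_batch):
            noise = np.exp(rng.normal(0.0, 1.0, n_an) * sigma_intra)
            is_noise = np.exp(rng.normal(0.0, is_sigma_intra, len(IS_NAMES)))
            samples.append(
                SampleRecord(
                    sample_id=f"pool_B{b + 1:02d}_{j + 1}",
                    case_id=None,
                    timepoint_label="pool",
                    sample_type="pool",
                    batch_id=f"B{b + 1:02d}",
                    time_since_death_h=None,
                    areas=dict(zip(analytes, pool_base * batch_factor[b] * noise)),
                    is_areas=dict(
                        zip(IS_NAMES, is_nominal * batch_factor_is[b] * is_noise)
                    ),
                )
            )

    pairs = [
        CasePair(
            case_id=f"case{i:04d}",
            t1_record=per_tp_records["t1"][i],
            t2_record=per_tp_records["t2"][i],
            delta_t_h=float(dt[i]),
        )
        for i in range(n)
    ]

    truth = {
        "kinetics": pd.DataFrame(
            {
                "analyte": analytes,
                "pattern": [kinetics[a].pattern for a in analytes],
                "rate_per_h": [kinetics[a].rate for a in analytes],
                "lag_h": [kinetics[a].lag_h for a in analytes],
                "baseline_log_mean": [
                    kinetics[a].baseline_log_mean for a in analytes
                ],
                "f_71h": [float(kinetics[a].f(71.0)) for a in analytes],
            }
        ),
        "batch_factors": pd.DataFrame(
            batch_factor,
            index=[f"B{b + 1:02d}" for b in range(config.n_batches)],
            columns=analytes,
        ),
        "prep_factors": pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in samples if r.sample_type == "study"],
                "true_prep_factor": [
                    r.true_prep_factor for r in samples if r.sample_type == "study"
                ],
            }
        ),
    }
    return Cohort(samples, pairs, truth, analytes, config)


def impute_tod(
    estimated_day: date,
    admission_time: datetime,
    exact_tod: datetime | None = None,
) -> datetime:
    """Impute the time of death from a day-level estimate.

    An exactly known ToD is returned unchanged.  When admission falls on a
    later day than the estimated day of death, ToD is set to 12:00 (noon) of
    that day.  When admission falls on the estimated day itself, the ToD is
    known only to lie between midnight and admission; the midpoint of that
    window is used.
    """
    if exact_tod is not None:
        return exact_tod
    day_start = datetime.combine(estimated_day, time(0, 0))
    if admission_time < day_start:
        raise ValueError("admission precedes the estimated day of death")
    if admission_time.date() > estimated_day:
        return datetime.combine(estimated_day, time(12, 0))
    return day_start + (admission_time - day_start) / 2


# ---------------------------------------------------------------------------
# Default kinetics panels
# ---------------------------------------------------------------------------

def _rate_for(pattern: str, pct: float) -> float:
    """Drift rate reproducing a target paired median change of ``pct`` %.

    Calibrated at the cohort's central pair (t1 = 8 h, t2 = 79 h): for the
    linear patterns, f(79)/f(8) = 1 + pct/100; for the exponential decrease,
    exp(-rate * 71) = 1 + pct/100.
    """
    c = 1.0 + abs(pct) / 100.0
    if pattern == "steady_increase":
        return (c - 1.0) / (79.0 - 8.0 * c)
    if pattern == "lag_then_increase":
        return (c - 1.0) / (79.0 - 36.0)
    if pattern == "decrease":
        c_dec = max(1.0 + pct / 100.0, 2.0 * DECREASE_FLOOR)
        return -float(np.log(c_dec)) / 71.0
    return 0.0


def default_panel_kinetics(
    panel: list[AnalyteSpec] | None = None,
    baseline_log_mean: float = 12.0,
    sigma_inter: float = 0.6,
    sigma_intra: float = 0.15,
) -> dict[str, KineticModel]:
    """Kinetic models for the shipped 38-analyte panel.

    Each analyte follows its published temporal pattern, with the drift
    magnitude calibrated from the magnitude of its published paired median
    percent change.
    """
    panel = panel if panel is not None else load_panel()
    kinetics = {}
    for spec in panel:
        pattern = spec.pattern or "stable"
        pct = spec.paired_median_pct if spec.paired_median_pct is not None else 0.0
        kinetics[spec.name] = KineticModel(
            pattern=pattern,
            baseline_log_mean=baseline_log_mean,
            sigma_inter=sigma_inter,
            sigma_intra=sigma_intra,
            rate=_rate_for(pattern, pct),
        )
    return kinetics


def well_separated_kinetics(
    n_per_pattern: int = 2,
    sigma_inter: float = 0.6,
    sigma_intra: float = 0.15,
) -> dict[str, KineticModel]:
    """Strongly separated exemplar kinetics, ``n_per_pattern`` per pattern.

    Drift magnitudes are chosen far from the 30%-band classification
    boundaries (roughly tripling, strong post-lag rise, halving-or-more
    decrease), for ground-truth recovery checks.  The lag exemplar uses a
    48 h lag: in delta-t space the apparent lag is shortened by the typical
    admission delay (median t1 of 8 h), so a 48 h absolute lag keeps the
    0-36 h delta-t bins flat.
    """
    target = {
        "steady_increase": 200.0,
        "lag_then_increase": 180.0,
        "decrease": -70.0,
        "stable": 0.0,
    }
    kinetics = {}
    for pattern in PATTERNS:
        for i in range(n_per_pattern):
            kinetics[f"{pattern}_{i + 1}"] = KineticModel(
                pattern=pattern,
                sigma_inter=sigma_inter,
                sigma_intra=sigma_intra,
                rate=_rate_for(pattern, target[pattern]),
                lag_h=48.0,
            )
    return kinetics


def stable_kinetics(
    n_analytes: int = 2,
    sigma_inter: float = 0.6,
    sigma_intra: float = 0.15,
) -> dict[str, KineticModel]:
    """Null panel: every analyte stable (no temporal drift)."""
    return {
        f"stable_{i + 1}": KineticModel(
            pattern="stable", sigma_inter=sigma_inter, sigma_intra=sigma_intra
        )
        for i in range(n_analytes)
    }
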