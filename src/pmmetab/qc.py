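"""Quality gates: IS outlier screening, RSD criteria, pool drift checks.

The internal standards are spiked into every sample before extraction, so
their batch-normalized areas should be exchangeable across the whole run.
A two-sided single-outlier Grubbs test (p < 0.05) per IS flags suspicious
injections; a sample is excluded only when it is flagged for all three
standards, since a single deviant IS more likely reflects that standard's
chemistry than a failed injection.

Pooled-QC injections monitor instrument drift: within-batch variation of
pool peak areas up to 20% and between-batch variation up to 30% of the mean
are considered acceptable, and an overall RSD below 30% counts as
sufficiently robust.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .simulate import IS_NAMES

__all__ = [
    "QCReport",
    "GrubbsResult",
    "rsd",
    "grubbs_test",
    "grubbs_critical",
    "screen_is_outliers",
    "drift_check",
    "run_qc",
]

RSD_LIMIT_PCT = 30.0
INTRA_BATCH_AREA_LIMIT_PCT = 20.0
INTER_BATCH_AREA_LIMIT_PCT = 30.0
RT_INTRA_LIMIT_MIN = 0.05
RT_INTER_LIMIT_MIN = 0.2


def rsd(values) -> float:
    """Relative standard deviation in percent: 100 * sd / mean (sample sd).

    Requires at least two values and a positive mean.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("RSD needs at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError("RSD undefined for non-positive mean")
    return float(100.0 * v.std(ddof=1) / mean)


def grubbs_critical(n: int, alpha: float = 0.05) -> float:
    """Two-sided single-outlier Grubbs critical value.

    G_crit = ((n-1)/sqrt(n)) * sqrt(t^2 / (n - 2 + t^2)) with t the upper
    alpha/(2n) quantile of Student's t with n-2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    t = sps.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t * t / (n - 2 + t * t))


@dataclass(frozen=True)
class GrubbsResult:
    statistic: float
    critical: float
    outlier_index: int | None
    degenerate: bool = False


def grubbs_test(values, alpha: float = 0.05) -> GrubbsResult:
    """Two-sided single-outlier Grubbs test.

    G = max|x_i - mean| / sd; the most extreme value is reported as an
    outlier iff G exceeds the critical value.  Zero variance returns a
    degenerate no-outlier result.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 3:
        raise ValueError("Grubbs test needs n >= 3")
    sd = v.std(ddof=1)
    if sd == 0:
        return GrubbsResult(0.0, grubbs_critical(n, alpha), None, degenerate=True)
    dev = np.abs(v - v.mean())
    idx = int(np.argmax(dev))
    g = float(dev[idx] / sd)
    crit = grubbs_critical(n, alpha)
    return GrubbsResult(g, crit, idx if g > crit else None)


@dataclass
class QCReport:
    """Aggregated quality-control findings."""

    is_rsd_pct: dict[str, float] = field(default_factory=dict)
    pool_rsd_pct: dict[str, float] = field(default_factory=dict)
    grubbs_flags: dict[str, set[str]] = field(default_factory=dict)  # sample -> ISs
    excluded_samples: list[str] = field(default_factory=list)
    intra_batch_area_rsd: pd.DataFrame | None = None
    inter_batch_area_rsd: dict[str, float] = field(default_factory=dict)
    incomplete_batches: list[str] = field(default_factory=list)
    criteria: dict[str, bool] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return all(self.criteria.values()) and not self.excluded_samples

    def summary(self) -> str:
        lines = ["Quality control summary", "======================="]
        for is_name, value in self.is_rsd_pct.items():
            lines.append(f"IS RSD {is_name}: {value:.1f}%")
        flagged = {s: sorted(f) for s, f in self.grubbs_flags.items() if f}
        lines.append(f"Grubbs-flagged samples: {len(flagged)}")
        for sample, standards in flagged.items():
            lines.append(f"  {sample}: flagged for {', '.join(standards)}")
        lines.append(
            "Excluded samples (flagged for all ISs): "
            + (", ".join(self.excluded_samples) or "none")
        )
        for name, ok in self.criteria.items():
            lines.append(f"criterion {name}: {'pass' if ok else 'FAIL'}")
        for warning in self.warnings:
            lines.append(f"warning: {warning}")
        return "\n".join(lines)


def _batch_normalized_is(samples: pd.DataFrame, is_name: str) -> pd.Series:
    """IS areas of study samples divided by their batch's pool-mean IS area."""
    col = f"is_{is_name}"
    pools = samples[samples["sample_type"] == "pool"]
    if pools.empty:
        raise ValueError("no pool records available for batch normalization")
    pool_means = pools.groupby("batch_id")[col].mean()
    study = samples[samples["sample_type"] == "study"]
    missing = set(study["batch_id"]) - set(pool_means.index)
    if missing:
        raise ValueError(f"batches without pool records: {sorted(missing)}")
    normalized = study[col].to_numpy() / pool_means.loc[
        study["batch_id"]
    ].to_numpy()
    return pd.Series(normalized, index=study["sample_id"].to_numpy())


def screen_is_outliers(
    samples: pd.DataFrame,
    alpha: float = 0.05,
    per_batch: bool = False,
) -> QCReport:
    """Grubbs screening of study samples on batch-normalized IS areas.

    One single-pass Grubbs test per internal standard, run on the pooled
    batch-normalized areas (or per batch with ``per_batch=True``).  A sample
    enters ``excluded_samples`` only when flagged for every IS.
    """
    report = QCReport()
    study_ids = samples.loc[samples["sample_type"] == "study", "sample_id"]
    flags: dict[str, set[str]] = {sid: set() for sid in study_ids}
    available = []
    for is_name in IS_NAMES:
        col = f"is_{is_name}"
        if col not in samples.columns or samples[col].isna().all():
            report.warnings.append(f"IS {is_name} absent; skipped")
            continue
        available.append(is_name)
        normalized = _batch_normalized_is(samples, is_name)
        report.is_rsd_pct[is_name] = rsd(normalized.to_numpy())
        groups = (
            [normalized]
            if not per_batch
            else [
                normalized[samples.set_index("sample_id").loc[normalized.index,
                                                              "batch_id"] == b]
                for b in samples["batch_id"].unique()
            ]
        )
        for series in groups:
            remaining = series.copy()
            result = grubbs_test(remaining.to_numpy(), alpha)
            if result.outlier_index is not None:
                flags[remaining.index[result.outlier_index]].add(is_name)
    report.grubbs_flags = flags
    if available:
        report.excluded_samples = sorted(
            s for s, f in flags.items() if f and f >= set(available)
        )
    report.criteria["is_rsd_below_30pct"] = all(
        v < RSD_LIMIT_PCT for v in report.is_rsd_pct.values()
    )
    return report


def drift_check(pool_areas: pd.DataFrame) -> QCReport:
    """Intra- and inter-batch drift of pooled-QC peak areas.

    ``pool_areas``: long table with columns batch_id, analyte, peak_area
    (pool records only).  Intra-batch RSD must stay within 20% and the RSD
    of batch means within 30% for every analyte.  Retention-time columns
    (rt_min) are checked against the 0.05 / 0.2 min gates when present and
    pass trivially when absent.
    """
    report = QCReport()
    for batch, group in pool_areas.groupby("batch_id"):
        if group.groupby("analyte").size().min() < 2:
            report.incomplete_batches.append(str(batch))
    intra = (
        pool_areas.groupby(["batch_id", "analyte"])["peak_area"]
        .apply(lambda v: rsd(v) if len(v) >= 2 else np.nan)
        .rename("intra_rsd_pct")
        .reset_index()
    )
    report.intra_batch_area_rsd = intra
    batch_means = pool_areas.groupby(["analyte", "batch_id"])["peak_area"].mean()
    for analyte, means in batch_means.groupby(level="analyte"):
        if len(means) >= 2:
            report.inter_batch_area_rsd[str(analyte)] = rsd(means.to_numpy())
        report.pool_rsd_pct[str(analyte)] = rsd(
            pool_areas.loc[pool_areas["analyte"] == analyte, "peak_area"].to_numpy()
        )
    report.criteria["intra_batch_area_within_20pct"] = bool(
        np.nanmax(intra["intra_rsd_pct"].to_numpy()) <= INTRA_BATCH_AREA_LIMIT_PCT
    )
    report.criteria["inter_batch_area_within_30pct"] = all(
        v <= INTER_BATCH_AREA_LIMIT_PCT for v in report.inter_batch_area_rsd.values()
    )
    if "rt_min" in pool_areas.columns:
        intra_rt = pool_areas.groupby(["batch_id", "analyte"])["rt_min"].std(ddof=1)
        inter_rt = (
            pool_areas.groupby(["analyte", "batch_id"])["rt_min"]
            .mean()
            .groupby(level="analyte")
            .std(ddof=1)
        )
        report.criteria["intra_batch_rt_within_0.05min"] = bool(
            np.nanmax(intra_rt.to_numpy()) <= RT_INTRA_LIMIT_MIN
        )
        report.criteria["inter_batch_rt_within_0.2min"] = bool(
            np.nanmax(inter_rt.to_numpy()) <= RT_INTER_LIMIT_MIN
        )
    return report


def run_qc(
    samples: pd.DataFrame,
    areas: pd.DataFrame,
    alpha: float = 0.05,
) -> QCReport:
    """Full QC pass: IS screening plus pool drift checks, merged report."""
    report = screen_is_outliers(samples, alpha=alpha)
    pools = areas[areas["sample_type"] == "pool"]
    if pools.empty:
        report.warnings.append("no pool records; drift checks skipped")
        return report
    drift = drift_check(pools)
    report.pool_rsd_pct = drift.pool_rsd_pct
    report.intra_batch_area_rsd = drift.intra_batch_area_rsd
    report.inter_batch_area_rsd = drift.inter_batch_area_rsd
    report.incomplete_batches = drift.incomplete_batches
    report.criteria.update(drift.criteria)
    report.warnings.extend(drift.warnings)
    return report
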