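"""Synthesis stage: temporal patterns, property correlations, concordance.

Analytes are assigned one of four temporal patterns from their per-bin
median percent changes: steady increase, lag-then-increase (flat through
roughly the first 36 h, rising afterwards), decrease, or stable (no change
beyond a 30% band).  The 30% band defines "no relevant change"; the
remaining thresholds are documented reconstruction choices, exposed as
parameters.

Correlation analyses ask whether the magnitude of postmortem change tracks
physicochemical properties (logP, molecular weight, retention time) and
whether the paired and unpaired analyses agree per analyte (Spearman).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .panel import AnalyteSpec
from .unpaired import GroupProfile, highest_change

__all__ = [
    "PatternCall",
    "CorrelationResult",
    "classify_pattern",
    "classify_panel",
    "correlate_properties",
    "paired_unpaired_concordance",
    "compare_normalization_modes",
    "cross_platform_concordance",
]


@dataclass(frozen=True)
class PatternCall:
    """Temporal pattern assigned to one analyte, with its evidence."""

    analyte: str
    pattern: str
    evidence: tuple[float, ...]  # per-bin median percent changes, ordered
    stable_band: float
    low_confidence: bool = False


def classify_pattern(
    medians: pd.Series,
    bin_upper_edges: np.ndarray | None = None,
    stable_band: float = 30.0,
    lag_limit_h: float = 36.0,
    analyte: str = "",
) -> PatternCall:
    """Classify a per-bin median percent-change profile into four patterns.

    ``medians``: ordered per-bin medians (earliest interval first);
    ``bin_upper_edges``: upper edge of each bin in hours (np.inf for the
    open last bin) — the lag window covers the bins whose upper edge is at
    most ``lag_limit_h``.

    Rules, applied in order:

    - stable: every |median| < stable_band;
    - decrease: final median <= -stable_band and no median exceeds
      +stable_band;
    - lag_then_increase: every lag-window bin flat (|median| below half the
      band — an early profile already drifting within the band signals a
      steady rise, not a lag) and a later bin above +stable_band;
    - steady_increase: the first out-of-band bin is positive and the
      profile ends at (or near) its running maximum.

    Profiles matching none of the rules fall back to the nearest rule with
    ``low_confidence=True`` (every analyte receives exactly one pattern).
    """
    m = np.asarray(medians, dtype=float)
    valid = ~np.isnan(m)
    if valid.sum() < 4:
        raise ValueError("need at least four populated bins")
    if bin_upper_edges is None:
        bin_upper_edges = np.asarray(
            [12.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 144.0, np.inf]
        )[: len(m)]
    edges = np.asarray(bin_upper_edges, dtype=float)
    mv = m[valid]
    ev = edges[valid]
    name = analyte

    def call(pattern, low=False):
        return PatternCall(name, pattern, tuple(mv), stable_band, low)

    within = np.abs(mv) < stable_band
    if within.all():
        return call("stable")
    if mv[-1] <= -stable_band and not np.any(mv > stable_band):
        return call("decrease")
    lag_mask = ev <= lag_limit_h
    later_up = np.any(mv[~lag_mask] > stable_band)
    flat = np.abs(mv) < stable_band / 2.0
    if lag_mask.any() and flat[lag_mask].all() and later_up:
        return call("lag_then_increase")
    out_idx = np.nonzero(~within)[0]
    first_out_positive = mv[out_idx[0]] > 0
    ends_at_max = mv[-1] >= np.max(mv) - stable_band / 2.0
    if first_out_positive and ends_at_max:
        return call("steady_increase")
    # fall-back: nearest rule, low confidence
    if mv[-1] < 0:
        return call("decrease", low=True)
    if later_up and np.abs(mv[lag_mask]).max(initial=0.0) < 2 * stable_band:
        return call("lag_then_increase", low=True)
    return call("steady_increase", low=True)


def classify_panel(
    paired_summary: pd.DataFrame,
    scheme_edges: np.ndarray | None = None,
    stable_band: float = 30.0,
    lag_limit_h: float = 36.0,
    min_pairs: int = 10,
) -> pd.DataFrame:
    """Classify every analyte of a paired-stage summary table.

    Uses the per-bin rows (bin != "all") ordered by the bin scheme; bins
    with fewer than ``min_pairs`` pairs are ignored (their medians are too
    noisy to serve as evidence).  On small cohorts the threshold relaxes
    until at least four bins qualify.
    """
    rows = []
    per_bin = paired_summary[paired_summary["bin"] != "all"]
    bin_order = list(dict.fromkeys(per_bin["bin"]))
    if scheme_edges is None:
        scheme_edges = np.asarray(
            [12.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 144.0, np.inf]
        )
    for analyte, group in per_bin.groupby("analyte", sort=False):
        ordered = group.set_index("bin").reindex(bin_order)
        counts = ordered["n_pairs"].fillna(0).to_numpy()
        threshold = min_pairs
        while threshold > 1 and (counts >= threshold).sum() < 4:
            threshold -= 1
        populated = counts >= threshold
        medians = ordered["median_pct"].to_numpy()[populated]
        edges = scheme_edges[: len(bin_order)][populated]
        pattern = classify_pattern(
            pd.Series(medians), edges, stable_band, lag_limit_h, analyte=str(analyte)
        )
        rows.append(
            dict(
                analyte=pattern.analyte,
                pattern=pattern.pattern,
                low_confidence=pattern.low_confidence,
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    property: str
    rho: float
    rho_sq: float
    p_raw: float
    n: int
    excluded: int = 0


def correlate_properties(
    changes: pd.Series,
    panel: list[AnalyteSpec],
    property_name: str,
) -> CorrelationResult:
    """Spearman correlation of per-analyte change with a panel property.

    ``property_name``: one of logp, mw, rt_rp, rt_hilic.  Analytes lacking
    the property (or the change) are excluded and counted.
    """
    values = {}
    for spec in panel:
        prop = getattr(spec, property_name)
        if prop is not None and spec.name in changes.index:
            change = changes.loc[spec.name]
            if not np.isnan(change):
                values[spec.name] = (change, prop)
    excluded = len(panel) - len(values)
    if len(values) < 3:
        raise ValueError(f"fewer than 3 analytes with {property_name}")
    x = np.array([v[0] for v in values.values()])
    y = np.array([v[1] for v in values.values()])
    res = stats.spearman(x, y)
    return CorrelationResult(
        property_name, res.rho, res.rho_sq, res.pvalue, res.n_used, excluded
    )


def paired_unpaired_concordance(
    paired_summary: pd.DataFrame,
    profiles: list[GroupProfile],
) -> CorrelationResult:
    """Spearman agreement between paired and unpaired change magnitudes.

    Per analyte: overall paired median percent change ("all" rows) against
    the highest median percent change vs group 1 from the unpaired
    profiles.  Raises on analyte set mismatch.
    """
    paired = (
        paired_summary[paired_summary["bin"] == "all"]
        .set_index("analyte")["median_pct"]
    )
    unpaired = pd.Series(
        {p.analyte: highest_change(p)[0] for p in profiles}, name="highest"
    )
    missing = set(paired.index) ^ set(unpaired.index)
    if missing:
        raise ValueError(f"analyte sets differ: {sorted(missing)}")
    unpaired = unpaired.loc[paired.index]
    res = stats.spearman(paired.to_numpy(), unpaired.to_numpy())
    return CorrelationResult(
        "paired_vs_unpaired", res.rho, res.rho_sq, res.pvalue, res.n_used
    )


def compare_normalization_modes(
    cohort,
    modes: tuple[str, ...] = ("batch_only", "is", "pqn"),
    pqn_reference: str = "pool_mean",
) -> dict:
    """Run the paired stage under each normalization mode, side by side.

    Returns a dict with per-mode paired summaries, a wide comparison table
    of overall median changes, and the PQN attenuation statistic: the
    median over drifting analytes (|batch-only change| >= 30%) of the
    ratio |PQN change| / |batch-only change|.  Missing inputs for a mode
    skip that mode with a notice.
    """
    from .normalize import batch_correct, is_normalize, pqn_normalize
    from .paired import run_paired_stage

    meta, wide = cohort.wide()
    bc = batch_correct(wide, meta)
    t1_ids = [p.t1_record.sample_id for p in cohort.pairs]
    t2_ids = [p.t2_record.sample_id for p in cohort.pairs]

    def stage(values: pd.DataFrame) -> pd.DataFrame:
        t1 = values.loc[t1_ids].set_axis([p.case_id for p in cohort.pairs])
        t2 = values.loc[t2_ids].set_axis([p.case_id for p in cohort.pairs])
        return run_paired_stage(
            cohort.pairs, cohort.analytes, per_bin=False, areas=(t1, t2)
        )

    summaries: dict[str, pd.DataFrame] = {}
    notes: list[str] = []
    for mode in modes:
        if mode == "batch_only":
            summaries[mode] = stage(bc.values)
        elif mode == "is":
            is_cols = [c for c in meta.columns if c.startswith("is_")]
            if not is_cols:
                notes.append("mode 'is' skipped: no IS areas in cohort")
                continue
            summaries[mode] = stage(is_normalize(wide, meta[is_cols]).values)
        elif mode == "pqn":
            summaries[mode] = stage(
                pqn_normalize(bc.values, reference=pqn_reference, meta=meta).values
            )
        else:
            notes.append(f"unknown mode {mode!r} skipped")

    comparison = pd.DataFrame(
        {
            mode: summary[summary["bin"] == "all"]
            .set_index("analyte")["median_pct"]
            for mode, summary in summaries.items()
        }
    )
    attenuation = np.nan
    if {"batch_only", "pqn"} <= set(comparison.columns):
        drifted = comparison["batch_only"].abs() >= 30.0
        if drifted.any():
            ratios = (
                comparison.loc[drifted, "pqn"].abs()
                / comparison.loc[drifted, "batch_only"].abs()
            )
            attenuation = float(ratios.median())
    return dict(
        summaries=summaries,
        comparison=comparison,
        pqn_attenuation_ratio=attenuation,
        notes=notes,
    )


def cross_platform_concordance(
    summary_a: pd.DataFrame,
    summary_b: pd.DataFrame,
) -> pd.DataFrame:
    """Per-analyte Spearman agreement of per-bin change profiles.

    Both inputs are paired-stage summaries (e.g. reversed-phase vs HILIC
    acquisitions of the same cohort).  Analytes present on both sides are
    correlated across their shared bins; discordant analytes (rho < 0) are
    flagged.  Raises when the analyte overlap is empty.
    """
    overlap = sorted(
        set(summary_a["analyte"]) & set(summary_b["analyte"])
    )
    if not overlap:
        raise ValueError("no overlapping analytes between platforms")
    rows = []
    for analyte in overlap:
        a = (
            summary_a[(summary_a["analyte"] == analyte)
                      & (summary_a["bin"] != "all")]
            .set_index("bin")["median_pct"]
        )
        b = (
            summary_b[(summary_b["analyte"] == analyte)
                      & (summary_b["bin"] != "all")]
            .set_index("bin")["median_pct"]
        )
        shared = a.index.intersection(b.index)
        av = a.loc[shared].to_numpy()
        bv = b.loc[shared].to_numpy()
        mask = ~(np.isnan(av) | np.isnan(bv))
        try:
            res = stats.spearman(av[mask], bv[mask])
            rows.append(dict(analyte=analyte, rho=res.rho, n_bins=int(mask.sum()),
                             discordant=res.rho < 0))
        except ValueError:
            rows.append(dict(analyte=analyte, rho=np.nan, n_bins=int(mask.sum()),
                             discordant=False))
    return pd.DataFrame(rows)
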