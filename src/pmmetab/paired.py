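"""Paired t2-vs-t1 analysis: percent change, delta-t binning, Wilcoxon tests.

Percent change is computed on raw peak areas, 100 * (t2 - t1) / t1, per
case and analyte: since both samples of a case are measured in the same
batch, batch-level instrument factors cancel in the ratio and no
normalization is needed for the paired contrast.  Cases are grouped into
delta-t intervals (0-12 h through > 144 h); per analyte, a two-sided
Wilcoxon signed-rank test compares t2 against t1 over all cases and within
each interval, with Holm adjustment across the analyte family of each
comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .simulate import CasePair

__all__ = [
    "BinScheme",
    "paired_dt_scheme",
    "unpaired_tod_scheme",
    "assign_bin",
    "percent_change",
    "pair_changes",
    "run_paired_stage",
]

PAIRED_EDGES = (0.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 144.0, np.inf)
UNPAIRED_EDGES = (0.0, 6.0, 12.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 144.0, np.inf)


@dataclass(frozen=True)
class BinScheme:
    """Ordered half-open time intervals [lo, hi); the last bin is open."""

    name: str
    edges: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) - 1:
            raise ValueError("need one label per interval")
        diffs = np.diff(self.edges)
        if np.any(diffs <= 0):
            raise ValueError("edges must be strictly increasing")


def _labels(edges) -> tuple[str, ...]:
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if np.isinf(hi):
            out.append(f">{lo:g} h")
        else:
            out.append(f"{lo:g}-{hi:g} h")
    return tuple(out)


def paired_dt_scheme() -> BinScheme:
    """Delta-t intervals of the paired analysis: 0-12 h ... > 144 h."""
    return BinScheme("paired_dt", PAIRED_EDGES, _labels(PAIRED_EDGES))


def unpaired_tod_scheme() -> BinScheme:
    """Time-since-death groups 1-10 of the unpaired analysis: 0-6 h ... > 144 h."""
    return BinScheme("unpaired_tod", UNPAIRED_EDGES, _labels(UNPAIRED_EDGES))


def assign_bin(value_h: float, scheme: BinScheme) -> str:
    """Label of the half-open bin containing ``value_h``.

    Boundary values go to the upper bin (12.0 h falls in "12-24 h").
    """
    if value_h < 0:
        raise ValueError("time values must be >= 0")
    idx = int(np.searchsorted(scheme.edges, value_h, side="right")) - 1
    idx = min(idx, len(scheme.labels) - 1)
    return scheme.labels[idx]


def assign_bins(values_h, scheme: BinScheme) -> np.ndarray:
    """Vectorized :func:`assign_bin`."""
    v = np.asarray(values_h, dtype=float)
    if np.any(v < 0):
        raise ValueError("time values must be >= 0")
    idx = np.searchsorted(scheme.edges, v, side="right") - 1
    idx = np.minimum(idx, len(scheme.labels) - 1)
    return np.asarray(scheme.labels, dtype=object)[idx]


def percent_change(pair: CasePair, analyte: str) -> float:
    """Percent difference of raw peak areas, 100 * (t2 - t1) / t1."""
    a1 = pair.t1_record.areas[analyte]
    a2 = pair.t2_record.areas[analyte]
    if a1 <= 0:
        raise ValueError(f"non-positive t1 area for {pair.case_id}/{analyte}")
    return 100.0 * (a2 - a1) / a1


def pair_changes(
    pairs: list[CasePair],
    analytes: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-pair raw areas and percent changes.

    Returns (t1 areas, t2 areas, percent changes) as case x analyte frames
    plus the list of skipped cases (non-positive t1 area).
    """
    ok = [all(p.t1_record.areas[a] > 0 for a in analytes) for p in pairs]
    usable = [p for p, good in zip(pairs, ok) if good]
    skipped = [p.case_id for p, good in zip(pairs, ok) if not good]
    index = [p.case_id for p in usable]
    t1 = pd.DataFrame(
        [[p.t1_record.areas[a] for a in analytes] for p in usable],
        index=index, columns=analytes,
    )
    t2 = pd.DataFrame(
        [[p.t2_record.areas[a] for a in analytes] for p in usable],
        index=index, columns=analytes,
    )
    changes = 100.0 * (t2 - t1) / t1
    changes["delta_t_h"] = [p.delta_t_h for p in usable]
    return t1, t2, changes, skipped


def run_paired_stage(
    pairs: list[CasePair],
    analytes: list[str],
    scheme: BinScheme | None = None,
    alpha: float = 0.05,
    exact_max_n: int = 25,
    per_bin: bool = True,
    areas: tuple[pd.DataFrame, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Per-analyte paired summaries over all cases and per delta-t bin.

    For each analyte the Wilcoxon signed-rank test compares t2 against t1
    areas over all usable pairs ("all" rows) and, with ``per_bin=True``,
    within each delta-t interval.  Holm adjustment runs across the analyte
    family separately for each comparison (the "all" family and each bin
    family).  Medians come with distribution-free 95% order-statistic
    confidence intervals.  ``areas`` may supply pre-normalized (t1, t2)
    matrices for normalization-mode comparisons; by default raw areas are
    used.

    Returns a tidy frame: analyte, bin, n_pairs, median_pct, ci_low,
    ci_high, statistic, p_raw, p_adj, code.
    """
    if not pairs:
        raise ValueError("need at least one pair")
    scheme = scheme or paired_dt_scheme()
    if areas is None:
        t1, t2, changes, _ = pair_changes(pairs, analytes)
    else:
        t1, t2 = areas
        changes = 100.0 * (t2[analytes] - t1[analytes]) / t1[analytes]
        changes["delta_t_h"] = [p.delta_t_h for p in pairs]
    bins = assign_bins(changes["delta_t_h"].to_numpy(), scheme)

    rows = []
    families = [("all", np.ones(len(changes), dtype=bool))]
    if per_bin:
        families += [(label, bins == label) for label in scheme.labels]
    for label, mask in families:
        n = int(mask.sum())
        p_raws = []
        for analyte in analytes:
            if n == 0:
                rows.append(
                    dict(analyte=analyte, bin=label, n_pairs=0,
                         median_pct=np.nan, ci_low=np.nan, ci_high=np.nan,
                         statistic=np.nan, p_raw=np.nan, p_adj=np.nan, code="")
                )
                p_raws.append(np.nan)
                continue
            pct = changes.loc[mask, analyte].to_numpy()
            ci = stats.median_ci(pct) if n >= 1 else None
            res = stats.wilcoxon_signed_rank(
                t2.loc[mask, analyte].to_numpy(),
                t1.loc[mask, analyte].to_numpy(),
                exact_max_n=exact_max_n,
            )
            rows.append(
                dict(analyte=analyte, bin=label, n_pairs=n,
                     median_pct=float(np.median(pct)),
                     ci_low=ci.low, ci_high=ci.high,
                     statistic=res.statistic, p_raw=res.pvalue,
                     p_adj=np.nan, code="")
            )
            p_raws.append(res.pvalue)
        valid = [i for i, p in enumerate(p_raws) if not np.isnan(p)]
        if valid:
            adjusted = stats.holm_adjust([p_raws[i] for i in valid])
            start = len(rows) - len(analytes)
            for j, i in enumerate(valid):
                rows[start + i]["p_adj"] = float(adjusted[j])
                rows[start + i]["code"] = stats.significance_code(adjusted[j])
    return pd.DataFrame(rows)
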