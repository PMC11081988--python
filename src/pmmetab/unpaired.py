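"""Unpaired time-since-death analysis of all individual blood samples.

Every study sample (t1 and t2 alike) is binned by its own interval from the
known or estimated time of death into ten groups (0-6 h = group 1 through
> 144 h = group 10).  Per analyte, a Kruskal-Wallis test over the populated
groups (Holm-adjusted across the analyte family) screens for any group
effect; Dunn's tie-corrected post-hoc test is then run on the
Kruskal-Wallis-significant analytes only, with Holm adjustment across the
45 group pairs of each analyte.  Because different cases sit in different
measurement batches, this stage consumes batch-corrected areas.

Percent differences of each group's median normalized area against group 1
summarize the temporal profile; their maximum-magnitude entry is the
"highest change" used for the paired/unpaired concordance comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats
from .paired import BinScheme, assign_bins, unpaired_tod_scheme
from .simulate import CasePair

__all__ = [
    "GroupProfile",
    "run_unpaired_stage",
    "highest_change",
    "compare_sampling_procedures",
    "count_pairs_same_group",
    "profiles_table",
]


@dataclass
class GroupProfile:
    """Temporal profile of one analyte across the time-since-death groups."""

    analyte: str
    group_labels: list[str]
    n_per_group: dict[str, int]
    median_per_group: dict[str, float]
    pct_vs_group1: dict[str, float]
    kw_statistic: float
    kw_p_raw: float
    kw_p_adj: float = np.nan
    kw_code: str = ""
    dunn_p_raw: pd.DataFrame | None = None
    dunn_p_adj: pd.DataFrame | None = None
    dropped_groups: list[str] = field(default_factory=list)
    degenerate: bool = False


def run_unpaired_stage(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    scheme: BinScheme | None = None,
    alpha: float = 0.05,
    dunn_gate: str = "p_adj",
) -> list[GroupProfile]:
    """Kruskal-Wallis + Dunn + Holm over time-since-death groups.

    ``values``: normalized sample x analyte matrix; ``meta``: frame indexed
    like ``values`` with ``sample_type`` and ``time_since_death_h``.  Only
    study samples enter the analysis.  Dunn's test runs on analytes whose
    Kruskal-Wallis p (``dunn_gate``: adjusted by default, ``"p_raw"`` to
    gate on the raw p) falls below ``alpha``; its p-values are
    Holm-adjusted across the group pairs of that analyte.
    """
    scheme = scheme or unpaired_tod_scheme()
    meta = meta.loc[values.index]
    study = meta["sample_type"] == "study"
    tod = meta.loc[study, "time_since_death_h"].astype(float)
    if tod.isna().any():
        raise ValueError("study samples lack time_since_death_h")
    data = values.loc[study.to_numpy(), :]
    bins = assign_bins(tod.to_numpy(), scheme)

    populated = [lab for lab in scheme.labels if (bins == lab).sum() > 0]
    dropped = [lab for lab in scheme.labels if lab not in populated]
    if len(populated) < 2:
        raise ValueError("need at least two populated time groups")

    profiles: list[GroupProfile] = []
    for analyte in values.columns:
        groups = [data.loc[bins == lab, analyte].to_numpy() for lab in populated]
        medians = {lab: float(np.median(g)) for lab, g in zip(populated, groups)}
        ref = medians[populated[0]]
        pct = {
            lab: 100.0 * (medians[lab] - ref) / ref if ref != 0 else np.nan
            for lab in populated
        }
        pooled = np.concatenate(groups)
        if np.all(pooled == pooled[0]):
            kw = stats.TestResult(0.0, 1.0, len(pooled), degenerate=True)
        else:
            kw = stats.kruskal_wallis(groups)
        profiles.append(
            GroupProfile(
                analyte=str(analyte),
                group_labels=populated,
                n_per_group={lab: int(len(g)) for lab, g in zip(populated, groups)},
                median_per_group=medians,
                pct_vs_group1=pct,
                kw_statistic=kw.statistic,
                kw_p_raw=kw.pvalue,
                dropped_groups=dropped,
                degenerate=kw.degenerate,
            )
        )

    adjusted = stats.holm_adjust([p.kw_p_raw for p in profiles])
    for profile, p_adj in zip(profiles, adjusted):
        profile.kw_p_adj = float(p_adj)
        profile.kw_code = stats.significance_code(p_adj)

    for profile in profiles:
        gate_p = profile.kw_p_adj if dunn_gate == "p_adj" else profile.kw_p_raw
        if profile.degenerate or gate_p >= alpha:
            continue
        groups = [
            data.loc[bins == lab, profile.analyte].to_numpy()
            for lab in profile.group_labels
        ]
        _, p_raw = stats.dunns_test(groups)
        k = len(groups)
        iu = np.triu_indices(k, 1)
        adj_flat = stats.holm_adjust(p_raw[iu])
        p_adj = np.ones_like(p_raw)
        p_adj[iu] = adj_flat
        p_adj.T[iu] = adj_flat
        labels = profile.group_labels
        profile.dunn_p_raw = pd.DataFrame(p_raw, index=labels, columns=labels)
        profile.dunn_p_adj = pd.DataFrame(p_adj, index=labels, columns=labels)
    return profiles


def highest_change(profile: GroupProfile) -> tuple[float, str]:
    """Maximum-|.| percent change vs group 1 and its group label.

    Considers groups 2..k; ties break toward the later group.  A flat
    profile (all zero) returns 0 with the earliest non-reference label.
    """
    labels = profile.group_labels[1:]
    if not labels:
        raise ValueError("need at least two populated groups")
    values = np.array([profile.pct_vs_group1[lab] for lab in labels])
    if np.all(values == 0):
        return 0.0, labels[0]
    best = np.max(np.abs(values))
    idx = int(np.nonzero(np.abs(values) == best)[0][-1])  # later group on ties
    return float(values[idx]), labels[idx]


def profiles_table(profiles: list[GroupProfile]) -> pd.DataFrame:
    """Tidy summary: one row per analyte with KW results and highest change."""
    rows = []
    for p in profiles:
        pct, group = highest_change(p)
        rows.append(
            dict(
                analyte=p.analyte,
                kw_statistic=p.kw_statistic,
                kw_p_raw=p.kw_p_raw,
                kw_p_adj=p.kw_p_adj,
                kw_code=p.kw_code,
                highest_pct_vs_group1=pct,
                highest_group=group,
            )
        )
    return pd.DataFrame(rows)


def compare_sampling_procedures(
    values: pd.DataFrame,
    meta: pd.DataFrame,
    bin_label: str = "24-36 h",
    scheme: BinScheme | None = None,
) -> pd.DataFrame:
    """Mann-Whitney t1-vs-t2 check within one time-since-death group.

    Within the given tx_ToD bin, samples collected at admission (t1) and at
    autopsy (t2) share the time since death, so systematic differences
    would indicate an effect of the sampling procedure itself.  Two-sided
    Mann-Whitney per analyte on the normalized areas, Holm across analytes,
    with the direction of the median difference (t2 relative to t1).
    """
    scheme = scheme or unpaired_tod_scheme()
    meta = meta.loc[values.index]
    study = meta["sample_type"] == "study"
    tod = meta.loc[study, "time_since_death_h"].astype(float)
    bins = assign_bins(tod.to_numpy(), scheme)
    in_bin = pd.Series(bins == bin_label, index=tod.index)
    sub_meta = meta.loc[study].loc[in_bin]
    sub = values.loc[study.to_numpy(), :].loc[in_bin]
    t1_mask = (sub_meta["timepoint_label"] == "t1").to_numpy()
    t2_mask = (sub_meta["timepoint_label"] == "t2").to_numpy()
    if not t1_mask.any() or not t2_mask.any():
        raise ValueError(f"bin {bin_label!r} lacks t1 or t2 samples")
    rows = []
    for analyte in values.columns:
        a = sub.loc[t1_mask, analyte].to_numpy()
        b = sub.loc[t2_mask, analyte].to_numpy()
        res = stats.mann_whitney(a, b)
        med1, med2 = float(np.median(a)), float(np.median(b))
        rows.append(
            dict(
                analyte=str(analyte),
                n_t1=len(a),
                n_t2=len(b),
                statistic=res.statistic,
                p_raw=res.pvalue,
                median_diff_pct=100.0 * (med2 - med1) / med1,
                direction="lower at t2" if med2 < med1 else "higher at t2",
            )
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = stats.holm_adjust(table["p_raw"])
    table["code"] = table["p_adj"].map(stats.significance_code)
    return table


def count_pairs_same_group(
    pairs: list[CasePair],
    scheme: BinScheme | None = None,
) -> pd.DataFrame:
    """Cases whose t1 and t2 fall into the same time-since-death group."""
    scheme = scheme or unpaired_tod_scheme()
    rows = []
    for p in pairs:
        b1 = assign_bins([p.t1_record.time_since_death_h], scheme)[0]
        b2 = assign_bins([p.t2_record.time_since_death_h], scheme)[0]
        if b1 == b2:
            rows.append(dict(case_id=p.case_id, group=b1))
    return pd.DataFrame(rows, columns=["case_id", "group"])
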