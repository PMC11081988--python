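"""End-to-end orchestration: configuration, table contracts, full pipeline.

A single long-format input schema serves synthetic and real cohorts alike:

``areas`` table (one row per sample x analyte):
    sample_id, case_id, timepoint_label (t1|t2|pool), sample_type
    (study|pool), batch_id, time_since_death_h, analyte, peak_area

``samples`` table (one row per sample): the same metadata plus the three
``is_<name>`` internal-standard area columns.

``run_pipeline`` executes qc -> normalization -> paired analysis ->
unpaired analysis -> interpretation and writes every stage table plus a
markdown report; all randomness flows through the single seed recorded in
the config, so reruns are byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import qc as qc_mod
from . import unpaired as unpaired_mod
from .interpret import (classify_panel, compare_normalization_modes,
                        correlate_properties, paired_unpaired_concordance)
from .normalize import batch_correct, pqn_normalize
from .paired import paired_dt_scheme, run_paired_stage, unpaired_tod_scheme
from .panel import load_panel
from .simulate import (CasePair, Cohort, CohortConfig, SampleRecord,
                       default_panel_kinetics, generate_cohort)

__all__ = [
    "PipelineConfig",
    "SchemaReport",
    "validate_table",
    "cohort_from_tables",
    "simulate_default_cohort",
    "run_pipeline",
]

logger = logging.getLogger("pmmetab")

AREA_COLUMNS = [
    "sample_id", "case_id", "timepoint_label", "sample_type",
    "batch_id", "time_since_death_h", "analyte", "peak_area",
]


@dataclass
class PipelineConfig:
    """Effective configuration of one pipeline run."""

    out_dir: str = "results/pipeline"
    areas_path: str | None = None
    samples_path: str | None = None
    panel_path: str | None = None
    normalization_mode: str = "batch_only"  # for the unpaired stage input
    pqn_reference: str = "pool_mean"
    alpha: float = 0.05
    adjust: str = "holm"
    exact_max_n: int = 25
    stable_band_pct: float = 30.0
    lag_limit_h: float = 36.0
    seed: int = 0
    n_cases: int = 427

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.adjust != "holm":
            raise ValueError("only Holm adjustment is supported")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)


@dataclass
class SchemaReport:
    violations: list[str] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.violations


def validate_table(areas: pd.DataFrame | str | Path) -> SchemaReport:
    """Check a long-format area table against the input contract.

    Verifies column presence, area positivity, and pairing completeness
    (each case has exactly one t1 and one t2 row per analyte); every
    violation is listed, none raises.
    """
    if not isinstance(areas, pd.DataFrame):
        areas = pd.read_csv(areas)
    report = SchemaReport()
    missing = [c for c in AREA_COLUMNS if c not in areas.columns]
    if missing:
        report.violations.append(f"missing columns: {missing}")
        return report
    bad_area = areas["peak_area"].astype(float) <= 0
    if bad_area.any():
        rows = areas.index[bad_area].tolist()[:5]
        report.violations.append(
            f"non-positive peak_area in {int(bad_area.sum())} rows (e.g. {rows})"
        )
    study = areas[areas["sample_type"] == "study"]
    counts = (
        study.drop_duplicates(["sample_id"])
        .groupby(["case_id", "timepoint_label"])
        .size()
        .unstack(fill_value=0)
    )
    for tp in ("t1", "t2"):
        if tp not in counts.columns:
            report.violations.append(f"no {tp} samples present")
            continue
        bad = counts.index[counts[tp] != 1].tolist()
        if bad:
            report.violations.append(
                f"cases without exactly one {tp} sample: {bad[:5]}"
            )
    pools = areas[areas["sample_type"] == "pool"]
    batches_without_pool = sorted(
        set(study["batch_id"]) - set(pools["batch_id"])
    )
    if batches_without_pool:
        report.violations.append(
            f"batches without pool records: {batches_without_pool}"
        )
    if "t1" in counts.columns and "t2" in counts.columns:
        same_batch = (
            study.drop_duplicates("sample_id")
            .groupby("case_id")["batch_id"]
            .nunique()
        )
        split = same_batch.index[same_batch > 1].tolist()
        if split:
            report.violations.append(
                f"cases whose t1/t2 sit in different batches: {split[:5]}"
            )
    return report


def cohort_from_tables(
    areas: pd.DataFrame,
    samples: pd.DataFrame | None = None,
) -> Cohort:
    """Reconstruct a :class:`Cohort` from long-format tables."""
    report = validate_table(areas)
    if not report.clean:
        raise ValueError("schema violations: " + "; ".join(report.violations))
    analytes = sorted(areas["analyte"].unique())
    wide = areas.pivot_table(
        index="sample_id", columns="analyte", values="peak_area"
    )
    meta_cols = [c for c in AREA_COLUMNS if c not in ("analyte", "peak_area")]
    meta = areas.drop_duplicates("sample_id").set_index("sample_id")[
        [c for c in meta_cols if c != "sample_id"]
    ]
    is_lookup = {}
    if samples is not None:
        is_cols = [c for c in samples.columns if c.startswith("is_")]
        is_lookup = samples.set_index("sample_id")[is_cols].to_dict("index")

    records: dict[str, SampleRecord] = {}
    for sample_id, row in meta.iterrows():
        tsd = row["time_since_death_h"]
        records[sample_id] = SampleRecord(
            sample_id=str(sample_id),
            case_id=str(row["case_id"]) or None
            if pd.notna(row["case_id"]) else None,
            timepoint_label=str(row["timepoint_label"]),
            sample_type=str(row["sample_type"]),
            batch_id=str(row["batch_id"]),
            time_since_death_h=float(tsd) if pd.notna(tsd) else None,
            areas=wide.loc[sample_id].to_dict(),
            is_areas={
                k.removeprefix("is_"): v
                for k, v in is_lookup.get(sample_id, {}).items()
            },
        )
    pairs = []
    study = meta[meta["sample_type"] == "study"]
    for case_id, group in study.groupby("case_id"):
        t1_id = group.index[group["timepoint_label"] == "t1"][0]
        t2_id = group.index[group["timepoint_label"] == "t2"][0]
        t1, t2 = records[t1_id], records[t2_id]
        pairs.append(
            CasePair(
                case_id=str(case_id),
                t1_record=t1,
                t2_record=t2,
                delta_t_h=t2.time_since_death_h - t1.time_since_death_h,
            )
        )
    config = CohortConfig(n_cases=len(pairs))
    return Cohort(list(records.values()), pairs, {}, analytes, config)


def simulate_default_cohort(seed: int, n_cases: int = 427) -> Cohort:
    """Default study-condition cohort over the shipped 38-analyte panel."""
    config = CohortConfig(n_cases=n_cases, seed=seed)
    return generate_cohort(config, default_panel_kinetics())


def run_pipeline(
    config: PipelineConfig,
    cohort: Cohort | None = None,
) -> dict:
    """Execute qc -> normalize -> paired -> unpaired -> interpretation.

    With no input tables configured, a synthetic default cohort is
    generated from the config seed.  All stage outputs are written as CSV
    under ``config.out_dir`` together with a markdown report; the returned
    dict carries the in-memory results.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logger.info("effective config: %s", asdict(config))

    if cohort is None:
        if config.areas_path:
            areas = pd.read_csv(config.areas_path)
            samples = (
                pd.read_csv(config.samples_path) if config.samples_path else None
            )
            cohort = cohort_from_tables(areas, samples)
        else:
            cohort = simulate_default_cohort(config.seed, config.n_cases)
            cohort.areas_table().to_csv(out / "areas.csv", index=False)
            cohort.samples_table().to_csv(out / "samples.csv", index=False)

    meta, wide = cohort.wide()
    panel = load_panel(config.panel_path)

    # --- QC ---------------------------------------------------------------
    qc_report = qc_mod.run_qc(cohort.samples_table(), cohort.areas_table())
    (out / "qc_report.txt").write_text(qc_report.summary() + "\n")

    # --- normalization ----------------------------------------------------
    bc = batch_correct(wide, meta)
    normalized = bc
    if config.normalization_mode == "pqn":
        normalized = pqn_normalize(
            bc.values, reference=config.pqn_reference, meta=meta
        )
        normalized.pqn_factors.rename_axis("sample_id").to_csv(
            out / "pqn_factors.csv"
        )
    normalized.values.rename_axis("sample_id").to_csv(out / "normalized.csv")

    # --- paired stage (raw areas) ------------------------------------------
    paired_summary = run_paired_stage(
        cohort.pairs,
        cohort.analytes,
        paired_dt_scheme(),
        alpha=config.alpha,
        exact_max_n=config.exact_max_n,
    )
    paired_summary.to_csv(out / "paired_summary.csv", index=False)

    # --- unpaired stage (normalized areas) ----------------------------------
    profiles = unpaired_mod.run_unpaired_stage(
        normalized.values, meta, unpaired_tod_scheme(), alpha=config.alpha
    )
    profile_table = unpaired_mod.profiles_table(profiles)
    profile_table.to_csv(out / "unpaired_profiles.csv", index=False)
    heat_dir = out / "dunn_heatmaps"
    heat_dir.mkdir(exist_ok=True)
    for profile in profiles:
        if profile.dunn_p_adj is not None:
            safe = profile.analyte.replace("/", "_").replace(" ", "_")
            profile.dunn_p_adj.to_csv(heat_dir / f"{safe}.csv")
    same_group = unpaired_mod.count_pairs_same_group(cohort.pairs)
    same_group.to_csv(out / "pairs_same_group.csv", index=False)

    # --- interpretation -----------------------------------------------------
    patterns = classify_panel(
        paired_summary,
        stable_band=config.stable_band_pct,
        lag_limit_h=config.lag_limit_h,
    )
    patterns.to_csv(out / "patterns.csv", index=False)

    overall = (
        paired_summary[paired_summary["bin"] == "all"]
        .set_index("analyte")["median_pct"]
    )
    correlations = []
    for prop in ("logp", "mw", "rt_rp"):
        try:
            correlations.append(correlate_properties(overall, panel, prop))
        except ValueError as exc:
            logger.warning("property correlation %s skipped: %s", prop, exc)
    concordance = paired_unpaired_concordance(paired_summary, profiles)
    correlations.append(concordance)
    corr_table = pd.DataFrame([c.__dict__ for c in correlations])
    corr_table.to_csv(out / "correlations.csv", index=False)

    modes = compare_normalization_modes(cohort)
    modes["comparison"].rename_axis("analyte").to_csv(
        out / "normalization_comparison.csv"
    )

    # --- report -------------------------------------------------------------
    n_sig = int(
        (paired_summary.loc[paired_summary["bin"] == "all", "p_adj"]
         < config.alpha).sum()
    )
    report = [
        "# Postmortem time-dependence pipeline report",
        "",
        f"- cases: {len(cohort.pairs)}; samples: {len(cohort.samples)}; "
        f"analytes: {len(cohort.analytes)}",
        f"- seed: {config.seed}; normalization mode (unpaired stage): "
        f"{config.normalization_mode}",
        f"- QC: {'pass' if qc_report.passed else 'warnings'}; "
        f"excluded samples: {len(qc_report.excluded_samples)}",
        f"- paired analysis: {n_sig}/{len(cohort.analytes)} analytes with "
        f"Holm-adjusted p < {config.alpha}",
        f"- paired/unpaired concordance: rho^2 = {concordance.rho_sq:.3f}",
        f"- pairs binned into the same time group: {len(same_group)}",
        f"- PQN attenuation ratio (drifting analytes): "
        f"{modes['pqn_attenuation_ratio']:.3f}",
        "",
        "Stage outputs: qc_report.txt, normalized.csv, paired_summary.csv, "
        "unpaired_profiles.csv, dunn_heatmaps/, patterns.csv, "
        "correlations.csv, normalization_comparison.csv",
    ]
    (out / "report.md").write_text("\n".join(report) + "\n")
    config.to_yaml(out / "config.yaml")

    return dict(
        cohort=cohort,
        qc=qc_report,
        normalized=normalized,
        paired_summary=paired_summary,
        profiles=profiles,
        profile_table=profile_table,
        patterns=patterns,
        correlations=corr_table,
        concordance=concordance,
        normalization_modes=modes,
        same_group_pairs=same_group,
    )
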