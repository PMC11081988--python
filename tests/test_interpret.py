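"""Pattern classification, property correlations, concordance checks."""

import numpy as np
import pandas as pd
import pytest

from pmmetab.interpret import (classify_panel, classify_pattern,
                               compare_normalization_modes,
                               correlate_properties, cross_platform_concordance,
                               paired_unpaired_concordance)
from pmmetab.panel import AnalyteSpec
from pmmetab.paired import run_paired_stage
from pmmetab.simulate import (CohortConfig, KineticModel, generate_cohort,
                              well_separated_kinetics)
from pmmetab.unpaired import GroupProfile


@pytest.mark.parametrize(
    "medians,expected",
    [
        ([0, 0, 0, 0, 0, 0], "stable"),
        ([5, -10, 12, 20, 8, -4], "stable"),
        ([5, 10, 25, 60, 120, 160], "steady_increase"),
        ([2, -3, 4, 45, 80, 120], "lag_then_increase"),
        ([-5, -12, -25, -40, -55, -70], "decrease"),
    ],
)
def test_classify_pattern_rules(medians, expected):
    edges = np.array([12.0, 24, 36, 48, 72, 96])[: len(medians)]
    call = classify_pattern(pd.Series(medians, dtype=float), edges)
    assert call.pattern == expected


def test_classify_pattern_needs_four_bins():
    with pytest.raises(ValueError):
        classify_pattern(pd.Series([0.0, 10.0, 20.0]), np.array([12.0, 24, 36]))


def test_classification_invariant_to_uniform_scaling():
    """Scaling every raw area by a constant leaves the pattern calls fixed."""
    kin = well_separated_kinetics(1)
    cohort = generate_cohort(CohortConfig(n_cases=200, seed=9), kin)
    summary = run_paired_stage(cohort.pairs, cohort.analytes)
    calls = classify_panel(summary)

    for pair in cohort.pairs:
        for rec in (pair.t1_record, pair.t2_record):
            for analyte in cohort.analytes:
                rec.areas[analyte] *= 1000.0
    summary_scaled = run_paired_stage(cohort.pairs, cohort.analytes)
    calls_scaled = classify_panel(summary_scaled)
    pd.testing.assert_frame_equal(calls, calls_scaled)


def _panel():
    return [
        AnalyteSpec("a", "x", logp=-2.0, mw=100.0),
        AnalyteSpec("b", "x", logp=-1.0, mw=150.0),
        AnalyteSpec("c", "x", logp=0.5, mw=200.0),
        AnalyteSpec("d", "x", logp=None, mw=300.0),
    ]


def test_correlate_properties_perfect_rank_agreement():
    changes = pd.Series({"a": 1.0, "b": 5.0, "c": 9.0, "d": 2.0})
    res = correlate_properties(changes, _panel(), "logp")
    assert res.rho == pytest.approx(1.0)
    assert res.n == 3 and res.excluded == 1  # analyte d lacks logP


def test_correlate_properties_too_few():
    changes = pd.Series({"a": 1.0})
    with pytest.raises(ValueError):
        correlate_properties(changes, _panel(), "logp")


def test_correlate_properties_null_when_drift_independent():
    """Drift assigned independently of logP: |rho| small in most reps."""
    rng = np.random.default_rng(33)
    panel = [
        AnalyteSpec(f"a{i}", "x", logp=float(rng.normal()), mw=100.0 + i)
        for i in range(38)
    ]
    small = 0
    for _ in range(200):
        changes = pd.Series(
            {f"a{i}": float(rng.normal(0, 50)) for i in range(38)}
        )
        res = correlate_properties(changes, panel, "logp")
        small += abs(res.rho) < 0.3
    assert small / 200 >= 0.9


def _profile(analyte, pcts):
    labels = [f"g{i + 1}" for i in range(len(pcts))]
    return GroupProfile(
        analyte=analyte,
        group_labels=labels,
        n_per_group={lab: 10 for lab in labels},
        median_per_group={lab: 1.0 for lab in labels},
        pct_vs_group1=dict(zip(labels, pcts)),
        kw_statistic=0.0,
        kw_p_raw=1.0,
    )


def test_concordance_identity_and_mismatch():
    summary = pd.DataFrame(
        dict(analyte=["a", "b", "c", "d"], bin=["all"] * 4,
             median_pct=[10.0, 40.0, -20.0, 90.0])
    )
    profiles = [
        _profile("a", [0, 10.0]),
        _profile("b", [0, 40.0]),
        _profile("c", [0, -20.0]),
        _profile("d", [0, 90.0]),
    ]
    res = paired_unpaired_concordance(summary, profiles)
    assert res.rho_sq == pytest.approx(1.0)
    with pytest.raises(ValueError, match="differ"):
        paired_unpaired_concordance(summary, profiles[:-1])


def test_cross_platform_discordance_flagged():
    base = []
    for analyte in ("a", "b"):
        for i, pct in enumerate([5.0, 20.0, 60.0, 150.0]):
            base.append(dict(analyte=analyte, bin=f"b{i}", median_pct=pct))
    rp = pd.DataFrame(base + [dict(analyte=analyte, bin="all", median_pct=0)
                              for analyte in ("a", "b")])
    hilic = rp.copy()
    flip = hilic["analyte"] == "b"
    hilic.loc[flip, "median_pct"] *= -1.0
    table = cross_platform_concordance(rp, hilic)
    assert table.set_index("analyte").loc["a", "rho"] == pytest.approx(1.0)
    assert bool(table.set_index("analyte").loc["b", "discordant"])
    with pytest.raises(ValueError, match="overlap"):
        cross_platform_concordance(rp, hilic.assign(analyte="zzz"))


def test_normalization_modes_agree_without_prep_or_drift():
    kin = {
        f"a{i}": KineticModel("stable", sigma_inter=0.3, sigma_intra=0.02)
        for i in range(6)
    }
    cohort = generate_cohort(
        CohortConfig(n_cases=40, seed=13, sigma_prep=0.0), kin
    )
    out = compare_normalization_modes(cohort)
    comparison = out["comparison"]
    assert set(comparison.columns) == {"batch_only", "is", "pqn"}
    spread = comparison.max(axis=1) - comparison.min(axis=1)
    assert (spread < 5.0).all()  # only measurement noise separates the modes


def test_pqn_attenuates_majority_drift():
    kin = {}
    for i in range(30):
        kin[f"d{i}"] = KineticModel("steady_increase", rate=0.02)
    for i in range(8):
        kin[f"s{i}"] = KineticModel("stable")
    cohort = generate_cohort(CohortConfig(n_cases=60, seed=3), kin)
    out = compare_normalization_modes(cohort, modes=("batch_only", "pqn"))
    assert out["pqn_attenuation_ratio"] < 1.0
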