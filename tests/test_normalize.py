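"""Batch correction, IS normalization, and PQN properties."""

import numpy as np
import pandas as pd
import pytest

from pmmetab.normalize import (NormalizationError, batch_correct, is_normalize,
                               pqn_normalize)
from pmmetab.simulate import CohortConfig, KineticModel, generate_cohort


def _toy_tables():
    meta = pd.DataFrame(
        {
            "batch_id": ["B1", "B1", "B1", "B2", "B2", "B2"],
            "sample_type": ["study", "pool", "pool", "study", "pool", "pool"],
        },
        index=[f"s{i}" for i in range(6)],
    )
    areas = pd.DataFrame(
        {
            "a": [2000.0, 900.0, 1100.0, 6000.0, 2700.0, 3300.0],
            "b": [50.0, 100.0, 100.0, 150.0, 300.0, 300.0],
        },
        index=meta.index,
    )
    return areas, meta


def test_batch_correct_definition_and_pool_mean_one():
    areas, meta = _toy_tables()
    out = batch_correct(areas, meta)
    assert out.values.loc["s0", "a"] == pytest.approx(2.0)  # 2000 / 1000
    pools = meta["sample_type"] == "pool"
    pool_means = out.values[pools].groupby(meta.loc[pools, "batch_id"]).mean()
    assert np.allclose(pool_means.to_numpy(), 1.0)


def test_batch_correct_cancels_batch_factors():
    """Same underlying sample measured in 1x and 3x batches corrects equally."""
    areas, meta = _toy_tables()
    out = batch_correct(areas, meta)
    # batch B2 is batch B1 scaled by 3 for both analytes
    assert out.values.loc["s3"].to_numpy() == pytest.approx(
        out.values.loc["s0"].to_numpy()
    )


def test_batch_correct_missing_pool_errors():
    areas, meta = _toy_tables()
    meta2 = meta.copy()
    meta2.loc[["s4", "s5"], "sample_type"] = "study"
    with pytest.raises(NormalizationError, match="B2"):
        batch_correct(areas, meta2)


def test_batch_correct_rejects_nonpositive():
    areas, meta = _toy_tables()
    areas.loc["s0", "a"] = -1.0
    with pytest.raises(NormalizationError):
        batch_correct(areas, meta)


def test_is_normalize_ratio_and_fallback():
    areas = pd.DataFrame({"Creatinine": [500.0], "Taurine": [300.0]},
                         index=["s0"])
    is_areas = pd.DataFrame(
        {"is_creatinine-d3": [100.0], "is_phenylalanine-d1": [150.0]},
        index=["s0"],
    )
    out = is_normalize(areas, is_areas)
    assert out.values.loc["s0", "Creatinine"] == pytest.approx(5.0)
    assert out.values.loc["s0", "Taurine"] == pytest.approx(2.0)  # fallback IS
    assert any("Taurine" in note for note in out.notes)


def test_is_normalize_cancels_prep_factor():
    rng = np.random.default_rng(0)
    prep = rng.lognormal(0, 0.3, size=8)
    areas = pd.DataFrame({"Creatinine": 500.0 * prep}, index=range(8))
    is_areas = pd.DataFrame({"is_creatinine-d3": 100.0 * prep}, index=range(8))
    out = is_normalize(areas, is_areas)
    assert np.allclose(out.values["Creatinine"], 5.0)


def test_is_normalize_missing_is_errors():
    areas = pd.DataFrame({"Creatinine": [500.0]}, index=["s0"])
    is_areas = pd.DataFrame({"is_creatinine-d3": [0.0]}, index=["s0"])
    with pytest.raises(NormalizationError, match="s0"):
        is_normalize(areas, is_areas)


def test_pqn_identity_and_pure_dilution():
    ref = pd.Series([10.0, 20.0, 30.0, 40.0], index=list("abcd"))
    table = pd.DataFrame([ref, ref * 0.5], index=["s0", "s1"])
    out = pqn_normalize(table, reference="median_all")
    # median spectrum = 0.75*ref, so factors are 4/3 and 2/3; s1 maps onto s0
    assert out.values.loc["s0"].to_numpy() == pytest.approx(
        out.values.loc["s1"].to_numpy()
    )
    pool_meta = pd.DataFrame(
        {"sample_type": ["pool", "study"]}, index=["s0", "s1"]
    )
    out2 = pqn_normalize(table, reference="pool_mean", meta=pool_meta)
    assert out2.pqn_factors.loc["s1"] == pytest.approx(0.5)
    assert out2.values.loc["s1"].to_numpy() == pytest.approx(ref.to_numpy())


def test_pqn_median_robust_to_minority_perturbation():
    """Factor stays exactly 2 when 10 of 38 quotients are perturbed."""
    rng = np.random.default_rng(4)
    ref = pd.Series(rng.lognormal(3, 0.5, 38), index=[f"a{i}" for i in range(38)])
    sample = 2.0 * ref.copy()
    sample.iloc[:10] *= rng.uniform(0.5, 1.5, 10)
    table = pd.DataFrame([ref, sample], index=["ref", "s"])
    out = pqn_normalize(table, reference="median_all")
    factor_ratio = out.pqn_factors.loc["s"] / out.pqn_factors.loc["ref"]
    assert factor_ratio == pytest.approx(2.0, rel=1e-12)


def test_pqn_needs_two_analytes():
    table = pd.DataFrame({"a": [1.0, 2.0]}, index=["s0", "s1"])
    with pytest.raises(NormalizationError):
        pqn_normalize(table, reference="median_all")


def _dilution_cohort(n_drift, seed):
    kin = {}
    for i in range(n_drift):
        kin[f"d{i}"] = KineticModel("steady_increase", rate=0.02,
                                    sigma_inter=0.0, sigma_intra=0.0)
    for i in range(38 - n_drift):
        kin[f"s{i}"] = KineticModel("stable", sigma_inter=0.0, sigma_intra=0.0)
    return generate_cohort(
        CohortConfig(n_cases=30, seed=seed, sigma_batch=0.1, sigma_prep=0.3),
        kin,
    )


def test_pqn_factor_recovery_degrades_with_drifted_majority():
    """Mean |log factor error| with 30/38 drifted exceeds the 3/38 case.

    This is the dilution-vs-effect confounding inherent to quotient
    normalization: when most analytes carry a real temporal effect, the
    median quotient absorbs it into the "dilution" factor.
    """
    errors = {}
    for n_drift in (3, 30):
        cohort = _dilution_cohort(n_drift, seed=5)
        meta, wide = cohort.wide()
        bc = batch_correct(wide, meta)
        out = pqn_normalize(bc.values, reference="pool_mean", meta=meta)
        truth = cohort.truth["prep_factors"].set_index("sample_id")
        f = out.pqn_factors.loc[truth.index]
        errors[n_drift] = np.abs(
            np.log(f) - np.log(truth["true_prep_factor"])
        ).mean()
    assert errors[30] > errors[3]
    assert errors[3] < 0.02  # minority drift: factors near-exact


def test_modes_preserve_shape_and_positivity(noisy_stable_cohort):
    meta, wide = noisy_stable_cohort.wide()
    bc = batch_correct(wide, meta)
    pqn = pqn_normalize(bc.values, reference="pool_mean", meta=meta)
    for table in (bc.values, pqn.values):
        assert table.shape == wide.shape
        assert (table.to_numpy() > 0).all()
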