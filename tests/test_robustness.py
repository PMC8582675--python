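"""IAV/IWV/CMV: hand-computed oracles, invariances, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mammotex import (
    BilateralCohortTable,
    PhantomFeatureTable,
    RobustnessModel,
    clinical_reference,
    cmv,
    iav,
    iwv,
    simulate_robustness_tables,
)


def make_cohort(values_by_feature: dict[str, list[float]],
                thickness: list[float] | None = None) -> BilateralCohortTable:
    """Cohort of n women whose left/right values are consecutive pairs."""
    n_images = len(next(iter(values_by_feature.values())))
    assert n_images % 2 == 0
    df = pd.DataFrame(
        {
            "subject_id": [f"W{i // 2}" for i in range(n_images)],
            "laterality": ["L", "R"] * (n_images // 2),
            "thickness_mm": thickness or [50.0] * n_images,
        }
        | values_by_feature
    )
    return BilateralCohortTable.from_dataframe(df)


def make_phantom(values_by_feature: dict[str, list[float]]) -> PhantomFeatureTable:
    return PhantomFeatureTable.from_dataframe(pd.DataFrame(values_by_feature))


# ---------------------------------------------------------------------------
# clinical reference percentiles
# ---------------------------------------------------------------------------

def test_percentiles_of_0_to_100_are_5_and_95():
    # 101 breast images valued 0..100: linear-interpolation percentiles
    # land exactly on 5 and 95, width 90
    df = pd.DataFrame(
        {
            "subject_id": [f"W{i // 2}" for i in range(101)],
            "laterality": ["L", "R"] * 50 + ["L"],
            "thickness_mm": 50.0,
            "f": np.arange(101.0),
        }
    )
    cohort = BilateralCohortTable.from_dataframe(df)
    ref = clinical_reference(cohort, (40, 60), min_images=20)
    assert ref.loc["f", "c5"] == pytest.approx(5.0, abs=1e-12)
    assert ref.loc["f", "c95"] == pytest.approx(95.0, abs=1e-12)
    assert not bool(ref.loc["f", "degenerate"])


def test_constant_feature_flagged_degenerate():
    cohort = make_cohort({"f": [3.0] * 30})
    ref = clinical_reference(cohort, (40, 60))
    assert bool(ref.loc["f", "degenerate"])
    phantom = make_phantom({"f": [1.0, 2.0]})
    assert np.isnan(iav(phantom, ref)["f"])  # missing, not infinite


def test_thickness_band_restricts_reference_population():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=60)
    thickness = [45.0] * 30 + [70.0] * 30  # half the images qualify
    cohort = make_cohort({"f": list(vals)}, thickness=thickness)
    ref = clinical_reference(cohort, (40, 60))
    in_band = np.sort(vals[:30])  # brute-force filter-then-sort oracle
    assert ref.loc["f", "c5"] == pytest.approx(np.percentile(in_band, 5))
    assert ref.loc["f", "c95"] == pytest.approx(np.percentile(in_band, 95))


def test_too_few_reference_images_rejected():
    cohort = make_cohort({"f": [1.0, 2.0] * 5})
    with pytest.raises(ValueError, match="percentiles"):
        clinical_reference(cohort, (40, 60), min_images=20)


# ---------------------------------------------------------------------------
# IAV
# ---------------------------------------------------------------------------

def reference_frame(c5: float, c95: float, feature: str = "f") -> pd.DataFrame:
    return pd.DataFrame(
        {"c5": [c5], "c95": [c95], "degenerate": [c95 <= c5]},
        index=pd.Index([feature], name="feature"),
    )


def test_iav_hand_computed():
    phantom = make_phantom({"f": [1.0, 2.0, 3.0]})
    result = iav(phantom, reference_frame(0.0, 10.0))
    assert result["f"] == pytest.approx(0.2, abs=1e-12)  # (3-1)/10


def test_iav_zero_when_phantom_constant():
    phantom = make_phantom({"f": [4.0] * 12})
    assert iav(phantom, reference_frame(0.0, 10.0))["f"] == 0.0


def test_iav_needs_two_acquisitions():
    with pytest.raises(ValueError, match="2 acquisitions"):
        make_phantom({"f": [1.0]})


# ---------------------------------------------------------------------------
# IWV
# ---------------------------------------------------------------------------

def test_iwv_hand_computed():
    cohort = make_cohort({"f": [1.0, 2.0, 5.0, 3.0, 10.0, 7.0]})
    result = iwv(cohort, reference_frame(0.0, 10.0), (40, 60))
    assert result["f"] == pytest.approx(0.2, abs=1e-12)  # median{1,2,3}/10


def test_iwv_zero_when_sides_equal():
    cohort = make_cohort({"f": [4.0, 4.0, 9.0, 9.0]})
    assert iwv(cohort, reference_frame(0.0, 10.0), (40, 60))["f"] == 0.0


def test_iwv_invariant_under_duplicating_every_woman():
    base = {"f": [1.0, 2.0, 5.0, 3.0, 10.0, 7.0]}
    cohort = make_cohort(base)
    doubled_df = pd.concat(
        [cohort.data, cohort.data.assign(subject_id=lambda d: d.subject_id + "x")]
    )
    doubled = BilateralCohortTable.from_dataframe(doubled_df)
    ref = reference_frame(0.0, 10.0)
    assert iwv(cohort, ref, (40, 60))["f"] == iwv(doubled, ref, (40, 60))["f"]


def test_woman_missing_one_side_excluded_with_warning():
    cohort = make_cohort({"f": [1.0, 2.0, 5.0, 3.0, 10.0, 7.0]})
    cohort.data.loc[3, "laterality"] = "L"  # second woman now has two lefts
    with pytest.warns(UserWarning, match="missing one side"):
        result = iwv(cohort, reference_frame(0.0, 10.0), (40, 60))
    # W1 dropped; median of {|1-2|, |10-7|} = 2 over width 10
    assert result["f"] == pytest.approx(0.2)


def test_woman_qualifies_with_one_side_in_band():
    cohort = make_cohort(
        {"f": [1.0, 2.0, 5.0, 3.0]}, thickness=[45.0, 70.0, 70.0, 72.0]
    )
    left, right = cohort.bilateral_pairs((40, 60))
    assert list(left.index) == ["W0"]  # W1 has neither side in band


# ---------------------------------------------------------------------------
# CMV
# ---------------------------------------------------------------------------

def test_cmv_values():
    assert cmv(0.0, 0.0) == 0.0
    assert cmv(0.3, 0.4) == pytest.approx(0.5, abs=1e-12)
    assert cmv(0.15, 0.0) == pytest.approx(0.15, abs=1e-15)


def test_cmv_rejects_negative_inputs():
    with pytest.raises(ValueError, match="nonnegative"):
        cmv(-0.1, 0.2)


def test_cmv_triangle_bounds(rng):
    a = rng.uniform(0, 2, size=200)
    b = rng.uniform(0, 2, size=200)
    c = cmv(a, b)
    assert np.all(c >= np.maximum(a, b) - 1e-12)
    assert np.all(c <= a + b + 1e-12)


# ---------------------------------------------------------------------------
# invariances and monotonicity
# ---------------------------------------------------------------------------

def test_affine_invariance_of_all_metrics():
    ph, co, _ = simulate_robustness_tables(n_features=5, n_women=30, seed=2)
    res1 = RobustnessModel(ph, co).fit().table
    a, b = 3.7, -12.0
    feats = [c for c in ph.columns if c.startswith("f")]
    ph2, co2 = ph.copy(), co.copy()
    ph2[feats] = a * ph2[feats] + b
    co2[feats] = a * co2[feats] + b
    res2 = RobustnessModel(ph2, co2).fit().table
    for metric in ("iav", "iwv", "cmv"):
        np.testing.assert_allclose(res1[metric], res2[metric], rtol=1e-9)


def test_adding_an_acquisition_never_decreases_iav():
    ref = reference_frame(0.0, 10.0)
    base = iav(make_phantom({"f": [1.0, 2.0, 3.0]}), ref)["f"]
    for extra in (-5.0, 2.5, 9.0):
        grown = iav(make_phantom({"f": [1.0, 2.0, 3.0, extra]}), ref)["f"]
        assert grown >= base - 1e-15


def test_widening_clinical_spread_never_increases_metrics():
    phantom = make_phantom({"f": [1.0, 2.0, 3.0]})
    cohort = make_cohort({"f": [1.0, 2.0, 5.0, 3.0, 10.0, 7.0]})
    narrow, wide = reference_frame(2.0, 8.0), reference_frame(0.0, 20.0)
    assert iav(phantom, wide)["f"] <= iav(phantom, narrow)["f"]
    assert iwv(cohort, wide, (40, 60))["f"] <= iwv(cohort, narrow, (40, 60))["f"]


def test_cmv_rank_recovers_true_physics_sensitivity():
    ph, co, truth = simulate_robustness_tables(
        n_features=60, n_acquisitions=12, n_women=100, seed=7
    )
    res = RobustnessModel(ph, co).fit()
    rho = spearmanr(res.cmv, truth.sensitivity.reindex(res.cmv.index)).statistic
    assert rho > 0.8


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def test_threshold_count_matches_direct_comparison():
    ph, co, _ = simulate_robustness_tables(n_features=10, n_women=30, seed=5)
    res = RobustnessModel(ph, co).fit()
    expected = sum(1 for v in res.table["cmv"] if v <= 0.15)
    assert len(res.below_threshold(0.15)) == expected
    summary = res.metric_summary()
    assert set(summary.index) == {"iav", "iwv", "cmv"}
    assert (summary["min"] <= summary["median"]).all()


def test_all_zero_features_fall_below_any_positive_threshold():
    phantom = make_phantom({"f1": [1.0, 1.0], "f2": [2.0, 2.0]})
    cohort = make_cohort(
        {"f1": list(np.arange(30.0)), "f2": list(np.arange(30.0))}
    )
    cohort.data.loc[:, "f1"] = cohort.data["f1"]
    # make sides equal so IWV = 0 while keeping clinical spread
    for f in ("f1", "f2"):
        vals = np.repeat(np.arange(15.0), 2)
        cohort.data[f] = vals
    res = RobustnessModel(phantom, cohort).fit()
    assert len(res.below_threshold(0.01)) == 2
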