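"""Matched CV structure, AUC computation, resampled design, mixed model."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from mammotex import (
    CaseControlEvaluation,
    EvaluationResults,
    RobustnessClasses,
    cv_auc,
    matched_kfold,
    max_features_per_model,
    mixed_model_auc,
    simulate_case_control_features,
)


def class_names(n_per_class: int = 12) -> dict[str, list[str]]:
    names = [f"f{k:03d}" for k in range(4 * n_per_class)]
    return {
        label: names[i * n_per_class : (i + 1) * n_per_class]
        for i, label in enumerate("ABCD")
    }


# ---------------------------------------------------------------------------
# matched k-fold
# ---------------------------------------------------------------------------

def test_fold_composition_115_strata_of_five():
    table, _ = simulate_case_control_features(
        115, 4, ["f0"], signal_features=[], effect_size=0.0, seed=0
    )
    folds = matched_kfold(table, k=5, seed=1)
    for fold in range(5):
        sel = table[folds == fold]
        assert sel["is_case"].sum() == 23
        assert (sel["is_case"] == 0).sum() == 92


def test_strata_never_straddle_folds():
    table, _ = simulate_case_control_features(
        30, 4, ["f0"], signal_features=[], effect_size=0.0, seed=0
    )
    folds = matched_kfold(table, k=5, seed=3)
    per_stratum = pd.Series(folds).groupby(table["stratum"]).nunique()
    assert (per_stratum == 1).all()
    # each image held out exactly once
    assert len(folds) == len(table)


def test_k_of_one_rejected():
    table, _ = simulate_case_control_features(
        10, 4, ["f0"], signal_features=[], effect_size=0.0
    )
    with pytest.raises(ValueError, match="k must be >= 2"):
        matched_kfold(table, k=1)


def test_same_seed_same_assignment():
    table, _ = simulate_case_control_features(
        20, 4, ["f0"], signal_features=[], effect_size=0.0
    )
    np.testing.assert_array_equal(
        matched_kfold(table, 5, seed=7), matched_kfold(table, 5, seed=7)
    )


# ---------------------------------------------------------------------------
# events-per-coefficient rule
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_cases,k,epc,expected",
    [(115, 5, 10, 9), (100, 5, 10, 8), (120, 4, 10, 9)],
)
def test_max_features_rule(n_cases, k, epc, expected):
    assert max_features_per_model(n_cases, k, epc) == expected


def test_max_features_zero_warns():
    with pytest.warns(UserWarning, match="no model"):
        assert max_features_per_model(10, 5, 10) == 0


def test_max_features_invalid_inputs():
    with pytest.raises(ValueError):
        max_features_per_model(0, 5, 10)
    with pytest.raises(ValueError):
        max_features_per_model(3, 5, 10)  # fewer cases than folds


# ---------------------------------------------------------------------------
# cross-validated AUC
# ---------------------------------------------------------------------------

def brute_force_auc(case_scores, control_scores) -> float:
    """All case-control pairs: wins + half-ties over total."""
    wins = 0.0
    for cs in case_scores:
        for ns in control_scores:
            wins += 1.0 if cs > ns else (0.5 if cs == ns else 0.0)
    return wins / (len(case_scores) * len(control_scores))


def test_rank_auc_matches_all_pairs_count():
    cases, controls = [0.9, 0.8], [0.7, 0.1]
    y = [1, 1, 0, 0]
    assert brute_force_auc(cases, controls) == 1.0
    assert roc_auc_score(y, cases + controls) == 1.0
    controls2 = [0.85, 0.1]  # one control now outranks the weaker case
    assert brute_force_auc(cases, controls2) == 0.75
    assert roc_auc_score(y, cases + controls2) == 0.75
    controls3 = [0.8, 0.1]  # tie with a case counts half
    assert brute_force_auc(cases, controls3) == 0.875
    assert roc_auc_score(y, cases + controls3) == 0.875


def test_null_features_give_chance_auc():
    table, _ = simulate_case_control_features(
        200, 4, [f"f{k}" for k in range(9)], signal_features=[],
        effect_size=0.0, seed=2,
    )
    folds = matched_kfold(table, 5, seed=0)
    auc = cv_auc(table, [f"f{k}" for k in range(9)], folds)
    assert auc == pytest.approx(0.5, abs=0.06)


def test_perfect_signal_gives_auc_near_one():
    table, _ = simulate_case_control_features(
        50, 4, ["f0"], signal_features=[], effect_size=0.0, seed=3
    )
    table["f0"] = table["is_case"] + 0.001 * np.random.default_rng(0).standard_normal(len(table))
    folds = matched_kfold(table, 5, seed=0)
    assert cv_auc(table, ["f0"], folds) > 0.99


def test_missing_feature_rejected():
    table, _ = simulate_case_control_features(
        10, 4, ["f0"], signal_features=[], effect_size=0.0
    )
    folds = matched_kfold(table, 5, seed=0)
    with pytest.raises(ValueError, match="not in table"):
        cv_auc(table, ["nope"], folds)


# ---------------------------------------------------------------------------
# resampled experiment
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def signal_experiment():
    classes = class_names(12)
    all_names = [n for v in classes.values() for n in v]
    table, _ = simulate_case_control_features(
        115, 4, all_names, signal_features=classes["A"],
        effect_size=0.4, seed=11,
    )
    return table, RobustnessClasses(classes=classes)


def test_default_design_yields_400_records(signal_experiment):
    table, classes = signal_experiment
    res = CaseControlEvaluation(
        table, classes, n_models=10, n_partitions=10, seed=0
    ).fit()
    counts = res.records.groupby("robustness_class").size()
    assert (counts == 100).all()
    assert len(res.records) == 400
    assert res.records["auc"].between(0, 1).all()


def test_minimal_design_yields_one_record_per_class(signal_experiment):
    table, classes = signal_experiment
    res = CaseControlEvaluation(
        table, classes, n_models=1, n_partitions=1, seed=0
    ).fit()
    assert len(res.records) == 4


def test_partitions_identical_across_calls(signal_experiment):
    table, classes = signal_experiment
    ev = CaseControlEvaluation(table, classes, n_models=1, n_partitions=3, seed=5)
    p1, p2 = ev.partitions(), ev.partitions()
    for a, b in zip(p1, p2):
        np.testing.assert_array_equal(a, b)


def test_small_class_rejected(signal_experiment):
    table, _ = signal_experiment
    tiny = RobustnessClasses(
        classes={lbl: [f"f{i:03d}"] for i, lbl in enumerate("ABCD")}
    )
    with pytest.raises(ValueError, match="needs >="):
        CaseControlEvaluation(table, tiny, seed=0)


def test_planted_signal_ranks_class_A_above_D():
    classes = class_names(12)
    all_names = [n for v in classes.values() for n in v]
    wins = 0
    n_rep = 20
    for seed in range(n_rep):
        table, _ = simulate_case_control_features(
            115, 4, all_names, signal_features=classes["A"],
            effect_size=0.4, seed=100 + seed,
        )
        res = CaseControlEvaluation(
            table, RobustnessClasses(classes=classes),
            n_models=4, n_partitions=2, seed=seed,
        ).fit()
        means = res.class_summary()["mean"]
        wins += means["A"] > means["D"]
    assert wins >= 0.95 * n_rep


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def simulate_auc_records(deltas, n_models=10, n_partitions=10, noise=0.01,
                         partition_sd=0.004, seed=0):
    rng = np.random.default_rng(seed)
    part_effect = rng.normal(0.0, partition_sd, size=n_partitions)
    rows = []
    for label, delta in deltas.items():
        for m in range(n_models):
            for p in range(n_partitions):
                rows.append(
                    {
                        "robustness_class": label,
                        "model_index": m,
                        "partition_index": p,
                        "auc": 0.54 + delta + part_effect[p]
                        + rng.normal(0, noise),
                    }
                )
    return pd.DataFrame(rows)


def test_mixed_model_recovers_planted_class_effects():
    deltas = {"A": 0.045, "B": 0.018, "C": 0.022, "D": 0.0}
    records = simulate_auc_records(deltas, seed=1)
    fit = mixed_model_auc(records)
    assert fit.reference == "D"
    for label in "ABC":
        coef = fit.params.loc[label, "coef"]
        se = fit.params.loc[label, "se"]
        assert abs(coef - deltas[label]) < 2 * se
    assert fit.overall_p < 0.05
    # CI consistent with SE
    np.testing.assert_allclose(
        fit.params["ci_high"] - fit.params["ci_low"],
        2 * 1.959964 * fit.params["se"],
        rtol=1e-3,
    )


def test_identical_aucs_give_zero_effects():
    records = simulate_auc_records(
        {l: 0.0 for l in "ABCD"}, noise=0.0, partition_sd=0.0
    )
    fit = mixed_model_auc(records)
    assert np.allclose(fit.params["coef"], 0.0, atol=1e-10)
    assert fit.random_effect_sd == pytest.approx(0.0, abs=1e-6)
    assert not fit.used_random_effect  # singular variance -> OLS fallback


def test_permuted_class_labels_give_uniform_pvalues():
    pvals = []
    for seed in range(20):
        records = simulate_auc_records(
            {l: 0.0 for l in "ABCD"}, n_models=5, n_partitions=5,
            noise=0.01, partition_sd=0.0, seed=seed,
        )
        rng = np.random.default_rng(seed)
        records["robustness_class"] = rng.permutation(
            records["robustness_class"].to_numpy()
        )
        pvals.append(mixed_model_auc(records).overall_p)
    # under the null the overall p-value is approximately uniform
    assert 0.2 < np.mean(pvals) < 0.8
    assert min(pvals) < 0.5 < max(pvals)


def test_evaluation_summary_includes_mixed_model(signal_experiment):
    table, classes = signal_experiment
    res = CaseControlEvaluation(
        table, classes, n_models=2, n_partitions=2, seed=0
    ).fit()
    text = res.summary()
    assert "robustness class" in text
    assert "reference D" in text
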