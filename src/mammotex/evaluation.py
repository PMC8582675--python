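"""Matched case-control evaluation of robustness classes.

For each robustness class, a number of logistic-regression models (each
on a random subset of the class's features) is evaluated by k-fold
cross-validated AUC on a matched case-control table; matching strata
(one case plus its controls) stay intact within folds, and the same
random partitions are reused for every class and model so performance
differences reflect the features, not the folds.  The resulting AUC
records are analysed with a random-intercept linear mixed model, AUC on
robustness class (reference: the least robust class), partition as the
random effect.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .reduction import RobustnessClasses

__all__ = [
    "matched_kfold",
    "max_features_per_model",
    "cv_auc",
    "CaseControlEvaluation",
    "EvaluationResults",
    "MixedModelFit",
    "mixed_model_auc",
]


def _check_table(table: pd.DataFrame) -> None:
    for col in ("stratum", "is_case"):
        if col not in table.columns:
            raise ValueError(f"case-control table missing column {col!r}")
    per_stratum = table.groupby("stratum")["is_case"].sum()
    if not (per_stratum == 1).all():
        bad = per_stratum[per_stratum != 1].index.tolist()
        raise ValueError(f"every stratum must contain exactly one case; bad: {bad[:5]}")


def matched_kfold(
    table: pd.DataFrame, k: int = 5, seed: int = 0
) -> np.ndarray:
    """Random fold assignment that keeps matching strata intact.

    Strata (not individual images) are shuffled and dealt into ``k``
    folds; returns an integer fold id per table row.  Fold sizes differ
    by at most one stratum when the stratum count is not divisible by k.
    """
    if k < 2:
        raise ValueError("k must be >= 2 (no held-out data otherwise)")
    _check_table(table)
    strata = np.asarray(sorted(table["stratum"].unique()))
    if k > len(strata):
        raise ValueError(f"k={k} exceeds the {len(strata)} available strata")
    if len(strata) % k != 0:
        warnings.warn(
            f"{len(strata)} strata not divisible by k={k}; fold sizes will "
            "differ by one stratum",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 6]))
    shuffled = rng.permutation(strata)
    fold_of = {s: i % k for i, s in enumerate(shuffled)}
    return table["stratum"].map(fold_of).to_numpy()


def max_features_per_model(
    n_cases: int, k: int, events_per_coefficient: int = 10
) -> int:
    """Largest feature count honouring the events-per-coefficient rule.

    With k-fold CV, each model trains on n_cases * (k-1)/k cases; one
    feature costs one coefficient, and the rule of thumb demands
    ``events_per_coefficient`` cases per coefficient.
    """
    if n_cases <= 0 or k <= 0 or events_per_coefficient <= 0:
        raise ValueError("n_cases, k and events_per_coefficient must be positive")
    if n_cases < k:
        raise ValueError("need at least one case per fold")
    n = math.floor(n_cases * (k - 1) / k / events_per_coefficient)
    if n == 0:
        warnings.warn(
            "events-per-coefficient rule permits no features; no model "
            "is possible at this design",
            stacklevel=2,
        )
    return n


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> LogisticRegression:
    """Maximum-likelihood logistic fit; ridge-stabilised under separation."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        model = LogisticRegression(penalty=None, max_iter=500, solver="lbfgs")
        model.fit(x, y)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            # likely complete separation: tiny ridge keeps the design balanced
            warnings.warn(
                "logistic fit did not converge (possible separation); "
                "refitting with a ridge penalty of 1e-4 * n",
                stacklevel=3,
            )
            model = LogisticRegression(
                penalty="l2", C=1.0 / (1e-4 * len(y)), max_iter=2000,
                solver="lbfgs",
            )
            model.fit(x, y)
    return model


def cv_auc(
    table: pd.DataFrame, features: list[str], partition: np.ndarray
) -> float:
    """Mean held-out AUC of a logistic model over the folds of a partition.

    Per fold: standardise features on the training folds, fit logistic
    regression, score the held-out images, compute the held-out AUC by
    the rank statistic; the unweighted mean over folds is returned.
    """
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features not in table: {missing[:5]}")
    x_all = table[features].to_numpy(dtype=float)
    if np.isnan(x_all).any():
        raise ValueError("case-control table contains missing feature values")
    y_all = table["is_case"].to_numpy(dtype=int)
    aucs = []
    for fold in np.unique(partition):
        test = partition == fold
        train = ~test
        assert y_all[test].min() != y_all[test].max(), (
            "single-class held-out fold; impossible under matched folding"
        )
        mu = x_all[train].mean(axis=0)
        sd = x_all[train].std(axis=0)
        sd[sd == 0] = 1.0
        x_train = (x_all[train] - mu) / sd
        x_test = (x_all[test] - mu) / sd
        model = _fit_logistic(x_train, y_all[train])
        scores = model.decision_function(x_test)
        aucs.append(roc_auc_score(y_all[test], scores))
    return float(np.mean(aucs))


class CaseControlEvaluation:
    """Resampled per-class evaluation design on a matched table.

    Parameters
    ----------
    table
        Matched feature table with ``stratum`` and ``is_case`` columns.
    classes
        Robustness classes (label -> feature names); every class needs
        at least ``features_per_model`` features.
    n_models, n_partitions
        Random feature subsets per class and random fold partitions
        (default 10 x 10 -> 100 AUC records per class).
    features_per_model
        Defaults to the events-per-coefficient rule.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        classes: RobustnessClasses,
        n_models: int = 10,
        n_partitions: int = 10,
        k: int = 5,
        features_per_model: int | None = None,
        events_per_coefficient: int = 10,
        seed: int = 0,
    ):
        _check_table(table)
        n_cases = int(table["is_case"].sum())
        if features_per_model is None:
            features_per_model = max_features_per_model(
                n_cases, k, events_per_coefficient
            )
        if features_per_model < 1:
            raise ValueError("features_per_model must be >= 1")
        for label, feats in classes.classes.items():
            if len(feats) < features_per_model:
                raise ValueError(
                    f"class {label} has {len(feats)} features; "
                    f"needs >= {features_per_model}"
                )
        self.table = table.reset_index(drop=True)
        self.classes = classes
        self.n_models = n_models
        self.n_partitions = n_partitions
        self.k = k
        self.features_per_model = features_per_model
        self.seed = int(seed)

    def partitions(self) -> list[np.ndarray]:
        """The shared fold partitions, identical across classes and models."""
        return [
            matched_kfold(self.table, self.k, seed=self._partition_seed(p))
            for p in range(self.n_partitions)
        ]

    def _partition_seed(self, p: int) -> int:
        return int(
            np.random.SeedSequence([self.seed, 7, p]).generate_state(1)[0]
            % (2**31)
        )

    def _model_features(self, class_index: int, model_index: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, 8, class_index, model_index])
        )

    def fit(self) -> "EvaluationResults":
        partitions = self.partitions()
        records = []
        for c_idx, (label, feats) in enumerate(self.classes.classes.items()):
            for m in range(self.n_models):
                rng = self._model_features(c_idx, m)
                subset = list(
                    rng.choice(feats, size=self.features_per_model, replace=False)
                )
                for p_idx, partition in enumerate(partitions):
                    auc = cv_auc(self.table, subset, partition)
                    records.append(
                        {
                            "robustness_class": label,
                            "model_index": m,
                            "partition_index": p_idx,
                            "auc": auc,
                        }
                    )
        return EvaluationResults(pd.DataFrame(records), self)


class EvaluationResults:
    """AUC records of the resampled design plus derived summaries."""

    def __init__(self, records: pd.DataFrame, design: CaseControlEvaluation | None = None):
        self.records = records
        self.design = design

    def class_summary(self) -> pd.DataFrame:
        g = self.records.groupby("robustness_class")["auc"]
        return pd.DataFrame({"mean": g.mean(), "sd": g.std(), "n": g.size()})

    def mixed_model(self, reference: str | None = None) -> "MixedModelFit":
        return mixed_model_auc(self.records, reference=reference)

    def summary(self) -> str:
        lines = [
            "Cross-validated AUC by robustness class",
            "=" * 45,
            self.class_summary().to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            self.mixed_model().summary(),
        ]
        return "\n".join(lines)

    def plot_box(self, path: str) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        labels = sorted(self.records["robustness_class"].unique())
        data = [
            self.records.loc[self.records["robustness_class"] == c, "auc"]
            for c in labels
        ]
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.boxplot(data, tick_labels=labels)
        ax.set_xlabel("robustness class (A = most robust)")
        ax.set_ylabel("cross-validated AUC")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)


@dataclass
class MixedModelFit:
    """Fixed effects of AUC on robustness class with a partition intercept."""

    params: pd.DataFrame  # coef, se, ci_low, ci_high, p per non-reference class
    reference: str
    random_effect_sd: float
    overall_p: float
    used_random_effect: bool
    converged: bool

    def coefficient(self, label: str) -> float:
        return float(self.params.loc[label, "coef"])

    def summary(self) -> str:
        lines = [
            f"Linear mixed model: auc ~ class (reference {self.reference}), "
            "random intercept per partition",
            self.params.to_string(float_format=lambda v: f"{v:.4f}"),
            f"random-effect SD: {self.random_effect_sd:.4f}"
            + ("" if self.used_random_effect else " (dropped: singular)"),
            f"overall p (all class effects zero): {self.overall_p:.3g}",
        ]
        return "\n".join(lines)


def mixed_model_auc(
    records: pd.DataFrame, reference: str | None = None
) -> MixedModelFit:
    """Random-intercept linear mixed model of AUC on robustness class.

    REML fit with Wald tests; the reference level defaults to the last
    class label in sort order (the least robust, D, in the standard
    design).  If the random-effect variance is singular the model is
    refit without it (plain OLS), flagged in the result.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    labels = sorted(records["robustness_class"].unique())
    if len(labels) < 2:
        raise ValueError("need >= 2 classes")
    if records["partition_index"].nunique() < 2:
        raise ValueError("need >= 2 partitions")
    reference = reference or labels[-1]
    data = records.rename(columns={"robustness_class": "cls"}).copy()
    formula = f"auc ~ C(cls, Treatment('{reference}'))"
    used_random = True
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm(
                formula, data=data, groups=data["partition_index"]
            ).fit(reml=True)
            re_var = float(np.squeeze(fit.cov_re.to_numpy()))
            if not np.isfinite(re_var) or re_var <= 1e-12:
                raise ValueError("singular random-effect variance")
        except Exception:
            used_random = False
            fit = smf.ols(formula, data=data).fit()
            re_var = 0.0
        converged = bool(getattr(fit, "converged", True))
    rows = {}
    term_names = []
    for label in labels:
        if label == reference:
            continue
        term = f"C(cls, Treatment('{reference}'))[T.{label}]"
        term_names.append(term)
        ci = fit.conf_int().loc[term]
        rows[label] = {
            "coef": fit.params[term],
            "se": fit.bse[term],
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues[term],
        }
    wald = fit.wald_test(
        " = 0, ".join(term_names) + " = 0", scalar=True
    )
    params = pd.DataFrame(rows).T
    params.index.name = "robustness_class"
    return MixedModelFit(
        params=params,
        reference=reference,
        random_effect_sd=float(np.sqrt(re_var)),
        overall_p=float(wald.pvalue),
        used_random_effect=used_random,
        converged=converged,
    )
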