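"""Dimensionality reduction and robustness-quartile classes.

Three steps:

1. *moment filter* -- drop features with heavy-tailed clinical
   distributions (skewness > 6 or non-excess kurtosis > 50; these
   moments are affine-invariant, so Z-scoring beforehand does not change
   them -- both raw and Z-scored moments are reported);
2. *correlation pruning* -- while any surviving pair has |Pearson r|
   above the threshold (default 0.95), resolve the highest-|r| pair by
   excluding its lower-IQR member (catalog order breaks IQR ties);
3. *quartile classes* -- survivors are ranked by CMV; the (count mod 4)
   highest-CMV features are trimmed so the remainder splits into four
   equal contiguous classes A (lowest CMV, most robust) through D.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReductionReport",
    "RobustnessClasses",
    "moment_filter",
    "correlation_prune",
    "make_classes",
    "reduce_features",
]

CLASS_LABELS = ["A", "B", "C", "D"]


@dataclass
class ReductionReport:
    """Disposition of every feature plus the moments that decided it."""

    moments: pd.DataFrame  # skewness, kurtosis, iqr per feature
    disposition: pd.Series  # none | degenerate | skew | kurtosis | correlated | trimmed

    @property
    def survivors(self) -> list[str]:
        return self.disposition.index[self.disposition == "none"].tolist()

    def merge(self, other: "ReductionReport") -> "ReductionReport":
        disp = self.disposition.copy()
        newly = other.disposition[other.disposition != "none"]
        disp.loc[newly.index] = newly
        return ReductionReport(self.moments, disp)

    def to_frame(self) -> pd.DataFrame:
        out = self.moments.copy()
        out["disposition"] = self.disposition
        return out


def moment_filter(
    clinical_features: pd.DataFrame,
    skew_threshold: float = 6.0,
    kurtosis_threshold: float = 50.0,
    feature_names: list[str] | None = None,
) -> ReductionReport:
    """Exclude features with heavy-tailed clinical distributions.

    Skewness is Fisher g1 and kurtosis the non-excess Pearson ratio
    (Gaussian = 3); constant features are excluded as degenerate.
    """
    if feature_names is None:
        feature_names = [
            c
            for c in clinical_features.columns
            if clinical_features[c].dtype.kind in "fi"
            and c not in ("thickness_mm", "kV", "mAs", "stratum", "is_case",
                          "replicate")
        ]
    vals = clinical_features[feature_names].to_numpy(dtype=float)
    if vals.shape[0] < 3:
        raise ValueError("need >= 3 observations per feature")
    sd = vals.std(axis=0)
    with warnings.catch_warnings():
        # constant features trigger scipy precision warnings; they are
        # handled explicitly via the degenerate disposition below
        warnings.simplefilter("ignore", RuntimeWarning)
        skew = stats.skew(vals, axis=0, bias=True)
        kurt = stats.kurtosis(vals, axis=0, fisher=False, bias=True)
        # moments of the Z-scored sample, logged alongside (identical up to
        # floating point because g1 and the kurtosis ratio are affine-invariant)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (vals - vals.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        z_skew = stats.skew(z, axis=0, bias=True)
        z_kurt = stats.kurtosis(z, axis=0, fisher=False, bias=True)
    q25, q75 = np.percentile(vals, [25, 75], axis=0)
    moments = pd.DataFrame(
        {
            "skewness": skew,
            "kurtosis": kurt,
            "z_skewness": z_skew,
            "z_kurtosis": z_kurt,
            "iqr": q75 - q25,
        },
        index=pd.Index(feature_names, name="feature"),
    )
    disposition = pd.Series("none", index=moments.index, name="disposition")
    disposition[moments["skewness"].abs() > skew_threshold] = "skew"
    disposition[
        (disposition == "none") & (moments["kurtosis"] > kurtosis_threshold)
    ] = "kurtosis"
    disposition[sd <= 0] = "degenerate"
    return ReductionReport(moments, disposition)


def correlation_prune(
    clinical_features: pd.DataFrame,
    survivors: list[str],
    r_threshold: float = 0.95,
    catalog_order: list[str] | None = None,
) -> ReductionReport:
    """Greedy pruning of highly correlated feature pairs.

    While any surviving pair has |Pearson r| > ``r_threshold``, the pair
    with the largest |r| is resolved by excluding its lower-IQR member
    (IQR on the raw clinical values); IQR ties exclude the later feature
    in catalog order.  Deterministic and invariant to row order.
    """
    if len(survivors) < 2:
        raise ValueError("need >= 2 surviving features to prune")
    order = {n: i for i, n in enumerate(catalog_order or survivors)}
    vals = clinical_features[survivors]
    corr = vals.corr().abs().to_numpy()
    np.fill_diagonal(corr, 0.0)
    q25, q75 = np.percentile(vals.to_numpy(dtype=float), [25, 75], axis=0)
    iqr = dict(zip(survivors, q75 - q25))
    alive = list(range(len(survivors)))
    excluded: list[str] = []
    while True:
        sub = corr[np.ix_(alive, alive)]
        if sub.size == 0 or sub.max() <= r_threshold:
            break
        i_loc, j_loc = np.unravel_index(np.argmax(sub), sub.shape)
        i, j = alive[i_loc], alive[j_loc]
        ni, nj = survivors[i], survivors[j]
        if iqr[ni] < iqr[nj]:
            drop = i
        elif iqr[nj] < iqr[ni]:
            drop = j
        else:  # IQR tie: drop the later catalog entry
            drop = i if order.get(ni, 0) > order.get(nj, 0) else j
        alive.remove(drop)
        excluded.append(survivors[drop])
    moments = pd.DataFrame(
        {"iqr": [iqr[n] for n in survivors]},
        index=pd.Index(survivors, name="feature"),
    )
    disposition = pd.Series("none", index=moments.index, name="disposition")
    disposition[excluded] = "correlated"
    return ReductionReport(moments, disposition)


@dataclass
class RobustnessClasses:
    """Equal-sized robustness quartiles A (lowest CMV) through D."""

    classes: dict[str, list[str]]
    cmv_ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    trimmed: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = {len(v) for v in self.classes.values()}
        if len(sizes) > 1:
            raise ValueError(f"classes must be equal-sized, got {sizes}")

    @property
    def labels(self) -> list[str]:
        return list(self.classes)

    def size(self) -> int:
        return len(next(iter(self.classes.values())))

    def to_json(self, path: str) -> None:
        payload = {
            "classes": self.classes,
            "cmv_ranges": {k: list(v) for k, v in self.cmv_ranges.items()},
            "trimmed": self.trimmed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "RobustnessClasses":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            classes=payload["classes"],
            cmv_ranges={k: tuple(v) for k, v in payload["cmv_ranges"].items()},
            trimmed=payload.get("trimmed", []),
        )


def make_classes(
    robustness_table: pd.DataFrame, survivors: list[str]
) -> RobustnessClasses:
    """Partition survivors into four equal CMV quartile classes.

    Survivors are sorted ascending by (CMV, feature name) -- the stable
    name tie-break keeps boundaries deterministic -- and the
    ``count mod 4`` highest-CMV features are trimmed first.
    """
    cmv = robustness_table["cmv"] if "cmv" in robustness_table else robustness_table
    cmv = cmv.reindex(survivors).dropna()
    if len(cmv) < 8:
        raise ValueError(
            f"need >= 8 survivors with valid CMV to form quartiles, got {len(cmv)}"
        )
    # name-sort then stable value-sort == ascending (CMV, name) order
    ranked = cmv.loc[sorted(cmv.index)].sort_values(kind="stable")
    n_trim = len(ranked) % 4
    trimmed = ranked.index[len(ranked) - n_trim :].tolist() if n_trim else []
    if trimmed:
        warnings.warn(
            f"trimming {n_trim} highest-CMV features to equalise quartiles",
            stacklevel=2,
        )
        ranked = ranked.iloc[: len(ranked) - n_trim]
    per_class = len(ranked) // 4
    classes: dict[str, list[str]] = {}
    ranges: dict[str, tuple[float, float]] = {}
    for c_idx, label in enumerate(CLASS_LABELS):
        chunk = ranked.iloc[c_idx * per_class : (c_idx + 1) * per_class]
        classes[label] = chunk.index.tolist()
        ranges[label] = (float(chunk.min()), float(chunk.max()))
    return RobustnessClasses(classes=classes, cmv_ranges=ranges, trimmed=trimmed)


def reduce_features(
    clinical_features: pd.DataFrame,
    robustness_table: pd.DataFrame,
    feature_names: list[str] | None = None,
    skew_threshold: float = 6.0,
    kurtosis_threshold: float = 50.0,
    r_threshold: float = 0.95,
) -> tuple[ReductionReport, RobustnessClasses]:
    """Full reduction pipeline: moments -> correlation -> quartiles."""
    report = moment_filter(
        clinical_features, skew_threshold, kurtosis_threshold, feature_names
    )
    pruned = correlation_prune(
        clinical_features,
        report.survivors,
        r_threshold,
        catalog_order=list(report.disposition.index),
    )
    report = report.merge(pruned)
    classes = make_classes(robustness_table, report.survivors)
    if classes.trimmed:
        disp = report.disposition.copy()
        disp.loc[classes.trimmed] = "trimmed"
        report = ReductionReport(report.moments, disp)
    return report, classes
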