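"""Feature robustness statistics: IAV, IWV and CMV.

For feature k, with p_ik the value in phantom acquisition i (i = 1..m)
and c5_k, c95_k the 5th/95th percentiles of the feature over all clinical
breast images in the thickness band:

    IAV_k = (max_i p_ik - min_i p_ik) / (c95_k - c5_k)

the imaging-acquisition variation -- how far varying the acquisition
physics moves a fixed object's feature value, in units of the middle-90%
width of the inter-woman clinical distribution;

    IWV_k = median_j |l_jk - r_jk| / (c95_k - c5_k)

the intra-woman variation -- the median absolute left-right difference
over the q women with at least one breast in the thickness band, on the
same scale; and

    CMV_k = sqrt(IAV_k^2 + IWV_k^2)

the composite measure of variation, the Euclidean distance of feature k
from the origin of the IAV x IWV plane.  Low CMV marks a robust feature.

Percentiles use linear interpolation between order statistics (the
numpy default); degenerate clinical widths (c95 = c5) yield missing
metrics, never infinities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import BilateralCohortTable, PhantomFeatureTable

__all__ = [
    "clinical_reference",
    "iav",
    "iwv",
    "cmv",
    "RobustnessModel",
    "RobustnessResults",
]

DEFAULT_THICKNESS_BAND = (40.0, 60.0)


def clinical_reference(
    cohort: BilateralCohortTable,
    thickness_band_mm: tuple[float, float] = DEFAULT_THICKNESS_BAND,
    min_images: int = 20,
) -> pd.DataFrame:
    """Per-feature (c5, c95) over clinical breast images in the band.

    Both sides of each woman count as separate images.  Features whose
    width c95 - c5 vanishes are flagged degenerate.
    """
    qualifying = cohort.qualifying_images(thickness_band_mm)
    if len(qualifying) < min_images:
        raise ValueError(
            f"only {len(qualifying)} breast images in thickness band "
            f"{thickness_band_mm}; need >= {min_images} for stable percentiles"
        )
    vals = qualifying[cohort.feature_names].to_numpy(dtype=float)
    c5 = np.percentile(vals, 5, axis=0)
    c95 = np.percentile(vals, 95, axis=0)
    ref = pd.DataFrame(
        {"c5": c5, "c95": c95}, index=pd.Index(cohort.feature_names, name="feature")
    )
    ref["degenerate"] = ref["c95"] <= ref["c5"]
    return ref


def iav(phantom: PhantomFeatureTable, reference: pd.DataFrame) -> pd.Series:
    """Imaging-acquisition variation per feature.

    Range of phantom values across acquisitions divided by the clinical
    middle-90% width; missing where the reference is degenerate.
    """
    if phantom.n_acquisitions < 2:
        raise ValueError("IAV requires >= 2 phantom acquisitions")
    vals = phantom.values()
    rng = vals.max(axis=0) - vals.min(axis=0)
    width = (reference["c95"] - reference["c5"]).reindex(vals.columns)
    out = rng / width
    out[reference["degenerate"].reindex(vals.columns).fillna(True)] = np.nan
    out.name = "iav"
    return out


def iwv(
    cohort: BilateralCohortTable,
    reference: pd.DataFrame,
    thickness_band_mm: tuple[float, float] = DEFAULT_THICKNESS_BAND,
) -> pd.Series:
    """Intra-woman variation per feature.

    Median absolute left-right difference over women with at least one
    breast in the thickness band (both sides must exist to form the
    difference), divided by the clinical middle-90% width.
    """
    left, right = cohort.bilateral_pairs(thickness_band_mm)
    if len(left) < 2:
        raise ValueError(
            f"only {len(left)} women qualify for the bilateral analysis; need >= 2"
        )
    med = (left - right).abs().median(axis=0)
    width = (reference["c95"] - reference["c5"]).reindex(med.index)
    out = med / width
    out[reference["degenerate"].reindex(med.index).fillna(True)] = np.nan
    out.name = "iwv"
    return out


def cmv(iav_k, iwv_k):
    """Composite measure of variation: Euclidean norm of (IAV, IWV).

    Accepts scalars or aligned vectors; negative inputs are rejected,
    missing inputs propagate to missing output.
    """
    a = np.asarray(iav_k, dtype=float)
    b = np.asarray(iwv_k, dtype=float)
    if np.any(a[~np.isnan(a)] < 0) or np.any(b[~np.isnan(b)] < 0):
        raise ValueError("IAV and IWV must be nonnegative")
    out = np.hypot(a, b)
    if np.isscalar(iav_k) and np.isscalar(iwv_k):
        return float(out)
    if isinstance(iav_k, pd.Series):
        return pd.Series(out, index=iav_k.index, name="cmv")
    return out


class RobustnessModel:
    """Joint robustness analysis of a phantom series and a bilateral cohort.

    Parameters
    ----------
    phantom
        Feature table of repeated phantom acquisitions (or a DataFrame
        with kV/mAs/replicate metadata plus feature columns).
    cohort
        Long feature table of the bilateral clinical cohort (or a
        DataFrame with subject_id/laterality/thickness_mm plus features).
    thickness_band_mm
        Clinical thickness band defining the reference population,
        default (40, 60) mm, matching a 50 mm phantom +/- 10 mm.
    """

    def __init__(
        self,
        phantom: PhantomFeatureTable | pd.DataFrame,
        cohort: BilateralCohortTable | pd.DataFrame,
        thickness_band_mm: tuple[float, float] = DEFAULT_THICKNESS_BAND,
        min_reference_images: int = 20,
    ):
        if isinstance(phantom, pd.DataFrame):
            phantom = PhantomFeatureTable.from_dataframe(phantom)
        if isinstance(cohort, pd.DataFrame):
            cohort = BilateralCohortTable.from_dataframe(cohort)
        common = [f for f in phantom.feature_names if f in set(cohort.feature_names)]
        if not common:
            raise ValueError("phantom and cohort share no feature columns")
        self.phantom = phantom
        self.cohort = cohort
        self.feature_names = common
        self.thickness_band_mm = tuple(thickness_band_mm)
        self.min_reference_images = min_reference_images

    def fit(self) -> "RobustnessResults":
        ref = clinical_reference(
            self.cohort, self.thickness_band_mm, self.min_reference_images
        )
        iav_k = iav(self.phantom, ref)
        iwv_k = iwv(self.cohort, ref, self.thickness_band_mm)
        table = pd.DataFrame(
            {
                "iav": iav_k.reindex(self.feature_names),
                "iwv": iwv_k.reindex(self.feature_names),
            },
            index=pd.Index(self.feature_names, name="feature"),
        )
        table["cmv"] = cmv(table["iav"], table["iwv"])
        table["c5"] = ref["c5"].reindex(self.feature_names)
        table["c95"] = ref["c95"].reindex(self.feature_names)
        table["degenerate"] = ref["degenerate"].reindex(self.feature_names)
        return RobustnessResults(table, self)


class RobustnessResults:
    """Per-feature IAV/IWV/CMV with the clinical reference percentiles."""

    def __init__(self, table: pd.DataFrame, model: RobustnessModel | None = None):
        self.table = table
        self.model = model

    @property
    def cmv(self) -> pd.Series:
        return self.table["cmv"]

    def valid(self) -> pd.DataFrame:
        return self.table[~self.table["degenerate"]]

    def below_threshold(self, threshold: float = 0.15) -> pd.Index:
        """Features whose CMV is at or below the threshold."""
        v = self.valid()
        return v.index[v["cmv"] <= threshold]

    def metric_summary(self) -> pd.DataFrame:
        """min/max/median/mean/IQR of each metric over valid features."""
        v = self.valid()
        rows = {}
        for metric in ("iav", "iwv", "cmv"):
            x = v[metric].dropna()
            q25, q75 = x.quantile([0.25, 0.75]) if len(x) else (np.nan, np.nan)
            rows[metric] = {
                "min": x.min(),
                "max": x.max(),
                "median": x.median(),
                "mean": x.mean(),
                "iqr_low": q25,
                "iqr_high": q75,
            }
        return pd.DataFrame(rows).T

    def scatter_frame(self) -> pd.DataFrame:
        """Plot-ready (feature, IAV, IWV, CMV) data for the scatter view."""
        v = self.valid()
        return v[["iav", "iwv", "cmv"]].reset_index()

    def summary(self, threshold: float = 0.15) -> str:
        n_valid = int((~self.table["degenerate"]).sum())
        n_below = len(self.below_threshold(threshold))
        lines = [
            "Feature robustness (IAV/IWV/CMV)",
            "=" * 40,
            f"features analysed:      {len(self.table)}",
            f"valid (non-degenerate): {n_valid}",
            f"CMV <= {threshold:g}:           {n_below} "
            f"({100.0 * n_below / max(n_valid, 1):.0f}%)",
            "",
            self.metric_summary().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def plot_scatter(
        self, path: str, threshold: float | None = 0.15
    ) -> None:
        """IAV x IWV scatter with an optional circular CMV threshold arc."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        v = self.valid()
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(v["iav"], v["iwv"], s=12, alpha=0.7)
        if threshold is not None:
            t = np.linspace(0, np.pi / 2, 100)
            ax.plot(threshold * np.cos(t), threshold * np.sin(t), "r--",
                    label=f"CMV = {threshold:g}")
            ax.legend()
        ax.set_xlabel("IAV")
        ax.set_ylabel("IWV")
        ax.set_title("Feature robustness")
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
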