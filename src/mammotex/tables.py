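"""Feature-table containers for the robustness analysis.

Both containers are thin, validated wrappers around pandas DataFrames
with a documented schema; metadata columns come first, feature columns
follow in catalog order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

__all__ = ["PhantomFeatureTable", "BilateralCohortTable"]

_PHANTOM_META = ["kV", "mAs", "replicate"]
_COHORT_META = ["subject_id", "laterality", "thickness_mm"]


def _feature_columns(df: pd.DataFrame, meta: list[str]) -> list[str]:
    ignore = set(meta) | {"view", "subject_id", "laterality", "thickness_mm",
                          "kV", "mAs", "replicate"}
    return [c for c in df.columns if c not in ignore]


@dataclass
class PhantomFeatureTable:
    """m acquisitions x K features; rows are repeated phantom exposures."""

    data: pd.DataFrame
    feature_names: list[str]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, feature_names: list[str] | None = None
    ) -> "PhantomFeatureTable":
        if feature_names is None:
            feature_names = _feature_columns(df, _PHANTOM_META)
        t = cls(data=df.reset_index(drop=True), feature_names=list(feature_names))
        t.validate()
        return t

    def validate(self) -> None:
        if len(self.data) < 2:
            raise ValueError(
                "phantom table needs >= 2 acquisitions (range is undefined "
                "as a variation measure otherwise)"
            )
        missing = [c for c in self.feature_names if c not in self.data.columns]
        if missing:
            raise ValueError(f"phantom table missing feature columns: {missing[:5]}")
        if self.data[self.feature_names].isna().any().any():
            raise ValueError("phantom table contains missing feature values")

    @property
    def n_acquisitions(self) -> int:
        return len(self.data)

    def values(self) -> pd.DataFrame:
        return self.data[self.feature_names]


@dataclass
class BilateralCohortTable:
    """Long table of individual breast images: one row per (woman, side)."""

    data: pd.DataFrame
    feature_names: list[str]

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, feature_names: list[str] | None = None
    ) -> "BilateralCohortTable":
        for col in _COHORT_META:
            if col not in df.columns:
                raise ValueError(f"cohort table missing column {col!r}")
        if feature_names is None:
            feature_names = _feature_columns(df, _COHORT_META)
        t = cls(data=df.reset_index(drop=True), feature_names=list(feature_names))
        t.validate()
        return t

    def validate(self) -> None:
        if self.data["subject_id"].nunique() < 2:
            raise ValueError("cohort needs >= 2 women")
        bad = set(self.data["laterality"]) - {"L", "R"}
        if bad:
            raise ValueError(f"laterality must be L or R, got {sorted(bad)}")

    def qualifying_images(
        self, thickness_band_mm: tuple[float, float]
    ) -> pd.DataFrame:
        """Individual breast images with thickness inside the band."""
        lo, hi = thickness_band_mm
        sel = self.data["thickness_mm"].between(lo, hi)
        return self.data.loc[sel]

    def bilateral_pairs(
        self, thickness_band_mm: tuple[float, float] | None = None
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(left, right) frames aligned by woman.

        A woman qualifies when at least one side's thickness is in the
        band (every woman when band is None); women missing a side are
        excluded with a warning since a left-right difference cannot be
        formed for them.
        """
        df = self.data
        if thickness_band_mm is not None:
            lo, hi = thickness_band_mm
            in_band = df["thickness_mm"].between(lo, hi)
            ok_women = df.loc[in_band, "subject_id"].unique()
            df = df[df["subject_id"].isin(ok_women)]
        counts = df.groupby("subject_id")["laterality"].nunique()
        incomplete = counts[counts < 2].index.tolist()
        if incomplete:
            warnings.warn(
                f"excluding {len(incomplete)} women missing one side "
                f"from the bilateral analysis",
                stacklevel=2,
            )
            df = df[~df["subject_id"].isin(incomplete)]
        left = (
            df[df["laterality"] == "L"]
            .drop_duplicates("subject_id")
            .set_index("subject_id")
            .sort_index()
        )
        right = (
            df[df["laterality"] == "R"]
            .drop_duplicates("subject_id")
            .set_index("subject_id")
            .sort_index()
        )
        return left[self.feature_names], right[self.feature_names]
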