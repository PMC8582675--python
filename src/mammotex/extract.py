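"""Lattice feature extraction: per-window values averaged over the breast.

For each catalog feature, the value reported for an image is the
unweighted mean of the per-window values over all lattice windows that
survive the mask-coverage filter.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog, default_catalog
from .lattice import LatticeSpec, Window, make_lattice
from .records import ImageRecord
from .window_features import compute_window_features

__all__ = ["extract_features", "extract_feature_table", "render_heatmap"]

META_COLUMNS = ["subject_id", "laterality", "view", "thickness_mm", "kV", "mAs"]


def _window_matrix(
    image: ImageRecord,
    windows: list[Window],
    catalog: FeatureCatalog,
    families: list[str] | None,
) -> np.ndarray:
    names = (
        catalog.names
        if families is None
        else [n for n in catalog.names if catalog.family_of(n) in families]
    )
    rows = np.empty((len(windows), len(names)))
    for w_idx, win in enumerate(windows):
        vals = compute_window_features(image.pixels[win.slices()], families)
        rows[w_idx] = [vals[n] for n in names]
    return rows


def extract_features(
    image: ImageRecord,
    catalog: FeatureCatalog | None = None,
    spec: LatticeSpec | None = None,
) -> pd.Series:
    """Extract the full feature vector of one image.

    Returns a Series indexed by catalog feature names.  If no lattice
    window survives the coverage filter, a warning is issued and an
    all-NaN vector is returned (missing, never silently zero).
    """
    catalog = catalog or default_catalog()
    spec = spec or LatticeSpec()
    windows = make_lattice(image.mask, spec, image.pixel_spacing_mm)
    if not windows:
        warnings.warn(
            f"no lattice window meets coverage >= {spec.min_mask_coverage} "
            f"for subject {image.subject_id!r}; returning missing values",
            stacklevel=2,
        )
        return pd.Series(np.nan, index=catalog.names)
    rows = _window_matrix(image, windows, catalog, None)
    return pd.Series(rows.mean(axis=0), index=catalog.names)


def extract_feature_table(
    images: list[ImageRecord],
    catalog: FeatureCatalog | None = None,
    spec: LatticeSpec | None = None,
) -> pd.DataFrame:
    """Feature table for a list of images: metadata columns then features."""
    catalog = catalog or default_catalog()
    records = []
    for img in images:
        row = {
            "subject_id": img.subject_id,
            "laterality": img.laterality,
            "view": img.view,
            "thickness_mm": img.thickness_mm,
            "kV": img.kv,
            "mAs": img.mas,
        }
        row.update(extract_features(img, catalog, spec).to_dict())
        records.append(row)
    return pd.DataFrame(records, columns=META_COLUMNS + catalog.names)


def render_heatmap(
    image: ImageRecord,
    feature_name: str,
    spec: LatticeSpec | None = None,
    catalog: FeatureCatalog | None = None,
    out_png: str | None = None,
) -> np.ndarray:
    """Per-window map of one feature aligned to the lattice geometry.

    Returns a 2D grid (lattice rows x lattice cols) with the feature
    value of each surviving window and NaN where windows were dropped.
    """
    catalog = catalog or default_catalog()
    spec = spec or LatticeSpec()
    if feature_name not in catalog:
        raise KeyError(f"unknown feature name: {feature_name!r}")
    family = catalog.family_of(feature_name)
    windows = make_lattice(image.mask, spec, image.pixel_spacing_mm)
    if not windows:
        return np.full((0, 0), np.nan)
    side = windows[0].side
    r0s = sorted({w.row0 for w in windows})
    c0s = sorted({w.col0 for w in windows})
    rmin, cmin = min(r0s), min(c0s)
    n_rows = (max(r0s) - rmin) // side + 1
    n_cols = (max(c0s) - cmin) // side + 1
    grid = np.full((n_rows, n_cols), np.nan)
    for win in windows:
        vals = compute_window_features(image.pixels[win.slices()], [family])
        grid[(win.row0 - rmin) // side, (win.col0 - cmin) // side] = vals[
            feature_name
        ]
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        im = ax.imshow(grid, cmap="inferno")
        fig.colorbar(im, ax=ax, label=feature_name)
        ax.set_title(feature_name)
        fig.savefig(out_png, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return grid
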