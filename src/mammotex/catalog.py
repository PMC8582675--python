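"""Catalog of the 341-feature lattice texture bank.

The bank comprises eight feature families computed inside square lattice
windows: first-order grey-level histogram statistics, grey-level
co-occurrence (Haralick-style) statistics, grey-level run-length
statistics, two fractal descriptors, rotation-invariant local binary
pattern frequencies, Laws texture-energy statistics, co-occurrence
statistics of Laws response maps, and Gabor wavelet magnitude statistics.

Family sizes are 12 / 7 / 7 / 2 / 36 / 125 / 120 / 32, i.e. 341 features
in total.  The catalog fixes the canonical feature order used by every
feature table in the package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

__all__ = [
    "CatalogEntry",
    "FeatureCatalog",
    "default_catalog",
    "FAMILY_SIZES",
]

FAMILY_SIZES = {
    "histogram": 12,
    "cooccurrence": 7,
    "runlength": 7,
    "fractal": 2,
    "lbp": 36,
    "laws": 125,
    "laws_cooccurrence": 120,
    "gabor": 32,
}

HISTOGRAM_STATS = [
    "mean", "sd", "skewness", "kurtosis", "energy", "entropy",
    "min", "max", "median", "p05", "p95", "iqr",
]

#: Haralick-style statistics of the grey-level co-occurrence matrix.
GLCM_STATS = [
    "energy", "contrast", "correlation", "homogeneity", "entropy",
    "cluster_shade", "cluster_prominence",
]

#: Classic Galloway/Chu run-length statistics.
RUNLENGTH_STATS = ["sre", "lre", "gln", "rln", "rp", "lgre", "hgre"]

FRACTAL_STATS = ["box_dim", "psd_beta"]

#: 1-D Laws filters (level, edge, spot, wave, ripple).
LAWS_1D = ["L5", "E5", "S5", "W5", "R5"]
LAWS_KERNELS = [a + b for a in LAWS_1D for b in LAWS_1D]
LAWS_STATS = ["mean", "meanabs", "sd", "energy", "entropy"]

#: Laws maps carried into co-occurrence analysis: the pure low-pass L5L5
#: map is excluded, leaving 24 maps x 5 statistics = 120 features.
LAWS_GLCM_KERNELS = [k for k in LAWS_KERNELS if k != "L5L5"]
LAWS_GLCM_STATS = ["energy", "contrast", "correlation", "homogeneity", "entropy"]

GABOR_ORIENTATIONS_DEG = [0, 45, 90, 135]
GABOR_WAVELENGTHS_PX = [2, 4, 8, 16]
GABOR_STATS = ["mean", "sd"]


def rotation_invariant_codes(n_bits: int = 8) -> list[int]:
    """Canonical (minimum-over-rotations) codes of ``n_bits``-bit patterns.

    For 8 bits there are exactly 36 such binary necklaces, which is what
    gives the LBP family its size.
    """
    codes = set()
    for value in range(1 << n_bits):
        best = value
        v = value
        for _ in range(n_bits - 1):
            v = ((v >> 1) | (v << (n_bits - 1))) & ((1 << n_bits) - 1)
            best = min(best, v)
        codes.add(best)
    return sorted(codes)


LBP_CODES = rotation_invariant_codes(8)


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    family: str
    index: int


class FeatureCatalog:
    """Ordered, validated collection of named texture features."""

    def __init__(self, entries: list[CatalogEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("catalog feature names must be unique")
        counts: dict[str, int] = {}
        for e in entries:
            counts[e.family] = counts.get(e.family, 0) + 1
        unknown = set(counts) - set(FAMILY_SIZES)
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        self.entries = list(entries)
        self._by_name = {e.name: e for e in entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[CatalogEntry]:
        return iter(self.entries)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def family_of(self, name: str) -> str:
        return self._by_name[name].family

    def family_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for e in self.entries:
            sizes[e.family] = sizes.get(e.family, 0) + 1
        return sizes

    def features_in_family(self, family: str) -> list[str]:
        return [e.name for e in self.entries if e.family == family]


def _build_names() -> list[tuple[str, str]]:
    pairs: list[tuple[str, str]] = []
    pairs += [(f"hist_{s}", "histogram") for s in HISTOGRAM_STATS]
    pairs += [(f"glcm_{s}", "cooccurrence") for s in GLCM_STATS]
    pairs += [(f"rle_{s}", "runlength") for s in RUNLENGTH_STATS]
    pairs += [(f"fractal_{s}", "fractal") for s in FRACTAL_STATS]
    pairs += [(f"lbp_ri_{c:03d}", "lbp") for c in LBP_CODES]
    pairs += [
        (f"laws_{k}_{s}", "laws") for k in LAWS_KERNELS for s in LAWS_STATS
    ]
    pairs += [
        (f"lawsglcm_{k}_{s}", "laws_cooccurrence")
        for k in LAWS_GLCM_KERNELS
        for s in LAWS_GLCM_STATS
    ]
    pairs += [
        (f"gabor_o{o:03d}_w{w:02d}_{s}", "gabor")
        for o in GABOR_ORIENTATIONS_DEG
        for w in GABOR_WAVELENGTHS_PX
        for s in GABOR_STATS
    ]
    return pairs


def default_catalog() -> FeatureCatalog:
    """Build the canonical 341-feature catalog."""
    entries = [
        CatalogEntry(name=n, family=f, index=i)
        for i, (n, f) in enumerate(_build_names())
    ]
    catalog = FeatureCatalog(entries)
    sizes = catalog.family_sizes()
    if sizes != FAMILY_SIZES:  # pragma: no cover - construction sanity
        raise AssertionError(f"catalog family sizes {sizes} != {FAMILY_SIZES}")
    return catalog
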