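"""Per-window texture feature computation for the eight-family bank.

Every function here operates on one square window of raw intensities
(a 2D float array) and returns an ordered ``dict`` of feature values whose
keys follow :mod:`mammotex.catalog`.  Windows are self-contained: filters
(Laws, Gabor) are applied to the cropped window with reflective boundary
handling, so a window's feature values depend only on its own pixels.

Conventions (recorded because several are genuine choices):

* grey-level quantization for co-occurrence and run-length analysis is a
  per-window linear rescale to 64 levels between the window minimum and
  maximum; a constant window maps entirely to level 0;
* entropies use base-2 logarithms;
* skewness is Fisher g1 and kurtosis is the non-excess Pearson moment
  ratio (a Gaussian scores 3); both are defined as 0 for a constant
  window;
* co-occurrence correlation is defined as 0 when a marginal variance
  vanishes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal, stats
from skimage.feature import graycomatrix
from skimage.filters import gabor_kernel

from .catalog import (
    GABOR_ORIENTATIONS_DEG,
    GABOR_WAVELENGTHS_PX,
    GLCM_STATS,
    HISTOGRAM_STATS,
    LAWS_1D,
    LAWS_GLCM_KERNELS,
    LAWS_KERNELS,
    LBP_CODES,
    RUNLENGTH_STATS,
)

__all__ = [
    "N_GREY_LEVELS",
    "quantize",
    "histogram_features",
    "cooccurrence_features",
    "runlength_features",
    "fractal_features",
    "lbp_features",
    "laws_features",
    "laws_cooccurrence_features",
    "gabor_features",
    "compute_window_features",
    "FAMILY_FUNCTIONS",
]

N_GREY_LEVELS = 64

_GLCM_ANGLES = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]

# 1-D Laws filters: level, edge, spot, wave, ripple.
_LAWS_VECTORS = {
    "L5": np.array([1.0, 4.0, 6.0, 4.0, 1.0]),
    "E5": np.array([-1.0, -2.0, 0.0, 2.0, 1.0]),
    "S5": np.array([-1.0, 0.0, 2.0, 0.0, -1.0]),
    "W5": np.array([-1.0, 2.0, 0.0, -2.0, 1.0]),
    "R5": np.array([1.0, -4.0, 6.0, -4.0, 1.0]),
}

#: 25 2-D Laws kernels as outer products (first letter varies vertically).
LAWS_KERNELS_2D = {
    a + b: np.outer(_LAWS_VECTORS[a], _LAWS_VECTORS[b])
    for a in LAWS_1D
    for b in LAWS_1D
}


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum()) if p.size else 0.0


def quantize(win: np.ndarray, levels: int = N_GREY_LEVELS) -> np.ndarray:
    """Linearly rescale a window to integer grey levels 0..levels-1.

    Uses the window's own min/max; a constant window maps to level 0.
    """
    win = np.asarray(win, dtype=np.float64)
    lo, hi = win.min(), win.max()
    if hi <= lo:
        return np.zeros(win.shape, dtype=np.uint8)
    q = np.floor((win - lo) / (hi - lo) * levels)
    return np.clip(q, 0, levels - 1).astype(np.uint8)


# ---------------------------------------------------------------------------
# First-order histogram statistics
# ---------------------------------------------------------------------------

def histogram_features(win: np.ndarray) -> dict[str, float]:
    x = np.asarray(win, dtype=np.float64).ravel()
    lo, hi = x.min(), x.max()
    constant = hi <= lo
    if constant:
        skew = kurt = 0.0
        energy, entropy = 1.0, 0.0
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=False, bias=True))
        counts, _ = np.histogram(x, bins=N_GREY_LEVELS, range=(lo, hi))
        p = counts / counts.sum()
        energy = float((p ** 2).sum())
        entropy = _entropy_bits(p)
    p05, q25, med, q75, p95 = np.percentile(x, [5, 25, 50, 75, 95])
    vals = {
        "mean": float(x.mean()),
        "sd": float(x.std()),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": energy,
        "entropy": entropy,
        "min": float(lo),
        "max": float(hi),
        "median": float(med),
        "p05": float(p05),
        "p95": float(p95),
        "iqr": float(q75 - q25),
    }
    return {f"hist_{k}": vals[k] for k in HISTOGRAM_STATS}


# ---------------------------------------------------------------------------
# Grey-level co-occurrence statistics
# ---------------------------------------------------------------------------

# precomputed index arrays for the 64-level GLCM statistics
_GLEV = np.arange(N_GREY_LEVELS, dtype=np.float64)
_GII, _GJJ = np.meshgrid(_GLEV, _GLEV, indexing="ij")
_GSUM = _GII + _GJJ
_GDIFF2 = (_GII - _GJJ) ** 2
_GHOM = 1.0 / (1.0 + np.abs(_GII - _GJJ))
_GPROD = _GII * _GJJ


def _glcm_stats_matrix(
    P: np.ndarray, stat_names: tuple[str, ...] | list[str]
) -> dict[str, float]:
    """Haralick-style statistics of one normalised 64-level GLCM."""
    out: dict[str, float] = {}
    pi = P.sum(axis=1)
    pj = P.sum(axis=0)
    mu_i = float(_GLEV @ pi)
    mu_j = float(_GLEV @ pj)
    if "energy" in stat_names:
        out["energy"] = float((P * P).sum())
    if "contrast" in stat_names:
        out["contrast"] = float((P * _GDIFF2).sum())
    if "correlation" in stat_names:
        var_i = float((_GLEV - mu_i) ** 2 @ pi)
        var_j = float((_GLEV - mu_j) ** 2 @ pj)
        if var_i > 0 and var_j > 0:
            cov = float((P * _GPROD).sum()) - mu_i * mu_j
            out["correlation"] = cov / np.sqrt(var_i * var_j)
        else:
            out["correlation"] = 0.0
    if "homogeneity" in stat_names:
        out["homogeneity"] = float((P * _GHOM).sum())
    if "entropy" in stat_names:
        out["entropy"] = _entropy_bits(P.ravel())
    if "cluster_shade" in stat_names or "cluster_prominence" in stat_names:
        dev = _GSUM - (mu_i + mu_j)
        pdev3 = P * dev ** 3
        if "cluster_shade" in stat_names:
            out["cluster_shade"] = float(pdev3.sum())
        if "cluster_prominence" in stat_names:
            out["cluster_prominence"] = float((pdev3 * dev).sum())
    return out


def _glcm_stats(q: np.ndarray, stat_names: list[str]) -> dict[str, float]:
    """Direction-averaged GLCM statistics of a quantized window.

    Symmetric matrices at distance 1 in the four principal directions;
    each statistic is computed per direction and then averaged.
    """
    P = graycomatrix(
        q,
        distances=[1],
        angles=_GLCM_ANGLES,
        levels=N_GREY_LEVELS,
        symmetric=True,
        normed=True,
    )
    acc = {s: 0.0 for s in stat_names}
    for a in range(P.shape[3]):
        per_dir = _glcm_stats_matrix(P[:, :, 0, a], stat_names)
        for s in stat_names:
            acc[s] += per_dir[s]
    return {s: acc[s] / P.shape[3] for s in stat_names}


def cooccurrence_features(win: np.ndarray) -> dict[str, float]:
    q = quantize(win)
    vals = _glcm_stats(q, GLCM_STATS)
    return {f"glcm_{s}": vals[s] for s in GLCM_STATS}


# ---------------------------------------------------------------------------
# Grey-level run-length statistics
# ---------------------------------------------------------------------------

def _direction_lines(q: np.ndarray, direction: int) -> list[np.ndarray]:
    """Pixel sequences along one of the four principal directions."""
    if direction == 0:
        return [q[r, :] for r in range(q.shape[0])]
    if direction == 90:
        return [q[:, c] for c in range(q.shape[1])]
    if direction == 45:
        flipped = q[::-1, :]
        return [
            np.diagonal(flipped, offset=d)
            for d in range(-flipped.shape[0] + 1, flipped.shape[1])
        ]
    if direction == 135:
        return [
            np.diagonal(q, offset=d)
            for d in range(-q.shape[0] + 1, q.shape[1])
        ]
    raise ValueError(f"unknown run direction {direction}")


def _run_lengths(line: np.ndarray) -> list[tuple[int, int]]:
    """(grey level, run length) pairs of one pixel sequence."""
    runs = []
    if line.size == 0:
        return runs
    start = 0
    for idx in range(1, line.size + 1):
        if idx == line.size or line[idx] != line[start]:
            runs.append((int(line[start]), idx - start))
            start = idx
    return runs


def _runlength_stats_one_direction(q: np.ndarray, direction: int) -> dict[str, float]:
    counts: dict[tuple[int, int], int] = {}
    for line in _direction_lines(q, direction):
        for g, l in _run_lengths(np.asarray(line)):
            counts[(g, l)] = counts.get((g, l), 0) + 1
    n_runs = sum(counts.values())
    n_pix = q.size
    gl = np.array([g for g, _ in counts], dtype=np.float64)
    rl = np.array([l for _, l in counts], dtype=np.float64)
    r = np.array(list(counts.values()), dtype=np.float64)
    by_level: dict[int, float] = {}
    by_length: dict[int, float] = {}
    for (g, l), c in counts.items():
        by_level[g] = by_level.get(g, 0.0) + c
        by_length[l] = by_length.get(l, 0.0) + c
    return {
        "sre": float((r / rl ** 2).sum() / n_runs),
        "lre": float((r * rl ** 2).sum() / n_runs),
        "gln": float(sum(v ** 2 for v in by_level.values()) / n_runs),
        "rln": float(sum(v ** 2 for v in by_length.values()) / n_runs),
        "rp": float(n_runs / n_pix),
        "lgre": float((r / (gl + 1.0) ** 2).sum() / n_runs),
        "hgre": float((r * (gl + 1.0) ** 2).sum() / n_runs),
    }


def runlength_features(win: np.ndarray) -> dict[str, float]:
    q = quantize(win)
    acc = {s: 0.0 for s in RUNLENGTH_STATS}
    for direction in (0, 45, 90, 135):
        per_dir = _runlength_stats_one_direction(q, direction)
        for s in RUNLENGTH_STATS:
            acc[s] += per_dir[s]
    return {f"rle_{s}": acc[s] / 4.0 for s in RUNLENGTH_STATS}


# ---------------------------------------------------------------------------
# Fractal descriptors
# ---------------------------------------------------------------------------

def _box_counting_dimension(win: np.ndarray) -> float:
    """Differential box-counting dimension of the intensity surface.

    Intensities are mapped to [0, M) (M = window side) so that boxes are
    cubes of side ``s`` pixels; for each scale the number of boxes needed
    to cover the surface is summed over an s x s block grid, and the
    dimension is the slope of log N against log(1/s).  A flat surface
    scores 2.
    """
    win = np.asarray(win, dtype=np.float64)
    m = min(win.shape)
    sizes = []
    s = 2
    while s <= m // 2:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        return 0.0
    lo, hi = win.min(), win.max()
    z = np.zeros_like(win) if hi <= lo else (win - lo) / (hi - lo) * (m - 1)
    counts = []
    for s in sizes:
        nr, nc = win.shape[0] // s, win.shape[1] // s
        blocks = z[: nr * s, : nc * s].reshape(nr, s, nc, s)
        bmax = blocks.max(axis=(1, 3))
        bmin = blocks.min(axis=(1, 3))
        n = np.floor(bmax / s) - np.floor(bmin / s) + 1.0
        counts.append(n.sum())
    slope = np.polyfit(np.log(1.0 / np.asarray(sizes, dtype=float)),
                       np.log(np.asarray(counts)), 1)[0]
    return float(slope)


def _power_spectrum_beta(win: np.ndarray) -> float:
    """Slope beta of the radially averaged power spectrum, P(f) ~ f^-beta."""
    win = np.asarray(win, dtype=np.float64)
    m = min(win.shape)
    if m < 8:
        return 0.0
    centered = win - win.mean()
    if not np.any(centered):
        return 0.0
    power = np.abs(np.fft.fft2(centered)) ** 2
    ky = np.fft.fftfreq(win.shape[0]) * win.shape[0]
    kx = np.fft.fftfreq(win.shape[1]) * win.shape[1]
    kr = np.sqrt(ky[:, None] ** 2 + kx[None, :] ** 2)
    ring = np.rint(kr).astype(int)
    max_ring = m // 2
    freqs, means = [], []
    for k in range(1, max_ring):
        sel = ring == k
        if sel.any():
            pk = power[sel].mean()
            if pk > 0:
                freqs.append(k)
                means.append(pk)
    if len(freqs) < 3:
        return 0.0
    slope = np.polyfit(np.log(freqs), np.log(means), 1)[0]
    return float(-slope)


def fractal_features(win: np.ndarray) -> dict[str, float]:
    return {
        "fractal_box_dim": _box_counting_dimension(win),
        "fractal_psd_beta": _power_spectrum_beta(win),
    }


# ---------------------------------------------------------------------------
# Rotation-invariant local binary patterns
# ---------------------------------------------------------------------------

def _make_ror_lut() -> np.ndarray:
    lut = np.zeros(256, dtype=np.uint8)
    for value in range(256):
        best = value
        v = value
        for _ in range(7):
            v = ((v >> 1) | (v << 7)) & 0xFF
            best = min(best, v)
        lut[value] = best
    return lut


_ROR_LUT = _make_ror_lut()
_LBP_BIN = {code: i for i, code in enumerate(LBP_CODES)}
_LBP_BIN_LUT = np.array([_LBP_BIN[int(c)] for c in _ROR_LUT], dtype=np.int64)

# Clockwise from top-left; the rotation-invariant code does not depend on
# the starting neighbour, only on the cyclic order.
_LBP_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
                (1, 1), (1, 0), (1, -1), (0, -1)]


def lbp_features(win: np.ndarray) -> dict[str, float]:
    """Normalised histogram of 8-neighbour rotation-invariant LBP codes.

    Classic square-neighbourhood LBP (threshold neighbour >= centre) over
    interior pixels; codes are reduced to their minimal cyclic rotation,
    yielding 36 distinct bins.
    """
    win = np.asarray(win, dtype=np.float64)
    if min(win.shape) < 3:
        return {f"lbp_ri_{c:03d}": 0.0 for c in LBP_CODES}
    centre = win[1:-1, 1:-1]
    codes = np.zeros(centre.shape, dtype=np.uint8)
    for bit, (dr, dc) in enumerate(_LBP_OFFSETS):
        nb = win[1 + dr : win.shape[0] - 1 + dr, 1 + dc : win.shape[1] - 1 + dc]
        codes |= ((nb >= centre).astype(np.uint8) << bit)
    bins = _LBP_BIN_LUT[codes]
    hist = np.bincount(bins.ravel(), minlength=len(LBP_CODES)).astype(np.float64)
    hist /= hist.sum()
    return {f"lbp_ri_{c:03d}": float(hist[i]) for i, c in enumerate(LBP_CODES)}


# ---------------------------------------------------------------------------
# Laws texture-energy statistics
# ---------------------------------------------------------------------------

def _response_stats(resp: np.ndarray) -> dict[str, float]:
    lo, hi = resp.min(), resp.max()
    if hi <= lo:
        entropy = 0.0
    else:
        counts, _ = np.histogram(resp, bins=N_GREY_LEVELS, range=(lo, hi))
        entropy = _entropy_bits(counts / counts.sum())
    return {
        "mean": float(resp.mean()),
        "meanabs": float(np.abs(resp).mean()),
        "sd": float(resp.std()),
        "energy": float((resp ** 2).mean()),
        "entropy": entropy,
    }


def _laws_responses(win: np.ndarray, kernels: list[str]) -> dict[str, np.ndarray]:
    win = np.asarray(win, dtype=np.float64)
    return {
        k: ndimage.convolve(win, LAWS_KERNELS_2D[k], mode="reflect")
        for k in kernels
    }


def laws_features(win: np.ndarray) -> dict[str, float]:
    out: dict[str, float] = {}
    for k, resp in _laws_responses(win, LAWS_KERNELS).items():
        s = _response_stats(resp)
        for stat, v in s.items():
            out[f"laws_{k}_{stat}"] = v
    return out


def laws_cooccurrence_features(win: np.ndarray) -> dict[str, float]:
    """Co-occurrence statistics of the 24 non-low-pass Laws response maps."""
    out: dict[str, float] = {}
    for k, resp in _laws_responses(win, LAWS_GLCM_KERNELS).items():
        q = quantize(resp)
        s = _glcm_stats(q, ["energy", "contrast", "correlation",
                            "homogeneity", "entropy"])
        for stat, v in s.items():
            out[f"lawsglcm_{k}_{stat}"] = v
    return out


# ---------------------------------------------------------------------------
# Gabor wavelet magnitude statistics
# ---------------------------------------------------------------------------

def _gabor_kernels() -> dict[tuple[int, int], np.ndarray]:
    kernels = {}
    for deg in GABOR_ORIENTATIONS_DEG:
        for wl in GABOR_WAVELENGTHS_PX:
            kernels[(deg, wl)] = gabor_kernel(
                frequency=1.0 / wl, theta=np.deg2rad(deg)
            )
    return kernels


_GABOR_KERNELS = _gabor_kernels()


def gabor_features(win: np.ndarray) -> dict[str, float]:
    """Mean and SD of Gabor filter magnitude responses.

    Four orientations x four wavelengths (2-16 px, geometric ladder);
    complex kernels applied with reflective (symmetric) boundary handling.
    FFT convolution over a symmetrically padded window is used for speed;
    it is numerically equivalent to direct reflect-mode convolution.
    """
    win = np.asarray(win, dtype=np.float64)
    out: dict[str, float] = {}
    for deg in GABOR_ORIENTATIONS_DEG:
        for wl in GABOR_WAVELENGTHS_PX:
            kern = _GABOR_KERNELS[(deg, wl)]
            ph, pw = kern.shape[0] // 2, kern.shape[1] // 2
            padded = np.pad(win, ((ph, ph), (pw, pw)), mode="symmetric")
            resp = signal.fftconvolve(padded, kern, mode="valid")
            mag = np.abs(resp)
            out[f"gabor_o{deg:03d}_w{wl:02d}_mean"] = float(mag.mean())
            out[f"gabor_o{deg:03d}_w{wl:02d}_sd"] = float(mag.std())
    return out


FAMILY_FUNCTIONS = {
    "histogram": histogram_features,
    "cooccurrence": cooccurrence_features,
    "runlength": runlength_features,
    "fractal": fractal_features,
    "lbp": lbp_features,
    "laws": laws_features,
    "laws_cooccurrence": laws_cooccurrence_features,
    "gabor": gabor_features,
}


def compute_window_features(
    win: np.ndarray, families: list[str] | None = None
) -> dict[str, float]:
    """All features of one window, optionally restricted to some families."""
    out: dict[str, float] = {}
    for family, fn in FAMILY_FUNCTIONS.items():
        if families is None or family in families:
            out.update(fn(win))
    return out
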