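"""Independent brute-force reimplementations of one feature per family.

These deliberately avoid the package's vectorised code paths: explicit
pixel loops, itertools run grouping, direct (non-FFT) convolution.  They
exist solely to cross-check the lattice extractor.
"""

import itertools

import numpy as np
from scipy import ndimage

from mammotex.catalog import LBP_CODES
from mammotex.window_features import LAWS_KERNELS_2D


def glcm_contrast(q: np.ndarray) -> float:
    """Explicit pair enumeration, symmetric distance-1 GLCM, 4 directions."""
    h, w = q.shape
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]  # 0, 45, 90, 135 degrees
    per_dir = []
    for dr, dc in offsets:
        counts = {}
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w:
                    for a, b in ((q[r, c], q[r2, c2]), (q[r2, c2], q[r, c])):
                        counts[(a, b)] = counts.get((a, b), 0) + 1
        total = sum(counts.values())
        per_dir.append(
            sum(n * (int(a) - int(b)) ** 2 for (a, b), n in counts.items()) / total
        )
    return float(np.mean(per_dir))


def runlength(q: np.ndarray) -> dict[str, float]:
    """Run enumeration with itertools.groupby along all four directions."""
    h, w = q.shape

    def lines(direction):
        if direction == 0:
            return [list(q[r, :]) for r in range(h)]
        if direction == 90:
            return [list(q[:, c]) for c in range(w)]
        cells = {}
        for r in range(h):
            for c in range(w):
                key = r + c if direction == 45 else r - c
                cells.setdefault(key, []).append(((c, r), q[r, c]))
        # order along the line is by column for both diagonal families
        return [
            [v for (_, v) in sorted(line)] for _, line in sorted(cells.items())
        ]

    out = {"sre": 0.0, "rp": 0.0}
    for direction in (0, 45, 90, 135):
        runs = []
        for line in lines(direction):
            for _, grp in itertools.groupby(line):
                runs.append(len(list(grp)))
        n_runs = len(runs)
        out["sre"] += sum(1.0 / l**2 for l in runs) / n_runs / 4.0
        out["rp"] += n_runs / q.size / 4.0
    return out


def box_dimension(win: np.ndarray) -> float:
    """Differential box counting with explicit block loops."""
    m = min(win.shape)
    lo, hi = win.min(), win.max()
    z = (win - lo) / (hi - lo) * (m - 1) if hi > lo else np.zeros_like(win)
    sizes, counts = [], []
    s = 2
    while s <= m // 2:
        total = 0
        for r0 in range(0, (win.shape[0] // s) * s, s):
            for c0 in range(0, (win.shape[1] // s) * s, s):
                block = z[r0 : r0 + s, c0 : c0 + s]
                total += int(block.max() // s) - int(block.min() // s) + 1
        sizes.append(s)
        counts.append(total)
        s *= 2
    return float(np.polyfit(np.log([1.0 / s for s in sizes]), np.log(counts), 1)[0])


def lbp_hist(win: np.ndarray) -> dict[int, float]:
    """Pixel-by-pixel 8-neighbour codes reduced by explicit rotation."""

    def min_rotation(v):
        best = v
        for _ in range(7):
            v = ((v >> 1) | (v << 7)) & 0xFF
            best = min(best, v)
        return best

    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]
    hist = {c: 0 for c in LBP_CODES}
    h, w = win.shape
    n = 0
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for bit, (dr, dc) in enumerate(offsets):
                if win[r + dr, c + dc] >= win[r, c]:
                    code |= 1 << bit
            hist[min_rotation(code)] += 1
            n += 1
    return {k: v / n for k, v in hist.items()}


def laws_response(win: np.ndarray, kernel_name: str) -> np.ndarray:
    """Laws response via explicit shift-and-sum convolution on a padded window."""
    k = LAWS_KERNELS_2D[kernel_name]
    padded = np.pad(win, 2, mode="symmetric")
    resp = np.zeros_like(win, dtype=float)
    for i in range(5):
        for j in range(5):
            # convolution flips the kernel relative to correlation
            resp += k[4 - i, 4 - j] * padded[i : i + win.shape[0], j : j + win.shape[1]]
    return resp


def laws_meanabs(win: np.ndarray, kernel_name: str) -> float:
    return float(np.abs(laws_response(win, kernel_name)).mean())


def gabor_mean(win: np.ndarray, deg: int, wl: int) -> float:
    """Gabor magnitude via direct ndimage convolution (non-FFT route)."""
    from skimage.filters import gabor_kernel

    k = gabor_kernel(frequency=1.0 / wl, theta=np.deg2rad(deg))
    real = ndimage.convolve(win, np.real(k), mode="reflect")
    imag = ndimage.convolve(win, np.imag(k), mode="reflect")
    return float(np.hypot(real, imag).mean())
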