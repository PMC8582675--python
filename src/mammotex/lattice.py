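"""Square-window lattice geometry over a breast mask.

The breast region is partitioned into non-overlapping square windows of a
fixed physical side (default 6.3 mm), tiled from the origin of the mask's
bounding box.  Only windows sufficiently covered by the mask are kept;
with the default coverage of 1.0 a window must lie fully inside the
breast.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = ["LatticeSpec", "Window", "make_lattice", "window_side_px"]


@dataclass(frozen=True)
class LatticeSpec:
    """Lattice geometry parameters.

    ``window_size_mm`` is the physical window side; ``min_mask_coverage``
    is the minimum fraction of in-mask pixels a window needs to be kept.
    """

    window_size_mm: float = 6.3
    min_mask_coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.window_size_mm <= 0:
            raise ValueError("window_size_mm must be positive")
        if not 0.0 <= self.min_mask_coverage <= 1.0:
            raise ValueError("min_mask_coverage must be in [0, 1]")


class Window(NamedTuple):
    row0: int
    col0: int
    side: int

    def slices(self) -> tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.side),
            slice(self.col0, self.col0 + self.side),
        )


def window_side_px(spec: LatticeSpec, pixel_spacing_mm: float) -> int:
    """Window side in pixels: round(window_size_mm / pixel_spacing_mm)."""
    if pixel_spacing_mm <= 0:
        raise ValueError("pixel_spacing_mm must be positive")
    side = int(round(spec.window_size_mm / pixel_spacing_mm))
    if side < 2:
        raise ValueError(
            f"window of {spec.window_size_mm} mm at {pixel_spacing_mm} mm/px "
            f"is {side} px per side; pixel spacing too coarse (need >= 2 px)"
        )
    return side


def make_lattice(
    mask: np.ndarray, spec: LatticeSpec, pixel_spacing_mm: float
) -> list[Window]:
    """Tile the mask bounding box with square windows and filter by coverage.

    Returns the (possibly empty) list of surviving windows.  Windows are
    anchored at the bounding-box corner of the mask and advance in steps
    of one window side; windows extending past the image edge are dropped.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    side = window_side_px(spec, pixel_spacing_mm)
    if not mask.any():
        return []
    rows, cols = np.nonzero(mask)
    rmin, cmin = rows.min(), cols.min()
    height, width = mask.shape
    windows: list[Window] = []
    for r0 in range(int(rmin), height - side + 1, side):
        for c0 in range(int(cmin), width - side + 1, side):
            coverage = mask[r0 : r0 + side, c0 : c0 + side].mean()
            if coverage >= spec.min_mask_coverage:
                windows.append(Window(r0, c0, side))
    return windows
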