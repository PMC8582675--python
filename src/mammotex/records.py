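"""In-memory container for one 2D image plus its acquisition metadata."""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageRecord"]


@dataclass
class ImageRecord:
    """A single 2D grayscale image with breast mask and acquisition metadata.

    Parameters
    ----------
    pixels
        2D array of nonnegative intensities (raw detector-like units).
    pixel_spacing_mm
        Physical size of one pixel in mm (isotropic).
    mask
        Binary array, same shape as ``pixels``; True marks the analysed
        region (the breast).  ``None`` means the whole image.
    subject_id, laterality, view
        Identification metadata; laterality is ``"L"``/``"R"`` (empty for
        a phantom), view is ``"CC"`` or ``"MLO"``.
    thickness_mm
        Compressed thickness of the imaged breast (or phantom).
    kv, mas
        Tube-voltage and exposure proxies of the acquisition.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float
    mask: np.ndarray | None = None
    subject_id: str = ""
    laterality: str = ""
    view: str = "CC"
    thickness_mm: float = math.nan
    kv: float = math.nan
    mas: float = math.nan
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2D array")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if np.any(self.pixels < 0):
            raise ValueError("pixel intensities must be nonnegative")
        if self.mask is None:
            self.mask = np.ones(self.pixels.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask).astype(bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError("mask shape must equal image shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape
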