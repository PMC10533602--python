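"""Grayscale B-mode image container.

The first image axis is the lateral direction (beamline index ``l``, size
``L``); the second axis is depth (axial sample index ``d``, size ``D``).
This matches the acquisition geometry: each row of the pixel matrix is one
beamline, i.e. one transmit/receive event of the probe.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np

#: Supported declared value ranges: raw 8-bit or normalised.
RANGE_RAW: Tuple[float, float] = (0.0, 255.0)
RANGE_NORM: Tuple[float, float] = (0.0, 1.0)

_RANGE_TOL = 1e-9


@dataclass
class USImage:
    """A 2-D ultrasound-like grayscale image.

    Parameters
    ----------
    pixels : ndarray, shape (L, D)
        Grey intensities; lateral (beamline) axis first, depth axis second.
    value_range : (low, high)
        Declared intensity range, ``(0, 255)`` for raw or ``(0, 1)`` for
        normalised data.  All pixels must lie inside it.
    acquired_mask : ndarray of bool, shape (L,), optional
        Per-beamline flag, ``True`` where the line was physically acquired
        by the probe and ``False`` where it was synthesised by
        interpolation.  Defaults to all-acquired.
    district_tag : str
        Free-form label, e.g. the anatomical district the image mimics.
    """

    pixels: np.ndarray
    value_range: Tuple[float, float] = RANGE_NORM
    acquired_mask: np.ndarray | None = None
    district_tag: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D (L x D), got {self.pixels.ndim}-D")
        L, D = self.pixels.shape
        # L >= 2 so decimated acquisitions (down to 2 lines at 4X) remain
        # representable; interpolation itself needs >= 4 lines of support.
        if L < 2 or D < 1:
            raise ValueError(f"image too small: need L >= 2 and D >= 1, got {L} x {D}")
        lo, hi = self.value_range
        if self.pixels.min() < lo - _RANGE_TOL or self.pixels.max() > hi + _RANGE_TOL:
            raise ValueError(
                f"pixel values [{self.pixels.min():g}, {self.pixels.max():g}] "
                f"outside declared range [{lo:g}, {hi:g}]"
            )
        if self.acquired_mask is None:
            self.acquired_mask = np.ones(L, dtype=bool)
        else:
            self.acquired_mask = np.asarray(self.acquired_mask, dtype=bool)
            if self.acquired_mask.shape != (L,):
                raise ValueError(
                    f"acquired_mask length {self.acquired_mask.shape} != lateral size {L}"
                )

    # -- geometry ---------------------------------------------------------
    @property
    def L(self) -> int:
        """Number of lateral lines (beamlines)."""
        return self.pixels.shape[0]

    @property
    def D(self) -> int:
        """Number of depth samples per line."""
        return self.pixels.shape[1]

    # -- intensity-scale helpers -----------------------------------------
    def to_normalised(self) -> "USImage":
        """Return a copy with pixels mapped onto [0, 1]."""
        lo, hi = self.value_range
        if (lo, hi) == RANGE_NORM:
            return self.copy()
        scaled = (self.pixels - lo) / (hi - lo)
        return replace(self, pixels=scaled, value_range=RANGE_NORM,
                       acquired_mask=self.acquired_mask.copy())

    def to_raw(self) -> "USImage":
        """Return a copy with pixels mapped onto the 0-255 scale (still float)."""
        lo, hi = self.value_range
        if (lo, hi) == RANGE_RAW:
            return self.copy()
        scaled = (self.pixels - lo) / (hi - lo) * 255.0
        return replace(self, pixels=scaled, value_range=RANGE_RAW,
                       acquired_mask=self.acquired_mask.copy())

    def copy(self) -> "USImage":
        return replace(self, pixels=self.pixels.copy(),
                       acquired_mask=self.acquired_mask.copy())

    def __eq__(self, other: object) -> bool:  # value equality, mainly for tests
        if not isinstance(other, USImage):
            return NotImplemented
        return (
            self.pixels.shape == other.pixels.shape
            and np.array_equal(self.pixels, other.pixels)
            and self.value_range == other.value_range
            and np.array_equal(self.acquired_mask, other.acquired_mask)
        )
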