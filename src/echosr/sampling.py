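"""Lateral beamline decimation and cubic-convolution up-sampling.

A probe acquiring at half or a quarter of the maximum line count produces an
image with every 2nd (0.5X) or 4th (0.25X) beamline.  ``downsample_beamlines``
emulates that acquisition from a full-resolution image; ``upsample_beamlines``
restores the full lateral grid with Keys' cubic-convolution interpolation,
applied strictly 1-D along the lateral axis (the depth axis is never
resampled).  ``make_training_pair`` chains the two to build the
(interpolated input, high-resolution target) pairs the network trains on.

The phase convention puts acquired lines at lateral indices l with
``(l - phase) mod s == 0``; interpolated lines sit at fractional low-res
coordinates between them, so the 2X and 4X grids are nested and index 0 is
always an acquired line when ``phase == 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .image import USImage

__all__ = [
    "SamplingScheme",
    "cubic_kernel",
    "downsample_beamlines",
    "upsample_beamlines",
    "make_training_pair",
]


@dataclass(frozen=True)
class SamplingScheme:
    """Decimation factor, phase and interpolation-kernel parameters.

    ``factor`` is the up/down-sampling factor s (2 or 4 in the intended use;
    1 is allowed and is the identity).  ``phase`` is the index of the first
    acquired line.  ``kernel_a`` is the free parameter of the cubic kernel,
    Keys' a = -0.5 by default.  ``boundary_mode`` selects the edge-extension
    rule; ``"quadratic"`` is Keys' cubic-precision-preserving extrapolation.
    """

    factor: int = 2
    phase: int = 0
    kernel_a: float = -0.5
    boundary_mode: str = "quadratic"

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError(f"factor must be a positive integer, got {self.factor}")
        if not 0 <= self.phase < max(self.factor, 1):
            raise ValueError(f"phase must satisfy 0 <= phase < factor, got {self.phase}")
        if self.kernel_a >= 0:
            raise ValueError(f"kernel_a must be negative, got {self.kernel_a}")
        if self.boundary_mode not in ("quadratic", "edge"):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")


def cubic_kernel(x, a: float = -0.5):
    """Keys' piecewise-cubic convolution kernel.

    ``(a+2)|x|^3 - (a+3)|x|^2 + 1`` for |x| <= 1,
    ``a|x|^3 - 5a|x|^2 + 8a|x| - 4a`` for 1 < |x| < 2, and 0 beyond.
    Interpolating (value 1 at 0, 0 at nonzero integers) with 4-sample
    support; a = -0.5 gives quadratic reproduction precision.
    """
    x = np.abs(np.asarray(x, dtype=float))
    near = (a + 2.0) * x**3 - (a + 3.0) * x**2 + 1.0
    far = a * x**3 - 5.0 * a * x**2 + 8.0 * a * x - 4.0 * a
    out = np.where(x <= 1.0, near, np.where(x < 2.0, far, 0.0))
    return out if out.ndim else float(out)


def _crop_lateral(img: USImage, s: int) -> USImage:
    """Trim trailing lines so the lateral size is divisible by s."""
    L = img.L
    keep = L - (L % s)
    if keep == L:
        return img
    return replace(img, pixels=img.pixels[:keep], acquired_mask=img.acquired_mask[:keep])


def downsample_beamlines(img: USImage, scheme: SamplingScheme) -> USImage:
    """Keep every s-th beamline, emulating reduced-line acquisition.

    Returns an image with L/s lines, holding exactly the lines at lateral
    indices l with ``(l - phase) mod s == 0``.  Depth is untouched.  The
    result's ``acquired_mask`` is all-True: every remaining line was
    physically acquired.
    """
    s = scheme.factor
    if s == 1:
        return img.copy()
    if img.L < 2 * s:
        raise ValueError(
            f"image too narrow for decimation: L={img.L} < 2*s={2 * s}"
        )
    img = _crop_lateral(img, s)
    kept = img.pixels[scheme.phase :: s]
    return USImage(
        pixels=kept.copy(),
        value_range=img.value_range,
        acquired_mask=np.ones(kept.shape[0], dtype=bool),
        district_tag=img.district_tag,
    )


def _extend_lateral(lines: np.ndarray, mode: str) -> np.ndarray:
    """Pad the line stack with 2 extrapolated lines at each lateral edge.

    ``"quadratic"`` applies Keys' rule f(-1) = 3 f(0) - 3 f(1) + f(2)
    recursively (and mirrored at the far edge), which preserves the
    kernel's quadratic precision at the borders.  ``"edge"`` replicates
    the boundary line.
    """
    N = lines.shape[0]
    ext = np.empty((N + 4,) + lines.shape[1:], dtype=lines.dtype)
    ext[2 : N + 2] = lines
    if mode == "quadratic":
        for i in (1, 0):  # ext index 1 = f(-1), 0 = f(-2)
            ext[i] = 3.0 * ext[i + 1] - 3.0 * ext[i + 2] + ext[i + 3]
        for i in (N + 2, N + 3):  # f(N), f(N+1)
            ext[i] = 3.0 * ext[i - 1] - 3.0 * ext[i - 2] + ext[i - 3]
    else:  # edge replication
        ext[0] = ext[1] = lines[0]
        ext[N + 2] = ext[N + 3] = lines[-1]
    return ext


def upsample_beamlines(lowres: USImage, scheme: SamplingScheme, target_L: int) -> USImage:
    """Cubic-convolution interpolation of missing beamlines.

    Acquired positions (``(l - phase) mod s == 0``) receive bit-identical
    copies of the low-resolution lines; each missing line at fractional
    low-res coordinate x is the kernel-weighted sum of the 4 nearest
    acquired lines, evaluated independently at every depth sample.
    """
    s = scheme.factor
    N = lowres.L
    if target_L != s * N:
        raise ValueError(f"target_L={target_L} must equal factor*L = {s * N}")
    if s == 1:
        return lowres.copy()
    if N < 4:
        raise ValueError(
            f"insufficient support: need at least 4 low-res lines, got {N}"
        )
    ext = _extend_lateral(lowres.pixels, scheme.boundary_mode)

    out = np.empty((target_L, lowres.D), dtype=float)
    mask = np.zeros(target_L, dtype=bool)
    l_idx = np.arange(target_L)
    x = (l_idx - scheme.phase) / s  # low-res coordinate of each output line
    acquired = (l_idx - scheme.phase) % s == 0
    out[acquired] = lowres.pixels
    mask[acquired] = True

    miss = l_idx[~acquired]
    i = np.floor(x[miss]).astype(int)  # left base index in low-res grid
    u = x[miss] - i  # fractional offset in (0, 1)
    acc = np.zeros((miss.size, lowres.D))
    for j, off in enumerate((-1, 0, 1, 2)):
        w = cubic_kernel(u - off, scheme.kernel_a)
        acc += w[:, None] * ext[i + off + 2]
    out[miss] = acc

    # clip interpolation overshoot back into the declared range
    lo, hi = lowres.value_range
    np.clip(out, lo, hi, out=out)
    out[acquired] = lowres.pixels  # clipping must not touch acquired lines

    return USImage(
        pixels=out,
        value_range=lowres.value_range,
        acquired_mask=mask,
        district_tag=lowres.district_tag,
    )


def make_training_pair(
    hr: USImage, scheme: SamplingScheme
) -> Tuple[USImage, USImage]:
    """Build an (interpolated input, high-resolution target) pair.

    The target is the (lateral-crop-adjusted) high-resolution image; the
    input is its decimation followed by cubic up-sampling.  Both share
    dimensions, and the input's ``acquired_mask`` distinguishes probe lines
    from interpolated ones.
    """
    s = scheme.factor
    target = _crop_lateral(hr, s)
    low = downsample_beamlines(target, scheme)
    inp = upsample_beamlines(low, scheme, target.L) if s > 1 else low
    return inp, target
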