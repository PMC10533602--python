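"""Image-quality metrics: PSNR, SSIM, MAE, error images and histograms.

All printed error magnitudes in the intended workflow (first-bin threshold
5, maximum prediction alterations around 20) refer to the 0-255 grey scale,
so the pipeline denormalises to that scale before computing metrics; the
functions here are scale-agnostic and operate on whatever arrays they get.

Argument order matters for PSNR only: the peak is taken from the FIRST
argument, which is by convention the target (reference) image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "mse",
    "psnr",
    "ssim",
    "mae",
    "abs_error_image",
    "error_histogram",
    "cohort_summary",
    "brightness",
    "MetricsReport",
]


def _check_same_shape(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    return A, B


def mse(A, B) -> float:
    """Mean squared error (1/(m*n)) * sum (A_ij - B_ij)^2."""
    A, B = _check_same_shape(A, B)
    return float(np.mean((A - B) ** 2))


def psnr(A, B) -> float:
    """Peak signal-to-noise ratio, 10*log10(max(A)^2 / MSE(A, B)), in dB.

    ``A`` is the target: its maximum defines the peak.  Identical images
    give ``inf``.  A degenerate all-zero target with nonzero error raises.
    """
    A, B = _check_same_shape(A, B)
    err = mse(A, B)
    if err == 0.0:
        return float("inf")
    peak = float(A.max())
    if peak <= 0.0:
        raise ValueError("degenerate target: max(A) = 0 with nonzero error")
    return float(10.0 * np.log10(peak**2 / err))


def ssim(
    A,
    B,
    value_range: float = 255.0,
    C1: float | None = None,
    C2: float | None = None,
    C3: float | None = None,
    window: int | None = None,
) -> float:
    """Structural similarity index, luminance * contrast * structure.

    Computed globally (single window) from the raw moments:
    l = (2 mu_A mu_B + C1)/(mu_A^2 + mu_B^2 + C1),
    c = (2 s_A s_B + C2)/(s_A^2 + s_B^2 + C2),
    s = (cov_AB + C3)/(s_A s_B + C3),
    with population (ddof=0) moments.  The stabilising constants default to
    C1 = (0.01 R)^2, C2 = (0.03 R)^2, C3 = C2/2 with R = ``value_range``.

    ``window`` switches to the sliding-window mean SSIM of scikit-image,
    useful as a locality-aware variant; the global form is the default.
    """
    A, B = _check_same_shape(A, B)
    if C1 is None:
        C1 = (0.01 * value_range) ** 2
    if C2 is None:
        C2 = (0.03 * value_range) ** 2
    if C3 is None:
        C3 = C2 / 2.0

    if window is not None:
        from skimage.metrics import structural_similarity

        return float(
            structural_similarity(A, B, win_size=window, data_range=value_range)
        )

    mu_a, mu_b = A.mean(), B.mean()
    sig_a, sig_b = A.std(), B.std()
    cov = float(np.mean((A - mu_a) * (B - mu_b)))
    lum = (2 * mu_a * mu_b + C1) / (mu_a**2 + mu_b**2 + C1)
    con = (2 * sig_a * sig_b + C2) / (sig_a**2 + sig_b**2 + C2)
    struct = (cov + C3) / (sig_a * sig_b + C3)
    return float(lum * con * struct)


def mae(A, B) -> float:
    """Mean absolute error (1/(m*n)) * sum |A_ij - B_ij|."""
    A, B = _check_same_shape(A, B)
    return float(np.mean(np.abs(A - B)))


def abs_error_image(A, B) -> tuple[np.ndarray, float]:
    """Pointwise absolute-error image |A - B| and its maximum.

    The maximum is the figure-caption statistic ("maximum error in the
    scale 0-255" when the inputs are on that scale).
    """
    A, B = _check_same_shape(A, B)
    err = np.abs(A - B)
    return err, float(err.max())


def error_histogram(A, B, bin_width: float = 5.0) -> np.ndarray:
    """Counts of |A - B| in half-open bins [0, w), [w, 2w), ...

    With the default width 5 on the 0-255 scale, the first bin counts the
    "visually indistinguishable" pixels (error strictly below 5).  Counts
    always sum to the pixel total.
    """
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    A, B = _check_same_shape(A, B)
    err = np.abs(A - B).ravel()
    n_bins = max(1, int(np.floor(err.max() / bin_width)) + 1)
    idx = np.minimum((err / bin_width).astype(int), n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def cohort_summary(values: Sequence[float]) -> Dict[str, float]:
    """Box-plot statistics of a metric over a test cohort.

    Median and quartiles use linear interpolation of order statistics;
    whiskers follow the Tukey convention: the most extreme data points
    within 1.5 IQR of the quartiles.
    """
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cohort_summary needs a nonempty list")
    q1, med, q3 = np.percentile(vals, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    in_lo = vals[vals >= q1 - 1.5 * iqr]
    in_hi = vals[vals <= q3 + 1.5 * iqr]
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "whisker_low": float(in_lo.min()),
        "whisker_high": float(in_hi.max()),
    }


def brightness(A) -> float:
    """Mean intensity over all pixels."""
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("empty image")
    return float(A.mean())


@dataclass
class MetricsReport:
    """Per-image and cohort quality statistics for one evaluation run.

    ``per_image`` holds one record per test image with keys ``psnr``,
    ``ssim``, ``mae``, ``first_bin_count`` and ``max_abs_error`` (for each
    of the compared reconstructions); ``cohort`` holds box-plot summaries
    per metric; ``m`` and ``n`` are the image dimensions entering the
    MSE/MAE denominators.
    """

    per_image: List[Dict[str, float]] = field(default_factory=list)
    cohort: Dict[str, Dict[str, float]] = field(default_factory=dict)
    m: int = 0
    n: int = 0
    schema_version: str = "1"

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.per_image).to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "m": self.m,
            "n": self.n,
            "cohort": self.cohort,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    def summarise(self, key: str) -> Dict[str, float]:
        """Box-plot summary of one per-image column."""
        return cohort_summary([rec[key] for rec in self.per_image])
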