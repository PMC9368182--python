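"""Image-quality and phase-quantification metrics.

SSIM (Wang et al. formulation: 11×11 Gaussian window, σ = 1.5,
K1 = 0.01, K2 = 0.03), PSNR, the two-NA incoherent resolution limit
λ/(2·NA), and microsphere phase-height statistics via the standard
quantitative-phase conversion h = φ·λ/(2π·Δn).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label as _label
from scipy.signal import fftconvolve

from .optics import PhaseMap

__all__ = ["ssim", "psnr", "theoretical_resolution", "HeightStats", "phase_height_stats"]


def _gaussian_kernel(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    k = np.outer(g, g)
    return k / k.sum()


def ssim(x: np.ndarray, y: np.ndarray, data_range: float | None = None,
         k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean local structural similarity between two 2-D images.

    Local means/variances/covariance are taken under an 11×11 Gaussian
    window (σ = 1.5) on the fully overlapping interior; ``data_range``
    defaults to the dynamic range of ``y`` (the reference image).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if data_range is None:
        data_range = float(y.max() - y.min())
        if data_range == 0:
            data_range = 1.0
    win = _gaussian_kernel()
    mode = "valid"
    mu_x = fftconvolve(x, win, mode=mode)
    mu_y = fftconvolve(y, win, mode=mode)
    xx = fftconvolve(x * x, win, mode=mode) - mu_x ** 2
    yy = fftconvolve(y * y, win, mode=mode) - mu_y ** 2
    xy = fftconvolve(x * y, win, mode=mode) - mu_x * mu_y
    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    num = (2 * mu_x * mu_y + c1) * (2 * xy + c2)
    den = (mu_x ** 2 + mu_y ** 2 + c1) * (xx + yy + c2)
    return float(np.mean(num / den))


def psnr(x: np.ndarray, y: np.ndarray, data_range: float) -> float:
    """Peak signal-to-noise ratio, 10·log10(range²/MSE), in dB.

    Identical inputs give infinite PSNR, reported as ``math.inf``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((x - y) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range ** 2 / mse)


def theoretical_resolution(wavelength: float, na: float) -> float:
    """Diffraction-limited two-point resolution λ/(2·NA), in µm."""
    if wavelength <= 0 or na <= 0:
        raise ValueError("wavelength and NA must be positive")
    return wavelength / (2.0 * na)


@dataclass
class HeightStats:
    """Per-sphere recovered heights (µm) with summary statistics."""

    heights: list[float]
    median: float
    mean_relative_error: float  # percent vs the nominal height
    n: int

    def __post_init__(self) -> None:
        if self.n != len(self.heights):
            raise ValueError("n must equal len(heights)")


def phase_height_stats(phase: PhaseMap, wavelength: float, delta_n: float,
                       nominal_height: float, min_area: int = 9) -> HeightStats:
    """Detect microspheres in a recovered phase map and report their heights.

    Spheres are segmented as connected components above half of the robust
    (99th-percentile) peak phase; each sphere's height is its component's
    95th-percentile phase minus the background median, converted through
    h = φ·λ/(2π·Δn).  Components smaller than ``min_area`` pixels are
    treated as hot-pixel debris and ignored.
    """
    if delta_n <= 0:
        raise ValueError("delta_n must be positive")
    # reference to the background (median) level so the statistics are
    # invariant to the arbitrary additive constant of a recovered phase map
    v = phase.values - np.median(phase.values)
    robust_peak = np.percentile(v, 99)
    threshold = 0.5 * robust_peak
    mask = v > threshold
    if robust_peak <= 0 or not mask.any():
        raise ValueError("zero detections: no phase peaks above threshold")
    labels, n_comp = _label(mask)
    background = float(np.median(v[~mask]))
    heights: list[float] = []
    for i in range(1, n_comp + 1):
        comp = labels == i
        if comp.sum() < min_area:
            continue
        peak = float(np.percentile(v[comp], 95)) - background
        heights.append(peak * wavelength / (2.0 * np.pi * delta_n))
    if not heights:
        raise ValueError("zero detections: all components below the area cutoff")
    heights_arr = np.asarray(heights)
    return HeightStats(
        heights=heights,
        median=float(np.median(heights_arr)),
        mean_relative_error=float(
            100.0 * np.mean(np.abs(heights_arr - nominal_height) / nominal_height)),
        n=len(heights),
    )
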