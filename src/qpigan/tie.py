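"""Transport-of-intensity phase retrieval.

Solves the paraxial transport-of-intensity equation

    -k ∂I/∂z = ∇·( I ∇φ ),    k = 2π/λ

for the phase φ from a three-plane defocus stack, using the standard
two-step auxiliary-function factorisation (ψ = ∇⁻²(−k ∂I/∂z), then
φ = ∇⁻²(∇·(I⁻¹∇ψ))) with FFT inverse Laplacians under homogeneous Neumann
boundary conditions.  Neumann boundaries are realised by even mirror
extension of every field to a doubled grid before transforming, which is
equivalent to a cosine-basis expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2

from .optics import DefocusStack, PhaseMap

logger = logging.getLogger(__name__)

__all__ = ["TieParams", "AxialDerivative", "axial_derivative", "inverse_laplacian", "solve_tie"]


@dataclass(frozen=True)
class TieParams:
    """Solver parameters.

    ``epsilon_dc`` is a Tikhonov addend on the inverse-Laplacian spectrum
    protecting near-zero frequencies; by default it scales with the field
    of view as 1e-9·(2π/FOV)² and the DC bin itself is hard-zeroed.
    ``intensity_floor`` clips the in-focus intensity, as a fraction of its
    mean, before the 1/I division.
    """

    wavelength: float = 0.55
    dz: float = 3.0
    epsilon_dc: float | None = None
    intensity_floor: float = 0.01

    def __post_init__(self) -> None:
        if self.wavelength <= 0 or self.dz <= 0:
            raise ValueError("wavelength and dz must be positive")
        if self.epsilon_dc is not None and self.epsilon_dc < 0:
            raise ValueError("epsilon_dc must be nonnegative")
        if not 0 < self.intensity_floor < 1:
            raise ValueError("intensity_floor must lie in (0, 1)")

    @property
    def wave_number(self) -> float:
        return 2.0 * np.pi / self.wavelength


@dataclass
class AxialDerivative:
    """Central-difference estimate of ∂I/∂z (intensity per µm)."""

    values: np.ndarray
    pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("axial derivative contains non-finite values")


def axial_derivative(stack: DefocusStack) -> AxialDerivative:
    """∂I/∂z ≈ (I(+Δz) − I(−Δz)) / (2Δz), elementwise."""
    if stack.plus.shape != stack.minus.shape:
        raise ValueError("stack planes have mismatched shapes")
    dz = stack.dz
    values = (stack.plus.values - stack.minus.values) / (2.0 * dz)
    return AxialDerivative(values, stack.pitch)


def _mirror_extend(field: np.ndarray) -> np.ndarray:
    """Even (half-sample symmetric) extension to a doubled grid."""
    top = np.concatenate([field, field[:, ::-1]], axis=1)
    return np.concatenate([top, top[::-1, :]], axis=0)


def _freq_grids(shape: tuple[int, int], pitch: float) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = shape
    fx = fftfreq(nx, d=pitch)[None, :]
    fy = fftfreq(ny, d=pitch)[:, None]
    return fx, fy


def _default_epsilon(shape: tuple[int, int], pitch: float) -> float:
    fov = max(shape) * pitch
    return 1e-9 * (2.0 * np.pi / fov) ** 2


def _inv_laplacian_spectrum(shape: tuple[int, int], pitch: float, epsilon_dc: float) -> np.ndarray:
    fx, fy = _freq_grids(shape, pitch)
    denom = -(4.0 * np.pi ** 2 * (fx * fx + fy * fy) + epsilon_dc)
    with np.errstate(divide="ignore"):
        inv = np.where(denom != 0.0, 1.0 / denom, 0.0)
    inv[0, 0] = 0.0  # DC is unrecoverable; hard-zeroed
    return inv


def inverse_laplacian(field: np.ndarray, pitch: float, epsilon_dc: float | None = None) -> np.ndarray:
    """Apply ∇⁻² under homogeneous Neumann boundary conditions.

    The field is mirror-extended to 2N×2M (enforcing zero normal derivative
    at the original borders), its spectrum divided by −(4π²f² + ε), the DC
    bin zeroed, and the result cropped back.  The output has zero mean.
    """
    field = np.asarray(field, dtype=np.float64)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    if epsilon_dc is None:
        epsilon_dc = _default_epsilon(field.shape, pitch)
    ext = _mirror_extend(field)
    inv = _inv_laplacian_spectrum(ext.shape, pitch, epsilon_dc)
    out = np.real(ifft2(fft2(ext) * inv))[: field.shape[0], : field.shape[1]]
    return out - out.mean()


def solve_tie(stack: DefocusStack, params: TieParams | None = None) -> PhaseMap:
    """Recover the phase map from a defocus stack.

    Intensities are first normalised by the mean of the in-focus plane so
    the result is invariant to the exposure scale.  The two inverse
    Laplacians, the gradient and the divergence are all evaluated
    spectrally on the mirror-extended grid, which keeps the even/odd
    symmetries of the intermediate fields mutually consistent.  The
    returned phase is zero-mean (the additive constant is unrecoverable).
    """
    if params is None:
        params = TieParams(dz=stack.dz)
    pitch = stack.pitch
    i0 = stack.focus.values
    scale = i0.mean()
    if scale <= 0:
        raise ValueError("in-focus intensity has non-positive mean")
    nonpos = np.mean(i0 <= 0)
    if nonpos > 0.01:
        logger.warning("in-focus intensity non-positive over %.1f%% of pixels", 100 * nonpos)

    didz = (stack.plus.values - stack.minus.values) / (2.0 * params.dz) / scale
    i_norm = i0 / scale
    floor = params.intensity_floor
    if np.any(i_norm < floor):
        logger.info("intensity floor active on %.2f%% of pixels", 100 * np.mean(i_norm < floor))
    i_clip = np.clip(i_norm, floor, None)

    eps = params.epsilon_dc
    if eps is None:
        eps = _default_epsilon(stack.focus.shape, pitch)

    rhs = _mirror_extend(-params.wave_number * didz)
    inv = _inv_laplacian_spectrum(rhs.shape, pitch, eps)
    fx, fy = _freq_grids(rhs.shape, pitch)
    psi_hat = fft2(rhs) * inv
    gx = np.real(ifft2(2j * np.pi * fx * psi_hat))
    gy = np.real(ifft2(2j * np.pi * fy * psi_hat))
    i_ext = _mirror_extend(i_clip)
    div = np.real(
        ifft2(2j * np.pi * fx * fft2(gx / i_ext) + 2j * np.pi * fy * fft2(gy / i_ext))
    )
    phi_ext = np.real(ifft2(fft2(div) * inv))
    phi = phi_ext[: stack.focus.shape[0], : stack.focus.shape[1]]
    phi = phi - phi.mean()
    return PhaseMap(phi, pitch)
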