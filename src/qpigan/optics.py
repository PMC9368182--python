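"""Bright-field defocus simulator for pure-phase microscopy specimens.

Builds phase phantoms (microspheres, cell-like blobs), propagates the
transmitted field with the angular-spectrum method, images it through a
partially coherent microscope of given NA/magnification, and assembles the
unpaired low-resolution-intensity / high-resolution-phase datasets used to
train the intensity-to-phase translation network.

Conventions: lengths in micrometres, phase in radians, row-major grids with
the origin at the top-left and pixel centres on integer indices.  Frequency
grids follow numpy FFT ordering.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.fft import fft2, fftfreq, ifft2

__all__ = [
    "OpticalConfig",
    "PhaseMap",
    "IntensityImage",
    "DefocusStack",
    "Sphere",
    "SpherePhantomSpec",
    "UnpairedDataset",
    "OBJECTIVE_PRESETS",
    "make_sphere_phantom",
    "random_sphere_spec",
    "make_blob_phantom",
    "propagate_angular_spectrum",
    "image_through_system",
    "image_low_res",
    "acquire_defocus_stack",
    "tile_to_fov",
    "build_unpaired_dataset",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OpticalConfig:
    """Microscope imaging geometry.

    Parameters
    ----------
    wavelength : float
        Centre wavelength of the (filtered) illumination, in µm.
    na_objective : float
        Numerical aperture of the objective, in (0, 1).
    magnification : float
        Lateral magnification of the objective.
    camera_pitch : float
        Sample spacing at the *object* plane (camera pixel / magnification),
        in µm per pixel.
    defocus_dz : float
        Defocus distance |Δz| used for the two out-of-focus captures, µm.
    coherence_s : float
        Coherence parameter S: ratio of the condenser aperture NA to the
        objective NA.  S = 0 is fully coherent illumination.
    """

    wavelength: float = 0.55
    na_objective: float = 0.65
    magnification: float = 40.0
    camera_pitch: float = 0.1625
    defocus_dz: float = 3.0
    coherence_s: float = 0.3

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        if not 0 < self.na_objective < 1:
            raise ValueError("na_objective must lie in (0, 1)")
        if not self.magnification > 0:
            raise ValueError("magnification must be positive")
        if not self.camera_pitch > 0:
            raise ValueError("camera_pitch must be positive")
        if not self.defocus_dz > 0:
            raise ValueError("defocus_dz must be positive")
        if self.coherence_s < 0:
            raise ValueError("coherence_s must be >= 0")


#: NA / magnification pairs of the four objectives the datasets emulate,
#: with the object-plane pixel pitch of a 6.5 µm camera behind each.
OBJECTIVE_PRESETS: dict[str, OpticalConfig] = {
    "4x": OpticalConfig(na_objective=0.1, magnification=4.0, camera_pitch=1.625),
    "10x": OpticalConfig(na_objective=0.25, magnification=10.0, camera_pitch=0.65),
    "20x": OpticalConfig(na_objective=0.4, magnification=20.0, camera_pitch=0.325),
    "40x": OpticalConfig(na_objective=0.65, magnification=40.0, camera_pitch=0.1625),
}


@dataclass
class PhaseMap:
    """2-D phase field φ(r) in radians with its pixel pitch in µm."""

    values: np.ndarray
    pitch: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or min(self.values.shape) < 8:
            raise ValueError("phase map must be 2-D with both dims >= 8")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phase map contains non-finite values")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class IntensityImage:
    """Nonnegative intensity image at a signed defocus z_offset (µm)."""

    values: np.ndarray
    pitch: float
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("intensity image must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("intensity image contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("intensity must be nonnegative")
        if not self.pitch > 0:
            raise ValueError("pitch must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class DefocusStack:
    """Through-focus triplet I(−Δz), I(0), I(+Δz) on a common grid."""

    minus: IntensityImage
    focus: IntensityImage
    plus: IntensityImage

    def __post_init__(self) -> None:
        shapes = {self.minus.shape, self.focus.shape, self.plus.shape}
        if len(shapes) != 1:
            raise ValueError("stack planes must share one grid shape")
        pitches = {self.minus.pitch, self.focus.pitch, self.plus.pitch}
        if len(pitches) != 1:
            raise ValueError("stack planes must share one pixel pitch")
        if not np.isclose(self.minus.z_offset, -self.plus.z_offset):
            raise ValueError("minus.z_offset must equal -plus.z_offset")
        if not self.plus.z_offset > 0:
            raise ValueError("plus.z_offset must be positive")

    @property
    def dz(self) -> float:
        return float(self.plus.z_offset)

    @property
    def pitch(self) -> float:
        return float(self.focus.pitch)


@dataclass(frozen=True)
class Sphere:
    center_x: float
    center_y: float
    diameter: float
    delta_n: float


@dataclass(frozen=True)
class SpherePhantomSpec:
    """A field of homogeneous dielectric microspheres on a square grid."""

    spheres: tuple[Sphere, ...]
    grid_size: int
    pitch: float
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "spheres", tuple(self.spheres))
        for i, s in enumerate(self.spheres):
            if s.diameter <= 0:
                raise ValueError(f"sphere {i}: diameter must be positive")
            if s.delta_n <= 0:
                raise ValueError(f"sphere {i}: delta_n must be positive")
        if self.grid_size < 8:
            raise ValueError("grid_size must be >= 8")
        if self.pitch <= 0:
            raise ValueError("pitch must be positive")


@dataclass
class UnpairedDataset:
    """Unpaired training material: LR intensity tiles vs HR phase maps.

    ``set_a`` and ``set_b`` carry no pairing index; their orders are
    independent random permutations.
    """

    set_a: list[IntensityImage]
    set_b: list[PhaseMap]
    split_fraction: float

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")


# --------------------------------------------------------------------------
# phantoms
# --------------------------------------------------------------------------

def make_sphere_phantom(spec: SpherePhantomSpec, wavelength: float) -> PhaseMap:
    """Projected-thickness phase map of a microsphere field.

    Each sphere of radius R contributes phase (2π/λ)·Δn·t(r) with the chord
    thickness t(r) = 2·sqrt(R² − r²) inside its footprint; overlapping
    spheres add their thicknesses.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    n = spec.grid_size
    extent = n * spec.pitch
    y, x = np.mgrid[0:n, 0:n].astype(np.float64) * spec.pitch
    phase = np.zeros((n, n))
    for i, s in enumerate(spec.spheres):
        r = s.diameter / 2.0
        if (s.center_x - r < 0 or s.center_x + r > extent
                or s.center_y - r < 0 or s.center_y + r > extent):
            raise ValueError(f"sphere {i} extends beyond the grid")
        rho2 = (x - s.center_x) ** 2 + (y - s.center_y) ** 2
        thickness = 2.0 * np.sqrt(np.clip(r * r - rho2, 0.0, None))
        phase += (2.0 * np.pi / wavelength) * s.delta_n * thickness
    return PhaseMap(phase, spec.pitch)


def random_sphere_spec(
    n_spheres: int,
    grid_size: int,
    pitch: float,
    seed: int,
    diameter: float = 3.0,
    delta_n: float = 0.1,
    margin: float | None = None,
) -> SpherePhantomSpec:
    """Draw ``n_spheres`` non-overlapping spheres uniformly inside the grid."""
    rng = np.random.default_rng(seed)
    extent = grid_size * pitch
    r = diameter / 2.0
    if margin is None:
        # Keep the defocus halo (~Δz·NA, about one diameter at Δz = 3 µm /
        # 0.65 NA) inside the field so border reflections cannot corrupt the
        # through-focus images; on small grids fall back to whatever margin
        # still leaves a placement zone a few pixels wide.
        margin = min(diameter, max(2.0 * pitch, (extent - 2 * r) / 2 - 2.0 * pitch))
    pad = r + margin
    if 2 * pad >= extent:
        raise ValueError("grid too small for the requested sphere diameter")
    centers: list[tuple[float, float]] = []
    for _ in range(100000):
        if len(centers) == n_spheres:
            break
        cx, cy = rng.uniform(pad, extent - pad, size=2)
        if all((cx - px) ** 2 + (cy - py) ** 2 > (2.2 * r) ** 2 for px, py in centers):
            centers.append((cx, cy))
    else:
        raise RuntimeError("could not place all spheres without overlap")
    spheres = tuple(Sphere(cx, cy, diameter, delta_n) for cx, cy in centers)
    return SpherePhantomSpec(spheres=spheres, grid_size=grid_size, pitch=pitch, seed=seed)


def make_blob_phantom(
    grid_size: int,
    pitch: float,
    seed: int,
    max_phase: float = 2.0,
    feature_um: float = 2.0,
) -> PhaseMap:
    """Smooth nonnegative cell-like phase blobs from band-limited noise.

    Gaussian white noise is low-pass filtered to a correlation length of
    ``feature_um``, rectified softly and scaled so the peak phase equals
    ``max_phase`` radians.
    """
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((grid_size, grid_size))
    f = fftfreq(grid_size, d=pitch)
    fx, fy = np.meshgrid(f, f)
    lowpass = np.exp(-((fx * fx + fy * fy) * (feature_um ** 2) * 2.0 * np.pi ** 2))
    smooth = np.real(ifft2(fft2(noise) * lowpass))
    smooth -= smooth.mean()
    smooth = np.clip(smooth, 0.0, None) ** 2
    peak = smooth.max()
    if peak > 0:
        smooth *= max_phase / peak
    return PhaseMap(smooth, pitch)


# --------------------------------------------------------------------------
# wave propagation and imaging
# --------------------------------------------------------------------------

def propagate_angular_spectrum(
    field: np.ndarray, distance: float, wavelength: float, pitch: float
) -> np.ndarray:
    """Exact scalar angular-spectrum propagation over ``distance`` µm.

    The transfer function exp(i·2π·d·sqrt(1/λ² − f²)) is applied in the
    frequency domain; evanescent components (f² > 1/λ²) are set to zero.
    """
    field = np.asarray(field, dtype=np.complex128)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    if distance == 0.0:
        return field.copy()
    ny, nx = field.shape
    fx = fftfreq(nx, d=pitch)
    fy = fftfreq(ny, d=pitch)
    fx2 = fx[None, :] ** 2
    fy2 = fy[:, None] ** 2
    arg = 1.0 / wavelength ** 2 - fx2 - fy2
    propagating = arg > 0
    kz = np.sqrt(np.where(propagating, arg, 0.0))
    transfer = np.where(propagating, np.exp(2j * np.pi * distance * kz), 0.0)
    return ifft2(fft2(field) * transfer)


def _source_points(config: OpticalConfig) -> list[tuple[float, float]]:
    """Condenser source sampled as centre + ring quadrature of the disk.

    The ring sits at the rms radius R/√2 of a uniformly filled disk of
    radius R = S·NA/λ, so the second moment of the true source is matched.
    """
    if config.coherence_s == 0.0:
        return [(0.0, 0.0)]
    radius = config.coherence_s * config.na_objective / config.wavelength
    ring = radius / np.sqrt(2.0)
    pts = [(0.0, 0.0)]
    for m in range(8):
        ang = 2.0 * np.pi * m / 8.0
        pts.append((ring * np.cos(ang), ring * np.sin(ang)))
    return pts


def _pupil_mask(shape: tuple[int, int], pitch: float, cutoff: float) -> np.ndarray:
    ny, nx = shape
    fx = fftfreq(nx, d=pitch)
    fy = fftfreq(ny, d=pitch)
    f2 = fx[None, :] ** 2 + fy[:, None] ** 2
    return f2 <= cutoff * cutoff


def image_through_system(
    phase: PhaseMap,
    config: OpticalConfig,
    z_offset: float,
    noise_seed: int | None = None,
    photon_budget: float = 1e4,
    gaussian_noise_frac: float = 0.005,
) -> IntensityImage:
    """Render the bright-field intensity of a pure-phase object.

    The unit-amplitude transmitted field exp(i·φ) is propagated by
    ``z_offset``, low-pass filtered by the circular objective pupil of
    radius NA/λ, and squared to intensity.  Partial coherence (S > 0) is
    modelled as an incoherent average over tilted condenser illumination
    directions filling a disk of radius S·NA/λ.  With ``noise_seed`` given,
    mixed Poisson–Gaussian camera noise is added.
    """
    ny, nx = phase.shape
    cutoff = config.na_objective / config.wavelength
    df = 1.0 / (min(nx, ny) * phase.pitch)
    if cutoff < df:
        raise ValueError("NA unresolvable at this grid")
    y, x = np.mgrid[0:ny, 0:nx].astype(np.float64) * phase.pitch
    pupil = _pupil_mask(phase.shape, phase.pitch, cutoff)
    total = np.zeros(phase.shape)
    points = _source_points(config)
    # snap illumination tilts to FFT-grid frequencies: a tilt between bins is
    # not periodic on the grid and would leak across the pupil edge
    dfx = 1.0 / (nx * phase.pitch)
    dfy = 1.0 / (ny * phase.pitch)
    for fx0, fy0 in points:
        fx0 = round(fx0 / dfx) * dfx
        fy0 = round(fy0 / dfy) * dfy
        tilt = np.exp(2j * np.pi * (fx0 * x + fy0 * y))
        u = np.exp(1j * phase.values) * tilt
        u = propagate_angular_spectrum(u, z_offset, config.wavelength, phase.pitch)
        u = ifft2(fft2(u) * pupil)
        total += np.abs(u) ** 2
    intensity = total / len(points)
    if noise_seed is not None:
        rng = np.random.default_rng(noise_seed)
        mean = intensity.mean()
        if mean > 0 and photon_budget > 0:
            counts = rng.poisson(intensity / mean * photon_budget)
            intensity = counts.astype(np.float64) / photon_budget * mean
        intensity = intensity + rng.normal(0.0, gaussian_noise_frac * mean, intensity.shape)
        intensity = np.clip(intensity, 0.0, None)
    return IntensityImage(intensity, phase.pitch, z_offset)


def image_low_res(
    phase: PhaseMap,
    config_low: OpticalConfig,
    mag_ratio: int,
    z_offset: float = 0.0,
    noise_seed: int | None = None,
) -> IntensityImage:
    """Low-magnification view of the same field: low-NA pupil filtering at
    the native grid followed by ``mag_ratio``× block-average downsampling,
    emulating coarse camera sampling rather than a generic blur."""
    if mag_ratio < 1 or phase.shape[0] % mag_ratio or phase.shape[1] % mag_ratio:
        raise ValueError("grid dims must be divisible by mag_ratio")
    hr = image_through_system(phase, config_low, z_offset, noise_seed=noise_seed)
    v = hr.values
    ny, nx = v.shape
    v = v.reshape(ny // mag_ratio, mag_ratio, nx // mag_ratio, mag_ratio).mean(axis=(1, 3))
    return IntensityImage(v, phase.pitch * mag_ratio, z_offset)


def acquire_defocus_stack(
    phase: PhaseMap, config: OpticalConfig, noise_seed: int | None = None
) -> DefocusStack:
    """Capture the −Δz / 0 / +Δz triplet with per-plane derived noise seeds."""
    if noise_seed is None:
        seeds: list[int | None] = [None, None, None]
    else:
        ss = np.random.SeedSequence(noise_seed).spawn(3)
        seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss]
    dz = config.defocus_dz
    minus = image_through_system(phase, config, -dz, noise_seed=seeds[0])
    focus = image_through_system(phase, config, 0.0, noise_seed=seeds[1])
    plus = image_through_system(phase, config, +dz, noise_seed=seeds[2])
    return DefocusStack(minus=minus, focus=focus, plus=plus)


# --------------------------------------------------------------------------
# dataset assembly
# --------------------------------------------------------------------------

def tile_to_fov(
    image: IntensityImage, mag_low: float, mag_high: float
) -> list[IntensityImage]:
    """Split a low-magnification image into (mag_high/mag_low)² equal tiles
    whose field of view each matches the high-magnification objective.
    Tiles are non-overlapping and returned in row-major order."""
    if not mag_high >= mag_low > 0:
        raise ValueError("need mag_high >= mag_low > 0")
    ratio_f = mag_high / mag_low
    ratio = int(round(ratio_f))
    if abs(ratio_f - ratio) > 1e-9:
        raise ValueError(f"magnification ratio {ratio_f} is not integral")
    ny, nx = image.shape
    if ny % ratio or nx % ratio:
        raise ValueError(f"image dims {image.shape} not divisible by ratio {ratio}")
    th, tw = ny // ratio, nx // ratio
    tiles = []
    for i in range(ratio):
        for j in range(ratio):
            block = image.values[i * th:(i + 1) * th, j * tw:(j + 1) * tw].copy()
            tiles.append(IntensityImage(block, image.pitch, image.z_offset))
    return tiles


def build_unpaired_dataset(
    phantom_specs: Sequence[SpherePhantomSpec],
    config_low: OpticalConfig,
    config_high: OpticalConfig,
    split_fraction: float = 0.85,
    seed: int = 0,
) -> tuple[UnpairedDataset, UnpairedDataset]:
    """Assemble unpaired (LR intensity, HR phase) training and test sets.

    Side A renders each phantom through the low-NA objective at the
    coarse camera pitch (one HR-FOV tile per phantom); side B holds phase
    maps of *independently drawn* phantoms, so no pairing exists even at
    generation time.  Both sides are shuffled with independent substreams
    of ``seed`` and split round(split·N) / remainder.
    """
    specs = list(phantom_specs)
    if len(specs) < 2:
        raise ValueError("need at least 2 phantoms")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must lie in (0, 1)")
    ratio_f = config_high.magnification / config_low.magnification
    ratio = max(1, int(round(ratio_f)))
    if abs(ratio_f - ratio) > 1e-9:
        raise ValueError("magnification ratio must be integral")
    ss = np.random.SeedSequence(seed).spawn(3)
    rng_a = np.random.default_rng(ss[0])
    rng_b = np.random.default_rng(ss[1])
    rng_specs = np.random.default_rng(ss[2])

    set_a: list[IntensityImage] = []
    for spec in specs:
        phase = make_sphere_phantom(spec, config_low.wavelength)
        set_a.append(image_low_res(phase, config_low, ratio))

    set_b: list[PhaseMap] = []
    for spec in specs:
        respec = random_sphere_spec(
            n_spheres=len(spec.spheres),
            grid_size=spec.grid_size,
            pitch=spec.pitch,
            seed=int(rng_specs.integers(2 ** 31)),
            diameter=spec.spheres[0].diameter if spec.spheres else 3.0,
            delta_n=spec.spheres[0].delta_n if spec.spheres else 0.1,
        )
        set_b.append(make_sphere_phantom(respec, config_high.wavelength))

    order_a = rng_a.permutation(len(set_a))
    order_b = rng_b.permutation(len(set_b))
    set_a = [set_a[i] for i in order_a]
    set_b = [set_b[i] for i in order_b]

    n = len(set_a)
    n_train = int(round(split_fraction * n))
    train = UnpairedDataset(set_a[:n_train], set_b[:n_train], split_fraction)
    test = UnpairedDataset(set_a[n_train:], set_b[n_train:], split_fraction)
    return train, test
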