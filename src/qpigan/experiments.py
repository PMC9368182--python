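"""Self-contained reference experiments on synthetic data.

These drive the quantitative checks of the toolkit end to end: the
50-microsphere phase-height recovery through the simulator and the TIE
solver, and a small unpaired-training task showing that the translation
network learns an intensity-to-phase mapping it was never shown pairs for.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .metrics import HeightStats, phase_height_stats, ssim
from .models import DiscriminatorConfig, GeneratorConfig
from .optics import (
    OBJECTIVE_PRESETS,
    OpticalConfig,
    UnpairedDataset,
    acquire_defocus_stack,
    make_blob_phantom,
    image_through_system,
    make_sphere_phantom,
    random_sphere_spec,
)
from .tie import TieParams, solve_tie
from .train import LossReport, TrainConfig, TrainResult, fit

__all__ = ["sphere_height_experiment", "ToyTaskResult", "toy_translation_experiment"]


def sphere_height_experiment(
    n_spheres: int = 50,
    seed: int = 0,
    grid_size: int = 128,
    config: OpticalConfig | None = None,
    diameter: float = 3.0,
    delta_n: float = 0.1,
    noise: bool = False,
) -> HeightStats:
    """Recover the heights of simulated polystyrene microspheres by TIE.

    Each sphere is placed in its own field, imaged as a noise-free defocus
    stack (Δz = 3 µm, 40×/0.65 NA by default) and inverted with the TIE
    solver; heights come from the component peak phase via
    h = φ·λ/(2π·Δn).  Coherent illumination (S = 0) is used: the TIE
    closed form being inverted assumes the coherent intensity-transport
    model, and the discrete condenser quadrature at this large defocus
    would otherwise add a source blur that biases heights low.
    """
    if config is None:
        config = OBJECTIVE_PRESETS["40x"]
    config = dataclasses.replace(config, coherence_s=0.0)
    ss = np.random.SeedSequence(seed).spawn(n_spheres)
    heights: list[float] = []
    for i in range(n_spheres):
        spec_seed = int(ss[i].generate_state(1)[0] % (2 ** 31))
        spec = random_sphere_spec(1, grid_size, config.camera_pitch, seed=spec_seed,
                                  diameter=diameter, delta_n=delta_n)
        phase = make_sphere_phantom(spec, config.wavelength)
        stack = acquire_defocus_stack(phase, config,
                                      noise_seed=spec_seed if noise else None)
        recovered = solve_tie(stack, TieParams(wavelength=config.wavelength,
                                               dz=config.defocus_dz))
        stats = phase_height_stats(recovered, config.wavelength, delta_n,
                                   nominal_height=diameter)
        # one sphere per field: take its single detected component
        heights.append(stats.heights[int(np.argmax(stats.heights))])
    arr = np.asarray(heights)
    return HeightStats(
        heights=heights,
        median=float(np.median(arr)),
        mean_relative_error=float(100.0 * np.mean(np.abs(arr - diameter) / diameter)),
        n=len(heights),
    )


@dataclass
class ToyTaskResult:
    history: list[LossReport]
    ssim_raw: float          # raw LR intensity vs hidden true phase
    ssim_generated: float    # G_AB output vs hidden true phase
    result: TrainResult


def _normalize(x: np.ndarray) -> np.ndarray:
    lo, hi = float(x.min()), float(x.max())
    return (x - lo) / (hi - lo) if hi > lo else np.zeros_like(x)


def toy_translation_experiment(
    seed: int = 0,
    n_items: int = 24,
    grid_size: int = 32,
    total_steps: int = 200,
    width_scale: float = 0.125,
) -> ToyTaskResult:
    """Desk-scale unpaired intensity→phase training task.

    Cell-like blob phantoms on a 32×32 grid are imaged in focus through a
    20×/0.4 NA objective (side A); side B holds phase maps of independently
    drawn phantoms, so training never sees a pair.  A width-scaled model is
    trained for ~``steps_hint`` steps.  The true phase of each side-A
    phantom is withheld from training and used only to score the outputs.
    """
    cfg = dataclasses.replace(OBJECTIVE_PRESETS["20x"], coherence_s=0.3)
    ss = np.random.SeedSequence(seed).spawn(3)
    seeds_a = np.random.default_rng(ss[0]).integers(2 ** 31, size=n_items)
    seeds_b = np.random.default_rng(ss[1]).integers(2 ** 31, size=n_items)

    phases_a, images_a = [], []
    for s in seeds_a:
        pm = make_blob_phantom(grid_size, cfg.camera_pitch, int(s), max_phase=2.0)
        phases_a.append(pm)
        images_a.append(image_through_system(pm, cfg, z_offset=0.0))
    set_b = [make_blob_phantom(grid_size, cfg.camera_pitch, int(s), max_phase=2.0)
             for s in seeds_b]

    train_set = UnpairedDataset(set_a=images_a, set_b=set_b, split_fraction=0.85)
    batch_size = 2
    steps_per_epoch = max(1, n_items // batch_size)
    epochs = max(1, round(total_steps / steps_per_epoch))
    train_cfg = TrainConfig(epochs=epochs, batch_size=batch_size,
                            seed=int(ss[2].generate_state(1)[0] % (2 ** 31)))
    gen_cfg = GeneratorConfig(img_size=grid_size, patch_size=4, window=4,
                              depths=(1, 1), num_heads=(2, 4), embed_dim=96,
                              cnn_channels=32, width_scale=width_scale)
    disc_cfg = DiscriminatorConfig(n_layers=1, width_scale=width_scale * 2)
    result = fit(train_set, train_cfg, gen_cfg, disc_cfg)

    ssim_raw, ssim_gen = [], []
    for img, truth in zip(images_a, phases_a):
        t = _normalize(truth.values)
        ssim_raw.append(ssim(_normalize(img.values), t, data_range=1.0))
        out = result.translate_a_to_b(img.values)
        ssim_gen.append(ssim(_normalize(out), t, data_range=1.0))
    return ToyTaskResult(
        history=result.history,
        ssim_raw=float(np.mean(ssim_raw)),
        ssim_generated=float(np.mean(ssim_gen)),
        result=result,
    )
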