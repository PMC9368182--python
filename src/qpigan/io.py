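"""Float TIFF and manifest plumbing."""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import numpy as np
import tifffile

from .optics import IntensityImage, PhaseMap

__all__ = ["write_phase", "read_phase", "write_intensity", "read_intensity",
           "write_manifest", "read_manifest"]


def write_phase(path, phase: PhaseMap) -> None:
    tifffile.imwrite(str(path), phase.values.astype(np.float32),
                     metadata={"pitch_um": phase.pitch, "kind": "phase_rad"})


def read_phase(path, pitch: float | None = None) -> PhaseMap:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray().astype(np.float64)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    pitch = pitch if pitch is not None else float(meta.get("pitch_um", 1.0))
    return PhaseMap(data, pitch)


def write_intensity(path, image: IntensityImage) -> None:
    tifffile.imwrite(str(path), image.values.astype(np.float32),
                     metadata={"pitch_um": image.pitch, "z_offset_um": image.z_offset,
                               "kind": "intensity"})


def read_intensity(path, pitch: float | None = None,
                   z_offset: float | None = None) -> IntensityImage:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray().astype(np.float64)
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    pitch = pitch if pitch is not None else float(meta.get("pitch_um", 1.0))
    z = z_offset if z_offset is not None else float(meta.get("z_offset_um", 0.0))
    return IntensityImage(data, pitch, z)


def write_manifest(path, entries: list[dict], config: dict, seed: int) -> None:
    """Record what was generated, from which config and seed, so any output
    directory can be reproduced from its manifest alone."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "config": config,
        "config_hash": hashlib.sha256(blob).hexdigest()[:16],
        "seed": seed,
        "package_version": __import__("qpigan").__version__,
        "entries": entries,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
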