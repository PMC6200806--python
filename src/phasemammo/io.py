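"""Float32 TIFF + JSON-sidecar serialization for stacks and images."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .interferometer import SteppingStack
from .retrieval import MultimodalImage

__all__ = ["save_stepping_stack", "load_stepping_stack",
           "save_multimodal", "load_multimodal"]


def save_stepping_stack(stack: SteppingStack, path) -> None:
    """Write a stack as a multi-page float32 TIFF plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.counts.astype(np.float32))
    sidecar = {
        "step_phases_rad": stack.step_phases.tolist(),
        "exposure_per_step_s": stack.exposure_per_step,
        "pixel_pitch_mm": stack.pixel_pitch,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_stepping_stack(path) -> SteppingStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return SteppingStack(
        tifffile.imread(path).astype(float),
        np.asarray(meta["step_phases_rad"]),
        meta["exposure_per_step_s"], meta["pixel_pitch_mm"])


def save_multimodal(image: MultimodalImage, stem) -> None:
    """Write the three channels + mask as ``<stem>_T/_dphi/_df/_mask.tif``."""
    stem = Path(stem)
    tifffile.imwrite(stem.parent / f"{stem.name}_T.tif",
                     image.transmission.astype(np.float32))
    tifffile.imwrite(stem.parent / f"{stem.name}_dphi.tif",
                     image.differential_phase.astype(np.float32))
    tifffile.imwrite(stem.parent / f"{stem.name}_df.tif",
                     image.dark_field.astype(np.float32))
    tifffile.imwrite(stem.parent / f"{stem.name}_mask.tif",
                     image.valid.astype(np.uint8))
    meta = {"pixel_pitch_mm": image.pixel_pitch,
            "provenance": image.provenance or {}}
    (stem.parent / f"{stem.name}_meta.json").write_text(
        json.dumps(meta, indent=1))


def load_multimodal(stem) -> MultimodalImage:
    stem = Path(stem)
    meta = json.loads((stem.parent / f"{stem.name}_meta.json").read_text())
    return MultimodalImage(
        tifffile.imread(stem.parent / f"{stem.name}_T.tif").astype(float),
        tifffile.imread(stem.parent / f"{stem.name}_dphi.tif").astype(float),
        tifffile.imread(stem.parent / f"{stem.name}_df.tif").astype(float),
        meta["pixel_pitch_mm"],
        tifffile.imread(stem.parent / f"{stem.name}_mask.tif").astype(bool),
        provenance=meta.get("provenance"))
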