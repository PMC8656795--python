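"""File formats: TIFF images, frame-stack sidecar metadata, masks, tables.

Frame stacks travel as multi-page TIFF plus a JSON sidecar (same stem,
``.json``) carrying wavelength, per-frame spatial frequency and phase,
pixel pitch and modulation axis.  Maps are 32-bit float TIFF (lossless
round trip); raw frames can optionally be quantized to 16-bit.  ROI
masks are written as a uint8 label TIFF with a JSON legend.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .demodulation import FrameStack

__all__ = [
    "write_map",
    "read_map",
    "write_frame_stack",
    "read_frame_stack",
    "write_roi_masks",
    "read_roi_masks",
]


def write_map(path, array) -> None:
    """Write a 2D map as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(array, dtype=np.float32))


def read_map(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.float64)


def write_frame_stack(path, stack: FrameStack, bits16: bool = False) -> None:
    """Multi-page TIFF + JSON sidecar.  With ``bits16`` frames are scaled
    to the full uint16 range (the scale is recorded in the sidecar)."""
    path = Path(path)
    frames = np.asarray(stack.frames)
    meta = {
        "wavelength": float(stack.wavelength),
        "fx": [float(v) for v in stack.fx],
        "phase": [float(v) for v in stack.phase],
        "pixel_pitch": float(stack.pixel_pitch),
        "modulation_axis": int(stack.modulation_axis),
        "scale": 1.0,
    }
    if bits16:
        scale = float(frames.max()) / 65535.0 if frames.max() > 0 else 1.0
        tifffile.imwrite(path, np.round(frames / scale).astype(np.uint16),
                         photometric="minisblack")
        meta["scale"] = scale
    else:
        tifffile.imwrite(path, frames.astype(np.float32), photometric="minisblack")
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_frame_stack(path) -> FrameStack:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    frames = tifffile.imread(path).astype(np.float64) * meta.get("scale", 1.0)
    if frames.ndim == 2:
        frames = frames[None]
    return FrameStack(
        frames=frames,
        wavelength=meta["wavelength"],
        fx=np.asarray(meta["fx"], dtype=float),
        phase=np.asarray(meta["phase"], dtype=float),
        pixel_pitch=meta["pixel_pitch"],
        modulation_axis=meta.get("modulation_axis", 1),
    )


def write_roi_masks(path, masks: dict) -> None:
    """Label TIFF (0 = background) with a JSON name->label legend."""
    path = Path(path)
    names = sorted(masks)
    label_map = None
    legend = {}
    for i, name in enumerate(names, start=1):
        m = np.asarray(masks[name], dtype=bool)
        if label_map is None:
            label_map = np.zeros(m.shape, dtype=np.uint8)
        label_map[m] = i
        legend[name] = i
    tifffile.imwrite(path, label_map)
    path.with_suffix(".json").write_text(json.dumps(legend, indent=1))


def read_roi_masks(path) -> dict:
    path = Path(path)
    label_map = tifffile.imread(path)
    legend = json.loads(path.with_suffix(".json").read_text())
    return {name: label_map == label for name, label in legend.items()}
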