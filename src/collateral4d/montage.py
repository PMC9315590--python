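"""Windowed normalisation, axial maximum intensity projection, and the
2x2 four-phase montage that forms the classifier input."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .subtraction import PhaseVolumeSet
from .synthetic import Volume, PHASE_KEYS

__all__ = [
    "MIPImage",
    "MontageImage",
    "normalize",
    "mip",
    "stitch",
    "montage_from_phase_set",
    "DEFAULT_WINDOW",
]

#: HU display window applied to subtracted volumes before projection;
#: 0-300 HU spans vessel contrast enhancement
DEFAULT_WINDOW = (0.0, 300.0)


@dataclass
class MIPImage:
    """Axial maximum intensity projection, values in [0, 1], (y, x)."""

    values: np.ndarray
    phase: str

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("MIP must be 2-D")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("MIP values must lie in [0, 1]")


@dataclass
class MontageImage:
    """2x2 stitched four-phase MIP; quadrant layout in row-major order."""

    values: np.ndarray
    layout: tuple[tuple[str, str], tuple[str, str]]

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("montage must be 2-D")
        if self.values.shape[0] % 2 or self.values.shape[1] % 2:
            raise ValueError("montage dimensions must be twice the MIP dimensions")


def normalize(volume: Volume, window: tuple[float, float] = DEFAULT_WINDOW) -> Volume:
    """Linear HU window to [0, 1] with clipping at the window edges."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    out = np.clip((volume.values.astype(np.float32) - lo) / (hi - lo), 0.0, 1.0)
    return Volume(out, spacing=volume.spacing)


def mip(volume: Volume, phase: str = "") -> MIPImage:
    """out(y, x) = max over z of volume(z, y, x); expects a normalized
    volume so the projection stays in [0, 1]."""
    return MIPImage(values=volume.values.max(axis=0), phase=phase)


def stitch(mips: dict[str, MIPImage]) -> MontageImage:
    """Stitch the four phase MIPs into one 2x2 montage, row-major
    [arterial, arteriovenous; venous, late_venous]; each quadrant is
    bit-identical to its source MIP."""
    missing = [k for k in PHASE_KEYS if k not in mips]
    if missing:
        raise ValueError(f"missing phases: {missing}")
    shapes = {mips[k].values.shape for k in PHASE_KEYS}
    if len(shapes) != 1:
        raise ValueError("all four MIPs must share dimensions")
    a, av, v, lv = (mips[k].values for k in PHASE_KEYS)
    top = np.concatenate([a, av], axis=1)
    bottom = np.concatenate([v, lv], axis=1)
    layout = ((PHASE_KEYS[0], PHASE_KEYS[1]), (PHASE_KEYS[2], PHASE_KEYS[3]))
    return MontageImage(values=np.concatenate([top, bottom], axis=0), layout=layout)


def montage_from_phase_set(
    phase_set: PhaseVolumeSet, window: tuple[float, float] = DEFAULT_WINDOW
) -> tuple[MontageImage, dict[str, MIPImage]]:
    """Normalize, project and stitch a subtracted phase volume set."""
    mips = {
        key: mip(normalize(vol, window), phase=key)
        for key, vol in phase_set.volumes.items()
    }
    return stitch(mips), mips
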