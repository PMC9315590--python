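"""Phase volume selection, NCCT subtraction and bone removal.

Each phase landmark maps to one acquired contrast frame; subtracting the
baseline non-contrast volume isolates the contrast column, and a bone
mask (thresholded on the NCCT) removes the skull so the subsequent
maximum intensity projections have a clean background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .landmarks import PhaseLandmarks
from .synthetic import DynamicStudy, Volume, PHASE_KEYS

__all__ = ["PhaseVolumeSet", "select_volume", "subtract_ncct", "build_phase_set"]

#: NCCT attenuation at or above which a voxel is treated as bone
DEFAULT_BONE_HU = 150.0


@dataclass
class PhaseVolumeSet:
    """One subtracted, bone-removed volume per phase, plus the contrast
    frame index each phase came from."""

    volumes: dict[str, Volume]
    frame_indices: dict[str, int]

    def __post_init__(self):
        if tuple(self.volumes) != PHASE_KEYS:
            raise ValueError(f"phase keys must be {PHASE_KEYS} in order")
        shapes = {v.shape for v in self.volumes.values()}
        spacings = {v.spacing for v in self.volumes.values()}
        if len(shapes) != 1 or len(spacings) != 1:
            raise ValueError("phase volumes must share dimensions and spacing")
        for key, vol in self.volumes.items():
            if np.any(vol.values < 0):
                raise ValueError(f"{key} phase volume contains negative values")


def select_volume(study: DynamicStudy, frame_index: int) -> Volume:
    """The contrast frame at ``frame_index`` (0-based, baseline excluded)."""
    n = len(study.contrast_frames)
    if not 0 <= frame_index < n:
        raise IndexError(f"frame index {frame_index} out of range 0..{n - 1}")
    return study.contrast_frames[frame_index][1]


def subtract_ncct(frame: Volume, ncct: Volume, bone_hu: float = DEFAULT_BONE_HU) -> Volume:
    """Voxelwise max(frame - ncct, 0), with voxels whose NCCT attenuation
    reaches ``bone_hu`` zeroed out (bone removal)."""
    if frame.shape != ncct.shape or frame.spacing != ncct.spacing:
        raise ValueError("frame and NCCT must share dimensions and spacing")
    out = np.maximum(frame.values.astype(np.float32) - ncct.values, 0.0)
    out[ncct.values >= bone_hu] = 0.0
    return Volume(out, spacing=frame.spacing)


def build_phase_set(
    study: DynamicStudy,
    lm: PhaseLandmarks,
    bone_hu: float = DEFAULT_BONE_HU,
) -> PhaseVolumeSet:
    """Subtract the NCCT from the four landmark frames."""
    volumes, indices = {}, {}
    for key, idx in zip(PHASE_KEYS, lm.frame_indices):
        volumes[key] = subtract_ncct(select_volume(study, idx), study.ncct, bone_hu)
        indices[key] = idx
    return PhaseVolumeSet(volumes=volumes, frame_indices=indices)
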