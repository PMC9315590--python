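"""Serialisation: NIfTI volumes, JSON sidecars, CSV tables, PNG images."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .landmarks import PhaseLandmarks, TimeDensityCurve
from .montage import MIPImage, MontageImage
from .subtraction import PhaseVolumeSet
from .synthetic import (
    AcquisitionProtocol,
    CohortRecord,
    DynamicStudy,
    GammaVariateParams,
    HemodynamicGroundTruth,
    Volume,
)

__all__ = [
    "save_volume",
    "load_volume",
    "save_study",
    "load_study",
    "save_cohort_table",
    "load_cohort_table",
    "save_image_png",
    "save_landmarks",
    "save_phase_set",
    "save_curves",
]


def save_volume(volume: Volume, path):
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32), affine), str(path))


def load_volume(path) -> Volume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(img.dataobj, dtype=np.float32), spacing=spacing)


def _gt_to_json(gt: HemodynamicGroundTruth) -> dict:
    out = {
        "arterial_tdc_params": dataclasses.asdict(gt.arterial_tdc_params),
        "venous_tdc_params": dataclasses.asdict(gt.venous_tdc_params),
        "collateral_tdc_params": dataclasses.asdict(gt.collateral_tdc_params),
        "collateral_fill_fraction_by_phase": list(gt.collateral_fill_fraction_by_phase),
        "occluded_side": gt.occluded_side,
    }
    for key in ("arterial_roi", "venous_roi"):
        roi = getattr(gt, key)
        out[key] = None if roi is None else np.asarray(roi).tolist()
    return out


def _gt_from_json(d: dict) -> HemodynamicGroundTruth:
    return HemodynamicGroundTruth(
        arterial_tdc_params=GammaVariateParams(**d["arterial_tdc_params"]),
        venous_tdc_params=GammaVariateParams(**d["venous_tdc_params"]),
        collateral_tdc_params=GammaVariateParams(**d["collateral_tdc_params"]),
        collateral_fill_fraction_by_phase=tuple(d["collateral_fill_fraction_by_phase"]),
        occluded_side=d["occluded_side"],
        arterial_roi=None if d["arterial_roi"] is None else np.asarray(d["arterial_roi"]),
        venous_roi=None if d["venous_roi"] is None else np.asarray(d["venous_roi"]),
    )


def save_study(study: DynamicStudy, out_dir):
    """Write a study directory: ncct.nii.gz, frame_XX.nii.gz, and a JSON
    sidecar with protocol, ground truth, grade and label."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(study.ncct, out / "ncct.nii.gz")
    for i, (_, vol) in enumerate(study.contrast_frames):
        save_volume(vol, out / f"frame_{i:02d}.nii.gz")
    sidecar = {
        "study_id": study.study_id,
        "frame_times": list(study.protocol.frame_times),
        "grade": study.grade,
        "label": study.label,
        "ground_truth": _gt_to_json(study.ground_truth),
    }
    (out / "study.json").write_text(json.dumps(sidecar, indent=2))


def load_study(study_dir) -> DynamicStudy:
    d = Path(study_dir)
    sidecar = json.loads((d / "study.json").read_text())
    protocol = AcquisitionProtocol(tuple(sidecar["frame_times"]))
    ncct = load_volume(d / "ncct.nii.gz")
    frames = [
        (float(t), load_volume(d / f"frame_{i:02d}.nii.gz"))
        for i, t in enumerate(protocol.contrast_times)
    ]
    return DynamicStudy(
        study_id=sidecar["study_id"],
        protocol=protocol,
        ncct=ncct,
        contrast_frames=frames,
        ground_truth=_gt_from_json(sidecar["ground_truth"]),
        grade=sidecar["grade"],
        label=sidecar["label"],
    )


def save_cohort_table(records: list[CohortRecord], path):
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


def load_cohort_table(path) -> list[CohortRecord]:
    df = pd.read_csv(path)
    return [CohortRecord(**row) for row in df.to_dict(orient="records")]


def save_image_png(image: MIPImage | MontageImage, path):
    """8-bit grayscale PNG; pixel = value * 255 rounded half-up."""
    v = np.asarray(image.values, dtype=np.float64)
    pixels = np.floor(v * 255.0 + 0.5).clip(0, 255).astype(np.uint8)
    Image.fromarray(pixels, mode="L").save(str(path))


def save_landmarks(lm: PhaseLandmarks, path):
    Path(path).write_text(json.dumps(dataclasses.asdict(lm), indent=2))


def save_curves(curves: list[TimeDensityCurve], path):
    payload = [
        {"site": c.site, "times": c.times.tolist(), "values": c.values.tolist()}
        for c in curves
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def save_phase_set(phase_set: PhaseVolumeSet, out_dir, stem: str = "phase"):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, vol in phase_set.volumes.items():
        save_volume(vol, out / f"{stem}_{key}.nii.gz")
    (out / f"{stem}_frames.json").write_text(json.dumps(phase_set.frame_indices, indent=2))
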