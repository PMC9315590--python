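"""Time-density-curve quality control and phase landmark detection.

From the arterial and venous time-density curves (TDCs) of a dynamic
study, four phase landmarks are derived, each resolved to an acquired
contrast frame: the arterial peak ("arterial phase"), the artery-vein
curve crossing ("arteriovenous phase"), the venous peak ("venous
phase"), and the first frame after the venous curve settles into its
plateau ("late venous phase").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .synthetic import DynamicStudy

__all__ = [
    "TimeDensityCurve",
    "CurveQCReport",
    "PhaseLandmarks",
    "extract_tdc",
    "qc_curve",
    "find_peak",
    "find_av_intersection",
    "find_late_venous",
    "landmarks",
]


@dataclass
class TimeDensityCurve:
    """Attenuation above baseline (HU) versus time at a vascular site,
    sampled at the contrast frames only."""

    times: np.ndarray
    values: np.ndarray
    site: str  # "artery" | "vein"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if len(self.times) < 3:
            raise ValueError("a curve needs at least 3 samples")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")


@dataclass(frozen=True)
class CurveQCReport:
    n_peaks: int
    is_bell_shaped: bool
    starts_after_zero: bool
    returns_to_plateau: bool


@dataclass(frozen=True)
class PhaseLandmarks:
    """Times (s) and contrast-frame indices of the four phases."""

    t_arterial_peak: float
    t_av_intersection: float
    t_venous_peak: float
    t_late_venous: float
    frame_arterial: int
    frame_arteriovenous: int
    frame_venous: int
    frame_late_venous: int
    av_flagged: bool = False
    late_venous_flagged: bool = False

    def __post_init__(self):
        if not (
            self.t_arterial_peak < self.t_av_intersection <= self.t_venous_peak
            < self.t_late_venous
        ):
            raise ValueError("phase ordering violated")

    @property
    def frame_indices(self) -> tuple[int, int, int, int]:
        return (
            self.frame_arterial,
            self.frame_arteriovenous,
            self.frame_venous,
            self.frame_late_venous,
        )

    @property
    def times(self) -> tuple[float, float, float, float]:
        return (
            self.t_arterial_peak,
            self.t_av_intersection,
            self.t_venous_peak,
            self.t_late_venous,
        )


# ---------------------------------------------------------------------------


def extract_tdc(study: DynamicStudy, roi: np.ndarray, site: str) -> TimeDensityCurve:
    """Mean attenuation over an ROI per contrast frame, baseline
    (NCCT mean over the same ROI) subtracted.

    ``roi`` is an (n, 3) array of (z, y, x) voxel indices; the
    measurement site is supplied by the caller, not auto-detected.
    """
    roi = np.asarray(roi)
    if roi.ndim != 2 or roi.shape[1] != 3 or len(roi) == 0:
        raise ValueError("roi must be a non-empty (n, 3) voxel index array")
    shape = study.ncct.shape
    if np.any(roi < 0) or np.any(roi >= np.array(shape)):
        raise ValueError("roi indices out of volume bounds")
    z, y, x = roi[:, 0], roi[:, 1], roi[:, 2]
    baseline = float(study.ncct.values[z, y, x].mean())
    times = np.array([t for t, _ in study.contrast_frames])
    values = np.array(
        [float(vol.values[z, y, x].mean()) - baseline for _, vol in study.contrast_frames]
    )
    return TimeDensityCurve(times=times, values=values, site=site)


def qc_curve(
    curve: TimeDensityCurve,
    prominence_frac: float = 0.1,
    rise_frac: float = 0.25,
    plateau_frac: float = 0.5,
) -> CurveQCReport:
    """Check the single-peaked bell shape required of a usable TDC.

    A curve passes when it has exactly one local maximum with prominence
    at least ``prominence_frac`` of the global maximum and that maximum
    is interior (not the first or last sample).  ``starts_after_zero``
    holds when the first sample is still near baseline (below
    ``rise_frac`` of the peak): the first contrast frame legitimately
    samples the early upslope, so the bound is loose.
    """
    v = curve.values
    vmax = float(v.max())
    if vmax <= 0:
        return CurveQCReport(0, False, False, False)
    peaks, _ = find_peaks(v, prominence=prominence_frac * vmax)
    n_peaks = int(len(peaks))
    argmax = int(np.argmax(v))
    interior = 0 < argmax < len(v) - 1
    bell = n_peaks == 1 and interior
    starts_after_zero = bool(v[0] <= rise_frac * vmax)
    returns_to_plateau = bool(v[-1] < plateau_frac * vmax)
    return CurveQCReport(n_peaks, bell, starts_after_zero, returns_to_plateau)


def _require_bell(curve: TimeDensityCurve):
    report = qc_curve(curve)
    if not report.is_bell_shaped:
        raise ValueError(f"{curve.site} curve is not single-peaked bell-shaped")


def find_peak(curve: TimeDensityCurve) -> tuple[float, int]:
    """Time and frame index of the curve's global maximum sample; ties
    break toward the earlier frame."""
    _require_bell(curve)
    idx = int(np.argmax(curve.values))  # argmax returns the first maximum
    return float(curve.times[idx]), idx


def _nearest_frame(times: np.ndarray, t: float) -> int:
    """Index of the sampled time nearest t; ties break earlier."""
    d = np.abs(times - t)
    return int(np.argmin(d))  # argmin takes the first (earlier) minimum


def find_av_intersection(
    arterial: TimeDensityCurve, venous: TimeDensityCurve
) -> tuple[float, int, bool]:
    """First crossing of the arterial and venous curves after the
    arterial peak.

    The linearly interpolated difference (arterial - venous) is scanned
    over (t_arterial_peak, t_venous_peak] for its first sign change from
    >= 0 to < 0; the returned frame is the acquired frame nearest the
    crossing time, bumped forward if snapping would collide with the
    arterial-peak frame (the phases must remain ordered).  If the curves
    never cross in the window, the frame minimising |difference| is
    returned with the flag set.
    """
    _require_bell(arterial)
    _require_bell(venous)
    if not np.allclose(arterial.times, venous.times):
        raise ValueError("curves must share the acquisition grid")
    t_a, i_a = find_peak(arterial)
    t_v, i_v = find_peak(venous)
    if t_a >= t_v:
        raise ValueError("arterial peak must precede venous peak")
    times = arterial.times
    diff = arterial.values - venous.values
    if np.allclose(diff, 0):
        raise ValueError("identical curves: intersection degenerate")
    for i in range(i_a, len(times) - 1):
        d0, d1 = diff[i], diff[i + 1]
        if d0 >= 0 > d1:
            t_star = times[i] + (times[i + 1] - times[i]) * d0 / (d0 - d1)
            if t_star > t_v + 1e-9:  # crossing falls outside (t_a, t_v]
                break
            frame = _nearest_frame(times, t_star)
            if frame <= i_a:
                frame = i_a + 1
            return float(t_star), frame, False
    # no crossing: fall back to the closest approach in the window
    window = slice(i_a + 1, i_v + 1)
    rel = int(np.argmin(np.abs(diff[window])))
    frame = rel + i_a + 1
    return float(times[frame]), frame, True


def find_late_venous(
    venous: TimeDensityCurve,
    plateau_frac: float = 0.5,
    slope_tol: float = 5.0,
) -> tuple[float, int, bool]:
    """First frame after the venous peak where the curve has dropped into
    its plateau: value <= ``plateau_frac`` of the peak and forward
    finite-difference slope magnitude <= ``slope_tol`` (HU/s).

    If no frame qualifies, the last frame is returned with the flag set.
    """
    _require_bell(venous)
    t_peak, i_peak = find_peak(venous)
    if i_peak >= len(venous.values) - 1:
        raise ValueError("venous peak at last frame: no post-peak samples")
    peak_val = venous.values[i_peak]
    for i in range(i_peak + 1, len(venous.values) - 1):
        slope = (venous.values[i + 1] - venous.values[i]) / (
            venous.times[i + 1] - venous.times[i]
        )
        if venous.values[i] <= plateau_frac * peak_val and abs(slope) <= slope_tol:
            return float(venous.times[i]), i, False
    last = len(venous.values) - 1
    return float(venous.times[last]), last, True


def landmarks(
    arterial: TimeDensityCurve,
    venous: TimeDensityCurve,
    *,
    plateau_frac: float = 0.5,
    slope_tol: float = 5.0,
) -> PhaseLandmarks:
    """Compose the three landmark finders into the four phase landmarks,
    enforcing the phase ordering.

    Raises if the venous peak does not follow the arterial peak (the
    curves were mis-selected and must be re-chosen).
    """
    t_a, i_a = find_peak(arterial)
    t_v, i_v = find_peak(venous)
    if t_v <= t_a:
        raise ValueError("venous peak must follow arterial peak; re-select curves")
    t_av, i_av, av_flag = find_av_intersection(arterial, venous)
    t_lv, i_lv, lv_flag = find_late_venous(
        venous, plateau_frac=plateau_frac, slope_tol=slope_tol
    )
    if i_lv <= i_v:
        raise ValueError("late venous frame must follow the venous peak frame")
    return PhaseLandmarks(
        t_arterial_peak=t_a,
        t_av_intersection=t_av,
        t_venous_peak=t_v,
        t_late_venous=t_lv,
        frame_arterial=i_a,
        frame_arteriovenous=i_av,
        frame_venous=i_v,
        frame_late_venous=i_lv,
        av_flagged=av_flag,
        late_venous_flagged=lv_flag,
    )
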