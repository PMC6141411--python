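"""Time-activity curves and first-pass window detection.

A dynamic (ungated) reconstruction of the acquisition yields a cardiac ROI
time-activity curve (TAC) with a sharp early peak — the tracer bolus
transiting the right then left cardiac cavities — followed by a sustained
plateau of tissue uptake.  The gated first-pass reconstruction must be
restricted to the bolus transit, so the transition point between the peak
and the plateau has to be located; here that is automated (with a manual
override preserved for the operator-in-the-loop workflow).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TimeActivityCurve",
    "FirstPassWindow",
    "central_box_roi",
    "extract_tac",
    "detect_first_pass_end",
    "override_window",
]


@dataclass
class TimeActivityCurve:
    """Mean ROI count rate per frame, sampled at frame mid-times."""

    times_s: np.ndarray
    values: np.ndarray
    roi: object = None  # box ((i0,i1),(j0,j1),(k0,k1)) or free-form descriptor
    frame_start_s: np.ndarray = None
    frame_duration_s: np.ndarray = None

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape or self.times_s.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("TAC values must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.times_s.size

    @property
    def acquisition_end_s(self) -> float:
        if self.frame_start_s is not None:
            return float(self.frame_start_s[-1] + self.frame_duration_s[-1])
        # fall back: extrapolate the last mid-time by half the last gap
        return float(self.times_s[-1] + 0.5 * (self.times_s[-1] - self.times_s[-2]))


@dataclass
class FirstPassWindow:
    """Time window of the tracer first pass; t_start defaults to scan start."""

    t_start_s: float
    t_end_s: float
    manual: bool = False

    def __post_init__(self):
        if not 0 <= self.t_start_s < self.t_end_s:
            raise ValueError("require 0 <= t_start < t_end")


def central_box_roi(shape, frac: float = 0.40):
    """Central box covering ``frac`` of each axis (the default cardiac ROI)."""
    roi = []
    for n in shape:
        half = max(1, int(round(n * frac))) / 2.0
        lo = int(np.floor(n / 2.0 - half))
        hi = int(np.ceil(n / 2.0 + half))
        roi.append((max(lo, 0), min(hi, n)))
    return tuple(roi)


def extract_tac(frames, roi=None) -> TimeActivityCurve:
    """Extract the mean ROI rate per frame of a dynamic sequence.

    Parameters
    ----------
    frames : DynamicFrameSequence
    roi : ((i0,i1),(j0,j1),(k0,k1)), optional
        Half-open voxel index bounds; defaults to the central box covering
        40% of each axis ("centred on the cardiac area").

    Returns
    -------
    TimeActivityCurve
        One sample per frame at frame mid-time; value = mean counts inside
        the ROI divided by the frame duration (a rate).
    """
    shape = frames.data.shape[1:]
    if roi is None:
        roi = central_box_roi(shape)
    roi = tuple((int(lo), int(hi)) for lo, hi in roi)
    for (lo, hi), n in zip(roi, shape):
        if not 0 <= lo < hi <= n:
            raise ValueError(f"ROI {roi} out of grid bounds {shape}")
    sel = (slice(None),) + tuple(slice(lo, hi) for lo, hi in roi)
    means = frames.data[sel].mean(axis=(1, 2, 3))
    return TimeActivityCurve(
        times_s=frames.mid_times_s,
        values=means / frames.duration_s,
        roi=roi,
        frame_start_s=frames.start_s,
        frame_duration_s=frames.duration_s,
    )


def detect_first_pass_end(
    tac: TimeActivityCurve,
    *,
    plateau_frac: float = 0.25,
    rel_floor: float = 0.05,
) -> FirstPassWindow:
    """Locate the TAC transition point between the bolus peak and the plateau.

    A linear plateau model is fitted to the last ``plateau_frac`` of the
    frames.  The first pass ends at the start of the earliest post-peak
    frame whose value is indistinguishable from the plateau, i.e. within
    ``max(one plateau-residual SD, rel_floor x peak height above plateau)``
    of the plateau fit.  The rule uses measured frame values rather than a
    decay extrapolation, which makes it exact on a piecewise-linear
    fall-then-flat curve and robust when the plateau is a sizeable fraction
    of the peak.

    Scale-invariant (both the SD and the relative floor scale with the TAC)
    and time-shift equivariant.

    Raises
    ------
    ValueError
        If the TAC has fewer than 6 samples or no strict interior maximum
        ("no first-pass peak detected").
    """
    if tac.n_frames < 6:
        raise ValueError("need at least 6 TAC samples")
    v, t = tac.values, tac.times_s
    p = int(np.argmax(v))
    if p == 0 or p == tac.n_frames - 1 or not (v[p] > v[p - 1] and v[p] > v[p + 1]):
        raise ValueError("no first-pass peak detected")

    n_pl = max(2, int(np.ceil(plateau_frac * tac.n_frames)))
    tp, vp = t[-n_pl:], v[-n_pl:]
    design = np.column_stack([np.ones(n_pl), tp])
    coef, *_ = np.linalg.lstsq(design, vp, rcond=None)
    resid = vp - design @ coef
    dof = max(n_pl - 2, 1)
    sd = float(np.sqrt(np.sum(resid**2) / dof))

    def plateau(x):
        return coef[0] + coef[1] * x

    peak_above = v[p] - plateau(t[p])
    tol = max(sd, rel_floor * max(peak_above, 0.0))
    for i in range(p + 1, tac.n_frames):
        if v[i] - plateau(t[i]) <= tol:
            if tac.frame_start_s is not None:
                t_end = float(tac.frame_start_s[i])
            else:
                t_end = float(0.5 * (t[i - 1] + t[i]))
            t_end = max(t_end, np.nextafter(t[p], np.inf))  # strictly after peak
            return FirstPassWindow(t_start_s=0.0, t_end_s=t_end)
    warnings.warn(
        "no peak-to-plateau transition found; using the last frame start",
        stacklevel=2,
    )
    if tac.frame_start_s is not None:
        return FirstPassWindow(t_start_s=0.0, t_end_s=float(tac.frame_start_s[-1]))
    return FirstPassWindow(t_start_s=0.0, t_end_s=float(0.5 * (t[-2] + t[-1])))


def override_window(tac: TimeActivityCurve, t_end_manual: float) -> FirstPassWindow:
    """Operator override: replace the detected window with a manual one."""
    end = tac.acquisition_end_s
    if not 0 < t_end_manual <= end:
        raise ValueError(
            f"manual first-pass end {t_end_manual} s outside acquisition (0, {end}] s"
        )
    return FirstPassWindow(t_start_s=0.0, t_end_s=float(t_end_manual), manual=True)
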