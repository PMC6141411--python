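"""Synthetic first-pass cardiac PET phantom with known ground truth.

The phantom emulates the data a dynamic + gated first-pass acquisition
produces after reconstruction and reorientation, so that every stage of the
analysis (TAC extraction, first-pass detection, immersion segmentation,
volumetry, curve fitting) can be validated against known volumes and
kinetics:

* indicator-dilution bolus kinetics — a gamma-variate input through the
  right heart, a delayed/dispersed copy through the left heart (convolution
  with a causal mono-exponential kernel), and a slowly rising myocardial
  uptake plateau;
* beating chambers — axis-aligned ellipsoids with a fixed long axis whose
  short axes scale with the cube root^0.5 of nothing fancier than the
  required volume: ``a = b = sqrt(3 V / (4 pi c))`` so the analytic volume
  tracks the physiologic gate-volume curve exactly;
* a myocardial shell around the LV, and an optional right-atrial
  filling-related "hot spot" near the RV base that brightens at
  end-systole (the reason the RV is quantified geometrically);
* Gaussian PSF blur and Poisson counting noise scaled to a configured
  number of prompt events detected over the first-pass window.

Gate 0 is end-diastole (ECG R-wave trigger convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import gammainc, gammaln

from .curvefit import cycle_shape
from .segmentation import CardiacPlanes, GatedImageSeries, Plane
from .tac import TimeActivityCurve, central_box_roi
from .volumetry import FunctionResult

__all__ = [
    "BolusConfig",
    "PhantomConfig",
    "DynamicFrameSequence",
    "GroundTruth",
    "chamber_volume_curve",
    "bolus_kinetics",
    "kinetics_integrals",
    "first_pass_end_true",
    "analytic_tac",
    "default_planes",
    "render",
]

FWHM_TO_SIGMA = 1.0 / 2.3548200450309493


class BolusConfig(BaseModel):
    """First-pass bolus kinetic parameters.

    The right-heart input is a gamma variate ``c_RV(t) = A g(t - arrival)``
    with ``g(x) ~ x^alpha exp(-x/theta)`` normalized to unit peak; the
    left-heart curve is the same input delayed by the pulmonary transit delay
    and convolved with a causal mono-exponential dispersion kernel; the
    myocardial concentration rises mono-exponentially toward a plateau
    fraction of the LV peak.
    """

    amplitude: float = Field(default=1.0, gt=0)
    arrival_s: float = Field(default=5.0, ge=0)
    gamma_shape: float = Field(default=3.0, gt=0)
    gamma_scale_s: float = Field(default=1.5, gt=0)
    lv_delay_s: float = Field(default=4.0, ge=0)
    dispersion_s: float = Field(default=2.5, gt=0)
    myo_plateau_frac: float = Field(default=0.10, ge=0, lt=1)
    myo_tau_s: float = Field(default=20.0, gt=0)
    #: LV concentration fraction of its peak defining the end of first pass.
    first_pass_frac: float = Field(default=0.05, gt=0, lt=0.5)

    @model_validator(mode="after")
    def _check_dispersion(self):
        if self.dispersion_s <= self.gamma_scale_s:
            raise ValueError(
                "dispersion_s must exceed gamma_scale_s (closed-form kinetics)"
            )
        return self


#: Dynamic frame schedule: (count, duration_s) blocks.
DEFAULT_FRAME_SCHEDULE = ((14, 5.0), (3, 10.0), (3, 20.0), (4, 30.0))


class PhantomConfig(BaseModel):
    """Full phantom description; every parameter is explicit, none hard-coded."""

    grid_shape: tuple[int, int, int] = (64, 64, 47)
    voxel_size_mm: float = Field(default=3.27, gt=0)
    n_gates: int = Field(default=8, ge=4)
    cycle_ms: float = Field(default=870.0, gt=0)

    lv_edv_ml: float = Field(default=100.0, gt=0)
    lv_ef_frac: float = Field(default=0.60, gt=0, lt=1)
    rv_edv_ml: float = Field(default=113.0, gt=0)
    rv_ef_frac: float = Field(default=0.531, gt=0, lt=1)
    systole_frac: float = Field(default=0.35, gt=0, lt=0.6)

    bolus: BolusConfig = Field(default_factory=BolusConfig)
    psf_fwhm_mm: float = Field(default=6.0, ge=0)
    total_prompts: float = Field(default=2.0e7, ge=0)
    poisson_noise: bool = True
    rng_seed: int = 0
    frame_schedule: tuple[tuple[int, float], ...] = DEFAULT_FRAME_SCHEDULE

    # geometry, as fractions of the field of view (so phantoms scale with
    # grid size) and absolute lengths in mm
    lv_center_frac: tuple[float, float, float] = (0.64, 0.50, 0.47)
    rv_center_frac: tuple[float, float, float] = (0.33, 0.50, 0.47)
    long_axis_mm: float = Field(default=70.0, gt=0)
    septal_x_frac: float = 0.49
    valve_z_frac: float = 0.72
    infundibular_z_frac: float = 0.70
    myo_gap_mm: float = Field(default=3.0, ge=0)
    myo_thickness_mm: float = Field(default=8.0, ge=0)
    hot_spot: bool = True
    hot_spot_center_frac: tuple[float, float, float] = (0.33, 0.50, 0.78)
    hot_spot_radius_mm: float = Field(default=9.0, gt=0)
    hot_spot_factor: float = Field(default=1.2, ge=0)

    @property
    def fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, dtype=float) * self.voxel_size_mm

    @property
    def voxel_volume_ml(self) -> float:
        return float(self.voxel_size_mm**3 / 1000.0)

    def frame_edges(self) -> tuple[np.ndarray, np.ndarray]:
        """Frame start times and durations (s) from the schedule."""
        durations = np.concatenate(
            [np.full(int(n), float(d)) for n, d in self.frame_schedule]
        )
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return starts, durations


@dataclass
class DynamicFrameSequence:
    """Ungated dynamic frame sequence (counts per frame)."""

    data: np.ndarray  # (n_frames, ni, nj, nk)
    start_s: np.ndarray
    duration_s: np.ndarray
    voxel_size_mm: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.start_s = np.asarray(self.start_s, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D dynamic sequence, got {self.data.ndim}D")
        if len(self.start_s) != self.data.shape[0] or len(self.duration_s) != len(
            self.start_s
        ):
            raise ValueError("frame timing does not match frame count")
        if np.any(self.duration_s <= 0):
            raise ValueError("frame durations must be positive")
        ends = self.start_s + self.duration_s
        if np.any(np.diff(self.start_s) <= 0) or not np.allclose(
            ends[:-1], self.start_s[1:]
        ):
            raise ValueError("frames must be contiguous with increasing times")

    @property
    def mid_times_s(self) -> np.ndarray:
        return self.start_s + 0.5 * self.duration_s

    @property
    def end_s(self) -> float:
        return float(self.start_s[-1] + self.duration_s[-1])


@dataclass
class GroundTruth:
    """As-rendered ground truth: per-gate volumes, function, kinetic timing.

    Per-gate volumes are the voxelized occupancy volumes actually rendered
    (voxel count x voxel volume), so EDV = max, ESV = min, SV = EDV - ESV and
    EF = SV / EDV hold exactly by construction against the rendered images.
    """

    gate_times_ms: np.ndarray
    lv_volumes_ml: np.ndarray
    rv_volumes_ml: np.ndarray
    lv: FunctionResult
    rv: FunctionResult
    first_pass_end_s: float
    lv_masks: np.ndarray  # (n_gates, ni, nj, nk) bool
    rv_masks: np.ndarray
    dyn_masks: dict  # structure name -> static 3D bool mask
    gated_count_scale: float
    dynamic_count_scale: float

    def to_dict(self) -> dict:
        return {
            "gate_times_ms": self.gate_times_ms.tolist(),
            "lv_volumes_ml": self.lv_volumes_ml.tolist(),
            "rv_volumes_ml": self.rv_volumes_ml.tolist(),
            "lv": self.lv.to_dict(),
            "rv": self.rv.to_dict(),
            "first_pass_end_s": float(self.first_pass_end_s),
            "gated_count_scale": float(self.gated_count_scale),
            "dynamic_count_scale": float(self.dynamic_count_scale),
        }


def chamber_volume_curve(
    edv_ml: float,
    ef_frac: float,
    n_gates: int,
    cycle_ms: float,
    systole_frac: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """True per-gate chamber volumes over one cardiac cycle.

    Gate g samples the physiologic cycle shape at phase g / n_gates; the
    end-systolic phase is snapped to the gate grid so that the sampled
    minimum equals ``edv_ml * (1 - ef_frac)`` exactly and the maximum (gate
    0, end-diastole) equals ``edv_ml``.

    Returns
    -------
    (volumes_ml, gate_times_ms)
    """
    if not 0.0 < ef_frac < 1.0:
        raise ValueError(f"ef_frac must be in (0, 1), got {ef_frac}")
    if n_gates < 4:
        raise ValueError(f"need at least 4 gates, got {n_gates}")
    p_es = np.clip(round(systole_frac * n_gates), 1, n_gates - 1) / n_gates
    phases = np.arange(n_gates) / n_gates
    volumes = edv_ml * cycle_shape(phases, ef_frac, p_es)
    gate_times_ms = phases * cycle_ms
    return volumes, gate_times_ms


# ---------------------------------------------------------------------------
# Kinetics (closed forms via the regularized lower incomplete gamma function)
# ---------------------------------------------------------------------------


def _gamma_variate(x, alpha, theta):
    """Unit-peak gamma variate; zero for x <= 0."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    xp = x[pos]
    out[pos] = np.exp(alpha * (np.log(xp / (alpha * theta)) + 1.0) - xp / theta)
    return out


def bolus_kinetics(config: PhantomConfig | BolusConfig, t):
    """Activity concentrations (rv, lv, myo) at time(s) t >= 0.

    The RV curve peaks before the LV curve by construction (pure delay plus
    causal dispersion); the myocardial curve rises monotonically toward
    ``myo_plateau_frac`` of the LV peak.
    """
    b = config.bolus if isinstance(config, PhantomConfig) else config
    t = np.asarray(t, dtype=float)
    alpha, theta, tau = b.gamma_shape, b.gamma_scale_s, b.dispersion_s
    rv = b.amplitude * _gamma_variate(t - b.arrival_s, alpha, theta)

    # LV: convolution of the (delayed) gamma variate with exp(-u/tau)/tau.
    x = t - b.arrival_s - b.lv_delay_s
    c = 1.0 / theta - 1.0 / tau
    lv = np.zeros_like(t)
    pos = x > 0
    if np.any(pos):
        xp = x[pos]
        lognorm = alpha * (np.log(alpha * theta) - 1.0)  # log of peak normalizer
        logpref = gammaln(alpha + 1.0) - (alpha + 1.0) * np.log(c) - np.log(tau)
        lv[pos] = (
            b.amplitude
            * np.exp(logpref - lognorm - xp / tau)
            * gammainc(alpha + 1.0, c * xp)
        )

    m_inf = b.myo_plateau_frac * _lv_peak(b)
    xm = t - b.arrival_s - b.lv_delay_s
    myo = np.where(xm > 0, m_inf * (1.0 - np.exp(-np.maximum(xm, 0) / b.myo_tau_s)), 0.0)
    return rv, lv, myo


def _lv_peak(b: BolusConfig) -> float:
    """Peak LV concentration (numeric; cached on the config object)."""
    cached = getattr(b, "_lv_peak_cache", None)
    if cached is not None:
        return cached
    t = np.arange(0.0, 200.0, 0.01)
    alpha, theta, tau = b.gamma_shape, b.gamma_scale_s, b.dispersion_s
    x = t - b.arrival_s - b.lv_delay_s
    c = 1.0 / theta - 1.0 / tau
    lv = np.zeros_like(t)
    pos = x > 0
    xp = x[pos]
    lognorm = alpha * (np.log(alpha * theta) - 1.0)
    logpref = gammaln(alpha + 1.0) - (alpha + 1.0) * np.log(c) - np.log(tau)
    lv[pos] = (
        b.amplitude * np.exp(logpref - lognorm - xp / tau) * gammainc(alpha + 1.0, c * xp)
    )
    peak = float(lv.max())
    object.__setattr__(b, "_lv_peak_cache", peak)
    return peak


def _lv_peak_time(b: BolusConfig) -> float:
    t = np.arange(0.0, 200.0, 0.01)
    _, lv, _ = bolus_kinetics(b, t)
    return float(t[np.argmax(lv)])


def kinetics_integrals(config: PhantomConfig | BolusConfig, t0, t1):
    """Closed-form time integrals of (rv, lv, myo) concentration over [t0, t1]."""
    b = config.bolus if isinstance(config, PhantomConfig) else config

    def cum(T):
        T = float(T)
        alpha, theta, tau = b.gamma_shape, b.gamma_scale_s, b.dispersion_s
        lognorm = alpha * (np.log(alpha * theta) - 1.0)
        lg = gammaln(alpha + 1.0)
        # RV
        xr = T - b.arrival_s
        if xr > 0:
            irv = b.amplitude * np.exp(
                lg + (alpha + 1.0) * np.log(theta) - lognorm
            ) * gammainc(alpha + 1.0, xr / theta)
        else:
            irv = 0.0
        # LV
        x = T - b.arrival_s - b.lv_delay_s
        if x > 0:
            c = 1.0 / theta - 1.0 / tau
            term1 = np.exp(lg + (alpha + 1.0) * np.log(theta) - lognorm) * gammainc(
                alpha + 1.0, x / theta
            )
            term2 = np.exp(lg - (alpha + 1.0) * np.log(c) - lognorm - x / tau) * gammainc(
                alpha + 1.0, c * x
            )
            ilv = b.amplitude * (term1 - term2)
        else:
            ilv = 0.0
        # myocardium
        xm = T - b.arrival_s - b.lv_delay_s
        if xm > 0:
            m_inf = b.myo_plateau_frac * _lv_peak(b)
            imyo = m_inf * (xm - b.myo_tau_s * (1.0 - np.exp(-xm / b.myo_tau_s)))
        else:
            imyo = 0.0
        return np.array([irv, ilv, imyo])

    return cum(t1) - cum(t0)


def first_pass_end_true(config: PhantomConfig | BolusConfig) -> float:
    """Ground-truth end of first pass (s).

    Defined as the time, after the LV peak, at which the LV chamber
    concentration has decayed to ``first_pass_frac`` of its peak — i.e. the
    bolus has essentially cleared the cardiac cavities and the myocardial
    plateau takes over.
    """
    b = config.bolus if isinstance(config, PhantomConfig) else config
    peak = _lv_peak(b)
    tp = _lv_peak_time(b)

    def f(t):
        return bolus_kinetics(b, np.array([t]))[1][0] - b.first_pass_frac * peak

    return float(brentq(f, tp, tp + 300.0))


# ---------------------------------------------------------------------------
# Geometry and rendering
# ---------------------------------------------------------------------------


def _semi_axes(volume_ml: float, long_axis_mm: float) -> tuple[float, float]:
    """(short, long) semi-axes (mm) of an ellipsoid with a fixed long axis.

    The two short semi-axes are equal and scale with the square root of the
    volume so that ``4/3 pi a^2 c`` equals the requested volume exactly.
    """
    c = long_axis_mm / 2.0
    a = np.sqrt(3.0 * volume_ml * 1000.0 / (4.0 * np.pi * c))
    return float(a), float(c)


def _voxel_centers(config: PhantomConfig):
    nx, ny, nz = config.grid_shape
    v = config.voxel_size_mm
    x = (np.arange(nx) + 0.5) * v
    y = (np.arange(ny) + 0.5) * v
    z = (np.arange(nz) + 0.5) * v
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _ellipsoid_mask(config, center_mm, semi_mm, name: str) -> np.ndarray:
    lo = np.asarray(center_mm) - np.asarray(semi_mm)
    hi = np.asarray(center_mm) + np.asarray(semi_mm)
    if np.any(lo < 0) or np.any(hi > config.fov_mm):
        raise ValueError(
            f"{name} geometry (extent {lo.round(1)}..{hi.round(1)} mm) "
            f"does not fit inside the grid (FOV {config.fov_mm.round(1)} mm)"
        )
    x, y, z = _voxel_centers(config)
    cx, cy, cz = center_mm
    a, b, c = semi_mm
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0


def _chamber_masks(config: PhantomConfig, volumes_ml, center_frac, name):
    center = np.asarray(center_frac) * config.fov_mm
    masks = []
    for v in volumes_ml:
        a, c = _semi_axes(v, config.long_axis_mm)
        masks.append(_ellipsoid_mask(config, center, (a, a, c), name))
    return np.stack(masks)


def _static_geometry(config: PhantomConfig, lv_vols, rv_vols):
    """Myocardial shell (around the LV at EDV) and optional hot-spot mask."""
    lv_center = np.asarray(config.lv_center_frac) * config.fov_mm
    a_ed, c_ed = _semi_axes(float(np.max(lv_vols)), config.long_axis_mm)
    inner = (
        a_ed + config.myo_gap_mm,
        a_ed + config.myo_gap_mm,
        c_ed + config.myo_gap_mm,
    )
    outer = tuple(s + config.myo_thickness_mm for s in inner)
    myo = _ellipsoid_mask(config, lv_center, outer, "myocardium") & ~_ellipsoid_mask(
        config, lv_center, inner, "myocardium"
    )
    hot = None
    if config.hot_spot:
        hc = np.asarray(config.hot_spot_center_frac) * config.fov_mm
        r = config.hot_spot_radius_mm
        hot = _ellipsoid_mask(config, hc, (r, r, r), "hot spot")
    return myo, hot


def default_planes(config: PhantomConfig) -> CardiacPlanes:
    """The true reference planes of the phantom geometry, in voxel coords."""
    nx, ny, nz = config.grid_shape

    def vox(frac, n):
        return frac * n - 0.5

    cy = vox(0.5, ny)
    septal = Plane(
        point=(vox(config.septal_x_frac, nx), cy, vox(0.5, nz)), normal=(1.0, 0.0, 0.0)
    )
    valve = Plane(
        point=(vox(0.5, nx), cy, vox(config.valve_z_frac, nz)), normal=(0.0, 0.0, -1.0)
    )
    infund = Plane(
        point=(vox(0.5, nx), cy, vox(config.infundibular_z_frac, nz)),
        normal=(0.0, 0.0, -1.0),
    )
    return CardiacPlanes(septal=septal, valve=valve, infundibular=infund)


def _es_gate(config: PhantomConfig) -> int:
    return int(np.clip(round(config.systole_frac * config.n_gates), 1, config.n_gates - 1))


def render(
    config: PhantomConfig,
) -> tuple[DynamicFrameSequence, GatedImageSeries, GroundTruth]:
    """Render the phantom: dynamic sequence, gated series and ground truth.

    Deterministic given ``config.rng_seed``.  The gated series integrates the
    kinetics over the (true) first-pass window, split evenly across gates;
    the dynamic sequence integrates them over each frame with the chambers
    frozen at their cycle-average volume (cardiac motion is averaged out in
    an ungated reconstruction).  Expected counts are scaled so the total over
    the first-pass window equals ``total_prompts``, then Poisson-sampled when
    ``poisson_noise`` is on.
    """
    rng = np.random.default_rng(config.rng_seed)
    lv_vols, gate_times_ms = chamber_volume_curve(
        config.lv_edv_ml, config.lv_ef_frac, config.n_gates, config.cycle_ms,
        config.systole_frac,
    )
    rv_vols, _ = chamber_volume_curve(
        config.rv_edv_ml, config.rv_ef_frac, config.n_gates, config.cycle_ms,
        config.systole_frac,
    )
    lv_masks = _chamber_masks(config, lv_vols, config.lv_center_frac, "LV")
    rv_masks = _chamber_masks(config, rv_vols, config.rv_center_frac, "RV")
    myo_mask, hot_mask = _static_geometry(config, lv_vols, rv_vols)

    t_end = first_pass_end_true(config)
    i_rv, i_lv, i_myo = kinetics_integrals(config, 0.0, t_end)
    n_gates = config.n_gates
    g_es = _es_gate(config)
    sigma_vox = config.psf_fwhm_mm * FWHM_TO_SIGMA / config.voxel_size_mm

    gated = np.zeros((n_gates,) + tuple(config.grid_shape))
    for g in range(n_gates):
        img = (
            lv_masks[g] * (i_lv / n_gates)
            + rv_masks[g] * (i_rv / n_gates)
            + myo_mask * (i_myo / n_gates)
        )
        if hot_mask is not None:
            w = np.exp(-0.5 * float(g - g_es) ** 2)
            img = img + hot_mask * (config.hot_spot_factor * i_rv / n_gates * w)
        if sigma_vox > 0:
            img = gaussian_filter(img, sigma=sigma_vox, mode="constant")
        gated[g] = img
    total_expected = gated.sum()
    gated_scale = config.total_prompts / total_expected if total_expected > 0 else 1.0
    gated *= gated_scale
    if config.poisson_noise:
        gated = rng.poisson(gated).astype(float)
    gated_series = GatedImageSeries(
        intensities=gated, voxel_size_mm=config.voxel_size_mm, cycle_ms=config.cycle_ms
    )

    # dynamic sequence: static chambers at cycle-average volume
    lv_dyn = _chamber_masks(
        config, [float(np.mean(lv_vols))], config.lv_center_frac, "LV"
    )[0]
    rv_dyn = _chamber_masks(
        config, [float(np.mean(rv_vols))], config.rv_center_frac, "RV"
    )[0]
    starts, durations = config.frame_edges()
    n_frames = len(starts)
    dyn = np.zeros((n_frames,) + tuple(config.grid_shape))
    window_counts = (
        int(rv_dyn.sum()) * i_rv + int(lv_dyn.sum()) * i_lv + int(myo_mask.sum()) * i_myo
    )
    dyn_scale = config.total_prompts / window_counts if window_counts > 0 else 1.0
    for f in range(n_frames):
        fr_rv, fr_lv, fr_myo = kinetics_integrals(
            config, starts[f], starts[f] + durations[f]
        )
        img = lv_dyn * fr_lv + rv_dyn * fr_rv + myo_mask * fr_myo
        if sigma_vox > 0:
            img = gaussian_filter(img, sigma=sigma_vox, mode="constant")
        dyn[f] = img
    dyn *= dyn_scale
    if config.poisson_noise:
        dyn = rng.poisson(dyn).astype(float)
    dynamic = DynamicFrameSequence(
        data=dyn, start_s=starts, duration_s=durations, voxel_size_mm=config.voxel_size_mm
    )

    vv = config.voxel_volume_ml
    lv_true = lv_masks.sum(axis=(1, 2, 3)) * vv
    rv_true = rv_masks.sum(axis=(1, 2, 3)) * vv
    truth = GroundTruth(
        gate_times_ms=gate_times_ms,
        lv_volumes_ml=lv_true,
        rv_volumes_ml=rv_true,
        lv=FunctionResult.from_volumes(lv_true, source="ground_truth"),
        rv=FunctionResult.from_volumes(rv_true, source="ground_truth"),
        first_pass_end_s=t_end,
        lv_masks=lv_masks,
        rv_masks=rv_masks,
        dyn_masks={"lv": lv_dyn, "rv": rv_dyn, "myo": myo_mask},
        gated_count_scale=float(gated_scale),
        dynamic_count_scale=float(dyn_scale),
    )
    return dynamic, gated_series, truth


def analytic_tac(config: PhantomConfig, roi=None) -> TimeActivityCurve:
    """Noiseless, blur-free ROI time-activity curve implied by the phantom.

    Computes the mean count rate per frame inside ``roi`` (default: the
    central box covering 40% of each axis) directly from the closed-form
    kinetic integrals and the static dynamic-geometry masks, without
    rendering full frames.  Useful for fast validation of first-pass
    detection over many kinetic settings.
    """
    lv_vols, _ = chamber_volume_curve(
        config.lv_edv_ml, config.lv_ef_frac, config.n_gates, config.cycle_ms,
        config.systole_frac,
    )
    rv_vols, _ = chamber_volume_curve(
        config.rv_edv_ml, config.rv_ef_frac, config.n_gates, config.cycle_ms,
        config.systole_frac,
    )
    lv_dyn = _chamber_masks(
        config, [float(np.mean(lv_vols))], config.lv_center_frac, "LV"
    )[0]
    rv_dyn = _chamber_masks(
        config, [float(np.mean(rv_vols))], config.rv_center_frac, "RV"
    )[0]
    myo_mask, _ = _static_geometry(config, lv_vols, rv_vols)
    if roi is None:
        roi = central_box_roi(tuple(config.grid_shape))
    sel = tuple(slice(lo, hi) for lo, hi in roi)
    n_roi = int(np.prod([hi - lo for lo, hi in roi]))
    n_rv = int(rv_dyn[sel].sum())
    n_lv = int(lv_dyn[sel].sum())
    n_myo = int(myo_mask[sel].sum())

    t_end = first_pass_end_true(config)
    i_rv, i_lv, i_myo = kinetics_integrals(config, 0.0, t_end)
    window_counts = (
        int(rv_dyn.sum()) * i_rv + int(lv_dyn.sum()) * i_lv + int(myo_mask.sum()) * i_myo
    )
    scale = config.total_prompts / window_counts if window_counts > 0 else 1.0

    starts, durations = config.frame_edges()
    values = np.empty(len(starts))
    for f in range(len(starts)):
        fr_rv, fr_lv, fr_myo = kinetics_integrals(config, starts[f], starts[f] + durations[f])
        values[f] = (
            scale * (n_rv * fr_rv + n_lv * fr_lv + n_myo * fr_myo) / (n_roi * durations[f])
        )
    return TimeActivityCurve(
        times_s=starts + 0.5 * durations,
        values=values,
        roi=roi,
        frame_start_s=starts,
        frame_duration_s=durations,
    )
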