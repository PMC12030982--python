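"""Ground-truth-labelled synthetic multi-sensor gait generator.

Emulates exoskeleton-assisted crutch gait as recorded by the four-peripheral
system, so that every pipeline stage (frame assembly, fuzzy gait-phase
estimation, CoP and crutch-GRF computation, event detection, validation
statistics) can be exercised without hardware:

* six plantar FSR channels follow per-phase High/Low activation templates
  taken mechanically from the eight-row rule table (High placements loaded,
  Low unloaded), with smooth transitions, a sharp impact transient on each
  heel at heel strike, additive Gaussian noise, slow linear drift and
  clipping at the empirical saturation level;
* each crutch carries a bell-shaped (raised-cosine) axial force burst per
  contralateral step, with the IMU sweeping a small sagittal inclination
  arc sized so that transverse force leakage stays below the configured
  fraction of the vertical force;
* toe/heel/sternum marker trajectories come from a planar leg-and-trunk
  kinematic model whose extrema coincide exactly with the ground-truth
  event times (the marker reference method's working assumption);
* cycle durations are drawn from a positive-truncated normal distribution
  (default 3.33 s mean, 1.16 s SD — slow exoskeleton stepping).

All randomness flows from the explicit seed in the configuration; the same
seed reproduces the same session bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .biomech_metrics import InsoleGeometry, cop_series
from .fuzzy_gait import PHASES, PLACEMENTS, default_rules
from .sensor_stream import RecordingSession, session_from_arrays

__all__ = [
    "GaitSimConfig",
    "GaitGroundTruth",
    "CopSweepSim",
    "CrutchLoadingSim",
    "simulate_session",
    "simulate_cop_sweep",
    "simulate_crutch_loading",
]


@dataclass(frozen=True)
class GaitSimConfig:
    """Study conditions for the synthetic gait generator.

    Defaults reproduce the conditions of the validation protocol: 130 Hz
    wearable sampling, 150 Hz markers, 3.33 +/- 1.16 s cycle durations,
    FSR noise of 2% full scale, ~300 N peak crutch loading with transverse
    leakage below 7% of vertical, and FSR plateaus that stop short of the
    theoretical sensor maximum (saturation at 85% of full scale).
    """

    n_strides: int = 10
    step_duration_mean: float = 3.33
    step_duration_sd: float = 1.16
    phase_fractions: tuple[float, ...] = (0.125,) * 8
    fsr_full_scale: float = 4095.0  # 12-bit ADC counts
    fsr_noise_sd: float = 0.02  # fraction of full scale
    fsr_drift_rate: float = 0.01  # fraction of full scale per minute
    saturation_level: float = 0.85  # fraction of the theoretical maximum
    baseline_level: float = 0.05  # unloaded-sensor preload, fraction of full scale
    plateau_level: float = 0.6  # loaded-placement plateau, fraction of full scale
    impact_peak: float = 0.8  # heel impact transient apex, fraction of full scale
    impact_width: float = 0.04  # impact transient Gaussian sigma, seconds
    transition_s: float = 0.08  # phase-template crossfade time constant, seconds
    crutch_peak_force: float = 300.0  # N
    crutch_transverse_fraction: float = 0.07
    crutch_axial_noise: float = 0.01  # fraction of peak force
    crutch_orientation_noise_deg: float = 2.0
    imu_noise_deg: float = 0.5
    marker_noise_m: float = 0.0
    step_length: float = 0.35  # m advanced per cycle (slow exoskeleton steps)
    foot_length: float = 0.25  # heel-to-toe marker distance, m
    sample_rate: float = 130.0
    marker_rate: float = 150.0
    lead_in: float = 1.0  # s of quiet stance before the first heel strike
    tail_out: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_strides < 1:
            raise ValueError("n_strides must be >= 1")
        if self.sample_rate <= 0 or self.marker_rate <= 0:
            raise ValueError("sampling rates must be positive")
        if len(self.phase_fractions) != 8:
            raise ValueError("phase_fractions must have 8 entries")
        if abs(sum(self.phase_fractions) - 1.0) > 1e-9:
            raise ValueError("phase_fractions must sum to 1")
        if min(self.phase_fractions) <= 0:
            raise ValueError("phase fractions must be positive")
        for name in ("fsr_noise_sd", "fsr_drift_rate", "crutch_axial_noise",
                     "crutch_orientation_noise_deg", "imu_noise_deg", "marker_noise_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.crutch_transverse_fraction < 1:
            raise ValueError("crutch_transverse_fraction must be in (0, 1)")
        if not (0 <= self.baseline_level < self.plateau_level < self.impact_peak
                <= self.saturation_level <= 1):
            raise ValueError(
                "require 0 <= baseline_level < plateau_level < impact_peak "
                "<= saturation_level <= 1"
            )
        if self.step_duration_mean <= 0 or self.step_duration_sd < 0:
            raise ValueError("step duration mean must be > 0 and SD >= 0")

    def noiseless(self) -> "GaitSimConfig":
        """Copy of this configuration with every noise source silenced."""
        return replace(
            self,
            fsr_noise_sd=0.0,
            fsr_drift_rate=0.0,
            crutch_axial_noise=0.0,
            crutch_orientation_noise_deg=0.0,
            imu_noise_deg=0.0,
            marker_noise_m=0.0,
        )


@dataclass
class GaitGroundTruth:
    """Everything the simulator knows that the sensors only estimate."""

    timestamps: np.ndarray  # 130 Hz master-clock grid, s
    phase_labels: list[str]  # crisp per-frame phase
    heel_strikes: dict[str, np.ndarray]  # side -> event times, s
    toe_offs: dict[str, np.ndarray]
    cycle_durations: np.ndarray
    cop_y: dict[str, np.ndarray]  # side -> true AP CoP (mm, NaN when unloaded)
    crutch_force_world: dict[str, np.ndarray]  # side -> (n, 3) vertical/AP/ML, N
    crutch_orientation: dict[str, np.ndarray]  # side -> (n, 4) quaternions (x,y,z,w)
    marker_time: np.ndarray  # 150 Hz grid, s
    markers: dict[str, np.ndarray]  # "<side>_heel"/"<side>_toe"/"sternum" -> (n, 3) m


# Per-phase loading templates, one row per rule-table phase in cycle order.
def _phase_templates() -> np.ndarray:
    """(8, 6) binary matrix: template[phase, placement] = 1 if loaded (High)."""
    base = default_rules()
    template = np.zeros((8, len(PLACEMENTS)))
    for row, rule in enumerate(base.rules):
        for col, placement in enumerate(PLACEMENTS):
            template[row, col] = 1.0 if rule.conditions[placement] == "High" else 0.0
    return template


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Positive-truncated normal draws (rejection sampling)."""
    if sd == 0:
        return np.full(n, mean)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draws = rng.normal(mean, sd, size=2 * (n - filled))
        draws = draws[draws > 0]
        take = min(draws.size, n - filled)
        out[filled:filled + take] = draws[:take]
        filled += take
    return out


def _euler_to_quat(roll_deg: np.ndarray, pitch_deg: np.ndarray, yaw_deg: np.ndarray) -> np.ndarray:
    eul = np.column_stack([roll_deg, pitch_deg, yaw_deg])
    return Rotation.from_euler("xyz", eul, degrees=True).as_quat()


def simulate_session(
    cfg: GaitSimConfig,
    geometry: InsoleGeometry | None = None,
) -> tuple[RecordingSession, GaitGroundTruth]:
    """Generate one synchronized multi-sensor recording with ground truth."""
    geometry = geometry or InsoleGeometry.default("medium")
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate
    full_scale = cfg.fsr_full_scale

    durations = _truncated_normal(rng, cfg.step_duration_mean, cfg.step_duration_sd,
                                  cfg.n_strides)
    cycle_starts = cfg.lead_in + np.concatenate([[0.0], np.cumsum(durations[:-1])])
    total = cfg.lead_in + float(durations.sum()) + cfg.tail_out
    n = int(round(total * fs))
    t = np.arange(n) / fs

    fractions = np.asarray(cfg.phase_fractions)
    bounds = np.concatenate([[0.0], np.cumsum(fractions)])  # 0..1 within a cycle

    # Crisp phase index per sample (lead-in and tail-out hold Terminal Swing,
    # the phase that precedes the right heel strike).
    phase_idx = np.full(n, 7, dtype=int)
    for k, (start, dur) in enumerate(zip(cycle_starts, durations)):
        for j in range(8):
            lo = start + bounds[j] * dur
            hi = start + bounds[j + 1] * dur
            phase_idx[(t >= lo) & (t < hi)] = j

    # Ground-truth events.  Right heel strike = cycle start (template row 1
    # turns RH High); left heel strike = start of Terminal Stance (row 4,
    # LH turns High).  Right toe-off = start of Initial Swing (row 6);
    # left toe-off = start of Mid-stance (row 3, the left foot's only fully
    # unloaded template row).
    hs_right = cycle_starts.copy()
    hs_left = cycle_starts + bounds[3] * durations
    to_right = cycle_starts + bounds[5] * durations
    to_left = cycle_starts + bounds[2] * durations

    # Smooth loading level per placement: the crisp template holds until each
    # phase boundary, then ramps linearly to the new value over transition_s
    # (a causal moving average of the crisp step train).  Keeping the signal
    # exactly crisp up to the boundary means the classifier's flip instant
    # coincides with the ground-truth label change.
    template = _phase_templates()
    ramp = max(1, int(round(cfg.transition_s * fs)))
    kernel = np.ones(ramp) / ramp
    levels = np.empty((n, 6))
    for col in range(6):
        crisp = template[phase_idx, col]
        padded = np.concatenate([np.full(ramp - 1, crisp[0]), crisp])
        levels[:, col] = np.convolve(padded, kernel, mode="valid")
    # Unloaded sensors sit at a small preload (FSRs never read exactly zero
    # in a fitted insole); loaded sensors plateau below saturation.
    levels = cfg.baseline_level + levels * (cfg.plateau_level - cfg.baseline_level)

    # Heel impact transients: pressure rises sharply to an apex exactly at
    # the heel-strike time, then settles onto the stance plateau without
    # dipping below it, so the local maximum of the heel trace marks the
    # event and the plateau carries no spurious high-prominence peaks.
    def add_impacts(level_col: np.ndarray, event_times: np.ndarray) -> np.ndarray:
        out = level_col.copy()
        for t_ev in event_times:
            lo = np.searchsorted(t, t_ev - 5 * cfg.impact_width)
            hi = np.searchsorted(t, t_ev + 5 * cfg.impact_width)
            tt = t[lo:hi]
            gauss = np.exp(-0.5 * ((tt - t_ev) / cfg.impact_width) ** 2)
            bump = np.where(
                tt < t_ev,
                cfg.impact_peak * gauss,
                cfg.plateau_level + (cfg.impact_peak - cfg.plateau_level) * gauss,
            )
            out[lo:hi] = np.maximum(out[lo:hi], bump)
        return out

    col = {p: i for i, p in enumerate(PLACEMENTS)}
    levels[:, col["RH"]] = add_impacts(levels[:, col["RH"]], hs_right)
    levels[:, col["LH"]] = add_impacts(levels[:, col["LH"]], hs_left)

    clean_raw = levels * full_scale  # noiseless loads, raw ADC units

    # True per-foot CoP from the noiseless loads.
    cop_truth: dict[str, np.ndarray] = {}
    for side, names in (("left", ("LH", "L1M", "L5M")), ("right", ("RH", "R1M", "R5M"))):
        triplet = clean_raw[:, [col[names[0]], col[names[1]], col[names[2]]]]
        y, _, _ = cop_series(triplet, geometry, min_total=0.02 * full_scale)
        cop_truth[side] = y

    # Measurement model: additive Gaussian noise, linear drift, clipping at
    # the saturation level, non-negative readings.
    noisy_raw = clean_raw.copy()
    if cfg.fsr_noise_sd > 0:
        noisy_raw += rng.normal(0.0, cfg.fsr_noise_sd * full_scale, size=noisy_raw.shape)
    if cfg.fsr_drift_rate > 0:
        drift_slopes = rng.uniform(-1.0, 1.0, size=6) * cfg.fsr_drift_rate
        noisy_raw += np.outer(t / 60.0, drift_slopes) * full_scale
    np.clip(noisy_raw, 0.0, cfg.saturation_level * full_scale, out=noisy_raw)

    # Crutch loading: each crutch bears a raised-cosine axial burst while the
    # contralateral foot swings, with a small sagittal sweep of the shaft.
    max_tilt = math.degrees(math.atan(0.9 * cfg.crutch_transverse_fraction))
    roll_tilt = math.degrees(math.atan(0.3 * cfg.crutch_transverse_fraction))
    crutch_truth_force: dict[str, np.ndarray] = {}
    crutch_truth_quat: dict[str, np.ndarray] = {}
    crutch_channels: dict[str, dict[str, np.ndarray]] = {}
    swing_windows = {
        # left crutch loads while the right foot swings and vice versa
        "left_crutch": (bounds[5], bounds[8]),
        "right_crutch": (bounds[2], bounds[3]),
    }
    for crutch, (f_lo, f_hi) in swing_windows.items():
        axial = np.zeros(n)
        pitch = np.zeros(n)
        for start, dur in zip(cycle_starts, durations):
            lo_t = start + f_lo * dur
            hi_t = start + f_hi * dur
            center = 0.5 * (lo_t + hi_t)
            width = hi_t - lo_t
            lo = np.searchsorted(t, lo_t)
            hi = np.searchsorted(t, hi_t)
            u = (t[lo:hi] - center) / width  # -0.5 .. 0.5
            axial[lo:hi] = cfg.crutch_peak_force * 0.5 * (1.0 + np.cos(2 * np.pi * u))
            pitch[lo:hi] = -2.0 * max_tilt * u  # sweeps +tilt/2 -> -tilt/2
        roll = roll_tilt * np.sin(2 * np.pi * t / max(durations.mean(), 1e-6))
        quat = _euler_to_quat(roll, pitch, np.zeros(n))
        rot = Rotation.from_quat(quat)
        local = np.zeros((n, 3))
        local[:, 2] = axial
        world = rot.apply(local)[:, [2, 0, 1]]  # vertical, AP, ML
        crutch_truth_force[crutch.split("_")[0]] = world
        crutch_truth_quat[crutch.split("_")[0]] = quat

        axial_meas = axial.copy()
        if cfg.crutch_axial_noise > 0:
            axial_meas += rng.normal(0.0, cfg.crutch_axial_noise * cfg.crutch_peak_force,
                                     size=n)
        ori_noise = cfg.crutch_orientation_noise_deg
        crutch_channels[crutch] = {
            "force_axial": axial_meas,
            "roll": roll + (rng.normal(0, ori_noise, n) if ori_noise > 0 else 0.0),
            "pitch": pitch + (rng.normal(0, ori_noise, n) if ori_noise > 0 else 0.0),
            "yaw": rng.normal(0, ori_noise, n) if ori_noise > 0 else np.zeros(n),
        }

    # Marker kinematics (planar): the sternum advances at the cycle-average
    # speed; each foot is stationary in stance and advances by one step
    # length during its swing with constant velocity, so the signed AP
    # heel-sternum offset peaks exactly at heel strike and the toe-sternum
    # offset bottoms out exactly at toe-off.
    n_m = int(round(total * cfg.marker_rate))
    t_m = np.arange(n_m) / cfg.marker_rate

    def _piecewise_advance(swing_starts: np.ndarray, swing_ends: np.ndarray,
                           x0: float) -> np.ndarray:
        x = np.full(n_m, x0)
        pos = x0
        for s, e in zip(swing_starts, swing_ends):
            in_swing = (t_m >= s) & (t_m < e)
            u = np.clip((t_m - s) / (e - s), 0.0, 1.0)
            x = np.where(in_swing, pos + cfg.step_length * u, x)
            x = np.where(t_m >= e, pos + cfg.step_length, x)
            pos += cfg.step_length
        return x

    session_end = cfg.lead_in + float(durations.sum())
    right_swing_start = to_right
    right_swing_end = np.concatenate([cycle_starts[1:], [session_end]])
    left_swing_start = to_left
    left_swing_end = hs_left

    x_right = _piecewise_advance(right_swing_start, right_swing_end, 0.0)
    x_left = _piecewise_advance(left_swing_start, left_swing_end, -cfg.step_length / 2)
    x_sternum = np.interp(
        t_m,
        np.concatenate([[0.0], cycle_starts + durations]),
        np.concatenate([[0.0], np.cumsum(np.full(cfg.n_strides, cfg.step_length))])
        - cfg.step_length / 4,
    )

    def lift(swing_starts: np.ndarray, swing_ends: np.ndarray) -> np.ndarray:
        z = np.zeros(n_m)
        for s, e in zip(swing_starts, swing_ends):
            in_swing = (t_m >= s) & (t_m < e)
            u = (t_m - s) / (e - s)
            z = np.where(in_swing, 0.05 * np.sin(np.pi * np.clip(u, 0, 1)), z)
        return z

    z_right = lift(right_swing_start, right_swing_end)
    z_left = lift(left_swing_start, left_swing_end)
    markers = {
        "right_heel": np.column_stack([x_right, np.full(n_m, 0.10), z_right]),
        "right_toe": np.column_stack([x_right + cfg.foot_length, np.full(n_m, 0.10), z_right]),
        "left_heel": np.column_stack([x_left, np.full(n_m, -0.10), z_left]),
        "left_toe": np.column_stack([x_left + cfg.foot_length, np.full(n_m, -0.10), z_left]),
        "sternum": np.column_stack([x_sternum, np.zeros(n_m), np.full(n_m, 1.30)]),
    }
    if cfg.marker_noise_m > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(0, cfg.marker_noise_m,
                                                       markers[name].shape)

    # Assemble the recording session.
    imu_noise = cfg.imu_noise_deg
    channel_arrays: dict[str, np.ndarray] = {}
    insole_cols = {"left_insole": ("LH", "L1M", "L5M"), "right_insole": ("RH", "R1M", "R5M")}
    for insole, (h, m1, m5) in insole_cols.items():
        channel_arrays[f"{insole}_fsr_heel"] = noisy_raw[:, col[h]]
        channel_arrays[f"{insole}_fsr_m1"] = noisy_raw[:, col[m1]]
        channel_arrays[f"{insole}_fsr_m5"] = noisy_raw[:, col[m5]]
        for ch in ("roll", "pitch", "yaw"):
            channel_arrays[f"{insole}_{ch}"] = (
                rng.normal(0, imu_noise, n) if imu_noise > 0 else np.zeros(n)
            )
        for ch in ("angacc_x", "angacc_y", "angacc_z"):
            channel_arrays[f"{insole}_{ch}"] = (
                rng.normal(0, 10 * imu_noise, n) if imu_noise > 0 else np.zeros(n)
            )
    for crutch, chans in crutch_channels.items():
        for ch, series in chans.items():
            channel_arrays[f"{crutch}_{ch}"] = series
        for ch in ("angacc_x", "angacc_y", "angacc_z"):
            channel_arrays[f"{crutch}_{ch}"] = (
                rng.normal(0, 10 * imu_noise, n) if imu_noise > 0 else np.zeros(n)
            )

    session = session_from_arrays(
        timestamps=t,
        channel_arrays=channel_arrays,
        nominal_rate=fs,
        active_peripherals=("left_insole", "right_insole", "left_crutch", "right_crutch"),
        metadata={"generator": "exogait.synthetic_gait", "seed": str(cfg.seed)},
    )
    truth = GaitGroundTruth(
        timestamps=t,
        phase_labels=[PHASES[j] for j in phase_idx],
        heel_strikes={"left": hs_left, "right": hs_right},
        toe_offs={"left": to_left, "right": to_right},
        cycle_durations=durations,
        cop_y=cop_truth,
        crutch_force_world=crutch_truth_force,
        crutch_orientation=crutch_truth_quat,
        marker_time=t_m,
        markers=markers,
    )
    return session, truth


@dataclass
class CopSweepSim:
    """A circular CoP sweep with the FSR triplet that reproduces it exactly."""

    timestamps: np.ndarray
    fsr: np.ndarray  # (n, 3) noisy readings (heel, m1, m5), raw units
    fsr_clean: np.ndarray
    true_y: np.ndarray  # mm
    true_x: np.ndarray  # mm


def _barycentric(points: np.ndarray, triangle: np.ndarray) -> np.ndarray:
    """Barycentric weights of (n, 2) points w.r.t. a 3x2 triangle."""
    a, b, c = triangle
    m = np.column_stack([b - a, c - a])  # 2x2
    inv = np.linalg.inv(m)
    uv = (points - a) @ inv.T
    w = np.column_stack([1.0 - uv.sum(axis=1), uv[:, 0], uv[:, 1]])
    return w


def simulate_cop_sweep(
    cfg: GaitSimConfig,
    geom: InsoleGeometry | None = None,
    n_cycles: int = 18,
    radius: float | None = None,
    period: float = 5.0,
    load_fraction: float = 0.8,
) -> CopSweepSim:
    """Circular CoP reference path plus FSRs constructed by inverting Eq. 6.

    The target path is a clockwise circle inside the sensor triangle; the
    FSR triplet carries the barycentric weights of each target point scaled
    by a constant total load, so the noiseless weighted-average CoP equals
    the path exactly.  Configured FSR noise is then added.
    """
    geom = geom or InsoleGeometry.default("medium")
    rng = np.random.default_rng(cfg.seed)
    tri = geom.xy  # (3, 2) (x, y) mm
    center = tri.mean(axis=0)
    if radius is None:
        # largest circle safely inside the triangle around its centroid
        radius = 0.8 * _min_edge_distance(center, tri)
    n = int(round(n_cycles * period * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    ang = -2 * np.pi * t / period  # clockwise
    path = center + radius * np.column_stack([np.cos(ang), np.sin(ang)])
    w = _barycentric(path, tri)
    if np.any(w < -1e-9):
        raise ValueError(
            f"CoP path of radius {radius:.1f} mm leaves the sensor hull; "
            "reduce the radius or widen the geometry"
        )
    w = np.clip(w, 0.0, None)
    total = load_fraction * cfg.fsr_full_scale
    clean = w * total
    noisy = clean.copy()
    if cfg.fsr_noise_sd > 0:
        noisy += rng.normal(0.0, cfg.fsr_noise_sd * cfg.fsr_full_scale, size=clean.shape)
        noisy = np.clip(noisy, 0.0, cfg.saturation_level * cfg.fsr_full_scale)
    return CopSweepSim(
        timestamps=t,
        fsr=noisy,
        fsr_clean=clean,
        true_y=path[:, 1],
        true_x=path[:, 0],
    )


def _min_edge_distance(point: np.ndarray, triangle: np.ndarray) -> float:
    dists = []
    for i in range(3):
        a = triangle[i]
        b = triangle[(i + 1) % 3]
        ab = b - a
        tt = np.clip(np.dot(point - a, ab) / np.dot(ab, ab), 0.0, 1.0)
        dists.append(float(np.linalg.norm(point - (a + tt * ab))))
    return min(dists)


@dataclass
class CrutchLoadingSim:
    """Axial-force/orientation series and the true world-frame force."""

    timestamps: np.ndarray
    axial: np.ndarray  # noisy load-cell reading, N
    axial_clean: np.ndarray
    quaternions: np.ndarray  # (n, 4) noisy orientation (x, y, z, w)
    quaternions_clean: np.ndarray
    true_world: np.ndarray  # (n, 3) vertical, AP, ML in N


def simulate_crutch_loading(
    cfg: GaitSimConfig,
    n_cycles: int = 18,
    cycle_period: float = 3.0,
    duty: float = 0.7,
) -> CrutchLoadingSim:
    """Repeated crutch loading cycles against a force reference.

    Each cycle applies a raised-cosine axial burst at the configured peak
    force while the shaft sweeps a sagittal arc bounded by the transverse
    force fraction.  The emitted truth is the exact decomposition of the
    clean axial force through the clean orientation; configured noise is
    applied to the measured axial reading and orientation independently.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(n_cycles * cycle_period * cfg.sample_rate))
    t = np.arange(n) / cfg.sample_rate
    phase = (t % cycle_period) / cycle_period
    burst = phase < duty
    u = np.where(burst, phase / duty - 0.5, 0.0)  # -0.5 .. 0.5 inside a burst
    axial = np.where(burst, cfg.crutch_peak_force * 0.5 * (1 + np.cos(2 * np.pi * u)), 0.0)
    max_tilt = math.degrees(math.atan(0.9 * cfg.crutch_transverse_fraction))
    roll_tilt = math.degrees(math.atan(0.3 * cfg.crutch_transverse_fraction))
    pitch = np.where(burst, -2.0 * max_tilt * u, 0.0)
    roll = roll_tilt * np.sin(2 * np.pi * t / cycle_period)
    quat_clean = _euler_to_quat(roll, pitch, np.zeros(n))
    local = np.zeros((n, 3))
    local[:, 2] = axial
    true_world = Rotation.from_quat(quat_clean).apply(local)[:, [2, 0, 1]]

    axial_meas = axial.copy()
    if cfg.crutch_axial_noise > 0:
        axial_meas += rng.normal(0.0, cfg.crutch_axial_noise * cfg.crutch_peak_force, n)
    ori_noise = cfg.crutch_orientation_noise_deg
    if ori_noise > 0:
        quat_meas = _euler_to_quat(
            roll + rng.normal(0, ori_noise, n),
            pitch + rng.normal(0, ori_noise, n),
            rng.normal(0, ori_noise, n),
        )
    else:
        quat_meas = quat_clean.copy()
    return CrutchLoadingSim(
        timestamps=t,
        axial=axial_meas,
        axial_clean=axial,
        quaternions=quat_meas,
        quaternions_clean=quat_clean,
        true_world=true_world,
    )
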