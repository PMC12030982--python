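"""End-to-end validation protocols on synthetic recordings.

Each function generates the stated synthetic inputs with the packaged
simulator, runs the corresponding analysis path, and returns the agreement
measure a hardware validation study would report:

* heel-strike timing error over repeated walking bouts,
* anteroposterior CoP error over circular sweeps,
* vertical crutch-force error over repeated loading cycles.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .biomech_metrics import (
    InsoleGeometry,
    cop_series,
    decompose_series,
    detect_heel_strikes_fsr,
    match_events,
)
from .signal_processing import FilterSpec, butterworth_filter
from .synthetic_gait import (
    GaitSimConfig,
    simulate_cop_sweep,
    simulate_crutch_loading,
    simulate_session,
)

__all__ = [
    "heel_strike_rmse_protocol",
    "cop_sweep_rmse_protocol",
    "crutch_grf_rmse_protocol",
]


def heel_strike_rmse_protocol(
    seeds=(1, 2, 3),
    n_bouts: int = 6,
    n_strides: int = 10,
    base_cfg: GaitSimConfig | None = None,
    filter_spec: FilterSpec = FilterSpec(order=2, cutoff_hz=10.0, zero_phase=True),
) -> dict[str, float]:
    """Pooled heel-strike timing RMSE of FSR peak detection vs ground truth.

    Runs ``len(seeds)`` simulated sessions of ``n_bouts`` bouts x
    ``n_strides`` strides each (cycle durations 3.33 +/- 1.16 s truncated
    positive, 2% full-scale FSR noise by default), low-pass filters each
    heel trace with a zero-phase Butterworth, detects local maxima with the
    default prominence (10% full scale) and refractory settings, and pools
    detected-vs-true differences over both sides and all runs.
    """
    base_cfg = base_cfg or GaitSimConfig()
    diffs: list[float] = []
    n_events = 0
    for seed in seeds:
        for bout in range(n_bouts):
            cfg = replace(base_cfg, n_strides=n_strides,
                          seed=int(seed) * 1000 + bout)
            session, truth = simulate_session(cfg)
            t = truth.timestamps
            for side in ("left", "right"):
                heel = np.array([f.channels[f"{side}_insole_fsr_heel"]
                                 for f in session.frames])
                heel = butterworth_filter(heel, cfg.sample_rate, filter_spec)
                detected = [e.time for e in detect_heel_strikes_fsr(
                    t, heel, side,
                    min_prominence=0.1 * cfg.fsr_full_scale, refractory=0.5)]
                pairs = match_events(detected, truth.heel_strikes[side])
                diffs.extend(d - tt for d, tt in pairs)
                n_events += len(truth.heel_strikes[side])
    arr = np.asarray(diffs)
    return {
        "rmse_s": float(np.sqrt(np.mean(arr**2))),
        "n_pairs": int(arr.size),
        "n_true_events": int(n_events),
    }


def cop_sweep_rmse_protocol(
    seed: int = 1,
    n_cycles: int = 18,
    noise_sd: float = 0.02,
    size: str = "medium",
) -> dict[str, float]:
    """Anteroposterior CoP RMSE over circular sweeps inside the sensor hull."""
    cfg = GaitSimConfig(seed=seed, fsr_noise_sd=noise_sd)
    geom = InsoleGeometry.default(size)
    sweep = simulate_cop_sweep(cfg, geom, n_cycles=n_cycles)
    y, _, valid = cop_series(sweep.fsr, geom, min_total=0.02 * cfg.fsr_full_scale)
    err = y[valid] - sweep.true_y[valid]
    return {
        "rmse_mm": float(np.sqrt(np.mean(err**2))),
        "n_samples": int(valid.sum()),
    }


def crutch_grf_rmse_protocol(
    seed: int = 1,
    n_cycles: int = 18,
    peak_force: float = 300.0,
    axial_noise: float = 0.01,
    orientation_noise_deg: float = 2.0,
) -> dict[str, float]:
    """Vertical crutch-force RMSE: noisy axial + orientation vs emitted truth."""
    cfg = GaitSimConfig(
        seed=seed,
        crutch_peak_force=peak_force,
        crutch_axial_noise=axial_noise,
        crutch_orientation_noise_deg=orientation_noise_deg,
    )
    sim = simulate_crutch_loading(cfg, n_cycles=n_cycles)
    world = decompose_series(sim.axial, sim.quaternions)
    err = world[:, 0] - sim.true_world[:, 0]
    return {
        "rmse_n": float(np.sqrt(np.mean(err**2))),
        "n_samples": int(err.size),
    }
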