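"""Biomechanical quantities and gait events.

Covers the system's three headline metrics:

* anteroposterior (and mediolateral) center of pressure from the
  three-sensor insole, as the load-weighted average of sensor coordinates

      y_CoP = (yH*FH + yM1*FM1 + yM5*FM5) / (FH + FM1 + FM5)

* crutch ground-reaction-force decomposition: the uniaxial load cell
  measures the force along the crutch shaft; the crutch IMU's orientation
  rotates that axial vector into world vertical / anteroposterior /
  mediolateral components;

* gait events: heel strikes as local maxima of the heel FSR trace, plus
  the marker-based reference method (extrema of the signed anteroposterior
  heel/toe offsets from the sternum).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.spatial.transform import Rotation

__all__ = [
    "InsoleGeometry",
    "CopSample",
    "CrutchForce",
    "GaitEvent",
    "cop_from_fsr",
    "cop_series",
    "decompose_crutch_grf",
    "decompose_series",
    "detect_heel_strikes_fsr",
    "detect_events_markers",
    "stride_metrics",
    "match_events",
    "event_rmse",
]


@dataclass(frozen=True)
class InsoleGeometry:
    """Planar sensor coordinates of one insole, millimetres.

    Origin at the heel sensor, +y anteroposterior toward the toes,
    +x mediolateral.  Each placement maps to an (x, y) pair.
    """

    heel: tuple[float, float]
    m1: tuple[float, float]
    m5: tuple[float, float]
    size: str = "medium"

    def __post_init__(self) -> None:
        for name, (x, y) in self.as_dict().items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise ValueError(f"non-finite coordinate for {name}: ({x}, {y})")
        if not (self.m1[1] > self.heel[1] and self.m5[1] > self.heel[1]):
            raise ValueError("metatarsal sensors must lie anterior to the heel sensor")

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {"heel": self.heel, "m1": self.m1, "m5": self.m5}

    @property
    def xy(self) -> np.ndarray:
        """3x2 array of sensor coordinates in (heel, m1, m5) order."""
        return np.array([self.heel, self.m1, self.m5], dtype=float)

    @classmethod
    def default(cls, size: str = "medium") -> "InsoleGeometry":
        """Shipped geometries per insole size, from shoe-size anthropometry."""
        table = {
            "small": cls(heel=(0.0, 0.0), m1=(27.0, 145.0), m5=(-27.0, 135.0), size="small"),
            "medium": cls(heel=(0.0, 0.0), m1=(30.0, 160.0), m5=(-30.0, 150.0), size="medium"),
            "large": cls(heel=(0.0, 0.0), m1=(33.0, 175.0), m5=(-33.0, 165.0), size="large"),
        }
        try:
            return table[size]
        except KeyError:
            raise ValueError(f"unknown insole size {size!r}; expected {sorted(table)}") from None


@dataclass(frozen=True)
class CopSample:
    """One center-of-pressure estimate; invalid when the foot is unloaded."""

    y_cop: float
    x_cop: float
    f_total: float
    valid: bool


@dataclass(frozen=True)
class CrutchForce:
    """Axial load-cell reading with its world-frame decomposition in newtons."""

    axial: float
    orientation: tuple[float, float, float, float]  # quaternion (x, y, z, w)
    vertical: float
    anteroposterior: float
    mediolateral: float

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.vertical, self.anteroposterior, self.mediolateral)


@dataclass(frozen=True)
class GaitEvent:
    kind: str  # "heel_strike" | "toe_off"
    side: str  # "left" | "right"
    time: float
    source: str  # "fsr" | "marker"


def cop_from_fsr(
    fsr_triplet: Sequence[float],
    geom: InsoleGeometry,
    min_total: float = 0.0,
) -> CopSample:
    """Center of pressure as the load-weighted average of sensor positions.

    ``fsr_triplet`` is (heel, m1, m5).  When the reading sum falls below
    ``min_total`` the foot is considered unloaded and the sample is invalid
    (no division by a vanishing total during swing).
    """
    forces = np.asarray(fsr_triplet, dtype=float)
    if forces.shape != (3,):
        raise ValueError("fsr_triplet must contain exactly (heel, m1, m5)")
    if np.any(forces < 0) or not np.all(np.isfinite(forces)):
        raise ValueError(f"FSR readings must be finite and non-negative, got {forces}")
    total = float(forces.sum())
    if total < min_total or total <= 0.0:
        return CopSample(y_cop=math.nan, x_cop=math.nan, f_total=total, valid=False)
    xy = geom.xy
    x_cop, y_cop = (forces @ xy) / total
    return CopSample(y_cop=float(y_cop), x_cop=float(x_cop), f_total=total, valid=True)


def cop_series(
    fsr_triplets: np.ndarray,
    geom: InsoleGeometry,
    min_total: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized CoP over an (n, 3) array of readings -> (y, x, valid)."""
    forces = np.asarray(fsr_triplets, dtype=float)
    if forces.ndim != 2 or forces.shape[1] != 3:
        raise ValueError("expected an (n, 3) array of (heel, m1, m5) readings")
    if np.any(forces < 0):
        raise ValueError("FSR readings must be non-negative")
    total = forces.sum(axis=1)
    valid = (total > 0) & (total >= min_total)
    xy = geom.xy
    with np.errstate(invalid="ignore", divide="ignore"):
        cop = (forces @ xy) / total[:, None]
    cop[~valid] = np.nan
    return cop[:, 1], cop[:, 0], valid


def _as_rotation(orientation, tol: float = 1e-6) -> Rotation:
    if isinstance(orientation, Rotation):
        return orientation
    q = np.asarray(orientation, dtype=float)
    if q.shape != (4,):
        raise ValueError("orientation must be a quaternion (x, y, z, w) or a Rotation")
    norm = float(np.linalg.norm(q))
    if abs(norm - 1.0) > tol:
        raise ValueError(f"quaternion norm {norm} deviates from 1 beyond tolerance {tol}")
    return Rotation.from_quat(q / norm)


def decompose_crutch_grf(axial: float, orientation) -> CrutchForce:
    """Decompose the axial load-cell force into world-frame components.

    The load cell measures along the crutch shaft (local +z, pointing up the
    shaft), so the identity orientation means a vertical crutch.  The IMU
    orientation rotates the axial vector into the world frame; the returned
    components are (vertical, anteroposterior, mediolateral) with the world
    x axis along the direction of travel.  Rotation is an isometry, so the
    component norm equals |axial| exactly.
    """
    rot = _as_rotation(orientation)
    world = rot.apply([0.0, 0.0, float(axial)])
    return CrutchForce(
        axial=float(axial),
        orientation=tuple(rot.as_quat()),
        vertical=float(world[2]),
        anteroposterior=float(world[0]),
        mediolateral=float(world[1]),
    )


def decompose_series(axial: np.ndarray, quaternions: np.ndarray) -> np.ndarray:
    """Vectorized decomposition -> (n, 3) array of (vertical, AP, ML)."""
    axial = np.asarray(axial, dtype=float)
    rot = Rotation.from_quat(np.asarray(quaternions, dtype=float))
    local = np.zeros((axial.size, 3))
    local[:, 2] = axial
    world = rot.apply(local)
    return world[:, [2, 0, 1]]


def detect_heel_strikes_fsr(
    timestamps,
    heel_series,
    side: str,
    min_prominence: float,
    refractory: float = 0.5,
) -> list[GaitEvent]:
    """Heel strikes as local maxima of the heel FSR trace.

    Peaks must exceed ``min_prominence`` (raw units; a good default is 10%
    of the sensor full scale) and be separated by at least ``refractory``
    seconds, which suppresses double counting within one stance.
    """
    if refractory <= 0:
        raise ValueError(f"refractory must be positive, got {refractory}")
    t = np.asarray(timestamps, dtype=float)
    x = np.asarray(heel_series, dtype=float)
    if t.shape != x.shape:
        raise ValueError("timestamps and heel series must have the same shape")
    if t.size < 3:
        return []
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(refractory / dt)))
    peaks, _ = find_peaks(x, prominence=min_prominence, distance=distance)
    return [GaitEvent(kind="heel_strike", side=side, time=float(t[i]), source="fsr")
            for i in peaks]


def detect_events_markers(
    timestamps,
    toe: np.ndarray,
    heel: np.ndarray,
    sternum: np.ndarray,
    side: str,
    refractory: float = 0.5,
    min_prominence: float = 0.02,
) -> list[GaitEvent]:
    """Marker-based reference events from heel/toe offsets to the sternum.

    Heel strikes are local maxima of the signed anteroposterior heel-sternum
    offset (the foot is maximally ahead of the trunk at contact); toe-offs
    are local minima of the toe-sternum offset (the foot is maximally
    behind at lift-off).  Trajectories are (n, 3) arrays sharing one time
    base; the anteroposterior axis is the first column.  ``min_prominence``
    is in metres.
    """
    t = np.asarray(timestamps, dtype=float)
    toe = np.atleast_2d(np.asarray(toe, dtype=float))
    heel = np.atleast_2d(np.asarray(heel, dtype=float))
    sternum = np.atleast_2d(np.asarray(sternum, dtype=float))
    if not (len(t) == len(toe) == len(heel) == len(sternum)):
        raise ValueError(
            f"trajectory lengths differ: t={len(t)} toe={len(toe)} "
            f"heel={len(heel)} sternum={len(sternum)}"
        )
    if refractory <= 0:
        raise ValueError(f"refractory must be positive, got {refractory}")
    if t.size < 3:
        return []
    dt = float(np.median(np.diff(t)))
    distance = max(1, int(round(refractory / dt)))
    heel_offset = heel[:, 0] - sternum[:, 0]
    toe_offset = toe[:, 0] - sternum[:, 0]
    hs_idx, _ = find_peaks(heel_offset, prominence=min_prominence, distance=distance)
    to_idx, _ = find_peaks(-toe_offset, prominence=min_prominence, distance=distance)
    events = [GaitEvent(kind="heel_strike", side=side, time=float(t[i]), source="marker")
              for i in hs_idx]
    events += [GaitEvent(kind="toe_off", side=side, time=float(t[i]), source="marker")
               for i in to_idx]
    return sorted(events, key=lambda e: e.time)


def stride_metrics(events: Sequence[GaitEvent]) -> dict[str, object]:
    """Per-stride durations and cadence from same-side heel strikes.

    Durations are successive same-side heel-strike differences pooled over
    sides; cadence is 60 divided by the mean duration (steps per minute at
    this system's one-heel-strike-per-cycle bookkeeping).
    """
    durations: list[float] = []
    for side in ("left", "right"):
        times = sorted(e.time for e in events
                       if e.kind == "heel_strike" and e.side == side)
        durations.extend(float(b - a) for a, b in zip(times, times[1:]))
    if not durations:
        raise ValueError("need at least two same-side heel strikes for stride metrics")
    arr = np.asarray(durations)
    mean = float(arr.mean())
    return {
        "durations": durations,
        "mean_duration": mean,
        "sd_duration": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "cadence": 60.0 / mean,
    }


def match_events(detected: Sequence[float], truth: Sequence[float],
                 max_offset: float = 0.5) -> list[tuple[float, float]]:
    """Mutual-nearest-neighbour pairing of detected and true event times.

    A pair forms only when each member is the other's nearest candidate and
    they lie within ``max_offset`` seconds, so a single detection straddling
    two close true events (e.g. after refractory suppression) pairs with at
    most one of them instead of contaminating the error statistics.
    """
    det = sorted(detected)
    tru = sorted(truth)
    pairs: list[tuple[float, float]] = []
    if not det or not tru:
        return pairs
    for t_true in tru:
        nearest_det = min(det, key=lambda t: abs(t - t_true))
        nearest_back = min(tru, key=lambda t: abs(t - nearest_det))
        if nearest_back == t_true and abs(nearest_det - t_true) <= max_offset:
            pairs.append((nearest_det, t_true))
    return pairs


def event_rmse(detected: Sequence[float], truth: Sequence[float],
               max_offset: float = 0.5) -> float:
    """RMSE of paired detected-vs-true event times, seconds."""
    pairs = match_events(detected, truth, max_offset)
    if not pairs:
        raise ValueError("no detected events matched the ground truth")
    diffs = np.array([d - t for d, t in pairs])
    return float(np.sqrt(np.mean(diffs**2)))
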