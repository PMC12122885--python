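"""Vehicle-relative-to-road metrics, trial classification and summaries.

The track centerline is an arc-length-parameterized sequence of straight
and constant-curvature sections.  Lateral quantities are signed in the
road frame: positive to the left of the centerline tangent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .flow import wrap_angle

__all__ = [
    "TrackSection",
    "TrackGeometry",
    "VehicleState",
    "TrialRecord",
    "heading_deviation",
    "lateral_displacement",
    "lateral_velocity_approx",
    "lateral_acceleration",
    "classify_trial",
    "roi_extract",
    "summarize_trials",
    "summarize_corrections",
    "fit_correction_angle_distribution",
    "read_states_csv",
    "write_states_csv",
    "read_track_json",
    "write_track_json",
]

G_ACCEL = 9.81

SECTION_LABELS = ("straight", "left_curve", "right_curve", "accel", "decel")


@dataclass(frozen=True)
class TrackSection:
    """One contiguous centerline span of constant curvature."""

    label: str
    length: float
    curvature: float  # 1/m; positive turns left, 0 on straights
    roi: bool = False

    def __post_init__(self) -> None:
        if self.label not in SECTION_LABELS:
            raise ValueError(f"unknown section label {self.label!r}")
        if self.length <= 0:
            raise ValueError("section length must be > 0")


class TrackGeometry:
    """Arc-length-parameterized planar track with lane geometry.

    The centerline starts at the origin heading along +x.  ``lane_center_offset``
    is the signed lateral offset (positive left) from the centerline to the
    midline of the designated driving lane.
    """

    def __init__(self, sections: Sequence[TrackSection], lane_width: float,
                 lane_center_offset: float = 0.0,
                 curve_radius: float | None = None) -> None:
        if not sections:
            raise ValueError("track needs at least one section")
        if lane_width <= 0:
            raise ValueError("lane_width must be > 0")
        self.sections = tuple(sections)
        self.lane_width = float(lane_width)
        self.lane_center_offset = float(lane_center_offset)
        curvatures = [abs(s.curvature) for s in self.sections if s.curvature]
        if curve_radius is None and curvatures:
            curve_radius = 1.0 / curvatures[0]
        self.curve_radius = curve_radius

        # Cumulative stations and start poses of every section.
        self._s0 = np.concatenate([[0.0], np.cumsum([s.length for s in self.sections])])
        poses = [(0.0, 0.0, 0.0)]
        for sec in self.sections:
            poses.append(self._advance(poses[-1], sec, sec.length))
        self._start_poses = poses
        self._tree: cKDTree | None = None
        self._tree_s: np.ndarray | None = None
        self._tree_poses: np.ndarray | None = None

    # -- geometry ----------------------------------------------------------

    @staticmethod
    def _advance(pose: tuple[float, float, float], sec: TrackSection,
                 ds: float) -> tuple[float, float, float]:
        x, y, th = pose
        k = sec.curvature
        if k == 0.0:
            return x + ds * math.cos(th), y + ds * math.sin(th), th
        dth = k * ds
        r = 1.0 / k
        return (
            x + r * (math.sin(th + dth) - math.sin(th)),
            y - r * (math.cos(th + dth) - math.cos(th)),
            th + dth,
        )

    @property
    def length(self) -> float:
        return float(self._s0[-1])

    def section_index_at(self, s: float) -> int:
        s = min(max(s, 0.0), self.length)
        i = int(np.searchsorted(self._s0, s, side="right")) - 1
        return min(max(i, 0), len(self.sections) - 1)

    def section_span(self, i: int) -> tuple[float, float]:
        return float(self._s0[i]), float(self._s0[i + 1])

    def curvature_at(self, s: float) -> float:
        return self.sections[self.section_index_at(s)].curvature

    def pose_at(self, s: float) -> tuple[float, float, float]:
        """Centerline point and tangent heading at station ``s``."""
        i = self.section_index_at(s)
        return self._advance(self._start_poses[i], self.sections[i],
                             min(max(s, 0.0), self.length) - self._s0[i])

    def point_at(self, s: float, lateral: float = 0.0) -> np.ndarray:
        """World point at station ``s`` offset ``lateral`` (positive left)."""
        x, y, th = self.pose_at(s)
        return np.array([x - lateral * math.sin(th),
                         y + lateral * math.cos(th)])

    def _polyline(self, ds: float = 0.25):
        if self._tree is None:
            s = np.arange(0.0, self.length + ds, ds)
            s[-1] = self.length
            poses = np.array([self.pose_at(si) for si in s])
            self._tree = cKDTree(poses[:, :2])
            self._tree_s = s
            self._tree_poses = poses
        return self._tree, self._tree_s, self._tree_poses

    def project(self, points) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-point projection of world points onto the centerline.

        Returns (stations, signed lateral offsets); positive lateral is left
        of the tangent.  Ties resolve to the smaller arc length (KD-tree
        returns the first nearest vertex).  The centerline is densified at
        0.25 m and treated as locally straight around the nearest vertex,
        which keeps the lateral error below a millimetre for the curvatures
        used here while staying fully vectorized.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        tree, s_grid, poses = self._polyline()
        _, idx = tree.query(pts)
        x, y, th = poses[idx, 0], poses[idx, 1], poses[idx, 2]
        tx, ty = np.cos(th), np.sin(th)
        dx, dy = pts[:, 0] - x, pts[:, 1] - y
        along = dx * tx + dy * ty
        s = np.clip(s_grid[idx] + along, 0.0, self.length)
        lat = -dx * ty + dy * tx  # cross(tangent, offset): left of tangent > 0
        return s, lat

    def lane_contains(self, points) -> np.ndarray:
        """True for world points inside the designated lane."""
        s, lat = self.project(points)
        inside = (np.abs(lat - self.lane_center_offset) <= self.lane_width / 2.0)
        return inside & (s > 0.0) & (s < self.length)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "lane_width": self.lane_width,
            "lane_center_offset": self.lane_center_offset,
            "curve_radius": self.curve_radius,
            "sections": [
                {"label": s.label, "length": s.length,
                 "curvature": s.curvature, "roi": s.roi}
                for s in self.sections
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrackGeometry":
        sections = [
            TrackSection(s["label"], float(s["length"]),
                         float(s["curvature"]), bool(s.get("roi", False)))
            for s in d["sections"]
        ]
        return cls(sections, float(d["lane_width"]),
                   float(d.get("lane_center_offset", 0.0)),
                   d.get("curve_radius"))


@dataclass(frozen=True)
class VehicleState:
    """Planar vehicle state at one sample."""

    t: float
    position: tuple[float, float]
    heading: float
    speed: float
    vx: float
    vy: float
    steering: float

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")


@dataclass
class TrialRecord:
    """One experimental trial: a state sequence plus its outcome."""

    states: list[VehicleState]
    outcome: str = "success"
    wheel_visible: bool = True

    @property
    def times(self) -> np.ndarray:
        return np.array([st.t for st in self.states])

    @property
    def positions(self) -> np.ndarray:
        return np.array([st.position for st in self.states])


def heading_deviation(theta_road, theta_veh):
    """Heading deviation ``wrap(theta_road - theta_veh)`` in (-pi, pi]."""
    return wrap_angle(np.asarray(theta_road, dtype=float) - np.asarray(theta_veh, dtype=float))


def lateral_displacement(y_lane, y_veh):
    """Lateral offset from the designated-lane midline, ``y_lane - y_veh``."""
    return np.asarray(y_lane, dtype=float) - np.asarray(y_veh, dtype=float)


def lateral_velocity_approx(speed, theta_h) -> tuple:
    """Lateral displacement velocity: exact ``v sin(theta_h)`` and the
    small-angle form ``v theta_h``."""
    speed = np.asarray(speed, dtype=float)
    theta_h = np.asarray(theta_h, dtype=float)
    exact = speed * np.sin(theta_h)
    small = speed * theta_h
    if exact.ndim == 0:
        return float(exact), float(small)
    return exact, small


def lateral_acceleration(speed: float, radius: float) -> tuple[float, float]:
    """Centripetal acceleration ``speed^2 / radius`` in m/s^2 and g-units."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    a = speed * speed / radius
    return a, a / G_ACCEL


def classify_trial(rec: TrialRecord, track: TrackGeometry,
                   slip_ratio_limit: float = 1.0,
                   vehicle_half_width: float = 0.75) -> str:
    """Label a trial ``failure`` if the vehicle ever fully exits the
    designated lane or loses control (|vy|/vx beyond the slip limit),
    else ``success``."""
    if not rec.states:
        raise ValueError("trial has no states")
    _, lat = track.project(rec.positions)
    y_l = lateral_displacement(track.lane_center_offset, lat)
    if np.any(np.abs(y_l) > track.lane_width / 2.0 + vehicle_half_width):
        return "failure"
    vx = np.array([st.vx for st in rec.states])
    vy = np.array([st.vy for st in rec.states])
    moving = vx > 0
    if np.any(np.abs(vy[moving]) / vx[moving] > slip_ratio_limit):
        return "failure"
    return "success"


def roi_extract(rec: TrialRecord, track: TrackGeometry,
                margin: float = 0.15) -> list[tuple[int, int]]:
    """Half-open sample-index spans whose station lies inside an ROI
    section, excluding the first and last ``margin`` fraction of its arc."""
    s, _ = track.project(rec.positions)
    keep = np.zeros(len(s), dtype=bool)
    for i, sec in enumerate(track.sections):
        if not sec.roi:
            continue
        s0, s1 = track.section_span(i)
        pad = margin * (s1 - s0)
        keep |= (s >= s0 + pad) & (s < s1 - pad)
    spans: list[tuple[int, int]] = []
    in_span = False
    start = 0
    for i, k in enumerate(keep):
        if k and not in_span:
            in_span, start = True, i
        elif not k and in_span:
            in_span = False
            spans.append((start, i))
    if in_span:
        spans.append((start, len(keep)))
    return spans


def summarize_trials(records: Sequence[TrialRecord]) -> pd.DataFrame:
    """Trial-outcome table by steering-wheel visibility.

    Rows: success, failure, total, failure_occurrence (percent, one
    decimal); columns: visible, not_visible, total.
    """
    def counts(recs):
        n_fail = sum(1 for r in recs if r.outcome == "failure")
        return len(recs) - n_fail, n_fail

    vis = [r for r in records if r.wheel_visible]
    invis = [r for r in records if not r.wheel_visible]
    cols = {}
    for name, recs in (("visible", vis), ("not_visible", invis),
                       ("total", list(records))):
        n_ok, n_fail = counts(recs)
        total = n_ok + n_fail
        pct = round(100.0 * n_fail / total, 1) if total else 0.0
        cols[name] = [n_ok, n_fail, total, pct]
    return pd.DataFrame(
        cols, index=["success", "failure", "total", "failure_occurrence"]
    )


def summarize_corrections(per_trial_counts: pd.DataFrame) -> dict:
    """Totals and averages of identified corrections.

    ``per_trial_counts`` is participants x trials.  Returns per-participant
    totals, per-trial totals and averages, the grand total, and the overall
    average corrections per trial.
    """
    counts = per_trial_counts.astype(float)
    n_trials = int(counts.size)
    total = float(counts.values.sum()) if n_trials else 0.0
    return {
        "participant_totals": counts.sum(axis=1),
        "trial_totals": counts.sum(axis=0),
        "trial_averages": counts.mean(axis=0) if len(counts) else counts.sum(axis=0),
        "total": total,
        "n_trials": n_trials,
        "average_per_trial": total / n_trials if n_trials else 0.0,
    }


def fit_correction_angle_distribution(deltas) -> tuple[float, float]:
    """Maximum-likelihood log-normal fit of absolute correction angles.

    Returns ``(mu, sigma_sq)`` where ``mu = mean(log d)`` and ``sigma_sq``
    is the (biased, MLE) variance of ``log d``.  All inputs must be > 0.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise ValueError("need at least one delta")
    if np.any(d <= 0):
        raise ValueError("correction angles must be strictly positive")
    logs = np.log(d)
    return float(np.mean(logs)), float(np.var(logs))


# ---------------------------------------------------------------------------
# I/O

STATE_COLUMNS = ["t", "x", "y", "heading", "speed", "vx", "vy", "delta"]


def write_states_csv(states: Sequence[VehicleState], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(s.t, s.position[0], s.position[1], s.heading, s.speed, s.vx, s.vy,
          s.steering) for s in states],
        columns=STATE_COLUMNS,
    )
    frame.to_csv(path, index=False, float_format="%.9g")


def read_states_csv(path: str | Path) -> list[VehicleState]:
    frame = pd.read_csv(path)
    return [
        VehicleState(float(r.t), (float(r.x), float(r.y)), float(r.heading),
                     float(r.speed), float(r.vx), float(r.vy), float(r.delta))
        for r in frame.itertuples()
    ]


def write_track_json(track: TrackGeometry, path: str | Path) -> None:
    Path(path).write_text(json.dumps(track.to_dict(), indent=1))


def read_track_json(path: str | Path) -> TrackGeometry:
    return TrackGeometry.from_dict(json.loads(Path(path).read_text()))
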