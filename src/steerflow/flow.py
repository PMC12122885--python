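"""Retinal optic flow reconstruction and lane-wise circular flow statistics.

Retinal optic flow is the head-fixed dense optic flow with the flow vector
at the gaze point subtracted, emulating the retinal image stabilization
produced by smooth-pursuit fixation (the fovea then sees zero flow).  The
scalar summary used downstream is the spatial circular mean of the flow
directions over the drivable-lane pixels.

Image convention: origin top-left, first vector component ``vy`` rightward,
second component ``vz`` downward; flow pointing straight down has direction
``+pi/2``.  Flow units are pixels/second.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ballistic import Signal

__all__ = [
    "FlowField",
    "GazeSample",
    "LaneMask",
    "RofAngleSeries",
    "retinal_flow_field",
    "flow_direction",
    "circular_mean_angle",
    "circular_median_angle",
    "rof_angle",
    "filter_gaze",
    "detilt",
    "gaze_headway",
    "wrap_angle",
    "read_flow_field",
    "write_flow_field",
    "read_lane_mask",
    "write_lane_mask",
    "read_gaze_csv",
    "write_gaze_csv",
]


def wrap_angle(theta):
    """Wrap angle(s) to the half-open interval (-pi, pi]."""
    theta = np.asarray(theta, dtype=float)
    out = -((-theta + math.pi) % (2.0 * math.pi) - math.pi)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class FlowField:
    """Dense 2-D flow on an image raster with pinhole-camera geometry.

    ``vy``/``vz`` are (height, width) arrays in pixels/second; the principal
    point is in (column, row) pixel coordinates.
    """

    vy: np.ndarray = field(repr=False)
    vz: np.ndarray = field(repr=False)
    focal_length: float
    principal_point: tuple[float, float]

    def __post_init__(self) -> None:
        vy = np.asarray(self.vy, dtype=float)
        vz = np.asarray(self.vz, dtype=float)
        object.__setattr__(self, "vy", vy)
        object.__setattr__(self, "vz", vz)
        if vy.ndim != 2 or vy.shape != vz.shape:
            raise ValueError("vy and vz must be 2-D arrays of equal shape")
        if not (np.all(np.isfinite(vy)) and np.all(np.isfinite(vz))):
            raise ValueError("flow components must be finite")
        if self.focal_length <= 0:
            raise ValueError("focal_length must be > 0")

    @property
    def height(self) -> int:
        return self.vy.shape[0]

    @property
    def width(self) -> int:
        return self.vy.shape[1]

    def sample(self, point: tuple[float, float]) -> np.ndarray:
        """Bilinear flow sample at sub-pixel ``(x, y)`` = (column, row)."""
        x, y = point
        if not (0.0 <= x <= self.width - 1 and 0.0 <= y <= self.height - 1):
            raise ValueError(f"point {point!r} outside raster "
                             f"{self.width}x{self.height}")
        x0, y0 = int(math.floor(x)), int(math.floor(y))
        x1, y1 = min(x0 + 1, self.width - 1), min(y0 + 1, self.height - 1)
        fx, fy = x - x0, y - y0
        w = np.array([(1 - fx) * (1 - fy), fx * (1 - fy),
                      (1 - fx) * fy, fx * fy])
        idx = ((y0, x0), (y0, x1), (y1, x0), (y1, x1))
        vy = sum(wi * self.vy[i] for wi, i in zip(w, idx))
        vz = sum(wi * self.vz[i] for wi, i in zip(w, idx))
        return np.array([vy, vz])


@dataclass(frozen=True)
class LaneMask:
    """Boolean raster flagging drivable-lane membership per pixel."""

    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValueError("mask must be a 2-D raster")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class GazeSample:
    """One eye-tracker sample in normalized screen coordinates."""

    t: float
    x: float
    y: float
    confidence: float
    valid: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.x <= 1.0 and 0.0 <= self.y <= 1.0):
            raise ValueError(f"gaze coordinates must be in [0, 1]: {(self.x, self.y)}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0, 1]: {self.confidence}")


@dataclass(frozen=True)
class RofAngleSeries:
    """Sampled retinal-optic-flow angles with per-sample validity flags."""

    signal: Signal
    valid: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.valid, dtype=bool)
        object.__setattr__(self, "valid", v)
        if v.shape != self.signal.values.shape:
            raise ValueError("validity flags must match the signal length")
        vals = self.signal.values[v]
        if vals.size and (np.any(vals <= -math.pi - 1e-12) or np.any(vals > math.pi + 1e-12)):
            raise ValueError("valid angles must lie in (-pi, pi]")

    @property
    def values(self) -> np.ndarray:
        return self.signal.values

    @property
    def times(self) -> np.ndarray:
        return self.signal.times


def retinal_flow_field(v: FlowField, gaze: tuple[float, float]) -> FlowField:
    """Subtract the gaze-point flow: ``v_r(p) = v(p) - v(p_g)``.

    ``gaze`` is a sub-pixel (x, y) point inside the raster; its flow is
    bilinearly interpolated.  The pixel nearest the gaze point is forced to
    the exact zero vector (null flow at the fovea).
    """
    g = v.sample(gaze)  # raises if outside the raster
    vy = v.vy - g[0]
    vz = v.vz - g[1]
    gx, gy = int(round(gaze[0])), int(round(gaze[1]))
    vy[gy, gx] = 0.0
    vz[gy, gx] = 0.0
    return FlowField(vy, vz, v.focal_length, v.principal_point)


def flow_direction(vector) -> float:
    """Full-quadrant direction of one ``(vy, vz)`` vector, in (-pi, pi].

    Raises on the zero vector — direction undefined; callers exclude such
    pixels from lane statistics.
    """
    vy, vz = float(vector[0]), float(vector[1])
    if vy == 0.0 and vz == 0.0:
        raise ValueError("zero vector has no direction")
    return wrap_angle(math.atan2(vz, vy))


def circular_mean_angle(angles, eps: float = 1e-9) -> float:
    """Circular mean ``arg(sum(exp(i theta)))`` of a nonempty angle set.

    Raises if the resultant vector length is below ``eps * n`` (mean
    undefined, e.g. for antipodal pairs).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("cannot average an empty angle set")
    s = np.sum(np.exp(1j * angles))
    if abs(s) < eps * angles.size:
        raise ValueError("circular mean undefined: near-zero resultant")
    return wrap_angle(float(np.angle(s)))


def circular_median_angle(angles) -> float:
    """Sample circular median: the input angle minimizing the summed
    absolute circular deviation to all other samples (O(n^2))."""
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("cannot take the median of an empty angle set")
    dev = np.abs(wrap_angle(angles[:, None] - angles[None, :]))
    return float(angles[int(np.argmin(dev.sum(axis=1)))])


def rof_angle(v_r: FlowField, mask: LaneMask) -> float:
    """Circular-mean direction of the masked retinal-flow vectors.

    Pixels with exactly zero flow are excluded (undefined direction).
    Returns NaN when the effective mask is empty or the resultant vanishes
    — an invalid sample to be flagged, not an error.
    """
    if mask.mask.shape != v_r.vy.shape:
        raise ValueError("mask dimensions must match the flow field")
    m = mask.mask & ((v_r.vy != 0.0) | (v_r.vz != 0.0))
    if not np.any(m):
        return float("nan")
    theta = np.arctan2(v_r.vz[m], v_r.vy[m])
    try:
        return circular_mean_angle(theta)
    except ValueError:
        return float("nan")


def filter_gaze(samples: Sequence[GazeSample],
                min_confidence: float = 0.6,
                border: float = 0.2) -> list[GazeSample]:
    """Keep validity-flagged samples with confidence >= 0.6 that lie inside
    the central screen region (outside the extreme 20 % border perimeter)."""
    lo, hi = border, 1.0 - border
    return [
        s for s in samples
        if s.valid
        and s.confidence >= min_confidence
        and lo < s.x < hi
        and lo < s.y < hi
    ]


def detilt(series: RofAngleSeries, straight_mask,
           min_samples: int = 10) -> tuple[RofAngleSeries, float]:
    """Remove the constant camera-tilt bias from a flow-angle series.

    Subtracts the circular median of the valid angles sampled during the
    straight track sections from every sample, re-centering the straight
    sections on zero.  Returns the corrected series and the removed bias.
    """
    straight_mask = np.asarray(straight_mask, dtype=bool)
    if straight_mask.shape != series.values.shape:
        raise ValueError("straight_mask must match the series length")
    sel = straight_mask & series.valid
    if int(sel.sum()) < min_samples:
        raise ValueError(
            f"need >= {min_samples} valid straight-section samples, got {int(sel.sum())}"
        )
    bias = circular_median_angle(series.values[sel])
    centered = wrap_angle(series.values - bias)
    out = RofAngleSeries(
        Signal(series.signal.t0, series.signal.dt, centered), series.valid
    )
    return out, bias


def gaze_headway(eye_position, gaze_ground_point, speed: float) -> tuple[float, float]:
    """Distance headway (eye to fixated ground point, m) and time headway
    (distance over speed, s).  Time headway is NaN for speed <= 0."""
    d = float(np.linalg.norm(
        np.asarray(eye_position, dtype=float) - np.asarray(gaze_ground_point, dtype=float)
    ))
    t_h = d / speed if speed > 0 else float("nan")
    return d, t_h


# ---------------------------------------------------------------------------
# I/O: raw float32 planes with a JSON sidecar, gaze as CSV.

def write_flow_field(field_: FlowField, path: str | Path, dt: float | None = None) -> None:
    """Write ``<path>`` as two row-major float32 planes (vy then vz) with a
    ``<path>.json`` sidecar describing the geometry."""
    path = Path(path)
    planes = np.stack([field_.vy, field_.vz]).astype("<f4")
    path.write_bytes(planes.tobytes())
    sidecar = {
        "width": field_.width,
        "height": field_.height,
        "focal_length": field_.focal_length,
        "principal_point": list(field_.principal_point),
    }
    if dt is not None:
        sidecar["dt"] = dt
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_flow_field(path: str | Path) -> FlowField:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    w, h = int(meta["width"]), int(meta["height"])
    raw = np.frombuffer(path.read_bytes(), dtype="<f4").reshape(2, h, w)
    return FlowField(
        raw[0].astype(float), raw[1].astype(float),
        float(meta["focal_length"]), tuple(meta["principal_point"]),
    )


def write_lane_mask(mask: LaneMask, path: str | Path, meta: dict | None = None) -> None:
    path = Path(path)
    path.write_bytes(mask.mask.astype(np.uint8).tobytes())
    sidecar = {"width": mask.mask.shape[1], "height": mask.mask.shape[0]}
    if meta:
        sidecar.update(meta)
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))


def read_lane_mask(path: str | Path) -> LaneMask:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    w, h = int(meta["width"]), int(meta["height"])
    raw = np.frombuffer(path.read_bytes(), dtype=np.uint8).reshape(h, w)
    return LaneMask(raw.astype(bool))


def write_gaze_csv(samples: Sequence[GazeSample], path: str | Path) -> None:
    frame = pd.DataFrame(
        [(s.t, s.x, s.y, s.confidence, int(s.valid)) for s in samples],
        columns=["t", "x", "y", "confidence", "valid"],
    )
    frame.to_csv(path, index=False, float_format="%.9g")


def read_gaze_csv(path: str | Path) -> list[GazeSample]:
    frame = pd.read_csv(path)
    return [
        GazeSample(float(r.t), float(r.x), float(r.y),
                   float(r.confidence), bool(r.valid))
        for r in frame.itertuples()
    ]
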