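"""Closed-loop synthetic data with known ground truth.

Everything the analysis pipeline consumes can be generated here: an
S-shaped track, a kinematic single-track vehicle steered by an intermittent
ballistic-correction driver with an injected response latency, a
smooth-pursuit gaze model, and analytic dense ground-plane optic flow from
a pinhole camera with an exact lane mask.

The driver triggers a correction whenever a leaky accumulator of the
perceived error (a weighted mix of heading deviation and lateral offset)
crosses a threshold; the scheduled correction's movement onset lags the
trigger by the injected latency and its travel is proportional to the
error at trigger time, so downstream latency scans have a known answer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .ballistic import BallisticCorrection, CorrectionSet, Signal, superpose
from .driving import TrackGeometry, TrackSection, TrialRecord, VehicleState, classify_trial
from .flow import FlowField, GazeSample, LaneMask
from .latency import LatencyComponents

__all__ = [
    "DriverParams",
    "CameraModel",
    "VehicleParams",
    "GroundTruth",
    "build_track",
    "simulate_drive",
    "simulate_stimulus_response",
    "corrections_from_cue",
    "gaze_model",
    "render_flow",
    "project_to_image",
    "inject_camera_tilt",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class DriverParams:
    """Intermittent ballistic-correction driver.

    Perceived error is ``heading_weight * theta_h + lateral_weight * y_l +
    rate_weight * d(theta_h)/dt``; its magnitude feeds a leaky evidence
    accumulator that, on crossing ``error_threshold``, schedules one
    correction with movement onset delayed by ``latency.tau_d`` and travel
    ``amplitude_gain * error`` (with optional multiplicative jitter).

    The heading-rate term is the lead perception that keeps the delayed
    intermittent loop stable.  With ``pure_heading_amplitude`` the scheduled
    travel is proportional to ``theta_h`` alone (the lead and lateral terms
    still shape the trigger timing): any phase-leading component in the
    amplitude would bias a cross-correlation latency scan, so recovery
    studies want the amplitude tied purely to the lagged stimulus.

    With ``feedforward`` enabled the driver also reacts to previewed
    road-curvature changes by scheduling a short train of anticipatory
    ballistic corrections that re-aim the steering wheel at the new
    steady-curve angle (split into ``feedforward_splits`` movements spaced
    ``feedforward_spacing`` apart, each delayed by the same latency).  This
    keeps curve entry/exit transients small enough for lane keeping at the
    low, stable error-feedback gains; the error-triggered path is unchanged.

    ``heading_disturbance_sd`` adds an Ornstein-Uhlenbeck yaw-rate
    disturbance (rad/s, timescale ``disturbance_timescale``), giving the
    heading cue stationary exogenous variation — useful on straight tracks
    where the closed loop alone would stay silent.  ``noise_sd`` is white
    noise added to the recorded steering rate only.
    """

    error_threshold: float = 0.008
    evidence_gain: float = 1.0
    evidence_leak: float = 1.0
    latency: LatencyComponents = LatencyComponents(0.15, 0.0, 0.0)
    amplitude_gain: float = 0.8
    sigma_range: tuple[float, float] = (0.0707, 0.1732)
    noise_sd: float = 0.0
    amplitude_jitter: float = 0.0
    heading_weight: float = 1.0
    lateral_weight: float = 0.02
    rate_weight: float = 0.9
    refractory: float = 0.3
    preview_distance: float = 10.0
    max_travel: float = 2.0
    heading_disturbance_sd: float = 0.0
    disturbance_timescale: float = 0.5
    pure_heading_amplitude: bool = False
    feedforward: bool = False
    feedforward_splits: int = 3
    feedforward_spacing: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.sigma_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"sigma_range must lie inside (0, 1): {self.sigma_range}")
        if self.error_threshold <= 0:
            raise ValueError("error_threshold must be > 0")


@dataclass(frozen=True)
class VehicleParams:
    """Kinematic single-track stand-in for the full vehicle dynamics."""

    wheelbase: float = 2.5
    steering_ratio: float = 10.0  # steering-wheel angle / road-wheel angle
    max_road_wheel_angle: float = 0.6

    def __post_init__(self) -> None:
        if self.wheelbase <= 0 or self.steering_ratio <= 0:
            raise ValueError("wheelbase and steering_ratio must be > 0")


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera rigidly mounted at the driver's eye point."""

    height: float = 1.1           # metres above the ground plane
    focal_length: float = 174.0   # pixels
    image_width: int = 400
    image_height: int = 360
    pitch: float = 0.15           # radians, positive pitches the view down

    def __post_init__(self) -> None:
        if self.height <= 0 or self.focal_length <= 0:
            raise ValueError("camera height and focal length must be > 0")
        if self.image_width < 2 or self.image_height < 2:
            raise ValueError("image must be at least 2x2 pixels")

    @property
    def principal_point(self) -> tuple[float, float]:
        return ((self.image_width - 1) / 2.0, (self.image_height - 1) / 2.0)


@dataclass
class GroundTruth:
    """Everything the simulator knows that the analysis must recover."""

    corrections: CorrectionSet
    tau_d: float
    per_curve_rof_bias: dict = field(default_factory=dict)
    tilt_bias: float = 0.0
    trigger_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    trigger_errors: np.ndarray = field(default_factory=lambda: np.empty(0))
    noise: Signal | None = None
    steering_rate: Signal | None = None
    heading_cue: Signal | None = None
    lateral_cue: Signal | None = None


def build_track(curve_diameter: float = 60.0,
                lane_width: float = 3.0,
                straight_lengths: tuple[float, float, float] = (80.0, 30.0, 80.0),
                lane_center_offset: float | None = None) -> TrackGeometry:
    """S-shaped track: acceleration straight, left semicircle, short
    straight, right semicircle, deceleration straight.

    The designated (right) lane midline sits half a lane width to the right
    of the centerline unless overridden.
    """
    if curve_diameter <= 0 or lane_width <= 0 or min(straight_lengths) <= 0:
        raise ValueError("all track dimensions must be > 0")
    radius = curve_diameter / 2.0
    arc = math.pi * radius
    accel, mid, decel = straight_lengths
    sections = [
        TrackSection("accel", accel, 0.0),
        TrackSection("left_curve", arc, 1.0 / radius, roi=True),
        TrackSection("straight", mid, 0.0),
        TrackSection("right_curve", arc, -1.0 / radius, roi=True),
        TrackSection("decel", decel, 0.0),
    ]
    if lane_center_offset is None:
        lane_center_offset = -lane_width / 2.0
    return TrackGeometry(sections, lane_width, lane_center_offset, radius)


def simulate_drive(track: TrackGeometry, driver: DriverParams,
                   speed: float = 13.0, dt: float = 1.0 / 90.0,
                   vehicle: VehicleParams = VehicleParams(),
                   max_time: float = 120.0,
                   world_margin: float = 200.0,
                   ) -> tuple[TrialRecord, GroundTruth]:
    """Drive the track once under intermittent ballistic steering control.

    Two passes: the closed loop first fixes the correction set causally (a
    correction cannot act before it is triggered), then the recorded
    steering rate is rebuilt as the exact superposition of all corrections
    plus the injected noise, and the trajectory is re-integrated from that
    recorded rate, so ``recorded rate - superpose(corrections) == noise``
    holds to float precision.  The passes differ only by the sub-percent
    pre-trigger Gaussian tails, so the trigger decisions stay consistent.

    Deterministic given ``driver.seed``.  Returns the trial (classified
    success/failure) and the full ground truth, including the perceived-cue
    signals used downstream as stimuli.
    """
    if dt <= 0 or speed <= 0:
        raise ValueError("dt and speed must be > 0")
    rng = np.random.default_rng(driver.seed)
    tau_d = driver.latency.tau_d
    sig_lo, sig_hi = driver.sigma_range

    # Start on the designated-lane midline at the track origin.
    x, y, th = 0.0, track.lane_center_offset, 0.0
    delta_wheel = 0.0
    evidence = 0.0
    corrections: list[BallisticCorrection] = []
    trigger_times: list[float] = []
    trigger_errors: list[float] = []

    n_max = int(max_time / dt)
    states: list[VehicleState] = []
    rates = np.zeros(n_max)
    noises = np.zeros(n_max)
    disturbances = np.zeros(n_max)
    thetas_h = np.zeros(n_max)
    ys_l = np.zeros(n_max)
    n_steps = 0
    track_len = track.length

    first_active = 0  # corrections are created in near-mu order; skip expired ones
    delta_road = 0.0
    kappa_prev: float | None = None
    disturbance = 0.0
    dist_decay = math.exp(-dt / driver.disturbance_timescale)
    dist_scale = driver.heading_disturbance_sd * math.sqrt(1.0 - dist_decay ** 2)
    for i in range(n_max):
        t = i * dt
        s, lat = track.project([(x, y)])
        s, lat = float(s[0]), float(lat[0])
        theta_road = track.pose_at(s)[2]
        theta_h = float(np.arctan2(math.sin(theta_road - th), math.cos(theta_road - th)))
        y_l = track.lane_center_offset - lat

        states.append(VehicleState(t, (x, y), th, speed, speed, 0.0, delta_wheel))
        thetas_h[i] = theta_h
        ys_l[i] = y_l

        # Perceived heading-error rate: previewed road-curvature sweep minus
        # the vehicle's own yaw rate (the stabilizing lead perception).
        kappa_ahead = track.curvature_at(s + driver.preview_distance)
        if driver.feedforward and kappa_ahead != kappa_prev and kappa_prev is not None:
            # Anticipatory re-aiming at the upcoming steady-curve wheel angle.
            d_wheel = vehicle.steering_ratio * (
                math.atan(vehicle.wheelbase * kappa_ahead)
                - math.atan(vehicle.wheelbase * kappa_prev)
            )
            for j in range(driver.feedforward_splits):
                sigma = float(rng.uniform(sig_lo, sig_hi))
                a = (d_wheel / driver.feedforward_splits) / (sigma * _SQRT_2PI)
                mu = (t + tau_d + j * driver.feedforward_spacing + 2.0 * sigma)
                corrections.append(BallisticCorrection(a, mu, sigma))
        kappa_prev = kappa_ahead
        theta_h_rate = (speed * kappa_ahead
                        - speed / vehicle.wheelbase * math.tan(delta_road))
        error = (driver.heading_weight * theta_h
                 + driver.lateral_weight * y_l
                 + driver.rate_weight * theta_h_rate)
        evidence += (driver.evidence_gain * abs(error)
                     - driver.evidence_leak * evidence) * dt
        if (evidence >= driver.error_threshold
                and (not trigger_times or t - trigger_times[-1] >= driver.refractory)):
            evidence = 0.0
            sigma = float(rng.uniform(sig_lo, sig_hi))
            amp_error = theta_h if driver.pure_heading_amplitude else error
            travel = driver.amplitude_gain * amp_error
            if driver.amplitude_jitter > 0:
                travel *= 1.0 + driver.amplitude_jitter * float(rng.standard_normal())
            travel = max(-driver.max_travel, min(driver.max_travel, travel))
            if travel != 0.0:
                a = travel / (sigma * _SQRT_2PI)
                mu = t + tau_d + 2.0 * sigma  # movement onset at t + tau_d
                corrections.append(BallisticCorrection(a, mu, sigma))
                trigger_times.append(t)
                trigger_errors.append(amp_error)

        # Steering-wheel rate: exact superposition of scheduled corrections.
        rate = 0.0
        while (first_active < len(corrections)
               and t > corrections[first_active].mu + 8.0 * sig_hi):
            first_active += 1
        for c in corrections[first_active:]:
            if t < c.mu - 8.0 * sig_hi:
                break  # later corrections start even further in the future
            u = (t - c.mu) / c.sigma
            rate += c.a * math.exp(-0.5 * u * u)
        noise = driver.noise_sd * float(rng.standard_normal()) if driver.noise_sd > 0 else 0.0
        rates[i] = rate + noise
        noises[i] = noise

        # Kinematic single-track advance.
        delta_wheel += rate * dt
        delta_road = max(-vehicle.max_road_wheel_angle,
                         min(vehicle.max_road_wheel_angle,
                             delta_wheel / vehicle.steering_ratio))
        if driver.heading_disturbance_sd > 0:
            disturbance = (dist_decay * disturbance
                           + dist_scale * float(rng.standard_normal()))
        disturbances[i] = disturbance
        th += (speed / vehicle.wheelbase * math.tan(delta_road) + disturbance) * dt
        x += speed * math.cos(th) * dt
        y += speed * math.sin(th) * dt
        n_steps = i + 1

        if s >= track_len - 1e-6:
            break
        if abs(x) > track_len + world_margin or abs(y) > track_len + world_margin:
            break  # left the world: truncated, will classify as failure

    # Pass 2: rebuild the recorded rate as the exact superposition of every
    # scheduled correction plus the injected noise, and re-integrate the
    # trajectory from it so states, cues and the recorded signal agree.
    cset = CorrectionSet(corrections)
    grid = Signal(0.0, dt, np.zeros(n_steps))
    exact = superpose(cset, grid).values
    recorded = exact + noises[:n_steps]

    x, y, th = 0.0, track.lane_center_offset, 0.0
    delta_wheel = 0.0
    states = []
    for i in range(n_steps):
        t = i * dt
        s, lat = track.project([(x, y)])
        s, lat = float(s[0]), float(lat[0])
        theta_road = track.pose_at(s)[2]
        thetas_h[i] = float(np.arctan2(math.sin(theta_road - th),
                                       math.cos(theta_road - th)))
        ys_l[i] = track.lane_center_offset - lat
        states.append(VehicleState(t, (x, y), th, speed, speed, 0.0, delta_wheel))
        delta_wheel += exact[i] * dt
        delta_road = max(-vehicle.max_road_wheel_angle,
                         min(vehicle.max_road_wheel_angle,
                             delta_wheel / vehicle.steering_ratio))
        th += (speed / vehicle.wheelbase * math.tan(delta_road)
               + disturbances[i]) * dt
        x += speed * math.cos(th) * dt
        y += speed * math.sin(th) * dt

    record = TrialRecord(states=states)
    left_world = (abs(x) > track_len + world_margin
                  or abs(y) > track_len + world_margin)
    record.outcome = "failure" if left_world else classify_trial(record, track)

    t0 = 0.0
    truth = GroundTruth(
        corrections=cset,
        tau_d=tau_d,
        trigger_times=np.array(trigger_times),
        trigger_errors=np.array(trigger_errors),
        noise=Signal(t0, dt, noises[:n_steps]),
        steering_rate=Signal(t0, dt, recorded),
        heading_cue=Signal(t0, dt, thetas_h[:n_steps]),
        lateral_cue=Signal(t0, dt, ys_l[:n_steps]),
    )
    return record, truth


def corrections_from_cue(cue: Signal, tau_d: float, seed: int = 0,
                         cue_valid=None,
                         amplitude_gain: float = 0.8,
                         amplitude_jitter: float = 0.05,
                         error_threshold: float = 0.008,
                         evidence_gain: float = 1.0,
                         evidence_leak: float = 1.0,
                         refractory: float = 0.25,
                         sigma_range: tuple[float, float] = (0.0707, 0.1732),
                         ) -> tuple[CorrectionSet, GroundTruth]:
    """Generate stimulus-proportional corrections from an arbitrary cue.

    The same evidence-accumulation trigger as the closed-loop driver, but
    listening to ``cue`` directly: each threshold crossing schedules a
    correction with movement onset ``tau_d`` after the trigger and travel
    ``amplitude_gain * cue(t_trigger)``.  Samples flagged invalid in
    ``cue_valid`` neither accumulate evidence nor trigger.

    Lets recovery studies wire any reconstructed perception signal (e.g. a
    rendered retinal-flow angle series) into a response generator with a
    known injected latency.
    """
    if tau_d < 0:
        raise ValueError("tau_d must be >= 0")
    rng = np.random.default_rng(seed)
    values = cue.values
    valid = (np.ones(values.size, dtype=bool) if cue_valid is None
             else np.asarray(cue_valid, dtype=bool))
    sig_lo, sig_hi = sigma_range
    corrections: list[BallisticCorrection] = []
    trigger_times: list[float] = []
    trigger_errors: list[float] = []
    evidence = 0.0
    last_trigger = -math.inf
    dt = cue.dt
    for i, t in enumerate(cue.times):
        if not valid[i]:
            continue
        evidence += (evidence_gain * abs(values[i]) - evidence_leak * evidence) * dt
        if evidence >= error_threshold and t - last_trigger >= refractory:
            evidence = 0.0
            last_trigger = t
            sigma = float(rng.uniform(sig_lo, sig_hi))
            travel = amplitude_gain * values[i]
            if amplitude_jitter > 0:
                travel *= 1.0 + amplitude_jitter * float(rng.standard_normal())
            if travel != 0.0:
                corrections.append(BallisticCorrection(
                    travel / (sigma * _SQRT_2PI), t + tau_d + 2.0 * sigma, sigma))
                trigger_times.append(float(t))
                trigger_errors.append(float(values[i]))
    truth = GroundTruth(
        corrections=CorrectionSet(corrections),
        tau_d=tau_d,
        trigger_times=np.array(trigger_times),
        trigger_errors=np.array(trigger_errors),
        heading_cue=cue,
    )
    return truth.corrections, truth


def simulate_stimulus_response(tau_d: float,
                               duration: float = 180.0,
                               dt: float = 1.0 / 90.0,
                               seed: int = 0,
                               cue_sd: float = 0.05,
                               cue_timescale: float = 0.8,
                               amplitude_gain: float = 0.8,
                               amplitude_jitter: float = 0.05,
                               error_threshold: float = 0.008,
                               evidence_gain: float = 1.0,
                               evidence_leak: float = 1.0,
                               refractory: float = 0.25,
                               sigma_range: tuple[float, float] = (0.0707, 0.1732),
                               ) -> tuple[CorrectionSet, Signal, GroundTruth]:
    """Controlled response-time benchmark: corrections from a stationary cue.

    The stimulus cue is a stationary Ornstein-Uhlenbeck process.  Its
    magnitude feeds the same leaky evidence accumulator as the closed-loop
    driver; each threshold crossing schedules one ballistic correction with
    movement onset exactly ``tau_d`` after the trigger and travel
    proportional to the cue value at trigger time — the stimulus-response
    relation a latency scan is supposed to recover.  Unlike the closed-loop
    drive, the response does not feed back into the cue, so the statistics
    stay stationary for arbitrarily long runs and any injected ``tau_d`` in
    the scan range is admissible.

    Returns (corrections, cue signal, ground truth).
    """
    if tau_d < 0 or duration <= 0 or dt <= 0:
        raise ValueError("tau_d must be >= 0 and duration, dt > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration / dt))
    decay = math.exp(-dt / cue_timescale)
    innovation = cue_sd * math.sqrt(1.0 - decay * decay)
    cue = np.empty(n)
    cue[0] = cue_sd * float(rng.standard_normal())  # stationary start
    for i in range(1, n):
        cue[i] = decay * cue[i - 1] + innovation * float(rng.standard_normal())

    sig_lo, sig_hi = sigma_range
    corrections: list[BallisticCorrection] = []
    trigger_times: list[float] = []
    trigger_errors: list[float] = []
    evidence = 0.0
    last_trigger = -math.inf
    for i in range(n):
        t = i * dt
        evidence += (evidence_gain * abs(cue[i]) - evidence_leak * evidence) * dt
        if evidence >= error_threshold and t - last_trigger >= refractory:
            evidence = 0.0
            last_trigger = t
            sigma = float(rng.uniform(sig_lo, sig_hi))
            travel = amplitude_gain * cue[i]
            if amplitude_jitter > 0:
                travel *= 1.0 + amplitude_jitter * float(rng.standard_normal())
            if travel != 0.0:
                corrections.append(BallisticCorrection(
                    travel / (sigma * _SQRT_2PI), t + tau_d + 2.0 * sigma, sigma))
                trigger_times.append(t)
                trigger_errors.append(cue[i])

    cue_signal = Signal(0.0, dt, cue)
    truth = GroundTruth(
        corrections=CorrectionSet(corrections),
        tau_d=tau_d,
        trigger_times=np.array(trigger_times),
        trigger_errors=np.array(trigger_errors),
        heading_cue=cue_signal,
    )
    return truth.corrections, cue_signal, truth


# ---------------------------------------------------------------------------
# Camera geometry helpers.  Body frame: X forward, Y right, Z down; the
# camera is pitched down by ``camera.pitch`` about the Y axis.  Image axes:
# first component rightward, second downward.

def _eye_position(state: VehicleState, camera: CameraModel) -> np.ndarray:
    return np.array([state.position[0], state.position[1], camera.height])


def project_to_image(point, state: VehicleState,
                     camera: CameraModel) -> tuple[float, float] | None:
    """Project a world point (x, y[, z]) to pixel (column, row) coordinates.

    Returns None when the point is behind the camera.
    """
    p = np.asarray(point, dtype=float)
    pz = p[2] if p.size == 3 else 0.0
    eye = _eye_position(state, camera)
    rel = np.array([p[0] - eye[0], p[1] - eye[1], pz - eye[2]])
    cth, sth = math.cos(state.heading), math.sin(state.heading)
    rb_fwd = rel[0] * cth + rel[1] * sth
    rb_right = rel[0] * sth - rel[1] * cth
    rb_down = -rel[2]
    cp, sp = math.cos(camera.pitch), math.sin(camera.pitch)
    cam_f = rb_fwd * cp + rb_down * sp
    cam_r = rb_right
    cam_d = -rb_fwd * sp + rb_down * cp
    if cam_f <= 1e-9:
        return None
    cx, cy = camera.principal_point
    return (cx + camera.focal_length * cam_r / cam_f,
            cy + camera.focal_length * cam_d / cam_f)


def _pixel_ground_points(state: VehicleState, camera: CameraModel
                         ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Back-project every pixel to the ground plane.

    Returns (Px, Py, visible) arrays of shape (H, W); ``visible`` is False
    above the horizon.
    """
    H, W = camera.image_height, camera.image_width
    cx, cy = camera.principal_point
    f = camera.focal_length
    u = np.arange(W, dtype=float)[None, :] - cx
    v = np.arange(H, dtype=float)[:, None] - cy
    cp, sp = math.cos(camera.pitch), math.sin(camera.pitch)
    # Unnormalized ray in body frame from camera-frame ray (1, u/f, v/f).
    d_fwd = cp - (v / f) * sp + np.zeros((H, W))
    d_right = np.broadcast_to(u / f, (H, W)).copy()
    d_down = sp + (v / f) * cp + np.zeros((H, W))
    visible = d_down > 1e-9
    tscale = np.where(visible, camera.height / np.where(visible, d_down, 1.0), np.nan)
    cth, sth = math.cos(state.heading), math.sin(state.heading)
    px = state.position[0] + tscale * (d_fwd * cth + d_right * sth)
    py = state.position[1] + tscale * (d_fwd * sth - d_right * cth)
    return px, py, visible


def render_flow(state: VehicleState, camera: CameraModel,
                gaze_ground_point=None, dt: float = 1.0 / 90.0,
                yaw_rate: float = 0.0, track: TrackGeometry | None = None,
                ) -> tuple[FlowField, LaneMask, tuple[float, float] | None]:
    """Analytic dense ground-plane optic flow over one frame interval.

    Every pixel below the horizon is back-projected to the ground, the
    camera is advanced by the vehicle's motion over ``dt`` (constant speed
    and the given yaw rate), and the fixed world point is re-projected; the
    flow is the pixel displacement divided by ``dt`` (pixels/second).
    Above-horizon pixels carry zero flow and are excluded from the mask.

    The lane mask is the exact projection of the designated-lane polygon
    when a ``track`` is supplied.  The gaze pixel is the projection of the
    gaze ground point, or None when it falls behind the camera.
    """
    if camera.height <= 0:
        raise ValueError("camera must be above the ground")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    H, W = camera.image_height, camera.image_width
    px, py, visible = _pixel_ground_points(state, camera)

    # Advance the vehicle over dt and re-project the fixed ground points.
    th2 = state.heading + yaw_rate * dt
    x2 = state.position[0] + state.speed * math.cos(state.heading) * dt
    y2 = state.position[1] + state.speed * math.sin(state.heading) * dt
    cth, sth = math.cos(th2), math.sin(th2)
    relx = px - x2
    rely = py - y2
    rb_fwd = relx * cth + rely * sth
    rb_right = relx * sth - rely * cth
    rb_down = camera.height  # ground points are a camera height below the eye
    cp, sp = math.cos(camera.pitch), math.sin(camera.pitch)
    cam_f = rb_fwd * cp + rb_down * sp
    cam_r = rb_right
    cam_d = -rb_fwd * sp + rb_down * cp
    ok = visible & (cam_f > 1e-9)
    cx, cy = camera.principal_point
    with np.errstate(invalid="ignore", divide="ignore"):
        u2 = cx + camera.focal_length * cam_r / cam_f
        v2 = cy + camera.focal_length * cam_d / cam_f
    u1 = np.broadcast_to(np.arange(W, dtype=float)[None, :], (H, W))
    v1 = np.broadcast_to(np.arange(H, dtype=float)[:, None], (H, W))
    vy = np.where(ok, (u2 - u1) / dt, 0.0)
    vz = np.where(ok, (v2 - v1) / dt, 0.0)
    field_ = FlowField(np.nan_to_num(vy), np.nan_to_num(vz),
                       camera.focal_length, camera.principal_point)

    if track is not None:
        mask = np.zeros((H, W), dtype=bool)
        pts = np.column_stack([px[ok], py[ok]])
        if pts.size:
            mask[ok] = track.lane_contains(pts)
        lane = LaneMask(mask)
    else:
        lane = LaneMask(ok)

    gaze_px = None
    if gaze_ground_point is not None:
        gaze_px = project_to_image(gaze_ground_point, state, camera)
        if gaze_px is not None:
            gx, gy = gaze_px
            if not (0 <= gx <= W - 1 and 0 <= gy <= H - 1):
                gaze_px = None
    return field_, lane, gaze_px


def gaze_model(rec: TrialRecord, track: TrackGeometry,
               headway_range: tuple[float, float] = (4.0, 25.0),
               dwell_range: tuple[float, float] = (0.3, 1.2),
               seed: int = 0,
               camera: CameraModel = CameraModel(),
               saccade_duration: float = 0.08,
               blink_rate: float = 0.02,
               low_conf_rate: float = 0.03,
               apex_bias: float = 0.5,
               ) -> tuple[list[GazeSample], np.ndarray]:
    """Smooth-pursuit gaze on the designated lane ahead of the vehicle.

    Fixation targets are drawn on the lane surface at a sampled distance
    headway, laterally biased toward the inner curve edge by ``apex_bias``
    (0 = lane midline, 1 = inner lane edge) with truncated-normal scatter.
    During a fixation the gaze tracks the fixed world point exactly
    (pursuit gain 1.0); saccade gaps between fixations emit invalid
    samples, and occasional samples carry sub-0.6 confidence.

    Returns the gaze samples (normalized screen coordinates) and the
    per-sample fixated ground points (NaN during saccades).
    """
    if not rec.states:
        raise ValueError("trial has no states")
    rng = np.random.default_rng(seed)
    samples: list[GazeSample] = []
    points = np.full((len(rec.states), 2), np.nan)

    fix_until = -np.inf
    saccade_until = -np.inf
    target = None
    half = track.lane_width / 2.0
    for i, st in enumerate(rec.states):
        t = st.t
        if t >= fix_until and t >= saccade_until:
            # Saccade to a new target on the lane ahead.
            saccade_until = t + saccade_duration
            fix_until = saccade_until + float(rng.uniform(*dwell_range))
            d_h = float(rng.uniform(*headway_range))
            ahead = math.sqrt(max(d_h * d_h - camera.height ** 2, 1.0))
            s_here, _ = track.project([st.position])
            s_tgt = min(float(s_here[0]) + ahead, track.length)
            kappa = track.curvature_at(s_tgt)
            inner = half * (1.0 if kappa > 0 else -1.0 if kappa < 0 else 0.0)
            lat_mean = track.lane_center_offset + apex_bias * inner
            lat = float(np.clip(
                rng.normal(lat_mean, half / 3.0),
                track.lane_center_offset - half, track.lane_center_offset + half,
            ))
            target = track.point_at(s_tgt, lat)

        in_saccade = t < saccade_until
        blink = rng.random() < blink_rate
        pix = None if target is None else project_to_image(target, st, camera)
        if pix is not None:
            nx = pix[0] / (camera.image_width - 1)
            ny = pix[1] / (camera.image_height - 1)
        if pix is None or not (0.0 <= nx <= 1.0 and 0.0 <= ny <= 1.0):
            samples.append(GazeSample(t, 0.5, 0.5, 0.0, valid=False))
            continue
        if rng.random() < low_conf_rate:
            confidence = float(rng.uniform(0.0, 0.6))
        else:
            confidence = float(rng.uniform(0.75, 1.0))
        valid = not (in_saccade or blink)
        samples.append(GazeSample(t, float(nx), float(ny), confidence, valid=valid))
        if valid:
            points[i] = target
    return samples, points


def inject_camera_tilt(field_: FlowField, tilt: float,
                       mask: LaneMask | None = None,
                       ) -> FlowField | tuple[FlowField, LaneMask]:
    """Rotate the image-plane flow (and optionally the mask) by ``tilt``.

    Emulates a constant camera roll bias: vector components are rotated
    exactly and the rasters are resampled about the principal point with
    nearest-neighbour interpolation.  Two successive tilts compose
    additively (up to raster resampling).
    """
    if abs(tilt) >= math.pi / 4:
        raise ValueError("|tilt| must be < pi/4")
    ct, st = math.cos(tilt), math.sin(tilt)
    vy = ct * field_.vy - st * field_.vz
    vz = st * field_.vy + ct * field_.vz
    if tilt != 0.0:
        deg = math.degrees(tilt)
        vy = ndimage.rotate(vy, -deg, reshape=False, order=0, mode="constant")
        vz = ndimage.rotate(vz, -deg, reshape=False, order=0, mode="constant")
    out = FlowField(vy, vz, field_.focal_length, field_.principal_point)
    if mask is None:
        return out
    m = mask.mask
    if tilt != 0.0:
        m = ndimage.rotate(m.astype(np.uint8), -math.degrees(tilt),
                           reshape=False, order=0, mode="constant").astype(bool)
    return out, LaneMask(m)
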