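"""End-to-end pipeline: simulate -> flow angle -> decompose -> latency -> report.

Every stage reads and writes self-describing artifacts inside a run
directory, so the pipeline can be restarted from any intermediate product.
One master seed deterministically derives all per-stage seeds; reruns with
the same configuration are bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
import tomllib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .ballistic import (CorrectionSet, Signal, read_corrections_csv,
                        write_corrections_csv)
from .decompose import DecompositionConfig, decompose_windows
from .driving import (TrialRecord, fit_correction_angle_distribution,
                      read_states_csv, read_track_json, roi_extract,
                      summarize_corrections, summarize_trials,
                      write_states_csv, write_track_json)
from .flow import (RofAngleSeries, detilt, filter_gaze, read_gaze_csv,
                   retinal_flow_field, rof_angle, write_gaze_csv)
from .latency import (LatencyComponents, StimulusResponsePairs,
                      pair_corrections_with_stimulus, recenter_by_curve,
                      robust_linreg, write_scan_csv)
from .synthetic import (CameraModel, DriverParams, build_track, gaze_model,
                        inject_camera_tilt, render_flow, simulate_drive)

__all__ = ["PipelineConfig", "run_pipeline", "StageError",
           "stage_simulate", "stage_flowangle", "stage_decompose",
           "stage_latency", "stage_report",
           "read_signal_csv", "write_signal_csv"]

log = logging.getLogger("steerflow.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for a full pipeline run."""

    seed: int = 0
    out_dir: str = "steerflow_run"
    log_level: str = "INFO"
    n_trials: int = 4
    speed: float = 13.0
    dt: float = 1.0 / 90.0
    curve_diameter: float = 60.0
    lane_width: float = 3.0
    straight_lengths: tuple[float, float, float] = (80.0, 30.0, 80.0)
    driver: DriverParams = DriverParams(noise_sd=0.02, amplitude_jitter=0.05)
    camera: CameraModel = CameraModel(image_width=120, image_height=108,
                                      focal_length=52.0)
    pso: DecompositionConfig = DecompositionConfig(n_max=6)
    camera_tilt: float = 0.05
    flow_stride: int = 3
    headway_range: tuple[float, float] = (4.0, 25.0)
    dwell_range: tuple[float, float] = (0.3, 1.2)
    scan_grid_step: float = 1.0 / 90.0
    scan_tau_range: tuple[float, float] = (0.0, 2.0)
    huber_delta: float = 0.1

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if self.flow_stride < 1:
            raise ValueError("flow_stride must be >= 1")

    def stage_seed(self, stage: str, index: int = 0) -> int:
        """Deterministic per-stage (and per-trial) seed from the master."""
        tag = sum(ord(c) * 31 ** i for i, c in enumerate(stage)) % (2 ** 31)
        ss = np.random.SeedSequence([self.seed, tag, index])
        return int(ss.generate_state(1)[0])

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        """Load from a TOML file with optional [driver]/[camera]/[pso]
        tables mirroring the corresponding dataclasses."""
        raw = tomllib.loads(Path(path).read_text())
        kwargs = dict(raw)
        for key, klass in (("driver", DriverParams), ("camera", CameraModel),
                           ("pso", DecompositionConfig)):
            if key in kwargs:
                sub = dict(kwargs[key])
                if key == "driver" and "latency" in sub:
                    sub["latency"] = LatencyComponents(**sub["latency"])
                for tup in ("sigma_range", "sigma_bounds"):
                    if tup in sub:
                        sub[tup] = tuple(sub[tup])
                kwargs[key] = klass(**sub)
        for tup in ("straight_lengths", "headway_range", "dwell_range",
                    "scan_tau_range"):
            if tup in kwargs:
                kwargs[tup] = tuple(kwargs[tup])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(getattr(v, k))
                        for k in (f.name for f in dataclasses.fields(v))}
            if isinstance(v, tuple):
                return list(v)
            return v
        return {f.name: enc(getattr(self, f.name))
                for f in dataclasses.fields(self)}


# ---------------------------------------------------------------------------
# Signal CSV helpers (t, value)

def write_signal_csv(signal: Signal, path: str | Path,
                     valid=None, value_name: str = "value") -> None:
    data = {"t": signal.times, value_name: signal.values}
    if valid is not None:
        data["valid"] = np.asarray(valid, dtype=int)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_signal_csv(path: str | Path, value_name: str | None = None
                    ) -> tuple[Signal, np.ndarray]:
    frame = pd.read_csv(path)
    t = frame["t"].to_numpy(float)
    if value_name is None:
        value_name = [c for c in frame.columns if c not in ("t", "valid")][0]
    values = frame[value_name].to_numpy(float)
    dt = float(np.median(np.diff(t))) if t.size > 1 else 1.0
    valid = (frame["valid"].to_numpy(int).astype(bool)
             if "valid" in frame.columns else np.ones(t.size, dtype=bool))
    return Signal(float(t[0]), dt, np.nan_to_num(values)), valid


def _trial_dir(out: Path, k: int) -> Path:
    return out / f"trial_{k:02d}"


# ---------------------------------------------------------------------------
# Stages

def stage_simulate(config: PipelineConfig) -> Path:
    """Simulate ``n_trials`` drives (first half with a visible wheel) and
    write states, steering rate, gaze, ground-truth corrections, track."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    track = build_track(config.curve_diameter, config.lane_width,
                        config.straight_lengths)
    write_track_json(track, out / "track.json")
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))

    for k in range(config.n_trials):
        tdir = _trial_dir(out, k)
        tdir.mkdir(exist_ok=True)
        driver = replace(config.driver, seed=config.stage_seed("simulate", k))
        rec, truth = simulate_drive(track, driver, config.speed, config.dt)
        wheel_visible = k < (config.n_trials + 1) // 2
        rec.wheel_visible = wheel_visible

        write_states_csv(rec.states, tdir / "states.csv")
        write_signal_csv(truth.steering_rate, tdir / "steering_rate.csv")
        write_signal_csv(truth.heading_cue, tdir / "heading_cue.csv",
                         value_name="theta_h")
        write_corrections_csv(truth.corrections, tdir / "truth_corrections.csv")
        samples, points = gaze_model(
            rec, track, config.headway_range, config.dwell_range,
            seed=config.stage_seed("gaze", k), camera=config.camera)
        write_gaze_csv(samples, tdir / "gaze.csv")
        pd.DataFrame(points, columns=["gx", "gy"]).to_csv(
            tdir / "gaze_points.csv", index=False, float_format="%.9g")
        meta = {"wheel_visible": wheel_visible, "outcome": rec.outcome,
                "tau_d": truth.tau_d, "dt": config.dt, "speed": config.speed,
                "camera_tilt": config.camera_tilt}
        (tdir / "meta.json").write_text(json.dumps(meta, indent=1))
        log.info("simulate: trial %d outcome=%s corrections=%d",
                 k, rec.outcome, len(truth.corrections))
    return out


def _rotate_pixel(p, center, tilt):
    c, s = math.cos(tilt), math.sin(tilt)
    dx, dy = p[0] - center[0], p[1] - center[1]
    return (center[0] + c * dx - s * dy, center[1] + s * dx + c * dy)


def stage_flowangle(config: PipelineConfig) -> None:
    """Render flow at gaze-valid frames, reconstruct retinal flow, compute
    the lane-masked circular-mean angle series, and de-tilt it."""
    out = Path(config.out_dir)
    track = read_track_json(out / "track.json")
    cam = config.camera
    for k in range(config.n_trials):
        tdir = _trial_dir(out, k)
        states = read_states_csv(tdir / "states.csv")
        gaze = read_gaze_csv(tdir / "gaze.csv")
        gaze_pts = pd.read_csv(tdir / "gaze_points.csv").to_numpy(float)
        ok_times = {round(s.t, 9) for s in filter_gaze(gaze)}

        stride = config.flow_stride
        idx = range(0, len(states) - 1, stride)
        n_out = len(list(idx))
        angles = np.zeros(n_out)
        valid = np.zeros(n_out, dtype=bool)
        positions = np.array([st.position for st in states])
        stations, _ = track.project(positions)
        for j, i in enumerate(range(0, len(states) - 1, stride)):
            st = states[i]
            if round(st.t, 9) not in ok_times or np.any(np.isnan(gaze_pts[i])):
                continue
            yaw_rate = (states[i + 1].heading - st.heading) / config.dt
            field_, mask, gaze_px = render_flow(
                st, cam, (gaze_pts[i][0], gaze_pts[i][1]), config.dt,
                yaw_rate, track)
            if gaze_px is None or mask.n_pixels == 0:
                continue
            if config.camera_tilt:
                field_, mask = inject_camera_tilt(field_, config.camera_tilt, mask)
                gaze_px = _rotate_pixel(gaze_px, cam.principal_point,
                                        config.camera_tilt)
                W, H = cam.image_width, cam.image_height
                if not (0 <= gaze_px[0] <= W - 1 and 0 <= gaze_px[1] <= H - 1):
                    continue
            v_r = retinal_flow_field(field_, gaze_px)
            theta = rof_angle(v_r, mask)
            if math.isfinite(theta):
                angles[j] = theta
                valid[j] = True

        series = RofAngleSeries(
            Signal(states[0].t, config.dt * stride, angles), valid)
        sample_stations = stations[::stride][:n_out]
        straight = np.array([
            track.sections[track.section_index_at(s)].label
            in ("straight", "accel", "decel") for s in sample_stations])
        try:
            series, bias = detilt(series, straight)
        except ValueError as exc:
            log.warning("flowangle: trial %d detilt skipped (%s)", k, exc)
            bias = 0.0
        write_signal_csv(series.signal, tdir / "rof_angle.csv",
                         valid=series.valid, value_name="theta_rof")
        labels = np.array([track.sections[track.section_index_at(s)].label
                           for s in sample_stations])
        pd.DataFrame({"t": series.times, "section": labels}).to_csv(
            tdir / "sections.csv", index=False, float_format="%.9g")
        log.info("flowangle: trial %d valid=%d/%d bias=%.4f",
                 k, int(valid.sum()), n_out, bias)


def stage_decompose(config: PipelineConfig) -> None:
    """Decompose each trial's steering rate inside the curve-bend regions
    of interest into ballistic corrections."""
    out = Path(config.out_dir)
    track = read_track_json(out / "track.json")
    for k in range(config.n_trials):
        tdir = _trial_dir(out, k)
        states = read_states_csv(tdir / "states.csv")
        z, _ = read_signal_csv(tdir / "steering_rate.csv")
        rec = TrialRecord(states=states)
        spans = roi_extract(rec, track)
        found = []
        for span_i, (i0, i1) in enumerate(spans):
            t0, t1 = states[i0].t, states[min(i1, len(states) - 1)].t
            zi = z.slice(t0, t1)
            cfg = replace(config.pso,
                          seed=config.stage_seed("decompose", k * 100 + span_i))
            for fit in decompose_windows(zi, cfg):
                found.extend(fit.corrections)
        cset = CorrectionSet(found)
        write_corrections_csv(cset, tdir / "corrections.csv")
        log.info("decompose: trial %d corrections=%d (ROI spans=%d)",
                 k, len(cset), len(spans))


def _pooled_pairs(trials: list[tuple[CorrectionSet, Signal, np.ndarray]],
                  tau: float) -> StimulusResponsePairs | None:
    resp, stim = [], []
    for cset, cue, valid in trials:
        if not len(cset):
            continue
        try:
            p = pair_corrections_with_stimulus(cset, cue, tau,
                                               cue_valid=valid)
        except ValueError:
            continue
        resp.append(p.response)
        stim.append(p.stimulus)
    if not resp:
        return None
    return StimulusResponsePairs(np.concatenate(resp), np.concatenate(stim), tau)


def pooled_latency_scan(trials: list[tuple[CorrectionSet, Signal, np.ndarray]],
                        grid_step: float,
                        tau_range: tuple[float, float] = (0.0, 2.0)):
    """ZNCC scan with stimulus-response pairs pooled over several trials."""
    from .latency import LatencyScan, zncc
    n_steps = int(round((tau_range[1] - tau_range[0]) / grid_step))
    taus = tau_range[0] + grid_step * np.arange(n_steps + 1)
    rho = np.full(taus.size, np.nan)
    for i, tau in enumerate(taus):
        pairs = _pooled_pairs(trials, float(tau))
        if pairs is None or len(pairs) < 3:
            continue
        if np.ptp(pairs.response) == 0 or np.ptp(pairs.stimulus) == 0:
            continue
        rho[i] = zncc(pairs)
    return LatencyScan(taus, rho, "pearson")


def _load_cue_trials(config: PipelineConfig, cue_file: str, value_name: str,
                     recenter: bool = False
                     ) -> list[tuple[CorrectionSet, Signal, np.ndarray]]:
    out = Path(config.out_dir)
    trials = []
    for k in range(config.n_trials):
        tdir = _trial_dir(out, k)
        cset = read_corrections_csv(tdir / "corrections.csv")
        cue, valid = read_signal_csv(tdir / cue_file, value_name)
        if recenter:
            labels = pd.read_csv(tdir / "sections.csv")["section"].to_numpy(str)
            try:
                series = recenter_by_curve(
                    RofAngleSeries(cue, valid), labels[: len(cue)])
                cue = series.signal
            except ValueError as exc:
                log.warning("recenter skipped for trial %d (%s)", k, exc)
        trials.append((cset, cue, valid))
    return trials


def stage_latency(config: PipelineConfig) -> dict:
    """Pooled ZNCC latency scans for the retinal-flow and heading cues."""
    out = Path(config.out_dir)
    scans = {}
    ldir = out / "latency"
    ldir.mkdir(exist_ok=True)
    for name, cue_file, value_name in (
            ("rof", "rof_angle.csv", "theta_rof"),
            ("heading", "heading_cue.csv", "theta_h")):
        trials = _load_cue_trials(config, cue_file, value_name)
        scan = pooled_latency_scan(trials, config.scan_grid_step,
                                   config.scan_tau_range)
        write_scan_csv(scan, ldir / f"scan_{name}.csv")
        scans[name] = scan
        log.info("latency: cue=%s tau_star=%.4f", name, scan.tau_star)
    return scans


def stage_report(config: PipelineConfig) -> dict:
    """Assemble the Markdown + JSON summary report."""
    out = Path(config.out_dir)
    track = read_track_json(out / "track.json")

    records, counts, travels = [], {}, []
    for k in range(config.n_trials):
        tdir = _trial_dir(out, k)
        meta = json.loads((tdir / "meta.json").read_text())
        rec = TrialRecord(states=read_states_csv(tdir / "states.csv"),
                          outcome=meta["outcome"],
                          wheel_visible=meta["wheel_visible"])
        records.append(rec)
        cset = read_corrections_csv(tdir / "corrections.csv")
        counts[k] = len(cset)
        travels.extend(abs(t) for t in cset.travels if t != 0.0)

    outcome_table = summarize_trials(records)
    counts_frame = pd.DataFrame([counts])
    corr_summary = summarize_corrections(counts_frame)
    lognorm = (fit_correction_angle_distribution(travels)
               if len(travels) >= 2 else (float("nan"), float("nan")))

    from .latency import read_scan_csv
    scans = {name: read_scan_csv(out / "latency" / f"scan_{name}.csv")
             for name in ("rof", "heading")}

    regressions = {}
    for name, cue_file, value_name in (
            ("rof", "rof_angle.csv", "theta_rof"),
            ("heading", "heading_cue.csv", "theta_h")):
        # The flow-angle predictor is recentered per curve bend so the
        # regression sees only incremental angle values.
        trials = _load_cue_trials(config, cue_file, value_name,
                                  recenter=(name == "rof"))
        tau_star = scans[name].tau_star
        pairs = _pooled_pairs(trials, tau_star)
        if pairs is not None and len(pairs) >= 3 and np.ptp(pairs.stimulus) > 0:
            slope, intercept = robust_linreg(pairs, config.huber_delta)
            regressions[name] = {"tau_star": tau_star, "slope": slope,
                                 "intercept": intercept, "n_pairs": len(pairs)}
        else:
            regressions[name] = {"tau_star": tau_star, "slope": float("nan"),
                                 "intercept": float("nan"), "n_pairs": 0}

    report = {
        "trial_outcomes": json.loads(outcome_table.to_json()),
        "corrections_per_trial": {str(k): v for k, v in counts.items()},
        "corrections_total": corr_summary["total"],
        "corrections_avg_per_trial": corr_summary["average_per_trial"],
        "correction_angle_lognormal": {"mu": lognorm[0], "sigma_sq": lognorm[1]},
        "latency_scans": {
            name: {"tau_star": s.tau_star,
                   "rho_max": float(np.nanmax(s.rho))}
            for name, s in scans.items()},
        "robust_regression": regressions,
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))

    md = ["# steerflow pipeline report", ""]
    md += ["## Trial outcomes", "", outcome_table.to_markdown(), ""]
    md += ["## Corrections per trial", "",
           pd.Series(counts, name="corrections").to_markdown(), "",
           f"Total: {corr_summary['total']:.0f}; "
           f"average per trial: {corr_summary['average_per_trial']:.2f}", ""]
    md += ["## Correction-angle distribution (log-normal MLE)", "",
           f"mu = {lognorm[0]:.4f}, sigma^2 = {lognorm[1]:.4f}, "
           f"n = {len(travels)}", ""]
    md += ["## Latency scans", ""]
    for name, s in scans.items():
        md += [f"- {name}: tau* = {s.tau_star:.4f} s, "
               f"max rho = {float(np.nanmax(s.rho)):.3f}"]
    md += ["", "## Robust regression (pseudo-Huber)", ""]
    for name, r in regressions.items():
        md += [f"- {name}: slope = {r['slope']:.4f}, "
               f"intercept = {r['intercept']:.4f}, n = {r['n_pairs']}"]
    (out / "report.md").write_text("\n".join(md) + "\n")
    return report


_STAGES = (
    ("simulate", stage_simulate),
    ("flowangle", stage_flowangle),
    ("decompose", stage_decompose),
    ("latency", stage_latency),
    ("report", stage_report),
)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order; any stage failure aborts with a
    stage-tagged :class:`StageError`.  Returns the report dictionary."""
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")
    log.info("run_pipeline: effective config %s", json.dumps(config.to_dict()))
    result: dict = {}
    for name, fn in _STAGES:
        try:
            res = fn(config)
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise StageError(name, exc) from exc
        if name == "report":
            result = res
    return result
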