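"""Stimulus-to-correction response-time estimation.

For each candidate delay ``tau`` the per-correction travel angles are
paired with the stimulus cue sampled at ``t_on - tau`` and correlated with
a zero-normalized cross-correlation (Pearson coefficient); the response
time is the ``tau`` maximizing the correlation.  Spearman and Kendall rank
statistics are available as alternatives, along with per-curve angular
recentering and a pseudo-Huber robust linear regressor for the
stimulus-response views.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import kendalltau, pearsonr, spearmanr

from .ballistic import CorrectionSet, Signal
from .flow import RofAngleSeries, circular_mean_angle, wrap_angle

__all__ = [
    "LatencyComponents",
    "StimulusResponsePairs",
    "LatencyScan",
    "ONSET_DEFINITIONS",
    "pair_corrections_with_stimulus",
    "zncc",
    "latency_scan",
    "rank_correlation_scan",
    "recenter_by_curve",
    "robust_linreg",
    "write_scan_csv",
    "read_scan_csv",
]

DEFAULT_TAU_RANGE = (0.0, 2.0)

# Correction-onset conventions: the default "mu - 2 sigma" marks movement
# onset; the alternatives trade numerical robustness against sensitivity to
# the movement's own travel time.
ONSET_DEFINITIONS = {
    "mu_minus_2sigma": lambda c: c.mu - 2.0 * c.sigma,
    "mu_minus_sigma": lambda c: c.mu - c.sigma,
    "mu": lambda c: c.mu,
}


@dataclass(frozen=True)
class LatencyComponents:
    """Perception + control-decision + muscular activation delays."""

    tau_p: float
    tau_c: float = 0.0
    tau_m: float = 0.0

    def __post_init__(self) -> None:
        if min(self.tau_p, self.tau_c, self.tau_m) < 0:
            raise ValueError("latency components must be >= 0")

    @property
    def tau_d(self) -> float:
        """Total response time."""
        return self.tau_p + self.tau_c + self.tau_m


@dataclass(frozen=True)
class StimulusResponsePairs:
    """Per-correction travel angles paired with lagged stimulus samples."""

    response: np.ndarray = field(repr=False)
    stimulus: np.ndarray = field(repr=False)
    tau: float = 0.0

    def __post_init__(self) -> None:
        r = np.asarray(self.response, dtype=float)
        s = np.asarray(self.stimulus, dtype=float)
        object.__setattr__(self, "response", r)
        object.__setattr__(self, "stimulus", s)
        if r.shape != s.shape or r.ndim != 1:
            raise ValueError("response and stimulus must be equal-length 1-D arrays")

    def __len__(self) -> int:
        return self.response.size


@dataclass(frozen=True)
class LatencyScan:
    """Correlation profile over candidate response times."""

    tau_grid: np.ndarray = field(repr=False)
    rho: np.ndarray = field(repr=False)
    method: str = "pearson"

    def __post_init__(self) -> None:
        tg = np.asarray(self.tau_grid, dtype=float)
        r = np.asarray(self.rho, dtype=float)
        object.__setattr__(self, "tau_grid", tg)
        object.__setattr__(self, "rho", r)
        if tg.shape != r.shape:
            raise ValueError("tau_grid and rho must have equal shapes")
        if np.any(np.diff(tg) <= 0):
            raise ValueError("tau_grid must be strictly ascending")
        finite = r[np.isfinite(r)]
        if finite.size and np.any(np.abs(finite) > 1.0 + 1e-9):
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def tau_star(self) -> float:
        """Delay maximizing the correlation; ties go to the smallest tau."""
        finite = np.isfinite(self.rho)
        if not np.any(finite):
            raise ValueError("scan has no defined correlations")
        rho = np.where(finite, self.rho, -np.inf)
        return float(self.tau_grid[int(np.argmax(rho))])


def pair_corrections_with_stimulus(cset: CorrectionSet, cue: Signal,
                                   tau: float,
                                   onset: str = "mu_minus_2sigma",
                                   cue_valid=None,
                                   ) -> StimulusResponsePairs:
    """Pair each correction's travel angle with the cue at ``t_on - tau``.

    The cue is linearly interpolated; pairs whose lagged time falls outside
    the cue domain — or, when a per-sample ``cue_valid`` mask is given,
    touches an invalid sample — are dropped.  Raises if no pair survives.
    """
    if onset not in ONSET_DEFINITIONS:
        raise ValueError(f"unknown onset definition {onset!r}")
    onsets = np.array([ONSET_DEFINITIONS[onset](c) for c in cset])
    responses = cset.travels
    lagged = onsets - tau
    stimuli = cue.interp(lagged)
    keep = np.isfinite(stimuli)
    if cue_valid is not None:
        ok = np.asarray(cue_valid, dtype=float)
        if ok.shape != cue.values.shape:
            raise ValueError("cue_valid must match the cue length")
        # Linear interpolation of the mask is < 1 whenever either
        # neighbouring sample is invalid.
        keep &= np.interp(lagged, cue.times, ok,
                          left=0.0, right=0.0) >= 1.0 - 1e-12
    if not np.any(keep):
        raise ValueError("all stimulus-response pairs dropped")
    return StimulusResponsePairs(responses[keep], stimuli[keep], tau)


def zncc(pairs: StimulusResponsePairs) -> float:
    """Zero-normalized cross-correlation (Pearson coefficient) of the pairs."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(pairs.response) == 0 or np.ptp(pairs.stimulus) == 0:
        raise ValueError("correlation undefined for a constant side")
    return float(pearsonr(pairs.response, pairs.stimulus).statistic)


_RANK_STATS = {
    "pearson": lambda r, s: pearsonr(r, s).statistic,
    "spearman": lambda r, s: spearmanr(r, s).statistic,
    "kendall": lambda r, s: kendalltau(r, s).statistic,
}


def _scan(cset: CorrectionSet, cue: Signal, grid_step: float,
          tau_range: tuple[float, float], method: str,
          onset: str, cue_valid=None) -> LatencyScan:
    if grid_step <= 0:
        raise ValueError("grid_step must be > 0")
    stat = _RANK_STATS[method]
    n_steps = int(round((tau_range[1] - tau_range[0]) / grid_step))
    taus = tau_range[0] + grid_step * np.arange(n_steps + 1)
    rho = np.full(taus.size, np.nan)
    for i, tau in enumerate(taus):
        try:
            pairs = pair_corrections_with_stimulus(cset, cue, float(tau),
                                                   onset, cue_valid)
            if len(pairs) < 3 or np.ptp(pairs.stimulus) == 0 or np.ptp(pairs.response) == 0:
                continue
            rho[i] = stat(pairs.response, pairs.stimulus)
        except ValueError:
            continue
    return LatencyScan(taus, rho, method)


def latency_scan(cset: CorrectionSet, cue: Signal, grid_step: float,
                 tau_range: tuple[float, float] = DEFAULT_TAU_RANGE,
                 onset: str = "mu_minus_2sigma", cue_valid=None) -> LatencyScan:
    """ZNCC scan over the delay grid; ``tau_star`` is the response time."""
    return _scan(cset, cue, grid_step, tau_range, "pearson", onset, cue_valid)


def rank_correlation_scan(cset: CorrectionSet, cue: Signal, grid_step: float,
                          method: str = "spearman",
                          tau_range: tuple[float, float] = DEFAULT_TAU_RANGE,
                          onset: str = "mu_minus_2sigma",
                          cue_valid=None) -> LatencyScan:
    """Spearman or Kendall alternative to :func:`latency_scan`."""
    if method not in ("spearman", "kendall"):
        raise ValueError(f"method must be spearman or kendall, got {method!r}")
    return _scan(cset, cue, grid_step, tau_range, method, onset, cue_valid)


def recenter_by_curve(series: RofAngleSeries, section_labels) -> RofAngleSeries:
    """Remove each curve bend's own circular-mean angle from its samples.

    ``section_labels`` assigns every sample a label; samples labelled
    ``left_curve`` / ``right_curve`` are recentered per curve, other samples
    pass through unchanged.  A curve with no valid samples raises.
    """
    labels = np.asarray(section_labels)
    if labels.shape != series.values.shape:
        raise ValueError("section_labels must match the series length")
    values = series.values.copy()
    for lab in ("left_curve", "right_curve"):
        sel = (labels == lab)
        if not np.any(sel):
            continue
        valid = sel & series.valid
        if not np.any(valid):
            raise ValueError(f"no valid samples in {lab}")
        mean = circular_mean_angle(values[valid])
        values[sel] = wrap_angle(values[sel] - mean)
    present = {str(l) for l in np.unique(labels)}
    if not {"left_curve", "right_curve"} & present:
        raise ValueError("no curve sections present")
    return RofAngleSeries(Signal(series.signal.t0, series.signal.dt, values),
                          series.valid)


def robust_linreg(pairs: StimulusResponsePairs,
                  huber_delta: float = 1.0) -> tuple[float, float]:
    """Linear fit response ~ stimulus under the pseudo-Huber loss.

    Minimizes ``sum delta^2 (sqrt(1 + (r/delta)^2) - 1)`` over slope and
    intercept, started from the least-squares solution.  Deterministic.
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x, y = pairs.stimulus, pairs.response
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all stimuli equal")
    if huber_delta <= 0:
        raise ValueError("huber_delta must be > 0")
    A = np.vstack([x, np.ones_like(x)]).T
    beta0, *_ = np.linalg.lstsq(A, y, rcond=None)

    d2 = huber_delta * huber_delta

    def loss_grad(beta):
        r = y - (beta[0] * x + beta[1])
        root = np.sqrt(1.0 + r * r / d2)
        loss = float(np.sum(d2 * (root - 1.0)))
        w = r / root  # d loss / d r = -w
        return loss, np.array([-np.sum(w * x), -np.sum(w)])

    res = minimize(loss_grad, beta0, jac=True, method="L-BFGS-B",
                   options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 500})
    slope, intercept = res.x
    return float(slope), float(intercept)


def write_scan_csv(scan: LatencyScan, path: str | Path) -> None:
    frame = pd.DataFrame({"tau": scan.tau_grid, "rho": scan.rho,
                          "method": scan.method})
    frame.to_csv(path, index=False, float_format="%.9g")


def read_scan_csv(path: str | Path) -> LatencyScan:
    frame = pd.read_csv(path)
    method = str(frame["method"].iloc[0])
    return LatencyScan(frame["tau"].to_numpy(float),
                       frame["rho"].to_numpy(float), method)
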