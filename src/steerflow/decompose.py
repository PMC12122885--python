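"""Decomposition of steering-rate signals into Gaussian ballistic corrections.

The observed steering-wheel angle rate ``z(t)`` is modelled as a sum of
Gaussian velocity pulses.  A particle swarm optimizer minimizes the
complexity-penalized L1 fitness

    max(N, 1)^alpha / (t1 - t0) * integral_{t0}^{t1} |z(t) - model(t)| dt

for every candidate model order ``N`` in ``0..n_max``; the order with the
lowest fitness wins.  The raw ``N^alpha`` factor would make the empty model
a trivial global optimum, so ``max(N, 1)`` scores it by its bare residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .ballistic import BallisticCorrection, CorrectionSet, Signal, travel_distance

__all__ = [
    "DecompositionConfig",
    "FitResult",
    "fitness",
    "segment_signal",
    "decompose",
    "decompose_windows",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)

DEFAULT_SIGMA_BOUNDS = (0.0707, 0.1732)


@dataclass(frozen=True)
class DecompositionConfig:
    """Settings for the penalized sum-of-Gaussians decomposition.

    ``a_bound`` of ``None`` resolves to four times the peak ``|z|`` of the
    window under fit.  PSO coefficients default to the standard constriction
    setup (inertia 0.729, cognitive/social 1.49445, global-best topology).
    """

    alpha: float = 1.0
    n_max: int = 8
    sigma_bounds: tuple[float, float] = DEFAULT_SIGMA_BOUNDS
    a_bound: float | None = None
    swarm_size: int = 60
    iterations: int = 400
    inertia: float = 0.729
    cognitive_coeff: float = 1.49445
    social_coeff: float = 1.49445
    seed: int = 0
    prune_threshold: float = 0.005
    polish: bool = True
    rate_threshold: float = 0.05
    max_window: float = 8.0

    def __post_init__(self) -> None:
        lo, hi = self.sigma_bounds
        if not (0.0 < lo < hi) or not math.isfinite(hi):
            raise ValueError(f"sigma_bounds must be ordered and positive: {self.sigma_bounds}")
        if self.alpha <= 0.0:
            raise ValueError("alpha must be > 0")
        if self.swarm_size < 10:
            raise ValueError("swarm_size must be >= 10")
        if self.n_max < 0 or self.iterations < 1:
            raise ValueError("n_max must be >= 0 and iterations >= 1")
        if self.a_bound is not None and (self.a_bound <= 0 or not math.isfinite(self.a_bound)):
            raise ValueError("a_bound must be positive and finite")


@dataclass(frozen=True)
class FitResult:
    """Outcome of decomposing one window of a steering-rate signal."""

    corrections: CorrectionSet
    fitness: float
    mean_abs_residual: float
    window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.fitness < 0 or self.mean_abs_residual < 0:
            raise ValueError("fitness and mean_abs_residual must be >= 0")


def _window_slice(z: Signal, window: tuple[float, float]) -> Signal:
    t0, t1 = window
    if not t1 > t0:
        raise ValueError(f"empty window {window}")
    # Windows are half-open [t0, t1); t1 may sit one step past the last sample.
    if t0 < z.t0 - 1e-9 or t1 > z.t_end + z.dt + 1e-9:
        raise ValueError(f"window {window} outside signal domain [{z.t0}, {z.t_end}]")
    return z.slice(t0, min(t1, z.t_end))


def _model_matrix(params: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Sum-of-Gaussians models for a whole swarm.

    ``params`` has shape (P, 3N) laid out as N blocks of (a, mu, sigma);
    returns model values with shape (P, T).
    """
    P, D = params.shape
    n = D // 3
    if n == 0:
        return np.zeros((P, t.size))
    blocks = params.reshape(P, n, 3)
    a = blocks[:, :, 0][:, :, None]
    mu = blocks[:, :, 1][:, :, None]
    sigma = blocks[:, :, 2][:, :, None]
    u = (t[None, None, :] - mu) / sigma
    return np.sum(a * np.exp(-0.5 * u * u), axis=1)


def _penalized_l1(resid_abs: np.ndarray, dt: float, span: float,
                  n: int, alpha: float) -> np.ndarray:
    integral = np.trapezoid(resid_abs, dx=dt, axis=-1)
    return max(n, 1) ** alpha / span * integral


def fitness(candidate: CorrectionSet | Sequence[BallisticCorrection],
            z: Signal,
            window: tuple[float, float],
            alpha: float = 1.0) -> float:
    """Penalized L1 misfit of ``candidate`` against ``z`` over ``window``.

    ``max(N, 1)^alpha / (t1 - t0) * trapz(|z - model|)`` on ``z``'s grid.
    """
    zw = _window_slice(z, window)
    candidate = list(candidate)
    if candidate:
        params = np.array(
            [[c.a, c.mu, c.sigma] for c in candidate], dtype=float
        ).reshape(1, -1)
        model = _model_matrix(params, zw.times)[0]
    else:
        model = np.zeros(len(zw))
    span = window[1] - window[0]
    return float(
        _penalized_l1(np.abs(zw.values - model), zw.dt, span, len(candidate), alpha)
    )


def segment_signal(z: Signal, rate_threshold: float,
                   max_window: float = math.inf,
                   min_quiet: float | None = None,
                   sigma_low: float = DEFAULT_SIGMA_BOUNDS[0]) -> list[tuple[float, float]]:
    """Split ``z`` into half-open fit windows at sustained quiet runs.

    A quiet run is ``|z| < rate_threshold`` lasting at least ``min_quiet``
    (default ``4 * sigma_low``, one minimal correction duration).  Windows
    longer than ``max_window`` are split evenly.  The union of the returned
    windows covers every supra-threshold sample.
    """
    if min_quiet is None:
        min_quiet = 4.0 * sigma_low
    active = np.abs(z.values) >= rate_threshold
    if not np.any(active):
        return []
    min_quiet_n = max(int(math.ceil(min_quiet / z.dt)), 1)
    t = z.times

    # Runs of consecutive active samples.
    edges = np.diff(active.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(active.size)

    # Merge runs separated by quiet gaps shorter than min_quiet.
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < min_quiet_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    windows: list[tuple[float, float]] = []
    for s, e in merged:
        w0 = t[s]
        w1 = t[e - 1] + z.dt  # half-open [t0, t1)
        n_split = max(int(math.ceil((w1 - w0) / max_window)), 1)
        cuts = np.linspace(w0, w1, n_split + 1)
        windows.extend(zip(cuts[:-1], cuts[1:]))
    return windows


def _pso_minimize(func: Callable[[np.ndarray], np.ndarray],
                  lower: np.ndarray, upper: np.ndarray,
                  swarm_size: int, iterations: int,
                  inertia: float, c1: float, c2: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """Global-best PSO with reflecting bounds; ``func`` is swarm-vectorized."""
    dim = lower.size
    span = upper - lower
    x = lower + rng.random((swarm_size, dim)) * span
    v = (rng.random((swarm_size, dim)) - 0.5) * span
    pbest_x = x.copy()
    pbest_f = func(x)
    g = int(np.argmin(pbest_f))
    gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])

    stall = 0
    for _ in range(iterations):
        r1 = rng.random((swarm_size, dim))
        r2 = rng.random((swarm_size, dim))
        v = (inertia * v
             + c1 * r1 * (pbest_x - x)
             + c2 * r2 * (gbest_x[None, :] - x))
        x = x + v
        # Reflect positions at the bounds and reverse the offending velocity.
        low_hit = x < lower
        x = np.where(low_hit, 2.0 * lower - x, x)
        high_hit = x > upper
        x = np.where(high_hit, 2.0 * upper - x, x)
        v = np.where(low_hit | high_hit, -v, v)
        np.clip(x, lower, upper, out=x)

        f = func(x)
        improved = f < pbest_f
        pbest_x[improved] = x[improved]
        pbest_f[improved] = f[improved]
        g = int(np.argmin(pbest_f))
        if pbest_f[g] < gbest_f - 1e-12 - 1e-6 * abs(gbest_f):
            gbest_x, gbest_f = pbest_x[g].copy(), float(pbest_f[g])
            stall = 0
        else:
            stall += 1
            if stall >= 80:  # converged: no meaningful gbest movement
                break
    return gbest_x, gbest_f


def _order_bounds(zw: Signal, n: int, config: DecompositionConfig,
                  a_bound: float) -> tuple[np.ndarray, np.ndarray]:
    sig_lo, sig_hi = config.sigma_bounds
    mu_lo = zw.t0 - 2.0 * sig_hi
    mu_hi = zw.t_end + 2.0 * sig_hi
    return (np.tile([-a_bound, mu_lo, sig_lo], n),
            np.tile([a_bound, mu_hi, sig_hi], n))


def _make_swarm_fitness(zw: Signal, span: float, n: int, alpha: float):
    t, zvals, dt = zw.times, zw.values, zw.dt

    def swarm_fitness(params: np.ndarray) -> np.ndarray:
        model = _model_matrix(params, t)
        return _penalized_l1(np.abs(zvals - model), dt, span, n, alpha)

    return swarm_fitness


def _polish(params: np.ndarray, zw: Signal, span: float,
            config: DecompositionConfig, a_bound: float) -> tuple[np.ndarray, float]:
    n = params.size // 3
    swarm_fitness = _make_swarm_fitness(zw, span, n, config.alpha)
    lower, upper = _order_bounds(zw, n, config, a_bound)
    res = minimize(
        lambda p: float(swarm_fitness(p[None, :])[0]),
        np.clip(params, lower, upper), method="Powell",
        bounds=list(zip(lower, upper)),
        options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 2000},
    )
    out = np.clip(res.x, lower, upper)
    return out, float(swarm_fitness(out[None, :])[0])


def _backward_eliminate(params: np.ndarray, f: float, zw: Signal, span: float,
                        config: DecompositionConfig, a_bound: float
                        ) -> tuple[np.ndarray, float]:
    """Drop superfluous components while the penalized fitness improves.

    PSO reaches overfit orders more easily than the exact one (extra
    components give an easier basin), so the descent to the minimal order is
    done deterministically: try removing each of the two smallest-|travel|
    components, re-polish, and keep the best removal if it beats the
    current fitness.
    """
    while params.size >= 3:
        blocks = params.reshape(-1, 3)
        travel = np.abs(blocks[:, 0] * blocks[:, 2])
        order = np.argsort(travel)[:2]
        best_trial: tuple[np.ndarray, float] | None = None
        for j in order:
            reduced = np.delete(blocks, j, axis=0).ravel()
            if reduced.size == 0:
                trial = (reduced, _penalized_l1(np.abs(zw.values), zw.dt,
                                                span, 0, config.alpha))
            else:
                trial = _polish(reduced, zw, span, config, a_bound)
            if best_trial is None or trial[1] < best_trial[1]:
                best_trial = trial
        if best_trial is not None and best_trial[1] < f:
            params, f = best_trial
        else:
            break
    return params, f


def decompose(z: Signal, config: DecompositionConfig,
              window: tuple[float, float] | None = None) -> FitResult:
    """Identify the ballistic corrections composing one window of ``z``.

    Runs PSO for every candidate order ``N`` in ``0..n_max``, keeps the
    order minimizing the penalized fitness, locally polishes the winner
    (deterministic Powell descent on the same objective — the L1 integrand
    is non-smooth but Powell copes), and prunes corrections whose |travel
    distance| falls below ``config.prune_threshold``.  Deterministic for a
    fixed ``config.seed``.
    """
    if window is None:
        window = (z.t0, z.t_end)
    zw = _window_slice(z, window)
    span = window[1] - window[0]
    peak = float(np.max(np.abs(zw.values))) if len(zw) else 0.0
    a_bound = config.a_bound if config.a_bound is not None else 4.0 * max(peak, 1e-12)

    rng = np.random.default_rng(config.seed)
    candidates: list[tuple[np.ndarray, float]] = []
    for n in range(1, config.n_max + 1):
        swarm_fitness = _make_swarm_fitness(zw, span, n, config.alpha)
        lower, upper = _order_bounds(zw, n, config, a_bound)
        candidates.append(_pso_minimize(
            swarm_fitness, lower, upper, config.swarm_size, config.iterations,
            config.inertia, config.cognitive_coeff, config.social_coeff, rng,
        ))

    best_params = np.empty(0)
    best_f = fitness((), z, window, config.alpha)  # N = 0 baseline
    if candidates:
        f_floor = min(f for _, f in candidates)
        for params, f in candidates:
            if config.polish and f <= 20.0 * f_floor + 1e-15:
                # Orders within reach of the best raw swarm must be compared
                # after full local convergence: an under-converged true order
                # would otherwise lose to an overfit one with more knobs.
                n = params.size // 3
                swarm_fitness = _make_swarm_fitness(zw, span, n, config.alpha)
                lower, upper = _order_bounds(zw, n, config, a_bound)
                res = minimize(
                    lambda p: float(swarm_fitness(p[None, :])[0]),
                    params, method="Powell",
                    bounds=list(zip(lower, upper)),
                    options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 2000},
                )
                if res.fun < f:
                    params, f = np.clip(res.x, lower, upper), float(res.fun)
            if f < best_f:
                best_params, best_f = params, f

    if config.polish and best_params.size:
        best_params, best_f = _backward_eliminate(
            best_params, best_f, zw, span, config, a_bound)

    corrections = [
        BallisticCorrection(float(a), float(mu), float(sigma))
        for a, mu, sigma in best_params.reshape(-1, 3)
    ]
    kept = CorrectionSet(
        c for c in corrections
        if abs(travel_distance(c)) >= config.prune_threshold
    )
    final_fitness = fitness(kept, z, window, config.alpha)
    residual = final_fitness / max(len(kept), 1) ** config.alpha
    return FitResult(
        corrections=kept,
        fitness=final_fitness,
        mean_abs_residual=residual,
        window=window,
    )


def decompose_windows(z: Signal, config: DecompositionConfig) -> list[FitResult]:
    """Segment ``z`` into active windows and decompose each.

    Per-window seeds are derived deterministically from ``config.seed``.
    """
    windows = segment_signal(
        z, config.rate_threshold, config.max_window,
        sigma_low=config.sigma_bounds[0],
    )
    results = []
    seeds = np.random.SeedSequence(config.seed).spawn(max(len(windows), 1))
    for win, seed_seq in zip(windows, seeds):
        sub = replace(config, seed=int(seed_seq.generate_state(1)[0]))
        results.append(decompose(z, sub, window=win))
    return results
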