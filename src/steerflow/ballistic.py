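"""Gaussian ballistic steering-correction model.

A single rapid aimed steering sub-movement ("ballistic correction") is
modelled as a Gaussian velocity pulse parameterized by strength ``a``
(rad/s, signed), mode ``mu`` (s) and rate ``sigma`` (s).  Complex steering
movements are superpositions of such pulses.  The position profile is the
sigmoid primitive of the pulse (a scaled Gauss error function), onset and
offset are ``mu -/+ 2 sigma``, and the net steering-angle change of one
correction is ``a * sigma * sqrt(2 pi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

__all__ = [
    "BallisticCorrection",
    "CorrectionSet",
    "Signal",
    "correction_velocity",
    "superpose",
    "onset_offset",
    "correction_position",
    "travel_distance",
    "coverage_fraction",
    "read_corrections_csv",
    "write_corrections_csv",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class BallisticCorrection:
    """One Gaussian steering sub-movement.

    Parameters
    ----------
    a : float
        Correction strength in rad/s (signed; sign is the steering direction).
    mu : float
        Correction mode time in seconds (time of peak velocity).
    sigma : float
        Correction rate parameter in seconds; must be positive.  Smaller
        values produce faster, shorter corrections.
    """

    a: float
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        for name in ("a", "mu", "sigma"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.sigma <= 0.0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def onset(self) -> float:
        """Movement onset time, ``mu - 2 sigma``."""
        return self.mu - 2.0 * self.sigma

    @property
    def offset(self) -> float:
        """Movement offset time, ``mu + 2 sigma``."""
        return self.mu + 2.0 * self.sigma

    @property
    def duration(self) -> float:
        """Total movement duration, ``4 sigma``."""
        return 4.0 * self.sigma

    def velocity(self, t):
        """Velocity profile at time(s) ``t`` (rad/s)."""
        return correction_velocity(t, self)

    def position(self, t, constant: float = 0.0):
        """Position profile at time(s) ``t`` (rad), offset by ``constant``."""
        return correction_position(t, self, constant)

    @property
    def travel(self) -> float:
        """Net steering-angle change of the full movement (rad)."""
        return travel_distance(self)


class CorrectionSet:
    """Ordered collection of :class:`BallisticCorrection`.

    Maintained sorted by mode time ascending; ties are broken by larger
    ``|a|`` first so serialization is deterministic.
    """

    __slots__ = ("_corrections",)

    def __init__(self, corrections: Iterable[BallisticCorrection] = ()) -> None:
        self._corrections = tuple(
            sorted(corrections, key=lambda c: (c.mu, -abs(c.a)))
        )

    def __len__(self) -> int:
        return len(self._corrections)

    def __iter__(self) -> Iterator[BallisticCorrection]:
        return iter(self._corrections)

    def __getitem__(self, i):
        return self._corrections[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CorrectionSet):
            return NotImplemented
        return self._corrections == other._corrections

    def __repr__(self) -> str:
        return f"CorrectionSet(n={len(self)})"

    def union(self, other: "CorrectionSet") -> "CorrectionSet":
        return CorrectionSet((*self, *other))

    @property
    def modes(self) -> np.ndarray:
        return np.array([c.mu for c in self], dtype=float)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([c.onset for c in self], dtype=float)

    @property
    def travels(self) -> np.ndarray:
        return np.array([c.travel for c in self], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Tabulate as a DataFrame with derived convenience columns."""
        rows = [
            {
                "a": c.a,
                "mu": c.mu,
                "sigma": c.sigma,
                "t_on": c.onset,
                "t_off": c.offset,
                "delta": c.travel,
            }
            for c in self
        ]
        return pd.DataFrame(
            rows, columns=["a", "mu", "sigma", "t_on", "t_off", "delta"]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CorrectionSet":
        """Build from a DataFrame; derived columns are ignored."""
        return cls(
            BallisticCorrection(float(r.a), float(r.mu), float(r.sigma))
            for r in frame.itertuples()
        )


@dataclass(frozen=True)
class Signal:
    """Uniformly sampled scalar time series."""

    t0: float
    dt: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if self.dt <= 0.0 or not math.isfinite(self.dt):
            raise ValueError(f"dt must be positive and finite, got {self.dt}")
        if not math.isfinite(self.t0):
            raise ValueError("t0 must be finite")
        if vals.ndim != 1 or vals.size < 1:
            raise ValueError("values must be a 1-D sequence of length >= 1")
        if not np.all(np.isfinite(vals)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        """Time of the last sample."""
        return self.t0 + self.dt * (self.values.size - 1)

    def slice(self, t0: float, t1: float) -> "Signal":
        """Samples with t0 <= t <= t1 (inclusive of boundary samples)."""
        t = self.times
        idx = np.flatnonzero((t >= t0 - 1e-12) & (t <= t1 + 1e-12))
        if idx.size == 0:
            raise ValueError(f"no samples in [{t0}, {t1}]")
        return Signal(t[idx[0]], self.dt, self.values[idx[0] : idx[-1] + 1])

    def interp(self, t) -> np.ndarray:
        """Linear interpolation at time(s) ``t``; NaN outside the domain."""
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.times, self.values, left=np.nan, right=np.nan)
        return out


def correction_velocity(t, c: BallisticCorrection):
    """Gaussian velocity profile ``a * exp(-(t-mu)^2 / (2 sigma^2))``.

    Even-symmetric about ``mu``; peak value ``a`` at ``t = mu``.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("t must be finite")
    u = (t - c.mu) / c.sigma
    out = c.a * np.exp(-0.5 * u * u)
    return float(out) if out.ndim == 0 else out


def superpose(corrections: CorrectionSet | Sequence[BallisticCorrection],
              grid: Signal) -> Signal:
    """Pointwise sum of the correction velocities on ``grid``'s time base.

    ``grid`` supplies only the domain (t0, dt, length); its values are
    ignored.  The empty set yields the identically-zero signal.
    """
    t = grid.times
    total = np.zeros_like(t)
    for c in corrections:
        total += correction_velocity(t, c)
    return Signal(grid.t0, grid.dt, total)


def onset_offset(c: BallisticCorrection) -> tuple[float, float]:
    """Movement (onset, offset) = ``(mu - 2 sigma, mu + 2 sigma)``."""
    return c.onset, c.offset


def correction_position(t, c: BallisticCorrection, constant: float = 0.0):
    """Sigmoid position profile: primitive of :func:`correction_velocity`.

    ``a * sigma * sqrt(pi/2) * erf((t - mu) / (sqrt(2) sigma)) + constant``.
    """
    t = np.asarray(t, dtype=float)
    scale = c.a * c.sigma * math.sqrt(math.pi / 2.0)
    out = scale * erf((t - c.mu) / (math.sqrt(2.0) * c.sigma)) + constant
    return float(out) if out.ndim == 0 else out


def travel_distance(c: BallisticCorrection) -> float:
    """Net steering-angle change ``a * sigma * sqrt(2 pi)`` (rad, signed)."""
    return c.a * c.sigma * _SQRT_2PI


def coverage_fraction(k: float) -> float:
    """Fraction of the total |velocity| integral within ``mu +/- k sigma``.

    Equals ``erf(k / sqrt(2))``; independent of the correction parameters.
    ``k = 2`` gives about 0.954 of the complete theoretical movement.
    """
    if k <= 0.0:
        raise ValueError(f"k must be > 0, got {k}")
    return float(erf(k / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# CSV serialization: columns a (rad/s), mu (s), sigma (s) plus derived
# t_on, t_off, delta written for convenience and ignored on read.

def write_corrections_csv(cset: CorrectionSet, path: str | Path) -> None:
    cset.to_frame().to_csv(path, index=False, float_format="%.9g")


def read_corrections_csv(path: str | Path) -> CorrectionSet:
    frame = pd.read_csv(path)
    missing = {"a", "mu", "sigma"} - set(frame.columns)
    if missing:
        raise ValueError(f"corrections CSV missing columns: {sorted(missing)}")
    return CorrectionSet.from_frame(frame)
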