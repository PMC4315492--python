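"""Spike trains and synthetic input generators.

A :class:`SpikeTrain` is the lingua franca of the package: an ordered
sequence of event times together with the total span it covers and a
time-unit tag.  Three generators produce the input classes every model in
the package is driven with:

* :func:`generate_periodic` -- strictly periodic trains with fixed
  inter-spike interval (period) ``T``,
* :func:`generate_gamma` -- renewal trains whose inter-spike intervals are
  gamma distributed with shape ``alpha`` and rate ``alpha * rate_in`` so
  that the mean interval is ``1 / rate_in`` and the relative standard
  deviation of the intervals is ``1 / sqrt(alpha)``,
* :func:`generate_sweep` -- slow frequency sweeps whose instantaneous rate
  changes linearly in time (events stepped by the instantaneous inverse
  rate).

Poisson input is the special case ``alpha = 1`` of the gamma generator; it
has no dedicated code path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import numpy as np

__all__ = [
    "SpikeTrain",
    "GammaInputSpec",
    "SweepSpec",
    "generate_periodic",
    "generate_gamma",
    "generate_sweep",
]

_VALID_UNITS = ("dimensionless", "ms")


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered event times covering ``[0, duration]``.

    Parameters
    ----------
    times:
        Strictly increasing event times, all within ``[0, duration]``.
    duration:
        Total span covered by the train (may extend past the last event).
    unit:
        Time-unit tag, either ``"dimensionless"`` (LIF / FHN model time)
        or ``"ms"`` (HH model time).
    """

    times: np.ndarray
    duration: float
    unit: str = "dimensionless"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("times must be a 1-d sequence")
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration + 1e-12:
                raise ValueError("event times must lie in [0, duration]")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return len(self)

    def intervals(self) -> np.ndarray:
        """Inter-spike intervals (length ``n_events - 1``)."""
        return np.diff(self.times)

    def crop(self, t_start: float, t_end: float | None = None) -> "SpikeTrain":
        """Return the sub-train with events in ``[t_start, t_end]``,
        re-referenced so that ``t_start`` maps to time 0."""
        if t_end is None:
            t_end = self.duration
        sel = (self.times >= t_start) & (self.times <= t_end)
        return SpikeTrain(self.times[sel] - t_start, t_end - t_start, self.unit)

    def rescaled(self, factor: float) -> "SpikeTrain":
        """Multiply all times (and the duration) by ``factor``."""
        if factor <= 0:
            raise ValueError("rescaling factor must be positive")
        return SpikeTrain(self.times * factor, self.duration * factor, self.unit)

    # ------------------------------------------------------------------
    # plain-text and JSON round-trips
    # ------------------------------------------------------------------
    def to_text(self, path: Union[str, Path]) -> None:
        """Write one timestamp per line; '#' header lines carry metadata."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# unit: {self.unit}\n")
            fh.write(f"# duration: {float(self.duration)!r}\n")
            for t in self.times:
                fh.write(f"{float(t)!r}\n")

    @classmethod
    def from_text(cls, path: Union[str, Path]) -> "SpikeTrain":
        unit = "dimensionless"
        duration = None
        times = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("unit:"):
                    unit = body.split(":", 1)[1].strip()
                elif body.startswith("duration:"):
                    duration = float(body.split(":", 1)[1])
                continue
            times.append(float(line))
        times_arr = np.asarray(times, dtype=float)
        if duration is None:
            duration = float(times_arr[-1]) if times_arr.size else 0.0
        return cls(times_arr, duration, unit)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = json.dumps(
            {"unit": self.unit, "duration": self.duration, "times": self.times.tolist()}
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: Union[str, Path]) -> "SpikeTrain":
        text = source
        if isinstance(source, Path) or (isinstance(source, str) and Path(source).exists()):
            text = Path(source).read_text()
        data = json.loads(text)
        return cls(np.asarray(data["times"], dtype=float), data["duration"], data["unit"])


@dataclass(frozen=True)
class GammaInputSpec:
    """Specification of a gamma-renewal input train.

    The inter-spike-interval density is a gamma distribution with shape
    ``alpha`` and rate parameter ``lam = alpha * rate_in``, i.e.

        p(dt) = lam**alpha * exp(-lam*dt) * dt**(alpha-1) / Gamma(alpha)

    so the mean interval is ``alpha / lam = 1 / rate_in`` and the relative
    standard deviation is ``1 / sqrt(alpha)``.
    """

    alpha: float
    rate_in: float
    n_events: int
    seed: int = 0
    unit: str = "dimensionless"

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("shape parameter alpha must be positive")
        if self.rate_in <= 0:
            raise ValueError("input rate must be positive")
        if self.n_events < 1:
            raise ValueError("need at least one event")

    @property
    def lam(self) -> float:
        """Rate parameter of the interval density (``alpha * rate_in``)."""
        return self.alpha * self.rate_in


@dataclass(frozen=True)
class SweepSpec:
    """Slow frequency sweep, linear in instantaneous rate over ``duration``."""

    rate_start: float
    rate_end: float
    duration: float
    unit: str = "dimensionless"

    def __post_init__(self) -> None:
        if self.rate_start <= 0 or self.rate_end <= 0:
            raise ValueError("sweep rates must be positive")
        if self.duration <= 0:
            raise ValueError("sweep duration must be positive")

    def rate_at(self, t: float) -> float:
        frac = np.clip(t / self.duration, 0.0, 1.0)
        return self.rate_start + (self.rate_end - self.rate_start) * frac


def generate_periodic(
    period: float, n_events: int, t0: float = 0.0, unit: str = "dimensionless"
) -> SpikeTrain:
    """Strictly periodic train: events at ``t0 + k*period``, k = 0..n-1."""
    if period <= 0:
        raise ValueError("period must be positive")
    if n_events < 1:
        raise ValueError("need at least one event")
    times = t0 + period * np.arange(n_events, dtype=float)
    return SpikeTrain(times, float(times[-1]), unit)


def generate_gamma(spec: GammaInputSpec) -> SpikeTrain:
    """Gamma-renewal train; first event at t = 0, ``n_events - 1`` intervals.

    Deterministic for a fixed ``spec.seed``: identical specs produce
    bit-identical trains.
    """
    rng = np.random.default_rng(spec.seed)
    scale = 1.0 / spec.lam
    intervals = rng.gamma(shape=spec.alpha, scale=scale, size=spec.n_events - 1)
    times = np.concatenate(([0.0], np.cumsum(intervals)))
    return SpikeTrain(times, float(times[-1]), spec.unit)


def generate_sweep(spec: SweepSpec) -> SpikeTrain:
    """Frequency sweep: ``t_{m+1} = t_m + 1/rate(t_m)``, first event at 0."""
    times = [0.0]
    t = 0.0
    while True:
        t_next = t + 1.0 / spec.rate_at(t)
        if t_next > spec.duration:
            break
        times.append(t_next)
        t = t_next
    return SpikeTrain(np.asarray(times), spec.duration, spec.unit)
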