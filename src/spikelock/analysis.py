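"""Turning spike sequences into rates, error bars and locking labels.

The estimators here are deliberately simple and apply to any pair of
timestamp files, simulated or recorded:

* the stationary output rate is the spike-count estimator
  ``lambda_out = (N - 1) / span`` with ``span`` the time between the first
  and the last spike -- exact on periodic trains;
* the error bound for a simulated rate measured over a window of length
  ``span`` is ``1 / (rate * span)``, i.e. counting at least 100 spikes
  bounds the relative error at 1%;
* for swept experimental protocols delivering a fixed number of input
  spikes per sweep (50 by default) the per-point error estimate is
  ``(lambda_in - lambda_out) / 50`` -- zero under 1:1 locking, where no
  output interval can be missed.

Locking classification labels a stationary response as locked n:m,
irregular, or silent.  A rational rate ratio alone is not sufficient (a
randomly thinned train matches one by chance): the classifier additionally
requires the sequence of input-spike counts between consecutive output
spikes to be periodic with period m, which is invariant under jitter that
the output tracks and under common time rescaling.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, NamedTuple, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .trains import SpikeTrain

__all__ = [
    "RateEstimate",
    "LockingLabel",
    "ResponseCurve",
    "estimate_rate",
    "experimental_error",
    "simulated_error_bound",
    "classify_locking",
    "detect_nonmonotonic",
]


class RateEstimate(NamedTuple):
    rate: float
    n_spikes: int
    span: Optional[float]  # None when fewer than 2 spikes
    error: Optional[float] = None

    @property
    def silent(self) -> bool:
        return self.n_spikes < 2


@dataclass(frozen=True)
class LockingLabel:
    """Classification of one stationary response.

    kind is "locked", "irregular" or "silent"; for locked responses n and m
    give the coprime cycle structure: n input spikes per m output spikes.
    """

    kind: str
    n: Optional[int] = None
    m: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("locked", "irregular", "silent"):
            raise ValueError("kind must be locked, irregular or silent")
        if self.kind == "locked":
            if not (self.n and self.m and self.n >= 1 and self.m >= 1):
                raise ValueError("locked labels need n >= 1 and m >= 1")
            if math.gcd(self.n, self.m) != 1:
                raise ValueError("locked n:m must be coprime")

    def __str__(self) -> str:
        if self.kind == "locked":
            return f"{self.n}:{self.m}"
        return self.kind

    @classmethod
    def parse(cls, text: str) -> "LockingLabel":
        text = text.strip()
        if text in ("irregular", "silent"):
            return cls(text)
        n, m = (int(v) for v in text.split(":"))
        return cls("locked", n, m)


def estimate_rate(train: SpikeTrain) -> RateEstimate:
    """Spike-count rate estimator (N - 1) / span; silent below 2 spikes."""
    n = len(train)
    if n < 2:
        return RateEstimate(0.0, n, None)
    span = float(train.times[-1] - train.times[0])
    return RateEstimate((n - 1) / span, n, span)


def experimental_error(rate_in: float, rate_out: float, divisor: int = 50) -> float:
    """Per-sweep error estimate for fixed-count stimulation protocols."""
    if rate_out < 0 or rate_in < rate_out:
        raise ValueError("need rate_in >= rate_out >= 0")
    return (rate_in - rate_out) / divisor


def simulated_error_bound(rate: float, span: float) -> float:
    """Maximum *relative* rate-estimation error over a window:
    ``|df|/f <= 1 / (rate * span)``.

    Counting one interval too few or too many over a window of length
    ``span`` shifts the rate by at most ``1/span``, i.e. a relative error of
    ``1/(rate*span)`` -- 1% once 100 spikes are counted.  The absolute error
    bar on the rate scale is ``rate`` times this value (= ``1/span``).
    """
    if rate <= 0 or span <= 0:
        raise ValueError("rate and span must be positive")
    return 1.0 / (rate * span)


def _count_sequence(input_times: np.ndarray, output_times: np.ndarray) -> np.ndarray:
    """Input spikes in (out_k, out_{k+1}] for consecutive output spikes."""
    idx = np.searchsorted(input_times, output_times, side="right")
    return np.diff(idx)


def classify_locking(
    input_train: SpikeTrain,
    output_train: SpikeTrain,
    max_n: int = 20,
    max_m: int = 10,
    tolerance: Optional[float] = None,
) -> LockingLabel:
    """Label a stationary response as locked n:m, irregular or silent.

    Locked n:m requires (i) the sequence of input-spike counts between
    consecutive output spikes to be periodic with period m with n inputs
    per cycle (at least two full cycles observed), and (ii) the measured
    rates to satisfy ``rate_out ~= (m/n) rate_in`` within ``tolerance``
    (default: twice the combined spike-count error bounds).  Candidates are
    tried lowest order first (smallest n + m, then smallest n).
    """
    out_est = estimate_rate(output_train)
    if out_est.silent:
        return LockingLabel("silent")
    in_est = estimate_rate(input_train)
    if in_est.silent:
        raise ValueError("input train must contain at least 2 spikes")

    counts = _count_sequence(input_train.times, output_train.times)
    if tolerance is None:
        # twice the combined absolute (rate-scale) error bars
        tol = 2.0 * (
            out_est.rate * simulated_error_bound(out_est.rate, out_est.span)
            + in_est.rate * simulated_error_bound(in_est.rate, in_est.span)
        )
    else:
        tol = tolerance

    candidates = sorted(
        (
            (n, m)
            for n in range(1, max_n + 1)
            for m in range(1, max_m + 1)
            if math.gcd(n, m) == 1
        ),
        key=lambda nm: (nm[0] + nm[1], nm[0]),
    )
    for n, m in candidates:
        if len(counts) < 2 * m:  # need at least two full cycles
            continue
        if np.any(counts[m:] != counts[:-m]):
            continue
        if int(counts[:m].sum()) != n:
            continue
        if abs(out_est.rate - (m / n) * in_est.rate) <= tol:
            return LockingLabel("locked", n, m)
    return LockingLabel("irregular")


def detect_nonmonotonic(
    curve: Union["ResponseCurve", pd.DataFrame], tolerance: float = 0.0
) -> List[Tuple[int, int]]:
    """Maximal index ranges where the response curve decreases.

    A step i -> i+1 counts as decreasing when rate_out drops by more than
    ``tolerance`` plus both points' error bounds.  Returns (start, end)
    index pairs (inclusive) of maximal decreasing runs.  Also accepts a
    plain DataFrame with rate_in/rate_out (and optionally error) columns,
    e.g. a closed-form theory curve.
    """
    df = curve.to_frame() if hasattr(curve, "to_frame") else curve
    if len(df) < 2:
        raise ValueError("curve needs at least 2 points")
    rates = df["rate_out"].to_numpy()
    if "error" in df.columns:
        errs = df["error"].fillna(0.0).to_numpy()
    else:
        errs = np.zeros(len(df))
    regions: List[Tuple[int, int]] = []
    start = None
    for i in range(len(rates) - 1):
        drop = rates[i] - rates[i + 1]
        if drop > tolerance + errs[i] + errs[i + 1]:
            if start is None:
                start = i
        else:
            if start is not None:
                regions.append((start, i))
                start = None
    if start is not None:
        regions.append((start, len(rates) - 1))
    return regions


@dataclass
class ResponseCurve:
    """Paired input/output rates with locking labels and error bounds."""

    rates_in: List[float] = field(default_factory=list)
    estimates: List[RateEstimate] = field(default_factory=list)
    labels: List[LockingLabel] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def append(
        self, rate_in: float, estimate: RateEstimate, label: LockingLabel
    ) -> None:
        if self.rates_in and rate_in <= self.rates_in[-1]:
            raise ValueError("rate_in must be strictly increasing")
        self.rates_in.append(float(rate_in))
        self.estimates.append(estimate)
        self.labels.append(label)

    def __len__(self) -> int:
        return len(self.rates_in)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rate_in": self.rates_in,
                "rate_out": [e.rate for e in self.estimates],
                "n_spikes": [e.n_spikes for e in self.estimates],
                "span": [e.span for e in self.estimates],
                "error": [e.error for e in self.estimates],
                "label": [str(l) for l in self.labels],
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: Union[str, Path, None] = None) -> str:
        payload = json.dumps(
            {"params": self.params, "points": self.to_frame().to_dict("records")},
            default=float,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_frame(cls, df: pd.DataFrame, params: Optional[dict] = None) -> "ResponseCurve":
        curve = cls(params=params or {})
        for _, row in df.iterrows():
            span = row.get("span")
            err = row.get("error")
            est = RateEstimate(
                float(row["rate_out"]),
                int(row.get("n_spikes", 0)),
                None if pd.isna(span) else float(span),
                None if pd.isna(err) else float(err),
            )
            curve.append(
                float(row["rate_in"]), est, LockingLabel.parse(str(row["label"]))
            )
        return curve

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ResponseCurve":
        return cls.from_frame(pd.read_csv(path))
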