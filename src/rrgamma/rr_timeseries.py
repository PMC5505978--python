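"""RR-interval tachograms and induced (time-derivative) series.

The observed variable is the sequence of R-peak occurrence times of an ECG.
Successive differences give the RR-interval tachogram x[n] — the instantaneous
heart period. "Induced" variables are obtained by repeatedly applying the
forward finite difference

    dx/dt[n] ≈ (x[n+1] − x[n]) / (t_{n+1} − t_n)

so that order 1 is the rate of change of the heart period, order 2 the heart
"jerk" by kinematic analogy, and so on up to order 10.

Conventions (fixed here, used everywhere downstream):

* the timestamp of interval x[n] is the occurrence time of the beat that
  *terminates* the interval — causal, computable in real time;
* each differencing step carries the *left* endpoint of the pair, so repeated
  differencing is well defined and all orders stay index-aligned from the
  start of the record;
* window truncation is anchored at the first beat of the record and the
  boundary is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import InsufficientData, InvalidBeatOrder, ZeroTimeStep

__all__ = [
    "BeatSequence",
    "RRSeries",
    "DerivativeStack",
    "beats_to_rr",
    "finite_difference",
    "derivative_stack",
    "truncate_to_duration",
]


@dataclass(frozen=True)
class BeatSequence:
    """Strictly increasing R-peak occurrence times, in seconds."""

    times: np.ndarray
    label: str = "unlabeled"  # "NSR" | "AF" | "unlabeled"
    record_id: str = ""

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or len(times) < 2:
            raise InsufficientData(
                f"need at least 2 beats, got {times.size} (record {self.record_id!r})"
            )
        if not np.all(np.isfinite(times)):
            raise InvalidBeatOrder(f"non-finite beat time (record {self.record_id!r})")
        if np.any(np.diff(times) <= 0):
            i = int(np.argmax(np.diff(times) <= 0))
            raise InvalidBeatOrder(
                f"beat times not strictly increasing at index {i} "
                f"(record {self.record_id!r})"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass(frozen=True)
class RRSeries:
    """A sampled series x[n] with time base t_n.

    ``order`` 0 is the tachogram itself (values are inter-beat intervals,
    seconds, all positive); order k is its k-th forward finite difference,
    with units s^(1−k).
    """

    values: np.ndarray
    timestamps: np.ndarray
    order: int = 0
    label: str = "unlabeled"
    record_id: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        ts = np.asarray(self.timestamps, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "timestamps", ts)
        if len(values) != len(ts):
            raise ValueError(
                f"values ({len(values)}) and timestamps ({len(ts)}) length mismatch"
            )
        if len(values) == 0:
            raise InsufficientData("empty series")
        if not (np.all(np.isfinite(values)) and np.all(np.isfinite(ts))):
            raise InvalidBeatOrder("non-finite value or timestamp")
        if np.any(np.diff(ts) <= 0):
            raise InvalidBeatOrder("timestamps not strictly increasing")
        if self.order < 0:
            raise ValueError("derivative order must be >= 0")
        if self.order == 0 and np.any(values <= 0):
            raise InvalidBeatOrder("order-0 tachogram has a non-positive interval")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DerivativeStack:
    """Orders 0..max_order of a tachogram; series[k] has order k."""

    series: tuple
    max_order: int = field(default=0)

    def __post_init__(self):
        series = tuple(self.series)
        object.__setattr__(self, "series", series)
        object.__setattr__(self, "max_order", len(series) - 1)
        for k, s in enumerate(series):
            if s.order != k:
                raise ValueError(f"stack slot {k} holds order {s.order}")
            if len(s) != len(series[0]) - k:
                raise ValueError(f"order-{k} length {len(s)} != {len(series[0]) - k}")

    def __getitem__(self, k: int) -> RRSeries:
        return self.series[k]

    def __len__(self) -> int:
        return len(self.series)


def beats_to_rr(beats: BeatSequence) -> RRSeries:
    """Tachogram from beat times: x[n] = t[n+1] − t[n], stamped at t[n+1]."""
    return RRSeries(
        values=np.diff(beats.times),
        timestamps=beats.times[1:],
        order=0,
        label=beats.label,
        record_id=beats.record_id,
    )


def finite_difference(s: RRSeries) -> RRSeries:
    """One forward-difference step; output keeps the left endpoint timestamps."""
    if len(s) < 2:
        raise InsufficientData(f"need >= 2 samples to difference, got {len(s)}")
    dt = np.diff(s.timestamps)
    if np.any(dt == 0):
        raise ZeroTimeStep("duplicate timestamps")
    return RRSeries(
        values=np.diff(s.values) / dt,
        timestamps=s.timestamps[:-1],
        order=s.order + 1,
        label=s.label,
        record_id=s.record_id,
    )


def derivative_stack(rr: RRSeries, max_order: int) -> DerivativeStack:
    """Repeated forward differencing of an order-0 tachogram.

    Requires ``len(rr) > max_order`` so the top order keeps at least one
    sample; the order-0 slot is the input unchanged.
    """
    if rr.order != 0:
        raise ValueError("derivative_stack expects an order-0 tachogram")
    if len(rr) <= max_order:
        raise InsufficientData(
            f"series of length {len(rr)} too short for order {max_order}"
        )
    series = [rr]
    for _ in range(max_order):
        series.append(finite_difference(series[-1]))
    return DerivativeStack(series=tuple(series))


def truncate_to_duration(beats: BeatSequence, duration_s: float) -> BeatSequence:
    """Keep beats within ``duration_s`` of the first beat (boundary inclusive)."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    mask = beats.times - beats.times[0] <= duration_s
    kept = beats.times[mask]
    if len(kept) < 2:
        raise InsufficientData(
            f"window of {duration_s} s retains {len(kept)} beat(s) "
            f"(record {beats.record_id!r})"
        )
    return replace(beats, times=kept)
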