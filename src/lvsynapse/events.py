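"""Presynaptic event trains and their discretization.

Training and validation inputs are Poisson random interval trains (RITs):
impulse sequences whose inter-event intervals are i.i.d. exponential. They
provide broadband excitation, which is what makes least-squares kernel
estimation well-posed across a wide range of input patterns. Events are
unitless impulses of amplitude 1; any physical scaling is absorbed by the
fitted Volterra coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EventTrain",
    "BinnedSignal",
    "generate_poisson_rit",
    "generate_poisson_rit_for_duration",
    "concatenate_hybrid",
    "bin_events",
]


@dataclass(frozen=True)
class EventTrain:
    """Ordered presynaptic (or release) event times.

    Parameters
    ----------
    times : ndarray
        Strictly increasing, non-negative event times in seconds.
    duration : float
        Total span of the train in seconds; every event time is <= duration.
        For generated trains this defaults to the time of the last event.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("event times must be a 1-D array")
        if times.size:
            if times[0] < 0:
                raise ValueError("event times must be non-negative")
            if np.any(np.diff(times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if times[-1] > self.duration + 1e-12:
                raise ValueError("event times must not exceed the duration")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def n_events(self) -> int:
        return int(self.times.size)

    def isi(self) -> np.ndarray:
        """Inter-event intervals (seconds)."""
        return np.diff(self.times)

    # -- plain-text round trips ------------------------------------------
    def to_text(self, path) -> None:
        """One event time (s) per line."""
        np.savetxt(path, self.times, fmt="%.17g",
                   header=f"duration_s={self.duration!r}")

    @classmethod
    def from_text(cls, path) -> "EventTrain":
        duration = None
        with open(path) as fh:
            first = fh.readline()
        if first.startswith("#") and "duration_s=" in first:
            duration = float(first.split("duration_s=")[1])
        times = np.loadtxt(path, ndmin=1)
        if duration is None:
            duration = float(times[-1]) if times.size else 0.0
        return cls(times=times, duration=duration)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTrain":
        df = pd.read_csv(path)
        times = df["time_s"].to_numpy(dtype=float)
        duration = float(times[-1]) if times.size else 0.0
        return cls(times=times, duration=duration)


@dataclass(frozen=True)
class BinnedSignal:
    """Uniformly sampled real-valued series.

    Bin ``k`` covers the half-open interval ``[t0 + k*dt, t0 + (k+1)*dt)``.
    """

    dt: float
    values: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if values.ndim != 1 or values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def times(self) -> np.ndarray:
        """Left edge of every bin (seconds)."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * self.values.size

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.times, "value": self.values}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BinnedSignal":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(dtype=float)
        dt = float(t[1] - t[0]) if t.size > 1 else 1.0
        return cls(dt=dt, values=df["value"].to_numpy(dtype=float),
                   t0=float(t[0]) if t.size else 0.0)


def generate_poisson_rit(mean_rate: float, n_events: int, seed: int,
                         pad: float = 0.0) -> EventTrain:
    """Generate a Poisson random interval train.

    Inter-event intervals are i.i.d. exponential with mean ``1/mean_rate``.
    The train's duration is the time of the last event plus ``pad``.
    Deterministic given ``seed`` (a fresh ``numpy.random.default_rng`` per
    call; no global state).
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be positive")
    if n_events < 1:
        raise ValueError("n_events must be at least 1")
    rng = np.random.default_rng(seed)
    isi = rng.exponential(1.0 / mean_rate, size=int(n_events))
    times = np.cumsum(isi)
    return EventTrain(times=times, duration=float(times[-1]) + pad)


def generate_poisson_rit_for_duration(mean_rate: float, duration: float,
                                      seed: int) -> EventTrain:
    """Poisson RIT truncated to a fixed duration (seconds).

    Draws exponential intervals until the span is exceeded and keeps the
    events inside ``[0, duration]``. May be empty at low rates.
    """
    if mean_rate <= 0:
        raise ValueError("mean_rate must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    # Draw in blocks until we have passed the requested span.
    block = max(16, int(np.ceil(mean_rate * duration * 1.5)))
    times = np.array([], dtype=float)
    last = 0.0
    while last <= duration:
        isi = rng.exponential(1.0 / mean_rate, size=block)
        new = last + np.cumsum(isi)
        times = np.concatenate([times, new])
        last = float(times[-1])
    times = times[times <= duration]
    return EventTrain(times=times, duration=float(duration))


def concatenate_hybrid(train_a: EventTrain, train_b: EventTrain) -> EventTrain:
    """Concatenate two trains; the second is offset by the first's duration.

    Used to build hybrid-rate training inputs (e.g. a 2 Hz segment followed
    by a 10 Hz segment).
    """
    offset = train_a.duration
    times = np.concatenate([train_a.times, train_b.times + offset])
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("concatenation produced non-increasing times; "
                         "first train's duration must exceed its last event")
    return EventTrain(times=times, duration=train_a.duration + train_b.duration)


def bin_events(train: EventTrain, dt: float,
               n_bins: int | None = None) -> BinnedSignal:
    """Discretize a train as unit impulses on a uniform grid.

    Each event contributes amplitude 1 to bin ``floor(t/dt)`` (0-based,
    half-open bins); coincident events in one bin sum. The sum of the binned
    values therefore equals the event count for any ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_bins is None:
        n_bins = int(np.floor(train.duration / dt)) + 1
    values = np.zeros(int(n_bins))
    if train.n_events:
        idx = bin_index(train.times, dt)
        idx = np.clip(idx, 0, n_bins - 1)
        np.add.at(values, idx, 1.0)
    return BinnedSignal(dt=dt, values=values)


def bin_index(times, dt: float) -> np.ndarray:
    """0-based bin of each time under the floor(t/dt) rule.

    A relative guard of 1e-9 bins absorbs float round-off so that times
    lying exactly on a bin edge land in the bin they open.
    """
    return np.floor(np.asarray(times) / dt + 1e-9).astype(np.int64)
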