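"""Spike-train container used throughout the package.

A :class:`SpikeTrain` holds the ordered spike times (in ms) of a single unit
together with the observation window ``[t_start, t_stop)``.  Spike times are
plain float64 arrays; all generators in this package emit times lying on the
simulation grid (default 0.1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain"]


@dataclass
class SpikeTrain:
    """Ordered spike times of one unit.

    Parameters
    ----------
    times
        Strictly increasing spike times in ms.
    t_start, t_stop
        Observation window in ms; every spike satisfies
        ``t_start <= t < t_stop``.
    """

    times: np.ndarray
    t_start: float = 0.0
    t_stop: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be a 1-d array")
        if self.t_stop is None:
            self.t_stop = float(self.times[-1]) + 1.0 if self.times.size else self.t_start + 1.0
        self.t_start = float(self.t_start)
        self.t_stop = float(self.t_stop)
        if self.t_stop <= self.t_start:
            raise ValueError("t_stop must be greater than t_start")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < self.t_start or self.times[-1] >= self.t_stop:
                raise ValueError("spike times must lie in [t_start, t_stop)")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        """Window length in ms."""
        return self.t_stop - self.t_start

    def rate(self) -> float:
        """Mean firing rate in s^-1 over the observation window."""
        return self.n_spikes / (self.duration / 1000.0)

    def isi(self) -> np.ndarray:
        """Inter-spike intervals in ms."""
        return np.diff(self.times)

    def time_slice(self, t0: float, t1: float) -> "SpikeTrain":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(self.times[m], t_start=t0, t_stop=t1)
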