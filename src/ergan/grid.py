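"""The fixed sampling grid of light-adapted ERG recordings.

Recordings are 235 samples covering -20 ms to +100 ms around the flash
(delivered at t = 0), i.e. a sampling step of about 0.513 ms (~1950 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time axis shared by every waveform in a dataset."""

    n_samples: int = 235
    t_start: float = -20.0  # ms
    t_end: float = 100.0  # ms

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")

    @property
    def dt(self) -> float:
        """Sampling period in ms."""
        return (self.t_end - self.t_start) / (self.n_samples - 1)

    @property
    def dt_seconds(self) -> float:
        return self.dt * 1e-3

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        return 1.0 / self.dt_seconds

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms; t = 0 is the flash."""
        return np.linspace(self.t_start, self.t_end, self.n_samples)

    def to_dict(self) -> dict:
        return {"n_samples": self.n_samples, "t_start": self.t_start, "t_end": self.t_end}

    @classmethod
    def from_dict(cls, d: dict) -> "TimeGrid":
        return cls(int(d["n_samples"]), float(d["t_start"]), float(d["t_end"]))


DEFAULT_GRID = TimeGrid()
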