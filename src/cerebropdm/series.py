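"""Core time-series containers.

Everything downstream operates on uniformly sampled series (1 Hz by
convention for 6-min resting recordings). Raw beat-to-beat / breath-to-breath
measurements are represented as :class:`EventSeries` until resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["UniformSeries", "EventSeries", "SubjectRecording"]

GROUPS = ("placebo", "sympathetic")
CONDITIONS = ("pre", "post")


@dataclass(frozen=True)
class UniformSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    values : array-like
        Signal samples; must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    label : str
        Short channel name, e.g. ``"bp"``.
    units : str
        Physical units, e.g. ``"mmHg"``.
    """

    values: np.ndarray
    fs: float = 1.0
    label: str = ""
    units: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite samples in series {self.label!r}")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) / self.fs

    def with_values(self, values: np.ndarray) -> "UniformSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class EventSeries:
    """Irregularly sampled events, e.g. beat-to-beat mean pressures."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D and equally long")
        if not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("non-finite event data")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.times.size


@dataclass
class SubjectRecording:
    """Aligned BP / end-tidal CO2 / cerebral flow-velocity series for one
    subject under one condition (pre or post treatment)."""

    subject_id: str
    group: str
    condition: str
    bp: UniformSeries
    co2: UniformSeries
    flow: UniformSeries
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        n = {len(self.bp), len(self.co2), len(self.flow)}
        if len(n) != 1:
            raise ValueError("bp, co2 and flow must share length")
        fs = {self.bp.fs, self.co2.fs, self.flow.fs}
        if len(fs) != 1:
            raise ValueError("bp, co2 and flow must share sampling rate")

    @property
    def n_samples(self) -> int:
        return len(self.bp)

    @property
    def fs(self) -> float:
        return self.bp.fs

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.group, self.condition)
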