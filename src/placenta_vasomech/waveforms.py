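"""Periodic waveform containers and Doppler-style indices.

A waveform holds one period of samples with the periodic convention that
the sample at t = T would repeat the sample at t = 0 (the stored time grid
excludes the period end point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PeriodicWaveform:
    """One period of a velocity, flow or normalised pressure trace."""

    t: np.ndarray  # s, in [0, period)
    v: np.ndarray
    period: float  # s

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.shape != self.v.shape or self.t.ndim != 1:
            raise ValueError("t and v must be matching 1-D arrays")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        if self.t[0] < 0 or self.t[-1] >= self.period:
            raise ValueError("times must lie in [0, period)")

    def sample(self, times: np.ndarray) -> np.ndarray:
        """Periodic linear interpolation at arbitrary times."""
        tt = np.mod(np.asarray(times, dtype=float), self.period)
        # append the wrap-around point for interpolation across the seam
        tp = np.concatenate([self.t, [self.period + self.t[0]]])
        vp = np.concatenate([self.v, [self.v[0]]])
        return np.interp(tt, tp, vp)

    def mean(self) -> float:
        """Cycle average (trapezoid over the closed period)."""
        tp = np.concatenate([self.t, [self.period + self.t[0]]])
        vp = np.concatenate([self.v, [self.v[0]]])
        return float(np.trapezoid(vp, tp) / self.period)


@dataclass
class PressureWaveform:
    """One period of a luminal pressure trace (mmHg)."""

    t: np.ndarray  # s
    p: np.ndarray  # mmHg
    period: float  # s

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.t.shape != self.p.shape or self.t.ndim != 1:
            raise ValueError("t and p must be matching 1-D arrays")
        if self.period <= 0:
            raise ValueError("period must be positive")

    def as_periodic(self) -> PeriodicWaveform:
        return PeriodicWaveform(t=self.t, v=self.p, period=self.period)


def resistance_index(v: np.ndarray) -> float:
    """RI = (systolic - diastolic) / systolic of one period of samples."""
    v = np.asarray(v, dtype=float)
    S, D = float(v.max()), float(v.min())
    if S <= 0:
        raise ValueError("no forward component: peak value is non-positive")
    return (S - D) / S


def pulsatility_index(v: np.ndarray, mean: float | None = None) -> float:
    """PI = (systolic - diastolic) / cycle mean."""
    v = np.asarray(v, dtype=float)
    m = float(np.mean(v)) if mean is None else float(mean)
    if m == 0:
        raise ValueError("cycle mean is zero; PI undefined")
    return (float(v.max()) - float(v.min())) / m
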