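"""Pressure-diameter mechanics: cycle segmentation, pressure-stretch curves,
distensibility.

Inflation-deflation records (time, luminal pressure, outer diameter) are
reduced to an averaged circumferential-stretch curve lambda(P) on a fixed
pressure grid, from which local distensibility d(lambda)/dP (mmHg^-1) and
maximum stretch are computed.  The protocol mirrors quasi-static arterial
inflation testing: repeated 0 -> 40 -> 0 mmHg cycles, the first cycles used
for preconditioning, the last three for analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: default analysis pressure grid, mmHg
DEFAULT_P_GRID = np.arange(0.0, 41.0, 1.0)

#: pressures at which distensibility is reported by default, mmHg
DEFAULT_EVAL_PRESSURES = (10.0, 15.0, 20.0, 25.0, 30.0, 35.0)

#: half-width of the least-squares window for distensibility, mmHg
DEFAULT_WINDOW = 2.5

# cycle-detection thresholds, mmHg
CYCLE_START_THRESHOLD = 2.0
CYCLE_PEAK_THRESHOLD = 38.0


@dataclass
class PressureDiameterRecord:
    """Raw multi-cycle inflation time series for one vessel.

    Arrays ``t`` (s), ``P`` (mmHg) and ``D_outer`` (mm) must share a length;
    time must be strictly increasing.  Small negative pressures (sensor
    offset) are tolerated down to -5 mmHg.
    """

    t: np.ndarray
    P: np.ndarray
    D_outer: np.ndarray
    vessel_id: str = "vessel"
    placenta_id: str = "placenta"
    group: str = "normal"
    axial_stretch: float = 1.1
    initial_length: float = 20.0  # mm

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.D_outer = np.asarray(self.D_outer, dtype=float)
        if not (self.t.shape == self.P.shape == self.D_outer.shape):
            raise ValueError("t, P and D_outer must have matching shapes")
        if self.t.size < 2:
            raise ValueError("record needs at least two samples")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.D_outer <= 0):
            raise ValueError("outer diameter must be positive")
        if np.any(self.P < -5.0):
            raise ValueError("pressure below -5 mmHg: not a sensor offset")


@dataclass
class PressureStretchCurve:
    """Averaged circumferential stretch lambda on an ascending pressure grid.

    ``lam`` is the outer-diameter stretch D(P)/D0 with ``D0`` the reference
    (zero-pressure) outer diameter in mm.
    """

    P_grid: np.ndarray
    lam: np.ndarray
    n_cycles_averaged: int = 0
    D0: float = float("nan")

    def __post_init__(self) -> None:
        self.P_grid = np.asarray(self.P_grid, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if self.P_grid.shape != self.lam.shape:
            raise ValueError("P_grid and lam must have matching shapes")
        if not np.all(np.diff(self.P_grid) > 0):
            raise ValueError("P_grid must be strictly ascending")
        if np.any(self.lam <= 0):
            raise ValueError("stretch must be positive")

    def monotone_violation(self, tol: float = 1e-3) -> float:
        """Largest decrease of lambda along the grid (0 for monotone curves)."""
        d = np.diff(self.lam)
        return float(max(0.0, -d.min())) if d.size else 0.0

    def is_monotone(self, tol: float = 1e-3) -> bool:
        return self.monotone_violation() <= tol


@dataclass
class DistensibilityResult:
    """Local distensibility d(lambda)/dP at one evaluation pressure."""

    pressure: float  # mmHg
    distensibility: float  # mmHg^-1
    window_halfwidth: float  # mmHg


@dataclass
class CycleSegmentation:
    """Index ranges of pressurization cycles found in a record.

    ``complete`` holds (start, end) slices of full 0->40->0 excursions
    (peak >= 38 mmHg); ``flagged`` holds excursions that never reached the
    peak threshold or never closed, with a reason string.
    """

    complete: list = field(default_factory=list)  # [(start, end)]
    flagged: list = field(default_factory=list)  # [(start, end, reason)]

    @property
    def n_complete(self) -> int:
        return len(self.complete)


def segment_cycles(record: PressureDiameterRecord) -> CycleSegmentation:
    """Split a record into pressurization/depressurization cycles.

    A cycle starts when pressure rises above 2 mmHg, must peak at or above
    38 mmHg to count as complete, and ends when pressure falls back below
    2 mmHg.  Excursions that never reach the peak threshold, or never close,
    are flagged rather than silently dropped.

    Raises ``ValueError`` if the record contains no pressurization ramp at
    all (pressure never crosses the start threshold).
    """
    P = record.P
    seg = CycleSegmentation()
    in_cycle = False
    start = 0
    for i in range(P.size):
        if not in_cycle:
            if P[i] > CYCLE_START_THRESHOLD:
                in_cycle = True
                start = i
        else:
            if P[i] < CYCLE_START_THRESHOLD:
                peak = float(P[start:i].max())
                if peak >= CYCLE_PEAK_THRESHOLD:
                    seg.complete.append((start, i))
                else:
                    seg.flagged.append(
                        (start, i, f"peak {peak:.1f} mmHg below "
                                   f"{CYCLE_PEAK_THRESHOLD:.0f} mmHg")
                    )
                in_cycle = False
    if in_cycle:
        seg.flagged.append(
            (start, P.size, "excursion never returned below "
                            f"{CYCLE_START_THRESHOLD:.0f} mmHg")
        )
    if not seg.complete and not seg.flagged:
        raise ValueError("record contains no pressurization ramp "
                         f"(pressure never exceeds {CYCLE_START_THRESHOLD} mmHg)")
    return seg


def _loading_limb(record: PressureDiameterRecord, start: int, end: int,
                  floor: int) -> slice:
    """Indices of the loading (pressurization) limb of one cycle.

    The detected cycle start is where P crosses the 2 mmHg threshold; the
    limb is extended backwards (not beyond ``floor``) while pressure keeps
    decreasing so the near-zero-pressure dwell is included, which anchors
    the reference diameter.
    """
    P = record.P
    peak = start + int(np.argmax(P[start:end]))
    s = start
    while s > floor and P[s - 1] < P[s]:
        s -= 1
    return slice(s, peak + 1)


def analysis_curve(
    record: PressureDiameterRecord,
    cycles: CycleSegmentation | None = None,
    n_analysis_cycles: int = 3,
    P_grid: np.ndarray | None = None,
) -> PressureStretchCurve:
    """Average the last ``n_analysis_cycles`` loading limbs onto a pressure grid.

    Each limb's diameter is linearly interpolated onto the grid; the
    interpolants are averaged pointwise and normalised by the averaged
    zero-pressure diameter D0, so lambda(0) = 1 by construction.
    """
    if cycles is None:
        cycles = segment_cycles(record)
    if P_grid is None:
        P_grid = DEFAULT_P_GRID
    if cycles.n_complete < n_analysis_cycles:
        raise ValueError(
            f"need {n_analysis_cycles} complete cycles for analysis, "
            f"found {cycles.n_complete}"
        )
    use = cycles.complete[-n_analysis_cycles:]
    all_ends = sorted([e for _, e in cycles.complete] +
                      [e for _, e, _ in cycles.flagged])
    D_interp = np.zeros((len(use), P_grid.size))
    for j, (s, e) in enumerate(use):
        floor = max([x for x in all_ends if x <= s], default=0)
        limb = _loading_limb(record, s, e, floor)
        p = record.P[limb]
        d = record.D_outer[limb]
        order = np.argsort(p, kind="stable")
        D_interp[j] = np.interp(P_grid, p[order], d[order])
    D_bar = D_interp.mean(axis=0)
    D0 = float(np.interp(0.0, P_grid, D_bar))
    return PressureStretchCurve(
        P_grid=P_grid, lam=D_bar / D0, n_cycles_averaged=len(use), D0=D0
    )


def distensibility_at(
    curve: PressureStretchCurve, pressure: float,
    window: float = DEFAULT_WINDOW,
) -> DistensibilityResult:
    """Distensibility d(lambda)/dP at ``pressure`` (mmHg^-1).

    Computed as the ordinary-least-squares slope of (P, lambda) over grid
    points within ``pressure +/- window``; at least 3 points are required.
    """
    lo, hi = pressure - window, pressure + window
    if lo < curve.P_grid[0] - 1e-9 or hi > curve.P_grid[-1] + 1e-9:
        raise ValueError(
            f"window [{lo}, {hi}] mmHg extends beyond the pressure grid "
            f"[{curve.P_grid[0]}, {curve.P_grid[-1]}]"
        )
    mask = (curve.P_grid >= lo - 1e-9) & (curve.P_grid <= hi + 1e-9)
    if mask.sum() < 3:
        raise ValueError(
            f"window +/-{window} mmHg around {pressure} mmHg contains only "
            f"{int(mask.sum())} grid points (need >= 3)"
        )
    slope = np.polyfit(curve.P_grid[mask], curve.lam[mask], 1)[0]
    return DistensibilityResult(
        pressure=float(pressure), distensibility=float(slope),
        window_halfwidth=float(window),
    )


def max_stretch(curve: PressureStretchCurve) -> float:
    """Stretch at the top of the pressure grid (the 40 mmHg end point)."""
    return float(curve.lam[-1])


def group_mean_curves(
    curves: list[PressureStretchCurve], groups: list[str]
) -> pd.DataFrame:
    """Pointwise mean +/- standard error of lambda per group.

    Returns a tidy frame with columns group, pressure, mean_lambda,
    se_lambda, n.  SE is NaN for groups with a single curve.  All curves
    must share the same pressure grid.
    """
    if len(curves) != len(groups):
        raise ValueError("one group label per curve required")
    if not curves:
        raise ValueError("no curves given")
    grid = curves[0].P_grid
    for c in curves[1:]:
        if not np.array_equal(c.P_grid, grid):
            raise ValueError("all curves must share the same pressure grid")
    rows = []
    for g in dict.fromkeys(groups):  # preserves first-seen order
        lam = np.array([c.lam for c, gg in zip(curves, groups) if gg == g])
        if lam.shape[0] == 0:
            warnings.warn(f"group {g!r} has no curves; omitted")
            continue
        n = lam.shape[0]
        mean = lam.mean(axis=0)
        se = lam.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else \
            np.full(grid.size, np.nan)
        rows.append(pd.DataFrame({
            "group": g, "pressure": grid, "mean_lambda": mean,
            "se_lambda": se, "n": n,
        }))
    return pd.concat(rows, ignore_index=True)
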