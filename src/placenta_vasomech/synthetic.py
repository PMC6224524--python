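"""Synthetic study inputs with controlled ground truth.

Emulates the three kinds of raw data the downstream analyses consume:

* multi-cycle pressure-diameter inflation records, generated by the Fung
  thick-wall forward model (so constitutive fitting can be validated by
  round-trip recovery), with additive Gaussian diameter noise and a
  preconditioning drift that decays over the first five cycles;
* umbilical Doppler-like periodic waveforms with a prescribed resistance
  index (raised-cosine systolic pulse, exponential diastolic decay);
* rooted binary vessel trees with generation-dependent radii and
  prescribed branching half-angle.

Every generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from . import fung
from .morphometry import VesselTree
from .pd_mechanics import PressureDiameterRecord
from .waveforms import PeriodicWaveform

#: Group constitutive parameters used as generating truth: (c mmHg, b1).
GROUP_PARAMS: dict[str, tuple[float, float]] = {
    "normal": (125.82, 20.63),
    "iugr": (99.91, 26.83),
    "severe_iugr": (345.65, 8.56),
}

#: Group geometry defaults (opening angle deg); wall ratio is shared.
GROUP_OPENING_ANGLE: dict[str, float] = {
    "normal": 91.48,
    "iugr": 106.45,
    "severe_iugr": 96.88,
}
GROUP_THICKNESS_RATIO: dict[str, float] = {
    "normal": 0.586,
    "iugr": 0.616,
    "severe_iugr": 0.654,
}


@dataclass
class SpecimenConfig:
    """Ground truth and protocol settings for one synthetic vessel."""

    group: str = "normal"
    c_true: float = 125.82  # mmHg
    b1_true: float = 20.63
    unloaded_outer_diameter: float = 2.0  # mm (chorionic-artery scale)
    thickness_to_diameter: float = 0.586  # wall thickness / luminal diameter
    opening_angle: float = 91.48  # degrees
    axial_stretch: float = 1.1
    noise_sd_diameter: float = 0.01  # mm
    n_cycles: int = 8
    seed: int = 0
    # preconditioning drift amplitude at cycle 1 (mm); halves per cycle,
    # exactly zero from cycle 6 on
    precondition_drift: float = 0.02
    # protocol timing: pressurization / release durations and sample interval
    ramp_up_s: float = 40.0
    ramp_down_s: float = 10.0
    dt_s: float = 0.2
    peak_pressure: float = 40.0  # mmHg

    def __post_init__(self) -> None:
        if self.group not in GROUP_PARAMS:
            raise ValueError(f"unknown group {self.group!r}")
        if not 0.0 < self.thickness_to_diameter < 1.0:
            raise ValueError("thickness_to_diameter must lie in (0, 1)")
        if not 0.0 <= self.opening_angle < 350.0:
            raise ValueError("opening_angle must lie in [0, 350) degrees")
        if self.axial_stretch < 1.0:
            raise ValueError("axial_stretch must be >= 1")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.c_true <= 0 or self.b1_true <= 0:
            raise ValueError("c_true and b1_true must be positive")
        if self.noise_sd_diameter < 0:
            raise ValueError("noise_sd_diameter must be nonnegative")

    @classmethod
    def for_group(cls, group: str, **overrides) -> "SpecimenConfig":
        """Config preset with a group's constitutive and geometry means."""
        c, b1 = GROUP_PARAMS[group]
        kw = dict(
            group=group, c_true=c, b1_true=b1,
            opening_angle=GROUP_OPENING_ANGLE[group],
            thickness_to_diameter=GROUP_THICKNESS_RATIO[group],
        )
        kw.update(overrides)
        return cls(**kw)

    def geometry(self) -> fung.StressFreeGeometry:
        return fung.StressFreeGeometry.from_ring(
            self.unloaded_outer_diameter, self.thickness_to_diameter,
            self.opening_angle)

    def params(self) -> fung.FungParameters:
        return fung.FungParameters(c=self.c_true, b1=self.b1_true)


@dataclass
class WaveformConfig:
    """Doppler-like waveform: prescribed peak and resistance index."""

    period: float = 0.43  # s (fetal heart rate ~140 bpm)
    systolic_fraction: float = 0.35
    target_RI: float = 0.6
    peak_value: float = 30.0  # velocity (cm/s) or any linear unit
    n_samples_per_cycle: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be positive")
        if not 0.0 < self.systolic_fraction < 1.0:
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if self.n_samples_per_cycle < 8:
            raise ValueError("need at least 8 samples per cycle")
        if self.peak_value <= 0:
            raise ValueError("peak_value must be positive")
        if self.target_RI < 0:
            raise ValueError("target_RI must be nonnegative")


@dataclass
class TreeConfig:
    """Binary branching tree with generation-dependent radii."""

    n_generations: int = 4
    root_radius: float = 1.5  # mm
    radius_ratio: float = 0.79  # daughter/mother
    branch_half_angle: float = 40.0  # degrees
    segment_length: float = 15.0  # mm
    jitter_sd: float = 0.0  # relative jitter on radius, length, angle
    seed: int = 0
    points_per_segment: int = 5

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if not 0.0 < self.radius_ratio < 1.0:
            raise ValueError("radius_ratio must lie in (0, 1)")
        if self.root_radius <= 0 or self.segment_length <= 0:
            raise ValueError("root_radius and segment_length must be positive")
        if self.points_per_segment < 2:
            raise ValueError("need at least 2 points per segment")


def gen_pd_record(cfg: SpecimenConfig) -> PressureDiameterRecord:
    """Simulate one multi-cycle inflation experiment.

    Pressure ramps linearly 0 -> peak -> 0 per cycle; the outer diameter
    follows the Fung forward model at each pressure (monotone PCHIP
    interpolation of the model curve), plus a preconditioning offset that
    halves each cycle and vanishes after cycle 5, plus additive Gaussian
    noise on diameter.
    """
    rng = np.random.default_rng(cfg.seed)
    geom = cfg.geometry()
    grid = np.arange(0.0, cfg.peak_pressure + 0.5, 1.0)
    curve = fung.forward_curve(geom, cfg.params(), cfg.axial_stretch,
                               P_grid=grid)
    lam_of_P = PchipInterpolator(curve.P_grid, curve.lam)
    D0 = curve.D0

    n_up = int(round(cfg.ramp_up_s / cfg.dt_s))
    n_down = int(round(cfg.ramp_down_s / cfg.dt_s))
    P_up = cfg.peak_pressure * np.arange(n_up) / n_up
    P_down = cfg.peak_pressure * (1.0 - np.arange(n_down) / n_down)
    P_cycle = np.concatenate([P_up, P_down])

    P = np.tile(P_cycle, cfg.n_cycles)
    t = cfg.dt_s * np.arange(P.size)
    D = D0 * lam_of_P(P)
    for cyc in range(cfg.n_cycles):
        offset = (-cfg.precondition_drift * 0.5 ** cyc) if cyc < 5 else 0.0
        D[cyc * P_cycle.size:(cyc + 1) * P_cycle.size] += offset
    if cfg.noise_sd_diameter > 0:
        D = D + rng.normal(0.0, cfg.noise_sd_diameter, size=D.size)
    return PressureDiameterRecord(
        t=t, P=P, D_outer=D,
        vessel_id=f"{cfg.group}-s{cfg.seed}",
        placenta_id=f"{cfg.group}-placenta",
        group=cfg.group, axial_stretch=cfg.axial_stretch,
    )


def gen_doppler_waveform(cfg: WaveformConfig,
                         allow_reversal: bool = False) -> PeriodicWaveform:
    """One period of a Doppler-like pulse with RI exactly ``target_RI``.

    Shape: raised-cosine systolic upstroke/downstroke over
    ``systolic_fraction`` of the period, then an exponential diastolic
    decay pinned to the prescribed minimum.  The samples are affinely
    rescaled so min and max match the prescription exactly.  A target RI
    above 1 (negative, reversed-flow trough) requires ``allow_reversal``.
    """
    if cfg.target_RI > 1.0 and not allow_reversal:
        raise ValueError(
            "target_RI > 1 implies a reversed-flow trough; pass "
            "allow_reversal=True to request it explicitly"
        )
    T, n = cfg.period, cfg.n_samples_per_cycle
    t = T * np.arange(n) / n
    if cfg.target_RI == 0.0:
        return PeriodicWaveform(t=t, v=np.full(n, cfg.peak_value), period=T)

    ts = cfg.systolic_fraction * T
    t_pk = 0.4 * ts
    shoulder = 0.25
    s = np.empty(n)
    rise = t <= t_pk
    fall = (t > t_pk) & (t <= ts)
    dias = t > ts
    s[rise] = 0.5 * (1.0 - np.cos(np.pi * t[rise] / t_pk))
    s[fall] = shoulder + (1.0 - shoulder) * 0.5 * (
        1.0 + np.cos(np.pi * (t[fall] - t_pk) / (ts - t_pk)))
    tau = (T - ts) / 3.0
    eps = np.exp(-(T - ts) / tau)
    s[dias] = shoulder * (np.exp(-(t[dias] - ts) / tau) - eps) / (1.0 - eps)

    vmin = cfg.peak_value * (1.0 - cfg.target_RI)
    s = (s - s.min()) / (s.max() - s.min())
    v = vmin + (cfg.peak_value - vmin) * s
    return PeriodicWaveform(t=t, v=v, period=T)


def _perpendicular(d: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(d, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    return u / np.linalg.norm(u)


def _rotate(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of v about a unit axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    return (v * c + np.cross(axis, v) * s
            + axis * np.dot(axis, v) * (1.0 - c))


def gen_vessel_tree(cfg: TreeConfig) -> VesselTree:
    """Grow a rooted binary tree of straight segments.

    Daughter radius = mother radius * radius_ratio * (1 + jitter); daughter
    directions deviate from the mother axis by +/- branch_half_angle
    (jittered multiplicatively), in a branching plane of random azimuth
    about the mother axis.
    """
    rng = np.random.default_rng(cfg.seed)
    nodes: list[dict] = []
    edges: list[dict] = []

    def jit() -> float:
        return 1.0 + rng.normal(0.0, cfg.jitter_sd) if cfg.jitter_sd > 0 else 1.0

    def add_node(pos: np.ndarray, radius: float, parent: int | None) -> int:
        nid = len(nodes)
        nodes.append({"id": nid, "x": pos[0], "y": pos[1], "z": pos[2],
                      "radius": radius})
        if parent is not None:
            edges.append({"parent": parent, "child": nid})
        return nid

    def grow(start_node: int, pos: np.ndarray, direction: np.ndarray,
             radius: float, gen: int) -> None:
        length = cfg.segment_length * jit()
        npts = cfg.points_per_segment
        node = start_node
        for i in range(1, npts + 1):
            p = pos + direction * (length * i / npts)
            node = add_node(p, radius, node)
        if gen >= cfg.n_generations:
            return
        end = pos + direction * length
        azim = rng.uniform(0.0, 2.0 * np.pi)
        plane_axis = _rotate(_perpendicular(direction), direction, azim)
        for sign in (+1.0, -1.0):
            ang = np.radians(cfg.branch_half_angle) * jit() * sign
            d = _rotate(direction, plane_axis, ang)
            d = d / np.linalg.norm(d)
            r = max(radius * cfg.radius_ratio * jit(), 1e-6)
            grow(node, end, d, r, gen + 1)

    root_dir = np.array([0.0, 0.0, 1.0])
    root = add_node(np.zeros(3), cfg.root_radius, None)
    grow(root, np.zeros(3), root_dir, cfg.root_radius, 1)
    return VesselTree(nodes=pd.DataFrame(nodes), edges=pd.DataFrame(edges),
                      root_id=root)
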