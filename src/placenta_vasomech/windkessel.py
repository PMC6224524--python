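"""Lumped-parameter (two-element Windkessel) umbilical-placental circulation.

The circulation is a series chain of RC compartments: umbilical artery,
10 generations of placental arteries, a lumped microvilli compartment,
10 generations of placental veins and the umbilical vein (23 in all).
Resistor ``R_i`` connects node i-1 to node i; capacitor ``C_i`` sits at
node i.  The inlet node (i = 0) follows the prescribed pressure waveform
``p_in(t)``; the node after the last resistance is held at the constant
venous pressure (5.3 mmHg by default), so the last compartment's capacitor
is inert and the chain of all 23 resistances carries the mean flow
(mean p_in - P_v) / sum(R).

Governing equations (i = 1 .. N-1):

    C_i dP_i/dt = Q_Ri - Q_R,i+1,    Q_Ri = (P_{i-1} - P_i) / R_i

a linear ODE system integrated with an implicit trapezoidal scheme (stiff
safe), cycling the periodic inlet until every node's cycle-mean pressure
is stationary.

Units: pressure mmHg, flow ml/s, time s, R mmHg*s/ml, C ml/mmHg; vessel
geometry in mm, viscosity in mPa*s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.linalg import lu_factor, lu_solve

from .waveforms import PeriodicWaveform, PressureWaveform

MMHG_PER_PA = 1.0 / 133.322
ML_PER_MM3 = 1e-3


@dataclass
class Compartment:
    """One RC element of the chain."""

    label: str
    generation: int
    kind: str  # umbilical_artery | placental_artery | microvilli | placental_vein | umbilical_vein
    R: float  # mmHg*s/ml
    C: float  # ml/mmHg
    n_parallel: int = 1
    radius: float = float("nan")  # mm
    length: float = float("nan")  # mm

    def __post_init__(self) -> None:
        if self.R <= 0:
            raise ValueError(f"compartment {self.label!r}: R must be positive")
        if self.C < 0:
            raise ValueError(f"compartment {self.label!r}: C must be >= 0")
        if self.n_parallel < 1:
            raise ValueError(f"compartment {self.label!r}: n_parallel >= 1")


@dataclass
class WindkesselNetwork:
    compartments: list
    venous_pressure: float = 5.3  # mmHg

    def __post_init__(self) -> None:
        if len(self.compartments) < 2:
            raise ValueError("network needs at least 2 compartments")

    @property
    def R(self) -> np.ndarray:
        return np.array([c.R for c in self.compartments])

    @property
    def C(self) -> np.ndarray:
        return np.array([c.C for c in self.compartments])

    @property
    def total_resistance(self) -> float:
        return float(self.R.sum())

    def scaled(self, k_R: float = 1.0, k_C: float = 1.0) -> "WindkesselNetwork":
        """Network with every R multiplied by k_R and every C by k_C."""
        if k_R <= 0 or k_C <= 0:
            raise ValueError("multipliers must be positive")
        comps = [replace(c, R=c.R * k_R, C=c.C * k_C)
                 for c in self.compartments]
        return WindkesselNetwork(compartments=comps,
                                 venous_pressure=self.venous_pressure)


@dataclass
class NetworkConfig:
    """Geometric rules for the default 23-compartment network.

    Per-generation placental radii shrink by ``radius_ratio`` while vessel
    counts double; veins mirror the arteries at ``vein_radius_scale`` times
    the radius.  Poiseuille resistance R = 8*mu*L/(pi r^4 n) and volume
    compliance C = n*pi*r^2*L*beta with an effective area distensibility
    ``beta``.  The microvilli are one lumped compartment whose resistance
    is ``microvilli_resistance_fraction`` times the summed resistance of
    all other compartments (>= 50% of the total for the default 1.0).
    """

    n_generations: int = 10
    umbilical_artery_radius: float = 2.0  # mm
    umbilical_artery_length: float = 500.0  # mm (cord length)
    first_artery_radius: float = 1.5  # mm
    radius_ratio: float = 0.79
    segment_length: float = 15.0  # mm
    vein_radius_scale: float = 1.3
    viscosity: float = 3.5  # mPa*s (blood)
    beta: float = 1e-4  # area distensibility, mmHg^-1
    microvilli_resistance_fraction: float = 1.0
    microvilli_compliance: float = 1e-4  # ml/mmHg
    venous_pressure: float = 5.3  # mmHg


def _poiseuille_R(radius: float, length: float, n: int,
                  viscosity_mPas: float) -> float:
    mu = viscosity_mPas * 1e-3 * MMHG_PER_PA  # mmHg*s
    r_mm3 = 8.0 * mu * length / (math.pi * radius ** 4 * n)
    return r_mm3 / ML_PER_MM3  # mmHg*s/ml


def _volume_C(radius: float, length: float, n: int, beta: float) -> float:
    return n * math.pi * radius ** 2 * length * beta * ML_PER_MM3  # ml/mmHg


def build_default_network(config: NetworkConfig | None = None,
                          R: list | None = None,
                          C: list | None = None) -> WindkesselNetwork:
    """Assemble the 23-compartment chain.

    Explicit ``R`` and ``C`` lists (length 23) override the geometric
    rules and are echoed verbatim.
    """
    cfg = config or NetworkConfig()
    ng = cfg.n_generations
    plan: list[tuple[str, int, str, float, float, int]] = []
    plan.append(("umbilical_artery", 0, "umbilical_artery",
                 cfg.umbilical_artery_radius, cfg.umbilical_artery_length, 1))
    for g in range(1, ng + 1):
        r = cfg.first_artery_radius * cfg.radius_ratio ** (g - 1)
        plan.append((f"placental_artery_g{g}", g, "placental_artery",
                     r, cfg.segment_length, 2 ** (g - 1)))
    plan.append(("microvilli", ng + 1, "microvilli",
                 float("nan"), float("nan"), 1))
    for g in range(ng, 0, -1):
        r = cfg.vein_radius_scale * cfg.first_artery_radius \
            * cfg.radius_ratio ** (g - 1)
        plan.append((f"placental_vein_g{g}", g, "placental_vein",
                     r, cfg.segment_length, 2 ** (g - 1)))
    plan.append(("umbilical_vein", 0, "umbilical_vein",
                 cfg.vein_radius_scale * cfg.umbilical_artery_radius,
                 cfg.umbilical_artery_length, 1))

    if R is not None or C is not None:
        if R is None or C is None or len(R) != len(plan) or len(C) != len(plan):
            raise ValueError(
                f"explicit R and C must both be given with length {len(plan)}"
            )
        comps = [Compartment(label=lab, generation=g, kind=kind,
                             R=float(rr), C=float(cc), n_parallel=n,
                             radius=rad, length=length)
                 for (lab, g, kind, rad, length, n), rr, cc
                 in zip(plan, R, C)]
        return WindkesselNetwork(comps, venous_pressure=cfg.venous_pressure)

    comps: list[Compartment] = []
    vessel_R_sum = 0.0
    for lab, g, kind, rad, length, n in plan:
        if kind == "microvilli":
            comps.append(None)  # placeholder, filled below
            continue
        r_val = _poiseuille_R(rad, length, n, cfg.viscosity)
        if not r_val > 0:
            raise ValueError(f"nonpositive resistance computed for {lab!r}")
        vessel_R_sum += r_val
        comps.append(Compartment(
            label=lab, generation=g, kind=kind, R=r_val,
            C=_volume_C(rad, length, n, cfg.beta),
            n_parallel=n, radius=rad, length=length))
    mv_idx = next(i for i, c in enumerate(comps) if c is None)
    comps[mv_idx] = Compartment(
        label="microvilli", generation=ng + 1, kind="microvilli",
        R=cfg.microvilli_resistance_fraction * vessel_R_sum,
        C=cfg.microvilli_compliance, n_parallel=1)
    return WindkesselNetwork(comps, venous_pressure=cfg.venous_pressure)


def scale_pressure_waveform(shape: PeriodicWaveform, systolic: float,
                            diastolic: float) -> PressureWaveform:
    """Affinely rescale a waveform shape to a systolic/diastolic range."""
    vmin, vmax = float(shape.v.min()), float(shape.v.max())
    if vmax == vmin:
        if systolic != diastolic:
            raise ValueError(
                "constant shape cannot be scaled to a pulsatile range")
        p = np.full_like(shape.v, float(systolic))
    else:
        norm = (shape.v - vmin) / (vmax - vmin)
        p = diastolic + (systolic - diastolic) * norm
    return PressureWaveform(t=shape.t.copy(), p=p, period=shape.period)


@dataclass
class SimulationResult:
    """Periodic steady state over one cycle (time grid includes both ends)."""

    t: np.ndarray  # (nt,)
    p_in: np.ndarray  # (nt,)
    P: np.ndarray  # (n_compartments, nt) node pressures
    Q_R: np.ndarray  # (n_compartments, nt) flow through each resistor
    Q_C: np.ndarray  # (n_compartments, nt) flow into each capacitor
    n_cycles: int
    converged: bool

    @property
    def umbilical_flow(self) -> np.ndarray:
        return self.Q_R[0]


def _system_matrices(network: WindkesselNetwork):
    """A, forcing structure for the interior-node linear ODE system."""
    R = network.R
    C = network.C
    N = len(R)
    n = N - 1  # interior nodes with dynamics
    if np.any(C[:n] <= 0):
        bad = int(np.argmax(C[:n] <= 0))
        raise ValueError(
            f"compartment {network.compartments[bad].label!r} has zero "
            "compliance; interior nodes must have C > 0"
        )
    A = np.zeros((n, n))
    for i in range(n):
        A[i, i] = -(1.0 / R[i] + 1.0 / R[i + 1]) / C[i]
        if i > 0:
            A[i, i - 1] = 1.0 / (R[i] * C[i])
        if i < n - 1:
            A[i, i + 1] = 1.0 / (R[i + 1] * C[i])
    b_const = np.zeros(n)
    b_const[n - 1] = network.venous_pressure / (R[N - 1] * C[n - 1])
    e_in = np.zeros(n)
    e_in[0] = 1.0 / (R[0] * C[0])
    return A, b_const, e_in


def _trapezoid_stepper(network: WindkesselNetwork, h: float):
    A, b_const, e_in = _system_matrices(network)
    n = A.shape[0]
    I = np.eye(n)
    lu = lu_factor(I - (h / 2.0) * A)
    K = lu_solve(lu, I + (h / 2.0) * A)
    u_in = lu_solve(lu, (h / 2.0) * e_in)
    w0 = lu_solve(lu, h * b_const)
    return K, u_in, w0


def simulate(network: WindkesselNetwork, p_in: PressureWaveform,
             steps_per_cycle: int = 400, tol: float = 1e-6,
             max_cycles: int = 200) -> SimulationResult:
    """Integrate to the periodic steady state and return the final cycle.

    Cycles of the inlet waveform are repeated until every interior node's
    cycle-mean pressure changes by less than ``tol`` (relative) between
    successive cycles; exceeding ``max_cycles`` raises with the
    convergence trace.
    """
    R = network.R
    N = len(R)
    T = p_in.period
    h = T / steps_per_cycle
    tgrid = h * np.arange(steps_per_cycle + 1)
    pin = p_in.as_periodic().sample(tgrid)
    K, u_in, w0 = _trapezoid_stepper(network, h)

    # initial state: resistive ladder at the cycle-mean inlet pressure
    pbar = p_in.as_periodic().mean()
    cumR = np.cumsum(R)
    P = pbar - (pbar - network.venous_pressure) * cumR[:N - 1] / R.sum()

    prev_mean = None
    trace = []
    traj = np.empty((steps_per_cycle + 1, N - 1))
    converged = False
    n_cycles = 0
    for cycle in range(max_cycles):
        traj[0] = P
        for k in range(steps_per_cycle):
            P = K @ P + u_in * (pin[k] + pin[k + 1]) + w0
            traj[k + 1] = P
        n_cycles = cycle + 1
        mean = traj[:-1].mean(axis=0)
        if prev_mean is not None:
            denom = np.maximum(np.abs(prev_mean), 1e-12)
            resid = float(np.max(np.abs(mean - prev_mean) / denom))
            trace.append(resid)
            if resid < tol:
                converged = True
                break
        prev_mean = mean
    if not converged:
        raise RuntimeError(
            f"periodic steady state not reached within {max_cycles} cycles; "
            f"convergence trace (last 10): {trace[-10:]}"
        )

    Pfull = np.empty((N, tgrid.size))
    Pfull[:N - 1] = traj.T
    Pfull[N - 1] = network.venous_pressure
    upstream = np.vstack([pin, Pfull[:N - 1]])
    Q_R = (upstream - Pfull) / R[:, None]
    Q_C = np.empty_like(Q_R)
    Q_C[:N - 1] = Q_R[:N - 1] - Q_R[1:]
    Q_C[N - 1] = 0.0
    return SimulationResult(t=tgrid, p_in=pin, P=Pfull, Q_R=Q_R, Q_C=Q_C,
                            n_cycles=n_cycles, converged=converged)


def transient_response(network: WindkesselNetwork, p_in_fn, duration: float,
                       steps: int, P_init: np.ndarray | None = None):
    """Open-loop transient integration (arbitrary inlet, no periodicity).

    ``p_in_fn`` maps time (s) to inlet pressure (mmHg).  Returns (t, P)
    with P of shape (n_interior_nodes, len(t)).  Used for step-response
    analyses; the periodic solver is ``simulate``.
    """
    h = duration / steps
    K, u_in, w0 = _trapezoid_stepper(network, h)
    n = len(network.compartments) - 1
    t = h * np.arange(steps + 1)
    pin = np.array([float(p_in_fn(tk)) for tk in t])
    P = np.zeros(n) if P_init is None else np.asarray(P_init, float).copy()
    out = np.empty((steps + 1, n))
    out[0] = P
    for k in range(steps):
        P = K @ P + u_in * (pin[k] + pin[k + 1]) + w0
        out[k + 1] = P
    return t, out.T


@dataclass
class FlowMetrics:
    """Doppler-style indices of one flow cycle."""

    mean_flow: float  # ml/s
    RI: float
    PI: float
    peak_backflow: float  # ml/s

    def __post_init__(self) -> None:
        if self.peak_backflow < 0:
            raise ValueError("peak_backflow must be >= 0")


def flow_metrics(t: np.ndarray, q: np.ndarray) -> FlowMetrics:
    """Compute mean flow, RI, PI and peak backflow from one closed cycle.

    ``t`` must span one period (both end points included); the cycle mean
    is a trapezoid average.  Raises when there is no forward flow.
    """
    t = np.asarray(t, float)
    q = np.asarray(q, float)
    S, D = float(q.max()), float(q.min())
    if S <= 0:
        raise ValueError("no forward flow: systolic peak is non-positive")
    mean = float(np.trapezoid(q, t) / (t[-1] - t[0]))
    return FlowMetrics(
        mean_flow=mean,
        RI=(S - D) / S,
        PI=(S - D) / mean,
        peak_backflow=max(0.0, -D),
    )


@dataclass
class MultiplierFit:
    k_R: float
    k_C: float
    network: WindkesselNetwork
    residual: float
    metrics: FlowMetrics


def fit_multipliers(network: WindkesselNetwork, p_in: PressureWaveform,
                    target_q: PeriodicWaveform,
                    steps_per_cycle: int = 400,
                    starts: tuple = ((1.0, 1.0), (2.0, 0.5),
                                     (0.5, 2.0), (4.0, 4.0)),
                    maxiter: int = 150) -> MultiplierFit:
    """Scale the whole network's R and C to match a target umbilical flow.

    Minimises the normalised L2 waveform mismatch plus squared RI and PI
    mismatches (equal weights) with Nelder-Mead in (log k_R, log k_C),
    multistart.
    """
    if abs(target_q.period - p_in.period) > 1e-9 * p_in.period:
        raise ValueError("target waveform period must match the inlet period")
    t_ref = (p_in.period / steps_per_cycle) * np.arange(steps_per_cycle + 1)
    qt = target_q.sample(t_ref)
    RI_t = (qt.max() - qt.min()) / qt.max()
    mean_t = float(np.trapezoid(qt, t_ref) / p_in.period)
    PI_t = (qt.max() - qt.min()) / mean_t
    qt_norm = float(np.sqrt(np.mean(qt ** 2)))

    def objective(logk):
        kR, kC = math.exp(logk[0]), math.exp(logk[1])
        try:
            sim = simulate(network.scaled(kR, kC), p_in, steps_per_cycle)
        except RuntimeError:
            return 1e6
        q = sim.umbilical_flow
        m = flow_metrics(sim.t, q)
        l2 = np.sqrt(np.mean((q - qt) ** 2)) / qt_norm
        return float(l2 ** 2 + (m.RI - RI_t) ** 2 + (m.PI - PI_t) ** 2)

    best = None
    for kR0, kC0 in starts:
        res = optimize.minimize(
            objective, x0=[math.log(kR0), math.log(kC0)],
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e6:
        raise RuntimeError("multiplier fit failed from every start")
    kR, kC = math.exp(best.x[0]), math.exp(best.x[1])
    fitted = network.scaled(kR, kC)
    sim = simulate(fitted, p_in, steps_per_cycle)
    return MultiplierFit(k_R=kR, k_C=kC, network=fitted,
                         residual=float(best.fun),
                         metrics=flow_metrics(sim.t, sim.umbilical_flow))


@dataclass
class SweepResult:
    """Metric surfaces over a grid of R and C multipliers."""

    r_multipliers: np.ndarray
    c_multipliers: np.ndarray
    mean_flow: np.ndarray  # (n_r, n_c)
    RI: np.ndarray
    PI: np.ndarray
    peak_backflow: np.ndarray

    def __post_init__(self) -> None:
        shape = (len(self.r_multipliers), len(self.c_multipliers))
        for name in ("mean_flow", "RI", "PI", "peak_backflow"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"surface {name} must have shape {shape}")


#: default multiplier grid for the parametric study; spans the regime in
#: which RI/PI grow monotonically with R and C and flow reversal sets in at
#: the high-R/high-C corner (far beyond it, with the network time constant
#: many times the cardiac period, RI saturates and recedes)
DEFAULT_SWEEP_GRID = np.geomspace(0.25, 4.0, 20)


def sweep(network: WindkesselNetwork, p_in: PressureWaveform,
          r_grid: np.ndarray | None = None,
          c_grid: np.ndarray | None = None,
          steps_per_cycle: int = 400) -> SweepResult:
    """Simulate every (k_R, k_C) pair and collect the four metric surfaces."""
    r_grid = DEFAULT_SWEEP_GRID if r_grid is None else np.asarray(r_grid, float)
    c_grid = DEFAULT_SWEEP_GRID if c_grid is None else np.asarray(c_grid, float)
    if np.any(r_grid <= 0) or np.any(c_grid <= 0):
        raise ValueError("multiplier grids must be positive")
    shape = (r_grid.size, c_grid.size)
    surfaces = {k: np.empty(shape) for k in
                ("mean_flow", "RI", "PI", "peak_backflow")}
    for i, kR in enumerate(r_grid):
        for j, kC in enumerate(c_grid):
            sim = simulate(network.scaled(kR, kC), p_in, steps_per_cycle)
            m = flow_metrics(sim.t, sim.umbilical_flow)
            surfaces["mean_flow"][i, j] = m.mean_flow
            surfaces["RI"][i, j] = m.RI
            surfaces["PI"][i, j] = m.PI
            surfaces["peak_backflow"][i, j] = m.peak_backflow
    return SweepResult(r_multipliers=r_grid, c_multipliers=c_grid, **surfaces)
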