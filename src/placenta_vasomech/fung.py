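"""Fung-type hyperelastic thick-wall artery model with residual stress.

The vessel wall is an incompressible, homogeneous thick-wall cylinder whose
stress-free reference configuration is an open sector: a radially cut ring
springs open by the *opening angle* (OA), the gap angle subtended at the
sector centre by the two cut faces.  Material therefore spans 2*pi - OA and
closing the ring imposes a transmural residual-strain gradient.

Strain energy (isotropic reduction of the Fung exponential, equal stiffness
in all three directions and no cross/shear coupling):

    W(E) = c/2 * (exp(b1*(E_theta^2 + E_z^2 + E_r^2)) - 1)

with Green strains E = (lambda^2 - 1)/2.  ``c`` carries the unit of the
pressure data (mmHg here); ``b1`` is dimensionless and controls strain
stiffening.

Kinematics (incompressible inflation/extension of the closed sector with
k = 2*pi / (2*pi - OA)):

    r(R)^2       = r_i^2 + (R^2 - R_i^2) / (k * lambda_z)
    lambda_theta = k * r / R
    lambda_r     = 1 / (lambda_theta * lambda_z)

Luminal pressure at zero outer gauge pressure follows from radial
equilibrium:

    P = int_{r_i}^{r_o} (sigma_theta - sigma_r) dr / r

with sigma_theta - sigma_r = c*b1*exp(Q)*(lambda_theta^2*E_theta
- lambda_r^2*E_r).  Material parameters are estimated by multistart
Nelder-Mead on pressure residuals, in log-parameter space to enforce
positivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import optimize

from .pd_mechanics import PressureStretchCurve

_EXP_GUARD = 700.0  # exp argument above which strain_energy refuses to evaluate


class PressureBracketError(RuntimeError):
    """Raised when the inner radius solving P(r_i) = P cannot be bracketed."""


@dataclass
class StressFreeGeometry:
    """Open-sector (stress-free) reference configuration of the wall.

    ``R_i``/``R_o`` are the sector inner/outer radii in mm; ``opening_angle``
    is the gap angle in degrees at the sector centre between the two cut
    faces (0 means no residual stress).
    """

    R_i: float
    R_o: float
    opening_angle: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.R_i < self.R_o:
            raise ValueError("need 0 < R_i < R_o")
        if not 0.0 <= self.opening_angle < 360.0:
            raise ValueError("opening angle must lie in [0, 360) degrees")

    @property
    def k(self) -> float:
        """Sector closure factor 2*pi / (2*pi - OA)."""
        oa = math.radians(self.opening_angle)
        return 2.0 * math.pi / (2.0 * math.pi - oa)

    @classmethod
    def from_ring(cls, outer_diameter: float, thickness_to_diameter: float,
                  opening_angle: float = 0.0) -> "StressFreeGeometry":
        """Build geometry from ring measurements.

        ``thickness_to_diameter`` is wall thickness over *luminal* (inner)
        diameter; for the chorionic arteries studied here this ratio is
        around 0.6, which is only geometrically consistent with the inner
        diameter as denominator.  The measured ring dimensions are taken
        directly as the stress-free sector radii.
        """
        if not 0.0 < thickness_to_diameter < 1.0:
            raise ValueError("thickness_to_diameter must lie in (0, 1)")
        R_o = outer_diameter / 2.0
        # D_o = D_i + 2 t = D_i (1 + 2 t/D_i)
        R_i = R_o / (1.0 + 2.0 * thickness_to_diameter)
        return cls(R_i=R_i, R_o=R_o, opening_angle=opening_angle)


@dataclass
class FungParameters:
    """Material constants: stress scale ``c`` (mmHg) and exponent ``b1``."""

    c: float
    b1: float

    def __post_init__(self) -> None:
        if self.c <= 0 or self.b1 <= 0:
            raise ValueError("c and b1 must be positive")


@dataclass
class StrainState:
    """Principal stretches of an incompressible wall material point."""

    lambda_r: float
    lambda_theta: float
    lambda_z: float

    def __post_init__(self) -> None:
        J = self.lambda_r * self.lambda_theta * self.lambda_z
        if abs(J - 1.0) > 1e-9:
            raise ValueError(f"incompressibility violated: det F = {J!r}")

    @classmethod
    def from_plane(cls, lambda_theta: float, lambda_z: float) -> "StrainState":
        """State with lambda_r fixed by incompressibility."""
        return cls(1.0 / (lambda_theta * lambda_z), lambda_theta, lambda_z)

    @property
    def E_r(self) -> float:
        return (self.lambda_r ** 2 - 1.0) / 2.0

    @property
    def E_theta(self) -> float:
        return (self.lambda_theta ** 2 - 1.0) / 2.0

    @property
    def E_z(self) -> float:
        return (self.lambda_z ** 2 - 1.0) / 2.0


@dataclass
class FitResult:
    params: FungParameters
    r_squared: float
    sse: float  # mmHg^2
    n_restarts: int
    converged: bool

    def __post_init__(self) -> None:
        if self.sse < 0:
            raise ValueError("sse must be nonnegative")


@dataclass
class WallKinematics:
    """Radial maps of the inflated/extended closed sector.

    Evaluate ``r``, ``lambda_theta`` and ``lambda_r`` at stress-free radii
    R in [R_i, R_o]; ``lambda_z`` is uniform.
    """

    geom: StressFreeGeometry
    r_i: float
    lambda_z: float

    def r(self, R):
        g = self.geom
        r2 = self.r_i ** 2 + (np.asarray(R, float) ** 2 - g.R_i ** 2) / (
            g.k * self.lambda_z)
        return np.sqrt(r2)

    def lambda_theta(self, R):
        return self.geom.k * self.r(R) / np.asarray(R, float)

    def lambda_r(self, R):
        return 1.0 / (self.lambda_theta(R) * self.lambda_z)

    @property
    def r_o(self) -> float:
        return float(self.r(self.geom.R_o))


def kinematics(geom: StressFreeGeometry, r_i: float,
               lambda_z: float) -> WallKinematics:
    """Deformation maps for a given deformed inner radius and axial stretch."""
    if r_i <= 0:
        raise ValueError("deformed inner radius must be positive")
    if lambda_z <= 0 or geom.k * lambda_z <= 0:
        raise ValueError("axial stretch (and k*lambda_z) must be positive")
    return WallKinematics(geom=geom, r_i=r_i, lambda_z=lambda_z)


def strain_energy(params: FungParameters, state: StrainState) -> float:
    """Strain-energy density W (same unit as c, mmHg)."""
    Q = params.b1 * (state.E_theta ** 2 + state.E_z ** 2 + state.E_r ** 2)
    if Q > _EXP_GUARD:
        raise OverflowError(
            f"Fung exponent {Q:.3g} exceeds the overflow guard ({_EXP_GUARD:g}); "
            "strains or b1 are unphysically large"
        )
    return params.c / 2.0 * math.expm1(Q)


def stress_difference(params: FungParameters, state: StrainState) -> float:
    """Cauchy stress difference sigma_theta - sigma_r (mmHg).

    Equals lambda_theta^2 dW/dE_theta - lambda_r^2 dW/dE_r for the
    incompressible wall, with the hydrostatic pressure eliminated.
    """
    Q = params.b1 * (state.E_theta ** 2 + state.E_z ** 2 + state.E_r ** 2)
    if Q > _EXP_GUARD:
        raise OverflowError(
            f"Fung exponent {Q:.3g} exceeds the overflow guard ({_EXP_GUARD:g})"
        )
    return (params.c * params.b1 * math.exp(Q)
            * (state.lambda_theta ** 2 * state.E_theta
               - state.lambda_r ** 2 * state.E_r))


@lru_cache(maxsize=8)
def _gauss(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def _pressures(geom: StressFreeGeometry, c: float, b1: float,
               r_i: np.ndarray, lambda_z: float,
               n_points: int = 200) -> np.ndarray:
    """Vectorised luminal pressure for an array of deformed inner radii.

    Gauss-Legendre quadrature of the equilibrium integral over the
    stress-free radial coordinate; the Fung exponent is clipped at the
    overflow guard so root-finders can probe extreme radii safely.
    """
    r_i = np.atleast_1d(np.asarray(r_i, dtype=float))
    x, w = _gauss(n_points)
    a, b = geom.R_i, geom.R_o
    R = 0.5 * (b - a) * x + 0.5 * (b + a)  # (n_points,)
    scale = 0.5 * (b - a)
    k = geom.k
    r2 = r_i[None, :] ** 2 + (R[:, None] ** 2 - a ** 2) / (k * lambda_z)
    lt2 = k ** 2 * r2 / R[:, None] ** 2
    lr2 = 1.0 / (lt2 * lambda_z ** 2)
    Et = (lt2 - 1.0) / 2.0
    Er = (lr2 - 1.0) / 2.0
    Ez = (lambda_z ** 2 - 1.0) / 2.0
    Q = b1 * (Et ** 2 + Er ** 2 + Ez ** 2)
    with np.errstate(over="ignore", invalid="ignore"):
        sd = c * b1 * np.exp(np.minimum(Q, _EXP_GUARD)) * (lt2 * Et - lr2 * Er)
        integrand = sd * R[:, None] / (k * lambda_z * r2)
        return scale * (w[:, None] * integrand).sum(axis=0)


def luminal_pressure(geom: StressFreeGeometry, params: FungParameters,
                     r_i: float, lambda_z: float,
                     n_points: int = 200) -> float:
    """Luminal pressure (mmHg) of the state with deformed inner radius r_i.

    Zero gauge pressure is assumed at the outer wall.  Raises if the
    integrand is non-finite anywhere across the wall.
    """
    kin = kinematics(geom, r_i, lambda_z)  # validates inputs
    P = _pressures(geom, params.c, params.b1, np.array([r_i]), lambda_z,
                   n_points)[0]
    if not np.isfinite(P):
        x, _ = _gauss(n_points)
        R = 0.5 * (geom.R_o - geom.R_i) * x + 0.5 * (geom.R_o + geom.R_i)
        lt = kin.lambda_theta(R)
        finite = np.isfinite(lt) & (lt > 0)
        bad = R[np.argmax(~finite)] if not finite.all() else R[0]
        raise FloatingPointError(
            f"non-finite equilibrium integrand near stress-free radius "
            f"R = {bad:.4g} mm (r_i = {r_i:.4g} mm)"
        )
    return float(P)


def zero_pressure_inner_radius(geom: StressFreeGeometry,
                               params: FungParameters, lambda_z: float,
                               n_points: int = 200) -> float:
    """Deformed inner radius of the closed, axially stretched, unpressurised
    vessel (the residual-stress self-equilibrated state).

    Independent of ``c`` since pressure is linear in c.
    """
    scan = geom.R_i * np.geomspace(0.08, 2.5, 80)
    P = _pressures(geom, params.c, params.b1, scan, lambda_z, n_points)
    sign = np.sign(P)
    idx = np.nonzero(np.diff(sign) > 0)[0]
    if idx.size == 0:
        raise PressureBracketError(
            "could not bracket the zero-pressure state: P(r_i) has no sign "
            "change over the scanned radii"
        )
    lo, hi = scan[idx[0]], scan[idx[0] + 1]
    return float(optimize.brentq(
        lambda ri: _pressures(geom, params.c, params.b1, np.array([ri]),
                              lambda_z, n_points)[0],
        lo, hi, xtol=1e-12, rtol=1e-14))


def _outer_radius(geom: StressFreeGeometry, r_i: float,
                  lambda_z: float) -> float:
    return math.sqrt(r_i ** 2 + (geom.R_o ** 2 - geom.R_i ** 2)
                     / (geom.k * lambda_z))


def forward_curve(geom: StressFreeGeometry, params: FungParameters,
                  lambda_z: float = 1.1,
                  P_grid: np.ndarray | None = None,
                  n_points: int = 200) -> PressureStretchCurve:
    """Predicted pressure-stretch curve of the model.

    For every grid pressure the deformed inner radius is solved by bracketed
    root finding on the (monotone) P(r_i) relation; the emitted stretch is
    the outer-diameter ratio D(P)/D(0), matching the experimental observable.
    """
    if P_grid is None:
        P_grid = np.arange(0.0, 41.0, 1.0)
    P_grid = np.asarray(P_grid, dtype=float)
    if not np.all(np.diff(P_grid) > 0):
        raise ValueError("P_grid must be strictly ascending")
    if P_grid[0] < 0 or P_grid[-1] > 60.0:
        raise ValueError("P_grid must lie within [0, 60] mmHg")
    ri0 = zero_pressure_inner_radius(geom, params, lambda_z, n_points)
    ro0 = _outer_radius(geom, ri0, lambda_z)

    def f(ri, target):
        return _pressures(geom, params.c, params.b1, np.array([ri]),
                          lambda_z, n_points)[0] - target

    lam = np.empty_like(P_grid)
    lo = ri0
    for i, Ptarget in enumerate(P_grid):
        if Ptarget <= 0.0:
            ri = ri0
        else:
            hi = lo * 1.02
            n_expand = 0
            while f(hi, Ptarget) < 0:
                hi *= 1.2
                n_expand += 1
                if n_expand > 200:
                    raise PressureBracketError(
                        f"could not bracket r_i at P = {Ptarget:g} mmHg"
                    )
            ri = optimize.brentq(f, lo, hi, args=(Ptarget,),
                                 xtol=1e-12, rtol=1e-14)
        lam[i] = _outer_radius(geom, ri, lambda_z) / ro0
        lo = ri
    return PressureStretchCurve(P_grid=P_grid, lam=lam,
                                n_cycles_averaged=0, D0=2.0 * ro0)


# multistart box for the Nelder-Mead fit (log-spaced starts)
_C_START_RANGE = (10.0, 1000.0)  # mmHg
_B1_START_RANGE = (1.0, 60.0)


def _fit_objective(geom: StressFreeGeometry, lambda_z: float,
                   lam_meas: np.ndarray, P_meas: np.ndarray,
                   n_points: int):
    span2 = (geom.R_o ** 2 - geom.R_i ** 2) / (geom.k * lambda_z)

    def sse(logp):
        c, b1 = math.exp(logp[0]), math.exp(logp[1])
        try:
            ri0 = zero_pressure_inner_radius(
                geom, FungParameters(c=1.0, b1=b1), lambda_z, n_points)
        except PressureBracketError:
            return 1e12
        ro0 = _outer_radius(geom, ri0, lambda_z)
        ro = lam_meas * ro0
        ri2 = ro ** 2 - span2
        if np.any(ri2 <= 0):
            return 1e12 * (1.0 + float(np.sum(np.minimum(ri2, 0) ** 2)))
        P_pred = _pressures(geom, c, b1, np.sqrt(ri2), lambda_z, n_points)
        return float(np.sum((P_pred - P_meas) ** 2))

    return sse


def fit_fung(curve: PressureStretchCurve, geom: StressFreeGeometry,
             lambda_z: float = 1.1, n_starts: int = 8,
             n_points: int = 200, maxiter: int = 400) -> FitResult:
    """Estimate (c, b1) from a measured pressure-stretch curve.

    Minimises the sum of squared *pressure* residuals at the measured
    stretches (pressure being the controlled, low-noise channel) with
    Nelder-Mead in (log c, log b1) from ``n_starts`` log-spaced starting
    points; returns the best run.  R^2 is the coefficient of determination
    on pressures.
    """
    P_meas = curve.P_grid
    lam_meas = curve.lam
    if P_meas.size < 10 or (P_meas[-1] - P_meas[0]) < 30.0:
        raise ValueError(
            "curve must have >= 10 points spanning >= 30 mmHg for a fit"
        )
    objective = _fit_objective(geom, lambda_z, lam_meas, P_meas, n_points)
    n_c = max(1, round(n_starts / 2))
    c_starts = np.geomspace(*_C_START_RANGE, n_c)
    b1_starts = np.geomspace(*_B1_START_RANGE, max(1, n_starts // n_c))
    starts = [(c0, b10) for c0 in c_starts for b10 in b1_starts]

    best = None
    any_ok = False
    for c0, b10 in starts:
        res = optimize.minimize(
            objective, x0=[math.log(c0), math.log(b10)],
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": maxiter,
                     "maxfev": 2 * maxiter},
        )
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"all {len(starts)} Nelder-Mead restarts failed "
            f"(best objective {None if best is None else best.fun!r})"
        )
    c_hat, b1_hat = math.exp(best.x[0]), math.exp(best.x[1])
    sstot = float(np.sum((P_meas - P_meas.mean()) ** 2))
    r2 = 1.0 - best.fun / sstot if sstot > 0 else float("nan")
    return FitResult(
        params=FungParameters(c=c_hat, b1=b1_hat),
        r_squared=r2, sse=float(best.fun),
        n_restarts=len(starts), converged=any_ok,
    )
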