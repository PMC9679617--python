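"""Mechanical stability, capillary bound and formation energy of gas pockets.

Three independent verdicts decide whether a cavity keeps its air pocket:

* **Mechanical stability.**  A Taylor expansion of the Young–Laplace and
  gas equations around an equilibrium shows that the sign of

      Psi = p_g / V + 2 * sigma * dH/dV,

  evaluated at the equilibrium, classifies it: Psi > 0 restoring (stable),
  Psi < 0 runaway (unstable).  In a cone both H and V are functions of the
  contact radius s alone, so dH/dV = (dH/ds) / (dV/ds) in closed form.

* **Capillary bound.**  Surface tension dominates gravity only below the
  capillary length l_c = sqrt(sigma / (rho g)); the cavity mouth radius s_c
  should not exceed it, or gravity distorts the spherical cap.

* **Formation energy.**  Replacing liquid by gas in the cavity costs/gains

      Delta_E = sigma * (-2 H V + A_lg + A_sg cos(theta)),

  the sum of a volume-displacement term, the cost of the new liquid/gas
  interface, and the solid-wall term.  Delta_E < 0 (air pocket favourable,
  the "ferrophobic" verdict in the liquid-iron application) reduces
  algebraically to the angle criterion theta > epsilon + 90 deg, which for
  a given contact angle restricts the cone to 0 < epsilon < theta - 90 deg.

The module also assembles the total-energy landscape E(s) used as an
independent cross-check: its stationary points must coincide with the
cubic's equilibrium roots, and its local minima with Psi > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    ConeCavity,
    cap_curvature,
    cap_volume,
    cone_volume,
    interface_areas,
    shape_coefficient,
)
from .equilibrium import FluidSolidSystem, GasPocket

__all__ = [
    "StabilityReport",
    "EnergyReport",
    "AngleInterval",
    "stability_psi",
    "capillary_length",
    "formation_energy",
    "ferrophobicity_criterion",
    "admissible_cone_angles",
    "dH_dV_analytic",
    "dH_dV_numeric",
    "energy_profile",
    "profile_stationary_points",
    "DHDV_FD_RELSTEP",
    "DHDV_CHECK_RTOL",
]

# relative step in s for the central-difference cross-check of dH/dV
DHDV_FD_RELSTEP = 1e-6
# analytic and finite-difference dH/dV must agree to this relative tolerance
DHDV_CHECK_RTOL = 1e-4


@dataclass(frozen=True)
class StabilityReport:
    """Stability verdict for one equilibrium pocket."""

    psi: float
    stable: bool
    dH_dV_analytic: float
    dH_dV_numeric: float
    capillary_length: float
    within_capillary_bound: bool


@dataclass(frozen=True)
class EnergyReport:
    """Formation-energy budget of a gas pocket at contact radius s.

    ``delta_E = delta_E_V + delta_E_lg + delta_E_sg`` (J): volume
    displacement, liquid/gas interface creation, and solid/gas wall term.
    ``ferrophobic`` is the air-pocket-favourable verdict (delta_E < 0),
    equivalent to theta > epsilon + pi/2.
    """

    delta_E: float
    delta_E_V: float
    delta_E_lg: float
    delta_E_sg: float
    ferrophobic: bool


@dataclass(frozen=True)
class AngleInterval:
    """Open interval (lower, upper) of admissible cone half-angles (rad)."""

    lower: float
    upper: float

    @property
    def is_empty(self) -> bool:
        return not (self.upper > self.lower)

    def contains(self, epsilon: float) -> bool:
        return self.lower < epsilon < self.upper


def capillary_length(system: FluidSolidSystem) -> float:
    """Capillary length ``sqrt(sigma / (rho g))`` of the liquid (m)."""
    return math.sqrt(system.sigma / (system.rho * system.g))


def dH_dV_analytic(s: float, theta: float, epsilon: float) -> float:
    """Closed-form dH/dV along the cone wall, (dH/ds)/(dV/ds) (1/m^4)."""
    C = shape_coefficient(theta, epsilon)
    return -math.cos(theta - epsilon) / (3.0 * C * s**4)


def dH_dV_numeric(
    s: float, theta: float, epsilon: float, rel_step: float = DHDV_FD_RELSTEP
) -> float:
    """Central-difference dH/dV, the independent check on the chain rule."""
    h = rel_step * s
    dH = cap_curvature(s + h, theta, epsilon) - cap_curvature(s - h, theta, epsilon)
    dV = cap_volume(s + h, theta, epsilon) - cap_volume(s - h, theta, epsilon)
    return dH / dV


def stability_psi(pocket: GasPocket) -> StabilityReport:
    """Evaluate the stability indicator Psi at an equilibrium pocket.

    Psi = p_g/V + 2 sigma dH/dV, all quantities at the equilibrium.  The
    analytic dH/dV is cross-checked against central finite differences.
    """
    if pocket.gas.p_g <= 0.0:
        raise ValueError(
            f"unphysical state: gas pressure p_g={pocket.gas.p_g!r} Pa is not positive"
        )
    s = pocket.s
    theta = pocket.system.theta
    epsilon = pocket.cavity.epsilon
    dhdv = dH_dV_analytic(s, theta, epsilon)
    dhdv_fd = dH_dV_numeric(s, theta, epsilon)
    scale = max(abs(dhdv), abs(dhdv_fd))
    if scale > 0.0 and abs(dhdv - dhdv_fd) > DHDV_CHECK_RTOL * scale:
        raise ArithmeticError(
            f"analytic dH/dV={dhdv:g} disagrees with finite differences {dhdv_fd:g}"
        )
    psi = pocket.gas.p_g / pocket.cap.V + 2.0 * pocket.system.sigma * dhdv
    l_c = capillary_length(pocket.system)
    return StabilityReport(
        psi=psi,
        stable=psi > 0.0,
        dH_dV_analytic=dhdv,
        dH_dV_numeric=dhdv_fd,
        capillary_length=l_c,
        within_capillary_bound=pocket.cavity.s_c <= l_c,
    )


def formation_energy(
    s: float, system: FluidSolidSystem, cavity: ConeCavity
) -> EnergyReport:
    """Energy difference between gas-pocket and fully wetted cavity states.

    Computed at contact radius ``s`` (0 < s <= s_c).  The sign of delta_E
    is independent of s (sigma s^2 factors out), so any s yields the same
    verdict; the reported flag uses the equivalent closed-form criterion
    theta > epsilon + pi/2, which avoids calling a rounding residual on the
    boundary line a verdict.
    """
    if s > cavity.s_c * (1.0 + 1e-12):
        raise ValueError(f"s={s!r} exceeds the cavity mouth radius s_c={cavity.s_c!r}")
    theta = system.theta
    epsilon = cavity.epsilon
    H = cap_curvature(s, theta, epsilon)
    V = cap_volume(s, theta, epsilon)
    a_lg, a_sg = interface_areas(s, theta, epsilon)
    d_ev = system.sigma * (-2.0 * H * V)
    d_elg = system.sigma * a_lg
    d_esg = system.sigma * a_sg * math.cos(theta)
    return EnergyReport(
        delta_E=d_ev + d_elg + d_esg,
        delta_E_V=d_ev,
        delta_E_lg=d_elg,
        delta_E_sg=d_esg,
        ferrophobic=ferrophobicity_criterion(theta, epsilon),
    )


def ferrophobicity_criterion(theta: float, epsilon: float) -> bool:
    """Air-pocket retention criterion: true iff theta > epsilon + pi/2."""
    return theta > epsilon + math.pi / 2.0


def admissible_cone_angles(theta: float) -> AngleInterval:
    """Open interval of cone half-angles compatible with air retention.

    (0, theta - pi/2) when theta > pi/2; empty otherwise (a wetting liquid
    retains no pocket in any cone).
    """
    if not (0.0 <= theta <= math.pi):
        raise ValueError(f"theta={theta!r} rad: must lie in [0, pi]")
    return AngleInterval(lower=0.0, upper=max(theta - math.pi / 2.0, 0.0))


def energy_profile(
    system: FluidSolidSystem,
    cavity: ConeCavity,
    nRT: float,
    s_grid: np.ndarray,
) -> pd.DataFrame:
    """Total energy of the pocket state as a function of contact radius.

    E(s) = sigma A_lg + sigma cos(theta) A_sg + p_l V - nRT ln(V / V_ref),
    relative to the fully wetted cavity: surface terms, displacement work
    against the liquid, and the isothermal free energy of the trapped gas
    (V_ref, the bare cone volume, fixes the irrelevant gauge constant).
    Stationary points of E reproduce the equilibrium cubic's roots; local
    minima are the Psi > 0 equilibria.  Used as the independent energy
    oracle for the equilibrium and stability machinery.
    """
    s = np.asarray(s_grid, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("s_grid must be a 1-D array with at least two points")
    if np.any(s <= 0.0) or np.any(np.diff(s) <= 0.0):
        raise ValueError("s_grid must be positive and strictly increasing")
    if not (nRT > 0.0):
        raise ValueError(f"nRT={nRT!r}: must be > 0")

    theta = system.theta
    epsilon = cavity.epsilon
    C = shape_coefficient(theta, epsilon)
    V = C * s**3
    a_lg = 2.0 * math.pi * s**2 / (1.0 + math.sin(theta - epsilon))
    a_sg = math.pi * s**2 / math.sin(epsilon)
    v_ref = cone_volume(cavity)

    e_lg = system.sigma * a_lg
    e_sg = system.sigma * math.cos(theta) * a_sg
    e_pressure = system.p_l * V
    e_gas = -nRT * np.log(V / v_ref)
    return pd.DataFrame(
        {
            "s": s,
            "E_total": e_lg + e_sg + e_pressure + e_gas,
            "E_lg": e_lg,
            "E_sg": e_sg,
            "E_pressure": e_pressure,
            "E_gas": e_gas,
        }
    )


def profile_stationary_points(profile: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Interior local minima and maxima of an energy profile.

    Returns ``(minima_idx, maxima_idx)``: indices into the profile where the
    discrete derivative of E_total changes sign.
    """
    e = profile["E_total"].to_numpy()
    d = np.diff(e)
    sign = np.sign(d)
    minima = np.flatnonzero((sign[:-1] < 0) & (sign[1:] > 0)) + 1
    maxima = np.flatnonzero((sign[:-1] > 0) & (sign[1:] < 0)) + 1
    return minima, maxima
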