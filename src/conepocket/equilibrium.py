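"""Existence and computation of the equilibrium gas/liquid interface.

Mechanical equilibrium of the interface requires the Young–Laplace balance

    p_g = p_l + 2 * sigma * H,

and the trapped gas is isothermal and ideal, p_g * V = nRT.  In a cone both
H and V are single-variable functions of the contact radius s
(H = cos(theta - epsilon)/s, V = C * s^3 with the shape factor C), so the
two conditions combine into a cubic in s:

    p_l * C * s^3 + 2 * sigma * cos(theta - epsilon) * C * s^2 - nRT = 0.

For p_l > 0 this cubic has exactly one real positive root (the coefficient
signs admit a single sign change); under tension (p_l < 0, the xylem
regime) zero, one or two positive roots may exist and the physical pick is
deferred to the stability classification.

Roots are obtained from the companion-matrix eigenvalues (`numpy.roots`),
which is robust near the flat-interface degeneracy where the quadratic
coefficient vanishes, then polished by Newton steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import (
    CapState,
    ConeCavity,
    cap_state,
    cone_volume,
    shape_coefficient,
)

__all__ = [
    "FluidSolidSystem",
    "GasState",
    "GasPocket",
    "EquilibriumResult",
    "cubic_coefficients",
    "equilibrium_radius",
    "young_laplace_residual",
    "gas_content_from_fill",
    "STANDARD_GRAVITY",
    "IMAG_ROOT_TOL",
    "YOUNG_LAPLACE_RTOL",
    "GAS_LAW_RTOL",
]

STANDARD_GRAVITY = 9.81  # m/s^2

# roots with |Im| > IMAG_ROOT_TOL * |root| are discarded as complex
IMAG_ROOT_TOL = 1e-9
# post-hoc contract tolerances on every returned equilibrium
YOUNG_LAPLACE_RTOL = 1e-6
GAS_LAW_RTOL = 1e-9


@dataclass(frozen=True)
class FluidSolidSystem:
    """Liquid/solid pairing and ambient state.

    Parameters
    ----------
    sigma : float
        Surface tension of the liquid/gas interface (N/m).
    rho : float
        Liquid density (kg/m^3).
    theta : float
        Contact angle of the liquid on the solid, in radians, measured
        through the liquid.
    p_l : float
        Liquid pressure at the cavity (Pa).  May be negative: water under
        transpiration-driven tension in the xylem routinely is.
    g : float
        Gravitational acceleration (m/s^2).
    """

    sigma: float
    rho: float
    theta: float
    p_l: float
    g: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        for name in ("sigma", "rho", "g"):
            value = getattr(self, name)
            if not (value > 0.0 and math.isfinite(value)):
                raise ValueError(f"{name}={value!r}: must be finite and > 0")
        if not (0.0 <= self.theta <= math.pi):
            raise ValueError(f"theta={self.theta!r} rad: must lie in [0, pi]")
        if not math.isfinite(self.p_l):
            raise ValueError(f"p_l={self.p_l!r}: must be finite")

    def with_theta(self, theta: float) -> "FluidSolidSystem":
        return replace(self, theta=theta)


@dataclass(frozen=True)
class GasState:
    """Isothermal gas content ``nRT`` (J) and its equilibrium pressure (Pa)."""

    nRT: float
    p_g: float

    def __post_init__(self) -> None:
        if not (self.nRT > 0.0 and math.isfinite(self.nRT)):
            raise ValueError(f"nRT={self.nRT!r}: must be finite and > 0")


@dataclass(frozen=True)
class GasPocket:
    """An equilibrium gas pocket: geometry, ambient system and gas state."""

    cavity: ConeCavity
    system: FluidSolidSystem
    gas: GasState
    s: float
    cap: CapState


@dataclass
class EquilibriumResult:
    """Outcome of the equilibrium search for one (system, cavity, nRT).

    ``pockets`` holds equilibria inside the cavity (0 < s <= s_c);
    ``overfilled`` holds formal roots with s > s_c, where the gas content
    exceeds what the cavity can accommodate — reported, never clamped.
    ``exists`` is true iff at least one in-cavity pocket was found.
    """

    pockets: list[GasPocket] = field(default_factory=list)
    overfilled: list[GasPocket] = field(default_factory=list)
    exists: bool = False
    message: str = ""

    @property
    def pocket(self) -> GasPocket:
        """The unique in-cavity pocket; raises if absent or ambiguous."""
        if len(self.pockets) != 1:
            raise ValueError(
                f"expected exactly one equilibrium pocket, found {len(self.pockets)} "
                f"({self.message})"
            )
        return self.pockets[0]


def cubic_coefficients(
    system: FluidSolidSystem, cavity: ConeCavity, nRT: float
) -> tuple[float, float, float, float]:
    """Coefficients (c3, c2, c1, c0) of the equilibrium cubic in s.

    Substituting V = C s^3 and H = cos(theta - epsilon)/s into
    p_g V = nRT with p_g = p_l + 2 sigma H gives

        c3 = p_l * C,   c2 = 2 sigma cos(theta - epsilon) * C,
        c1 = 0,         c0 = -nRT,

    so evaluating the polynomial at any s reproduces p_g(s) V(s) - nRT.
    """
    if not (nRT > 0.0 and math.isfinite(nRT)):
        raise ValueError(f"nRT={nRT!r}: must be finite and > 0")
    C = shape_coefficient(system.theta, cavity.epsilon)
    cos_d = math.cos(system.theta - cavity.epsilon)
    return (system.p_l * C, 2.0 * system.sigma * cos_d * C, 0.0, -nRT)


def _positive_real_roots(coeffs: tuple[float, float, float, float]) -> list[float]:
    """Positive real roots of the cubic, polished by Newton iteration."""
    c3, c2, c1, c0 = coeffs
    arr = np.array([c3, c2, c1, c0], dtype=float)
    if np.all(arr == 0.0):
        raise ValueError("identically zero polynomial")
    raw = np.roots(arr)  # companion-matrix eigenvalues
    scale = max(abs(c3), abs(c2), abs(c0), 1e-300)

    roots: list[float] = []
    for z in raw:
        if abs(z.imag) > IMAG_ROOT_TOL * max(abs(z), 1e-300):
            continue
        s = float(z.real)
        if s <= 0.0:
            continue
        # Newton polish on f(s) = c3 s^3 + c2 s^2 + c0
        for _ in range(8):
            f = ((c3 * s + c2) * s + c1) * s + c0
            df = (3.0 * c3 * s + 2.0 * c2) * s + c1
            if df == 0.0:
                break
            step = f / df
            s_new = s - step
            if s_new <= 0.0:
                break
            s = s_new
            if abs(step) < 1e-16 * s:
                break
        if s <= 0.0:
            continue
        roots.append(s)

    # dedupe nearly identical roots (double-root boundary under tension)
    roots.sort()
    deduped: list[float] = []
    for s in roots:
        if deduped and abs(s - deduped[-1]) <= 1e-9 * max(s, deduped[-1]):
            continue
        deduped.append(s)
    del scale
    return deduped


def equilibrium_radius(
    system: FluidSolidSystem, cavity: ConeCavity, nRT: float
) -> EquilibriumResult:
    """Solve the equilibrium cubic and package every physical root.

    For p_l > 0 the root is provably unique; a numerical violation of that
    uniqueness raises.  For p_l <= 0 all positive real roots (possibly
    none) are returned for downstream stability classification.  Roots with
    s > s_c are reported as overfilled.  An empty result (``exists=False``
    and no overfilled roots) is the no-interface report: the liquid fills
    the cavity completely.
    """
    coeffs = cubic_coefficients(system, cavity, nRT)
    roots = _positive_real_roots(coeffs)

    if system.p_l > 0.0 and len(roots) != 1:
        raise ArithmeticError(
            f"expected exactly one positive root for p_l={system.p_l!r} > 0, "
            f"found {len(roots)}: {roots!r}"
        )

    result = EquilibriumResult()
    for s in roots:
        cap = cap_state(s, system.theta, cavity.epsilon)
        p_g = nRT / cap.V
        if p_g <= 0.0:  # unreachable with V > 0, kept as an explicit guard
            result.message += f" root s={s:g} discarded: non-positive gas pressure;"
            continue
        pocket = GasPocket(
            cavity=cavity, system=system, gas=GasState(nRT=nRT, p_g=p_g), s=s, cap=cap
        )
        _verify_contracts(pocket)
        if s <= cavity.s_c * (1.0 + 1e-12):
            result.pockets.append(pocket)
        else:
            result.overfilled.append(pocket)

    result.exists = bool(result.pockets)
    if not roots:
        result.message = (
            "no positive real root: the system does not admit a gas/liquid interface"
        )
    elif not result.exists and result.overfilled:
        result.message = (
            "all equilibria lie beyond the cavity mouth (gas content exceeds capacity)"
        )
    else:
        result.message = f"{len(result.pockets)} in-cavity equilibrium root(s)"
    return result


def _verify_contracts(pocket: GasPocket) -> None:
    """Enforce the gas-law and Young–Laplace contracts on a returned pocket."""
    gas_residual = abs(pocket.gas.p_g * pocket.cap.V - pocket.gas.nRT)
    if gas_residual > GAS_LAW_RTOL * pocket.gas.nRT:
        raise ArithmeticError(
            f"gas-law residual {gas_residual:g} J exceeds tolerance at s={pocket.s:g}"
        )
    yl = young_laplace_residual(pocket)
    scale = max(abs(pocket.system.p_l), pocket.gas.p_g, 1.0)
    if abs(yl) > YOUNG_LAPLACE_RTOL * scale:
        raise ArithmeticError(
            f"Young–Laplace residual {yl:g} Pa exceeds tolerance at s={pocket.s:g}"
        )


def young_laplace_residual(pocket: GasPocket) -> float:
    """Pressure-balance defect ``p_g - p_l - 2 sigma H`` (Pa); ~0 at equilibrium."""
    return (
        pocket.gas.p_g
        - pocket.system.p_l
        - 2.0 * pocket.system.sigma * pocket.cap.H
    )


def gas_content_from_fill(
    cavity: ConeCavity, fill_pressure: float, fill_fraction: float = 1.0
) -> float:
    """Gas content nRT (J) from an initial-fill specification.

    A recess charges with ambient air before immersion: gas at pressure
    ``fill_pressure`` occupying ``fill_fraction`` of the bare cone volume
    carries ``nRT = fill_pressure * fill_fraction * V_cone``.
    """
    if not (fill_pressure > 0.0 and math.isfinite(fill_pressure)):
        raise ValueError(f"fill_pressure={fill_pressure!r}: must be finite and > 0")
    if not (0.0 < fill_fraction <= 1.0):
        raise ValueError(f"fill_fraction={fill_fraction!r}: must lie in (0, 1]")
    return fill_pressure * fill_fraction * cone_volume(cavity)
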