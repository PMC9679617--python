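"""Closed-form geometry of a spherical-cap gas/liquid interface in a cone.

A rotationally symmetric recess (an "ice-cream cone" cavity, the idealised
shape of a xylem pit chamber) holds a gas pocket bounded by the cone wall
and a spherical-cap interface.  Because liquid and gas pressures are
uniform, the interface has constant mean curvature and is necessarily a
spherical section; everything about it is then elementary trigonometry in
three quantities:

``s``        radius of the circular contact line on the cone wall (m),
``theta``    contact angle of the liquid on the solid, through the liquid (rad),
``epsilon``  acute half-opening angle of the cone, measured from its axis,
             so that ``tan(epsilon) = mouth_radius / depth`` (rad).

The sign convention for the mean curvature ``H`` follows the interface
orientation: ``H > 0`` for a cap bulging into the liquid (convex,
``theta - epsilon < 90°``), ``H < 0`` for a cap dipping into the gas
(concave), and ``H = 0`` for the flat interface at ``theta - epsilon = 90°``.

All quantities are SI (metres, radians); degree conversion happens at the
user interfaces, never here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ConeCavity",
    "PitChamber",
    "CapState",
    "cap_shape_term",
    "shape_coefficient",
    "cap_volume",
    "cap_curvature",
    "interface_areas",
    "cap_state",
    "cone_volume",
    "pit_to_cone",
    "EPSILON_MIN",
    "EPSILON_MAX",
    "COS_DEGENERACY_TOL",
]

# cot(epsilon) and 1/sin(epsilon) must stay finite: physical cones have
# finite depth and a genuinely conical wall.
EPSILON_MIN = 1e-6
EPSILON_MAX = math.pi / 2 - 1e-6

# |cos(theta - epsilon)| below this is treated as the flat-interface
# degeneracy: the 0/0 spherical-cap term of the volume formula is replaced
# by its analytic limit (zero; the term vanishes linearly in the offset).
COS_DEGENERACY_TOL = 1e-8


def _check_epsilon(epsilon: float) -> None:
    if not (EPSILON_MIN <= epsilon <= EPSILON_MAX):
        raise ValueError(
            f"epsilon={epsilon!r} rad: cone half-angle must lie in "
            f"[{EPSILON_MIN}, pi/2 - {EPSILON_MIN}] rad"
        )


def _check_theta(theta: float) -> None:
    if not (0.0 <= theta <= math.pi):
        raise ValueError(f"theta={theta!r} rad: contact angle must lie in [0, pi]")


def _check_positive(name: str, value: float) -> None:
    if not (value > 0.0 and math.isfinite(value)):
        raise ValueError(f"{name}={value!r}: must be finite and > 0")


@dataclass(frozen=True)
class ConeCavity:
    """A conical recess: half-opening angle ``epsilon`` and mouth radius ``s_c``.

    ``epsilon`` is measured between wall and axis, so the cavity depth is
    ``s_c / tan(epsilon)``.
    """

    epsilon: float
    s_c: float

    def __post_init__(self) -> None:
        _check_epsilon(self.epsilon)
        _check_positive("s_c", self.s_c)

    @property
    def depth(self) -> float:
        """Axial depth of the cone, ``s_c / tan(epsilon)`` (m)."""
        return self.s_c / math.tan(self.epsilon)

    @classmethod
    def from_mouth_and_depth(cls, s_c: float, depth: float) -> "ConeCavity":
        _check_positive("s_c", s_c)
        _check_positive("depth", depth)
        return cls(epsilon=math.atan2(s_c, depth), s_c=s_c)


@dataclass(frozen=True)
class PitChamber:
    """Double-funnel pit chamber reduced to the half that traps gas.

    A xylem pit resembles two funnels joined at their wide ends; the wide
    chamber is the functional part for interface formation, the narrow pit
    channel merely connects to the conduit lumen.
    """

    chamber_half_angle: float
    chamber_radius: float
    channel_radius: float

    def __post_init__(self) -> None:
        _check_epsilon(self.chamber_half_angle)
        _check_positive("chamber_radius", self.chamber_radius)
        _check_positive("channel_radius", self.channel_radius)
        if not (self.channel_radius < self.chamber_radius):
            raise ValueError(
                f"channel_radius={self.channel_radius!r} must be smaller than "
                f"chamber_radius={self.chamber_radius!r}"
            )


@dataclass(frozen=True)
class CapState:
    """Full geometric state of a wall-attached spherical cap at radius ``s``."""

    s: float
    theta: float
    epsilon: float
    V: float
    H: float
    A_lg: float
    A_sg: float


def cap_shape_term(theta: float, epsilon: float) -> float:
    """Spherical-cap contribution to V/s^3 (dimensionless).

    Equals ``(1 - sin d)^2 (2 + sin d) / cos^3 d`` with ``d = theta - epsilon``:
    positive for a convex cap, negative for a concave one, and zero in the
    flat-interface limit ``|cos d| -> 0`` (removable singularity, evaluated
    by its analytic limit below :data:`COS_DEGENERACY_TOL`).
    """
    d = theta - epsilon
    c = math.cos(d)
    if abs(c) < COS_DEGENERACY_TOL:
        return 0.0
    sn = math.sin(d)
    return (1.0 - sn) ** 2 * (2.0 + sn) / c**3


def shape_coefficient(theta: float, epsilon: float) -> float:
    """Volume shape factor ``C(theta, epsilon) = V / s^3``.

    ``C = (pi/3) * (cot(epsilon) + cap_shape_term)``; the first term is the
    cone below the contact circle, the second the signed spherical cap.
    """
    _check_theta(theta)
    _check_epsilon(epsilon)
    return math.pi / 3.0 * (1.0 / math.tan(epsilon) + cap_shape_term(theta, epsilon))


def cap_volume(s: float, theta: float, epsilon: float) -> float:
    """Gas volume (m^3) enclosed by cone apex, wall and spherical cap."""
    _check_positive("s", s)
    v = shape_coefficient(theta, epsilon) * s**3
    if v <= 0.0:
        # cannot occur for theta in [0, pi], epsilon in (0, pi/2); guard anyway
        raise ValueError(
            f"non-positive gas volume for s={s!r}, theta={theta!r}, epsilon={epsilon!r}"
        )
    return v


def cap_curvature(s: float, theta: float, epsilon: float) -> float:
    """Signed mean curvature ``H = cos(theta - epsilon) / s`` (1/m)."""
    _check_positive("s", s)
    _check_theta(theta)
    _check_epsilon(epsilon)
    return math.cos(theta - epsilon) / s


def interface_areas(s: float, theta: float, epsilon: float) -> tuple[float, float]:
    """Areas of the gas-side interfaces at contact radius ``s``.

    Returns ``(A_lg, A_sg)``: the liquid/gas spherical-cap area
    ``2 pi s^2 / (1 + sin(theta - epsilon))`` and the solid/gas lateral cone
    area ``pi s^2 / sin(epsilon)``.
    """
    _check_positive("s", s)
    _check_theta(theta)
    _check_epsilon(epsilon)
    denom = 1.0 + math.sin(theta - epsilon)
    if denom < 1e-12:
        raise ValueError(
            f"degenerate liquid/gas area denominator 1 + sin(theta - epsilon) = {denom!r}"
        )
    a_lg = 2.0 * math.pi * s**2 / denom
    a_sg = math.pi * s**2 / math.sin(epsilon)
    return a_lg, a_sg


def cap_state(s: float, theta: float, epsilon: float) -> CapState:
    """Assemble the complete :class:`CapState` at contact radius ``s``."""
    a_lg, a_sg = interface_areas(s, theta, epsilon)
    return CapState(
        s=s,
        theta=theta,
        epsilon=epsilon,
        V=cap_volume(s, theta, epsilon),
        H=cap_curvature(s, theta, epsilon),
        A_lg=a_lg,
        A_sg=a_sg,
    )


def cone_volume(cavity: ConeCavity) -> float:
    """Volume of the bare cone (m^3), ``(pi/3) s_c^3 cot(epsilon)``."""
    return math.pi / 3.0 * cavity.s_c**3 / math.tan(cavity.epsilon)


def pit_to_cone(pit: PitChamber) -> ConeCavity:
    """Map a pit chamber to its equivalent cone.

    Elongating the tilted chamber walls closes the funnel at its bottom,
    yielding a cone with the chamber's half-angle and mouth radius.  The pit
    channel only connects the chamber to the conduit and is discarded; any
    gas it might hold is not counted.
    """
    return ConeCavity(epsilon=pit.chamber_half_angle, s_c=pit.chamber_radius)
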