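"""Shared fixtures and independent oracles for the test-suite."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import conepocket as cp


@pytest.fixture(scope="session")
def iron_corundum():
    """Liquid iron on a corundum coating, ambient pressure 1 bar."""
    return cp.MATERIALS["iron-corundum"].system(p_l=1.0e5)


@pytest.fixture(scope="session")
def iron_copper():
    """Liquid iron on bare copper (wetting), ambient pressure 1 bar."""
    return cp.MATERIALS["iron-copper"].system(p_l=1.0e5)


@pytest.fixture(scope="session")
def prototype_cavity():
    """The tested prototype cone: mouth radius 2.5 mm, half-angle 30 deg."""
    return cp.ConeCavity(epsilon=math.radians(30.0), s_c=2.5e-3)


@pytest.fixture(scope="session")
def flat_case():
    """Constructed flat-interface equilibrium: theta - epsilon = 90 deg.

    With p_l = 1e5 Pa and nRT = (pi/3) * 1e-4 J the unique root is exactly
    s = 1 mm (H = 0, p_g = p_l).
    """
    system = cp.FluidSolidSystem(
        sigma=1.0, rho=1000.0, theta=math.radians(135.0), p_l=1.0e5
    )
    cavity = cp.ConeCavity(epsilon=math.radians(45.0), s_c=3.0e-3)
    return system, cavity, math.pi / 3.0 * 1.0e-4


@pytest.fixture(scope="session")
def scenario_suite():
    """Seeded scenario list spanning both criterion regimes and tension."""
    return cp.fixture_suite(seed=20260924 % 2**31)


def volume_by_quadrature(s: float, theta: float, epsilon: float) -> float:
    """Solid-of-revolution volume of the gas pocket, by numerical quadrature.

    Independent of the closed-form route: integrates pi*r(z)^2 along the
    axis over the cone below the contact circle, then adds (convex cap) or
    subtracts (concave cap) the quadrature of the spherical-cap profile.
    """
    tan_e = math.tan(epsilon)
    z_s = s / tan_e  # height of the contact circle above the apex
    cone, _ = quad(lambda z: math.pi * (z * tan_e) ** 2, 0.0, z_s)

    c = math.cos(theta - epsilon)
    if abs(c) < 1e-8:
        return cone
    R = s / abs(c)
    h = s * abs(c) / (1.0 + math.sin(theta - epsilon))  # cap height

    def sphere_slice(u):  # u: axial distance from the contact plane into the cap
        zc = h - R  # sphere centre, cap measured from its base
        return math.pi * (R**2 - (u - zc) ** 2)

    cap, _ = quad(sphere_slice, 0.0, h)
    return cone + cap if c > 0.0 else cone - cap


def angle_volume_grid(n_theta: int = 5, n_eps: int = 5, n_s: int = 4):
    """Deterministic (s, theta, epsilon) triples spanning the angle ranges."""
    thetas = np.radians(np.linspace(5.0, 175.0, n_theta))
    epsilons = np.radians(np.linspace(2.0, 84.0, n_eps))
    radii = np.array([5e-6, 1e-4, 1e-3, 4e-3])[:n_s]
    return [
        (float(s), float(t), float(e))
        for t in thetas
        for e in epsilons
        for s in radii
    ]
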