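"""Shared fixtures: analytic oracle curves and standard bead models."""

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import scrdimer as sd

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def sphere_intensity(q: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form scattering of a homogeneous sphere (unit I(0))."""
    x = q * radius
    return (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2


def sphere_pr(r: np.ndarray, radius: float) -> np.ndarray:
    """Closed-form distance distribution of a homogeneous sphere."""
    d = 2.0 * radius
    p = r**2 * (1.0 - 1.5 * r / d + 0.5 * (r / d) ** 3)
    return np.where(r <= d, np.clip(p, 0.0, None), 0.0)


@pytest.fixture(scope="session")
def sphere_curve():
    """Sphere of radius 2 nm on a wide Q grid (R_G = sqrt(3/5)*2 nm)."""
    q = np.linspace(0.05, 4.0, 300)
    return sd.ScatteringCurve(q, sphere_intensity(q, 2.0), label="sphere_r2")


@pytest.fixture(scope="session")
def guinier_curve():
    """Pure Guinier-law curve, R_G = 3 nm, I(0) = 100."""
    q = np.linspace(0.01, 0.8, 150)
    return sd.ScatteringCurve(q, 100.0 * np.exp(-(3.0**2) * q**2 / 3.0))


@pytest.fixture(scope="session")
def cylinder_curve():
    """Randomly oriented solid cylinder, R = 1 nm, L = 50 nm.

    Independent oracle for the cross-section fit: R_XS = R / sqrt(2).
    """
    from scipy.integrate import quad
    from scipy.special import j1

    def intensity(qq: float, R: float, L: float) -> float:
        def integrand(alpha: float) -> float:
            qa = qq * R * math.sin(alpha)
            ql = qq * L * math.cos(alpha) / 2.0
            fa = 2.0 * j1(qa) / qa if qa > 1e-9 else 1.0
            fl = math.sin(ql) / ql if abs(ql) > 1e-9 else 1.0
            return (fa * fl) ** 2 * math.sin(alpha)

        return quad(integrand, 0.0, math.pi / 2.0, limit=200)[0]

    q = np.linspace(0.05, 2.0, 250)
    return sd.ScatteringCurve(q, np.array([intensity(x, 1.0, 50.0) for x in q]))


@pytest.fixture
def two_domain_spec():
    return sd.FragmentSpec("SCR-19/20", (19, 20), 14700.0)


@pytest.fixture
def two_domain_model(two_domain_spec):
    return sd.build_fragment_model(two_domain_spec, seed=0)


@pytest.fixture(scope="session")
def observed_kd_panel():
    """The seven-fragment panel with its observed K_D values (uM)."""
    return [
        (sd.FragmentSpec("SCR-19/20", (19, 20), 14700.0), math.inf),
        (sd.FragmentSpec("SCR-18/20", (18, 19, 20), 24000.0), 590.0),
        (sd.FragmentSpec("SCR-16/20", (16, 17, 18, 19, 20), 38000.0), 31.0),
        (sd.FragmentSpec("SCR-16/18H", (16, 17, 18), 29000.0), 6.0),
        (sd.FragmentSpec("SCR-17/18H", (17, 18), 22000.0), 3.0),
        (sd.FragmentSpec("SCR-17H", (17,), 10000.0), 5.0),
        (sd.FragmentSpec("SCR-18H", (18,), 11000.0), 37.0),
    ]
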