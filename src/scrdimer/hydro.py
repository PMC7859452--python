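"""Bead-model hydrodynamics and sedimentation-coefficient conventions.

Sedimentation coefficients of bead models are computed with the
Kirkwood-Riseman double-sum approximation (bead radii inflated by a
0.31 nm hydration shell); experimental s values are standardized to
s_20,w, converted to frictional ratios f/f0, and inverted to molar
masses under the same hydration convention.

Svedberg units: 1 S = 1e-13 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .conventions import Conventions, WATER_20C
from .fragments import OVERLAP_TOLERANCE, BeadModel

__all__ = [
    "BufferSpec",
    "HydroResult",
    "kirkwood_s",
    "s_to_s20w",
    "f_over_f0",
    "mass_from_s_f",
    "diffusion_from_s_ff0",
]

_NM_TO_CM = 1e-7
_SVEDBERG = 1e-13  # s
_GAS_CONSTANT = 8.314462618e7  # erg / (mol K)


@dataclass(frozen=True)
class BufferSpec:
    """Solvent density (g/cm^3), viscosity (poise) and temperature (C)."""

    density: float
    viscosity: float
    temperature: float = 20.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


def water_20c_buffer(conventions: Conventions = WATER_20C) -> BufferSpec:
    return BufferSpec(
        density=conventions.solvent_density_20c,
        viscosity=conventions.solvent_viscosity_20c,
        temperature=20.0,
        label="water 20C",
    )


@dataclass
class HydroResult:
    s20w: float  # Svedberg
    f: float  # g/s
    f0: float  # g/s
    f_over_f0: float
    mass: float  # g/mol


def _stokes_f0(mass: float, conventions: Conventions) -> float:
    """Friction of the hydrated equal-volume sphere, g/s."""
    r_cm = conventions.hydrated_sphere_radius_nm(mass) * _NM_TO_CM
    return 6.0 * math.pi * conventions.solvent_viscosity_20c * r_cm


def kirkwood_s(
    model: BeadModel,
    mass: float,
    conventions: Conventions = WATER_20C,
    overlap_tolerance: float = OVERLAP_TOLERANCE,
) -> HydroResult:
    """Sedimentation coefficient of a bead model (Kirkwood approximation).

    Bead radii are inflated by the hydration shell radius; the translational
    friction is the generalized Kirkwood double sum

        f = 6 pi eta (sum a_i) / (1 + (sum a_i)^-1 sum_{i != j} a_i a_j / d_ij)

    and s = M (1 - vbar rho) / (N_A f) in water at 20 C.  f0 is the Stokes
    friction of the hydrated equal-volume sphere of the same mass.

    Raises ``ValueError`` if beads overlap beyond tolerance (the point-force
    approximation breaks down) or the mass is non-positive.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    ov = model.max_overlap()
    if ov > overlap_tolerance:
        raise ValueError(
            f"beads overlap by {ov:.3f} of the smaller radius; Kirkwood sum invalid"
        )
    eta = conventions.solvent_viscosity_20c
    a = (model.radii + conventions.hydration_shell_radius) * _NM_TO_CM
    sum_a = a.sum()
    if model.n_beads > 1:
        d = squareform(pdist(model.centers)) * _NM_TO_CM
        np.fill_diagonal(d, np.inf)
        double_sum = (np.outer(a, a) / d).sum()
    else:
        double_sum = 0.0
    f = 6.0 * math.pi * eta * sum_a / (1.0 + double_sum / sum_a)

    buoyancy = 1.0 - conventions.partial_specific_volume * conventions.solvent_density_20c
    s = mass * buoyancy / (conventions.avogadro * f)  # seconds
    f0 = _stokes_f0(mass, conventions)
    return HydroResult(
        s20w=s / _SVEDBERG, f=f, f0=f0, f_over_f0=f / f0, mass=mass
    )


def s_to_s20w(
    s_obs: float,
    buffer: BufferSpec,
    vbar: float | None = None,
    conventions: Conventions = WATER_20C,
) -> float:
    """Standardize an observed s (any buffer) to water at 20 C.

    s20w = s_obs * (eta_b / eta_20w) * (1 - vbar rho_20w) / (1 - vbar rho_b).
    """
    if vbar is None:
        vbar = conventions.partial_specific_volume
    num = 1.0 - vbar * conventions.solvent_density_20c
    den = 1.0 - vbar * buffer.density
    if den <= 0:
        raise ValueError("(1 - vbar * buffer density) must be positive")
    return s_obs * (buffer.viscosity / conventions.solvent_viscosity_20c) * num / den


_FF0_TOLERANCE = 0.03


def f_over_f0(
    s20w: float,
    mass: float,
    conventions: Conventions = WATER_20C,
) -> float:
    """Frictional ratio from a standardized sedimentation coefficient.

    f = M (1 - vbar rho) / (N_A s); f0 is the hydrated equal-volume-sphere
    friction.  Ratios below 1 beyond a small tolerance indicate a
    convention mismatch (e.g. wrong mass) and raise ``ValueError``.
    """
    if s20w <= 0 or mass <= 0:
        raise ValueError("s20w and mass must be positive")
    buoyancy = 1.0 - conventions.partial_specific_volume * conventions.solvent_density_20c
    f = mass * buoyancy / (conventions.avogadro * s20w * _SVEDBERG)
    ratio = f / _stokes_f0(mass, conventions)
    if ratio < 1.0 - _FF0_TOLERANCE:
        raise ValueError(
            f"f/f0 = {ratio:.3f} < 1: sedimentation faster than the hydrated "
            "sphere limit; check mass and hydration convention"
        )
    return ratio


def mass_from_s_f(
    s20w: float,
    ff0: float,
    conventions: Conventions = WATER_20C,
    max_iter: int = 100,
    rtol: float = 1e-12,
) -> float:
    """Molar mass from (s20w, f/f0) by fixed-point iteration.

    Inverts s = M (1 - vbar rho) / (N_A * ff0 * f0(M)) where f0 depends on
    M through the hydrated sphere radius; M scales as s^(3/2) at fixed
    shape.  Used to label species-distribution peaks as monomer or dimer.
    """
    if s20w <= 0:
        raise ValueError("s20w must be positive")
    if ff0 < 1.0 - _FF0_TOLERANCE:
        raise ValueError("f/f0 < 1 is unphysical")
    buoyancy = 1.0 - conventions.partial_specific_volume * conventions.solvent_density_20c
    s_sec = s20w * _SVEDBERG
    m = 2e4  # starting guess, g/mol
    for _ in range(max_iter):
        f = ff0 * _stokes_f0(m, conventions)
        m_new = conventions.avogadro * s_sec * f / buoyancy
        if abs(m_new - m) <= rtol * m:
            return m_new
        m = m_new
    raise RuntimeError("mass_from_s_f did not converge in 100 iterations")


def diffusion_from_s_ff0(
    s20w: float,
    ff0: float,
    conventions: Conventions = WATER_20C,
    temperature_c: float = 20.0,
) -> float:
    """Diffusion coefficient (cm^2/s) consistent with (s, f/f0).

    Uses the Svedberg relation D = s R T / (M (1 - vbar rho)) with M from
    :func:`mass_from_s_f`.
    """
    mass = mass_from_s_f(s20w, ff0, conventions)
    buoyancy = 1.0 - conventions.partial_specific_volume * conventions.solvent_density_20c
    t_kelvin = temperature_c + 273.15
    return s20w * _SVEDBERG * _GAS_CONSTANT * t_kelvin / (mass * buoyancy)
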