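"""Forward simulation of sedimentation-velocity experiments.

Two forward models for the concentration profile of an ideal,
non-interacting species in a sector-shaped ultracentrifuge cell:

* :func:`lamm_fd` — a Claverie-style conservative finite-difference
  solution of the Lamm equation on a fixed radial grid with an explicit
  time step under a CFL guard (the default forward model);
* :func:`faxen_boundary` — the Faxén approximate closed form, a moving
  erf-shaped boundary at r_mid(t) = r_meniscus * exp(s w^2 t) with
  square-root-of-time diffusional spreading and e^(-2 s w^2 t) radial
  dilution (fast path; also used to build inversion dictionaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import erf

__all__ = [
    "SedimentationRun",
    "default_run_geometry",
    "faxen_boundary",
    "lamm_fd",
    "simulate_sv_run",
    "boundary_midpoints",
]

_SVEDBERG = 1e-13  # s


@dataclass
class SedimentationRun:
    """Radial scans of a sedimentation-velocity cell.

    ``signals`` has shape (n_times, n_radii); ``rotor_speed`` is the
    angular velocity in rad/s; ``meniscus`` and ``base`` bound the solution
    column in cm.
    """

    radii: np.ndarray  # cm
    times: np.ndarray  # s
    signals: np.ndarray | None = None  # (time, radius)
    rotor_speed: float = 50000.0 * 2.0 * math.pi / 60.0  # rad/s (50,000 rpm)
    meniscus: float = 6.0
    base: float = 7.2
    temperature: float = 20.0

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.times = np.asarray(self.times, dtype=float).ravel()
        if np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if self.meniscus >= self.base:
            raise ValueError("meniscus must lie below (inside) the base")
        if self.rotor_speed <= 0:
            raise ValueError("rotor speed must be positive")
        if self.signals is not None:
            self.signals = np.asarray(self.signals, dtype=float)
            if self.signals.shape != (self.times.size, self.radii.size):
                raise ValueError("signals must have shape (n_times, n_radii)")

    @property
    def omega2(self) -> float:
        return self.rotor_speed**2


def default_run_geometry(
    n_radii: int = 200,
    n_scans: int = 20,
    t_first: float = 600.0,
    t_last: float = 12000.0,
    meniscus: float = 6.0,
    base: float = 7.2,
    rpm: float = 50000.0,
) -> SedimentationRun:
    """A typical small-protein SV geometry: 12 mm column, 50,000 rpm."""
    return SedimentationRun(
        radii=np.linspace(meniscus, base, n_radii),
        times=np.linspace(t_first, t_last, n_scans),
        rotor_speed=rpm * 2.0 * math.pi / 60.0,
        meniscus=meniscus,
        base=base,
    )


def faxen_boundary(
    s: float,
    d: float,
    run: SedimentationRun,
    c0: float = 1.0,
) -> np.ndarray:
    """Faxén approximate solution for one ideal species.

    Parameters
    ----------
    s : sedimentation coefficient in Svedberg.
    d : diffusion coefficient in cm^2/s (0 gives a sharp step boundary).
    """
    if s <= 0:
        raise ValueError("s must be positive")
    if d < 0:
        raise ValueError("D must be non-negative")
    s_sec = s * _SVEDBERG
    w2 = run.omega2
    r = run.radii[None, :]
    t = run.times[:, None]
    r_mid = run.meniscus * np.exp(s_sec * w2 * t)
    plateau = c0 * np.exp(-2.0 * s_sec * w2 * t)
    if d == 0:
        shape = (r >= r_mid).astype(float)
    else:
        spread = 2.0 * np.sqrt(d * np.maximum(t, 1e-30))
        shape = 0.5 * (1.0 + erf((r - r_mid) / spread))
    out = plateau * shape
    out[run.times == 0.0, :] = c0
    return out


def lamm_fd(
    s: float,
    d: float,
    run: SedimentationRun,
    c0: float = 1.0,
    n_grid: int = 200,
    safety: float = 0.4,
) -> np.ndarray:
    """Finite-difference solution of the ideal Lamm equation.

    Conservative finite-volume discretization of

        dc/dt = (1/r) d/dr [ r ( D dc/dr - s w^2 r c ) ]

    on ``n_grid`` radial cells between meniscus and base, explicit Euler
    stepping under a CFL guard (``safety`` times the stability limit).
    Advection uses central face averages when the cell Peclet number
    v dr / D stays below 2 (stable and free of numerical diffusion) and
    falls back to first-order upwinding otherwise.  Returns signals
    interpolated onto ``run.radii`` at ``run.times``.
    """
    if s <= 0 or d < 0:
        raise ValueError("need s > 0 and D >= 0")
    s_sec = s * _SVEDBERG
    w2 = run.omega2
    rm, rb = run.meniscus, run.base
    edges = np.linspace(rm, rb, n_grid + 1)
    r_cell = 0.5 * (edges[:-1] + edges[1:])
    dr = edges[1] - edges[0]
    r_face = edges[1:-1]  # interior faces

    v_face = s_sec * w2 * r_face  # outward advection velocity, cm/s
    dt_adv = dr / max(v_face.max(), 1e-30)
    dt_dif = dr**2 / (2.0 * d) if d > 0 else np.inf
    dt = safety * min(dt_adv, dt_dif)
    peclet = v_face.max() * dr / d if d > 0 else np.inf
    central = peclet < 2.0

    c = np.full(n_grid, float(c0))
    out = np.empty((run.times.size, run.radii.size))
    t_now = 0.0
    order = np.argsort(run.times)
    for idx in order:
        t_target = run.times[idx]
        while t_now < t_target - 1e-12:
            step = min(dt, t_target - t_now)
            # interior face fluxes: advection + central diffusion
            if central:
                adv = v_face * 0.5 * (c[:-1] + c[1:])
            else:  # upwind from the inner (centripetal) cell
                adv = v_face * c[:-1]
            dif = -d * (c[1:] - c[:-1]) / dr if d > 0 else 0.0
            flux = r_face * (adv + dif)  # r * J at faces
            div = np.zeros(n_grid)
            div[:-1] += flux
            div[1:] -= flux
            # closed ends: zero flux at meniscus and base
            c = c - step * div / (r_cell * dr)
            np.clip(c, 0.0, None, out=c)
            t_now += step
        out[idx] = np.interp(run.radii, r_cell, c)
    return out


def simulate_sv_run(
    species: Sequence[tuple[float, float, float]],
    run: SedimentationRun,
    noise_level: float = 0.005,
    seed: int = 0,
    c0: float = 1.0,
    method: str = "fd",
) -> SedimentationRun:
    """Superpose ideal species into a noisy sedimentation-velocity run.

    ``species`` is a sequence of ``(s_svedberg, D_cm2_s, fraction)``; the
    fractions must sum to 1.  Additive Gaussian noise with standard
    deviation ``noise_level * c0`` (relative to the initial plateau) is
    applied with the given seed.
    """
    if not species:
        raise ValueError("need at least one species")
    fractions = np.array([sp[2] for sp in species], dtype=float)
    if abs(fractions.sum() - 1.0) > 1e-8:
        raise ValueError("species fractions must sum to 1")
    solver = {"fd": lamm_fd, "faxen": faxen_boundary}[method]
    signals = np.zeros((run.times.size, run.radii.size))
    for s, d_coef, frac in species:
        if s <= 0 or d_coef < 0:
            raise ValueError("non-physical s or D")
        signals += frac * solver(s, d_coef, run, c0=c0)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        signals = signals + rng.normal(0.0, noise_level * c0, signals.shape)
    return SedimentationRun(
        radii=run.radii.copy(),
        times=run.times.copy(),
        signals=signals,
        rotor_speed=run.rotor_speed,
        meniscus=run.meniscus,
        base=run.base,
        temperature=run.temperature,
    )


def boundary_midpoints(run: SedimentationRun, plateau: np.ndarray | None = None) -> np.ndarray:
    """Radius where each scan crosses half its plateau signal.

    ``plateau`` may supply the theoretical plateau per scan; otherwise the
    mean signal over the 0.55-0.80 fractional span of the column is used —
    outboard of the boundary for typical scan times but clear of the
    solute pile-up at the base.  Returns nan for scans without a crossing.
    """
    if run.signals is None:
        raise ValueError("run has no signals")
    n_t = run.times.size
    mids = np.full(n_t, np.nan)
    span = run.radii[-1] - run.radii[0]
    outer = (run.radii >= run.radii[0] + 0.55 * span) & (
        run.radii <= run.radii[0] + 0.80 * span
    )
    for i in range(n_t):
        sig = run.signals[i]
        p = plateau[i] if plateau is not None else sig[outer].mean()
        half = 0.5 * p
        above = sig >= half
        if above.all() or not above.any():
            continue
        j = int(np.argmax(above))
        if j == 0:
            continue
        x0, x1 = run.radii[j - 1], run.radii[j]
        y0, y1 = sig[j - 1], sig[j]
        mids[i] = x0 + (half - y0) * (x1 - x0) / (y1 - y0) if y1 != y0 else x1
    return mids
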