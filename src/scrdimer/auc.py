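"""Sedimentation-coefficient distributions from sedimentation boundaries.

A documented, simplified stand-in for full c(s) analysis: the scan set is
decomposed by non-negative Tikhonov-regularized least squares (ls-g*(s)
style) against a dictionary of ideal single-species Lamm boundaries on an
s grid (finite-difference by default, Faxén closed form as a fast path).  Diffusion within the dictionary is either switched off (pure
apparent distribution) or tied to a fixed frictional ratio f/f0, from
which each s value's diffusion coefficient follows through the Svedberg
relation.  Meniscus and baseline are taken from the run metadata; they
are not floated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import nnls

from .conventions import Conventions, WATER_20C
from .hydro import diffusion_from_s_ff0
from .sedimentation import SedimentationRun, faxen_boundary, lamm_fd

__all__ = ["SpeciesDistribution", "Peak", "lsg_distribution", "integrate_peaks"]

#: default Tikhonov weight; see methods note for the calibration sweep
DEFAULT_ALPHA = 0.005


@dataclass
class Peak:
    label: str
    s_center: float  # Svedberg, weight-averaged within the window
    fraction: float
    window: tuple[float, float]


@dataclass
class SpeciesDistribution:
    """Apparent sedimentation-coefficient distribution g*(s)."""

    s_grid: np.ndarray  # Svedberg
    weights: np.ndarray  # signal units per S, >= 0
    alpha: float
    diffusion_model: str = "none"
    ff0: float | None = None
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.s_grid = np.asarray(self.s_grid, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.s_grid.shape != self.weights.shape:
            raise ValueError("s_grid and weights must have the same shape")
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be non-negative")


def lsg_distribution(
    run: SedimentationRun,
    s_grid: np.ndarray | None = None,
    alpha: float = DEFAULT_ALPHA,
    diffusion_model: str = "fixed_ff0",
    ff0: float = 1.4,
    conventions: Conventions = WATER_20C,
    edge_margin: float = 0.06,
    base_margin: float = 0.15,
    dictionary: str = "fd",
) -> SpeciesDistribution:
    """Invert a scan set into an apparent s distribution.

    Parameters
    ----------
    run : SedimentationRun with ``signals`` filled.
    s_grid : s values (Svedberg) of the dictionary; defaults to 60 points
        on [0.5, 8].
    alpha : second-difference regularization weight (relative to the
        dictionary scale).
    diffusion_model : ``"none"`` for sharp step boundaries (apparent
        ls-g*(s)), ``"fixed_ff0"`` to give every dictionary species the
        diffusion coefficient implied by its s and a common f/f0.
    edge_margin, base_margin : cm trimmed at the meniscus and at the base
        respectively; the ideal boundary model ignores back-diffusion from
        the solute pile-up at the base, so the base trim is wider.
    dictionary : ``"fd"`` solves the Lamm equation per dictionary species
        (accurate); ``"faxen"`` uses the approximate closed form (faster
        but with a small systematic boundary-shape error).

    Raises ``ValueError`` on missing/rank-deficient data or a silent cell.
    """
    if run.signals is None:
        raise ValueError("run carries no signals")
    if run.times.size < 10:
        raise ValueError("need at least 10 scans for a stable inversion")
    if s_grid is None:
        s_grid = np.linspace(0.5, 8.0, 60)
    s_grid = np.asarray(s_grid, dtype=float)
    if np.any(s_grid <= 0) or np.any(np.diff(s_grid) <= 0):
        raise ValueError("s_grid must be positive and increasing")
    if diffusion_model not in ("none", "fixed_ff0"):
        raise ValueError(f"unknown diffusion_model {diffusion_model!r}")

    keep = (run.radii >= run.meniscus + edge_margin) & (
        run.radii <= run.base - base_margin
    )
    if keep.sum() < 10:
        raise ValueError("too few radii inside the trimmed window")
    sub = SedimentationRun(
        radii=run.radii[keep],
        times=run.times,
        rotor_speed=run.rotor_speed,
        meniscus=run.meniscus,
        base=run.base,
        temperature=run.temperature,
    )
    y = run.signals[:, keep].ravel()
    if np.max(np.abs(y)) <= 0:
        raise ValueError("no signal in the scan set")

    if dictionary not in ("fd", "faxen"):
        raise ValueError(f"unknown dictionary solver {dictionary!r}")
    solver = lamm_fd if dictionary == "fd" else faxen_boundary
    cols = []
    for s in s_grid:
        if diffusion_model == "fixed_ff0":
            d = diffusion_from_s_ff0(s, ff0, conventions, run.temperature)
        else:
            d = 0.0
        cols.append(solver(s, d, sub).ravel())
    b = np.column_stack(cols)

    n = s_grid.size
    d2 = np.zeros((n, n))
    for i in range(n):
        d2[i, i] = -2.0
        if i > 0:
            d2[i, i - 1] = 1.0
        if i < n - 1:
            d2[i, i + 1] = 1.0
    scale = np.linalg.norm(b, ord="fro") / math.sqrt(n)
    stacked = np.vstack([b, alpha * scale * d2])
    rhs = np.concatenate([y, np.zeros(n)])
    w, _ = nnls(stacked, rhs, maxiter=20 * max(stacked.shape))
    if w.sum() <= 0:
        raise ValueError("inversion returned an empty distribution")

    dist = SpeciesDistribution(
        s_grid=s_grid,
        weights=w,
        alpha=alpha,
        diffusion_model=diffusion_model,
        ff0=ff0 if diffusion_model == "fixed_ff0" else None,
    )
    dist.peaks = integrate_peaks(dist, "auto")
    return dist


# ----------------------------------------------------------------------
# peak integration
# ----------------------------------------------------------------------

def _significant_maxima(s: np.ndarray, w: np.ndarray, rel_height: float = 0.02):
    """Indices of local maxima above ``rel_height`` of the global maximum."""
    wmax = w.max()
    idx = []
    for i in range(w.size):
        left = w[i - 1] if i > 0 else -np.inf
        right = w[i + 1] if i < w.size - 1 else -np.inf
        if w[i] >= left and w[i] > right and w[i] >= rel_height * wmax:
            idx.append(i)
    # merge flat-topped plateaus: keep the first index of each run
    merged = []
    for i in idx:
        if merged and i - merged[-1] == 1 and np.isclose(w[i], w[merged[-1]]):
            continue
        merged.append(i)
    return merged


def integrate_peaks(
    dist: SpeciesDistribution,
    boundaries: Sequence[float] | str = "auto",
) -> list[Peak]:
    """Split the distribution into peaks and integrate their fractions.

    ``boundaries="auto"`` places cut points at the valley minimum between
    consecutive significant maxima (ties broken toward the lower-s
    valley); explicit boundaries are s cut points inside the grid.
    Fractions are trapezoidal areas normalized by the total area and sum
    to 1 by construction.
    """
    s, w = dist.s_grid, dist.weights
    total = np.trapezoid(w, s)
    if total <= 0:
        raise ValueError("distribution has zero total area")

    if isinstance(boundaries, str):
        if boundaries != "auto":
            raise ValueError(f"unknown boundary mode {boundaries!r}")
        maxima = _significant_maxima(s, w)
        cuts: list[float] = []
        for a, b in zip(maxima, maxima[1:]):
            valley = a + int(np.argmin(w[a : b + 1]))
            cuts.append(float(s[valley]))
    else:
        cuts = sorted(float(c) for c in boundaries)
        for c in cuts:
            if not (s[0] < c < s[-1]):
                raise ValueError(f"peak boundary {c} S lies outside the s grid")

    edges = [s[0], *cuts, s[-1]]
    peaks: list[Peak] = []
    for k, (lo, hi) in enumerate(zip(edges, edges[1:])):
        m = (s >= lo) & (s <= hi)
        if m.sum() < 2:
            continue
        area = np.trapezoid(w[m], s[m])
        frac = float(area / total)
        center = float(np.trapezoid(w[m] * s[m], s[m]) / area) if area > 0 else 0.5 * (lo + hi)
        peaks.append(Peak(label=f"peak{k + 1}", s_center=center, fraction=frac, window=(float(lo), float(hi))))
    if not peaks:
        raise ValueError("no integrable peaks found")
    # renormalize against truncation of sub-threshold segments
    ssum = sum(p.fraction for p in peaks)
    for p in peaks:
        p.fraction /= ssum
    return peaks
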