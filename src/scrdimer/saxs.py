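"""Small-angle X-ray scattering analysis.

Implements the standard solution-scattering toolkit for elongated
multi-domain proteins:

* Guinier fit ``ln I(Q) = ln I(0) - R_G^2 Q^2 / 3`` with a self-consistent
  low-Q window bounded by ``Q.R_G <= max_qrg`` (default 1.5);
* rod cross-section fit ``ln(I(Q) Q) = const - R_XS^2 Q^2 / 2`` over an
  intermediate-Q window bounded by ``Q.R_XS`` limits;
* regularized indirect Fourier transform to the distance distribution
  P(r), reporting the maximum dimension L, the modal distance M, and the
  real-space R_G;
* the elongation ratio R_G / R_O, where R_O is the R_G of a sphere with
  the hydrated volume of the protein.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .conventions import Conventions, WATER_20C

__all__ = [
    "ScatteringCurve",
    "GuinierFit",
    "PrDistribution",
    "guinier_fit",
    "cross_section_fit",
    "ift_pr",
    "rg_ro_ratio",
]


@dataclass
class ScatteringCurve:
    """A one-dimensional scattering profile I(Q).

    ``q`` is the momentum transfer in 1/nm (strictly increasing, positive);
    ``sigma`` is the optional per-point uncertainty in the same units as
    ``intensity``.
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    label: str = ""
    concentration: float | None = None  # mg/ml

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).ravel()
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        if self.q.size != self.intensity.size:
            raise ValueError("q and intensity must have equal length")
        if self.q.size == 0:
            raise ValueError("empty curve")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float).ravel()
            if self.sigma.size != self.q.size:
                raise ValueError("sigma must match q in length")

    def __len__(self) -> int:
        return self.q.size

    def crop(self, q_min: float = -np.inf, q_max: float = np.inf) -> "ScatteringCurve":
        m = (self.q >= q_min) & (self.q <= q_max)
        if not m.any():
            raise ValueError("crop window contains no points")
        return ScatteringCurve(
            self.q[m],
            self.intensity[m],
            None if self.sigma is None else self.sigma[m],
            label=self.label,
            concentration=self.concentration,
        )


@dataclass
class GuinierFit:
    """Result of a Guinier-type linear fit.

    ``kind`` is ``"rg"`` for the overall radius of gyration and ``"rxs"``
    for the rod cross-section; for the latter ``rxs`` carries the value and
    ``rg`` is set equal to it for convenience.
    """

    rg: float
    i0: float
    q_window: tuple[float, float]
    max_qrg: float
    n_points: int
    residual_rms: float
    kind: str = "rg"
    rxs: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class PrDistribution:
    """Real-space distance distribution with derived scalar descriptors."""

    r: np.ndarray
    p: np.ndarray
    dmax: float  # maximum dimension L (support end)
    mode: float  # most frequent distance M
    rg_real: float
    i0_real: float
    alpha: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.p = np.asarray(self.p, dtype=float)


# ----------------------------------------------------------------------
# Guinier analysis
# ----------------------------------------------------------------------

def _wlsq_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Weighted least squares line y = a + b x; returns (a, b, rms)."""
    sw = w.sum()
    xm = (w * x).sum() / sw
    ym = (w * y).sum() / sw
    sxx = (w * (x - xm) ** 2).sum()
    if sxx <= 0:
        raise ValueError("degenerate abscissa in linear fit")
    b = (w * (x - xm) * (y - ym)).sum() / sxx
    a = ym - b * xm
    resid = y - (a + b * x)
    rms = float(np.sqrt((w * resid**2).sum() / sw))
    return float(a), float(b), rms


_SLOPE_TOL = 1e-9  # slopes in (-tol, +inf) of this size are treated as flat


def guinier_fit(
    curve: ScatteringCurve,
    max_qrg: float = 1.5,
    q_min_hint: float | None = None,
    min_points: int = 5,
) -> GuinierFit:
    """Self-consistent Guinier fit of ln I versus Q^2 at low Q.

    Starting from the first positive-intensity point (or ``q_min_hint``),
    the window is extended to the largest upper limit satisfying
    ``q_max * R_G <= max_qrg``, iterating the fitted R_G to convergence and
    breaking ties toward the wider window.

    Returns R_G = sqrt(-3 * slope) and I(0) = exp(intercept).  A flat curve
    yields ``rg = 0`` with a ``"flat"`` flag; a rising curve raises
    ``ValueError``.
    """
    q, I = curve.q, curve.intensity
    pos = I > 0
    start = int(np.argmax(pos)) if pos.any() else 0
    if q_min_hint is not None:
        start = max(start, int(np.searchsorted(q, q_min_hint)))
    q, I = q[start:], I[start:]
    sig = None if curve.sigma is None else curve.sigma[start:]
    good = I > 0
    if good.sum() < 10:
        raise ValueError("need at least 10 positive low-Q points for a Guinier fit")
    # keep the leading run of positive intensities
    n_lead = int(np.argmin(good)) if not good.all() else good.size
    q, I = q[:n_lead], I[:n_lead]
    sig = None if sig is None else sig[:n_lead]

    x = q**2
    y = np.log(I)
    if sig is None:
        w_all = np.ones_like(x)
    else:
        s = np.where(sig > 0, sig, np.inf)
        w_all = (I / s) ** 2  # sigma_lnI = sigma / I
        if not np.any(w_all > 0):
            w_all = np.ones_like(x)

    end = q.size  # exclusive
    prev_ends: list[int] = []
    a = b = rms = 0.0
    for _ in range(60):
        if end < min_points:
            raise ValueError("Guinier window shrank below the minimum point count")
        a, b, rms = _wlsq_line(x[:end], y[:end], w_all[:end])
        if b > _SLOPE_TOL:
            raise ValueError("non-decaying curve: positive Guinier slope")
        rg = math.sqrt(max(-3.0 * b, 0.0))
        if rg == 0.0:
            new_end = q.size  # flat: the whole range is admissible
        else:
            new_end = int(np.searchsorted(q, max_qrg / rg, side="right"))
            new_end = max(new_end, min_points)
            new_end = min(new_end, q.size)
        if new_end == end:
            break
        if new_end in prev_ends:  # oscillation: take the wider window
            end = max(end, new_end)
            a, b, rms = _wlsq_line(x[:end], y[:end], w_all[:end])
            break
        prev_ends.append(end)
        end = new_end

    rg = math.sqrt(max(-3.0 * b, 0.0))
    flags = ["flat"] if rg == 0.0 else []
    return GuinierFit(
        rg=rg,
        i0=math.exp(a),
        q_window=(float(q[0]), float(q[end - 1])),
        max_qrg=max_qrg,
        n_points=end,
        residual_rms=rms,
        kind="rg",
        flags=flags,
    )


def cross_section_fit(
    curve: ScatteringCurve,
    max_qrxs: float = 1.0,
    min_qrxs: float = 0.4,
    window: tuple[float, float] | None = None,
    min_points: int = 5,
) -> GuinierFit:
    """Rod cross-section Guinier fit: ln(I Q) vs Q^2, R_XS = sqrt(-2 slope).

    If no explicit ``window`` is given, the fit starts above the overall
    Guinier region (Q.R_G > 1.5) and the limits are iterated to satisfy
    ``min_qrxs <= Q.R_XS <= max_qrxs``.  Fits with strong residual
    curvature are flagged ``"no_rod_plateau"`` — the cross-section
    approximation only holds for elongated particles.
    """
    if window is not None:
        sub = curve.crop(*window)
    else:
        try:
            g = guinier_fit(curve)
            q_lo = 1.5 / g.rg if g.rg > 0 else curve.q[0]
        except ValueError:
            q_lo = curve.q[0]
        sub = curve.crop(q_min=q_lo)

    for _ in range(40):
        m = sub.intensity > 0
        if m.sum() < min_points:
            raise ValueError("cross-section window shrank below the minimum point count")
        q, I = sub.q[m], sub.intensity[m]
        sig = None if sub.sigma is None else sub.sigma[m]
        x = q**2
        y = np.log(I * q)
        w = np.ones_like(x) if sig is None else np.where(sig > 0, (I / sig) ** 2, 0.0)
        if not np.any(w > 0):
            w = np.ones_like(x)
        a, b, rms = _wlsq_line(x, y, w)
        if b >= 0:
            raise ValueError("positive cross-section slope: no rod-like decay")
        rxs = math.sqrt(-2.0 * b)
        if window is not None:
            break
        lo, hi = min_qrxs / rxs, max_qrxs / rxs
        new = curve.crop(q_min=max(lo, curve.q[0]), q_max=hi)
        if new.q.size == sub.q.size and np.allclose(new.q[[0, -1]], sub.q[[0, -1]]):
            sub = new
            break
        sub = new

    # curvature check: does a quadratic term in Q^2 explain much more?
    flags: list[str] = []
    try:
        coef = np.polyfit(x, y, 2)
        resid2 = y - np.polyval(coef, x)
        rms2 = float(np.sqrt(np.mean(resid2**2)))
        if rms > 0.02 and rms2 < 0.5 * rms:
            flags.append("no_rod_plateau")
    except np.linalg.LinAlgError:  # pragma: no cover - tiny windows
        pass

    return GuinierFit(
        rg=rxs,
        i0=math.exp(a),
        q_window=(float(q[0]), float(q[-1])),
        max_qrg=max_qrxs,
        n_points=int(q.size),
        residual_rms=rms,
        kind="rxs",
        rxs=rxs,
        flags=flags,
    )


# ----------------------------------------------------------------------
# indirect Fourier transform
# ----------------------------------------------------------------------

def _ift_design(q: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Design matrix A with I(Q) = A @ p for p sampled on r (trapezoid)."""
    dr = r[1] - r[0]
    qr = np.outer(q, r)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(qr > 1e-12, np.sin(qr) / qr, 1.0)
    w = np.full(r.size, dr)
    w[0] = w[-1] = dr / 2
    return k * w


def _second_difference(n: int) -> np.ndarray:
    """Second-difference operator on interior nodes with zero end conditions."""
    d = np.zeros((n, n))
    for i in range(n):
        d[i, i] = -2.0
        if i > 0:
            d[i, i - 1] = 1.0
        if i < n - 1:
            d[i, i + 1] = 1.0
    return d


def _ift_solve(aw: np.ndarray, yw: np.ndarray, d2: np.ndarray, alpha: float):
    n = aw.shape[1]
    stacked = np.vstack([aw, math.sqrt(alpha) * d2])
    rhs = np.concatenate([yw, np.zeros(n)])
    p, _ = nnls(stacked, rhs, maxiter=10 * n)
    resid = float(np.linalg.norm(aw @ p - yw))
    rough = float(np.linalg.norm(d2 @ p))
    return p, resid, rough


def ift_pr(
    curve: ScatteringCurve,
    dmax: float,
    n_r: int = 201,
    alpha: float | None = None,
) -> PrDistribution:
    """Regularized indirect Fourier transform of I(Q) to P(r).

    Solves a non-negative least-squares inversion of
    ``I(Q) = integral P(r) sin(Qr)/(Qr) dr`` on ``[0, dmax]`` with a
    second-difference smoothness penalty (weight ``alpha``) and implicit
    endpoint conditions P(0) = P(dmax) = 0.  When ``alpha`` is not given it
    is chosen by an L-curve corner search over a logarithmic grid.

    Returns the distribution together with the real-space R_G, the modal
    distance M (parabolically refined argmax), the support end L (smallest
    r beyond which P stays below 1% of its peak) and I(0).
    """
    if dmax <= 0:
        raise ValueError("dmax must be positive")
    if curve.q[-1] * dmax < math.pi:
        raise ValueError("curve does not span Q*dmax >= pi; cannot invert")

    r = np.linspace(0.0, dmax, n_r)
    a_full = _ift_design(curve.q, r)
    # endpoint constraints: drop first and last columns (P=0 there)
    a = a_full[:, 1:-1]
    y = curve.intensity.copy()
    if curve.sigma is not None and np.all(curve.sigma > 0):
        wt = 1.0 / curve.sigma
    else:
        wt = np.ones_like(y) / max(abs(y).max(), 1e-300)
    aw = a * wt[:, None]
    yw = y * wt
    d2 = _second_difference(a.shape[1])

    # scale-aware alpha grid
    a_norm = np.linalg.norm(aw, ord="fro") ** 2 / a.shape[1]
    if alpha is None:
        grid = a_norm * np.logspace(-6, 1, 12)
        log_rho, log_eta, sols = [], [], []
        for al in grid:
            p, resid, rough = _ift_solve(aw, yw, d2, al)
            log_rho.append(math.log10(max(resid, 1e-300)))
            log_eta.append(math.log10(max(rough, 1e-300)))
            sols.append(p)
        # discrete L-curve corner: maximum curvature of (log_rho, log_eta)
        best, best_curv = len(grid) // 2, -np.inf
        for i in range(1, len(grid) - 1):
            v1 = np.array([log_rho[i] - log_rho[i - 1], log_eta[i] - log_eta[i - 1]])
            v2 = np.array([log_rho[i + 1] - log_rho[i], log_eta[i + 1] - log_eta[i]])
            cross = v1[0] * v2[1] - v1[1] * v2[0]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            curv = cross / denom if denom > 0 else 0.0
            if curv > best_curv:
                best_curv, best = curv, i
        alpha_used = float(grid[best])
        p_in = sols[best]
    else:
        alpha_used = float(alpha)
        p_in, _, _ = _ift_solve(aw, yw, d2, alpha_used)

    p = np.zeros(n_r)
    p[1:-1] = p_in
    if p.max() <= 0:
        raise ValueError("IFT produced an all-zero distribution")

    dr = r[1] - r[0]
    total = np.trapezoid(p, r)
    rg_real = math.sqrt(np.trapezoid(r**2 * p, r) / (2.0 * total))
    i0_real = float(total)  # same arbitrary scale as the design matrix

    # modal distance with parabolic refinement
    im = int(np.argmax(p))
    mode = r[im]
    if 0 < im < n_r - 1:
        y0, y1, y2 = p[im - 1], p[im], p[im + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            mode = r[im] + 0.5 * dr * (y0 - y2) / denom

    # support end: last r where p exceeds 1% of the peak
    above = np.nonzero(p > 0.01 * p.max())[0]
    support_end = float(r[min(above[-1] + 1, n_r - 1)])

    return PrDistribution(
        r=r,
        p=p,
        dmax=support_end,
        mode=float(mode),
        rg_real=rg_real,
        i0_real=i0_real,
        alpha=alpha_used,
    )


# ----------------------------------------------------------------------
# elongation ratio
# ----------------------------------------------------------------------

def rg_ro_ratio(
    rg: float,
    monomer_mass: float,
    conventions: Conventions = WATER_20C,
) -> float:
    """Elongation ratio R_G / R_O.

    R_O is the radius of gyration of a sphere with the hydrated volume of
    the *monomer*: V_h = M (vbar + hydration) / N_A.  The monomer mass is
    used even when ``rg`` belongs to a dimer species — the ratio then
    measures the elongation of the dimer relative to the monomer's
    reference sphere, the convention under which published monomer and
    dimer ratios are mutually consistent.
    """
    if rg <= 0 or monomer_mass <= 0:
        raise ValueError("rg and monomer_mass must be positive")
    r_sphere = conventions.hydrated_sphere_radius_nm(monomer_mass)
    r_o = math.sqrt(3.0 / 5.0) * r_sphere
    return rg / r_o
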