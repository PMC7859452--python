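"""Theoretical scattering from bead models and R-factor model ranking.

The forward model is the exact Debye double sum over beads with
uniform-sphere form-factor amplitudes; candidate models are compared to an
experimental curve with the normalized absolute-deviation R-factor

    R = 100 * sum_i |I_exp(Q_i) - c * I_model(Q_i)| / sum_i |I_exp(Q_i)|

after an optional one-parameter scale fit, and ranked after a radius-of-
gyration pre-filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist

from .fragments import BeadModel
from .saxs import GuinierFit, ScatteringCurve, guinier_fit

__all__ = ["ModelFitResult", "debye_intensity", "r_factor", "rank_models"]


@dataclass
class ModelFitResult:
    model_id: str
    r_factor: float  # percent
    scale: float
    model_rg: float  # nm
    passed_filter: bool


def _sphere_amplitude(x: np.ndarray) -> np.ndarray:
    """Normalized uniform-sphere amplitude 3(sin x - x cos x)/x^3."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    out = 3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3
    return np.where(small, 1.0 - x**2 / 10.0, out)


def debye_intensity(
    model: BeadModel, q_grid: np.ndarray, chunk: int = 64
) -> ScatteringCurve:
    """Exact Debye-sum scattering curve of a bead model.

    I(Q) = sum_ij F_i(Q) F_j(Q) sin(Q d_ij)/(Q d_ij), with
    F_i(Q) = V_i * Phi(Q a_i) and a_i = (3 V_i / 4 pi)^(1/3) the scattering
    radius of bead i.  At Q = 0 this reduces to (sum_i V_i)^2.

    O(N^2) in the bead count; evaluated in q-chunks to bound memory.
    """
    q = np.asarray(q_grid, dtype=float).ravel()
    if model.n_beads == 0:
        raise ValueError("empty model")
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    a_sc = (3.0 * model.volumes / (4.0 * np.pi)) ** (1.0 / 3.0)
    n = model.n_beads
    d = pdist(model.centers) if n > 1 else np.empty(0)
    iu, ju = np.triu_indices(n, k=1)

    intensity = np.empty(q.size)
    for lo in range(0, q.size, chunk):
        qs = q[lo : lo + chunk]
        f = model.volumes[None, :] * _sphere_amplitude(np.outer(qs, a_sc))  # (m, N)
        self_term = (f**2).sum(axis=1)
        if n > 1:
            qd = np.outer(qs, d)
            with np.errstate(invalid="ignore", divide="ignore"):
                sinc = np.where(qd > 1e-12, np.sin(qd) / qd, 1.0)
            cross = 2.0 * (f[:, iu] * f[:, ju] * sinc).sum(axis=1)
        else:
            cross = 0.0
        intensity[lo : lo + chunk] = self_term + cross

    # strictly-positive q grid is required by ScatteringCurve
    if q[0] <= 0:
        raise ValueError("q grid must be strictly positive for a curve object")
    return ScatteringCurve(q, intensity, label=model.label)


def _interp_log(
    q_exp: np.ndarray, model: ScatteringCurve
) -> tuple[np.ndarray, np.ndarray]:
    """Model intensity on the experimental grid, linear in log I.

    Points of the experimental grid outside the model's q range are
    dropped; returns (mask, interpolated intensity on masked points).
    """
    m = (q_exp >= model.q[0]) & (q_exp <= model.q[-1])
    if not m.any():
        raise ValueError("experimental and model q grids do not overlap")
    safe = np.clip(model.intensity, 1e-300, None)
    log_i = np.interp(q_exp[m], model.q, np.log(safe))
    return m, np.exp(log_i)


def r_factor(
    exp: ScatteringCurve,
    model: ScatteringCurve,
    fit_scale: bool = True,
) -> tuple[float, float]:
    """Normalized absolute-deviation R-factor (percent) and fitted scale.

    With ``fit_scale`` the scale c minimizing ``sum |I_exp - c I_model|``
    is found by golden-section search (the objective is convex in c);
    otherwise c = 1.
    """
    denom = np.abs(exp.intensity).sum()
    if denom == 0:
        raise ValueError("all-zero experimental curve")
    m, i_mod = _interp_log(exp.q, model)
    i_exp = exp.intensity[m]

    if fit_scale:
        ratio = i_exp[i_mod > 0] / i_mod[i_mod > 0]
        if ratio.size == 0:
            raise ValueError("model curve is non-positive everywhere")
        lo = max(ratio.min(), 1e-12) * 0.5
        hi = ratio.max() * 2.0

        def objective(c: float) -> float:
            return np.abs(i_exp - c * i_mod).sum()

        res = minimize_scalar(
            objective, bracket=None, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-12 * hi},
        )
        scale = float(res.x)
        # polish with golden-section around the bounded minimum
        res2 = minimize_scalar(
            objective, bracket=(max(lo, scale * 0.5), scale, min(hi, scale * 2.0 + 1e-12)),
            method="golden", options={"xtol": 1e-14},
        ) if lo < scale < hi else res
        if res2.fun <= res.fun:
            scale = float(res2.x)
    else:
        scale = 1.0

    r = 100.0 * np.abs(i_exp - scale * i_mod).sum() / np.abs(i_exp).sum()
    return float(r), scale


def rank_models(
    library: Sequence[BeadModel],
    exp: ScatteringCurve,
    rg_tolerance: float = 0.3,
    top_n: int = 100,
    exp_rg: float | None = None,
    fit_scale: bool = True,
) -> list[ModelFitResult]:
    """Score a model library against an experimental curve.

    Models whose volume-weighted R_G lies within ``rg_tolerance`` nm of the
    experimental Guinier R_G are scored by R-factor; the results are sorted
    ascending by R-factor (ties broken by model id) and the best ``top_n``
    returned.  Raises ``ValueError`` when no model passes the filter.
    """
    if len(library) == 0:
        raise ValueError("empty model library")
    if exp_rg is None:
        exp_rg = guinier_fit(exp).rg

    results: list[ModelFitResult] = []
    for k, model in enumerate(library):
        mid = model.label or f"model_{k:04d}"
        m_rg = model.rg
        if abs(m_rg - exp_rg) > rg_tolerance:
            continue
        curve = debye_intensity(model, exp.q)
        r, scale = r_factor(exp, curve, fit_scale=fit_scale)
        results.append(ModelFitResult(mid, r, scale, m_rg, True))

    if not results:
        raise ValueError(
            f"no model passed the R_G filter (+-{rg_tolerance} nm around {exp_rg:.2f} nm)"
        )
    results.sort(key=lambda fr: (fr.r_factor, fr.model_id))
    return results[:top_n]
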