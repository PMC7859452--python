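"""Monomer-dimer mass action: K_D estimation and dimer-site localization.

The working convention expresses the total protein concentration in
monomer-equivalent molar units, c = 10^6 * (c_mg_ml / M) in uM, and
defines

    K_D = c * (1 - f_D)^2 / f_D

where f_D is the mass fraction of protein in the dimer.  The textbook
convention K_D = [monomer]^2 / [dimer] (a factor of 2 larger) is available
behind ``convention="molar"``.  Fragment panels of per-concentration dimer
fractions are aggregated into per-fragment K_D estimates and combined by
set logic into the inferred dimerization domain(s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .fragments import FragmentSpec

__all__ = [
    "KdEstimate",
    "PanelEntry",
    "FragmentPanel",
    "SiteInference",
    "fractions_to_kd",
    "kd_from_series",
    "mass_action_fraction",
    "localize_site",
]

_CONVENTIONS = ("monomer_equivalent", "molar")


def _monomer_equivalent_um(concentration: float, monomer_mass: float) -> float:
    """mg/ml -> monomer-equivalent uM."""
    if concentration <= 0 or monomer_mass <= 0:
        raise ValueError("concentration and monomer_mass must be positive")
    return 1e6 * concentration / monomer_mass


@dataclass
class KdEstimate:
    """Per-fragment dissociation constant with its spread over a series."""

    kd: float  # uM (inf when no dimer was ever seen)
    spread: float  # uM, half-range across the series
    n_points: int
    convention: str = "monomer_equivalent"
    n_excluded: int = 0  # points with f_D = 0 (no dimer)


@dataclass
class PanelEntry:
    spec: FragmentSpec
    points: list[tuple[float, float]]  # (concentration mg/ml, dimer fraction)
    buffer: str = ""


@dataclass
class FragmentPanel:
    entries: list[PanelEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for e in self.entries:
            for c, f in e.points:
                if c <= 0:
                    raise ValueError("concentrations must be positive")
                if not (0.0 <= f <= 1.0):
                    raise ValueError("dimer fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class SiteInference:
    primary_domains: frozenset[int]
    contributing_domains: frozenset[int]
    threshold: float  # uM
    evidence: dict[str, str]  # fragment name -> strong/weak/monomeric
    status: str = "ok"  # ok | ambiguous | no_site


# ----------------------------------------------------------------------
# mass action
# ----------------------------------------------------------------------

def fractions_to_kd(
    dimer_fraction: float,
    concentration: float,
    monomer_mass: float,
    convention: str = "monomer_equivalent",
) -> float:
    """Dissociation constant (uM) from one (concentration, f_D) point.

    ``f_D = 0`` (no dimer) returns ``inf``; ``f_D = 1`` returns 0.0 — both
    limits carry no finite information and callers should treat them as
    flags rather than estimates.
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if not (0.0 <= dimer_fraction <= 1.0):
        raise ValueError("dimer_fraction must lie in [0, 1]")
    c = _monomer_equivalent_um(concentration, monomer_mass)
    if dimer_fraction == 0.0:
        return math.inf
    if dimer_fraction == 1.0:
        return 0.0
    kd = c * (1.0 - dimer_fraction) ** 2 / dimer_fraction
    return 2.0 * kd if convention == "molar" else kd


def mass_action_fraction(
    concentration: float,
    kd: float,
    monomer_mass: float,
    convention: str = "monomer_equivalent",
) -> float:
    """Equilibrium dimer mass fraction at a given loading concentration.

    Inverts the K_D convention by solving c f^2 - (2c + K) f + c = 0 for
    the root in [0, 1], using the numerically stable form
    f = 2c / ((2c + K) + sqrt((2c + K)^2 - 4 c^2)).
    """
    if convention not in _CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if kd < 0:
        raise ValueError("kd must be non-negative")
    c = _monomer_equivalent_um(concentration, monomer_mass)
    if math.isinf(kd):
        return 0.0
    k = kd / 2.0 if convention == "molar" else kd
    if k == 0.0:
        return 1.0
    b = 2.0 * c + k
    # discriminant b^2 - 4c^2 written as k(k + 4c) to avoid cancellation
    return 2.0 * c / (b + math.sqrt(k * (k + 4.0 * c)))


def kd_from_series(
    points: Sequence[tuple[float, float]],
    monomer_mass: float,
    convention: str = "monomer_equivalent",
) -> KdEstimate:
    """Aggregate per-point K_D values over a concentration series.

    Points with f_D = 0 are excluded (counted in ``n_excluded``); the
    estimate is the mean of the per-point values and the spread is the
    half-range, mirroring the +- ranges quoted for series that do not obey
    simple mass action exactly.
    """
    if len(points) == 0:
        raise ValueError("empty concentration series")
    kds = []
    n_excluded = 0
    for c, f in points:
        kd = fractions_to_kd(f, c, monomer_mass, convention=convention)
        if math.isinf(kd):
            n_excluded += 1
        else:
            kds.append(kd)
    if not kds:
        return KdEstimate(
            kd=math.inf, spread=0.0, n_points=0,
            convention=convention, n_excluded=n_excluded,
        )
    arr = np.asarray(kds)
    spread = float((arr.max() - arr.min()) / 2.0)
    return KdEstimate(
        kd=float(arr.mean()),
        spread=spread,
        n_points=len(kds),
        convention=convention,
        n_excluded=n_excluded,
    )


# ----------------------------------------------------------------------
# site localization
# ----------------------------------------------------------------------

def localize_site(
    panel: Sequence[tuple[FragmentSpec, float]] | Mapping[FragmentSpec, float],
    strong_threshold: float = 10.0,
) -> SiteInference:
    """Locate the dimerization domain(s) from per-fragment K_D values.

    Fragments are classified as *strong* (K_D <= threshold), *weak*
    (finite K_D above threshold) or *monomeric* (no dimer, K_D infinite).
    The primary site is the intersection of the domain sets of all strong
    fragments.  Weak fragments whose domain sets are disjoint from, or
    strict supersets of, the primary site point to secondary contributions;
    the contributing set is the intersection of their domains outside the
    primary site.

    The result is deterministic and invariant to panel ordering.  An empty
    strong intersection is reported as ``status="ambiguous"``; a panel with
    neither strong nor weak fragments as ``status="no_site"``.
    """
    if isinstance(panel, Mapping):
        items = list(panel.items())
    else:
        items = list(panel)
    if len(items) < 2:
        raise ValueError("need at least two fragments to localize a site")
    if strong_threshold <= 0:
        raise ValueError("strong_threshold must be positive")

    evidence: dict[str, str] = {}
    strong: list[FragmentSpec] = []
    weak: list[FragmentSpec] = []
    for spec, kd in sorted(items, key=lambda it: it[0].name):
        if kd < 0:
            raise ValueError(f"negative K_D for {spec.name}")
        if math.isinf(kd) or math.isnan(kd):
            evidence[spec.name] = "monomeric"
        elif kd <= strong_threshold:
            evidence[spec.name] = "strong"
            strong.append(spec)
        else:
            evidence[spec.name] = "weak"
            weak.append(spec)

    if not strong and not weak:
        return SiteInference(
            primary_domains=frozenset(),
            contributing_domains=frozenset(),
            threshold=strong_threshold,
            evidence=evidence,
            status="no_site",
        )

    if strong:
        primary = frozenset.intersection(*(s.domain_set for s in strong))
        status = "ambiguous" if not primary else "ok"
    else:
        primary = frozenset()
        status = "ok"

    qualifying = [
        w for w in weak
        if (w.domain_set.isdisjoint(primary) or w.domain_set > primary)
    ]
    if qualifying:
        contributing = frozenset.intersection(
            *(w.domain_set - primary for w in qualifying)
        )
    else:
        contributing = frozenset()

    return SiteInference(
        primary_domains=primary,
        contributing_domains=contributing,
        threshold=strong_threshold,
        evidence=evidence,
        status=status,
    )
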