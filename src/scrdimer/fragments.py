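"""Coarse-grained bead models of tandem SCR-domain fragments.

Each short-complement-regulator (SCR) domain is represented by three
collinear touching beads spanning the 3.6 nm per-domain length seen in
solution; inter-domain linkers are 0.4 nm surface-to-surface gaps.  Bead
*radii* encode the packing geometry while bead *volumes* carry the
scattering mass (total volume = M * vbar / N_A), so a chain can be thin
geometrically yet scatter with the correct forward intensity.

Optional decorations emulate the expression constructs used for domain
panels: one 1.1 nm bead per N-linked glycan and three 0.5 nm beads for an
extended C-terminal purification tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .conventions import Conventions, WATER_20C

# geometry constants (nm)
DOMAIN_LENGTH = 3.6
BEADS_PER_DOMAIN = 3
BEAD_RADIUS = DOMAIN_LENGTH / (2 * BEADS_PER_DOMAIN)  # 0.6 nm, touching beads
LINKER_GAP = 0.4  # surface-to-surface gap between adjacent domains

GLYCAN_BEAD_RADIUS = 1.1
GLYCAN_MASS = 2200.0  # g/mol, biantennary disialylated chain
TAG_BEAD_RADIUS = 0.5
TAG_N_BEADS = 3
TAG_MASS = 2500.0  # g/mol, 23-residue extended tag

#: fractional overlap tolerated between beads (relative to the smaller radius)
OVERLAP_TOLERANCE = 0.01


@dataclass(frozen=True)
class FragmentSpec:
    """A contiguous run of SCR domains with its sequence-predicted mass.

    Parameters
    ----------
    name : str
        Fragment label, e.g. ``"SCR-17/18H"``.
    domains : tuple of int
        Ordered, contiguous domain numbers (e.g. ``(16, 17, 18)``).
    monomer_mass : float
        Sequence-predicted monomer mass in g/mol (protein part only; glycan
        and tag masses are added by the model builder when flagged).
    has_tag : bool
        Whether the construct carries a C-terminal purification tag.
    glycan_count : int
        Number of occupied N-glycosylation sites.
    """

    name: str
    domains: tuple[int, ...]
    monomer_mass: float
    has_tag: bool = False
    glycan_count: int = 0

    def __post_init__(self) -> None:
        if self.monomer_mass <= 0:
            raise ValueError("monomer_mass must be positive")
        if len(self.domains) < 1:
            raise ValueError("a fragment needs at least one domain")
        doms = tuple(self.domains)
        if any(b - a != 1 for a, b in zip(doms, doms[1:])):
            raise ValueError(f"domains must be contiguous, got {doms}")
        if self.glycan_count < 0 or self.glycan_count > len(doms):
            raise ValueError("glycan_count must be between 0 and n_domains")

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def domain_set(self) -> frozenset[int]:
        return frozenset(self.domains)


@dataclass
class BeadModel:
    """A set of spheres with independent packing radii and scattering volumes.

    Attributes
    ----------
    centers : (N, 3) array, nm
    radii : (N,) array, nm — packing radii used for overlap checks and
        hydrodynamics.
    volumes : (N,) array, nm^3 — scattering volumes (sum = M * vbar / N_A).
    domain_ids : (N,) int array — domain number of each bead, or -1 for
        glycan/tag beads.
    oligomer_state : 1 for monomer, 2 for dimer.
    """

    centers: np.ndarray
    radii: np.ndarray
    volumes: np.ndarray
    label: str = ""
    oligomer_state: int = 1
    domain_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.volumes = np.asarray(self.volumes, dtype=float).ravel()
        n = len(self.radii)
        if self.centers.shape != (n, 3):
            raise ValueError("centers must have shape (N, 3)")
        if len(self.volumes) != n:
            raise ValueError("volumes must match radii in length")
        if n == 0:
            raise ValueError("empty bead model")
        if np.any(self.radii <= 0) or np.any(self.volumes <= 0):
            raise ValueError("all radii and volumes must be positive")
        if self.domain_ids is None:
            self.domain_ids = np.full(n, -1, dtype=int)
        else:
            self.domain_ids = np.asarray(self.domain_ids, dtype=int).ravel()
            if len(self.domain_ids) != n:
                raise ValueError("domain_ids must match radii in length")

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.radii)

    @property
    def total_volume(self) -> float:
        """Total scattering volume, nm^3."""
        return float(self.volumes.sum())

    @property
    def domains(self) -> frozenset[int]:
        return frozenset(int(d) for d in self.domain_ids if d >= 0)

    def center_of_mass(self) -> np.ndarray:
        """Volume-weighted center, nm."""
        return self.centers.T @ self.volumes / self.volumes.sum()

    def recenter(self) -> "BeadModel":
        """Translate so the volume-weighted center of mass is at the origin."""
        self.centers = self.centers - self.center_of_mass()
        return self

    @property
    def length(self) -> float:
        """Maximum extent: largest pairwise (center distance + both radii)."""
        if self.n_beads == 1:
            return float(2 * self.radii[0])
        d = squareform(pdist(self.centers))
        ext = d + self.radii[:, None] + self.radii[None, :]
        np.fill_diagonal(ext, 2 * self.radii)
        return float(ext.max())

    @property
    def rg(self) -> float:
        """Volume-weighted radius of gyration, nm.

        Includes the 3/5 a^2 self-term of each bead using its *scattering*
        radius (3V/4pi)^(1/3), matching the low-Q expansion of the
        bead-model scattering curve.
        """
        com = self.center_of_mass()
        d2 = np.sum((self.centers - com) ** 2, axis=1)
        a_sc2 = (3.0 * self.volumes / (4.0 * math.pi)) ** (2.0 / 3.0)
        w = self.volumes / self.volumes.sum()
        return float(np.sqrt(np.sum(w * (d2 + 0.6 * a_sc2))))

    def max_overlap(self) -> float:
        """Worst pairwise overlap depth relative to the smaller radius."""
        if self.n_beads == 1:
            return 0.0
        d = squareform(pdist(self.centers))
        sum_r = self.radii[:, None] + self.radii[None, :]
        min_r = np.minimum(self.radii[:, None], self.radii[None, :])
        rel = (sum_r - d) / min_r
        np.fill_diagonal(rel, -np.inf)
        return float(rel.max())

    def validate(self, overlap_tolerance: float = OVERLAP_TOLERANCE) -> None:
        """Raise if beads overlap beyond tolerance or the COM is off-origin."""
        ov = self.max_overlap()
        if ov > overlap_tolerance:
            raise ValueError(
                f"beads overlap by {ov:.3f} of the smaller radius "
                f"(tolerance {overlap_tolerance})"
            )

    def copy(self) -> "BeadModel":
        return BeadModel(
            centers=self.centers.copy(),
            radii=self.radii.copy(),
            volumes=self.volumes.copy(),
            label=self.label,
            oligomer_state=self.oligomer_state,
            domain_ids=self.domain_ids.copy(),
        )


# ----------------------------------------------------------------------
# builders
# ----------------------------------------------------------------------

def build_fragment_model(
    spec: FragmentSpec,
    conventions: Conventions = WATER_20C,
    seed: int = 0,
) -> BeadModel:
    """Build a linear bead chain for a fragment monomer.

    The chain runs along +x: each domain is three touching beads of radius
    0.6 nm spanning 3.6 nm, domains separated by 0.4 nm surface gaps.
    Glycan beads sit at +z on the middle bead of evenly spaced domains
    (small seeded azimuthal jitter); tag beads extend beyond the C-terminal
    bead along +x.  Scattering volumes are partitioned so that the total
    equals (protein + decorations) mass * vbar / N_A.
    """
    rng = np.random.default_rng(seed)
    n_dom = spec.n_domains

    centers: list[list[float]] = []
    radii: list[float] = []
    dom_ids: list[int] = []
    for k, dom in enumerate(spec.domains):
        x0 = k * (DOMAIN_LENGTH + LINKER_GAP)
        for b in range(BEADS_PER_DOMAIN):
            centers.append([x0 + BEAD_RADIUS * (2 * b + 1), 0.0, 0.0])
            radii.append(BEAD_RADIUS)
            dom_ids.append(dom)

    n_protein = len(centers)
    v_protein = conventions.dry_volume_nm3(spec.monomer_mass)
    volumes = [v_protein / n_protein] * n_protein

    # glycans: one bead per occupied site, on the middle bead of evenly
    # spread domains, pointing +z with a small random tilt
    if spec.glycan_count > 0:
        v_glycan = conventions.dry_volume_nm3(GLYCAN_MASS)
        idx = np.unique(
            np.round(np.linspace(0, n_dom - 1, spec.glycan_count)).astype(int)
        )
        offset = BEAD_RADIUS + GLYCAN_BEAD_RADIUS
        for k in idx:
            anchor = centers[k * BEADS_PER_DOMAIN + BEADS_PER_DOMAIN // 2]
            tilt = rng.uniform(-0.26, 0.26)  # +/- 15 degrees about +z
            centers.append(
                [
                    anchor[0],
                    anchor[1] + offset * math.sin(tilt),
                    anchor[2] + offset * math.cos(tilt),
                ]
            )
            radii.append(GLYCAN_BEAD_RADIUS)
            dom_ids.append(-1)
            volumes.append(v_glycan)

    # extended C-terminal tag: three beads continuing along +x
    if spec.has_tag:
        v_tag = conventions.dry_volume_nm3(TAG_MASS) / TAG_N_BEADS
        x_last = (n_dom - 1) * (DOMAIN_LENGTH + LINKER_GAP) + DOMAIN_LENGTH - BEAD_RADIUS
        x = x_last + BEAD_RADIUS + TAG_BEAD_RADIUS
        for _ in range(TAG_N_BEADS):
            centers.append([x, 0.0, 0.0])
            radii.append(TAG_BEAD_RADIUS)
            dom_ids.append(-1)
            volumes.append(v_tag)
            x += 2 * TAG_BEAD_RADIUS

    model = BeadModel(
        centers=np.array(centers),
        radii=np.array(radii),
        volumes=np.array(volumes),
        label=spec.name,
        oligomer_state=1,
        domain_ids=np.array(dom_ids),
    ).recenter()
    model.validate()
    return model


_SIDE_MODES = ("side_by_side_parallel", "side_by_side_antiparallel")
_MODES = _SIDE_MODES + ("end_to_end",)

# copy-2 rotations chosen so glycan beads (placed at +z on the monomer)
# point away from the dimer interface
_ROTATIONS = {
    "side_by_side_parallel": np.diag([1.0, -1.0, -1.0]),  # 180 deg about x
    "side_by_side_antiparallel": np.diag([-1.0, 1.0, -1.0]),  # 180 deg about y
    "end_to_end": np.eye(3),
}


def build_dimer_model(
    monomer: BeadModel,
    mode: str = "side_by_side_parallel",
    contact_domains: Iterable[int] | None = None,
) -> BeadModel:
    """Duplicate a monomer into a dimer with a chosen association geometry.

    ``side_by_side_*`` modes place the second copy alongside the first so
    that the beads of the *contact domains* touch, roughly doubling the
    cross-section while keeping the length; ``end_to_end`` joins the chains
    head-to-tail, roughly doubling the length.

    Raises
    ------
    ValueError
        If a contact domain is absent from the monomer or the placement
        produces an unresolvable steric overlap.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown dimer mode {mode!r}; choose from {_MODES}")
    contact = (
        frozenset(int(d) for d in contact_domains)
        if contact_domains is not None
        else monomer.domains
    )
    if not contact:
        raise ValueError("contact_domains must be non-empty")
    if not contact <= monomer.domains:
        missing = sorted(contact - monomer.domains)
        raise ValueError(f"contact domains {missing} absent from monomer")

    a = monomer.copy()
    # work in the chain frame: protein beads on the x axis (recentering of
    # decorated monomers shifts the chain off-axis, which would break the
    # flip symmetry used below)
    chain = a.domain_ids >= 0
    off = a.centers[chain].mean(axis=0)
    a.centers = a.centers - np.array([0.0, off[1], off[2]])
    b = a.copy()
    b.centers = b.centers @ _ROTATIONS[mode].T

    if mode in _SIDE_MODES:
        mask = np.isin(a.domain_ids, list(contact))
        dy = a.radii[mask].max() + b.radii[mask].max()
        dx = a.centers[mask, 0].mean() - b.centers[mask, 0].mean()
        b.centers = b.centers + np.array([dx, dy, 0.0])
    else:  # end_to_end: surfaces of terminal beads touch along x
        shift = (a.centers[:, 0] + a.radii).max() - (b.centers[:, 0] - b.radii).min()
        b.centers = b.centers + np.array([shift, 0.0, 0.0])

    dimer = BeadModel(
        centers=np.vstack([a.centers, b.centers]),
        radii=np.concatenate([a.radii, b.radii]),
        volumes=np.concatenate([a.volumes, b.volumes]),
        label=f"{monomer.label or 'model'}_dimer_{mode}",
        oligomer_state=2,
        domain_ids=np.concatenate([a.domain_ids, b.domain_ids]),
    ).recenter()
    try:
        dimer.validate()
    except ValueError as exc:
        raise ValueError(f"unresolvable steric overlap in {mode} dimer: {exc}") from exc
    return dimer
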