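"""Text file formats and analysis configuration.

All on-disk artifacts are plain text: 3-column ``.dat`` scattering curves
with ``#`` headers, 2-column P(r) tables, per-scan sedimentation files
plus a YAML manifest, delimited fragment-panel and bead-model tables, and
a YAML analysis configuration with strict key checking.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .equilibrium import FragmentPanel, PanelEntry
from .fragments import BeadModel, FragmentSpec
from .saxs import PrDistribution, ScatteringCurve
from .sedimentation import SedimentationRun

__all__ = [
    "read_saxs_dat",
    "write_saxs_dat",
    "write_pr_dat",
    "read_bead_model",
    "write_bead_model",
    "read_sv_run",
    "write_sv_run",
    "read_panel",
    "write_panel",
    "AnalysisConfig",
]


# ----------------------------------------------------------------------
# scattering curves
# ----------------------------------------------------------------------

def write_saxs_dat(curve: ScatteringCurve, path: str | Path) -> None:
    """Write a curve as whitespace-delimited text: Q (1/nm), I, [sigma]."""
    path = Path(path)
    lines = ["# scrdimer scattering curve", "# units: q=1/nm"]
    if curve.label:
        lines.append(f"# label: {curve.label}")
    if curve.concentration is not None:
        lines.append(f"# concentration_mg_ml: {curve.concentration:g}")
    has_sigma = curve.sigma is not None
    lines.append("# columns: q intensity" + (" sigma" if has_sigma else ""))
    for i in range(len(curve)):
        row = f"{curve.q[i]:.8e} {curve.intensity[i]:.8e}"
        if has_sigma:
            row += f" {curve.sigma[i]:.8e}"
        lines.append(row)
    path.write_text("\n".join(lines) + "\n")


def read_saxs_dat(path: str | Path) -> ScatteringCurve:
    """Read a 2- or 3-column curve; '#' lines are headers.

    The Q unit defaults to 1/nm; a header containing ``q=1/angstrom``
    converts Q by a factor 10 on read.  Malformed rows raise ``ValueError``
    naming the line number.
    """
    path = Path(path)
    q, i_vals, sig = [], [], []
    unit_scale = 1.0
    label = ""
    concentration = None
    n_cols = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip().lower()
            if "q=1/angstrom" in body.replace(" ", ""):
                unit_scale = 10.0
            if body.startswith("label:"):
                label = line.split(":", 1)[1].strip()
            if body.startswith("concentration_mg_ml:"):
                concentration = float(body.split(":", 1)[1])
            continue
        parts = line.split()
        if len(parts) not in (2, 3):
            raise ValueError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value in {line!r}") from exc
        if n_cols is None:
            n_cols = len(parts)
        elif len(parts) != n_cols:
            raise ValueError(f"{path}:{lineno}: inconsistent column count")
        q.append(vals[0] * unit_scale)
        i_vals.append(vals[1])
        if n_cols == 3:
            sig.append(vals[2])
    if not q:
        raise ValueError(f"{path}: no data rows")
    qa = np.asarray(q)
    if np.any(np.diff(qa) <= 0):
        raise ValueError(f"{path}: Q must be strictly increasing")
    return ScatteringCurve(
        qa,
        np.asarray(i_vals),
        np.asarray(sig) if sig else None,
        label=label,
        concentration=concentration,
    )


def write_pr_dat(pr: PrDistribution, path: str | Path) -> None:
    """Write P(r) as 2-column text with summary scalars in the header."""
    path = Path(path)
    lines = [
        "# scrdimer distance distribution",
        f"# dmax_nm: {pr.dmax:.6g}",
        f"# mode_nm: {pr.mode:.6g}",
        f"# rg_real_nm: {pr.rg_real:.6g}",
        f"# alpha: {pr.alpha:.6g}",
        "# columns: r_nm p",
    ]
    for r, p in zip(pr.r, pr.p):
        lines.append(f"{r:.6e} {p:.6e}")
    path.write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# bead models
# ----------------------------------------------------------------------

def write_bead_model(model: BeadModel, path: str | Path) -> None:
    """One bead per line: x y z radius volume domain_id (nm, nm^3)."""
    path = Path(path)
    lines = [
        "# scrdimer bead model",
        f"# label: {model.label}",
        f"# oligomer_state: {model.oligomer_state}",
        "# columns: x y z radius volume domain_id",
    ]
    for c, r, v, d in zip(model.centers, model.radii, model.volumes, model.domain_ids):
        lines.append(
            f"{c[0]:.6e} {c[1]:.6e} {c[2]:.6e} {r:.6e} {v:.6e} {int(d)}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_bead_model(path: str | Path) -> BeadModel:
    """Read a bead-model file (x y z radius [volume] [domain_id]).

    A missing volume column defaults to the sphere volume of the radius.
    """
    path = Path(path)
    centers, radii, volumes, dom = [], [], [], []
    label = ""
    state = 1
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.lower().startswith("label:"):
                label = body.split(":", 1)[1].strip()
            if body.lower().startswith("oligomer_state:"):
                state = int(body.split(":", 1)[1])
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}:{lineno}: need at least x y z radius")
        try:
            x, y, z, r = (float(p) for p in parts[:4])
            v = float(parts[4]) if len(parts) >= 5 else 4.0 / 3.0 * math.pi * r**3
            d = int(parts[5]) if len(parts) >= 6 else -1
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
        centers.append([x, y, z])
        radii.append(r)
        volumes.append(v)
        dom.append(d)
    if not centers:
        raise ValueError(f"{path}: no beads")
    return BeadModel(
        centers=np.array(centers),
        radii=np.array(radii),
        volumes=np.array(volumes),
        label=label,
        oligomer_state=state,
        domain_ids=np.array(dom),
    )


# ----------------------------------------------------------------------
# sedimentation runs
# ----------------------------------------------------------------------

def write_sv_run(run: SedimentationRun, directory: str | Path) -> None:
    """Write one 2-column file per scan plus a YAML manifest."""
    if run.signals is None:
        raise ValueError("run has no signals to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scans = []
    for i, t in enumerate(run.times):
        name = f"scan{i + 1:04d}.txt"
        lines = [f"# time_s: {t:g}", "# columns: radius_cm signal"]
        for r, sgn in zip(run.radii, run.signals[i]):
            lines.append(f"{r:.6e} {sgn:.6e}")
        (directory / name).write_text("\n".join(lines) + "\n")
        scans.append({"file": name, "time_s": float(t)})
    manifest = {
        "rotor_speed_rad_s": float(run.rotor_speed),
        "meniscus_cm": float(run.meniscus),
        "base_cm": float(run.base),
        "temperature_c": float(run.temperature),
        "scans": scans,
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def read_sv_run(directory: str | Path) -> SedimentationRun:
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    times, rows = [], []
    radii = None
    for entry in manifest["scans"]:
        data = np.loadtxt(directory / entry["file"], comments="#")
        if radii is None:
            radii = data[:, 0]
        rows.append(data[:, 1])
        times.append(float(entry["time_s"]))
    return SedimentationRun(
        radii=radii,
        times=np.array(times),
        signals=np.vstack(rows),
        rotor_speed=float(manifest["rotor_speed_rad_s"]),
        meniscus=float(manifest["meniscus_cm"]),
        base=float(manifest["base_cm"]),
        temperature=float(manifest.get("temperature_c", 20.0)),
    )


# ----------------------------------------------------------------------
# fragment panels
# ----------------------------------------------------------------------

def _domains_to_str(domains: Sequence[int]) -> str:
    return "-".join(str(d) for d in domains)


def _str_to_domains(text: str) -> tuple[int, ...]:
    return tuple(int(t) for t in str(text).split("-"))


def write_panel(panel: FragmentPanel, path: str | Path) -> None:
    """Write the panel as a TSV table, one row per (fragment, concentration)."""
    rows = []
    for e in panel.entries:
        for c, f in e.points:
            rows.append(
                {
                    "fragment": e.spec.name,
                    "domains": _domains_to_str(e.spec.domains),
                    "monomer_mass": e.spec.monomer_mass,
                    "has_tag": int(e.spec.has_tag),
                    "glycan_count": e.spec.glycan_count,
                    "buffer": e.buffer,
                    "concentration_mg_ml": c,
                    "dimer_fraction": f,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_panel(path: str | Path) -> FragmentPanel:
    df = pd.read_csv(path, sep="\t")
    required = {"fragment", "domains", "monomer_mass", "concentration_mg_ml", "dimer_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"panel table missing columns: {sorted(missing)}")
    entries = []
    for name, grp in df.groupby("fragment", sort=False):
        first = grp.iloc[0]
        spec = FragmentSpec(
            name=str(name),
            domains=_str_to_domains(first["domains"]),
            monomer_mass=float(first["monomer_mass"]),
            has_tag=bool(first.get("has_tag", 0)),
            glycan_count=int(first.get("glycan_count", 0)),
        )
        points = [
            (float(r["concentration_mg_ml"]), float(r["dimer_fraction"]))
            for _, r in grp.iterrows()
        ]
        entries.append(
            PanelEntry(spec=spec, points=points, buffer=str(first.get("buffer", "") or ""))
        )
    return FragmentPanel(entries=entries)


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration (YAML-loadable, strict keys)."""

    seed: int = 0
    q_min: float = 0.05  # 1/nm
    q_max: float = 3.0
    n_q: int = 240
    max_qrg: float = 1.5
    max_qrxs: float = 1.0
    dmax_factor: float = 1.3  # dmax = factor * model length
    alpha_pr: float | None = None  # None -> L-curve
    strong_threshold: float = 10.0  # uM
    concentrations: list[float] = field(default_factory=lambda: [0.2, 0.5, 1.0, 2.0, 3.0])
    panel_jitter: float = 0.0
    saxs_noise: float = 0.01
    include_auc: bool = True
    auc_alpha: float = 0.005
    auc_noise: float = 0.005
    reference_concentration: float = 1.0  # mg/ml for the SAXS stage

    def __post_init__(self) -> None:
        for name in ("q_min", "q_max", "n_q", "max_qrg", "max_qrxs",
                     "dmax_factor", "strong_threshold", "auc_alpha",
                     "reference_concentration"):
            if getattr(self, name) is not None and getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.q_min >= self.q_max:
            raise ValueError("q_min must be below q_max")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))
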