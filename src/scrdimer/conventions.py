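"""Physical conventions shared across the SAXS/AUC analysis.

All hydrodynamic and volumetric calculations in this package are tied to a
single :class:`Conventions` record so that the partial specific volume,
hydration and solvent constants cannot silently diverge between modules.

Units
-----
* partial specific volume  cm^3/g
* hydration                g water per g protein
* solvent density          g/cm^3
* solvent viscosity        poise (g cm^-1 s^-1)
* hydration shell radius   nm (bead-radius inflation for hydrodynamics)
"""

from __future__ import annotations

from dataclasses import dataclass, replace

AVOGADRO = 6.02214076e23  # 1/mol

#: nm^3 per cm^3
_CM3_TO_NM3 = 1e21


@dataclass(frozen=True)
class Conventions:
    """Solvent and protein constants used throughout the pipeline.

    The defaults are water at 20 degrees C with the standard protein partial
    specific volume 0.73 cm^3/g and hydration 0.30 g/g.  The hydration shell
    radius of 0.31 nm is the conventional per-element inflation used by shell
    hydrodynamic calculations.
    """

    partial_specific_volume: float = 0.73
    hydration: float = 0.30
    solvent_density_20c: float = 0.99823
    solvent_viscosity_20c: float = 0.01002
    hydration_shell_radius: float = 0.31
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        for name in (
            "partial_specific_volume",
            "hydration",
            "solvent_density_20c",
            "solvent_viscosity_20c",
            "avogadro",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.hydration_shell_radius < 0:
            raise ValueError("hydration_shell_radius must be non-negative")

    # ------------------------------------------------------------------
    # volume helpers
    # ------------------------------------------------------------------
    def dry_volume_nm3(self, mass: float) -> float:
        """Anhydrous protein volume V = M * vbar / N_A, in nm^3."""
        if mass <= 0:
            raise ValueError("mass must be positive")
        return mass * self.partial_specific_volume / self.avogadro * _CM3_TO_NM3

    def hydrated_volume_nm3(self, mass: float) -> float:
        """Hydrated volume V_h = M * (vbar + hydration) / N_A, in nm^3."""
        if mass <= 0:
            raise ValueError("mass must be positive")
        vh_cm3 = mass * (self.partial_specific_volume + self.hydration) / self.avogadro
        return vh_cm3 * _CM3_TO_NM3

    def hydrated_sphere_radius_nm(self, mass: float) -> float:
        """Radius of the sphere with the protein's hydrated volume, in nm."""
        import math

        vh = self.hydrated_volume_nm3(mass)
        return (3.0 * vh / (4.0 * math.pi)) ** (1.0 / 3.0)

    def with_(self, **kwargs) -> "Conventions":
        """Return a copy with selected fields overridden."""
        return replace(self, **kwargs)


#: default conventions: water at 20 C
WATER_20C = Conventions()
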