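"""Cell geometry, carbon-content models, and motion allometry.

Cells are treated as spheres of a given equivalent spherical diameter
(ESD, μm).  Cellular carbon is either a fixed volumetric density
(gC per litre of cell volume) or an allometric power law
``C_cell = a · Volume^b`` (pgC, volume in μm³), following the standard
plankton biovolume–carbon regressions.  Motion is either a swimming
allometry for flagellated protists or Stokes sedimentation for diatoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal

from .errors import NutrikinError
from .units import diffusivity_um2_per_day


@dataclass(frozen=True)
class Environment:
    """Physical constants of the seawater environment.

    Parameters
    ----------
    D : float
        Molecular diffusivity of the nutrient, m² s⁻¹.  The default of
        1.5×10⁻⁹ is typical for small inorganic nitrogen ions near 20 °C.
    eta : float
        Dynamic viscosity of seawater, Pa s.
    rho_org, rho_w : float
        Organism and seawater densities, kg L⁻¹.  ``rho_org > rho_w`` is
        required for a positive sedimentation speed.
    g : float
        Gravitational acceleration, m s⁻².
    molar_mass_N : float
        Molar mass used for μM ↔ mass-concentration conversion, g mol⁻¹.
    """

    D: float = 1.5e-9
    eta: float = 1.0846e-3
    rho_org: float = 1.0634
    rho_w: float = 1.033
    g: float = 9.8
    molar_mass_N: float = 14.0

    def __post_init__(self) -> None:
        for name in ("D", "eta", "rho_org", "rho_w", "g", "molar_mass_N"):
            if getattr(self, name) <= 0:
                raise NutrikinError(f"Environment.{name} must be positive")

    @property
    def D_um2_d(self) -> float:
        """Diffusivity in internal units, μm² d⁻¹."""
        return diffusivity_um2_per_day(self.D)


@dataclass(frozen=True)
class CarbonModel:
    """Cellular carbon content as a function of cell volume.

    ``fixed_density`` holds carbon density constant (``density``,
    gC (L cell)⁻¹) so that C_cell scales with volume; ``allometric`` uses
    ``C_cell = a · volume^b`` with volume in μm³ and C_cell in pgC, so
    carbon density falls with size whenever ``b < 1`` (vacuolation).
    """

    kind: Literal["fixed_density", "allometric"]
    density: float | None = None  # gC (L cell)^-1
    a: float | None = None
    b: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "fixed_density":
            if self.density is None or self.density <= 0:
                raise NutrikinError("fixed_density model requires density > 0")
        elif self.kind == "allometric":
            if self.a is None or self.a <= 0:
                raise NutrikinError("allometric model requires a > 0")
            if self.b is None or not (0 < self.b <= 1):
                raise NutrikinError("allometric model requires 0 < b <= 1")
        else:
            raise NutrikinError(f"unknown carbon model kind {self.kind!r}")

    @classmethod
    def fixed(cls, density: float) -> "CarbonModel":
        return cls(kind="fixed_density", density=density)

    @classmethod
    def allometric(cls, a: float, b: float) -> "CarbonModel":
        return cls(kind="allometric", a=a, b=b)

    def carbon_content(self, volume_um3: float) -> float:
        """Cellular carbon (pgC) for a cell of the given volume (μm³)."""
        if volume_um3 <= 0:
            raise NutrikinError("cell volume must be positive")
        if self.kind == "fixed_density":
            # density gC/L × volume in L (1 μm³ = 1e-15 L) × 1e12 pg/g
            return self.density * volume_um3 * 1e-3
        return self.a * volume_um3**self.b


#: Named carbon-model presets.
#:
#: * ``C150`` — constant 150 gC (L cell)⁻¹.
#: * ``Cprot`` — general non-diatom protist biovolume regression
#:   (C = 0.216·V^0.939), used for cell-size scans.
#: * ``Cprot_small`` — small-protist (<3000 μm³) variant of the same
#:   regression family (C = 0.261·V^0.86), appropriate for the nano-sized
#:   reference organisms in the worked cell budgets.
#: * ``Cdiat`` — diatom regression (C = 0.288·V^0.811).
CARBON_MODEL_PRESETS: dict[str, CarbonModel] = {
    "C150": CarbonModel.fixed(150.0),
    "Cprot": CarbonModel.allometric(0.216, 0.939),
    "Cprot_small": CarbonModel.allometric(0.261, 0.86),
    "Cdiat": CarbonModel.allometric(0.288, 0.811),
}


def resolve_carbon_model(model: CarbonModel | str) -> CarbonModel:
    """Return a CarbonModel from an instance or a preset name."""
    if isinstance(model, CarbonModel):
        return model
    try:
        return CARBON_MODEL_PRESETS[model]
    except KeyError:
        raise NutrikinError(
            f"unknown carbon model preset {model!r}; "
            f"choose from {sorted(CARBON_MODEL_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class CellMorphology:
    """Derived geometry and carbon budget of a spherical cell.

    ``C_cell`` (pgC) and ``carbon_density`` (gC (L cell)⁻¹) are ``None``
    until a carbon model has been applied via :func:`cell_carbon`.
    """

    ESD: float            # μm
    radius: float         # μm
    volume: float         # μm³
    SA: float             # μm²
    C_cell: float | None = None
    carbon_density: float | None = None


def sphere_geometry(ESD: float) -> CellMorphology:
    """Geometry of a spherical cell of the given equivalent diameter.

    Returns a :class:`CellMorphology` with radius = ESD/2,
    volume = (4/3)π(ESD/2)³ and SA = 4π(ESD/2)².
    """
    if ESD <= 0:
        raise NutrikinError("ESD must be positive")
    r = ESD / 2.0
    return CellMorphology(
        ESD=ESD,
        radius=r,
        volume=(4.0 / 3.0) * math.pi * r**3,
        SA=4.0 * math.pi * r**2,
    )


def cell_carbon(
    morphology: CellMorphology, carbon_model: CarbonModel | str
) -> tuple[float, float]:
    """Cellular carbon content and volumetric carbon density.

    Returns ``(C_cell, carbon_density)`` in (pgC cell⁻¹, gC (L cell)⁻¹);
    the density is ``C_cell / volume × 10³`` (pg μm⁻³ → g L⁻¹).
    """
    model = resolve_carbon_model(carbon_model)
    C = model.carbon_content(morphology.volume)
    return C, C / morphology.volume * 1e3


def morphology(ESD: float, carbon_model: CarbonModel | str) -> CellMorphology:
    """Full morphology (geometry plus carbon budget) for one cell."""
    geom = sphere_geometry(ESD)
    C, dens = cell_carbon(geom, carbon_model)
    return replace(geom, C_cell=C, carbon_density=dens)


def swimming_speed(ESD: float) -> float:
    """Allometric swimming speed of a flagellated protist, μm s⁻¹.

    c = 38.542 · ESD^0.5424 with ESD in μm.
    """
    if ESD <= 0:
        raise NutrikinError("ESD must be positive")
    return 38.542 * ESD**0.5424


def sinking_speed(radius: float, env: Environment) -> float:
    """Stokes sedimentation speed, μm s⁻¹, for a cell of given radius (μm).

    c_sed = 2 g r² (ρ_org − ρ_w) / (9 η), evaluated in SI units and
    converted back to μm s⁻¹.  Buoyant ascent (ρ_org < ρ_w) is not
    modelled and raises an error.
    """
    if radius <= 0:
        raise NutrikinError("radius must be positive")
    if env.rho_org < env.rho_w:
        raise NutrikinError(
            "rho_org < rho_w: buoyant ascent is not modelled"
        )
    r_m = radius * 1e-6
    drho = (env.rho_org - env.rho_w) * 1e3  # kg L^-1 -> kg m^-3
    c_m_s = 2.0 * env.g * r_m**2 * drho / (9.0 * env.eta)
    return c_m_s * 1e6
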