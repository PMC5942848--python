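"""Diffusive boundary layer between bulk medium and cell membrane.

Transport into the cell must be sustained by diffusion down the
concentration gradient between the bulk medium (S_∞) and the membrane
surface (S_0).  For a sphere of radius r moving at speed c the flux is

    T = 4π r D (1 + 0.5·r·c/D) (S_∞ − S_0)

where the dimensionless factor ``1 + 0.5·r·c/D`` (a Péclet-number
enhancement) captures the thinning of the boundary layer by swimming or
sinking.  Concentrations cross this module's API in μM and are converted
to pg μm⁻³ internally so that T is in pgN cell⁻¹ d⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import NutrikinError
from .geometry import Environment
from .units import micromolar_to_pg_um3, pg_um3_to_micromolar, speed_per_day


@dataclass(frozen=True)
class DiffusionContext:
    """Geometry, diffusivity and motion entering the boundary-layer flux.

    radius : μm; D : μm² d⁻¹; speed : μm d⁻¹ (0 for a non-motile cell);
    molar_mass : g mol⁻¹, for the μM ↔ pg μm⁻³ conversion.
    """

    radius: float
    D: float
    speed: float = 0.0
    molar_mass: float = 14.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.D <= 0 or self.molar_mass <= 0:
            raise NutrikinError("radius, D and molar_mass must be positive")
        if self.speed < 0:
            raise NutrikinError("speed must be non-negative")

    @classmethod
    def from_environment(
        cls, radius: float, env: Environment, speed_um_s: float = 0.0
    ) -> "DiffusionContext":
        """Build a context from SI environment constants and a speed in μm s⁻¹."""
        return cls(
            radius=radius,
            D=env.D_um2_d,
            speed=speed_per_day(speed_um_s),
            molar_mass=env.molar_mass_N,
        )

    @property
    def enhancement(self) -> float:
        """Motion enhancement factor 1 + 0.5·r·c/D (≥ 1; 1 when c = 0)."""
        return 1.0 + 0.5 * self.radius * self.speed / self.D

    @property
    def conductance(self) -> float:
        """Diffusive conductance 4π·r·D·enhancement, μm³ d⁻¹."""
        import math

        return 4.0 * math.pi * self.radius * self.D * self.enhancement


def transport_from_gradient(
    S_inf: float, S0: float, ctx: DiffusionContext
) -> float:
    """Diffusive supply (pgN cell⁻¹ d⁻¹) across the gradient S_∞ − S_0 (μM)."""
    if S0 < 0 or S_inf < S0:
        raise NutrikinError("need S_inf >= S0 >= 0 (no efflux modelled)")
    gradient = micromolar_to_pg_um3(S_inf - S0, ctx.molar_mass)
    return ctx.conductance * gradient


def bulk_substrate(T: float, S0: float, ctx: DiffusionContext) -> float:
    """Bulk concentration S_∞ (μM) sustaining transport T at surface S0.

    Exact inverse of :func:`transport_from_gradient` at fixed S0.
    """
    if T < 0:
        raise NutrikinError("T must be non-negative")
    if S0 < 0:
        raise NutrikinError("S0 must be non-negative")
    gradient = T / ctx.conductance
    return S0 + pg_um3_to_micromolar(gradient, ctx.molar_mass)
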