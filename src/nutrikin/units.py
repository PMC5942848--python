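"""Internal unit system and converters.

The package works in micrometres, days and picograms throughout; substrate
concentrations cross the API boundary in μmol L⁻¹ (μM).  The converters
below are the single place where those conventions are encoded:

* speeds measured in μm s⁻¹ (swimming/sinking allometries) are multiplied
  by 86 400 to obtain μm d⁻¹;
* molecular diffusivities given in m² s⁻¹ become μm² d⁻¹;
* 1 μM of a nutrient of molar mass M g mol⁻¹ equals M μg L⁻¹, and with
  1 μm³ = 10⁻¹⁵ L this is M×10⁻⁹ pg μm⁻³.
"""

SECONDS_PER_DAY: float = 86_400.0

#: pg μm⁻³ per (μM × g mol⁻¹); 1 μM = M μg/L = M×1e6 pg / 1e15 μm³
_PG_PER_UM3_PER_UM_MOLAR = 1e-9


def speed_per_day(speed_um_s: float) -> float:
    """Convert a speed from μm s⁻¹ to μm d⁻¹."""
    return speed_um_s * SECONDS_PER_DAY


def diffusivity_um2_per_day(D_m2_s: float) -> float:
    """Convert a molecular diffusivity from m² s⁻¹ to μm² d⁻¹."""
    return D_m2_s * 1e12 * SECONDS_PER_DAY


def micromolar_to_pg_um3(conc_uM: float, molar_mass: float) -> float:
    """Convert μmol L⁻¹ to pg μm⁻³ for a nutrient of given molar mass."""
    return conc_uM * molar_mass * _PG_PER_UM3_PER_UM_MOLAR


def pg_um3_to_micromolar(conc_pg_um3: float, molar_mass: float) -> float:
    """Convert pg μm⁻³ back to μmol L⁻¹."""
    return conc_pg_um3 / (molar_mass * _PG_PER_UM3_PER_UM_MOLAR)
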