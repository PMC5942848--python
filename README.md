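# nutrikin

Mechanistic nutrient-transport and growth kinetics for phytoplankton.

Nutrient-limited growth of phytoplankton is almost always summarized by a
Monod curve: a maximum growth rate `G_max` and a half-saturation constant
`K_G` treated as an input parameter. In reality `K_G` is an *emergent*
property of cell physiology. This package computes it mechanistically from
the traits that actually set it:

- **cell size** (equivalent spherical diameter, ESD) and spherical geometry;
- **cellular carbon density** — fixed, or falling allometrically with size
  as cells (diatoms especially) become vacuolate, via biovolume–carbon
  regressions `C_cell = a·V^b`;
- **N:C stoichiometry** — a normalized quota `NCu ∈ [0, 1]` between
  `NC_min` (growth stops) and `NC_max` (growth at `G_max`), with
  `G = G_max·NCu`;
- **transporter rate density (TRD)** — the membrane can hold only so many
  transporter proteins per μm² (ceiling `TRD_max`, default 0.4 pgN μm⁻² d⁻¹),
  and nutrient-stressed cells up-regulate their instantaneous maximum
  transport rate `T_max` within that headroom;
- **Michaelis–Menten transport** at the membrane with half-saturation
  `K_T` (default 1 μM), defined at the *cell-surface* concentration `S_0`;
- **diffusion boundary layers** — transport must be supplied by diffusion
  across the gradient between the bulk medium (`S_∞`) and the membrane
  (`S_0`), `T = 4πrD(1 + 0.5·r·c/D)(S_∞ − S_0)`, with motion (swimming
  allometry for flagellates, Stokes sedimentation for diatoms) thinning
  the boundary layer.

For a growth rate `G` the forward chain — quota inverse → transport demand
`T = G·NC·C_cell` → stress-dependent capacity `T_max` → `S_0` (Michaelis–
Menten inverse) → `S_∞` (diffusion inverse) — is explicit and requires no
iteration. The bulk concentration at `G = G_max/2` is `K_G`. On top of the
point solver the package provides growth sweeps (emergent kinetic curves),
cell-size scans, power-law fits of `G_max/K_G` versus ESD, rectangular-
hyperbola ("RHt2") fits that quantify how poorly a Monod curve describes
the emergent kinetics, transporter-density feasibility surfaces, and
seeded synthetic-data generators for uptake experiments and measured-shape
`T_max`(N:C) response tables.

All transport masses are picograms of nutrient-N throughout (a legacy
"ng cell⁻¹ d⁻¹" unit annotation in the source literature's flux equation is
inconsistent with its own tabulated pgN values and is treated as a typo).

## Worked example

```python
import nutrikin as nk

env = nk.Environment()                       # seawater constants, D = 1.5e-9 m²/s
cfg = nk.OrganismConfig(ESD=10.0, carbon_model="C150", motion="none")

state = nk.solve_state_at_growth(0.693 / 2, cfg, env)
print(f"NC  = {state.NC:.4f} gN/gC")         # NC  = 0.1119 gN/gC
print(f"T   = {state.T:.3f} pgN/cell/d")     # T   = 3.045 pgN/cell/d
print(f"S0  = {state.S0:.4f} uM")            # S0  = 0.0270 uM
print(f"Sinf= {state.S_inf:.4f} uM")         # Sinf= 0.0537 uM

res = nk.half_saturation_growth(cfg, env)
print(f"K_G = {res.K_G:.4f} uM")             # K_G = 0.0537 uM
```

A 10 μm cell of fixed carbon density (150 gC per litre of cell volume)
growing at half its maximum rate must import 3.05 pgN d⁻¹; sustaining that
through its boundary layer and transporters requires only 0.027 μM at the
membrane but 0.054 μM in the bulk medium — so `K_G` ≈ 0.054 μM, far below
the transporter's own `K_T` of 1 μM, and roughly half of it is pure
diffusion limitation. Halving `K_T` lowers `K_G` to ~75 % (not 50 %),
because the diffusion component does not care about the transporter:

```python
print(nk.kt_sensitivity(cfg, env, factors=[0.5, 2.0]))
#    factor       K_G     ratio
# 0     0.5  0.040193  0.748855
# 1     2.0  0.080632  1.502290
```

The same machinery from the shell:

```sh
nutrikin kg --esd 10 --model C150
nutrikin scan --model Cdiat --motion sink --out scan.csv
nutrikin powerfit --model Cdiat --motion sink
nutrikin tables --outdir tables/
nutrikin synth uptake --vmax 2 --k 0.5 --cv 0.1 --seed 1
```

Every CSV embeds the resolved configuration and package version in a
comment header; re-running with the same configuration reproduces the file
byte-identically.

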