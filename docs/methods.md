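# Methods

## Model structure

The package computes steady-state nutrient-limited growth kinetics for a
spherical osmotroph from a deterministic forward chain. For a growth rate
`G ∈ [0, G_max)`:

1. **Quota.** Growth is controlled by the normalized N:C quota,
   `NCu = (1+KQ)(NC−NC_min) / ((NC−NC_min) + KQ(NC_max−NC_min))`, with
   `G = G_max·NCu`. The chain inverts this exactly:
   `NC = NC_min + NCu·KQ·(NC_max−NC_min)/(1+KQ−NCu)`.
2. **Demand.** Steady state requires importing `T = G·NC·C_cell`
   (pgN cell⁻¹ d⁻¹), with `C_cell` from the carbon model.
3. **Capacity.** The C-specific maximum transport rate is
   `T_max = G_max·NC_max·(1 + T_add·(1+KT_con)(1−NCu)/((1−NCu)+KT_con))`.
   The stress term is a normalized hyperbola equal to 0 at the replete
   quota and exactly 1 at full stress for any `KT_con`. The headroom
   multiplier `T_add = (TRD_max − TRD_Gmax)/TRD_Gmax` comes from the
   membrane packing ceiling `TRD_max` and the density needed at `G_max`,
   `TRD_Gmax = G_max·NC_max·C_cell/SA`. Alternative capacity modes: a
   flat `T_max = G_max·NC_max` (the implicit assumption of most ecosystem
   models) and an empirical mode driven by a tabulated `T_max`(N:C) curve
   interpolated with a monotone-preserving PCHIP scheme (no overshoot, so
   no spurious negative capacity).
4. **Membrane substrate.** Michaelis–Menten inversion:
   `S_0 = T·K_T/(T_max·C_cell − T)`; demand at or above capacity raises a
   saturation error (no finite concentration suffices).
5. **Bulk substrate.** Diffusion inversion:
   `S_∞ = S_0 + T / (4πrD(1 + 0.5·r·c/D))`, where the enhancement factor
   captures boundary-layer thinning by motion. Swimming speed follows the
   flagellate allometry `c = 38.542·ESD^0.5424` μm s⁻¹; sedimentation
   follows Stokes' law with a fixed organism density.

`K_G` is `S_∞` evaluated at `NCu = 0.5` — a single direct evaluation, no
root finding, since the chain is explicit. It decomposes additively into
the membrane component `S_0` (exactly linear in `K_T`) and the diffusion
gradient (independent of `K_T`), which is why rescaling `K_T` moves `K_G`
less than proportionally.

A structural consequence of the capacity curve: at the replete quota the
stress term vanishes, so demand equals capacity *exactly* at `G = G_max`
in every mode and that endpoint always saturates. Growth sweeps therefore
use grids on `[0, G_max)` (default 200 evenly spaced points).

## Parameters and defaults

| Parameter | Default | Units | Meaning |
|---|---|---|---|
| `K_T` | 1.0 | μM | transporter half-saturation at the membrane |
| `TRD_max` | 0.4 | pgN μm⁻² d⁻¹ | membrane packing ceiling on transport density |
| `KT_con` | 0.1 | – | steepness of the stress up-regulation curve |
| `NC_max`, `NC_min` | 0.18, 0.05 | gN gC⁻¹ | quota bounds |
| `KQ` | 10 | – | quota curvature (near-linear NC→G map) |
| `G_max` | 0.693 | d⁻¹ | one doubling per day |
| `D` | 1.5×10⁻⁹ | m² s⁻¹ | diffusivity of small inorganic N ions (~20 °C) |
| `η` | 1.0846×10⁻³ | Pa s | seawater dynamic viscosity |
| `ρ_org`, `ρ_w` | 1.0634, 1.033 | kg L⁻¹ | organism and seawater densities |

Carbon presets: `C150` (fixed 150 gC per litre of cell volume), `Cprot`
(general non-diatom protist biovolume regression, `C = 0.216·V^0.939`),
`Cprot_small` (small-protist variant `0.261·V^0.86`, appropriate below
~3000 μm³ and used for the nano-sized reference organisms in the budget
tables), `Cdiat` (diatom regression `0.288·V^0.811`). The general protist
relation is the correct choice for multi-decade size scans; the small-cell
variant flattens the size scaling artificially when extrapolated to large
volumes. Organism density for Stokes sedimentation is held constant across
diatom sizes even though vacuolation varies — a deliberate simplification;
a variable-density Stokes model is out of scope.

## Units

Internal units are μm, days and pg; substrate concentrations cross the API
in μM. 1 μM of N (molar mass 14 g mol⁻¹) is 14×10⁻⁹ pg μm⁻³; speeds from
the s-based allometries are multiplied by 86 400. Transport masses are pgN
everywhere.

## Scans and fits

- **Size scans** default to 25 log-spaced ESD points on [2, 80] μm.
  Infeasible sizes (`TRD_Gmax > TRD_max`, i.e. `G_max` physically
  unattainable) are recorded per-point and excluded from fits.
- **Power fits** of `G_max/K_G = a·ESD^b` are ordinary least squares on
  log10 scale; R² is reported on that scale. Because `G_max/K_G` is
  invariant under `G_max` (verified to <10 % over 0.2–1.4 d⁻¹), the scan
  is run at a single `G_max`; pooling over a `G_max` grid changes the
  exponents by <0.01. The coefficient `a` is sensitive to the assumed
  diffusivity `D`, which is not tightly constrained; the exponents `b`
  are robust and are the quantitative reproduction targets.
- **RHt2 fits** (`V·S/(S+K)`) use bounded nonlinear least squares with
  double-reciprocal initialization, either free or with the plateau
  pinned to `G_max`. Two loss options: linear residuals (the default,
  matching conventional curve fitting of model output) and log residuals,
  the maximum-likelihood choice for data with multiplicative lognormal
  noise. Fitted half-saturations from bulk-concentration curves are
  apparent (`K_U`-style) parameters and are never labelled `K_T`.

## Synthetic data

`gen_uptake_experiment` emulates a short-incubation uptake assay: an
exact rectangular hyperbola on a log-spaced substrate grid (default 20
points spanning 0.05·K to 50·K, three decades bracketing the
half-saturation as a practitioner would design the assay) times
mean-one lognormal noise with a stated CV (default 10 %; uptake
measurement error scales with magnitude, so noise is multiplicative).
All generators draw from a local, explicitly seeded generator; there is
no global random state and outputs are bit-reproducible per seed.

`gen_tmax_table` emulates measured transport-capacity response curves: a
Gaussian bump over a linear baseline on the normalized-quota axis, holding
a floor just above the growth requirement at the replete quota, peaking
under moderate N stress (position and width drawn reproducibly from the
seed), collapsing at extreme stress, with an optional nitrate-style
repression of the replete end below the growth requirement. Parameter
combinations that break unimodality or non-negativity are rejected.

What the generators do *not* emulate: incubation-time dynamics of
satiation feedback, inter-replicate substrate depletion, biphasic
transporter systems, or the specific published response curves behind the
empirical mode (only their qualitative shape). Passing tests therefore
demonstrate correctness of the estimation and pipeline machinery under
the stated statistical assumptions, not fidelity to any particular
organism's measured kinetics.

## Numerical choices and edge cases

- Quota, transport and diffusion inversions are algebraically exact;
  round-trips hold to 1e-12/1e-10 relative in well-conditioned regimes.
  The Michaelis–Menten inversion is ill-conditioned when `S_0 ≫ K_T`
  (transport within rounding of saturation); property tests bound the
  ratio accordingly.
- Monte-Carlo validation of the fitter (500 replicate experiments at
  CV = 10 %) recovers the half-saturation with median relative error
  below 5 % using the log-residual loss; the linear-loss estimator is
  noticeably less efficient under multiplicative noise (~8–9 % median
  error on the same designs).
- Saturated points in growth sweeps are truncated with a logged warning;
  infeasible configurations raise at construction; queries outside an
  empirical `T_max` table are clamped to the end values with a warning.
- CSV output fixes float formatting at 6 significant digits so repeated
  runs are byte-identical.

## Known limitations

Non-spherical shapes, chains and colonies, multi-nutrient co-limitation,
mixotrophy, biphasic transporters, ammonium–nitrate interactions,
turbulence beyond the motion enhancement term, and nutrient-status-
dependent cell size or density are all outside the model's scope. The
predicted `K_G` values are often near or below chemical detection limits;
they should be read as mechanistic expectations, not as directly
measurable quantities.
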