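# Methods

This note documents the model equations, the numerical choices, the
synthetic-data design and the open design decisions, in the package's
own terms. Units follow a single internal convention: length m, time
days, concentration kg C/m³, areal stock kg C/m², litter input
kg C/m²/day. Analysis output converts to g C/m²/yr (or /month) where
that is the natural reporting unit. One model year is 365 days for
rate conversions; the simulation clock itself follows the real
calendar (leap days are simulated like any other day).

## State and discretization

The domain is a uniform square grid (default 2 m cells) with a single
boundary outlet. Each cell carries a soil column of initial
thickness 1 m, discretized into layers of 5–60 cm (default
0.05/0.05/0.10/0.10/0.20/0.20/0.30 m, chosen so interfaces fall at
0.05 m — the managed surface depth — and 0.20 m — the tillage depth).
Each layer holds three pools: litter (fast) C_l, humus (slow) C_h and
microbial biomass C_b. The surface layer thickness evolves with
erosion/deposition and is re-meshed into [0.05, 0.60] m by exchanging
material (with its concentration) with the layers below, which is
exactly mass-conserving.

## Landscape evolution

Elevation follows the Exner balance ∂η/∂t = −∇·q_d − ∇·q_s with zero
uplift (no bedrock weathering on the 50-year horizon; soil thickness
changes only through the surface). Hillslope diffusion uses a
face-centred conservative stencil with zero-flux domain boundaries;
the default diffusivity 0.002 m²/yr is at the low end of published
soil-creep values, appropriate for semi-arid shrubland and engineered
riser walls. Explicit Euler daily stepping is guarded by the
diffusion CFL check (D·dt/Δx² ≤ 0.25).

Overland transport operates on a D8 network built by priority-flood
depression filling with an epsilon gradient (flats drain; ties break
to the lowest linear index, so routing is deterministic). Because the
network changes slowly, it is rebuilt every 30 days. Discharge
accumulates runoff down the network; transport capacity is a stream
power law q_cap = (k_t/n)·q^1.5·S^1.1 and detachment capacity
D_c = (k_d/n)·q^0.5·S, with Manning's n per landcover (0.13 shrub,
0.09 cropland) and k_t = k_d = 4·10⁻⁴ by default — values chosen so a
15-m-relief synthetic watershed erodes at mm/yr order, consistent
with post-revegetation Loess Plateau rates. Cells are processed from
upstream to downstream; each erodes at min(D_c, capacity deficit) or
deposits when inflow exceeds capacity, and its *actual* outgoing flux
feeds the next cell, which makes the scheme exactly conservative:
area-integrated divergence equals outlet export. Exit cells pass
flux through unchanged (open boundary).

## Lateral SOC flux

Moving soil carries carbon: the SOC flux is k_soc·C₁·q for both
transport modes, with C₁ the surface-layer concentration of each pool
and k_soc the enrichment ratio (default 1 = no preferential
transport; configurable up to ~3). The diffusive part uses
donor-upwind concentrations on faces, so eroded material carries the
upslope cell's carbon. The overland part walks the same network:
detachment-limited cells contribute k_soc·C₁·D_c; capacity-branch
cells ship k_soc·C₁·q_out downstream, so deposition delivers the
donor mixture, partitioned across pools in donor proportions. Carbon
reaching an exit cell leaves the domain intact (it is counted as
export, not respired — the fate of fluvially exported SOC is outside
scope). Erosion exceeding the surface layer consumes sub-layers
top-down; pools are floored at zero and the floored mass is logged
and carried in the global budget.

## Hydrology

A single-bucket daily scheme per cell (1 m depth; porosity 0.45,
field capacity 0.30, wilting point 0.08 — loess-typical): rainfall
splits into infiltration (limited by a 20 mm/day capacity and the
remaining pore space) and same-day runoff; storage loses
moisture-limited evapotranspiration (monthly potential-ET
climatology) and free drainage above field capacity. The balance
closes to machine precision. The decomposition moisture factor
f_d(θ) is piecewise linear: 0 at oven-dry, 1 at field capacity,
falling to 0.25 at saturation. This bucket is deliberately simple —
it exists to supply runoff pulses and a realistic f_d trajectory, not
to resolve infiltration physics.

## Biogeochemical transformation

The three-pool total obeys

d(C_l + C_h + C_b)/dt = I_litter − r_r(K_l C_l + K_h C_h),
K_i = φ(C/N)·f_d(θ)·k_i·C_b.

Only this total balance is constrained by theory; the internal
transfer matrix is a design choice: litter decomposition splits
r_r → CO₂, r_h → humus, (1−r_r−r_h) → biomass; humus decomposition
splits r_r → CO₂, remainder → biomass; biomass dies back to humus at
a constant mortality rate. Any mass-conserving matrix satisfies the
total balance; this one is the conventional humification/microbial
loop. φ = 1 throughout (fertilised cropland; nitrogen never limits),
r_r = 0.7 (centre of the accepted 0.6–0.8 range), r_h = 0.2.

Parameter anchoring. The surface-carbon mean residence time is
defined as MRT = 1/(r_r·k_h·C_b,ref·f_d,ref·φ) at a frozen reference
state: C_b,ref = 0.2 kg C/m³ (5 % of the ~4.0 kg C/m³ ambient surface
SOC) and f_d,ref = 0.73, the multi-decadal mean of f_d under the
default bucket and regional climate. k_h is set so the ambient MRT is
exactly 12.9 years, giving k_h = 2.078·10⁻³ m³ day⁻¹ (kg C)⁻¹; k_l =
0.02 gives the litter pool a ~1-year surface turnover. Biomass
mortality (2.13·10⁻³/day) is the unique value that makes C_b
stationary at the reference state — a faster literature-style
mortality would drain the biomass pool and silently lengthen every
residence time, breaking the anchor.

Depth attenuation. Measured deep loess SOC is nearly inert, but a
uniform pool partition with K ∝ C_b would turn deep carbon over on
decadal timescales. Decomposition is therefore attenuated below the
surface layer by exp(−(z − z₁)/0.15 m), applied as a multiplier on
f_d before the rate law, so the surface-layer rates (and the MRT
anchor) are untouched while 0.5-m carbon turns over ~25× slower.

Bioturbation mixes all pools vertically with D(z) = D₀·e^(−z/0.3 m),
D₀ = 10⁻⁴ m²/yr, by an explicit conservative scheme with zero-flux
ends (sub-stepping if unstable). This weak mixing is what couples a
surface residence-time extension to the deeper column and produces
the saturating (diminishing-returns) response of stock to MRT: as the
surface loss rate shrinks, downward mixing into still-active layers
caps the gain.

Tillage uniformly mixes the top 20 cm of every cropland column each
April 1. The standalone column operation splits the layer straddling
the plough plane exactly; the gridded engine mixes to the layer
interface nearest 0.20 m (identical at the default layering), both
exactly mass-conserving.

Litter input splits 60 % above-ground (surface layer) / 40 % roots
(exponential profile, 10 cm e-folding, truncated at 30 cm).

## Daily step and ledgers

Operator order: hydrology → sediment transport + elevation → lateral
SOC transport → transformation → bioturbation (→ tillage on April 1).
Transformation therefore sees the post-transport surface layer. The
lateral and vertical ledgers record the *measured* stock difference
produced by their operators, so the per-cell identity
Δstock = lateral + vertical holds to machine precision by
construction — the ledgers are diagnostics of the actual arithmetic,
not parallel estimates. Globally,
litter − efflux − export + floored = Δ(total stock) to ~10⁻¹⁴
relative (the "floored" term is the logged non-negativity clipping,
zero in typical natural-watershed runs).

## Synthetic watersheds

The generators reproduce the statistical structure the analysis
relies on, not any particular real site.

- Terrain: a sine-bend main valley (1.5 bends, amplitude 22 % of the
  grid height) descending to an eastern outlet, hillslopes rising as
  dist^0.8 to the divide, plus smoothed Gaussian incision noise;
  everything scales with a single `relief` parameter (default 15 m on
  the 64-m desk-scale domain — ~45 % gully-wall slopes). The boundary
  rim is raised above its inward neighbours so the carved outlet is
  the only exit; an exhaustive D8 walk confirms full drainage. The
  consolidated variant replaces the valley floor with 6 terraced
  parcels (0.05 % tilt — flat at the 0.5 % criterion) separated by
  step risers, and marks them cropland.
- Weather: two-state Markov occurrence (persistence 0.3) with
  monthly stationary wet-day probabilities and gamma amounts; the
  packaged monthly table (wet-day probability, gamma shape, derived
  scale) makes the expected monthly totals sum to exactly 560 mm with
  a July–September maximum. The generator is unbiased (2000-year
  mean 561 ± 2 mm); a 40-year ensemble has ~2.7 % standard error on
  its mean annual total.
- NDVI: deterministic day-of-year curves — natural cover 0.12
  dormant/0.45 peak, cornfield 0.10/0.75 (denser canopy), growing
  season May–September.
- Litter: rate = baseline·exp(4·NDVI). The class baselines
  (cornfield 3.68·10⁻⁵, natural 1.062·10⁻⁴ kg C/m²/day) were
  calibrated once, by bisection on an 8-year single-column
  integration at the reference moisture factor, so each class's
  annual input (≈57 and ≈98 g C/m²/yr) balances decomposition at its
  initial profile — i.e. the ambient state sits near the saturated
  stock the residence-time anchor implies. The natural class needs
  more carbon than the cornfield because its surface SOC (and hence
  respiration) is higher; litterfall per unit NDVI differs freely
  between classes.
- Initial SOC: surface maps are class means (cornfield 3.08 g C/kg ≈
  4.0 kg C/m³ at the 1300 kg/m³ default bulk density; natural 3.60)
  with 8 % smoothed spatial noise; depth profiles use the fitted
  class constants (natural b = 9.63 /m, c = 2.55 g/kg; crops
  b = 7.06, c = 2.27), pools partitioned 0.10/0.85/0.05.

What the synthetic fixtures do *not* emulate: real drainage-network
geometry and hypsometry, spatially correlated storms, NDVI
interannual variability, measurement error in surveys, and any
absolute erosion-rate validation. Passing tests therefore demonstrate
internal consistency (conservation, identities, qualitative regime
contrasts and scenario orderings) — not site-level predictive skill.

## Problem sizes used in the shipped checks

Desk-scale sizes keep the full suite fast while exercising every
coupling: ledger identity on 16×16 × 1 yr; carbon closure on
32×32 × 5 yr; regime contrast (transport vs transformation, ratio
> 10 on consolidated parcels) on 32×32 × 3 yr; the 3 litter × 6 MRT
sweep on 32×32 × 20 yr (18 full engine runs). The "order of
magnitude" comparison uses monthly-climatology flux magnitudes
(mean over months of |monthly flux|), since long-run *net*
transformation is near zero at quasi-equilibrium and its magnitude
would be meaningless as a denominator.

## Numerical details and degenerate inputs

- Tie-breaks: routing picks the steepest descent, then the lowest
  linear index; an all-flat DEM routes deterministically with a
  logged warning. Zone classification at boundaries: a zero flux
  defers to the non-zero component; the exact origin is a seventh
  internal "neutral" code excluded from the six-way percentages.
- Kriging uses an exponential variogram fitted by weighted least
  squares to binned empirical semivariances; a singular or
  non-finite system falls back to inverse-distance weighting
  (power 2) with a logged warning. Both interpolators are exact at
  sample locations.
- The transformation step sub-divides itself (recursive halving, cap
  12) whenever a pool would cross zero; bioturbation sub-steps on its
  stability number. Elevation stepping floors soil thickness at zero
  and logs the deficit.
- Seeds: every stochastic generator takes one explicit seed;
  identical seeds give bit-identical outputs end to end.

## Known limitations

- The hydrology is a stand-in bucket; no sub-daily routing, dynamic
  surface water depth, Richards flow or snow.
- No temperature regulation of decomposition, explicit nitrogen
  cycling, or grain-size-selective transport.
- Check dams act only through their topographic expression (flat
  parcels); trapping mechanics are not modelled.
- The concavity of the stock-vs-MRT response at 20 years is
  shallow near the long-MRT end; increments are compared with a 1 %
  -of-span tolerance to absorb the discretization wiggle.
- The desk-scale domain (64 m) compresses a real ~0.45 km² watershed;
  absolute flux magnitudes are indicative, not calibrated.
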