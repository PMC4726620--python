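# Methods

`rspm` simulates microbial life on hydrated rough soil surfaces.  The domain
is a bounded hexagonal lattice of *patches* (pointy-top, six neighbours,
centre spacing `l_p`, default 500 µm; a 100×100 domain spans ~5 cm).  A patch
is not a pore: it is a statistically averaged piece of rough surface whose
hydration physics is carried by two roughness measures, and it can host many
cells of many species.

## 1. Patch water physics

Each patch is a mixture of a smooth surface fraction and a porous fraction
(areal share Φ ∈ [0,1]) made of square-pyramid surface pores (base and depth
r).  Pore sizes follow a truncated power law with integration weight
r^-(D+1) on [r_min, r_max] (defaults 10⁻⁷ m and 10⁻³ m), D ∈ (1,2) the
fractal dimension of the roughness.  At matric potential ψ_m (Pa, < 0):

- **Capillary water** fills a pore from the apex to the height z\* where the
  inscribed radius of the square cross-section (z/2) equals the
  Young–Laplace radius r_cap = 2σ cosθ/|ψ_m| (σ = 0.072 N/m, θ = 0), i.e.
  z\* = min(r, 2 r_cap), holding volume z\*³/3.
- **Adsorbed films** cover everything else with
  h_µ = max(h_min, (A/(6π|ψ_m|))^{1/3}); A is tuned so h_µ ≈ 2 nm at
  ψ_m = −10⁵ kPa (a few molecular layers under extreme drought).

The patch-scale **effective film thickness** is the expected water volume
per expected area under the pore-size weight,

    w_eff(ψ) = [∫(Φ V(r,ψ) + (1−Φ) h_µ r²) r^-(D+1) dr] / [∫ r² r^-(D+1) dr],

which is affine in Φ — the property that lets a whole heterogeneous domain
be evaluated from one quadrature per ψ_m plus the per-patch porosity field.
Degree of saturation is S(ψ) = w_eff(ψ)/w_eff(−1 Pa); −1 Pa is the
near-saturation reference (the adsorbed-film term diverges as ψ → 0⁻, so a
finite wet reference is needed; any |ψ| ≤ 1 Pa changes S by < 1%).

Integrals use adaptive quadrature split at the fill-rule kink (2 r_cap);
tests hold them to 10⁻⁶ relative against 10⁵-node trapezoid oracles.

## 2. Domain heterogeneity

Surface porosity is spatially self-affine with Hurst exponent H = 2 − D.
Fields are synthesised spectrally (power spectrum ∝ k^-(2H+2)) on a 2×
oversampled lattice and subsampled — without oversampling the missing power
beyond the Nyquist frequency flattens the increment scaling at small lags —
then scaled to standard deviation 0.15 (a realistic patch-to-patch porosity
spread that rarely clips at [0,1] for Φ̄ ≈ 0.4–0.5), shifted to the target
mean and iteratively re-centred after clipping (mean honoured to 10⁻³).
Mono-scale experimental surfaces (porous ceramic) use i.i.d. Φ ~ U[0,1]
instead.

Each patch draws a local percolation threshold from
Normal(⟨p_c⟩(H), 0.08) truncated to (0.05, 0.95), with ⟨p_c⟩ interpolated
piecewise-linearly through the known self-affine values (0, 0.5),
(0.2, 0.46), (1, 0.386).

## 3. Motility force balance and calibration

Swim speed in a film of thickness w follows
v = v₀ (F_M − F_λ − F_c)/F_M clamped at 0, with v₀ = 14 µm/s:

- lubrication drag F_λ/F_M = c·(a/(w−a))^n for w > cell radius a = 0.5 µm
  (diverges as the film approaches the cell radius);
- capillary pinning F_c/F_M ∝ σ × exposed contact perimeter for w < cell
  diameter (enormous relative to the ~0.6 pN flagellar thrust, so any
  partially emerged cell is pinned; the drag term already forces v = 0 well
  above this regime).

The two free constants are solved *once* (`scripts/calibrate_forces.py`)
from two anchors evaluated through the retention model itself:
v(w_eff(Φ=0.4, D=1.8, −0.1 kPa)) = 10 µm/s (roughness lowers the wet-limit
mean speed from 14 to ~10 µm/s) and v(w_eff(Φ=0.5, D=1.8, −2 kPa)) = 0
(onset of pinning at the mean-porosity surface).  This puts the motility
film threshold at 5.37 µm — several cell diameters, because w_eff is a
patch average over mostly-dry area.  The calibrated values are frozen as
defaults (`c = 5.4848360`, `n = 0.7476053`).

## 4. Habitat connectivity

A patch is **motile** when (1) v(w_eff) > 0 and (2) the occupation
probability p of accessible pore regions exceeds the patch's local
percolation threshold; otherwise cells there are pinned (**sessile**).

p is defined over the pore network (the conduits of within-patch motion):
the area share F of pore regions that are capillary-wetted
(min(1, (2 r_cap/r)²) of each pore) *and* whose water pocket depth
z\* + h_µ reaches the force-model film threshold, plus the smooth-surface
route when the adsorbed film alone supports swimming:
p = F + (1−F)·1{v(h_µ) > 0}.  Design note: scaling p by Φ instead was
rejected — the smooth term is zero at every realistic ψ_m, so p ≤ Φ would
hold at *all* hydrations and domains with Φ̄ ≈ 0.4–0.5 could never
percolate even saturated, contradicting the wet-connected behaviour the
model must show.  As defined, p → 1 as ψ → 0⁻, p → 0 when all films fall
below the motility threshold, and p is strongly ψ-dependent over the
ecologically active −0.5…−3.6 kPa range.

**Aqueous habitats** are connected components of motile patches (hex
adjacency, `scipy.sparse.csgraph`); the global percolation probability P is
the largest-cluster share of the whole domain.  Local connectivity is the
piecewise ξ = P if p > p_c else p·P; tortuosity is 1/ξ; the minimum
residence time of a cell in a patch is T_r = l_p/(v ξ), infinite on sessile
patches.  The domain average T̄_r is reported both over all patches
(divergent once any patch is sessile) and over motile patches.

## 5. Nutrient transport

Dissolved nutrients move by film diffusion between adjacent patches with
conductance g = D_aq · τ_MQ(S_min) · w_min L_edge / l_p, where the *thinner*
film of the pair sets both the cross-section w_min and the saturation in
the Millington–Quirk tortuosity τ_MQ = S^{7/3} (exponent switchable to 1).
The update is explicit, conservative Euler on the conductance Laplacian,
sub-stepped to the stability bound 0.5·min(V_w/Σg); closed domains conserve
mass to 10⁻¹⁰ relative over 10³ steps.  Boundary modes: closed, or
Dirichlet (boundary patches pinned to C₀).  Patch water volume is
V_w = patch area × w_eff with area (3√3/8) l_p² (regular hexagon of
circumdiameter l_p).

## 6. Individual-based dynamics

Cells carry biomass, patch, an in-patch displacement accumulator and a
starvation clock.  Per step (operator splitting: diffuse → grow/consume →
divide/die → move):

- **Growth**: multi-nutrient min-law Monod, µ = µ_max·min_j C_j/(K_j+C_j),
  maintenance m = α_m µ_max (default α_m = 0.1), net µ̃ = µ − m (may be
  negative).  The stochastic **sharing factor** f_p = ξ + χ_p(1−ξ),
  χ_p ~ U[0,1] drawn per cell per step, scales each cell's realised Monod
  rate: in a fully connected patch (ξ=1) uptake is deterministic and the
  fittest species wins; in a fragmented patch (ξ→0) access is random,
  which is the mechanism that equalises species under dry conditions.
  Design note: applying f_p to consumption only (leaving growth at the
  concentration-only rate) would let cells at ξ = 0 fix more biomass than
  the substrate they consume; scaling the realised rate closes the
  substrate-to-biomass ledger exactly (growth = Y × uptake when
  maintenance is off) while preserving every stated limit.
- **Caps**: patch uptake is limited by available mass; growth rescales
  proportionally and concentrations never go negative.
- **By-products**: a producer diverts β of gross growth, excreting mass
  β µ b dt into its by-product nutrient and growing at (1−β) µ̃.
- **Division/death**: division at 2× initial mass into equal halves
  (3×10⁻¹⁶ kg threshold, E. coli-scale dry mass); the starvation clock
  accrues while µ̃ ≤ 0, resets otherwise, and kills at 24 h (configurable).
- **Motion**: on motile patches displacement grows by v dt; when it
  exceeds the tortuous path length l_p/ξ the cell draws one of 7 directions
  (6 neighbours + stay) with probability ∝ w_i exp(α ∇µ·ê_i), where
  α = χ₀/(2 µ_max v) and the gradient projection is the neighbour
  difference of the species' growth-rate field.  Crossings never leave the
  cell's aqueous habitat.  Unbiased cells (χ₀ = 0) perform a diffusive
  random walk (MSD linear in time), a property test.

RNG: one named stream per concern (field, placement, sharing, motion),
spawned from the master seed — runs are bit-reproducible.

## 7. Population-level theory and metrics

With run durations T(u) = t₀ e^{α|∇µ|u} the biased walk has closed-form
drift v_eff = v·R_c, R_c(x) = I₁(x)/I₀(x) (computed with exponentially
scaled Bessels), the chemotactic retardation factor; the chemotactic
residence time is T\* = T̄_r/R_c.  The mean-field analytic expansion rate
of a chemotactic ring is v·R_c(α|∇µ|)·ξ̄ with the domain summarised by its
mean porosity and a one-patch-wide growth-rate front |∇µ| = µ(C₀)/l_p.
χ₀ is calibrated (same script) so this rate is 500 µm/hr at −0.5 kPa on
the Φ̄ = 0.5 reference domain; it vanishes at −2 kPa automatically via the
force-model anchor.  χ₀ = 5.556×10⁻¹⁰ m²/s with the reference species
(µ_max = 1 hr⁻¹, K_s = 1 mg/L).

Community metrics: normalised Shannon evenness
H_D = −(1/ln N_s) Σ p_i ln p_i; coexistence index CI = generation length
(|v_eff| ln2/µ̃) over habitat linear size (√patches × l_p).  On a run, CI
is evaluated per living cell at the final snapshot using the patch-local
concentration (drift from the strongest neighbour growth-rate difference;
sessile cells count 0, cells with µ̃ ≤ 0 are excluded) and averaged per
species into the manifest.  Colony diameter is reported as twice the
95th-percentile radial cell distance from the inoculation centroid (robust
to stragglers), with expansion rates fitted over the final
half of the pre-boundary transit, or measured as the running-maximum
footprint secant in the scaled-down comparisons (demography can shrink the
percentile radius; a colony's reached footprint does not retreat).

## 8. Scenario presets and scaled problem sizes

- *Dispersion*: mono-scale U[0,1] porosity, D=1.8; 1 mg/L nutrient held at
  the boundary; 100 cells at 4 central patches; −0.5/−1/−3 kPa; 60 h.
- *Trophic*: Φ̄=0.4, D=1.2 self-affine; 0.2 mg/L boundary nutrients; 50+50
  cells mixed at the centre; competition = two obligatory nutrients with
  cross-ranked yields (each species converts its preferred nutrient *less*
  efficiently, hence drains it harder); mutualism = producer (β=0.3) feeding
  a by-product consumer.
- *Diversity*: 50 species differing only in Monod parameters, µ_max uniform
  on 0.44–1.23 hr⁻¹ and K_s log-uniform on 40 µg/L–99 mg/L (the E. coli
  spans); single closed nutrient; sand (D=1.35) vs silty-clay (D=1.65);
  mixed-at-centre vs random inoculation.

Presets default to the reference 100×100 grid with a `--small` (32×32)
switch.  The shipped tests run deliberately scaled problems chosen for
desk-scale reproduction: 32×32 dispersion domains over 12 h windows
(≈4× the wet front's domain-transit time, so both regimes are measured on
one protocol), 24×24 diversity domains over 12 h (populations are
nutrient-limited and stationary well before that), 5 paired seeds per
comparison.

## 9. What the tests do and do not show

The generators emulate the *statistical* structure of hydrated rough
surfaces (self-affine porosity, stochastic local thresholds); they do not
represent explicit pore geometry, vertical structure, advective flow,
surfactant effects, dormancy, or cell–cell attachment, so passing tests
support the mechanisms (hydration-controlled connectivity, diffusion-
limited competition, fragmentation-promoted coexistence) rather than
site-specific prediction.  Two further caveats:

- Dispersal in wet, connected domains is dominated by the unbiased
  component of the patch-crossing walk, so colony footprints grow faster
  than the chemotactic-front theory predicts; the wet/dry contrast (~40×)
  is reproduced, absolute wet simulated rates exceed the analytic rate.
- Once the domain fragments (below about −2.5 kPa) the largest-cluster
  connectivity makes per-patch crossing lengths longer than the domain, so
  simulated expansion stops there rather than persisting to −3 kPa; see
  the known-red acceptance test for the quantitative statement.

Degenerate inputs are rejected early (grids < 4×4, ψ_m ≥ 0, Φ outside
[0,1], D outside (1,2), inconsistent species/nutrient tables); NaNs in the
nutrient field abort a run with a diagnostic.
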