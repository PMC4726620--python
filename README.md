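# rspm — rough-surface patch model

An individual-based simulator of microbial communities living in the water
films of rough soil surfaces.  Soil microbes grow, compete and disperse in
micrometric aqueous habitats whose geometry is set by the soil's matric
potential ψ_m: as the surface dries, films thin, capillary pinning stops
flagellated swimming, and the connected aqueous phase fragments into
isolated habitats.  `rspm` is aimed at quantitative soil microbial
ecologists who want to ask how hydration and surface roughness (soil
texture) shape dispersal, trophic interactions and community diversity —
at scales from single patches (~500 µm) to centimetre domains — without
resolving explicit pore geometry.

## Model core

A domain is a hexagonal lattice of roughness patches.  Two measures per
patch carry all hydration physics: the surface porosity Φ (areal share of
pyramid-shaped surface pores) and the fractal dimension D of the pore-size
power law N(r) (weight r^-(D+1), cutoffs r_min, r_max).  From these the
effective water film thickness follows as a pore-ensemble expectation,

    w_eff(ψ_m) = ∫[Φ V(r, ψ_m) + (1−Φ) h_µ(ψ_m) r²] r^-(D+1) dr
                 / ∫ r² r^-(D+1) dr,

combining capillary pore water V (Young–Laplace fill rule) and adsorbed
van der Waals films h_µ.  Swim speed obeys a force balance
v = v₀(F_M − F_λ − F_c)/F_M (propulsion vs lubrication drag and capillary
pinning); patches are motile where v > 0 and the occupation probability of
accessible pore regions exceeds a local, Hurst-exponent-dependent
percolation threshold (⟨p_c⟩(H): 0.5 at H=0, 0.46 at H=0.2, 0.386 at H=1).
Motile patches form aqueous habitats with local connectivity
ξ = P if p > p_c else p·P.  On this landscape, nutrients diffuse through
the thinner of adjacent films (Millington–Quirk-corrected), and individual
cells follow min-law Monod growth with maintenance, stochastic nutrient
sharing f_p = ξ + χ_p(1−ξ), division, starvation death, by-product
mutualism, and a chemotactic biased random walk whose population drift is
the Bessel ratio v·I₁(α|∇µ|)/I₀(α|∇µ|).  Community output includes the
normalised Shannon evenness H_D and the coexistence index (generation
length over habitat size).

See `docs/methods.md` for assumptions, calibration and numerical choices.

## Worked example

```python
from rspm import (RoughnessParams, effective_film_thickness, swim_speed,
                  build_grid, compute_hydration_state, analytic_expansion_rate)
from rspm.ibm import CAL_CHI0

surface = RoughnessParams(Phi=0.4, D=1.8)
for psi_kpa in (-0.5, -2.0, -3.6):
    w = effective_film_thickness(surface, psi_kpa * 1e3)
    v = swim_speed(w)
    print(f"psi={psi_kpa:+.1f} kPa  w_eff={w*1e6:6.2f} um  v={v*1e6:5.2f} um/s")

grid = build_grid(32, 32, RoughnessParams(Phi=0.5, D=1.8), seed=1,
                  porosity="uniform")
for psi_kpa in (-0.5, -2.0):
    st = compute_hydration_state(grid, psi_kpa * 1e3)
    rate = analytic_expansion_rate(RoughnessParams(Phi=0.5, D=1.8),
                                   psi_kpa * 1e3, CAL_CHI0, 1/3600, 0.5)
    print(f"psi={psi_kpa:+.1f} kPa  motile={st.motile_fraction:.2f}  "
          f"P={st.P_global:.3f}  analytic rate={rate*3600e6:5.1f} um/hr")
```

prints

```
psi=-0.5 kPa  w_eff= 19.41 um  v= 8.92 um/s
psi=-2.0 kPa  w_eff=  4.31 um  v= 0.00 um/s
psi=-3.6 kPa  w_eff=  2.17 um  v= 0.00 um/s
psi=-0.5 kPa  motile=0.90  P=0.898  analytic rate=500.0 um/hr
psi=-2.0 kPa  motile=0.26  P=0.023  analytic rate=  0.0 um/hr
```

Reading this: at −0.5 kPa the Φ=0.4 surface holds a ~19 µm effective film
and cells swim at ~9 µm/s (the wet-limit patch mean is ~10 µm/s, down from
v₀ = 14 µm/s in bulk water); by −2 kPa capillary pinning has stopped
swimming entirely.  On a heterogeneous 32×32 domain, 90% of patches are
motile and percolate at −0.5 kPa (P ≈ 0.9, a single connected habitat),
while at −2 kPa only 26% remain motile and the largest habitat covers 2%
of the domain; the analytic chemotactic ring expands at 500 µm/hr wet and
stalls at −2 kPa.

Full experiments run from the CLI:

```bash
rspm preset dispersion --psi-kpa -0.5 --small --out out/   # colony spread
rspm preset trophic --kind mutualism --psi-kpa -3.6 --small --out out/
rspm preset diversity --texture silty_clay --inoculation random --small --out out/
rspm hydrate config.yaml --psi-kpa -1.0          # abiotic state only
rspm run config.yaml --out out/                  # any YAML scenario
```

Each run writes `metrics.csv` (abundances, evenness, colony diameter over
time), `hydration.csv`, `cells.csv`, `fields.h5` and a JSON manifest with
the config, seeds and divergence flags.

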