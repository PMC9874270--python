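# mcfsim — coarse-grained mechanics of mineralized collagen fibrils

Mineralized collagen fibrils (MCFs) — staggered tropocollagen molecules
interpenetrated by hydroxyapatite (HAp) mineral — are the basic building
block of bone and mineralized tendon. How the *amount* and the *spatial
pattern* of mineral set the fibril's strength, ductility and fracture
mode is hard to probe experimentally on a single fibril. `mcfsim`
implements a coarse-grained molecular-dynamics framework for exactly
this question: it builds idealized D-periodic bead fibrils, patterns
them with FCC-packed mineral, pulls them in uniaxial tension with a
breakable force field, and resolves stress, sliding and fracture at the
level of individual protofibrils (single collagen molecules).

It is aimed at researchers in fibril/bone micromechanics who want a
small, fully scriptable, reproducible alternative to driving a general
MD engine plus a pile of one-off analysis scripts.

## Model

Each collagen molecule is a chain of beads spaced 14 Å apart
(219 beads/molecule by default); chains sit on a quasi-hexagonal lattice
(15.3 Å spacing) and are axially staggered by multiples of the D-period
(67 nm) with tandem period 5D, which produces the Hodge–Petruska gap
(0.445 D) / overlap (0.555 D) structure. Mineral beads fill cylindrical
regions of length *l*·D and radius *r* on an FCC lattice and are carved
away within a cutoff of collagen; the cutoff is tuned by bisection to a
target mineral mass fraction (degree of mineralization, % w/w).

Interactions (kcal/mol, Å):

* **Bilinear breakable bond** between consecutive beads:
  U = ½k⁽⁰⁾(r−r₀)² for r < r₁; ½k⁽¹⁾(r−r̄₁)² + U_off for r₁ ≤ r < r₂;
  0 for r ≥ r₂, with k⁽⁰⁾ = 17.13, k⁽¹⁾ = 97.66, r₀ = 14.00,
  r₁ = 18.20, r₂ = 21.00. r̄₁ and U_off follow from force and energy
  continuity at r₁; the drop at the breaking distance r₂ models bond
  rupture.
* **Harmonic angle** U = ½k_θ(θ−θ₀)², k_θ = 14.98, θ₀ taken from the
  as-built geometry clamped to [164°, 180°].
* **Truncated Lennard-Jones pairs** 4ε[(σ/r)¹²−(σ/r)⁶] for r below the
  cutoff, per species pair: collagen–collagen (6.87, 14.72, 21.0),
  HAp–HAp (193.7, 10.28, 13.85), collagen–HAp (137.1, 9.88, 20.0).

Dynamics: velocity Verlet (dt = 10 fs) with Nosé–Hoover chains (or
Langevin), a z-axis Berendsen barostat for NPT equilibration of the
periodic cell, and a constant-strain-rate tension protocol that rigidly
pulls the top 2.5 %-length end region while holding the bottom one
fixed. Stress is the configurational per-bead virial (tensile
positive), divided by the current fibril volume πR²L; phase stresses
use volumes proportional to bead fractions. Derived metrics: secant
modulus at 4 % strain, UTS, fracture strain (10 %-of-UTS drop rule),
toughness (area under the curve), residual stress/strain, per-
protofibril non-affine sliding, and broken-protofibril accounting.

## Worked example

The one-shot reduced pipeline (5 nm × 5D fibril, 35 % w/w gap-only
mineral, short equilibration, tension at 2×10⁹ s⁻¹):

```bash
mcfsim demo --seed 7 --out out/
```

prints (abridged):

```json
{
  "n_beads": 2360,
  "n_molecules": 7,
  "uts_MPa": 765.99,
  "uts_strain": 0.0335,
  "secant_modulus_MPa": 14610.1,
  "residual_stress_MPa": 345.99,
  "residual_strain": 0.0137,
  "n_broken_protofibrils_final": 6,
  "mean_abs_sliding_A": 244.3
}
```

meaning: this (tiny, fast-pulled) mineralized fibril reaches its
ultimate tensile strength of ~766 MPa at 3.4 % strain, starts from a
~346 MPa residual (mineral-induced) stress state at zero applied
strain, stores 1.4 % residual bond strain from equilibration, and
fails by rupture of 6 of its 7 protofibrils. `out/stress_strain.csv`
holds the full global and per-phase (collagen/mineral tensile + shear)
curves; `out/protofibril_metrics.csv` the per-protofibril radius
ordering, sliding, stress and break flags.

The same stages are available separately (`build`, `mineralize`,
`equilibrate`, `pull`, `analyze`) with a YAML config; library users
call `mcfsim.pipeline.simulate_tension_case` directly.

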