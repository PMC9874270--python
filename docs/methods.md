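# Methods

This note documents the model, the numerical choices, and what the
synthetic structures do and do not capture. Everything quantitative
stated here is computed by the test suite or `scripts/acceptance.py`.

## Structure generator

The fibril is an idealized stand-in for a crystallographically derived
microfibril bundle. Straight bead chains (beads every 14 Å,
219 beads/molecule, contour 305.2 nm) are placed on a quasi-hexagonal
lattice; the 15.3 Å lattice constant was chosen so that a 20 nm
diameter holds ≈155 molecules (the generator yields 151 for the default
stagger rule), consistent with the reference cross-section. Chains at
lattice site (i, j) are staggered axially by ((i + 2j) mod 5)·D with
tandem period 5D; alternative rules ("2i+j", "i+3j", …) permute the
phase field and serve as structure replicates. The default D = 67 nm
makes 5D = 335 nm and 50D = 3.35 µm.

With contour c = 218 × 1.4 nm, every D-period splits into a vacant gap
interval of g·D, g = (5D − c)/D ≈ 0.445, and an overlap interval of
(1 − g)·D. The generator labels every bead accordingly; the gap
fraction recovered from the built geometry equals the closed form to
machine precision (a test asserts this per lattice site).

Builds are axially periodic by default (molecule count = lattice
sites), which is the natural cell for NPT equilibration. For tension,
`open_chain_ends` cuts the bonds that wrap the axial boundary of the
*equilibrated* coordinates — equivalent to excising a finite segment
from an infinite fibril — and the resulting chain fragments count as
separate protofibrils. Protofibril IDs are assigned by sorting
molecules on mean axial-distance from the fibril axis (ties broken by
azimuth, then molecule id), so larger IDs sit at larger radius.

A plain-text import path (`molecule_id x y z` per bead) accepts
externally derived bead axes, so a user holding coordinates extracted
from the PDB microfibril structure can substitute them for the
idealized lattice; crystallographic processing itself is out of scope.

## Mineralization

Mineral beads fill cylinders (length l·D centred on each gap midpoint,
radius r) on an FCC lattice whose conventional-cell edge
a = √2·2^{1/6}·σ_HAp ≈ 16.32 Å puts nearest neighbours at the HAp–HAp
LJ minimum. The lattice is anchored at the region corner; beads from
abutting regions closer than a/2 are de-duplicated. Carving removes
mineral beads whose nearest collagen distance is below a cutoff; the
cutoff is found by bisection on the precomputed nearest-distance array
until the mineral mass fraction is within 0.25 % (absolute) of target,
which is deterministic and exact up to single-bead granularity.

Bead masses are not part of the calibrated parameter set; the default
assigns the tropocollagen mass spread over its beads
(285 kDa / 219 ≈ 1301 amu) to both species, so w/w equals the
bead-count fraction. This reproduces the reference system sizes: the
35 % w/w, 20 nm × 5D build has ≈51 000 beads, the non-mineralized one
≈34 000. Both masses are configurable.

Gap-only patterns (l = 0.44D < g·D) give exactly zero overlap-region
mineral concentration. For l = D at 35 % w/w the overlap concentration
computed by the acceptance script is ≈11.7 % w/w (mean over three
stagger variants); the idealized lattice carves slightly more
aggressively in the overlap than the crystallographic structure does,
so this sits a little below the reference table value (13.7 %).

## Force field and units

Units are LAMMPS-style "real" (kcal/mol, Å, fs, amu); the stress
conversion is 1 kcal mol⁻¹ Å⁻³ = 6947.7 MPa and the acceleration
constant (kcal/mol/Å per amu → Å/fs²) is exactly 4.184×10⁻⁴.

The bilinear bond as printed leaves r̄₁ (the second-branch equilibrium
distance) unconstrained and is energy-discontinuous at r₁ for any
single choice. Dynamics depend on forces, so the closure used here is
force continuity, r̄₁ = r₁ − (k⁽⁰⁾/k⁽¹⁾)(r₁ − r₀) ≈ 17.463 Å, plus an
energy offset ≈124.59 kcal/mol that restores energy continuity. The
discontinuous drop to zero at r₂ (≈735 kcal/mol of stored energy) is
the rupture event; it is asserted, not hidden. Break flags are
recorded whenever a bond is observed at r ≥ r₂. The potential itself
is stateless (re-engages below r₂) by default; a permanent-break mode
skips flagged bonds, and fracture accounting always uses the
"ever exceeded r₂" flags, so counts are monotone either way. An angle
is inactive while either of its bonds exceeds r₂.

Nonbonded exclusions: 1–2 and 1–3 intra-molecular pairs. A bonded pair
at 14 Å sits far inside the collagen LJ σ = 14.72 Å and would
otherwise add an enormous spurious repulsion; 1–3 pairs at ≈28 Å are
beyond the 21 Å cutoff anyway. LJ is truncated without shift, exactly
as specified. Per-angle θ₀ is the as-built angle clamped to
[164°, 180°] — 180° for the straight synthetic chains — and is frozen
at build time so later stages do not re-baseline thermal curvature.

## Dynamics

Velocity Verlet with dt = 10 fs (the lightest bead is ≈1301 amu; the
stiffest bond gives a ≈1.1 ps period, ~110 steps/period; the NVE suite
verifies |ΔE/E| < 10⁻⁴ over 10⁵ steps). Thermostat: Nosé–Hoover
chains (length 3, τ = 100·dt) on the free beads — deterministic, so
every stage is bit-reproducible per seed; Langevin is available as an
option. Velocities initialize Maxwell–Boltzmann at 300 K with zero net
momentum.

Axial NPT for equilibration uses a weak Berendsen-style barostat: every
10 steps the periodic z box and coordinates are rescaled toward 1 bar
axial stress (rate-clamped to 10⁻⁴ per application); the full
anisotropic MTK equations are intentionally not implemented. The x/y
directions are open (free fibril surface). Stress for the barostat and
all reporting uses the fibril volume πR²L with R the 95th-percentile
collagen radial distance (robust to stray beads) and L the axial cell
length (periodic) or bead span (open).

Tension: grips are the beads within 2.5 % of the total length at each
end; the top grip moves rigidly at v = strain-rate × L_free(0), where
L_free(0) is the initial distance between the inner grip faces, so
engineering strain is exactly rate × time. Grip beads are excluded
from the thermostat and their coordinates are imposed exactly each
step. Before dynamics, a capped steepest-descent minimization relaxes
the lattice-placed mineral contacts (carve cutoffs below the
collagen–HAp σ leave steep repulsive contacts that would otherwise
require a much smaller timestep).

## Observables

Per-bead virial: pair/bond terms contribute ½·(dU/dr / r)·d⊗d to both
partners, angle terms −(Σ r_k⊗F_k)/3 to each of the triple, with the
kinetic term excluded (configurational stress only); the sign
convention is tensile positive. A test verifies the summed σ_zz
against the numerical strain derivative of the energy to 1 %, and the
analytic forces against central differences to 10⁻⁶.

Phase stress divides each species' virial sum by V × (bead fraction),
so the fraction-weighted phase tensors recombine to the global tensor
identically. "Shear stress" of a phase is √(σ_xz² + σ_yz²) — the
axial-shear magnitude — since the observable is reported without naming
a component. Curve metrics operate on an 11-sample centred moving
average (raw curves are always stored): secant modulus = σ(0.04)/0.04,
UTS = max, fracture strain = last strain before the smoothed stress
first drops below 10 % of UTS after the peak (the "final fracture
event" needs an operational rule), toughness = trapezoidal area to the
fracture strain.

Sliding of protofibril i is its z-centre-of-mass displacement minus the
affine expectation, [z_i(t) − z_i(0)] − ε(t)[z_i(0) − z_fixed]; it
vanishes identically under affine deformation and is invariant to
translating the whole trajectory. Residual strain is the mean bond
strain r/r₀ − 1 after equilibration at zero load, per protofibril and
bond-weighted for the fibril. A protofibril is "mineralized" when any
mineral bead is within the collagen–HAp cutoff (20 Å) of any of its
beads.

## Reduced-scale study conditions

The full-size system (20 nm × 50D, ≈3.4×10⁵ beads, 20 ns equilibration
+ tension at 2.5×10⁶ s⁻¹ to >25 % strain, i.e. ≥10⁷ steps) is far
beyond a single-CPU test suite; it can be configured but not run here.
The suite instead compares 0 % and 35 % w/w gap-only fibrils at
8 nm × 5D (≈4 200 / 6 400 beads), equilibrated 200 ps (NPT-z) and
pulled at 5×10⁸ s⁻¹ to 50 % strain — sizes chosen as the smallest at
which the mineralization contrasts are developed. At this scale the
*orderings* are the meaningful output, and all of them reproduce:
mineralization raises the UTS, the mineral phase out-stresses collagen
below ~5 % strain with the reversal at large strain, mineralized
fibrils hold about an order of magnitude more residual bond strain and
a higher residual stress, and protofibril sliding (mean |sliding| up to
30 % strain) is suppressed. Magnitudes are not expected to match the
full-scale system: the strain rate is 200× higher, the cross-section
25× smaller, and the crossover strain sits lower than at full scale
(~15 %).

Two reduced-scale caveats follow from the idealized geometry rather
than the method: (i) straight chains give the fibril no crimp, so there
is no toe region and collagen loads immediately; (ii) the residual bond
strain stored by mineralized equilibration is compressive here (the
mineral adhesion contracts the periodic cell axially), whereas curved
crystallographic chains can store tensile residual strain. The
magnitude ordering is robust to this sign.

## Known limitations

No water, no cross-links, no extrafibrillar matrix (all outside the
model's scope); mineral is an FCC bead packing, not crystalline
platelets; the barostat is Berendsen-style (no true NPT ensemble
statistics); bond rupture releases its stored energy discontinuously;
LAMMPS data/dump files are interchange formats only — the integrator is
internal.
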