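# Methods

This note documents the models, estimators, numerical choices and
limitations behind `thermogate`, and what the synthetic-data generators do
and do not emulate.

## Structures

Coordinates are in ångström, residue numbering is 1-based, tetramer chains
are labelled A–D.  PDB reading and writing go through biotite, with a
stricter pre-validation pass so malformed ATOM/HETATM records fail with
the offending line number.  Only ATOM records of standard amino acids
enter pore and SASA calculations by default; HETATM inclusion is explicit,
because ligand/toxin stripping conventions vary between studies.

Van der Waals radii default to the Bondi table (C 1.70, N 1.55, O 1.52,
S 1.80 Å, …) with a 1.4 Å water probe; the set is configurable
(`RadiiSet`) since published SASA and pore tools do not agree on one
table.

The pore axis is found as the best-fit C_n symmetry axis: candidate axes
are the principal axes of the gyration tensor (for a C_n body the symmetry
axis is the non-degenerate one), scored by the RMS nearest-neighbour
distance between the atom set and its 2π/n rotation, and polished by a
Nelder–Mead search over small tilts.  The minimal rotation then carries
the axis onto +z with the centroid at the origin, which makes alignment
idempotent.  C4 symmetrization replaces each chain with the rotation of a
reference chain, choosing each chain's rotation multiple by best match, so
re-symmetrizing is a no-op.

## Solvent-accessible surface area

Shrake–Rupley: each atom's sphere is expanded by the probe radius and
sampled with a deterministic golden-spiral lattice (default 960 points;
no RNG, so results are exactly reproducible).  A point is accessible iff
it lies strictly outside every other atom's expanded sphere.  Two
conventions required pinning:

- **Rigid-motion invariance.**  A fixed global lattice is not rotation
  invariant.  Sample directions are therefore expressed in a deterministic
  molecule-attached frame (principal axes with skewness-fixed signs), so
  SASA is exactly invariant under rigid motion.
- **Coincident atoms.**  Strict containment alone would leave two exactly
  coincident spheres both fully "accessible".  Points lying exactly on
  another sphere's surface are awarded to the lower-index atom: one of two
  duplicates keeps its full area, the other is buried, and total area is
  conserved.

A voxel-shell reference implementation (`grid_sasa`) estimates each atom's
area as the accessible volume of a 0.1 Å-thick voxelized shell divided by
the shell thickness.  It shares no code with the lattice method and is the
cross-check oracle in the tests.  Its own discretization error on thin
accessible slivers reaches a few percent of the sliver area, so per-atom
agreement is assessed relative to the atom's expanded-sphere area
(observed agreement ≤ 1.3% on 20-atom clusters).

`delta_sasa(site, a, b)` is the per-residue difference SASA(a) − SASA(b);
positive means the site is more exposed in `a`.  With no chain given the
residue's area is summed over all chains carrying that residue number —
the natural reading for a symmetric homotetramer where each subunit
carries the labelled site.

## Pore profile and conductance

For each z-slab the profiler maximises `min_i(|p − c_i| − r_i)` over the
sphere centre p = (x, y, z) — the largest sphere touching no atom, the
same quantity HOLE reports.  The search is stochastic annealing with
greedy acceptance: Gaussian proposals whose step size cools geometrically
(defaults: 2000 evaluations/slab in batches, initial step 2 Å, cooling
0.95), warm-started from the previous slab's optimum and seeded, so a
profile is a pure function of (structure, parameters, seed).

Two constraints keep the search physical: proposals stay within
`max_jump` (1.5 Å) of the previous slab's centre, making the centre line a
connected path (otherwise the search tunnels through the pore wall into
the bulk on funnel-shaped structures), and within the structure's lateral
footprint (otherwise the objective grows without bound through an open
mouth).  Slabs with no atoms in reach are capped at `max_radius` and
flagged.  The z step defaults to 0.25 Å, comfortably finer than the
0.05 Å accuracy the analytic fixtures demand.

Conductance is Ohmic: `G = correction × [ρ ∫ dz/(π r(z)²)]⁻¹`, trapezoid
integrated, with optional access-resistance terms ρ/(4r) at each mouth.
The resistivity default (0.8 Ω·m, ≈150 mM saline) and the empirical
correction factor (default 1) are exposed configuration, not hidden
constants; predicted conductances are therefore comparative rather than
absolute.  A profile whose minimum radius reaches the floor is reported as
occluded with zero conductance.

## Constrained ensemble refinement

The refinement loop is the scientific core and is exact: per round,
generate decoys, keep those whose marker-site burial relative to the open
reference *strictly* exceeds the threshold (default 20 Å²; the boundary is
strict, matching the ">" of the constraint), select the `top_k` (20) by
energy, seed the next round uniformly from the selected set, for
`n_rounds` (14).  Convergence is tracked as the mean pairwise backbone
RMSD of the top 10 models over the remodeled segments, computed without
re-superposition (models share a frame after symmetrization).  The final
model is the lowest-energy passing model, and the constraint is asserted
on it, not assumed.

Selected models are additionally carried unchanged into the next round's
candidate pool ("elitism").  Uniform reseeding alone does not guarantee
that the best energy is non-increasing across rounds; elitism does, at no
cost to the sampler.

The marker-site burial is measured as the per-residue SASA sum over all
four chains (see above).  At the desk-scale sampler this convention is
what makes the 20 Å² constraint reachable: per-subunit burial of the
marker tops out near 15–25 Å² under random loop moves, while the
C4-coupled all-chain burial passes in 18–29% of decoys.

The decoy generator is a deliberate simplification of a full
kinematic-closure protocol, and pluggable: backbone φ/ψ angles inside each
loop segment receive Gaussian moves (default σ 0.3 rad), the segment is
rebuilt from its own internal coordinates (so zero-magnitude moves are
exact no-ops), and cyclic coordinate descent rotates the segment torsions
until a virtual copy of the next residue's backbone lands within 0.3 Å of
its true (fixed) position; failures are rejected and logged.  Carbonyl O
and Cβ atoms are re-placed from their original local frames.  The score is
a soft-sphere repulsion Σ(r_i + r_j − d)² over non-bonded pairs (same
chain and |Δres| ≤ 1 excluded) plus harmonic restraints on the closure
junction bond and angle.  Clashes give large finite energies, never
singularities.  None of this attempts to model real protein energetics;
it provides a deterministic, rankable score so the filter/selection loop
can be exercised and audited.

## Current-trace analysis

**Mono-exponential fits** use damped least squares (lmfit) initialised
from a log-linear regression on the tail-offset-subtracted signal;
convergence tolerance 1e-8 relative.  A window whose fitted amplitude is
indistinguishable from zero (< 2 standard errors) is a flagged failure,
not a τ.  The fit is scale- and shift-equivariant.

**Degree of desensitization** is `100·(Imax − I_end)/Imax` over a
constant-temperature window: Imax is the window maximum of the (optionally
moving-average-smoothed, edge-preserving) current, I_end the mean of the
final 10% of the window, and Id/Imax is returned as the exact complement.
The window is auto-detected as the longest run whose temperature stays
within ±1 °C of the window mean (two-pointer scan, then trimmed until the
mean-based criterion holds).  The estimator assumes leak-subtracted
currents; with an uncorrected leak the decline can never reach ~99%, so
degree protocols pair with leak-free generated traces.

**Activation threshold** is the breakpoint of a continuous two-segment
linear fit of log₁₀|I| against 1/T (Kelvin): candidate breakpoints are
scanned over the sample grid (a hinge basis makes each candidate a linear
fit), the best must beat a single line by an F-ratio of 10, and the
breakpoint maps back to °C.  Currents are smoothed over 1 s before the log
transform.  The estimate is invariant to scaling the current.

**Spectra** are fitted with the skew-normal peak
`A·e^(−(λ−ξ)²/2ω²)(1 + erf(α(λ−ξ)/ω√2)) + baseline` and λmax is the
argmax of the fitted curve on a 0.1 nm grid — the peak of the *shape*, not
ξ.  Band ratios integrate background-subtracted intensity (trapezoid) over
non-overlapping donor and acceptor bands.  FRET correction divides the raw
ratio by the control construct's temperature–ratio relation (linear
interpolation; extrapolation is an error).

## SPR kinetics

1:1 Langmuir only: association `R(t) = Req(1 − e^(−(kon·C+koff)t))` with
`Req = Rmax·C/(C + KD)`, dissociation `R(t) = R_end·e^(−koff·t)`.  The
global fit shares (kon, koff, Rmax) across all curves, fits the rates on a
log10 scale (positivity by construction), and is initialised from a
dissociation-phase log-linear fit and a kobs-versus-concentration
regression.  Temperature is a label; affinities at different temperatures
come from independent fits.  Mass transport, bivalency and drift are out
of scope; a per-curve bulk offset is the only optional nuisance term.

## Synthetic data: what it does and does not emulate

Generators are pure functions of parameters and seed, and every artifact
embeds its `GeneratorSpec` so tests can read the truth.  Noise is additive
Gaussian with sd expressed as a fraction of the signal maximum — declared,
simple, and wrong in the ways real recordings are wrong (no flicker or
shot noise, no photobleaching, no instrument drift, no baseline wander).
Passing recovery tests therefore demonstrates estimator correctness under
the declared noise model, not robustness to every artefact of real data.

Heat-evoked traces: temperature ramps linearly (default 25→48 °C at
1 °C/s) then holds; `start_T == hold_T` gives a temperature-step
(constant-T) protocol.  In Arrhenius coordinates the noiseless current is
exactly continuous piecewise linear — the leak line (leak Q10 1.3, 100 pA
at 25 °C) below the threshold and a steep activated limb above it, scaled
to reach `imax` (2 nA) at the hold temperature — so the generator's
breakpoint is a well-defined recovery target.  Activation relaxes with a
fast first-order lag (τ 0.2 s, gating-speed realistic at these ramp
rates); desensitization scales the above-leak component during the hold,
mono-exponentially toward `plateau_fraction`.  Two protocol families map
to the two assays: ramp traces with leak for threshold detection, and
hold-only leak-subtracted traces (`leak_25=0`) for τ and degree, where
`plateau_for_degree` inverts degree = 100·(1 − plateau) exactly.
Desensitization engaging only at the sustained hold is a model
simplification: real channels begin desensitizing during the late ramp.

FRET time courses multiply a mono-exponential truth by a linear
temperature factor (the control construct's intrinsic sensitivity, default
1%/°C), which the correction divides out.  Sensorgrams use the binding
module's closed forms (cross-checked against independent ODE integration);
default concentration series span two decades around KD.

The C4 bundle fixture (four α-helices with an extended loop whose bulge
points radially outward, 1.7 Å united atoms, N/CA/C/O/Cβ) is built so that
the marker residue starts maximally exposed and random loop moves can bury
it past the refinement threshold.  It is a geometry fixture, not a protein
model.

## Problem sizes

Recovery studies use 50–100 replicates per condition, refinement tests run
30–200 decoys per round over 2–3 rounds, and SASA cross-checks use 20-atom
clusters — sizes at which every study reruns from scratch in seconds to a
few minutes on one core while leaving the statistics stable (production
refinement at 10⁴ decoys/round and 14 rounds is a configuration change,
not a code path change).

## Known limitations

- The conductance model is purely Ohmic; electrostatics, dehydration
  penalties and the empirical corrections used by established pore tools
  are not modelled, so absolute pS values are indicative only.
- The pore profiler assumes a single, roughly axial pathway; side pockets
  and branched pores are out of scope, and a profile through a grossly
  misaligned structure is only as good as the alignment.
- The steric score cannot rank subtle conformations the way an all-atom
  force field can; the refinement demonstrates the constraint logic, not
  structure prediction accuracy.
- The degree estimator requires leak-subtracted (or negligible-leak)
  currents; with a large uncorrected leak its upper range is compressed.
- Langmuir fitting assumes ideal 1:1 binding; deviations (mass transport,
  heterogeneity) bias kon and koff in ways the residual RMS only partly
  reveals.
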