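# Methods

## The forward model

The crystal is represented as a flat list of atoms (element, Cartesian
coordinates in Å, occupancy, isotropic B or anisotropic U in the
Cartesian basis, optional f′/f″) plus a unit cell and space group; a
chain → residue → conformer hierarchy is derived from chain id, residue
number and altloc.  Fractionalization uses the standard orthogonalization
with *a* along *x*; B = 8π²·U_iso throughout.  Symmetry is handled by
expanding the operator list at structure-factor time (a P1 expansion):
correct and simple at the 5–200-atom scale this engine targets, at the
cost of redundancy that would matter for real-sized problems.
Anisotropic U tensors are supported in P1 only; rotating U by the
symmetry operators is not implemented, and the higher-symmetry fixtures
use isotropic ADPs.

Atomic structure factors come from 4-Gaussian international-tables form
factors (per-element coefficients from gemmi).  Two routes exist:
exact direct summation (reference; carries anomalous scattering and all
analytic parameter gradients) and an FFT route that samples each atom's
real-space Gaussian density on a grid of spacing d_min/3 (default) after
folding in the atomic B.  Atoms sharper than B = 15 Å² are smeared by an
extra B that is divided out of the transform afterwards — the standard
artificial-temperature-factor device that keeps coarse grids accurate.
The two routes agree to better than 10⁻³ relative at d_min/4 gridding.

The bulk solvent is the flat model: a binary mask set to zero within
(vdW radius + r_solvent) of any atom, with the solvent region then
re-grown by r_shrink (FFT dilation with periodic wrap).  Defaults
r_solvent = 1.1 Å, r_shrink = 0.9 Å, grid d_min/4; both radii can be
optimized per macro-cycle by grid search on R_work, with ties broken
toward the defaults.  The total structure factor is

    F_model = k_overall · exp(−2π² sᵗ U_cryst s) · [F_calc + k_sol e^(−B_sol s²/4) F_mask].

Scales are fitted by a coarse grid over (k_sol ∈ [0, 0.6] step 0.05,
B_sol ∈ [10, 80] step 5) with closed-form k_overall and a log-linear
constrained U_cryst fit at each node, then a bounded polish of
(k_sol, B_sol).  U_cryst keeps all six components in P1 and the diagonal
in orthorhombic cells.  Because an isotropic component of U_cryst is
degenerate with a uniform shift of all atomic Bs, the trace of U_cryst
is folded into the atomic Bs at the start of isotropic ADP refinement;
without this the recovered Bs carry an arbitrary offset.

Twinned amplitudes mix intensities across the operator,
|F|² → (1−α)|F(h)|² + α|F(Th)|²; α is estimated by grid search over
[0, 0.5] in steps of 0.01 on R_work, ties toward smaller α.  Gradient
refinement through the twin mixing is not implemented; twin handling is
scale-level (α re-estimated per macro-cycle).

## Targets and weights

Two experimental targets: the LS amplitude residual Σw(|Fo| − k|Fm|)²
with closed-form k, and the amplitude likelihood — Rice for acentric,
folded-Gaussian (Woolfson) for centric reflections, with centric flags
and ε factors from the space-group operators.  The error model is a
per-resolution-bin pair (α, β): α scales the model amplitude (the D of
likelihood-weighted maps), β is the complex-plane variance of the model
error.  Both are fitted per bin by Nelder–Mead on the free-set
likelihood (work set with a warning when fewer than 25 free reflections
exist), and interpolated linearly in 1/d² per reflection; the figure of
merit is m = I₁/I₀(2FoDFc/εβ) (acentric) or tanh(FoDFc/εβ) (centric).
The error model is re-estimated every macro-cycle; it is *not* updated
inside a single minimization, so a badly wrong start flattens the ML
landscape until the next update — visible in the annealing experiments
below.

Total targets are T = wxc_scale·wxc·T_exp + wc·T_restraints (wxu/wu for
ADPs).  The automatic weight is the restraint-to-experimental
gradient-norm ratio, fixed at the start of each minimization (recomputing
it per evaluation makes the objective non-stationary under L-BFGS).  One
degenerate case matters: a start model at ideal geometry has a vanishing
restraint gradient, which would drive the ratio — and with it the entire
X-ray term — to zero.  In that case the restraint-gradient norm is
measured on a deterministic 0.05 Å-shaken probe copy, so the ratio
reflects the restraint stiffness rather than the accident of starting on
the ideal.  The slower weight-scan alternative refines briefly at
wxc_scale ∈ {10, 5, 2, 1, 0.5, 0.25, 0.1}·auto and picks the lowest
R_free whose bond rmsd stays within 0.015 Å (smallest-violation
fallback; ties toward the smaller scale).

## Restraints

Geometry: harmonic bonds and angles with ideals/sigmas from a small
shipped dictionary covering the toy residue types (a glycine-like
N–CA–C–O unit, a C–C–S ligand, water), plus a quadratic nonbonded
repulsion below 2.2 Å that skips 1-2/1-3 pairs and pairs in different
altloc conformers.  Dihedral, chirality and planarity terms are not in
the dictionary; the restraint interface is a plain list of harmonic
terms, so they can be added without structural change.  Nonbonded
contacts across symmetry/periodic images are not restrained — acceptable
because the generator keeps symmetry mates ≥ 2.4 Å apart.

Isotropic ADP smoothness uses the sphere restraint
Σᵢ Σ_{j∈sphere(R,i)} (Uᵢ−Uⱼ)² / (r_ij^p · ((Uᵢ+Uⱼ)/2)^q) with defaults
(R, p, q) = (5.0 Å, 1.69, 1.03); with p = q = 0 it reduces to the plain
pairwise similarity sum.  The placement of the mean-U power is a
transcription choice; the reduction property and an independent scalar
re-evaluation pin the implemented form in the tests.  Anisotropic ADPs
get squared-Frobenius similarity over bonded pairs.  TLS groups
synthesize U_TLS = T + A·L·Aᵗ + A·S + Sᵗ·Aᵗ with A the antisymmetric
matrix of the offset from the group origin; trace(S) = 0 leaves
6+6+8 = 20 parameters, verified by constraint rank rather than asserted.
NCS copies are superposed by least squares (quaternion method via
scipy's Rotation) onto the running average; the harmonic ADP penalty
applies to U_local only, so TLS contributions never leak into it.

## Engines

Coordinates, ADPs, occupancies and f′/f″ each refine by L-BFGS-B with
analytic gradients chained through the direct-summation structure
factors (dT/dF_model sensitivities → per-atom ∂F/∂x, ∂F/∂B, ∂F/∂U,
∂F/∂occ, ∂F/∂f′,f″); every engine leaves the other parameter classes
bit-identical and reverts if the optimizer somehow ends above its start.
Occupancy constraints: altloc groups eliminate the last conformer
(q_last = 1 − Σ others), so the sum-to-one constraint holds exactly by
construction; single-parameter groups are bounded boxes for L-BFGS-B.
f′/f″ refinement needs measured Bijvoet pairs and warns (leaving values
unchanged) when the mean absolute Bijvoet difference carries no signal.

Rigid-body refinement follows the growing-resolution-zone protocol:
LS refinement of per-group rotation+translation starting from the 300
lowest-resolution reflections, doubling the zone until the full set is
used.  The optimizer is bounded L-BFGS-B with numerical gradients
(rotation vector ±0.25 rad, translation ±3 Å).

Simulated annealing is Cartesian velocity-Verlet on the weighted total
target with element masses, Maxwell initial velocities from the seed, a
geometric cooling schedule, per-step displacement capping (≤ 0.12 Å) and
a thermostat that combines velocity rescaling with a Langevin momentum
randomization (γ = 0.2 by default).  The Langevin term matters: with a
small mobile selection, pure rescaling leaves a lone atom ballistic — it
travels in a straight line and never diffuses into its well.
Temperature is kinetic energy per degree of freedom in target units;
against bond weights of 1/0.02² Å⁻², kT ≈ 30 sustains excursions of a
few tenths of an Å without melting the structure, and hot annealing of a
selection (kT ≈ 300) lets a trapped fragment search while the rest stays
fixed.  The run ends with geometry regularization and a short
minimization.

Real-space refinement computes the σ-scaled 2mFo−DFc map once, applies a
per-residue rigid translation grid search into density (radius 1.2 Å,
step 0.3 Å — a desk-scale stand-in for rotamer-library corrections),
then polishes all atoms against −w·Σocc·ρ(x) + T_geom for each trial
weight, keeping the largest weight whose bond rmsd stays within 0.02 Å.
If R_work rises more than 1.5 percentage points the whole result is
discarded.

The water update removes waters failing B (≤ 80 Å²), occupancy (≥ 0.1),
distance-to-model (within [2.2, 3.6] Å of something, ≥ 2.2 Å from
everything) or 2mFo−DFc map-value (≥ 1σ) criteria; re-centers survivors
onto the local density maximum (gradient ascent, ≤ 0.6 Å); and adds
mFo−DFc peaks ≥ 3σ in the distance window as O atoms with B set to the
model average and occupancy 1.  New peaks must also show ≥ 3σ of
2mFo−DFc support: with σ-scaled maps from noiseless or low-noise data,
series-termination ripples in the difference map otherwise pass the 3σ
cut, and this second criterion separates them cleanly from genuine
solvent sites.

A macro-cycle runs, in order: scale/bulk-solvent refit (optionally mask
parameter optimization) → error-model update → water update → real-space
then reciprocal-space coordinate refinement (annealing in the early
cycles if requested) → ADP refinement → occupancy refinement → final
rescale; R factors and geometry statistics are recorded per cycle.  The
scales-before-waters order is a configuration choice (strategy flags
control every step).

## Maps

Coefficients (p·m·|Fo| − q·D·|Fm|)·exp(iφ_model), unweighted variants
without m and D.  Missing reflections inside the data sphere (and
outlier-excluded ones) can be filled with D|F_model| (default), the
resolution-bin mean of |Fo|, plain |F_model|, or seeded Gaussian draws
around the bin mean; filled coefficients carry the substitute amplitude
itself — the expected value of the weighted coefficient for an
unobserved acentric reflection — and are flagged so filled and unfilled
maps can be produced side by side.  The anomalous difference map divides
Bijvoet differences by 2i: amplitude (F⁺−F⁻)/2 on phase φ_model − 90°.
Synthesis Friedel-completes the hemisphere, inverse-FFTs, and σ-scales
to rms 1; Parseval closure is tested to 10⁻⁶.  B-factor sharpening
applies exp(+B s²/4) with B from a Wilson-line fit of amplitude falloff.

## The synthetic generator

Toy crystals are built from rigid ideal-geometry residue templates
(constructed from the restraint dictionary itself, so the geometry
target is exactly zero at truth) placed self-avoidingly (≥ 2.4 Å between
residues, symmetry and periodic images included) in P1 or P2₁2₁2₁ cells
of 10–40 Å.  Waters are placed in the 2.6–3.3 Å hydration shell of the
macromolecule — uniformly placed waters would be correctly deleted by
the distance-to-model criterion of the water update.  Altloc residues
are duplicated with a 0.6 Å rigid offset at occupancies 0.6/0.4 (or as
specified); anomalous truth assigns (f′, f″) per element.  Observed
amplitudes come from the full forward model (solvent truth
k_sol = 0.35, B_sol = 45 Å² by default, matching typical protein-crystal
values), optional twin mixing, and Gaussian noise at a fractional σ of
5% by default, with free flags at 5%.  Perturbations (shake to an exact
target rmsd, domain rotation, ADP reset, water stripping) mirror the
standard ways of preparing a refinement test problem.

What the generator does not emulate: real chemistry (no peptide links,
rotamers, hydrogens), experimental-error structure beyond i.i.d.
Gaussian amplitude noise, radiation damage, anisotropic or incomplete
data pathologies beyond deliberate deletion.  Passing recovery tests
therefore demonstrates the correctness and convergence machinery of the
algorithms under controlled conditions, not performance on real
crystallographic data.

## Numerical choices and degenerate cases

- Amplitude-only targets leave the P1 origin floating; rmsd comparisons
  against truth remove the best global translation.
- French–Wilson conversion evaluates the truncated-Gaussian × Wilson
  posterior by quadrature per reflection (high-signal limit F = √I with
  delta-method σ beyond I/σ = 30); binning is equal-count, 150 per bin
  target, 20 minimum, with all-negative bins falling back to the global
  prior.
- Outlier detection flags amplitudes with acentric-Wilson tail
  probability exp(−F²/S_bin) below 10⁻⁶; flags exclude reflections from
  work/free sets without deleting them.
- L-BFGS results are reverted whenever the final value exceeds the
  start; U eigenvalues are clamped to ≥ 0 after anisotropic refinement;
  occupancies are clipped to their bounds.
- Tie rules: mask-parameter ties toward the conventional defaults, twin
  ties toward smaller α, weight-scan ties toward the smaller scale.

## Problem sizes

Test fixtures use 13–40 atoms, 10–24 Å cells and 1.0–2.5 Å data
(3000–10000 reflections), chosen so each recovery experiment represents
its full-scale counterpart faithfully while the complete suite runs in
minutes on one CPU.  The strategy-comparison experiment (1 Å shake, ADP
reset, water stripping; dual-space vs minimization-only vs
minimization+annealing) uses five macro-cycles, by which point the
dual-space run has converged and the minimization-only run has long
plateaued.
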