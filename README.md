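# picorefine

A desk-scale macromolecular crystallographic refinement engine.  It
implements the complete reciprocal/real-space refinement macro-cycle —
total model structure factors with a flat bulk-solvent correction and
anisotropic scaling, least-squares and maximum-likelihood amplitude
targets with automatic weighting, restrained refinement of coordinates,
atomic displacement parameters (ADPs), occupancies and anomalous
scattering coefficients, TLS-generated ADPs, twin-fraction estimation,
ordered-solvent (water) updating, and likelihood-weighted
2mFo−DFc / mFo−DFc map output — on toy crystals small enough that every
stage can be exercised, tested and cross-checked in seconds on one CPU.

It is aimed at people who want a transparent, fully testable model of how
a production refinement program works: methods students, developers
prototyping refinement ideas, and anyone who needs a ground-truth-backed
sandbox where "the right answer" is known by construction.

## The model

The total structure factor of a model crystal is assembled as

    F_model(h) = k_overall · exp(−2π² sᵗ U_cryst s)
                 · [ F_calc(h) + k_sol · exp(−B_sol s²/4) · F_mask(h) ]

where `s` is the reciprocal-lattice vector of reflection `h` (|s| = 1/d),
`U_cryst` the symmetry-constrained overall anisotropic scale (Å²),
`F_calc` the atomic structure factors (direct summation or FFT, 4-Gaussian
form factors, isotropic or anisotropic Debye–Waller factors, optional
f′/f″), and `F_mask` the Fourier transform of a binary solvent mask grown
from van der Waals radii by `r_solvent` and shrunk back by `r_shrink`.
For twinned data amplitudes mix as
|F_twin(h)|² = (1−α)|F(h)|² + α|F(Th)|², with the twin fraction α found
by a 0.01-step grid search over [0, 0.5].

Refinement minimizes `T = wxc_scale · wxc · T_exp + wc · T_restraints`
(and the `wxu`/`wu` analogue for ADPs), where `T_exp` is either a
least-squares amplitude residual or the Rice/Woolfson amplitude
likelihood with per-resolution-bin error parameters (α, β) estimated from
the free reflections — the same parameters that give the figure of merit
m and amplitude coefficient D used in the 2mFo−DFc map coefficients.
One macro-cycle runs: scale/bulk-solvent refit → error-model update →
water update → real-space then reciprocal-space coordinate refinement
(L-BFGS, optionally simulated annealing) → ADP refinement → occupancy
refinement.

## Worked example

Everything runs from synthetic crystals whose ground truth is recorded,
so recovery can be checked against it:

```sh
$ picorefine simulate --seed 4 --noise 0.0 --out-prefix toy
wrote toy.pdb/.csv/.json (20 atoms, 4066 reflections)

$ picorefine fmodel toy.pdb toy.csv
R_work 0.0005  R_free 0.0005  k_sol 0.35  B_sol 45.0
```

The simulated data carry a flat bulk solvent with k_sol = 0.35 and
B_sol = 45 Å²; `fmodel` refits those scales from scratch and recovers
them, and against the generating model (after the PDB-precision round
trip of the coordinates) the R factors sit at 5·10⁻⁴.  The same closure
drives refinement:

```sh
$ picorefine refine toy.pdb toy.csv --cycles 2 --strategy scales+xyz_reciprocal+adp --no-water-update
   cycle_1  R_work 0.0001  R_free 0.0001  bonds 0.0001  angles 0.01
   cycle_2  R_work 0.0001  R_free 0.0001  bonds 0.0000  angles 0.00
wrote refined.pdb
```

Starting instead from a deliberately damaged model (1 Å coordinate
shake, ADPs reset to the mean, waters deleted), the dual-space strategy
(`scales+waters+xyz_real+xyz_reciprocal+adp`) brings R_work from ≈ 0.5
back below 0.06 in five cycles, while an L-BFGS-only strategy stalls
above 0.3 — the comparison is run by the test suite
(`tests/test_engines.py::TestMacroCycles`).

In Python the same pieces compose directly:

```python
from picorefine import ToySpec, make_toy_structure, simulate_fobs
from picorefine.engines import RefinementState, run_macro_cycles

spec = ToySpec(seed=3, noise=0.05)
truth = make_toy_structure(spec)
data = simulate_fobs(truth, spec)
state = RefinementState.create(truth.copy(), data)
run_macro_cycles(state, 3)
print(state.history[-1])   # per-cycle R_work/R_free, bond/angle rmsd
```

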