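# Methods

## Coordinate model and superposition

Structures are parsed from PDB ATOM/HETATM records into a flat,
file-ordered residue list keyed by author numbering (chain, residue
number, insertion code); nothing is renumbered. Only the first-encountered
alternate-location conformer of an atom is kept — deterministic and the
common convention. Hydrogens are parsed and written back but excluded from
every metric, which operate on Cα or heavy atoms only. Hetero-residues are
skipped by default (`read_pdb(..., include_hetatm=True)` opts in); they
never enter metric computations.

Docking partners are assigned from a `<chains1>_<chains2>` string; the
partner with more residues is the receptor, with the first-listed partner
winning ties. Superposition is closed-form least squares (SVD with a
determinant guard, via Biopython's `SVDSuperimposer`), so returned
rotations are always proper; the test suite cross-checks it against an
independently coded quaternion-eigenvalue solver.

## Accuracy metrics

- **Lrmsd**: Cα RMSD of the ligand after fitting the decoy receptor onto
  the native receptor Cαs; the ligand is *not* refit.
- **Irmsd**: the interface residue set is determined **on the native
  complex only** (any inter-partner heavy-atom distance ≤ 4.0 Å), so it is
  identical for every decoy of a target; the shared heavy atoms of those
  residues are superposed decoy-onto-native and the fit RMSD reported.
- **fnat**: native inter-partner residue contacts (any heavy-atom pair
  ≤ 5.0 Å) recovered in the decoy.

All cutoffs are inclusive. Heavy atoms only, everywhere, so results do not
depend on hydrogen placement. Residues are matched by identity; unmatched
residues are dropped pairwise with a warning. Quality classes come from
Irmsd alone — high < 1.0 Å ≤ medium < 2.0 Å ≤ acceptable ≤ 4.0 Å <
incorrect — with "near-native" meaning Irmsd ≤ 4.0 Å. (Full CAPRI ranking
also folds fnat into the class boundaries; this package implements the
Irmsd-only variant used in benchmark summaries.)

## Funnel criterion and aggregation

Decoy sets are ranked by interface energy `I_sc` ascending, ties broken by
decoy description so rankings are deterministic. N5 counts near-native
decoys among the top five; success is N5 ≥ 3; the reported quality is that
of the closest decoy in the top five. Aggregation reports per-category
success counts and integer percentages. The packaged benchmark
transcription has 115 rows while the published text counts 116 targets;
aggregate percentages against published rates therefore use the published
denominators (116 overall, 84 rigid-body, …), exposed as
`decoy_eval.PUBLISHED_CATEGORY_SIZES`.

## Bootstrap reliability statistics

`bootstrap_n5` draws B resampled decoy sets of the original size, with
replacement, and reports the sample mean µ(N5), sample standard deviation
σ(N5) (denominator B−1; the alternative B changes nothing at B = 5000,
the default), and the success fraction P_success = P(N5 ≥ 3). The
randomized null (`bootstrap_randomized`) additionally draws, per resample,
a second with-replacement sample of interface energies from the original
set and assigns them to the resampled decoys, destroying the decoy–score
relationship while preserving the marginal score distribution. One seeded
NumPy generator per call; the decoy-index block is drawn before the
score-index block, making results reproducible. Ties among reassigned
scores are broken by the receiving decoy's original energy rank.
Statistics-based success uses µ(N5) ≥ 2.5 AND P_success ≥ 0.3, both
inclusive.

Exactness is verified by enumeration: for an n-decoy set all n^n
resamples can be enumerated when n ≤ 7, and the Monte-Carlo estimates must
agree within three standard errors.

## Failure classification

Given a failed standard run plus unbound-refine and bound-refine control
sets, with E_std = min I_sc over all standard decoys, E_ub = min I_sc over
near-native unbound-refine decoys (+∞ if none), E_b likewise for
bound-refine, and a margin m (default 1.0 score units):

1. **RB sampling** if E_ub + m < E_std;
2. else **BB sampling** if E_b + m < min(E_ub, E_std);
3. else **discrimination**.

The cascade is total and deterministic. The margin formalizes "located
lower-energy near-native decoys" against float noise; the published
analysis made this call from scatter plots, so the margin is exposed as a
parameter, as is an option to restrict the refine sets to their ten
lowest-energy decoys (the scatter-plot convention; default uses all).
The baseline is deliberately the standard run's *overall* minimum, not its
near-native minimum, matching the discrimination-failure definition.

## Docking engine

A deliberately simple two-stage Metropolis Monte-Carlo protocol on a
fixed receptor and a rigid ligand (rotation about the ligand centroid +
translation):

1. **Perturbation**: Gaussian translation (sd 3.0 Å per axis) and
   Gaussian rotation (sd 8.0°) about a random axis, plus an optional
   uniform "spin" about the receptor→ligand centre-of-mass axis.
2. **Coarse stage**: 500 Metropolis steps (kT = 0.8) in a centroid
   representation — backbone heavy atoms plus one pseudo-atom at the
   side-chain heavy-atom centroid (Cα for glycine). Step sizes adapt every
   50 steps toward 25% acceptance: ×1.1 when the window ran hot, ×0.6 when
   cold. The asymmetry is intentional: symmetric ±10% factors cannot bring
   the step size from the 3 Å start into the 25% regime within 500 steps
   (measured acceptance stays under 5%), while the strong shrink converges
   and then oscillates stably around the target. The lowest-scoring pose
   visited is passed on.
3. **Refinement**: 50 cycles of {Gaussian move (0.1 Å / 3.0°);
   derivative-free coordinate-descent minimization over the six rigid-body
   DOF, *skipped* when the move raised the score by more than +15;
   Metropolis test}. Side-chain packing points are no-op hooks (every 8th
   cycle), kept so packing-aware schedules keep their shape; this engine
   does not model side-chain flexibility.

**Score functions are documented stand-ins, not Rosetta potentials.** The
coarse score is the weighted sum (contact 2.0, clash 1.0, environment 1.0,
pair 1.0) of: a capped count of cross-partner centroid contacts (≤ 6.0 Å,
at most 5 credited per residue per side); a quadratic soft-clash penalty
Σ (r_min − d)²/r_min over overlapping cross-partner atoms with per-element
radii (C 1.7, N 1.55, O 1.52, S 1.8 Å; centroid 1.8 Å); and pluggable
environment/pair lookup tables defaulting to a Kyte–Doolittle
hydrophobicity potential (buried hydrophobics favourable; hydrophobic
cross-partner pairs favourable). All four terms vanish for separated
partners, are invariant under global rigid transforms, and the clash term
is non-negative. The default all-atom score is a capped soft 6-12
potential plus the pair table on side-chain centroids; both stages accept
user-supplied score callables. Interface energy is score(pose) minus
score(ligand displaced 500 Å along the receptor→ligand axis).

The minimizer is coordinate descent over translation (0.2 Å start) and
rotation (2.0° start) axes with step halving, ≤ 5 sweeps, 1e-3 score
tolerance — robust without gradients and cheap at toy-system sizes.

## Synthetic data

`make_decoy_set` draws interface RMSD from a two-population mixture
(near: uniform [0.3, 4.0] Å with probability p; far: uniform (4.0, 20] Å)
and scores it with a linear-plus-plateau funnel,
`i_sc = slope · (10 − min(irmsd, 10)) + N(0, noise_sd)`. A negative slope
deepens near-native energies (a funnel); zero decouples score from
accuracy. Default conditions are 1000 decoys per set and B = 5000
bootstrap resamples, the sizes used in benchmark practice; the
significance demonstration uses a 2% near-native fraction, the regime
where a funnel call must not arise by chance. The generator reproduces the
*statistical* structure of real decoy sets (near-native fraction, funnel
depth, score noise) and nothing else: no energetics, no clustering of
decoys in conformation space, no heavy-tailed score outliers. Tests that
pass on it validate the evaluation machinery, not docking accuracy on real
proteins.

`make_toy_complex` builds idealized two-chain models (mirrored parallel
helix pair, beta-hairpin pair, or self-avoiding random coil; backbone
N/CA/C/O plus a CB pseudo-side-chain on non-glycine residues) and scans
the inter-partner separation at 0.1 Å resolution for the clash-free pose
whose native contact count is closest to the requested target. "Unbound"
variants add Gaussian noise to backbone and/or side-chain coordinates to
emulate rigid-body versus backbone-change difficulty.
`make_failure_fixture` builds standard/unbound-refine/bound-refine score
triples whose energy minima deterministically fire exactly one rule of the
failure cascade. Everything is bit-reproducible under a fixed seed.

## Problem sizes

Tests and the acceptance script run at desk scale by design: 16-residue
partners for engine properties, ≤ 8–20 decoys for pipeline checks,
1000-decoy synthetic sets with B = 5000 for the statistics. Exhaustive
bootstrap enumeration is used at n = 6 (46 656 resamples).

## Known limitations

- No side-chain packing, rotamers, backbone flexibility, ensembles, or
  ligand/cofactor parameterization; the high-resolution stage moves only
  the six rigid-body DOF.
- The score stand-ins rank toy geometries sensibly but have no claim to
  realism; do not compare their magnitudes to production energies.
- The packaged benchmark CSV is a transcription of published summary
  tables, used for evaluation/tests only; this package cannot regenerate
  it (that requires the full 116-complex benchmark and a production
  energy model).
- CLI commands that only print to stdout log their run manifest to stderr
  instead of writing a file; commands with an output directory write
  `manifest.json` there.
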