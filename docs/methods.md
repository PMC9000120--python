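# Methods

## Membrane contact probability

A residue is in direct contact with the bilayer's hydrophobic core in a
frame when its Cα lies within `cutoff_A` of any lipid acyl-chain carbon.
The MCP is the occupancy of that event over the analysis window.
Conventions fixed here:

- **Closed boundary.** A distance exactly equal to the cutoff counts as a
  contact. "Within 6 Å" admits either convention; one had to be fixed and
  tested, and the closed boundary is the one the kernel, the brute-force
  oracle, and the boundary tests all share.
- **Cα-based selection.** The contact group is the protein Cα against
  lipid tail carbons. The selector is exposed (`ContactConfig.
  tail_selector`, role tags on `FrameSet`), so an any-atom variant can be
  configured without touching the kernel.
- **Frame window.** Default is the trailing 80 % of frames, generalizing
  the convention of averaging over the equilibrated production tail of a
  trajectory (e.g. the final 800 ns of a 1 µs run); an inclusive index
  range is accepted instead.
- **No periodic-boundary handling.** Inputs are assumed whole and imaged.
  This is a documented limitation: occupancies computed from wrapped
  trajectories will under-count contacts across the box boundary.
- **Centroids are unweighted** in the center-of-mass distance series;
  coarse-grained beads have near-uniform masses and dropping force-field
  mass tables keeps the analysis reproducible from coordinates alone.
- The first principal axis is the leading eigenvector of the coordinate
  covariance matrix; its sign is arbitrary, so tilt angles are folded to
  [0°, 90°].

Annotated structures store per-residue contact probability in the PDB
B-factor column. Deposited files use either a 0–1 or a 0–100 scale; the
reader treats values as probabilities when the maximum Cα B-factor is
≤ 1 and divides by 100 otherwise (with a warning). Writing rounds to two
decimals, the B-factor field precision, so round-trips are exact to 0.005.

## Dataset assembly

Chains are split into single-chain records; exact duplicate sequences
collapse to one record. Length filtering keeps 26–700 residues inclusive;
the standard-alphabet filter drops anything outside the 20 canonical
letters.

**Sequence identity** is a global Needleman–Wunsch/Gotoh alignment with
match +1, mismatch 0, affine gaps (open −10, extend −0.5); identity is
identical aligned pairs divided by the shorter length. Because co-optimal
alignments can differ in match count, the implementation maximizes
(score, matches) lexicographically, which makes identity well-defined and
exactly symmetric. The min-length denominator is stricter than
alignment-length normalization, the safer choice for redundancy
filtering. Redundancy reduction is greedy: records visited longest-first
(ties by id), kept iff identity to every kept record is strictly below
the threshold (default 0.40). The post-hoc property — no kept pair at or
above threshold — is verified in tests.

The large corpus mixes membrane chains (with MD-derived labels) and
soluble chains whose labels are set to zero everywhere, since a soluble
residue never touches an acyl chain: defaults are 5000 + 5000 training
chains, 400 validation and 500 test membrane chains, sampled
disjointly with a seeded generator. The small corpus splits 898
redundancy-reduced chains 8:1:1 (718/90/90) by seeded shuffle with
largest-remainder rounding.

## The MCP predictor

Features per residue: 3 secondary-structure-state probabilities, 3
solvent-accessibility-state probabilities, 20 PSSM columns — a 26-vector,
zero-padded to a 700×26 block with a validity mask. Feature files come
from external predictors; the toolkit never shells out to them.

Architecture: three parallel 1-D convolutions over the sequence (kernels
3, 7, 9; 64 channels each by default) with ReLU, concatenated, then a
bidirectional GRU (hidden 64 per direction by default; the value is a
choice, exposed in config), then a per-position affine head. The output
nonlinearity is a sigmoid because MCP lives in [0, 1]; a hard clamp is
available as a config alternative. The recurrence runs over the true
sequence length, never over padding — this is what makes predictions
provably padding-invariant (asserted bitwise in tests).

Loss: residual sum of squares over masked positions plus λ·Σθ² (default
λ = 1e-5). Soluble all-zero records participate with weight 1. Training
uses Adam at batch size 1, seeded; the gradient of the full
conv+GRU+head graph is checked against central finite differences.

Evaluation reports MSE and Pearson correlation overall and per
secondary-structure class (H/E/C). Residues are pooled across proteins by
default; a `per_protein` flag averages per-protein correlations instead,
since both conventions are in use. Undefined correlations (zero variance,
fewer than two residues) are reported as `None`, never as NaN. Seeded
k-fold cross-validation returns per-fold tables with mean/SD.

Because torch-scale training is out of scope, the networks run on a small
reverse-mode autodiff engine over numpy (`memcontact.autodiff`):
convolutions are expressed as gather + matmul, recurrence as explicit
per-step graphs. This keeps the architecture faithful while making the
whole stack testable on one CPU.

## Surface characterization

Quadrant classification at cutoff c = 0.5: region I (mcp > c, sa > c,
water–membrane interface), II (mcp > c, sa ≤ c, lipid-exposed), III
(both ≤ c, buried), IV (sa > c only, water-exposed). Ties at exactly c
fall on the "not exceeding" side, consistent with regions I/II being
defined by strict "larger than". Region shares are reported as percent
rounded to three decimals (14 of 79 796 → 0.018 %).

The anchoring rule: a protein passes when some window of 10 consecutive
residues contains at least 3 MCP values above 0.5. The high-MCP threshold
is implied rather than stated in the source analysis; 0.5 is the default
and configurable. Reported segments are maximal merged passing windows —
an extension beyond the bare pass/fail rule. Proteins shorter than the
window are checked as a single full-length window.

## Contact maps and their statistics

Native contacts: Cβ–Cβ distance ≤ 8 Å, with Cα substituting for glycine
(standard convention; glycine has no Cβ). Top-L/k precision ranks
band-restricted pairs by predicted probability with a lexicographic
(i, j) tie-break for determinism and takes floor(L/k). Bands: short
[6, 11], medium [12, 23], long ≥ 24 sequence separation. Whole-map PCC
excludes pairs with separation < 6 by default so trivially-correct
near-diagonal entries don't inflate the correlation; a flag disables the
exclusion. Classification metrics threshold at 0.5 over all
upper-triangle pairs; the confusion matrix is row-normalized by true
class, and AUC is the rank statistic (verified against a Mann–Whitney
oracle).

Mutual information uses the 21-symbol alphabet (20 amino acids + gap)
with one pseudo-observation per joint cell; marginals come from the
smoothed joint, so MI ≥ 0 with a bias floor set by the pseudocount (the
tests measure background MI against that floor, not against zero).
Alignments of depth < 2 return zeros. APC correction is available by
flag. The averaged pairwise potential is the mean of table lookups across
non-gapped alignment rows; pairs gapped in every row are NaN. The default
20×20 table is a deterministic hydrophobicity-derived surrogate
(`potentials.POTENTIAL_VERSION`), shaped like knowledge-based contact
potentials; its identity is configuration, and any symmetric 20×20 table
is accepted.

## The contact network

Per-residue features (including MCP as one more 1-D channel, parallel to
SA) pass through a 1-D residual convolution stack (kernel 17, two layers
by default), are lifted to pairs by concatenating the processed vectors
at i, j and ⌊(i+j)/2⌋ — the conversion follows the established
1D-to-2D lineage of residual contact predictors, since no single
convention is canonical — and are joined with the symmetric 2-D channels
(coevolution matrix, averaged potential, mutual information). The 2-D
stack is a sequence of residual blocks: two 5×5 convolutions and two
ReLU activations per block with an identity shortcut, optional
per-channel instance normalization (both choices configurable). A 1×1
head plus sigmoid gives per-pair probabilities; the map is symmetrized
as (M + Mᵀ)/2 with a zero diagonal.

Depth is a parameter: 6 blocks (12 layers) by default, 30 blocks
reproducing the full 60-layer depth. Training is binary cross-entropy on
upper-triangle pairs with separation ≥ 6, Adam, batch size 1, seeded,
with a per-epoch training top-L/10 precision curve. The channel manifest
makes ablations config-only: dropping the `mcp` entry retrains the same
architecture minus that channel.

## Model selection

Restraints: each selected contact becomes a bounded distance restraint
(3.5–8 Å). The backend is pluggable; the shipped stub perturbs a
reference trace with replicate-indexed noise and scores models by their
flat-bottom restraint violation. Backend scores are energies: lower is
better. The satisfaction score is defined here as the realized fraction
of the top L/5 long-range predicted contacts (the scoring internals of
the original model-building tool are not public); ranking ties break by
provenance. TM-score uses d0 = max(0.5, 1.24·(L−15)^⅓ − 1.8),
normalizes by the common length (fixed residue correspondence, hence
symmetric), and iterates superposition from the full-length fit,
refitting on residues within the distance threshold until the included
set repeats; the maximum score over iterations is returned, and tests
assert it dominates the single-fit score. Clustering is average-linkage
agglomerative on 1 − TM, cut at k = 5; the medoid maximizes mean
within-cluster TM-score (ties: smallest index). Kabsch RMSD uses SVD
superposition restricted to proper rotations.

## Synthetic data: what it shows and what it does not

The membrane-system generator builds a canonical helix (rise 1.5 Å,
radius 2.3 Å, 100°/residue) crossing a lipid slab (half-thickness 15 Å)
of uniformly placed tail pseudo-atoms, with seeded Gaussian frame jitter
(σ = 0.5 Å default). Its ground truth is computed by an embedded plain
double loop over frames, residues and lipid atoms — deliberately
independent of the vectorized kernel it validates. The planted-signal
training set marks 1–3 hydrophobic windows (19–23 residues) per
sequence; the target is a smoothed window indicator scaled by
hydrophobicity rank, and the feature surrogates carry the same signal.
Toy MSAs have independent columns except listed pairs co-mutating with a
set coupling probability. Hairpin structures supply long-range contacts
for the contact-network fixtures.

Passing tests on these fixtures demonstrates correctness of the
*computations* — exact occupancy counting, metric formulas, bookkeeping,
and that the networks can extract a signal that is present. They say
nothing about accuracy on real proteins: the feature surrogates are not
outputs of real predictors, lipid placement has no physics, and the
planted mapping is far easier than the real sequence-to-MCP problem.

## Problem sizes and numerics

Test and acceptance runs use 20-seed membrane systems (20–30 residues,
6–10 frames), a 32-protein planted-signal corpus (lengths 30–50; 24
train / 8 test, 25 epochs, 8 conv channels, hidden 12) for the
predictor, and 5 proteins of length 28 (2 blocks, hidden 8, 8 epochs)
for the contact network — sizes chosen so the full stack, including
training, runs in well under a minute each on one CPU while leaving the
architectures intact. Sigmoid inputs are clipped at ±60 to avoid
overflow; BCE uses ε = 1e-7; instance normalization uses ε = 1e-5;
degenerate statistics return `None` markers rather than NaN. All
generators and training loops are pure functions of their seeds.

## Known limitations

- No PBC unwrapping; no lipid headgroup or solvent contact statistics.
- PSSM/SS3/SA3 for real proteins must be supplied as files; external
  predictors and coevolution tools are consumed, never invoked.
- The folding backend is a stub; plugging a real builder in reproduces
  the bookkeeping but model quality depends entirely on the backend.
- Full-scale training (thousands of chains, 60 2-D layers) is expressed
  by configuration but not exercised by the test suite.
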