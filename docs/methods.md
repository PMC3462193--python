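# Methods

This note documents the models, estimators and numerical choices behind
`territory_coupling`, and what the synthetic data can and cannot say
about real nuclei.

## Distance and activity matrices

**IPD.** Homologues of an autosome cannot be distinguished
experimentally, so a chromosome pair contributes up to four
centroid–centroid distances per nucleus. `compute_ipd` aggregates the
pairings per nucleus (mean by default, minimum as a variant) and then
averages over every nucleus containing both chromosomes; nuclei missing
one member of a pair are skipped for that pair only, and the number of
contributing nuclei is logged. The diagonal holds the mean
homologue–homologue separation and carries an excluded flag that all
correlation code honors — only the 231 off-diagonal pairs (for 22
autosomes) ever enter a correlation. Coordinates are in units of the
nuclear radius, which makes the analysis invariant to nuclear size and
to rigid motions of each nucleus.

**IAD.** Probe intensities are normalized per array (replicate) to the
array mean, averaged replicate-first then probe-wise into gene
activities, summed per chromosome and divided by the *annotated* gene
count N — not the observed count — so unmeasured annotated genes dilute
the mean. IAD is the absolute difference of natural-log activities; it
is a one-dimensional embedding metric (symmetric, zero diagonal,
triangle inequality) and exactly invariant under global intensity
rescaling, both asserted in tests. Natural log is used everywhere;
Pearson correlations are base-invariant but slopes are not, so the
choice is recorded here.

**Gene selections.** The high-expresser variant keeps genes above a
fraction (default 0.4) of their chromosome's mean *observed* activity.
The two-cell-type differential selection histograms per-gene activity
differences, measures the full width at half maximum around the modal
bin (Freedman–Diaconis binning by default, no smoothing; the
contiguous run of bins at or above half the modal count defines the
width), and selects genes farther than one FWHM from the mode. The same
gene set feeds both cell types' IAD matrices, so per-chromosome counts
match by construction. Differences can be taken on the linear or the
log scale; the log scale is the right choice when the perturbation is
multiplicative, and both are exposed. A degenerate pure-triangle
difference distribution has every gene within one FWHM of the mode;
the empty selection raises an explicit error rather than returning an
empty matrix.

## Permutation inference

The null model relabels chromosomes: rows and columns of one matrix are
permuted together, which preserves the entry multiset and every metric
property of the input. Two implementations exist by design:

* the cumulative swap chain (uniform random transposition applied to
  the previously swapped matrix) for trajectory analyses — this is the
  process whose decay and H-trajectories are reported;
* uniform random permutations for null ensembles (FDR), the swap
  chain's limiting distribution, cheaper and exactly uniform.

One subtlety: a chain of exactly k transpositions reaches only
permutations of sign (−1)^k, so a fixed-length chain samples one parity
class. The property tests check uniformity on the reachable class; the
FDR ensemble is unaffected because it draws from all of S_n directly.

FDR uses strict inequality (ties are non-discoveries) and includes the
identity in the null ensemble; with 10⁴–10⁵ permutations the identity's
contribution is negligible. Exhaustive enumeration over all n!
permutations is available for small label sets and serves as the oracle
for the sampled estimator.

## The network energy H

H sums A_ij (Φ_if − Φ_jf)² over *unordered* pairs i < j; summing ordered
pairs would double H but leave ΔH and p unchanged. Φ is computed from
**raw-scale** (un-normalized) intensities: Φ_if = ln Σ(activities of
network f's genes on chromosome i), exactly 0 where the network has no
genes. The zero-for-absent convention only behaves as intended when
integrated intensities are well above 1 (typical raw array units, the
generator's default scale ≈ 500·exp(activity)); with order-1 normalized
activities, ln of a sum straddles 0 and absence becomes
indistinguishable from presence. Catalog genes absent from the
expression table are dropped with a logged count; a network with no
genes found yields an all-zero column and a warning.

Randomization swaps chromosome identities in the adjacency only (Φ
fixed). Cumulative mode records H after each of n_iterations swaps of
one chain (default 10⁴); independent mode records H for n_iterations
matrices each 100 swaps from the original. σ is the sample SD of the
recorded H values; ΔH = (⟨H⟩ − H₀)/σ, undefined (NaN, flagged) when σ
= 0, which happens exactly when every Φ column is constant. Two
p-values are reported: the two-sided Gaussian tail 2(1 − Φ_N(ΔH)) —
which reproduces the conventional pairs 1.97→0.05, 1.02→0.31, 0.71→0.48
at two decimals — and the empirical fraction of recorded H ≤ H₀.
The `exclude_homologues` flag zeroes the adjacency diagonal before
randomizing; diagonal terms multiply (Φ_if − Φ_if)² = 0 and never
contribute, so the flag is bookkeeping fidelity, asserted to leave all
statistics unchanged.

The λ-scan rebuilds the adjacency for each λ on a grid (default
0.02–0.80 of the nuclear radius, step 0.01), runs a reduced-iteration
randomization (default 2000–3000 steps), and averages ΔH over a few
independent replicates per grid point before taking the argmax — the
ΔH(λ) curve has a shallow maximum over a high plateau, and without
replicate averaging Monte-Carlo noise occasionally hands the argmax to
a plateau point.

Per-network sensitivity computes H from one Φ column at a time, using
randomization chains shared across networks so trajectories are
comparable, and reports ΔH_f/H_0f after 200 swaps (about one mixing
time for 22 labels) averaged over 20 chains. Networks with H_0f = 0 are
flagged rather than divided by zero.

## The synthetic nucleus model

The generator's defaults are the study conditions: 54 nuclei, 22
autosome pairs, duplicate arrays, 3 probes per gene, 87 networks with
sizes log-uniform on [5, 300].

**Placement.** Ground-truth per-chromosome log activities are drawn
N(0, 0.6²). Chromosomes sorted by activity are placed along a helix
with exact chordal spacing `coupling_length` between neighbors (6
points per turn, axial rise 0.4·spacing). The tight winding is the key
design choice: positions decorrelate from activity rank beyond a few
steps, so the coupling is *short-ranged* with `coupling_length` as its
length scale. A globally monotone curve (e.g. chromosomes along an
open arc) would couple positions to activity at every distance, and the
ΔH(λ) curve would then keep rising with λ instead of peaking near the
placement spacing — the length scale would not be recoverable. Base
positions are a convex blend of helix and uniform-in-ball positions
with weight `coupling_beta`; each homologue in each nucleus adds
isotropic Gaussian jitter (default SD 0.05 radii) and is radially
clipped to the unit ball. The jitter default is deliberately below the
placement spacing: homologue scatter convolves into the IPD and
compresses its short-distance structure, and with jitter ≳ the spacing
the adjacency length scale is no longer identifiable. Real fibroblast
nuclei show much larger cell-to-cell variability; the generator is a
calibration phantom, not a variability model.

**Expression.** Each chromosome carries a housekeeping class (default
30% of genes, ids `hk_*`) expressed at one common low level everywhere,
and a chromosome-specific class whose mean is set so the chromosome's
overall mean activity equals its ground-truth activity exactly —
chromosome-to-chromosome differences live entirely in the specific
class, as they do in real transcriptomes where a minority of genes
drives differential activity. Gene and probe/replicate noise are
multiplicative log-normal with SD `noise_sd` (default 0.3),
mean-corrected so expectations are unbiased; with zero noise and unit
intensity scale the per-chromosome mean recovers the input exactly.

**Networks.** Each network's occupied-chromosome count follows
n_chrom·(1 − exp(−size/s₀)) with s₀ calibrated so the mean occupancy
hits `occupancy_target` (default 0.6), reproducing the exponential
size–occupancy law. With probability exp(−size/s₀) a network is
"cell-type-specific": it occupies a contiguous block of the
activity-rank order and recruits specific genes — under coupling its
chromosomes are spatially proximate and its Φ column tracks local
activity. Otherwise it is "housekeeping-like": scattered chromosomes,
housekeeping genes, flat Φ. This two-regime structure is what produces
the inverse relation between network size and ΔH_f/H_0f together with
a majority of networks rising under randomization; with all networks
drawing genes uniformly, large networks inherit the global
activity–position gradient and dominate the sensitivity ranking
instead.

**Paint phantoms.** Blobs (spheres or axis-aligned cuboids) are
rasterized on a voxel grid; background intensity is uniform on [8, 12]
and blob voxels uniform on [100, 110] — bounded noise, so the mean+SD
threshold separates the classes deterministically. The primary ground
truth per homologue pairing is the exhaustive all-pairs minimum
distance between the blobs' per-slice 2D edge voxels, computed from the
known masks with a brute-force scan — this is the quantity the
edge-based measurement estimates. The minimum over full 3D surface
voxels is reported alongside (`surface_gap_um`); it can undercut the
edge-based value by more than a voxel near blob caps, where a z-section
has no in-plane edge — an inherent artifact of slice-wise edge
detection that users of the imaging pipeline should know about.

## What passing tests do and do not show

The synthetic generator has exactly the structure the estimators
assume: log-normal noise, one activity per chromosome, isotropic
jitter, networks built from the same gene table. Passing recovery tests
therefore demonstrates the estimators' correctness and calibration
under the model, not that real nuclei couple position to expression.
Real data differ in known ways: homologue scatter is far larger,
chromosome activity differences are smaller, probe effects are not
log-normal, and network catalogs are curated rather than sampled. The
matrices-from-files interfaces (coordinate TSV, expression TSV, GMT)
accept real exports unchanged.

## Numerical choices and degenerate inputs

* Matrix symmetry is exact by construction; file round-trips symmetrize
  against formatting noise and reject asymmetry above 10⁻⁹.
* Zero-variance off-diagonal vectors (constant matrices) raise rather
  than returning NaN correlations.
* Chromosomes with no observed genes are excluded from IAD and dropped
  jointly (by label) from any matrix correlation.
* The permutation-FDR estimator chunks permutation batches (20 000 at a
  time) to bound memory at ~40 MB for 22 labels.
* KD-tree interface distances are asserted to equal the O(n²) brute
  force exactly — both evaluate the same Euclidean norm in double
  precision.
* All randomness flows from integer seeds through numpy's PCG64;
  fixed seeds give bit-identical outputs across runs.

## Problem sizes

The default test and acceptance runs use the full 54-nucleus,
22-chromosome, 87-network configuration throughout; reduced iteration
counts (2000–3000 randomization steps instead of 10⁴) and replicate
averaging are used inside λ-scans, where 79 grid points × 10 studies
would otherwise repeat the full randomization 790 times for no extra
information. Monte-Carlo checks use 10–50 seeds per claim; binomial or
3-standard-error bands size every tolerance.
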