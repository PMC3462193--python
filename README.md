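# territory-coupling

Tools for quantifying how the 3D arrangement of chromosome territories
in the interphase nucleus relates to transcriptional output, with a
synthetic-data generator that makes the whole analysis chain testable
without microscope or microarray data.

## The scientific problem

Chromosomes occupy discrete territories in the interphase nucleus, and
their relative positions are non-random. This package implements a
quantitative framework for asking whether chromosomes that sit close to
one another also transcribe at similar levels, at two resolutions:

**Whole-chromosome matrices.** From per-nucleus homologue centroid
coordinates (in units of the nuclear radius) it builds the
inter-chromosome physical distance matrix

> IPD_ij = mean over nuclei of the mean (or minimum) of the four
> homologue-pairing distances between chromosomes i and j,

and from probe-level expression the activity distance matrix

> IAD_ij = | ln A_i − ln A_j |,  A_i = (Σ_k x_ik) / N_i,

where the sum runs over observed genes on chromosome i and N_i is the
*annotated* gene count. A basepair-length difference matrix
IBD_ij = |Chrbp(i) − Chrbp(j)| serves as a size control. Two matrices
are compared Mantel-style: Pearson correlation of the off-diagonal
entries (the diagonal holds homologue separations and is excluded),
with significance from a permutation null — rows and columns of one
matrix are shuffled together, and the FDR is the fraction of permuted
correlations strictly exceeding the observed PCC₀.

**Network energy.** At the level of transcription-factor networks (TFNs)
the coupling is scored by the energy

> H = Σ_f Σ_{i<j} A_ij (Φ_if − Φ_jf)²,  A_ij = exp(−IPD_ij / λ),

where Φ_if is the natural log of the summed expression of network f's
genes on chromosome i (exactly 0 when none are present) and λ is a
length scale in nuclear radii (default 0.07). H is small when proximal
chromosomes carry similar network activity. Whether an observed
arrangement is near-optimal is tested by swapping chromosome identities
in A and tracking H; the deviate ΔH = (⟨H_rand⟩ − H₀)/σ maps to a
p-value through the two-sided normal tail 2(1 − Φ_N(ΔH)).

**Interface distances.** For chromosome-paint confocal z-stacks the
package reimplements the classic measurement: threshold each channel at
mean + SD of the stack, split into the two largest 3D components
(homologues), extract per-slice 2D edges, and take the minimum 3D
distance over all edge-voxel pairs for each of the four homologue
pairings.

**Synthetic data.** A generator produces nucleus populations (default
54 nuclei × 22 autosome pairs) with a tunable position–activity
coupling: chromosomes sorted by activity are placed along a tightly
winding helix with neighbor spacing `coupling_length` and blended with
uniform positions by weight `coupling_beta`. It also emits probe-level
log-normal expression with housekeeping and chromosome-specific gene
classes, TFN catalogs with a controlled size–occupancy law, and paint
phantoms with exhaustively computed ground-truth gaps.

## Worked example

```python
import territory_coupling as tc

study = tc.generate_study(tc.SimulationConfig(seed=1))   # beta = 1: fully coupled
res = tc.permutation_fdr(
    study["ipd"],
    tc.compute_iad(tc.chromosome_activity(study["genes"], study["annotation"])),
    n_perm=10_000, seed=1,
)
print(f"PCC {res.pcc:.3f}, slope {res.slope:.2f}, FDR {res.fdr:.4f}")

adj = tc.build_adjacency(study["ipd"], 0.07)
summary = tc.randomize_H(adj, study["phi"],
                         tc.EnergyConfig(n_iterations=10_000, seed=1))
print(f"delta_H {summary.delta_h:.2f}, p {summary.p_gaussian:.2g}")
```

On the seed-1 study this prints (numbers from an actual run):

```
PCC 0.885, slope 2.87, FDR 0.0000
delta_H 10.54, p 5.4e-26
```

A PCC of 0.885 with FDR ≈ 0 says the generated arrangement couples
position to activity far beyond what row/column shuffles produce, and
ΔH ≈ 10.5 says randomizing chromosome identities raises the network
energy by more than ten null standard deviations — the arrangement is
near-optimal for its own transcriptional program. The same adjacency
scored against an independently regenerated activity profile gives
ΔH ≈ −1.3: the optimality is profile-specific.

The numbered drivers under `analysis/` run the full study
(`01_simulate_nucleus_population.py` → `02_distance_activity_correlation.py`
→ `03_network_energy.py` → `04_interface_distances.py`), printing their
findings and writing tables under `results/`.

A `territory-coupling` console script exposes each stage
(`simulate`, `ipd`, `ibd`, `iad`, `iad-pair`, `correlate`, `fdr`,
`decay`, `permute`, `energy`, `scan-lambda`, `network-sensitivity`,
`occupancy`, `interface-distance`, `validate`, `run`); see
`territory-coupling --help`.

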