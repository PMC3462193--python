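"""Probe the coupling between chromosome adjacency and TF-network activity.

Builds the network matrix from the study's raw-scale activities and the
GMT catalog, evaluates H at lambda = 0.07, runs the 10^4-step cumulative
randomization for the matched profile and for an independently
regenerated (mismatched) one, scans lambda over 2-80% of the nuclear
radius, and measures the per-network sensitivity and occupancy laws.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

import territory_coupling as tc

ROOT = Path(__file__).resolve().parent.parent
STUDY = ROOT / "results" / "study"
OUT = ROOT / "results"
SEED = 1
LAMBDA = 0.07


def main() -> None:
    nuclei = tc.NucleusSet.from_tsv(STUDY / "coordinates.tsv")
    expr = tc.ExpressionTable.from_tsv(STUDY / "expression.tsv")
    annotation = tc.GenomeAnnotation.from_tsv(STUDY / "annotation.tsv")
    catalog = tc.NetworkCatalog.from_gmt(STUDY / "networks.gmt")
    ipd = tc.compute_ipd(nuclei)

    genes_raw = tc.aggregate_probes(expr, require_normalized=False)
    phi = tc.build_network_matrix(genes_raw, catalog, chromosomes=ipd.labels)
    adjacency = tc.build_adjacency(ipd, LAMBDA)

    summary = tc.randomize_H(
        adjacency, phi, tc.EnergyConfig(lambda_=LAMBDA, n_iterations=10_000, seed=SEED)
    )
    print(f"H0 = {summary.h0:.1f};  randomized H = {summary.h_av:.1f} "
          f"+/- {summary.sigma:.1f}")
    print(f"delta_H = {summary.delta_h:.2f}  (p_gaussian {summary.p_gaussian:.2g}, "
          f"p_empirical {summary.p_empirical:.2g})")
    np.savetxt(OUT / "h_trajectory.tsv", summary.trajectory, fmt="%.8g")

    # mismatched profile: an independently regenerated cell type
    other = tc.generate_study(tc.SimulationConfig(seed=SEED + 7000))
    mism = tc.randomize_H(
        adjacency, other["phi"],
        tc.EnergyConfig(lambda_=LAMBDA, n_iterations=10_000, seed=SEED + 1),
    )
    print(f"mismatched-profile delta_H = {mism.delta_h:.2f} "
          f"(matched {summary.delta_h:.2f})")

    scan = tc.scan_lambda(
        ipd, phi, config=tc.EnergyConfig(n_iterations=3000, seed=SEED), reps=4
    )
    pd.DataFrame({"lambda": scan["lambda"], "delta_h": scan["delta_h"]}).to_csv(
        OUT / "lambda_scan.tsv", sep="\t", index=False
    )
    print(f"lambda scan argmax: {scan['argmax_lambda']:.2f} "
          f"(placement spacing was 0.07)")

    sens = tc.per_network_sensitivity(adjacency, phi, n_steps=200, reps=20, seed=SEED)
    occ = tc.occupancy(phi)
    sens["occupancy"] = occ.to_numpy()
    sens.to_csv(OUT / "network_sensitivity.tsv", sep="\t", index=False)
    ok = sens.dropna()
    rho = stats.spearmanr(ok["size"], ok["delta_h_rel"]).statistic
    print(f"networks rising under randomization: "
          f"{(ok['delta_h_rel'] > 0).mean():.0%}")
    print(f"rank correlation of dH/H0 with network size: {rho:+.2f}")
    print(f"rank correlation of occupancy with size: "
          f"{stats.spearmanr(phi.network_sizes(), occ).statistic:+.2f}")

    npc = tc.networks_per_chromosome(phi, annotation)
    # with equal per-chromosome gene counts the gene-count PCC is
    # undefined (zero variance) and reported as NaN by design
    print(f"networks per chromosome: vs basepair length "
          f"PCC {npc['pcc_vs_basepairs']:+.2f}, vs gene count "
          f"PCC {npc['pcc_vs_gene_count']:+.2f}")


if __name__ == "__main__":
    main()
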