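"""From probe-level expression to chromosome activity and IAD matrices.

The activity pipeline mirrors standard microarray summarization:
intensities are normalized to the array mean, probes are averaged into
gene activities (replicate mean first, then probe mean), gene activities
are summed per chromosome and divided by the *annotated* gene count N —
not by chromosome size and not by the number of genes observed on the
array.  The inter-chromosome activity distance is then

    IAD_ij = | ln A_i - ln A_j |

which is a one-dimensional embedding metric: symmetric, zero diagonal,
and obeying the triangle inequality.  Because only log differences enter,
IAD is exactly invariant under global rescaling of all intensities.

Two gene-selection schemes restrict the activity calculation:

* high expressers — genes above a fraction (default 40%) of their
  chromosome's mean observed activity;
* differential selection — for a pair of cell types, genes whose
  activity difference lies more than one FWHM (full width at half
  maximum of the difference histogram) from the histogram mode.  The
  same selected gene set feeds both cell types' IAD matrices, so the
  per-chromosome gene counts match between the pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .matrices import DistanceMatrix, GenomeAnnotation

__all__ = [
    "ExpressionTable",
    "ActivityVector",
    "DifferentialSelection",
    "normalize_to_array_mean",
    "aggregate_probes",
    "chromosome_activity",
    "compute_iad",
    "select_high_expressers",
    "differential_selection",
    "build_pairwise_iads",
]

log = logging.getLogger(__name__)

EXPR_COLUMNS = ["probe_id", "gene_id", "chromosome", "replicate", "intensity"]


@dataclass(frozen=True)
class ExpressionTable:
    """Probe-level intensities with gene and chromosome annotation."""

    table: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in EXPR_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"expression table missing columns {missing}")
        x = df["intensity"].to_numpy(float)
        if not np.all(np.isfinite(x)) or np.any(x <= 0):
            raise ValueError("intensities must be strictly positive and finite")
        n_chrom = df.groupby("gene_id")["chromosome"].nunique()
        if (n_chrom > 1).any():
            bad = n_chrom[n_chrom > 1].index[:3].tolist()
            raise ValueError(f"genes mapped to multiple chromosomes: {bad}")

    def to_tsv(self, path: str | Path) -> None:
        self.table[EXPR_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, normalized: bool = False) -> "ExpressionTable":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        return cls(df, normalized=normalized)

    @classmethod
    def from_probe_dump(
        cls, probe_tsv: str | Path, map_tsv: str | Path, replicate: int = 1
    ) -> "ExpressionTable":
        """Assemble a table from a two-column probe/intensity dump plus a
        probe -> gene -> chromosome map (for externally exported data)."""
        probes = pd.read_csv(probe_tsv, sep="\t")
        mapping = pd.read_csv(map_tsv, sep="\t", dtype={"chromosome": str})
        for col, src in (("probe_id", probe_tsv), ("intensity", probe_tsv)):
            if col not in probes.columns:
                raise ValueError(f"{src}: missing column {col!r}")
        for col in ("probe_id", "gene_id", "chromosome"):
            if col not in mapping.columns:
                raise ValueError(f"{map_tsv}: missing column {col!r}")
        df = probes.merge(mapping, on="probe_id", how="inner")
        df["replicate"] = replicate
        return cls(df[EXPR_COLUMNS])


@dataclass(frozen=True)
class ActivityVector:
    """Per-chromosome mean activity A_chr with annotated-count bookkeeping.

    ``excluded`` lists chromosomes with no observed genes (A undefined);
    downstream matrix construction drops them jointly from both matrices.
    """

    table: pd.DataFrame  # chromosome, activity, log_activity, genes_used
    excluded: tuple[str, ...] = ()

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.table["chromosome"])

    def log_activity(self) -> pd.Series:
        return self.table.set_index("chromosome")["log_activity"]

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class DifferentialSelection:
    """Genes differentially expressed between two cell types.

    The same gene set serves both directions of the pair, so selected
    per-chromosome counts are identical in the two IAD matrices built
    from it.
    """

    genes: tuple[str, ...]
    fwhm: float
    mode_center: float
    bins: int
    direction: tuple[str, str] = ("A", "B")


# ---------------------------------------------------------------------- #


def normalize_to_array_mean(t: ExpressionTable) -> ExpressionTable:
    """Divide every intensity by its array's (replicate's) mean intensity.

    Each replicate is treated as one array and normalized independently,
    so the post-normalization mean of every array is exactly 1.  The
    operation is idempotent.
    """
    df = t.table.copy()
    means = df.groupby("replicate")["intensity"].transform("mean")
    df["intensity"] = df["intensity"] / means
    return ExpressionTable(df, normalized=True)


def aggregate_probes(t: ExpressionTable, require_normalized: bool = True) -> pd.DataFrame:
    """One activity per gene: replicate-mean per probe, then probe-mean.

    Returns a DataFrame (gene_id, chromosome, activity).
    """
    if require_normalized and not t.normalized:
        log.warning("aggregating an unnormalized table")
    per_probe = (
        t.table.groupby(["gene_id", "chromosome", "probe_id"], sort=False)["intensity"]
        .mean()
        .reset_index()
    )
    per_gene = (
        per_probe.groupby(["gene_id", "chromosome"], sort=False)["intensity"]
        .mean()
        .reset_index()
        .rename(columns={"intensity": "activity"})
    )
    if per_gene.empty:
        raise ValueError("no genes in expression table")
    return per_gene


def chromosome_activity(
    genes: pd.DataFrame, annotation: GenomeAnnotation
) -> ActivityVector:
    """Mean chromosome activity A_i = (sum of observed gene activities) / N_i.

    N_i is the *annotated* gene count for chromosome i, so unobserved
    annotated genes dilute the mean rather than being ignored.
    Chromosomes with zero observed genes are flagged and excluded.
    """
    unknown = set(genes["chromosome"].astype(str)) - set(annotation.chromosomes)
    if unknown:
        raise KeyError(f"chromosomes not in annotation: {sorted(unknown)[:5]}")
    totals = genes.groupby("chromosome")["activity"].agg(["sum", "size"])
    rows, excluded = [], []
    for chrom in annotation.chromosomes:
        if chrom in totals.index:
            a = float(totals.loc[chrom, "sum"]) / annotation.gene_counts[chrom]
            rows.append(
                {
                    "chromosome": chrom,
                    "activity": a,
                    "log_activity": float(np.log(a)),
                    "genes_used": int(totals.loc[chrom, "size"]),
                }
            )
        else:
            excluded.append(chrom)
    if excluded:
        log.warning("chromosomes with no observed genes excluded: %s", excluded)
    return ActivityVector(table=pd.DataFrame(rows), excluded=tuple(excluded))


def compute_iad(a: ActivityVector) -> DistanceMatrix:
    """IAD_ij = |ln A_i - ln A_j| over the non-excluded chromosomes."""
    la = a.table["log_activity"].to_numpy(float)
    labels = a.chromosomes
    values = np.abs(la[:, None] - la[None, :])
    return DistanceMatrix(
        labels=labels, values=values, units="log_activity", role="IAD",
        diagonal_excluded=True,
    )


def select_high_expressers(
    genes: pd.DataFrame, fraction_of_chr_mean: float = 0.4
) -> pd.DataFrame:
    """Keep genes above ``fraction`` x (mean observed activity of their
    chromosome); builds the high-expresser IAD variant."""
    if fraction_of_chr_mean <= 0:
        raise ValueError("fraction must be positive")
    chr_mean = genes.groupby("chromosome")["activity"].transform("mean")
    kept = genes[genes["activity"] > fraction_of_chr_mean * chr_mean]
    empty = set(genes["chromosome"]) - set(kept["chromosome"])
    if empty:
        log.warning("no genes pass the threshold on chromosomes %s", sorted(empty))
    return kept.reset_index(drop=True)


def _fwhm_from_histogram(d: np.ndarray, bins) -> tuple[float, float, int]:
    """FWHM of the difference histogram and the modal bin center.

    The width is measured on the raw (unsmoothed) histogram: from the
    modal bin, walk left and right while counts stay at or above half the
    modal count; the FWHM is the span of that contiguous run of bins.
    """
    counts, edges = np.histogram(d, bins=bins)
    if counts.max() == 0:
        raise ValueError("empty histogram")
    k = int(np.argmax(counts))
    half = counts[k] / 2.0
    lo = k
    while lo > 0 and counts[lo - 1] >= half:
        lo -= 1
    hi = k
    while hi < len(counts) - 1 and counts[hi + 1] >= half:
        hi += 1
    fwhm = float(edges[hi + 1] - edges[lo])
    center = float((edges[k] + edges[k + 1]) / 2.0)
    return fwhm, center, len(counts)


def differential_selection(
    a: pd.DataFrame,
    b: pd.DataFrame,
    bins="fd",
    log_scale: bool = False,
    center_at_zero: bool = False,
    direction: tuple[str, str] = ("A", "B"),
) -> DifferentialSelection:
    """Select genes whose expression differs by more than one FWHM.

    ``a`` and ``b`` are per-gene activity tables for the two cell types
    (inner-joined on gene_id).  The per-gene difference d_g is histogrammed
    (Freedman-Diaconis bins by default), the FWHM of the histogram is
    measured around its mode, and genes with |d_g - mode| > FWHM are
    selected.  ``log_scale=True`` differences log activities instead of
    linear ones; ``center_at_zero=True`` replaces the mode with 0.
    """
    merged = a.merge(b, on="gene_id", suffixes=("_a", "_b"))
    if merged.empty:
        raise ValueError("no shared genes between the two tables")
    xa = merged["activity_a"].to_numpy(float)
    xb = merged["activity_b"].to_numpy(float)
    d = np.log(xa) - np.log(xb) if log_scale else xa - xb
    if np.ptp(d) == 0:
        raise ValueError(
            "all expression differences identical — nothing to select "
            "(coarsen bins or check the inputs)"
        )
    fwhm, center, n_bins = _fwhm_from_histogram(d, bins)
    if center_at_zero:
        center = 0.0
    mask = np.abs(d - center) > fwhm
    genes = tuple(merged.loc[mask, "gene_id"])
    if not genes:
        raise ValueError(
            f"no gene differs by more than one FWHM ({fwhm:.4g}); "
            "coarsen the histogram bins"
        )
    return DifferentialSelection(
        genes=genes, fwhm=fwhm, mode_center=center, bins=n_bins, direction=direction
    )


def build_pairwise_iads(
    selection: DifferentialSelection,
    a: pd.DataFrame,
    b: pd.DataFrame,
    annotation: GenomeAnnotation,
) -> tuple[DistanceMatrix, DistanceMatrix]:
    """IAD matrices for a cell-type pair from the shared selected genes.

    Returns (IAD with activities from A, IAD with activities from B);
    per-chromosome selected gene counts are identical by construction.
    """
    genes = set(selection.genes)
    if not genes:
        raise ValueError("empty selection")
    sub_a = a[a["gene_id"].isin(genes)]
    sub_b = b[b["gene_id"].isin(genes)]
    act_a = chromosome_activity(sub_a, annotation)
    act_b = chromosome_activity(sub_b, annotation)
    # joint exclusion keeps the two matrices on identical labels
    excluded = set(act_a.excluded) | set(act_b.excluded)
    keep = [c for c in act_a.chromosomes if c not in excluded]
    iad_a = compute_iad(act_a).subset(keep)
    iad_b = compute_iad(act_b).subset(keep)
    return iad_a, iad_b
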