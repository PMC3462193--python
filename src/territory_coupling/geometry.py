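"""Inter-chromosome physical distances and matrix randomization.

Chromosome territories are summarized by their centroid, one per
homologue, in units of the nuclear radius.  Because homologues cannot be
distinguished experimentally, a chromosome pair contributes up to four
centroid-centroid distances per nucleus; the per-nucleus aggregate (mean
or minimum over pairings) is then averaged over nuclei to form the IPD
matrix.  The diagonal holds the homologue-homologue separation and is
flagged as excluded from all correlation analysis.

Null models randomize chromosome *identities*, not coordinates: rows and
columns of a distance matrix are swapped together, which preserves the
entry multiset and therefore every metric property of the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .matrices import DistanceMatrix, GenomeAnnotation

__all__ = [
    "NucleusSet",
    "compute_ipd",
    "compute_ibd",
    "permute_matrix",
    "swap_chain",
    "uniform_permutation",
]

log = logging.getLogger(__name__)

COORD_COLUMNS = ["nucleus_id", "chromosome", "homologue", "x", "y", "z"]


@dataclass(frozen=True)
class NucleusSet:
    """Per-nucleus, per-homologue chromosome centroid coordinates.

    ``table`` columns: nucleus_id, chromosome, homologue (1 or 2), x, y, z;
    coordinates in units of the nuclear radius (norm <= 1).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in COORD_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"coordinate table missing columns {missing}")
        if df[["x", "y", "z"]].isna().any().any():
            raise ValueError("NaN coordinates")
        norms = np.linalg.norm(df[["x", "y", "z"]].to_numpy(float), axis=1)
        if np.any(norms > 1 + 1e-9):
            raise ValueError("coordinates outside the unit nuclear radius")
        if not df["homologue"].isin([1, 2]).all():
            raise ValueError("homologue index must be 1 or 2")
        if df.duplicated(["nucleus_id", "chromosome", "homologue"]).any():
            raise ValueError("duplicate (nucleus, chromosome, homologue) keys")
        counts = df.groupby(["nucleus_id", "chromosome"]).size()
        if (counts > 2).any():
            raise ValueError("more than two homologues for a chromosome")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.table["chromosome"].astype(str):
            seen.setdefault(c, None)
        return tuple(seen)

    @property
    def n_nuclei(self) -> int:
        return self.table["nucleus_id"].nunique()

    def to_tsv(self, path: str | Path) -> None:
        self.table[COORD_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "NucleusSet":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        return cls(df)


def compute_ipd(
    nuclei: NucleusSet, mode: Literal["mean", "min"] = "mean"
) -> DistanceMatrix:
    """Inter-chromosome physical distance matrix.

    For each nucleus and chromosome pair, the distances between all
    homologue pairings (four when both chromosomes have both homologues)
    are aggregated by ``mode`` and then averaged over every nucleus that
    contains both chromosomes.  The diagonal entry is the mean
    homologue-homologue distance of that chromosome and is marked
    excluded from correlation.
    """
    if mode not in ("mean", "min"):
        raise ValueError(f"mode must be 'mean' or 'min', got {mode!r}")
    labels = nuclei.chromosomes
    n = len(labels)
    if n < 1:
        raise ValueError("empty nucleus set")
    idx = {c: k for k, c in enumerate(labels)}
    sums = np.zeros((n, n))
    counts = np.zeros((n, n), dtype=int)

    for _, grp in nuclei.table.groupby("nucleus_id", sort=False):
        chroms = grp["chromosome"].astype(str).to_numpy()
        coords = grp[["x", "y", "z"]].to_numpy(float)
        present: dict[str, np.ndarray] = {}
        for c in np.unique(chroms):
            present[c] = coords[chroms == c]
        keys = list(present)
        for a_i, ca in enumerate(keys):
            pa = present[ca]
            # diagonal: homologue-homologue distance, needs both homologues
            if len(pa) == 2:
                d = float(np.linalg.norm(pa[0] - pa[1]))
                sums[idx[ca], idx[ca]] += d
                counts[idx[ca], idx[ca]] += 1
            for cb in keys[a_i + 1 :]:
                block = cdist(pa, present[cb])
                d = float(block.mean() if mode == "mean" else block.min())
                i, j = idx[ca], idx[cb]
                sums[i, j] += d
                sums[j, i] += d
                counts[i, j] += 1
                counts[j, i] += 1

    iu = np.triu_indices(n, k=1)
    empty = counts[iu] == 0
    if np.any(empty):
        bad = [(labels[i], labels[j]) for i, j in zip(iu[0][empty], iu[1][empty])]
        raise ValueError(f"no nucleus contains both chromosomes for pairs {bad[:5]}")
    values = np.zeros((n, n))
    nz = counts > 0
    values[nz] = sums[nz] / counts[nz]
    log.info(
        "IPD(%s): %d chromosomes, %d nuclei, min contributing nuclei per pair = %d",
        mode, n, nuclei.n_nuclei, int(counts[iu].min()),
    )
    return DistanceMatrix(
        labels=labels,
        values=values,
        units="nuclear_radius",
        role="IPD_mean" if mode == "mean" else "IPD_min",
        diagonal_excluded=True,
    )


def compute_ibd(annotation: GenomeAnnotation, labels=None) -> DistanceMatrix:
    """Basepair-length difference matrix: |Chrbp(i) - Chrbp(j)|."""
    labels = tuple(labels) if labels is not None else annotation.chromosomes
    missing = [c for c in labels if c not in annotation.basepairs]
    if missing:
        raise KeyError(f"chromosomes missing from annotation: {missing}")
    bp = np.array([annotation.basepairs[c] for c in labels], dtype=float)
    values = np.abs(bp[:, None] - bp[None, :])
    return DistanceMatrix(
        labels=labels, values=values, units="basepairs", role="IBD",
        diagonal_excluded=True,
    )


# ------------------------- randomization ------------------------------ #


def swap_chain(
    n_labels: int, rng: np.random.Generator
) -> Iterator[tuple[np.ndarray, tuple[int, int]]]:
    """Infinite cumulative swap chain over ``n_labels`` positions.

    Yields ``(perm, (i, j))`` after each swap, where ``perm`` is the
    accumulated permutation (a view; copy to keep) and ``(i, j)`` the
    unordered position pair just exchanged.  Each swap is drawn uniformly
    over the n(n-1)/2 unordered pairs and applied to the previously
    swapped state, so the chain randomizes progressively.
    """
    perm = np.arange(n_labels)
    while True:
        i = int(rng.integers(n_labels))
        j = int(rng.integers(n_labels - 1))
        if j >= i:
            j += 1
        perm[[i, j]] = perm[[j, i]]
        yield perm, (i, j)


def permute_matrix(
    m: DistanceMatrix,
    n_swaps: int,
    seed: int | np.random.Generator,
    cumulative: bool = True,
) -> tuple[DistanceMatrix, dict]:
    """Randomize a matrix by swapping rows and columns together.

    ``n_swaps`` random transpositions are composed (cumulatively, each
    applied to the previously swapped matrix) and the conjugated matrix is
    returned with a record of the swaps and the final permutation.  With
    ``cumulative=False`` the chain is still a single fresh chain from the
    input matrix — the flag matters only to callers drawing repeated
    matrices, who restart the chain for each draw.

    Because entries are only relabeled, the multiset of values — and the
    triangle inequality, when the input is metric — is preserved exactly.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perm = np.arange(m.n)
    swaps: list[tuple[int, int]] = []
    chain = swap_chain(m.n, rng)
    for _ in range(n_swaps):
        perm, pair = next(chain)
        swaps.append(pair)
    record = {"swaps": swaps, "permutation": perm.copy(), "cumulative": cumulative}
    return m.permuted(perm), record


def uniform_permutation(n_labels: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform random permutation — the swap chain's limiting ensemble.

    Used for null ensembles (permutation FDR) where only the fully
    randomized state matters; identical in distribution to a long
    cumulative swap chain but cheaper and exactly uniform.
    """
    return rng.permutation(n_labels)
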