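"""Labeled symmetric matrices shared across the pipeline.

A single container class serves the inter-chromosome physical distance
(IPD), activity distance (IAD), basepair-length distance (IBD) and
adjacency matrices: all are square, symmetric, chromosome-labeled real
matrices that differ only in units and in whether the diagonal is
meaningful for correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DistanceMatrix", "GenomeAnnotation"]

#: roles understood by downstream stages
ROLES = {"IPD_mean", "IPD_min", "IAD", "IBD", "adjacency", "other"}
UNITS = {"nuclear_radius", "log_activity", "basepairs", "dimensionless", "micron"}


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric matrix with chromosome labels.

    Parameters
    ----------
    labels
        Ordered chromosome names; defines row/column order.
    values
        Square, symmetric, finite array of shape ``(len(labels),) * 2``.
    units
        Physical units of the entries (``nuclear_radius``, ``log_activity``,
        ``basepairs``, ``micron`` or ``dimensionless``).
    role
        What the matrix represents; correlation code treats all roles
        identically but records the role in its output.
    diagonal_excluded
        If True (the default for distance roles) the diagonal holds
        homologue-homologue distances that are kept out of every
        correlation; only off-diagonal entries are ever compared.
    """

    labels: tuple[str, ...]
    values: np.ndarray
    units: str = "dimensionless"
    role: str = "other"
    diagonal_excluded: bool = True

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        n = len(self.labels)
        if vals.shape != (n, n):
            raise ValueError(f"matrix shape {vals.shape} does not match {n} labels")
        if not np.all(np.isfinite(vals)):
            raise ValueError("matrix contains non-finite entries")
        if np.max(np.abs(vals - vals.T), initial=0.0) != 0.0:
            raise ValueError("matrix is not exactly symmetric")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.role == "adjacency" and (np.any(vals <= 0) or np.any(vals > 1)):
            raise ValueError("adjacency values must lie in (0, 1]")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels")

    # ------------------------------------------------------------------ #

    @property
    def n(self) -> int:
        return len(self.labels)

    def offdiag(self) -> np.ndarray:
        """Upper-triangle (i < j) entries in label order.

        The diagonal is never included: for distance roles it holds
        homologue separations that are excluded from correlation analysis,
        and for the remaining roles it is structurally zero.
        """
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return the sub-matrix for ``labels`` (in the given order)."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels not present: {missing}")
        idx = np.array([self.labels.index(l) for l in labels])
        return replace(self, labels=tuple(labels), values=self.values[np.ix_(idx, idx)])

    def align_with(self, other: "DistanceMatrix", intersect: bool = False):
        """Return the two matrices on a common label order.

        With ``intersect=False`` the label sets must be equal; otherwise the
        shared subset (in this matrix's order) is used.
        """
        if set(self.labels) == set(other.labels):
            common = list(self.labels)
        elif intersect:
            common = [l for l in self.labels if l in set(other.labels)]
            if len(common) < 3:
                raise ValueError("fewer than 3 shared labels")
        else:
            raise ValueError(
                "label sets differ; pass intersect=True to use the shared subset"
            )
        return self.subset(common), other.subset(common)

    def permuted(self, perm: np.ndarray) -> "DistanceMatrix":
        """Conjugate by a permutation: ``out[k, l] = in[perm[k], perm[l]]``.

        Labels are unchanged — this relabels which chromosome sits at which
        position, which is exactly the randomization used for null models.
        """
        perm = np.asarray(perm, dtype=int)
        if sorted(perm.tolist()) != list(range(self.n)):
            raise ValueError("not a permutation of 0..n-1")
        return replace(self, values=self.values[np.ix_(perm, perm)])

    # ------------------------------- io ------------------------------- #

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, index=self.labels, columns=self.labels)
        df.to_csv(path, sep="\t", index_label="chromosome")

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.columns = [str(c) for c in df.columns]
        labels = tuple(str(i) for i in df.index)
        if tuple(df.columns) != labels:
            raise ValueError(f"{path}: row and column labels disagree")
        vals = df.to_numpy(dtype=float)
        # symmetrize exactly against round-trip formatting noise
        asym = np.max(np.abs(vals - vals.T), initial=0.0)
        if asym > 1e-9:
            raise ValueError(f"{path}: matrix asymmetric (max |M - M^T| = {asym:g})")
        vals = (vals + vals.T) / 2.0
        return cls(labels=labels, values=vals, **kwargs)


@dataclass(frozen=True)
class GenomeAnnotation:
    """Per-chromosome basepair length and annotated gene count.

    The annotated count ``N`` is the divisor for mean chromosome activity:
    total observed activity is normalized by the number of annotated genes,
    not by chromosome size and not by the number of observed genes.
    """

    basepairs: dict[str, float]
    gene_counts: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.basepairs) != set(self.gene_counts):
            raise ValueError("basepairs and gene_counts cover different chromosomes")
        if any(v <= 0 for v in self.basepairs.values()):
            raise ValueError("basepair lengths must be positive")
        if any(v < 1 for v in self.gene_counts.values()):
            raise ValueError("gene counts must be >= 1")

    @property
    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self.basepairs)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "chromosome": list(self.basepairs),
                "basepairs": [self.basepairs[c] for c in self.basepairs],
                "gene_count": [self.gene_counts[c] for c in self.basepairs],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeAnnotation":
        df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
        for col in ("chromosome", "basepairs", "gene_count"):
            if col not in df.columns:
                raise ValueError(f"{path}: missing column {col!r}")
        return cls(
            basepairs=dict(zip(df["chromosome"], df["basepairs"].astype(float))),
            gene_counts=dict(zip(df["chromosome"], df["gene_count"].astype(int))),
        )
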