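"""Correlation between labeled matrices with a permutation null.

This is a Mantel-style analysis: two symmetric chromosome-labeled
matrices are compared through the Pearson correlation of their
off-diagonal entries, and significance is assessed by conjugating one
matrix with random label permutations (rows and columns moved together).
The false discovery rate is the fraction of permuted correlations that
strictly exceed the observed one.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np
from scipy import stats

from .geometry import swap_chain, uniform_permutation
from .matrices import DistanceMatrix

__all__ = [
    "CorrelationResult",
    "offdiag_vector",
    "correlate",
    "permutation_fdr",
    "randomization_decay",
]


@dataclass(frozen=True)
class CorrelationResult:
    """Observed correlation plus (optionally) its permutation null."""

    pcc: float
    slope: float
    intercept: float
    n_pairs: int
    fdr: float | None = None
    n_permutations: int = 0
    null_mean: float | None = None
    null_sd: float | None = None
    roles: tuple[str, str] = ("other", "other")

    def to_dict(self) -> dict:
        return asdict(self)


def offdiag_vector(m: DistanceMatrix) -> np.ndarray:
    """Upper-triangle (i < j) entries in fixed label order.

    By symmetry the lower triangle would give the identical vector, and
    the diagonal — homologue distances — is never included.
    """
    return m.offdiag()


def _pearson_slope(v1: np.ndarray, v2: np.ndarray) -> tuple[float, float, float]:
    if np.std(v1) == 0 or np.std(v2) == 0:
        raise ValueError("zero variance in off-diagonal entries")
    res = stats.linregress(v1, v2)
    return float(res.rvalue), float(res.slope), float(res.intercept)


def correlate(
    m1: DistanceMatrix, m2: DistanceMatrix, intersect: bool = False
) -> CorrelationResult:
    """Pearson correlation and least-squares fit of m2 regressed on m1.

    Matrices are aligned on a common label order first; at least three
    chromosome pairs are required.
    """
    a, b = m1.align_with(m2, intersect=intersect)
    v1, v2 = a.offdiag(), b.offdiag()
    if v1.size < 3:
        raise ValueError("need at least 3 chromosome pairs")
    pcc, slope, intercept = _pearson_slope(v1, v2)
    return CorrelationResult(
        pcc=pcc, slope=slope, intercept=intercept, n_pairs=int(v1.size),
        roles=(a.role, b.role),
    )


def _batch_pcc(M: np.ndarray, perms: np.ndarray, v2: np.ndarray) -> np.ndarray:
    """Pearson r between v2 and the upper triangle of M conjugated by each
    permutation in ``perms`` (shape n_perm x L), vectorized."""
    L = M.shape[0]
    iu0, iu1 = np.triu_indices(L, k=1)
    V = M[perms[:, iu0], perms[:, iu1]]  # (n_perm, n_pairs)
    Vc = V - V.mean(axis=1, keepdims=True)
    v2c = v2 - v2.mean()
    denom = np.sqrt((Vc**2).sum(axis=1) * (v2c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Vc @ v2c) / denom
    return r


def permutation_fdr(
    m1: DistanceMatrix,
    m2: DistanceMatrix,
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
    randomize: Literal["first", "second"] = "first",
    exhaustive: bool = False,
    intersect: bool = False,
    chunk: int = 20_000,
) -> CorrelationResult:
    """Permutation false discovery rate for a matrix correlation.

    ``n_perm`` uniform label permutations of the chosen matrix are each
    correlated with the other matrix; FDR is the fraction with PCC
    strictly greater than the observed PCC_0 (ties count as
    non-discoveries).  ``exhaustive=True`` enumerates all L! permutations
    instead of sampling — feasible for small label sets and used as the
    exact oracle.
    """
    if n_perm < 1 and not exhaustive:
        raise ValueError("n_perm must be >= 1")
    a, b = m1.align_with(m2, intersect=intersect)
    if randomize == "second":
        a, b = b, a
    obs = correlate(a, b)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    M, v2 = a.values, b.offdiag()
    L = a.n

    null: list[np.ndarray] = []
    if exhaustive:
        perms = np.array(list(itertools.permutations(range(L))), dtype=int)
        for start in range(0, len(perms), chunk):
            null.append(_batch_pcc(M, perms[start : start + chunk], v2))
        n_used = len(perms)
    else:
        n_used = int(n_perm)
        done = 0
        while done < n_used:
            k = min(chunk, n_used - done)
            perms = np.stack([uniform_permutation(L, rng) for _ in range(k)])
            null.append(_batch_pcc(M, perms, v2))
            done += k
    r = np.concatenate(null)
    r = r[np.isfinite(r)]
    fdr = float(np.sum(r > obs.pcc) / len(r))
    return CorrelationResult(
        pcc=obs.pcc, slope=obs.slope, intercept=obs.intercept,
        n_pairs=obs.n_pairs, fdr=fdr, n_permutations=int(len(r)),
        null_mean=float(r.mean()), null_sd=float(r.std(ddof=1)) if len(r) > 1 else 0.0,
        roles=(a.role, b.role) if randomize == "first" else (b.role, a.role),
    )


def randomization_decay(
    m: DistanceMatrix,
    reference: DistanceMatrix,
    max_swaps: int = 200,
    reps: int = 20,
    seed: int | np.random.Generator = 0,
):
    """Correlation decay along a cumulative swap chain.

    For each swap count s in 0..max_swaps, the mean (over ``reps``
    independent chains) Pearson correlation between ``reference`` and the
    s-times-swapped ``m`` is recorded.  Structured matrices decay from
    PCC(reference, m) toward the fully-randomized null level within a few
    tens of swaps.

    Returns a dict with keys ``swaps``, ``mean_pcc``, ``se_pcc``.
    """
    a, ref = m.align_with(reference)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v_ref = ref.offdiag()
    curves = np.empty((reps, max_swaps + 1))
    pcc0, _, _ = _pearson_slope(a.offdiag(), v_ref)
    for rep in range(reps):
        curves[rep, 0] = pcc0
        chain = swap_chain(a.n, rng)
        for s in range(1, max_swaps + 1):
            perm, _ = next(chain)
            curves[rep, s] = _batch_pcc(a.values, perm[None, :], v_ref)[0]
    return {
        "swaps": np.arange(max_swaps + 1),
        "mean_pcc": curves.mean(axis=0),
        "se_pcc": curves.std(axis=0, ddof=1) / np.sqrt(reps) if reps > 1 else np.zeros(max_swaps + 1),
    }
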