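"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates the full experimental stack at desk scale:

* nucleus populations — 54 nuclei with 22 autosome pairs by default,
  each chromosome's two homologue centroids jittered around a base
  position inside the unit-radius nucleus.  A tunable coupling places
  chromosomes, sorted by their ground-truth log activity, along a smooth
  curve with a fixed neighbor spacing (``coupling_length``), then blends
  those curve positions with independent uniform positions by weight
  ``coupling_beta``: beta = 0 decouples geometry from activity entirely,
  beta = 1 makes placement fully activity-ordered.
* probe-level expression — log-normal probe intensities around each
  chromosome's activity level, multiple probes per gene and replicate
  arrays, mean-corrected so the expected intensity equals the activity.
* network catalogs — gene sets with a log-uniform size distribution in
  which small networks concentrate on few chromosomes, reproducing the
  empirical size-occupancy law.
* paint phantoms — two-channel voxel stacks with two blobs (homologues)
  per channel and an exhaustively computed ground-truth minimum
  surface-voxel gap for each homologue pairing.

Everything is driven by one integer seed through ``numpy``'s PCG64
generator, so outputs are bit-reproducible.
"""

from __future__ import annotations


import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import cdist

from .activity import ExpressionTable
from .energy import NetworkCatalog
from .geometry import NucleusSet
from .imaging import LabeledStack
from .matrices import GenomeAnnotation

__all__ = [
    "SimulationConfig",
    "generate_nuclei",
    "generate_expression",
    "derive_second_cell_type",
    "generate_networks",
    "generate_study",
    "Sphere",
    "Cuboid",
    "generate_paint_stack",
]

log = logging.getLogger(__name__)

#: human autosome lengths in basepairs (reference assembly, rounded to 0.1 Mb);
#: recycled when more chromosomes are requested than listed
HUMAN_AUTOSOME_BP = (
    247_200_000, 242_700_000, 199_500_000, 191_300_000, 180_900_000,
    170_900_000, 158_800_000, 146_300_000, 140_300_000, 135_400_000,
    134_500_000, 132_300_000, 114_100_000, 106_400_000, 100_300_000,
    88_800_000, 78_800_000, 76_100_000, 63_800_000, 62_400_000,
    46_900_000, 49_700_000,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic pipeline.

    Defaults follow the measured setting the pipeline emulates: 54 nuclei,
    22 autosomes with two homologues each, duplicate arrays with several
    probes per gene, and 87 networks spanning <10 to several hundred
    genes.  ``coupling_beta`` interpolates between activity-independent
    (0) and fully activity-ordered (1) placement; ``coupling_length`` is
    the curve spacing, in nuclear radii, between activity-adjacent
    chromosomes.
    """

    n_nuclei: int = 54
    n_chromosomes: int = 22
    coupling_beta: float = 1.0
    coupling_length: float = 0.07
    jitter_sd: float = 0.05
    activity_log_sd: float = 0.6
    genes_per_chromosome: int | tuple[int, int] = 150
    probes_per_gene: int = 3
    replicate_count: int = 2
    noise_sd: float = 0.3
    intensity_scale: float = 500.0
    housekeeping_fraction: float = 0.3
    n_networks: int = 87
    network_size_range: tuple[int, int] = (5, 300)
    occupancy_target: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_nuclei": self.n_nuclei,
            "n_chromosomes": self.n_chromosomes,
            "probes_per_gene": self.probes_per_gene,
            "replicate_count": self.replicate_count,
            "n_networks": self.n_networks,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.coupling_beta <= 1.0:
            raise ValueError("coupling_beta must lie in [0, 1]")
        if self.coupling_length <= 0:
            raise ValueError("coupling_length must be positive")
        if self.jitter_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.intensity_scale <= 0:
            raise ValueError("intensity_scale must be positive")
        if not 0.0 <= self.housekeeping_fraction < 1.0:
            raise ValueError("housekeeping_fraction must lie in [0, 1)")
        lo, hi = self.network_size_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid network_size_range")
        if not 0.0 < self.occupancy_target <= 1.0:
            raise ValueError("occupancy_target must lie in (0, 1]")

    def chromosome_labels(self) -> tuple[str, ...]:
        return tuple(f"chr{i + 1}" for i in range(self.n_chromosomes))

    def rng(self, stream: int = 0) -> np.random.Generator:
        """Independent child generator; each stage uses its own stream."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


# ------------------------------ nuclei -------------------------------- #


def _uniform_ball(rng: np.random.Generator, n: int, radius: float = 1.0) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    r = radius * rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
    return v * r


def _clip_to_ball(points: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(points, axis=-1, keepdims=True)
    over = norms > 1.0
    return np.where(over, points / np.maximum(norms, 1e-300), points)


def _curve_positions(
    n: int, spacing: float, turn_steps: int = 6, rise_frac: float = 0.4
) -> np.ndarray:
    """n points on a helix with exact chordal ``spacing`` between neighbors.

    The helix winds quickly (``turn_steps`` points per turn with a small
    axial rise), so positions decorrelate from curve order beyond a few
    steps: the position-activity coupling is *short-ranged*, with
    ``spacing`` as its length scale, rather than a global gradient.
    Chordal stepping makes consecutive inter-center distances exactly
    ``spacing``; the chain is centered on the origin.
    """
    dz = rise_frac * spacing
    chord = np.sqrt(spacing**2 - dz**2)
    dtheta = 2.0 * np.pi / turn_steps
    radius = chord / (2.0 * np.sin(dtheta / 2.0))
    k = np.arange(n)
    pts = np.column_stack(
        [radius * np.cos(k * dtheta), radius * np.sin(k * dtheta), k * dz]
    )
    pts -= pts.mean(axis=0)
    if np.linalg.norm(pts, axis=1).max() > 1.0:
        raise ValueError(
            "chromosome chain does not fit inside the nucleus; "
            "reduce coupling_length or n_chromosomes"
        )
    return pts


def generate_nuclei(
    config: SimulationConfig, log_activity: Sequence[float] | None = None
) -> tuple[NucleusSet, dict]:
    """Simulate homologue centroid coordinates for a nucleus population.

    Chromosome base positions are a convex blend (weight
    ``coupling_beta``) of activity-sorted curve positions and independent
    uniform positions in the unit ball; each homologue of each nucleus
    adds isotropic Gaussian jitter (``jitter_sd``) around the base, and
    coordinates are radially clipped to the nucleus.  Returns the
    nucleus set together with ground truth: the per-chromosome log
    activity and base positions.
    """
    if config.n_chromosomes < 2:
        raise ValueError("need at least 2 chromosomes")
    labels = config.chromosome_labels()
    rng = config.rng(stream=1)
    if log_activity is None:
        la = rng.normal(0.0, config.activity_log_sd, size=config.n_chromosomes)
    else:
        la = np.asarray(log_activity, dtype=float)
        if la.shape != (config.n_chromosomes,):
            raise ValueError("log_activity length must equal n_chromosomes")

    order = np.argsort(la)  # activity rank -> chromosome index
    curve = np.empty((config.n_chromosomes, 3))
    curve[order] = _curve_positions(config.n_chromosomes, config.coupling_length)
    uniform = _uniform_ball(rng, config.n_chromosomes)
    base = config.coupling_beta * curve + (1.0 - config.coupling_beta) * uniform
    base = _clip_to_ball(base)

    jitter = rng.normal(
        0.0, config.jitter_sd, size=(config.n_nuclei, config.n_chromosomes, 2, 3)
    ) if config.jitter_sd > 0 else np.zeros(
        (config.n_nuclei, config.n_chromosomes, 2, 3)
    )
    coords = _clip_to_ball(base[None, :, None, :] + jitter)

    records = []
    for n in range(config.n_nuclei):
        for c, label in enumerate(labels):
            for h in (0, 1):
                x, y, z = coords[n, c, h]
                records.append(
                    {
                        "nucleus_id": f"nuc{n + 1:03d}",
                        "chromosome": label,
                        "homologue": h + 1,
                        "x": x,
                        "y": y,
                        "z": z,
                    }
                )
    nuclei = NucleusSet(pd.DataFrame.from_records(records))
    truth = {
        "log_activity": pd.Series(la, index=labels, name="log_activity"),
        "base_positions": pd.DataFrame(base, index=labels, columns=["x", "y", "z"]),
        "curve_positions": pd.DataFrame(curve, index=labels, columns=["x", "y", "z"]),
    }
    return nuclei, truth


# ---------------------------- expression ------------------------------ #


def _genes_per_chromosome(config: SimulationConfig, rng) -> np.ndarray:
    spec = config.genes_per_chromosome
    if isinstance(spec, int):
        if spec < 1:
            raise ValueError("genes_per_chromosome must be >= 1")
        return np.full(config.n_chromosomes, spec, dtype=int)
    lo, hi = spec
    if lo < 1 or hi < lo:
        raise ValueError("invalid genes_per_chromosome range")
    return rng.integers(lo, hi + 1, size=config.n_chromosomes)


def generate_expression(
    config: SimulationConfig, log_activity: Sequence[float]
) -> tuple[ExpressionTable, GenomeAnnotation]:
    """Probe-level log-normal intensities around chromosome activities.

    Each chromosome carries two gene classes, mirroring real
    transcriptomes:

    * housekeeping genes (fraction ``housekeeping_fraction``, ids
      ``hk_*``) expressed at one common level on every chromosome;
    * chromosome-specific genes (ids ``g_*``) whose mean is set so that
      the chromosome's overall mean activity equals exp(log_activity)
      exactly — the activity differences between chromosomes live
      entirely in this class.

    Gene means are log-normal around their class mean and
    probe/replicate intensities log-normal around the gene mean, both
    with scale ``noise_sd`` and mean-corrected (the -sd^2/2 shift) so
    expectations are unbiased; with ``noise_sd = 0`` and
    ``intensity_scale = 1`` the per-chromosome mean activity equals the
    input activity exactly.  ``intensity_scale`` puts intensities on a
    typical raw array scale (hundreds); all log-difference statistics
    are exactly invariant to it.  The matching annotation (every
    generated gene annotated, reference basepair lengths) is returned
    alongside.
    """
    la = np.asarray(log_activity, dtype=float)
    if la.shape != (config.n_chromosomes,):
        raise ValueError("log_activity length must equal n_chromosomes")
    labels = config.chromosome_labels()
    rng = config.rng(stream=2)
    n_genes = _genes_per_chromosome(config, rng)
    sd = config.noise_sd
    f_hk = config.housekeeping_fraction
    a = np.exp(la)
    # common housekeeping level, low enough that every chromosome's
    # specific-gene mean stays positive
    hk_level = 0.5 * a.min()

    n_probes, n_reps = config.probes_per_gene, config.replicate_count
    frames = []
    for c, label in enumerate(labels):
        n_hk = int(round(f_hk * n_genes[c])) if n_genes[c] > 1 else 0
        n_spec = n_genes[c] - n_hk
        # class means average exactly to the chromosome activity
        spec_mean = (n_genes[c] * a[c] - n_hk * hk_level) / n_spec
        class_means = np.concatenate(
            [np.full(n_spec, spec_mean), np.full(n_hk, hk_level)]
        )
        gene_z = rng.normal(size=n_genes[c])
        gene_mean = (
            config.intensity_scale * class_means * np.exp(sd * gene_z - sd**2 / 2.0)
        )
        probe_z = rng.normal(size=(n_genes[c], n_probes, n_reps))
        x = gene_mean[:, None, None] * np.exp(sd * probe_z - sd**2 / 2.0)
        gene_ids = np.array(
            [
                f"{'g' if g < n_spec else 'hk'}_{label}_{g + 1:04d}"
                for g in range(n_genes[c])
            ]
        )
        probe_ids = np.array(
            [f"{gid}_p{p + 1}" for gid in gene_ids for p in range(n_probes)]
        )
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": np.repeat(probe_ids, n_reps),
                    "gene_id": np.repeat(gene_ids, n_probes * n_reps),
                    "chromosome": label,
                    "replicate": np.tile(
                        np.arange(1, n_reps + 1), n_genes[c] * n_probes
                    ),
                    "intensity": x.ravel(),
                }
            )
        )
    table = ExpressionTable(pd.concat(frames, ignore_index=True))
    bp = {
        labels[c]: float(HUMAN_AUTOSOME_BP[c % len(HUMAN_AUTOSOME_BP)])
        for c in range(config.n_chromosomes)
    }
    annotation = GenomeAnnotation(
        basepairs=bp,
        gene_counts={labels[c]: int(n_genes[c]) for c in range(config.n_chromosomes)},
    )
    return table, annotation


def derive_second_cell_type(
    table: ExpressionTable,
    fraction_shifted: float = 0.2,
    log_offset: float = 2.0,
    seed: int = 0,
) -> tuple[ExpressionTable, tuple[str, ...]]:
    """A second cell type: a random gene fraction shifted by ``log_offset``.

    Multiplies every intensity of the chosen genes by exp(log_offset),
    emulating a cell-type-specific expression program; returns the new
    table and the shifted gene ids (ground truth for differential
    selection).
    """
    if not 0.0 < fraction_shifted <= 1.0:
        raise ValueError("fraction_shifted must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    genes = table.table["gene_id"].unique()
    k = max(1, int(round(fraction_shifted * len(genes))))
    shifted = tuple(sorted(rng.choice(genes, size=k, replace=False)))
    df = table.table.copy()
    mask = df["gene_id"].isin(shifted)
    df.loc[mask, "intensity"] *= np.exp(log_offset)
    return ExpressionTable(df, normalized=table.normalized), shifted


# ----------------------------- networks ------------------------------- #


def _occupancy_scale(sizes: np.ndarray, target: float, n_chrom: int) -> float:
    """Size scale s0 such that mean over networks of the expected
    occupancy 1 - exp(-size / s0) hits the target."""
    if target >= 1.0:
        return 1e-9  # everything occupies every chromosome

    def gap(s0: float) -> float:
        return float(np.mean(1.0 - np.exp(-sizes / s0))) - target

    return brentq(gap, 1e-6, 1e7)


def generate_networks(
    config: SimulationConfig,
    gene_catalog: pd.DataFrame,
    chromosome_order: Sequence[str] | None = None,
) -> NetworkCatalog:
    """Gene-set catalog with a controlled size-occupancy relationship.

    Sizes are log-uniform over ``network_size_range``.  Each network is
    assigned a number of occupied chromosomes that grows with its size
    (n_chrom * (1 - exp(-size/s0)), with s0 calibrated so the mean
    occupancy approximates ``occupancy_target``), reproducing the
    exponential size-occupancy law.

    The catalog mirrors the two regulatory regimes of real TF networks:

    * small, cell-type-specific networks (probability exp(-size/s0))
      occupy a *contiguous block* of ``chromosome_order`` (activity-rank
      order) around a random anchor and recruit chromosome-specific
      genes — their target genes co-cluster, so under position-activity
      coupling the occupied chromosomes are also spatially proximate and
      the network tracks local activity;
    * large, housekeeping-like networks occupy chromosomes drawn
      uniformly and preferentially recruit housekeeping genes (ids
      ``hk_*``, expressed at a common level everywhere), so their
      network-matrix column is flat rather than tracking chromosome
      activity.

    Without ``chromosome_order`` every network draws its chromosomes
    uniformly (no spatial clustering); on catalogs without ``hk_`` ids
    the housekeeping preference degrades gracefully to uniform sampling.
    """
    if gene_catalog.empty:
        raise ValueError("empty gene catalog")
    rng = config.rng(stream=3)
    lo, hi = config.network_size_range
    sizes = np.round(
        np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_networks))
    ).astype(int)
    sizes = np.clip(sizes, 1, None)
    chroms = gene_catalog["chromosome"].astype(str).unique()
    if chromosome_order is not None:
        if set(chromosome_order) != set(chroms):
            raise ValueError("chromosome_order must cover the catalog's chromosomes")
        chroms = np.asarray([str(c) for c in chromosome_order])
    s0 = _occupancy_scale(sizes.astype(float), config.occupancy_target, len(chroms))

    catalog = gene_catalog.copy()
    catalog["chromosome"] = catalog["chromosome"].astype(str)
    catalog["_hk"] = catalog["gene_id"].astype(str).str.startswith("hk_")
    by_chrom = {c: grp for c, grp in catalog.groupby("chromosome", sort=False)}

    networks: dict[str, tuple[str, ...]] = {}
    for k, size in enumerate(sizes):
        n_occ = int(
            np.clip(round(len(chroms) * (1.0 - np.exp(-size / s0))), 1, len(chroms))
        )
        clustered = (
            chromosome_order is not None and rng.uniform() < np.exp(-size / s0)
        )
        if clustered:
            anchor = int(rng.integers(len(chroms) - n_occ + 1))
            chosen = chroms[anchor : anchor + n_occ]
            sub = pd.concat([by_chrom[c] for c in chosen])
            specific = sub.loc[~sub["_hk"], "gene_id"].to_numpy()
            pool = specific if len(specific) >= size else sub["gene_id"].to_numpy()
        else:
            chosen = rng.choice(chroms, size=n_occ, replace=False)
            sub = pd.concat([by_chrom[c] for c in chosen])
            hk = sub.loc[sub["_hk"], "gene_id"].to_numpy()
            pool = hk if len(hk) >= size else sub["gene_id"].to_numpy()
        take = min(size, len(pool))
        genes = rng.choice(pool, size=take, replace=False)
        networks[f"net{k + 1:03d}"] = tuple(sorted(genes))
    return NetworkCatalog(
        networks=networks,
        descriptions={name: "synthetic TF network" for name in networks},
    )


# --------------------------- paint phantoms --------------------------- #


@dataclass(frozen=True)
class Sphere:
    """Spherical territory blob; center (z, y, x) and radius in voxels."""

    center: tuple[float, float, float]
    radius: float


@dataclass(frozen=True)
class Cuboid:
    """Axis-aligned blob; inclusive voxel bounds lo/hi as (z, y, x)."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]


def _blob_mask(blob, shape: tuple[int, int, int]) -> np.ndarray:
    if isinstance(blob, Sphere):
        zc, yc, xc = blob.center
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        mask = (zz - zc) ** 2 + (yy - yc) ** 2 + (xx - xc) ** 2 <= blob.radius**2
        lo = [c - blob.radius for c in blob.center]
        hi = [c + blob.radius for c in blob.center]
    else:
        if any(l > h for l, h in zip(blob.lo, blob.hi)):
            raise ValueError("cuboid lo exceeds hi")
        mask = np.zeros(shape, dtype=bool)
        mask[
            blob.lo[0] : blob.hi[0] + 1,
            blob.lo[1] : blob.hi[1] + 1,
            blob.lo[2] : blob.hi[2] + 1,
        ] = True
        lo, hi = blob.lo, blob.hi
    if any(l < 0 for l in lo) or any(h > s - 1 for h, s in zip(hi, shape)):
        raise ValueError(f"blob {blob} extends outside the stack bounds {shape}")
    if not mask.any():
        raise ValueError(f"blob {blob} rasterizes to no voxels")
    return mask


def _surface_voxels(mask: np.ndarray, spacing) -> np.ndarray:
    """3D boundary voxels (6-connectivity) in physical (x, y, z) microns."""
    from scipy import ndimage

    interior = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    zz, yy, xx = np.nonzero(mask & ~interior)
    dx, dy, dz = spacing
    return np.column_stack([xx * dx, yy * dy, zz * dz])


def generate_paint_stack(
    channels: dict[str, Sequence],
    shape: tuple[int, int, int] = (64, 64, 64),
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2),
    seed: int = 0,
    background: tuple[float, float] = (8.0, 12.0),
    foreground: tuple[float, float] = (100.0, 110.0),
) -> tuple[LabeledStack, dict]:
    """Two-channel phantom stack with known inter-territory gaps.

    ``channels`` maps each of two chromosome labels to its two homologue
    blobs (Sphere or Cuboid, voxel coordinates).  Background intensity
    is uniform in ``background`` and blob voxels uniform in
    ``foreground`` — bounded noise, so the mean+SD threshold always
    separates the classes.  For every cross-channel homologue pairing
    the ground truth (``distances_um``) is the exhaustive all-pairs
    minimum distance between the blobs' per-slice 2D edge voxels — the
    quantity the edge-based measurement estimates — computed from the
    known masks by brute force; ``surface_gap_um`` additionally reports
    the minimum over full 3D surface voxels (which can be smaller near
    blob caps, where a z-section has no in-plane edge).  Overlapping
    blobs give zero.  All distances in microns.
    """
    if len(channels) != 2:
        raise ValueError("need exactly two channels")
    for name, blobs in channels.items():
        if len(blobs) != 2:
            raise ValueError(f"channel {name!r} needs exactly two homologue blobs")
    rng = np.random.default_rng(seed)
    arrays: dict[str, np.ndarray] = {}
    masks: dict[str, list[np.ndarray]] = {}
    for name, blobs in channels.items():
        stack = rng.uniform(*background, size=shape)
        masks[name] = []
        for blob in blobs:
            mask = _blob_mask(blob, shape)
            stack[mask] = rng.uniform(*foreground, size=int(mask.sum()))
            masks[name].append(mask)
        arrays[name] = stack

    from .imaging import extract_edges

    def _min_dist(pts_a: np.ndarray, pts_b: np.ndarray) -> float:
        best = np.inf
        for start in range(0, len(pts_a), 2048):
            best = min(best, float(cdist(pts_a[start : start + 2048], pts_b).min()))
        return best

    name_a, name_b = channels
    truth: dict[str, float] = {}
    surface: dict[str, float] = {}
    for a in range(2):
        edge_a = extract_edges(masks[name_a][a], spacing)
        surf_a = _surface_voxels(masks[name_a][a], spacing)
        for b in range(2):
            key = f"{a + 1}-{b + 1}"
            if (masks[name_a][a] & masks[name_b][b]).any():
                truth[key] = surface[key] = 0.0
                continue
            truth[key] = _min_dist(edge_a, extract_edges(masks[name_b][b], spacing))
            surface[key] = _min_dist(surf_a, _surface_voxels(masks[name_b][b], spacing))
    ground_truth = {
        "pair": list(channels),
        "distances_um": truth,
        "surface_gap_um": surface,
        "spacing_um": list(spacing),
    }
    return LabeledStack(channels=arrays, spacing=spacing), ground_truth


# ----------------------------- study bundle --------------------------- #


def generate_study(config: SimulationConfig) -> dict:
    """One coherent synthetic study: nuclei, expression, catalog, matrices.

    Runs the full generative chain with consistent seeds and returns a
    dict with the pieces every analysis needs: ``nuclei``, ``truth``,
    ``expression``, ``annotation``, ``genes`` (array-mean normalized per-
    gene activities, for IAD work), ``genes_raw`` (raw-scale activities,
    for the network matrix), ``catalog`` (networks clustered in activity-
    rank order), ``phi``, and ``ipd`` (mean mode).
    """
    from .activity import aggregate_probes, normalize_to_array_mean
    from .energy import build_network_matrix
    from .geometry import compute_ipd

    nuclei, truth = generate_nuclei(config)
    expr, annotation = generate_expression(config, truth["log_activity"].to_numpy())
    genes = aggregate_probes(normalize_to_array_mean(expr))
    genes_raw = aggregate_probes(expr, require_normalized=False)
    order = list(truth["log_activity"].sort_values().index)
    catalog = generate_networks(
        config, genes[["gene_id", "chromosome", "activity"]], chromosome_order=order
    )
    phi = build_network_matrix(
        genes_raw, catalog, chromosomes=config.chromosome_labels()
    )
    return {
        "config": config,
        "nuclei": nuclei,
        "truth": truth,
        "expression": expr,
        "annotation": annotation,
        "genes": genes,
        "genes_raw": genes_raw,
        "catalog": catalog,
        "phi": phi,
        "ipd": compute_ipd(nuclei, "mean"),
    }
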