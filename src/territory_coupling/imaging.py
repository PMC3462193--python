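"""Interface distances between painted chromosome territories.

The confocal pipeline mirrors the classic chromosome-paint measurement:
each channel's z-stack is binarized at a single global threshold of
mean + SD of the stack intensity, the two largest 3D-connected
components are taken as the two homologues, per-slice 2D edges are
extracted from each component, and the interface distance between two
territories is the minimum 3D Euclidean distance over all pairs of edge
voxels (anisotropic voxel spacing applied before the distance).  With
two chromosomes painted per nucleus there are four homologue pairings;
both their mean and their minimum are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = [
    "LabeledStack",
    "InterfaceResult",
    "threshold_stack",
    "split_homologues",
    "extract_edges",
    "interface_distance",
    "brute_force_interface_distance",
    "pair_ipd",
    "read_stack",
    "write_stack",
]

log = logging.getLogger(__name__)

#: in-plane 4-connectivity used to define 2D edges
_CROSS_2D = ndimage.generate_binary_structure(2, 1)
#: 26-connectivity for 3D component labeling
_FULL_3D = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class LabeledStack:
    """Two-channel confocal z-stack with physical voxel spacing.

    ``channels`` maps a chromosome label to a (z, y, x) intensity array;
    ``spacing`` is (dx, dy, dz) in microns.
    """

    channels: dict[str, np.ndarray]
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        shapes = {a.shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("channels have differing shapes")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        for name, arr in self.channels.items():
            if arr.ndim != 3:
                raise ValueError(f"channel {name!r} is not a z-stack")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.channels)


@dataclass(frozen=True)
class InterfaceResult:
    """Four homologue-pairing interface distances for one chromosome pair."""

    pair: tuple[str, str]
    distances: dict[tuple[int, int], float]
    voxel_counts: dict[str, tuple[int, int]]

    @property
    def mean(self) -> float:
        return float(np.mean(list(self.distances.values())))

    @property
    def min(self) -> float:
        return float(np.min(list(self.distances.values())))

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "distances_um": {f"{a + 1}-{b + 1}": d for (a, b), d in self.distances.items()},
            "mean_um": self.mean,
            "min_um": self.min,
            "voxel_counts": {k: list(v) for k, v in self.voxel_counts.items()},
        }


def threshold_stack(channel: np.ndarray) -> np.ndarray:
    """Binarize at mean + SD of the whole z-stack (one global threshold)."""
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty stack")
    sd = channel.std()
    if sd == 0:
        raise ValueError("constant-intensity stack — nothing to threshold")
    return channel > (channel.mean() + sd)


def split_homologues(
    mask: np.ndarray, min_size: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Two largest 26-connected components of a binary mask.

    Components below ``min_size`` voxels are treated as noise and
    dropped (logged); fewer than two surviving components is an error.
    """
    labeled, n = ndimage.label(mask, structure=_FULL_3D)
    if n == 0:
        raise ValueError("no foreground components")
    sizes = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1]
    big = [int(order[k]) + 1 for k in range(len(order)) if sizes[order[k]] >= min_size]
    dropped = n - len(big)
    if dropped:
        log.info("dropped %d components below %d voxels", dropped, min_size)
    if len(big) < 2:
        raise ValueError(
            f"only {len(big)} component(s) of >= {min_size} voxels; "
            "expected two homologue territories"
        )
    return labeled == big[0], labeled == big[1]


def extract_edges(
    component: np.ndarray, spacing: tuple[float, float, float]
) -> np.ndarray:
    """Per-slice 2D boundary voxels of a component, in physical microns.

    A voxel is an edge voxel if it is foreground and has at least one
    in-plane (4-neighbor) background neighbor in its z-section; slices
    are processed independently and the union returned as an (n, 3)
    array of (x, y, z) coordinates scaled by the voxel spacing.
    """
    component = np.asarray(component, dtype=bool)
    if not component.any():
        raise ValueError("empty component")
    dx, dy, dz = spacing
    coords = []
    for z in range(component.shape[0]):
        sec = component[z]
        if not sec.any():
            continue
        interior = ndimage.binary_erosion(sec, structure=_CROSS_2D, border_value=0)
        yy, xx = np.nonzero(sec & ~interior)
        if len(xx):
            coords.append(
                np.column_stack([xx * dx, yy * dy, np.full(len(xx), z * dz)])
            )
    return np.concatenate(coords, axis=0)


def interface_distance(edges_a: np.ndarray, edges_b: np.ndarray) -> float:
    """Minimum 3D distance between two edge-coordinate sets (microns).

    Accelerated with a KD-tree; agrees exactly with the all-pairs brute
    force since both evaluate the same Euclidean norm.
    """
    if len(edges_a) == 0 or len(edges_b) == 0:
        raise ValueError("empty edge list")
    tree = cKDTree(edges_b)
    d, _ = tree.query(edges_a, k=1)
    return float(d.min())


def brute_force_interface_distance(edges_a: np.ndarray, edges_b: np.ndarray) -> float:
    """Exhaustive all-pairs minimum distance — the reference oracle."""
    if len(edges_a) == 0 or len(edges_b) == 0:
        raise ValueError("empty edge list")
    best = np.inf
    # chunk rows to bound memory on large edge sets
    for start in range(0, len(edges_a), 2048):
        block = cdist(edges_a[start : start + 2048], edges_b)
        best = min(best, float(block.min()))
    return best


def pair_ipd(stack: LabeledStack, min_size: int = 5) -> InterfaceResult:
    """All four homologue-pairing interface distances for a stack.

    Both channels are thresholded and split into their two homologue
    components; the 2x2 cross-channel pairings are measured and the mean
    and minimum reported.  (Which aggregate serves as the IPD entry is a
    caller decision; both are carried.)
    """
    if len(stack.labels) != 2:
        raise ValueError("need exactly two channels")
    name_a, name_b = stack.labels
    comps = {}
    for name in stack.labels:
        try:
            mask = threshold_stack(stack.channels[name])
            comps[name] = split_homologues(mask, min_size=min_size)
        except ValueError as err:
            raise ValueError(f"channel {name!r}: {err}") from err
    edges = {
        name: [extract_edges(c, stack.spacing) for c in comps[name]]
        for name in stack.labels
    }
    distances = {
        (a, b): interface_distance(edges[name_a][a], edges[name_b][b])
        for a in range(2)
        for b in range(2)
    }
    counts = {
        name: (int(comps[name][0].sum()), int(comps[name][1].sum()))
        for name in stack.labels
    }
    return InterfaceResult(pair=(name_a, name_b), distances=distances, voxel_counts=counts)


# ------------------------------- io ----------------------------------- #


def write_stack(stack: LabeledStack, directory: str | Path) -> dict[str, Path]:
    """Write each channel as a multi-page TIFF; returns the paths."""
    import tifffile

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in stack.channels.items():
        path = directory / f"{name}.tif"
        tifffile.imwrite(path, arr.astype(np.float32))
        paths[name] = path
    return paths


def read_stack(
    paths: dict[str, str | Path], spacing: tuple[float, float, float]
) -> LabeledStack:
    """Read one multi-page TIFF per channel into a LabeledStack."""
    import tifffile

    channels = {name: tifffile.imread(p) for name, p in paths.items()}
    return LabeledStack(channels=channels, spacing=spacing)
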