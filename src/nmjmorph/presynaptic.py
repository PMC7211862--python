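"""Nerve-terminal (pre-synaptic) measures: area, perimeter, axon handling,
skeleton branch statistics and the composite complexity score."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import polygon2mask
from skimage.measure import perimeter as _sk_perimeter
from skimage.morphology import skeletonize as _sk_skeletonize

from .binary_ops import S8, BinaryMask
from .errors import EmptyMaskError


@dataclass(frozen=True)
class SkeletonStats:
    """Branch statistics of a 1-px skeleton.

    ``complexity`` is ``None`` (missing) whenever any contributing factor is
    zero — a degenerate terminal is flagged rather than scored −∞.
    """

    n_terminal_branches: int
    n_branch_points: int
    n_end_points: int = 0
    total_branch_length_um: float = 0.0
    average_branch_length_um: float = 0.0
    complexity: Optional[float] = None


@dataclass(frozen=True)
class AxonInput:
    """User-supplied axon annotations: a diameter line and an erase polygon.

    Coordinates are (row, col) pixels, 0-based. The erase polygon is applied
    after the diameter has been measured, mirroring the retained manual
    measure-then-erase step.
    """

    line_endpoints: tuple[tuple[float, float], tuple[float, float]]
    erase_region: Optional[Sequence[tuple[float, float]]] = None

    def __post_init__(self) -> None:
        (r0, c0), (r1, c1) = self.line_endpoints
        if (r0, c0) == (r1, c1):
            raise ValueError("axon line endpoints must be distinct")
        if self.erase_region is not None and len(self.erase_region) < 3:
            raise ValueError("erase polygon requires at least 3 vertices")


def measure_region(mask: BinaryMask) -> tuple[float, float]:
    """Area (µm²) and perimeter (µm) of all foreground particles.

    Area is the foreground pixel count × calibration². Perimeter follows the
    through-pixel-centre contour convention (a 10×10 px square measures 36 px
    of boundary), summed over outer and hole contours of every particle.
    """
    if mask.is_empty():
        raise EmptyMaskError("measure_region requires a non-empty mask")
    area = mask.area_um2
    perim = float(_sk_perimeter(mask.pixels, neighborhood=4))
    return area, perim * mask.calibration_um_per_px


def erase_axon(nerve_mask: BinaryMask, axon: AxonInput) -> BinaryMask:
    """Remove foreground inside the axon erase polygon; no-op without one."""
    if axon.erase_region is None:
        return nerve_mask
    verts = np.asarray(axon.erase_region, dtype=float)
    if (verts < -0.5).any() or (verts[:, 0] > nerve_mask.pixels.shape[0] - 0.5).any() or (
        verts[:, 1] > nerve_mask.pixels.shape[1] - 0.5
    ).any():
        raise ValueError("erase polygon extends outside the image bounds")
    region = polygon2mask(nerve_mask.pixels.shape, verts)
    return BinaryMask(nerve_mask.pixels & ~region, nerve_mask.calibration_um_per_px)


def axon_diameter(axon: AxonInput, calibration_um_per_px: float) -> float:
    """Euclidean length of the axon diameter line, in µm."""
    (r0, c0), (r1, c1) = axon.line_endpoints
    return math.hypot(r1 - r0, c1 - c0) * calibration_um_per_px


def skeletonize(mask: BinaryMask) -> BinaryMask:
    """Topology-preserving 1-px medial skeleton (standard thinning)."""
    if mask.is_empty():
        raise EmptyMaskError("skeletonize requires a non-empty mask")
    return BinaryMask(_sk_skeletonize(mask.pixels), mask.calibration_um_per_px)


def _neighbor_counts(skel: np.ndarray) -> np.ndarray:
    """Skeleton-pixel degree under corner-pruned 8-adjacency.

    Orthogonal neighbours always count; a diagonal neighbour counts only when
    neither mediating orthogonal pixel is in the skeleton (otherwise the
    L-corner would be double-counted — e.g. the arm tips of a 5-px plus sign
    must read as degree-1 end points, not degree-3 junctions).
    """
    p = np.pad(skel.astype(bool), 1)
    deg = np.zeros(p.shape, dtype=np.uint8)
    orth = ((0, 1), (0, -1), (1, 0), (-1, 0))
    for dr, dc in orth:
        deg += p & np.roll(p, (-dr, -dc), axis=(0, 1))
    for dr, dc in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        q = np.roll(p, (-dr, -dc), axis=(0, 1))
        med1 = np.roll(p, (-dr, 0), axis=(0, 1))
        med2 = np.roll(p, (0, -dc), axis=(0, 1))
        deg += p & q & ~med1 & ~med2
    return deg[1:-1, 1:-1].astype(np.int64)


def _count_segments(segments: np.ndarray, skeleton: np.ndarray) -> int:
    """Connected segments under corner-pruned 8-adjacency.

    Two segment pixels are adjacent orthogonally, or diagonally only when
    neither mediating orthogonal pixel belongs to the skeleton. The pruning
    stops arms from reconnecting *around* a deleted branch-point pixel (e.g.
    the four arms of a plus sign stay four separate segments).
    """
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    idx = np.full(segments.shape, -1, dtype=np.int64)
    rows, cols = np.nonzero(segments)
    n = rows.size
    if n == 0:
        return 0
    idx[rows, cols] = np.arange(n)
    edges_i: list[np.ndarray] = []
    edges_j: list[np.ndarray] = []

    def link(sel: np.ndarray, dr: int, dc: int) -> None:
        r, c = np.nonzero(sel)
        edges_i.append(idx[r, c])
        edges_j.append(idx[r + dr, c + dc])

    p = segments
    link(p[:-1, :] & p[1:, :], 1, 0)
    link(p[:, :-1] & p[:, 1:], 0, 1)
    s = skeleton
    dr_ok = p[:-1, :-1] & p[1:, 1:] & ~s[:-1, 1:] & ~s[1:, :-1]
    dl_ok = p[:-1, 1:] & p[1:, :-1] & ~s[:-1, :-1] & ~s[1:, 1:]
    r, c = np.nonzero(dr_ok)
    edges_i.append(idx[r, c])
    edges_j.append(idx[r + 1, c + 1])
    r, c = np.nonzero(dl_ok)
    edges_i.append(idx[r, c + 1])
    edges_j.append(idx[r + 1, c])

    i = np.concatenate(edges_i) if edges_i else np.empty(0, dtype=np.int64)
    j = np.concatenate(edges_j) if edges_j else np.empty(0, dtype=np.int64)
    graph = coo_matrix((np.ones(i.size), (i, j)), shape=(n, n))
    n_comp, _ = connected_components(graph, directed=False)
    return int(n_comp)


def classify_skeleton(skel: BinaryMask) -> SkeletonStats:
    """Count end points, branch points and terminal branches of a skeleton.

    Each skeleton pixel is classified by its number of 8-neighbours within
    the skeleton: 1 → end point, ≥3 → branch-point pixel. Adjacent
    branch-point pixels (thinning artifacts at junctions) are merged into a
    single branch point. Terminal branches are the segments that remain
    after deleting all branch-point pixels, counted under corner-pruned
    8-adjacency (see :func:`_count_segments`).
    """
    px = skel.pixels
    counts = _neighbor_counts(px)
    end_points = px & (counts == 1)
    branch_px = px & (counts >= 3)
    _, n_branch_points = ndi.label(branch_px, structure=S8)
    segments = px & ~branch_px
    n_branches = _count_segments(segments, px)
    return SkeletonStats(
        n_terminal_branches=int(n_branches),
        n_branch_points=int(n_branch_points),
        n_end_points=int(np.count_nonzero(end_points)),
    )


def _chamfer_length_px(px: np.ndarray, context: np.ndarray | None = None) -> float:
    """Sum of 8-connected steps: 1 per orthogonal pair, √2 per diagonal pair.

    A diagonal adjacency is skipped when either of its two orthogonal
    mediating pixels is foreground (the corner would otherwise be counted
    twice along an L-turn). ``context`` supplies the foreground used for the
    mediator check when measuring a subset of a larger skeleton.
    """
    p = px.astype(bool)
    s = p if context is None else context.astype(bool)
    n_orth = int(np.count_nonzero(p[:-1, :] & p[1:, :])) + int(
        np.count_nonzero(p[:, :-1] & p[:, 1:])
    )
    # down-right diagonals: mediators are right-of-p and below-p
    dr = p[:-1, :-1] & p[1:, 1:] & ~s[:-1, 1:] & ~s[1:, :-1]
    # down-left diagonals
    dl = p[:-1, 1:] & p[1:, :-1] & ~s[:-1, :-1] & ~s[1:, 1:]
    n_diag = int(np.count_nonzero(dr)) + int(np.count_nonzero(dl))
    return n_orth + math.sqrt(2.0) * n_diag


def branch_lengths(
    skel: BinaryMask,
    n_terminal_branches: int | None = None,
    imagej_parity: bool = False,
) -> tuple[float, float]:
    """Total and average branch length of a skeleton, in µm.

    The default length is the calibrated chamfer sum over skeleton steps
    (1 orthogonal, √2 diagonal); ``imagej_parity`` substitutes the calibrated
    pixel count. The average divides the total by the number of terminal
    branches (zero branches → average 0).
    """
    if n_terminal_branches is None:
        n_terminal_branches = classify_skeleton(skel).n_terminal_branches
    if imagej_parity:
        total = skel.area_px * skel.calibration_um_per_px
    else:
        total = _chamfer_length_px(skel.pixels) * skel.calibration_um_per_px
    average = total / n_terminal_branches if n_terminal_branches > 0 else 0.0
    return total, average


def complexity(
    n_terminal_branches: int, n_branch_points: int, total_branch_length_um: float
) -> Optional[float]:
    """Composite arborisation score.

    ``log10(branches × branch points × total length / 100)``; missing when
    any factor is zero (logarithm undefined).
    """
    product = n_terminal_branches * n_branch_points * total_branch_length_um
    if product <= 0:
        return None
    return math.log10(product / 100.0)


def skeleton_stats(
    mask: BinaryMask, imagej_parity: bool = False
) -> SkeletonStats:
    """Skeletonize a nerve-terminal mask and compute the full branch record."""
    skel = skeletonize(mask)
    counts = classify_skeleton(skel)
    total, average = branch_lengths(
        skel, counts.n_terminal_branches, imagej_parity=imagej_parity
    )
    return SkeletonStats(
        n_terminal_branches=counts.n_terminal_branches,
        n_branch_points=counts.n_branch_points,
        n_end_points=counts.n_end_points,
        total_branch_length_um=total,
        average_branch_length_um=average,
        complexity=complexity(
            counts.n_terminal_branches, counts.n_branch_points, total
        ),
    )
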