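"""AChR / endplate (post-synaptic) measures: cluster counting with enclosure
handling, Feret (maximum caliper) diameter, compactness, fragmentation and
synaptic overlap."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull

from .binary_ops import (
    S4,
    BinaryMask,
    LabelImage,
    SegmentationQC,
    particles_in_footprint,
)
from .errors import EmptyMaskError
from .presynaptic import measure_region


@dataclass(frozen=True)
class ClusterStats:
    """AChR cluster record; all fields missing together when segmentation is
    aberrant (or the endplate is empty)."""

    n_clusters: Optional[int]
    average_cluster_area_um2: Optional[float]
    fragmentation: Optional[float]
    note: str = ""

    @property
    def missing(self) -> bool:
        return self.n_clusters is None


def count_clusters(
    achr_labels: LabelImage,
    achr_mask: BinaryMask,
    footprint: BinaryMask,
    qc: SegmentationQC | None = None,
    containment: str = "centroid",
) -> ClusterStats:
    """Count AChR clusters within the endplate footprint.

    Each watershed particle is hole-filled individually and the filled
    particles are recombined onto the footprint; a particle lying entirely
    inside a hole of another (an enclosed cluster) is absorbed by its host
    and not counted separately. Particles outside the footprint are
    extraneous and excluded. The average cluster area divides the total AChR
    area by the cluster count, so ``average × n == AChR area`` exactly;
    fragmentation is ``1 − 1/n``.
    """
    if qc is not None and qc.aberrant:
        return ClusterStats(None, None, None, note=f"aberrant segmentation: {qc.reason}")

    lab = achr_labels.labels
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        return ClusterStats(None, None, None, note="no particles")

    # Union of every particle's interior holes, built per particle so that
    # watershed neighbours do not spuriously close each other's gaps.
    holes = np.zeros(lab.shape, dtype=bool)
    slices = ndi.find_objects(lab)
    for i in ids:
        sl = slices[i - 1]
        part = lab[sl] == i
        filled = ndi.binary_fill_holes(part, structure=S4)
        holes[sl] |= filled & ~part
    absorbed = {
        int(i)
        for i, sl in ((i, slices[i - 1]) for i in ids)
        if bool(np.all(holes[sl][lab[sl] == i]))
    }

    survivors = [i for i in particles_in_footprint(achr_labels, footprint, containment)
                 if i not in absorbed]
    n = len(survivors)
    if n == 0:
        return ClusterStats(None, None, None, note="no clusters within footprint")
    area = achr_mask.area_um2
    return ClusterStats(
        n_clusters=n,
        average_cluster_area_um2=area / n,
        fragmentation=1.0 - 1.0 / n,
    )


def _pixel_corners(pixels: np.ndarray) -> np.ndarray:
    """Corner coordinates of all foreground pixels (unit-square pixel model)."""
    rows, cols = np.nonzero(pixels)
    pts = np.concatenate(
        [
            np.stack([rows + dr, cols + dc], axis=1)
            for dr in (0, 1)
            for dc in (0, 1)
        ]
    )
    return np.unique(pts, axis=0).astype(float)


def feret_diameter(mask: BinaryMask) -> float:
    """Maximum caliper distance across the region, in µm.

    Computed over the convex hull of the foreground pixel *corner*
    coordinates, for parity with ImageJ's Feret on pixel selections: a single
    pixel measures √2 × calibration.
    """
    if mask.is_empty():
        raise EmptyMaskError("feret_diameter requires a non-empty mask")
    corners = _pixel_corners(mask.pixels)
    hull_pts = corners[ConvexHull(corners).vertices]
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    return float(dist.max()) * mask.calibration_um_per_px


def endplate_measures(footprint: BinaryMask) -> tuple[float, float, float]:
    """Endplate area (µm²), perimeter (µm) and Feret diameter (µm)."""
    area, perim = measure_region(footprint)
    return area, perim, feret_diameter(footprint)


def compactness(achr_area_um2: float, endplate_area_um2: float) -> float:
    """AChR area as a percentage of endplate area; (0, 100] for footprint ⊇ mask."""
    if achr_area_um2 <= 0:
        raise EmptyMaskError("compactness undefined without receptor signal")
    if endplate_area_um2 <= 0:
        raise ValueError("endplate area must be positive")
    return achr_area_um2 / endplate_area_um2 * 100.0


def synaptic_contact(
    nerve_mask: BinaryMask, achr_mask: BinaryMask
) -> tuple[float, float]:
    """Area of synaptic contact (nerve ∩ AChR, µm²) and overlap (% of AChR area)."""
    if nerve_mask.pixels.shape != achr_mask.pixels.shape:
        raise ValueError("masks must share the same shape")
    if nerve_mask.calibration_um_per_px != achr_mask.calibration_um_per_px:
        raise ValueError("masks must share the same calibration")
    achr_area = achr_mask.area_um2
    if achr_area <= 0:
        raise EmptyMaskError("overlap undefined for an empty AChR mask")
    contact = (
        int(np.count_nonzero(nerve_mask.pixels & achr_mask.pixels))
        * nerve_mask.calibration_um_per_px**2
    )
    return contact, contact / achr_area * 100.0
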