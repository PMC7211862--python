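"""Shared binary machinery: thresholding, hole filling, watershed splitting,
endplate-footprint construction and segmentation QC.

Connectivity convention: 8-connectivity for foreground particles,
4-connectivity for background hole detection (the standard dual pair, so
holes cannot leak out through diagonal gaps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk, local_maxima
from skimage.segmentation import watershed

from .errors import EmptyMaskError
from .image_io import CalibratedImage

#: 3x3 structuring element for 8-connected labelling.
S8 = np.ones((3, 3), dtype=int)
#: Cross structuring element for 4-connected background operations.
S4 = ndi.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class BinaryMask:
    """A boolean foreground map sharing the source image's calibration."""

    pixels: np.ndarray
    calibration_um_per_px: float

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2 or p.dtype != bool:
            raise ValueError("BinaryMask requires a 2-D boolean array")
        if not self.calibration_um_per_px > 0:
            raise ValueError("calibration must be positive")

    @property
    def area_px(self) -> int:
        return int(np.count_nonzero(self.pixels))

    @property
    def area_um2(self) -> float:
        return self.area_px * self.calibration_um_per_px**2

    def is_empty(self) -> bool:
        return not self.pixels.any()


@dataclass(frozen=True)
class ThresholdRecord:
    """Provenance of a thresholding step: method and the value actually applied."""

    method: str
    lower_value: float
    channel_role: str = ""
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class LabelImage:
    """Integer particle labels (0 = background, particles numbered 1..K)."""

    labels: np.ndarray
    calibration_um_per_px: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2 or not np.issubdtype(lab.dtype, np.integer):
            raise ValueError("LabelImage requires a 2-D integer array")
        if lab.min() < 0:
            raise ValueError("labels must be non-negative")

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    def mask(self) -> BinaryMask:
        return BinaryMask(self.labels > 0, self.calibration_um_per_px)


@dataclass(frozen=True)
class SegmentationQC:
    aberrant: bool
    reason: str
    particle_count: int
    median_particle_area_um2: float

    def __post_init__(self) -> None:
        if self.aberrant and not self.reason:
            raise ValueError("aberrant QC requires a reason")


def otsu_threshold(pixels: np.ndarray) -> float:
    """Otsu's threshold under the foreground = ``intensity >= t`` convention.

    Maximises the between-class variance over every distinct intensity as a
    candidate lower bound. Exact (no histogram binning), so it agrees with a
    brute-force scan by construction.
    """
    values, counts = np.unique(np.asarray(pixels).ravel(), return_counts=True)
    if values.size < 2:
        return float(values[0])
    n = counts.sum()
    # For candidate t = values[i], the low class is values[:i] (strictly below t).
    w_low = np.cumsum(counts)[:-1]  # class sizes for t = values[1:]
    sum_low = np.cumsum(values * counts)[:-1]
    w_high = n - w_low
    total = float((values * counts).sum())
    mu_low = sum_low / w_low
    mu_high = (total - sum_low) / w_high
    between = w_low * w_high * (mu_low - mu_high) ** 2
    return float(values[1:][np.argmax(between)])


def threshold_mask(
    image: CalibratedImage,
    method: str = "manual",
    manual_value: Optional[float] = None,
    channel_role: str | None = None,
) -> tuple[BinaryMask, ThresholdRecord]:
    """Threshold an image into foreground (``intensity >= lower_value``).

    Empty or full-frame foreground attaches a QC warning to the record; it
    is deliberately not fatal so a batch run can continue and flag the image.
    """
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual thresholding requires manual_value")
        value = float(manual_value)
    elif method == "otsu":
        value = otsu_threshold(image.pixels)
    else:
        raise ValueError(f"unknown threshold method {method!r}")

    fg = np.asarray(image.pixels) >= value
    warnings: list[str] = []
    if not fg.any():
        warnings.append("empty foreground after thresholding")
    elif fg.all():
        warnings.append("full-frame foreground after thresholding")
    record = ThresholdRecord(
        method=method,
        lower_value=value,
        channel_role=channel_role or image.channel_role,
        warnings=tuple(warnings),
    )
    return BinaryMask(fg, image.calibration_um_per_px), record


def fill_holes(mask: BinaryMask) -> BinaryMask:
    """Fill every background region not 4-connected to the image border."""
    filled = ndi.binary_fill_holes(mask.pixels, structure=S4)
    return BinaryMask(filled, mask.calibration_um_per_px)


def _merge_markers_by_distance(markers: np.ndarray, min_sep: float) -> np.ndarray:
    """Union markers whose centroids are closer than ``min_sep`` pixels."""
    ids = np.unique(markers)
    ids = ids[ids > 0]
    if ids.size < 2:
        return markers
    cents = np.array(ndi.center_of_mass(markers > 0, markers, ids))
    parent = {int(i): int(i) for i in ids}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.hypot(*(cents[i] - cents[j])) < min_sep:
                parent[find(int(ids[j]))] = find(int(ids[i]))
    out = markers.copy()
    for i in ids:
        out[markers == i] = find(int(i))
    return out


def _component_markers(edt: np.ndarray, comp: np.ndarray, tolerance: float) -> np.ndarray:
    """Tolerance-merged regional maxima of the EDT within one component.

    A maximum is merged into a higher (already-seeded) one when the two are
    connected within the superlevel set ``edt >= value - tolerance`` — the
    behaviour of ImageJ's maxima finding, which keeps near-flat ridges (e.g.
    the crest of an annulus) as a single seed instead of shattering them.
    """
    lm, n_max = ndi.label(local_maxima(edt, connectivity=2) & comp, structure=S8)
    markers = np.zeros(edt.shape, dtype=np.int32)
    if n_max == 0:
        markers[comp] = 1
        return markers
    if n_max == 1:
        markers[lm == 1] = 1
        return markers
    vals = ndi.maximum(edt, lm, index=np.arange(1, n_max + 1))
    next_id = 0
    for idx in np.argsort(-vals, kind="stable"):
        mid = idx + 1
        sup, _ = ndi.label((edt >= vals[idx] - tolerance) & comp, structure=S8)
        seed_px = tuple(np.argwhere(lm == mid)[0])
        region = sup == sup[seed_px]
        prev = np.unique(markers[region])
        prev = prev[prev > 0]
        if prev.size:
            markers[lm == mid] = prev[0]
        else:
            next_id += 1
            markers[lm == mid] = next_id
    return markers


def watershed_split(
    mask: BinaryMask,
    min_seed_separation_px: float = 3.0,
    seed_tolerance: float = 1.0,
) -> LabelImage:
    """Split touching blobs along Euclidean-distance-transform ridge lines.

    Seeds are regional maxima of the EDT, merged under ``seed_tolerance``
    (ridge depth) and ``min_seed_separation_px`` (centroid distance), then
    flooded with a marker-controlled watershed restricted to the mask. Every
    connected component receives at least one label; the union of all labels
    equals the input foreground; labels are consecutive ``1..K``.
    """
    if mask.is_empty():
        raise EmptyMaskError("watershed_split requires a non-empty mask")
    comps, n_comp = ndi.label(mask.pixels, structure=S8)
    edt = ndi.distance_transform_edt(mask.pixels)
    out = np.zeros(mask.pixels.shape, dtype=np.int32)
    next_label = 0
    slices = ndi.find_objects(comps)
    for ci, sl in enumerate(slices, start=1):
        # Pad the crop by 1 px so EDT superlevel sets are not clipped.
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, dim))
            for s, dim in zip(sl, mask.pixels.shape)
        )
        comp = comps[sl] == ci
        sub_edt = np.where(comp, edt[sl], 0.0)
        markers = _component_markers(sub_edt, comp, seed_tolerance)
        if min_seed_separation_px > 0:
            markers = _merge_markers_by_distance(markers, min_seed_separation_px)
        ws = watershed(-sub_edt, markers, mask=comp, connectivity=2)
        ids = np.unique(ws)
        ids = ids[ids > 0]
        remap = {int(v): next_label + k + 1 for k, v in enumerate(ids)}
        for v, new in remap.items():
            out[sl][ws == v] = new
        next_label += len(ids)
    return LabelImage(out, mask.calibration_um_per_px)


def _center_hull_image(pixels: np.ndarray) -> np.ndarray:
    """Pixels whose centre lies inside or on the convex hull of all
    foreground pixel centres.

    Exactly idempotent: the output's centres all lie within the hull, so
    re-hulling reproduces the same polygon. Degenerate hulls (points,
    collinear masks) are handled by GEOS and fill the spanned line.
    """
    from shapely import contains_xy
    from shapely.geometry import MultiPoint

    rows, cols = np.nonzero(pixels)
    pts = MultiPoint(np.stack([cols, rows], axis=1).astype(float))
    poly = pts.convex_hull.buffer(1e-9)  # closed boundary; handles degeneracy
    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    inside = contains_xy(poly, cc.ravel().astype(float), rr.ravel().astype(float))
    out = np.zeros(pixels.shape, dtype=bool)
    out[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rr.shape)
    return out | pixels


def _padded_closing(pixels: np.ndarray, radius: int) -> np.ndarray:
    """Morphological closing padded by the structuring radius, so endplates
    near the frame edge do not erode away at the border."""
    pad = radius + 1
    padded = np.pad(pixels, pad)
    closed = ndi.binary_closing(padded, structure=disk(radius))
    return closed[pad:-pad, pad:-pad]


def build_footprint(
    achr_mask: BinaryMask,
    method: str = "convex_hull",
    close_radius_px: int | None = None,
) -> BinaryMask:
    """Construct the endplate footprint: one connected region ⊇ the AChR mask.

    ``convex_hull`` (default) is parameter-free, deterministic and exactly
    idempotent: pixels whose centres fall within the convex hull of the
    foreground pixel centres (a convex region is its own footprint).
    ``close_fill`` applies morphological closing with ``close_radius_px``
    followed by hole filling, doubling the radius as needed until the result
    is a single connected region.
    """
    if achr_mask.is_empty():
        raise EmptyMaskError("cannot build a footprint from an empty mask (no endplate)")
    if method == "convex_hull":
        fp = _center_hull_image(achr_mask.pixels)
    elif method == "close_fill":
        radius = int(close_radius_px or 5)
        fp = achr_mask.pixels
        for _ in range(16):
            fp = _padded_closing(achr_mask.pixels, radius)
            fp = ndi.binary_fill_holes(fp, structure=S4)
            if ndi.label(fp, structure=S8)[1] <= 1:
                break
            radius *= 2
    else:
        raise ValueError(f"unknown footprint method {method!r}")
    fp = fp | achr_mask.pixels
    return BinaryMask(fp, achr_mask.calibration_um_per_px)


def select_endplate_region(
    achr_mask: BinaryMask, aggregate_radius_px: int = 10
) -> BinaryMask:
    """Restrict an AChR mask to its dominant cluster aggregate.

    Components are grouped by dilating the mask with the given radius, so
    two particles join one aggregate whenever their gap is below twice the
    radius; the aggregate with the largest original-mask area is kept and
    the mask is intersected with it. Extraneous particles far from the
    endplate (adjacent endplates, background debris) are thereby excluded
    before any footprint construction or measurement.
    """
    if achr_mask.is_empty():
        return achr_mask
    dilated = ndi.binary_dilation(achr_mask.pixels, structure=disk(aggregate_radius_px))
    lab, n = ndi.label(dilated, structure=S8)
    if n <= 1:
        return achr_mask
    areas = ndi.sum_labels(achr_mask.pixels.astype(float), lab, index=np.arange(1, n + 1))
    keep = int(np.argmax(areas)) + 1
    return BinaryMask(achr_mask.pixels & (lab == keep), achr_mask.calibration_um_per_px)


def particles_in_footprint(
    labels: LabelImage, footprint: BinaryMask, containment: str = "centroid"
) -> list[int]:
    """Label ids of particles lying within the footprint.

    ``centroid`` containment (default) is robust to 1-px boundary overhang
    from closing/hull construction; ``strict`` requires every particle pixel
    inside the footprint.
    """
    ids = np.unique(labels.labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        return []
    if containment == "centroid":
        cents = ndi.center_of_mass(labels.labels > 0, labels.labels, ids)
        fp = footprint.pixels
        kept = [
            int(i)
            for i, (r, c) in zip(ids, cents)
            if fp[min(int(round(r)), fp.shape[0] - 1), min(int(round(c)), fp.shape[1] - 1)]
        ]
        return kept
    if containment == "strict":
        outside = np.unique(labels.labels[~footprint.pixels])
        return [int(i) for i in ids if i not in set(outside.tolist())]
    raise ValueError(f"unknown containment rule {containment!r}")


def check_segmentation(
    labels: LabelImage,
    footprint: BinaryMask,
    max_clusters: int = 50,
    min_cluster_area_um2: float = 0.25,
    containment: str = "centroid",
) -> SegmentationQC:
    """Flag aberrant ('spider web' / 'broken window') watershed output.

    The segmentation is aberrant when the particle count inside the footprint
    exceeds ``max_clusters``, or the median particle area falls below
    ``min_cluster_area_um2``, or there are no particles at all. Deterministic
    given the configuration.
    """
    kept = particles_in_footprint(labels, footprint, containment)
    if not kept:
        return SegmentationQC(True, "no particles", 0, 0.0)
    areas = ndi.sum_labels(
        np.ones_like(labels.labels, dtype=float), labels.labels, index=kept
    )
    areas_um2 = np.asarray(areas) * labels.calibration_um_per_px**2
    median_area = float(np.median(areas_um2))
    count = len(kept)
    reasons = []
    if count > max_clusters:
        reasons.append(f"particle count {count} exceeds maximum {max_clusters}")
    if median_area < min_cluster_area_um2:
        reasons.append(
            f"median particle area {median_area:.4f} um2 below minimum "
            f"{min_cluster_area_um2} um2"
        )
    return SegmentationQC(bool(reasons), "; ".join(reasons), count, median_area)
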