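"""Calibrated TIFF/OME-TIFF input, maximum-intensity projection and results output.

Only TIFF and OME-TIFF are supported; proprietary microscope formats must be
converted upstream. Spatial calibration is resolved in strict precedence
order — OME ``PhysicalSizeX`` metadata, then the TIFF resolution tags, then an
explicit configuration override — and the absence of all three is an error,
never a silent default: every downstream measurement is reported in µm/µm².
"""

from __future__ import annotations

import csv
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import tifffile

from .errors import CalibrationError, ConfigurationError

CHANNEL_ROLES = ("nerve", "achr")

#: OME length units convertible to micrometres.
_UNIT_TO_UM = {
    "µm": 1.0,
    "um": 1.0,
    "micron": 1.0,
    "micrometer": 1.0,
    "nm": 1e-3,
    "mm": 1e3,
}


@dataclass(frozen=True)
class CalibratedImage:
    """A single-channel 2-D image with µm/pixel calibration."""

    pixels: np.ndarray
    calibration_um_per_px: float
    channel_role: str = ""

    def __post_init__(self) -> None:
        if np.asarray(self.pixels).ndim != 2:
            raise ValueError("CalibratedImage requires a 2-D pixel array")
        if not self.calibration_um_per_px > 0:
            raise ValueError("calibration must be positive")


@dataclass
class ZStack:
    """A (channel, slice, row, col) intensity volume with calibration.

    ``voxels`` is always stored 4-D; 2-D and 3-D inputs are promoted on
    construction (a bare 2-D image becomes a 1-channel, 1-slice stack).
    """

    voxels: np.ndarray
    calibration_um_per_px: float
    channel_labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim == 2:
            v = v[np.newaxis, np.newaxis]
        elif v.ndim == 3:
            v = v[np.newaxis]
        if v.ndim != 4:
            raise ValueError("voxels must be 2-D, 3-D or 4-D")
        if v.size == 0:
            raise ValueError("empty stack")
        if np.min(v) < 0:
            raise ValueError("intensities must be non-negative")
        if not self.calibration_um_per_px > 0:
            raise ValueError("calibration must be positive")
        self.voxels = v
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(v.shape[0])]
        if len(self.channel_labels) != v.shape[0]:
            raise ValueError("one label per channel required")
        non_empty = [l for l in self.channel_labels if l]
        if len(set(non_empty)) != len(non_empty):
            raise ValueError("channel roles must be unique")

    @property
    def n_channels(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[1]

    def channel_index(self, role: str) -> int:
        if role not in self.channel_labels:
            raise KeyError(f"channel role {role!r} not present in stack")
        return list(self.channel_labels).index(role)


def _calibration_from_ome(tf: tifffile.TiffFile) -> float | None:
    if not tf.is_ome or not tf.ome_metadata:
        return None
    try:
        root = ET.fromstring(tf.ome_metadata)
    except ET.ParseError:
        return None
    for el in root.iter():
        if el.tag.endswith("Pixels"):
            size = el.attrib.get("PhysicalSizeX")
            if size is None:
                continue
            unit = el.attrib.get("PhysicalSizeXUnit", "µm")
            factor = _UNIT_TO_UM.get(unit)
            if factor is None:
                return None
            return float(size) * factor
    return None


def _calibration_from_tags(tf: tifffile.TiffFile) -> float | None:
    page = tf.pages[0]
    tags = page.tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    px_per_unit = num / den
    unit = tags["ResolutionUnit"].value  # 2 = inch, 3 = centimetre
    um_per_unit = {2: 25400.0, 3: 10000.0}.get(int(unit))
    if um_per_unit is None:
        return None
    return um_per_unit / px_per_unit


def load_stack(
    path: str | Path,
    channel_map: Mapping[str, int],
    calibration_um_per_px: float | None = None,
) -> ZStack:
    """Read a TIFF/OME-TIFF file into a role-labelled :class:`ZStack`.

    Parameters
    ----------
    path:
        TIFF or OME-TIFF file. 2-D images are accepted as depth-1 stacks.
    channel_map:
        Mapping from channel role (``"nerve"``/``"achr"``) to the channel
        index in the file. Channel assignment is always explicit; there is
        no heuristic channel guessing.
    calibration_um_per_px:
        Configuration fallback used only when the file itself carries no
        calibration metadata.

    Raises
    ------
    ConfigurationError
        If a channel index is out of bounds.
    CalibrationError
        If neither metadata nor configuration provides a pixel size.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes.upper()
        meta_cal = _calibration_from_ome(tf) or _calibration_from_tags(tf)

    data = np.asarray(data)
    # Normalise to (C, Z, Y, X) using the series axes string where available.
    if data.ndim == 2:
        data = data[np.newaxis, np.newaxis]
    elif data.ndim == 3:
        if "C" in axes:
            data = np.moveaxis(data, axes.index("C"), 0)[:, np.newaxis]
        elif "Z" in axes:
            data = data[np.newaxis]
        elif len(set(channel_map.values())) > 1:
            # No channel axis recorded but two roles requested: treat the
            # leading axis as channels (common for bare multi-channel TIFFs).
            data = data[:, np.newaxis]
        else:
            data = data[np.newaxis]  # plain Z-stack, single channel
    elif data.ndim == 4:
        if "C" in axes and "Z" in axes:
            data = np.moveaxis(data, (axes.index("C"), axes.index("Z")), (0, 1))
        # else assume already (C, Z, Y, X)
    else:
        raise ConfigurationError(f"{path.name}: unsupported dimensionality {data.ndim}")

    n_channels = data.shape[0]
    labels = [""] * n_channels
    for role, idx in channel_map.items():
        if not 0 <= idx < n_channels:
            raise ConfigurationError(
                f"{path.name}: channel index {idx} for role {role!r} out of "
                f"bounds (file has {n_channels} channel(s))"
            )
        labels[idx] = role

    cal = meta_cal if meta_cal is not None else calibration_um_per_px
    if cal is None:
        raise CalibrationError(
            f"{path.name}: no calibration in TIFF metadata and no config override"
        )
    for i, lab in enumerate(labels):
        if not lab:
            labels[i] = f"ch{i}"
    return ZStack(voxels=data, calibration_um_per_px=float(cal), channel_labels=labels)


def write_stack(
    path: str | Path,
    voxels: np.ndarray,
    calibration_um_per_px: float,
    channel_labels: Sequence[str] | None = None,
    embed_calibration: bool = True,
) -> None:
    """Write a (C, Z, Y, X) volume as OME-TIFF, optionally embedding pixel size."""
    voxels = np.asarray(voxels)
    if voxels.ndim == 3:
        voxels = voxels[np.newaxis]
    if voxels.ndim != 4:
        raise ValueError("write_stack expects a 3-D or 4-D array")
    # tifffile stores singleton leading axes squeezed; drop them from the
    # axes string (and data) so the OME declaration matches the stored shape.
    axes = "CZYX"
    if voxels.shape[1] == 1:
        voxels = voxels[:, 0]
        axes = "CYX"
    if voxels.shape[0] == 1:
        voxels = voxels[0]
        axes = axes[1:]
    metadata: dict = {"axes": axes}
    if embed_calibration:
        metadata.update(
            PhysicalSizeX=calibration_um_per_px,
            PhysicalSizeY=calibration_um_per_px,
            PhysicalSizeXUnit="µm",
            PhysicalSizeYUnit="µm",
        )
    if channel_labels and "C" in axes:
        metadata["Channel"] = {"Name": list(channel_labels)}
    tifffile.imwrite(path, voxels, ome=True, photometric="minisblack", metadata=metadata)


def max_project(stack: ZStack, role: str) -> CalibratedImage:
    """Maximum-intensity projection of one channel across all z-slices."""
    idx = stack.channel_index(role)
    pixels = stack.voxels[idx].max(axis=0)
    return CalibratedImage(
        pixels=pixels,
        calibration_um_per_px=stack.calibration_um_per_px,
        channel_role=role,
    )


# ---------------------------------------------------------------------------
# Results table

#: The 19 morphological variables, in canonical output order.
METRIC_COLUMNS = (
    "nerve_terminal_area_um2",
    "nerve_terminal_perimeter_um",
    "n_terminal_branches",
    "n_branch_points",
    "total_branch_length_um",
    "average_branch_length_um",
    "complexity",
    "achr_area_um2",
    "achr_perimeter_um",
    "endplate_area_um2",
    "endplate_perimeter_um",
    "endplate_diameter_um",
    "n_achr_clusters",
    "average_cluster_area_um2",
    "fragmentation",
    "compactness_pct",
    "overlap_pct",
    "synaptic_contact_area_um2",
    "axon_diameter_um",
)

PROVENANCE_COLUMNS = (
    "image_id",
    "image_width_px",
    "image_height_px",
    "calibration_um_per_px",
    "threshold_nerve",
    "threshold_achr",
    "qc_flags",
)

RESULT_COLUMNS = METRIC_COLUMNS + PROVENANCE_COLUMNS


def write_results(records: Sequence, path: str | Path) -> None:
    """Write NMJ records to a curated CSV (one row per NMJ).

    Columns are the 19 metric columns in canonical order followed by the
    provenance columns; missing values are written as empty cells. The
    column set is fixed and identical across runs.
    """
    if not records:
        raise ValueError("write_results requires at least one record")
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=RESULT_COLUMNS)
        writer.writeheader()
        for rec in records:
            row = rec.to_row() if hasattr(rec, "to_row") else dict(rec)
            writer.writerow(
                {k: ("" if row.get(k) is None else row.get(k, "")) for k in RESULT_COLUMNS}
            )


def read_results(path: str | Path):
    """Load a results CSV written by :func:`write_results` as a DataFrame."""
    import pandas as pd

    return pd.read_csv(path)


def save_overlay(
    achr_image: CalibratedImage,
    footprint,
    labels,
    path: str | Path,
    nerve_image: CalibratedImage | None = None,
) -> None:
    """Write a QC overlay PNG: AChR channel, footprint outline, particle labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(achr_image.pixels, cmap="gray")
    if nerve_image is not None:
        ax.imshow(
            np.ma.masked_where(nerve_image.pixels <= 0, nerve_image.pixels),
            cmap="Greens",
            alpha=0.4,
        )
    if labels is not None:
        lines = find_boundaries(labels.labels, mode="outer")
        ax.imshow(np.ma.masked_where(~lines, lines), cmap="autumn", alpha=0.9)
    if footprint is not None:
        outline = find_boundaries(footprint.pixels, mode="inner")
        ax.imshow(np.ma.masked_where(~outline, outline), cmap="cool", alpha=0.9)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=150)
    plt.close(fig)
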