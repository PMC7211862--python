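"""Seven-stage analysis flow for single NMJ images and batch folders.

The guided windows of the interactive workflow are recast as seven named
pipeline stages; the stages (not the windows) are the contract here. Default
operation is headless with thresholds from configuration; ``interactive``
re-exposes the threshold/segmentation confirmations on the terminal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import binary_ops, image_io, postsynaptic, presynaptic
from .binary_ops import BinaryMask
from .errors import ConfigurationError, NMJMorphError
from .image_io import METRIC_COLUMNS, ZStack, max_project
from .presynaptic import AxonInput

log = logging.getLogger("nmjmorph")

PIPELINE_STAGES = (
    "project channels",
    "threshold AChR channel",
    "threshold nerve channel",
    "axon measure/erase",
    "post-synaptic measures + footprint",
    "segmentation check + cluster count",
    "assemble record",
)


def pipeline_stages() -> tuple[str, ...]:
    """The ordered stage names executed by :func:`analyze_image` (dry run)."""
    return PIPELINE_STAGES


@dataclass
class NMJMetrics:
    """One NMJ's curated record: the 19 morphological variables + provenance.

    Missing values (aberrant segmentation, absent axon input, empty channel)
    are ``None`` and serialise to empty CSV cells.
    """

    # pre-synaptic (1-7)
    nerve_terminal_area_um2: Optional[float] = None
    nerve_terminal_perimeter_um: Optional[float] = None
    n_terminal_branches: Optional[int] = None
    n_branch_points: Optional[int] = None
    total_branch_length_um: Optional[float] = None
    average_branch_length_um: Optional[float] = None
    complexity: Optional[float] = None
    # post-synaptic (8-18)
    achr_area_um2: Optional[float] = None
    achr_perimeter_um: Optional[float] = None
    endplate_area_um2: Optional[float] = None
    endplate_perimeter_um: Optional[float] = None
    endplate_diameter_um: Optional[float] = None
    n_achr_clusters: Optional[int] = None
    average_cluster_area_um2: Optional[float] = None
    fragmentation: Optional[float] = None
    compactness_pct: Optional[float] = None
    overlap_pct: Optional[float] = None
    synaptic_contact_area_um2: Optional[float] = None
    # associated nerve (19)
    axon_diameter_um: Optional[float] = None
    # provenance
    image_id: str = ""
    image_width_px: int = 0
    image_height_px: int = 0
    calibration_um_per_px: float = 0.0
    threshold_nerve: Optional[float] = None
    threshold_achr: Optional[float] = None
    qc_flags: tuple[str, ...] = ()

    def metric_values(self) -> dict[str, Optional[float]]:
        return {name: getattr(self, name) for name in METRIC_COLUMNS}

    def to_row(self) -> dict:
        row = self.metric_values()
        row.update(
            image_id=self.image_id,
            image_width_px=self.image_width_px,
            image_height_px=self.image_height_px,
            calibration_um_per_px=self.calibration_um_per_px,
            threshold_nerve=self.threshold_nerve,
            threshold_achr=self.threshold_achr,
            qc_flags=";".join(self.qc_flags),
        )
        return row

    def check_consistency(self, rel_tol: float = 1e-9) -> None:
        """Raise if derived fields disagree with their core inputs."""

        def close(a, b):
            return math.isclose(a, b, rel_tol=rel_tol, abs_tol=1e-12)

        if self.n_terminal_branches and self.total_branch_length_um is not None:
            assert close(
                self.average_branch_length_um,
                self.total_branch_length_um / self.n_terminal_branches,
            ), "average branch length inconsistent"
        if self.n_achr_clusters is not None:
            assert close(
                self.fragmentation, 1.0 - 1.0 / self.n_achr_clusters
            ), "fragmentation inconsistent"
            assert close(
                self.average_cluster_area_um2 * self.n_achr_clusters,
                self.achr_area_um2,
            ), "average cluster area inconsistent"
        if self.overlap_pct is not None and self.achr_area_um2:
            assert close(
                self.overlap_pct,
                self.synaptic_contact_area_um2 / self.achr_area_um2 * 100.0,
            ), "overlap inconsistent"
        if self.compactness_pct is not None and self.endplate_area_um2:
            assert close(
                self.compactness_pct,
                self.achr_area_um2 / self.endplate_area_um2 * 100.0,
            ), "compactness inconsistent"


@dataclass
class RunConfig:
    """Validated batch/single-image run configuration."""

    channel_map: Mapping[str, int] = field(default_factory=lambda: {"nerve": 0, "achr": 1})
    calibration_um_per_px: Optional[float] = None
    threshold_method: str = "otsu"
    threshold_value_nerve: Optional[float] = None
    threshold_value_achr: Optional[float] = None
    footprint_method: str = "convex_hull"
    footprint_close_radius_px: int = 10
    qc_max_clusters: int = 50
    qc_min_cluster_area_um2: float = 0.25
    containment: str = "centroid"
    min_seed_separation_px: float = 3.0
    imagej_parity: bool = False
    interactive: bool = False
    output_dir: Optional[str] = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for role in ("nerve", "achr"):
            if role not in self.channel_map:
                raise ConfigurationError(f"channel_map must assign role {role!r}")
        if len(set(self.channel_map.values())) != len(self.channel_map):
            raise ConfigurationError("channel_map indices must be distinct")
        if self.threshold_method not in ("manual", "otsu"):
            raise ConfigurationError(
                f"unknown threshold method {self.threshold_method!r}"
            )
        if self.threshold_method == "manual" and (
            self.threshold_value_nerve is None or self.threshold_value_achr is None
        ):
            raise ConfigurationError(
                "manual thresholding requires threshold.value.nerve and threshold.value.achr"
            )
        if self.footprint_method not in ("convex_hull", "close_fill"):
            raise ConfigurationError(
                f"unknown footprint method {self.footprint_method!r}"
            )
        if self.calibration_um_per_px is not None and self.calibration_um_per_px <= 0:
            raise ConfigurationError("calibration override must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        thr = raw.get("threshold", {})
        thr_values = thr.get("value", {}) if isinstance(thr, Mapping) else {}
        fp = raw.get("footprint", {})
        qc = raw.get("qc", {})
        kwargs = dict(
            channel_map=dict(raw.get("channel_map", {"nerve": 0, "achr": 1})),
            calibration_um_per_px=raw.get("calibration_um_per_px"),
            threshold_method=thr.get("method", "otsu"),
            threshold_value_nerve=thr_values.get("nerve"),
            threshold_value_achr=thr_values.get("achr"),
            footprint_method=fp.get("method", "convex_hull"),
            footprint_close_radius_px=fp.get("close_radius_px", 10),
            qc_max_clusters=qc.get("max_clusters", 50),
            qc_min_cluster_area_um2=qc.get("min_cluster_area_um2", 0.25),
            containment=raw.get("containment", "centroid"),
            interactive=bool(raw.get("interactive", False)),
            imagej_parity=bool(raw.get("imagej_parity", False)),
            seed=int(raw.get("seed", 0)),
        )
        return cls(**kwargs)


def _threshold_channel(image, cfg: RunConfig, role: str, override=None):
    if override is not None:
        return binary_ops.threshold_mask(image, "manual", override, channel_role=role)
    if cfg.threshold_method == "manual":
        value = (
            cfg.threshold_value_nerve if role == "nerve" else cfg.threshold_value_achr
        )
        return binary_ops.threshold_mask(image, "manual", value, channel_role=role)
    return binary_ops.threshold_mask(image, "otsu", channel_role=role)


def _confirm(prompt: str, interactive: bool) -> bool:
    if not interactive:
        return True
    reply = input(f"{prompt} [Y/n] ").strip().lower()
    return reply in ("", "y", "yes")


def analyze_image(
    stack: ZStack,
    cfg: RunConfig,
    axon: Optional[AxonInput] = None,
    image_id: str = "",
    threshold_overrides: Optional[Mapping[str, float]] = None,
) -> NMJMetrics:
    """Run the seven-stage flow on one two-channel stack.

    Aberrant segmentation leaves the cluster-count-dependent fields missing
    while every other variable is still measured and recorded; a missing
    axon annotation leaves ``axon_diameter_um`` missing with a QC flag.
    """
    qc_flags: list[str] = []
    overrides = threshold_overrides or {}
    cal = stack.calibration_um_per_px
    rec = NMJMetrics(
        image_id=image_id,
        image_width_px=stack.voxels.shape[3],
        image_height_px=stack.voxels.shape[2],
        calibration_um_per_px=cal,
    )

    log.info("[stage 1/7] %s", PIPELINE_STAGES[0])
    nerve_img = max_project(stack, "nerve")
    achr_img = max_project(stack, "achr")

    log.info("[stage 2/7] %s", PIPELINE_STAGES[1])
    achr_mask, achr_thr = _threshold_channel(achr_img, cfg, "achr", overrides.get("achr"))
    rec.threshold_achr = achr_thr.lower_value
    qc_flags += [f"achr: {w}" for w in achr_thr.warnings]
    if not _confirm("AChR threshold acceptable?", cfg.interactive):
        qc_flags.append("achr threshold rejected by user")

    log.info("[stage 3/7] %s", PIPELINE_STAGES[2])
    nerve_mask, nerve_thr = _threshold_channel(
        nerve_img, cfg, "nerve", overrides.get("nerve")
    )
    rec.threshold_nerve = nerve_thr.lower_value
    qc_flags += [f"nerve: {w}" for w in nerve_thr.warnings]
    if not _confirm("Nerve threshold acceptable?", cfg.interactive):
        qc_flags.append("nerve threshold rejected by user")

    log.info("[stage 4/7] %s", PIPELINE_STAGES[3])
    if axon is not None:
        rec.axon_diameter_um = presynaptic.axon_diameter(axon, cal)
        nerve_mask = presynaptic.erase_axon(nerve_mask, axon)
    else:
        qc_flags.append("axon input missing; axon diameter not measured")

    if not nerve_mask.is_empty():
        area, perim = presynaptic.measure_region(nerve_mask)
        rec.nerve_terminal_area_um2 = area
        rec.nerve_terminal_perimeter_um = perim
        skel = presynaptic.skeleton_stats(nerve_mask, imagej_parity=cfg.imagej_parity)
        rec.n_terminal_branches = skel.n_terminal_branches
        rec.n_branch_points = skel.n_branch_points
        rec.total_branch_length_um = skel.total_branch_length_um
        rec.average_branch_length_um = skel.average_branch_length_um
        rec.complexity = skel.complexity
        if skel.complexity is None:
            qc_flags.append("complexity undefined (a skeleton factor is zero)")
    else:
        qc_flags.append("empty nerve mask; pre-synaptic variables not measured")

    log.info("[stage 5/7] %s", PIPELINE_STAGES[4])
    footprint = None
    if not achr_mask.is_empty():
        endplate_mask = binary_ops.select_endplate_region(
            achr_mask, cfg.footprint_close_radius_px
        )
        if endplate_mask.area_px < achr_mask.area_px:
            qc_flags.append("extraneous particles outside the endplate excluded")
        achr_area, achr_perim = presynaptic.measure_region(endplate_mask)
        rec.achr_area_um2 = achr_area
        rec.achr_perimeter_um = achr_perim
        footprint = binary_ops.build_footprint(
            endplate_mask, cfg.footprint_method, cfg.footprint_close_radius_px
        )
        ep_area, ep_perim, ep_diam = postsynaptic.endplate_measures(footprint)
        rec.endplate_area_um2 = ep_area
        rec.endplate_perimeter_um = ep_perim
        rec.endplate_diameter_um = ep_diam
        rec.compactness_pct = postsynaptic.compactness(achr_area, ep_area)
        if not nerve_mask.is_empty():
            contact, overlap = postsynaptic.synaptic_contact(nerve_mask, endplate_mask)
            rec.synaptic_contact_area_um2 = contact
            rec.overlap_pct = overlap
    else:
        qc_flags.append("empty AChR mask; post-synaptic variables not measured")

    log.info("[stage 6/7] %s", PIPELINE_STAGES[5])
    if footprint is not None:
        labels = binary_ops.watershed_split(
            endplate_mask, min_seed_separation_px=cfg.min_seed_separation_px
        )
        seg_qc = binary_ops.check_segmentation(
            labels,
            footprint,
            max_clusters=cfg.qc_max_clusters,
            min_cluster_area_um2=cfg.qc_min_cluster_area_um2,
            containment=cfg.containment,
        )
        if seg_qc.aberrant and _confirm(
            f"Segmentation flagged ({seg_qc.reason}); accept anyway?", cfg.interactive
        ) and cfg.interactive:
            seg_qc = binary_ops.SegmentationQC(
                False, "", seg_qc.particle_count, seg_qc.median_particle_area_um2
            )
        if seg_qc.aberrant:
            qc_flags.append(f"aberrant segmentation: {seg_qc.reason}")
        clusters = postsynaptic.count_clusters(
            labels, endplate_mask, footprint, qc=seg_qc, containment=cfg.containment
        )
        rec.n_achr_clusters = clusters.n_clusters
        rec.average_cluster_area_um2 = clusters.average_cluster_area_um2
        rec.fragmentation = clusters.fragmentation

    log.info("[stage 7/7] %s", PIPELINE_STAGES[6])
    rec.qc_flags = tuple(qc_flags)
    rec.check_consistency()
    return rec


def read_axon_sidecar(path: str | Path) -> dict[str, AxonInput]:
    """Parse a per-image axon annotation CSV.

    Columns: ``image_id, role, order, row, col`` with role ``line`` (exactly
    two rows per image) or ``erase`` (≥3 polygon vertices); coordinates are
    0-based (row, col) pixels.
    """
    df = pd.read_csv(path)
    required = {"image_id", "role", "order", "row", "col"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"axon sidecar must have columns {sorted(required)}"
        )
    out: dict[str, AxonInput] = {}
    for image_id, grp in df.groupby("image_id"):
        line = grp[grp["role"] == "line"].sort_values("order")
        erase = grp[grp["role"] == "erase"].sort_values("order")
        if len(line) != 2:
            raise ConfigurationError(
                f"{image_id}: axon line requires exactly 2 endpoints"
            )
        endpoints = tuple((float(r), float(c)) for r, c in line[["row", "col"]].values)
        region = (
            [(float(r), float(c)) for r, c in erase[["row", "col"]].values]
            if len(erase)
            else None
        )
        out[str(image_id)] = AxonInput(line_endpoints=endpoints, erase_region=region)
    return out


def read_thresholds_sidecar(path: str | Path) -> dict[str, dict[str, float]]:
    """Parse per-image manual thresholds (``image_id, nerve_value, achr_value``)."""
    df = pd.read_csv(path)
    required = {"image_id", "nerve_value", "achr_value"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"thresholds sidecar must have columns {sorted(required)}"
        )
    return {
        str(row.image_id): {"nerve": float(row.nerve_value), "achr": float(row.achr_value)}
        for row in df.itertuples()
    }


def analyze_folder(
    directory: str | Path,
    cfg: RunConfig,
    axon_inputs: Optional[Mapping[str, AxonInput]] = None,
    threshold_overrides: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> list[NMJMetrics]:
    """Analyse every TIFF in a folder in sorted order.

    Per-image failures are logged and skipped; the run continues. An empty
    folder is an error.
    """
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir()
        if p.suffix.lower() in (".tif", ".tiff") and p.is_file()
    )
    if not paths:
        raise ConfigurationError(f"no TIFF images found in {directory}")
    axon_inputs = axon_inputs or {}
    threshold_overrides = threshold_overrides or {}
    records: list[NMJMetrics] = []
    for path in paths:
        image_id = path.stem
        try:
            stack = image_io.load_stack(
                path, cfg.channel_map, cfg.calibration_um_per_px
            )
            rec = analyze_image(
                stack,
                cfg,
                axon=axon_inputs.get(image_id),
                image_id=image_id,
                threshold_overrides=threshold_overrides.get(image_id),
            )
            records.append(rec)
        except (NMJMorphError, OSError, ValueError) as exc:
            log.error("skipping %s: %s", path.name, exc)
    return records


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.to_row() for r in records])


def validate_against_reference(
    records_a, records_b, variables: Sequence[str] = METRIC_COLUMNS
) -> pd.DataFrame:
    """Per-variable Pearson and Spearman concordance between two record sets.

    Records are matched on ``image_id``; both sets must cover the same ids.
    Intended for validating this pipeline against reference output produced
    by another workflow on the same images.
    """
    a = _records_frame(records_a).set_index("image_id")
    b = _records_frame(records_b).set_index("image_id")
    if set(a.index) != set(b.index):
        raise ConfigurationError("record sets must contain the same image ids")
    b = b.loc[a.index]
    rows = []
    for var in variables:
        xa = pd.to_numeric(a[var], errors="coerce")
        xb = pd.to_numeric(b[var], errors="coerce")
        ok = xa.notna() & xb.notna()
        n = int(ok.sum())
        if n >= 2 and xa[ok].nunique() > 1 and xb[ok].nunique() > 1:
            pr = float(sps.pearsonr(xa[ok], xb[ok]).statistic)
            sr = float(sps.spearmanr(xa[ok], xb[ok]).statistic)
        else:
            pr = sr = float("nan")
        rows.append({"variable": var, "n": n, "pearson_r": pr, "spearman_r": sr})
    return pd.DataFrame(rows)
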