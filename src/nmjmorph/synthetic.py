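"""Synthetic two-channel NMJ fixtures with exhaustively known ground truth.

Fixtures are shipped as generator code, never as binary images. The
rasterization rule is fixed: a pixel is foreground iff its centre lies inside
the analytic shape, so analytic-vs-measured tolerances are computable per
fixture. The AChR channel renders filled clusters (optionally an annulus with
a second cluster enclosed in its hole, plus extraneous particles outside the
endplate); the nerve channel renders a 1-px branched polyline tree plus an
axon stub. Noise is additive Gaussian on a constant background, clipped to
the dtype range; every random draw takes an explicit seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.draw import line as _draw_line

from . import binary_ops, postsynaptic, presynaptic
from .binary_ops import BinaryMask
from .image_io import ZStack, write_stack
from .pipeline import NMJMetrics, RunConfig
from .presynaptic import AxonInput

BACKGROUND = 10
SIGNAL = 200
#: Threshold used by the matching default fixture config; halfway up the
#: signal step so mild noise cannot flip a pixel.
FIXTURE_THRESHOLD = 100.0


@dataclass(frozen=True)
class ClusterSpec:
    """One AChR cluster: a disc, optionally with a hole, optionally enclosed
    inside the hole of another cluster (``enclosed_in`` = host index)."""

    center: tuple[float, float]
    radius: float
    hole_radius: Optional[float] = None
    enclosed_in: Optional[int] = None


@dataclass(frozen=True)
class TreeSpec:
    """A nerve-terminal tree: one horizontal trunk with vertical side arms.

    ``branches`` are (column, direction, length) triples; direction is ±1
    (up/down in row coordinates) and arms attach at interior trunk columns,
    so the branch topology is known analytically: ``n_side`` arms give
    ``2·n_side + 1`` terminal branches and ``n_side`` branch points.
    """

    trunk_row: int
    trunk_cols: tuple[int, int]
    branches: tuple[tuple[int, int, int], ...] = ()


@dataclass(frozen=True)
class AxonSpec:
    """Axon stub (1-px horizontal line entering the trunk) + annotations."""

    stub_cols: tuple[int, int]  # rendered at trunk_row, stub_cols[0]..stub_cols[1]
    line_endpoints: tuple[tuple[float, float], tuple[float, float]]
    erase_margin_px: int = 6


@dataclass
class NMJSpec:
    """Full geometric specification of one synthetic NMJ."""

    shape: tuple[int, int] = (192, 192)
    calibration_um_per_px: float = 0.1
    clusters: Sequence[ClusterSpec] = field(default_factory=list)
    tree: Optional[TreeSpec] = None
    axon: Optional[AxonSpec] = None
    extraneous: Sequence[ClusterSpec] = field(default_factory=list)
    noise_sigma: float = 0.0
    n_slices: int = 2
    footprint_method: str = "convex_hull"


@dataclass
class SyntheticGroundTruth:
    """Generator-side truth: the spec, the rendered truth masks and the
    analytically expected metrics record."""

    spec: NMJSpec
    achr_endplate_mask: BinaryMask  # genuine clusters only
    achr_full_mask: BinaryMask  # clusters + extraneous particles
    nerve_terminal_mask: BinaryMask  # tree only (axon stub erased)
    axon_input: Optional[AxonInput]
    expected: NMJMetrics


def _disc(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _rasterize_cluster(shape: tuple[int, int], c: ClusterSpec) -> np.ndarray:
    m = _disc(shape, c.center, c.radius)
    if c.hole_radius:
        m &= ~_disc(shape, c.center, c.hole_radius)
    return m


def _rasterize_tree(shape: tuple[int, int], tree: TreeSpec) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    r, (c0, c1) = tree.trunk_row, tree.trunk_cols
    rr, cc = _draw_line(r, c0, r, c1)
    m[rr, cc] = True
    for col, direction, length in tree.branches:
        rr, cc = _draw_line(r, col, r + direction * length, col)
        m[rr, cc] = True
    return m


def _axon_input(spec: NMJSpec) -> Optional[AxonInput]:
    if spec.axon is None or spec.tree is None:
        return None
    r = spec.tree.trunk_row
    m = spec.axon.erase_margin_px
    c_lo = spec.axon.stub_cols[0] - 2
    c_hi = spec.tree.trunk_cols[0] - 0.5  # exclude the first trunk column
    region = [(r - m, c_lo), (r - m, c_hi), (r + m, c_hi), (r + m, c_lo)]
    return AxonInput(line_endpoints=spec.axon.line_endpoints, erase_region=region)


def render_masks(spec: NMJSpec) -> tuple[BinaryMask, BinaryMask, BinaryMask]:
    """Rasterize the spec into (endplate AChR, full AChR, nerve tree) masks."""
    cal = spec.calibration_um_per_px
    endplate = np.zeros(spec.shape, dtype=bool)
    for c in spec.clusters:
        endplate |= _rasterize_cluster(spec.shape, c)
    full = endplate.copy()
    for c in spec.extraneous:
        full |= _rasterize_cluster(spec.shape, c)
    nerve = (
        _rasterize_tree(spec.shape, spec.tree)
        if spec.tree is not None
        else np.zeros(spec.shape, dtype=bool)
    )
    return (
        BinaryMask(endplate, cal),
        BinaryMask(full, cal),
        BinaryMask(nerve, cal),
    )


def truth_metrics(spec: NMJSpec, image_id: str = "") -> NMJMetrics:
    """Analytically expected metrics for a spec.

    Integer metrics (cluster/branch counts) come straight from the geometry;
    pixel-count areas and polyline lengths are exact under the documented
    rasterization rule. Contour-convention quantities (perimeters, footprint,
    Feret diameter) are evaluated on the generator-side truth masks, which
    the pipeline must recover exactly on noise-free fixtures.
    """
    endplate_mask, _full, nerve_mask = render_masks(spec)
    cal = spec.calibration_um_per_px
    rec = NMJMetrics(image_id=image_id)
    rec.image_height_px, rec.image_width_px = spec.shape
    rec.calibration_um_per_px = cal

    if spec.tree is not None:
        n_side = len(spec.tree.branches)
        rec.n_terminal_branches = 2 * n_side + 1 if n_side else 1
        rec.n_branch_points = n_side
        trunk_steps = abs(spec.tree.trunk_cols[1] - spec.tree.trunk_cols[0])
        total = (trunk_steps + sum(b[2] for b in spec.tree.branches)) * cal
        rec.total_branch_length_um = total
        rec.average_branch_length_um = total / rec.n_terminal_branches
        rec.complexity = presynaptic.complexity(
            rec.n_terminal_branches, rec.n_branch_points, total
        )
        area, perim = presynaptic.measure_region(nerve_mask)
        rec.nerve_terminal_area_um2 = area
        rec.nerve_terminal_perimeter_um = perim

    if spec.clusters:
        rec.achr_area_um2, rec.achr_perimeter_um = presynaptic.measure_region(
            endplate_mask
        )
        n_clusters = sum(1 for c in spec.clusters if c.enclosed_in is None)
        rec.n_achr_clusters = n_clusters
        rec.average_cluster_area_um2 = rec.achr_area_um2 / n_clusters
        rec.fragmentation = 1.0 - 1.0 / n_clusters
        footprint = binary_ops.build_footprint(endplate_mask, spec.footprint_method)
        (
            rec.endplate_area_um2,
            rec.endplate_perimeter_um,
            rec.endplate_diameter_um,
        ) = postsynaptic.endplate_measures(footprint)
        rec.compactness_pct = postsynaptic.compactness(
            rec.achr_area_um2, rec.endplate_area_um2
        )
        if spec.tree is not None:
            contact, overlap = postsynaptic.synaptic_contact(nerve_mask, endplate_mask)
            rec.synaptic_contact_area_um2 = contact
            rec.overlap_pct = overlap

    axon = _axon_input(spec)
    if axon is not None:
        rec.axon_diameter_um = presynaptic.axon_diameter(axon, cal)
    rec.threshold_nerve = FIXTURE_THRESHOLD
    rec.threshold_achr = FIXTURE_THRESHOLD
    return rec


def _render_channel(
    structure: np.ndarray, spec: NMJSpec, rng: np.random.Generator
) -> np.ndarray:
    """Render one channel as a small z-stack: the structure lives in slice 0,
    deeper slices hold background only, so the max projection recovers it."""
    shape = (spec.n_slices, *spec.shape)
    img = np.full(shape, float(BACKGROUND))
    img[0][structure] = SIGNAL
    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=shape)
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_nmj(spec: NMJSpec, seed: int) -> tuple[ZStack, SyntheticGroundTruth]:
    """Render a spec into a two-channel z-stack plus its ground truth.

    The same seed always yields a byte-identical stack.
    """
    rng = np.random.default_rng(seed)
    endplate_mask, full_mask, nerve_tree = render_masks(spec)
    nerve_structure = nerve_tree.pixels.copy()
    if spec.axon is not None and spec.tree is not None:
        rr, cc = _draw_line(
            spec.tree.trunk_row,
            spec.axon.stub_cols[0],
            spec.tree.trunk_row,
            spec.axon.stub_cols[1],
        )
        nerve_structure[rr, cc] = True
    nerve_ch = _render_channel(nerve_structure, spec, rng)
    achr_ch = _render_channel(full_mask.pixels, spec, rng)
    stack = ZStack(
        voxels=np.stack([nerve_ch, achr_ch]),
        calibration_um_per_px=spec.calibration_um_per_px,
        channel_labels=["nerve", "achr"],
    )
    truth = SyntheticGroundTruth(
        spec=spec,
        achr_endplate_mask=endplate_mask,
        achr_full_mask=full_mask,
        nerve_terminal_mask=nerve_tree,
        axon_input=_axon_input(spec),
        expected=truth_metrics(spec),
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Presets


def nominal_spec(noise_sigma: float = 4.0) -> NMJSpec:
    """A well-behaved multi-cluster endplate with a branched terminal."""
    return NMJSpec(
        clusters=[
            ClusterSpec((90, 70), 10),
            ClusterSpec((85, 95), 9),
            ClusterSpec((110, 85), 10),
            ClusterSpec((105, 110), 8),
        ],
        tree=TreeSpec(
            trunk_row=97,
            trunk_cols=(60, 120),
            branches=((70, -1, 14), (85, 1, 12), (100, -1, 16), (110, 1, 10)),
        ),
        axon=AxonSpec(
            stub_cols=(42, 59),
            line_endpoints=((95.0, 50.0), (99.0, 50.0)),
        ),
        noise_sigma=noise_sigma,
    )


def enclosed_spec() -> NMJSpec:
    """The enclosure worked example: five direct particles, four clusters.

    An annulus hosts a separate cluster fully inside its hole; three further
    discs complete the endplate. Direct component count is five; the
    fill-holes overlay absorbs the enclosed cluster, leaving four.
    """
    spec = nominal_spec(noise_sigma=0.0)
    spec.clusters = [
        ClusterSpec((80, 80), 20, hole_radius=12),
        ClusterSpec((80, 80), 5, enclosed_in=0),
        ClusterSpec((80, 118), 8),
        ClusterSpec((112, 88), 8),
        ClusterSpec((108, 115), 7),
    ]
    return spec


def extraneous_spec() -> NMJSpec:
    """Nominal endplate plus a background particle far outside it; every
    metric must match the nominal truth (the exclusion property)."""
    spec = nominal_spec(noise_sigma=0.0)
    spec.extraneous = [ClusterSpec((30, 160), 5)]
    return spec


PRESETS = {
    "nominal": nominal_spec,
    "enclosed": enclosed_spec,
    "extraneous": extraneous_spec,
}


def _random_spec(rng: np.random.Generator) -> NMJSpec:
    """One randomised but geometrically safe NMJ for batch fixtures.

    Clusters are placed on a ring so that neighbours stay disjoint (gap
    ≥ 3 px, so the direct component count equals the cluster count) yet close
    enough (gap ≤ 18 px) that endplate aggregation keeps them together.
    """
    center = np.array([96.0, 96.0]) + rng.uniform(-8, 8, size=2)
    k = int(rng.integers(3, 6))
    # Ring radius bounded per k so adjacent gaps stay within [3, 18] px:
    # ≥3 keeps clusters disjoint, ≤18 keeps them inside one closing aggregate.
    ring_bounds = {3: (14.5, 17.5), 4: (16.0, 20.5), 5: (19.0, 24.0)}
    ring = rng.uniform(*ring_bounds[k])
    base = rng.uniform(0, 2 * math.pi)
    clusters = []
    for i in range(k):
        ang = base + 2 * math.pi * i / k + rng.uniform(-0.08, 0.08)
        pos = center + ring * np.array([math.sin(ang), math.cos(ang)])
        clusters.append(ClusterSpec((float(pos[0]), float(pos[1])), float(rng.uniform(7, 9))))
    # verify separation/aggregation bounds; shrink radii if a pair touches
    for i in range(k):
        for j in range(i + 1, k):
            d = math.dist(clusters[i].center, clusters[j].center)
            if d < clusters[i].radius + clusters[j].radius + 3:
                clusters[j] = ClusterSpec(clusters[j].center, max(5.0, d - clusters[i].radius - 3))

    trunk_row = int(round(center[0])) + int(rng.integers(-4, 5))
    half = int(rng.integers(26, 34))
    c_mid = int(round(center[1]))
    trunk = (c_mid - half, c_mid + half)
    n_side = int(rng.integers(1, 5))
    cols = rng.choice(
        np.arange(trunk[0] + 4, trunk[1] - 3, 5), size=n_side, replace=False
    )
    branches = tuple(
        (int(c), -1 if i % 2 == 0 else 1, int(rng.integers(8, 17)))
        for i, c in enumerate(sorted(cols))
    )
    gap = float(rng.uniform(2.5, 6.0))
    axon = AxonSpec(
        stub_cols=(trunk[0] - 18, trunk[0] - 1),
        line_endpoints=(
            (trunk_row - gap / 2, trunk[0] - 10.0),
            (trunk_row + gap / 2, trunk[0] - 10.0),
        ),
    )
    return NMJSpec(
        clusters=clusters,
        tree=TreeSpec(trunk_row, trunk, branches),
        axon=axon,
        noise_sigma=0.0,
    )


def make_batch(
    n: int = 40, seed: int = 0
) -> list[tuple[ZStack, SyntheticGroundTruth]]:
    """Generate ``n`` noise-free randomised fixtures (the ``batch40`` preset)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = _random_spec(rng)
        out.append(generate_nmj(spec, seed=int(rng.integers(0, 2**31))))
    return out


def generate_failure_case(kind: str, seed: int) -> ZStack:
    """Fixtures engineered to trip segmentation/threshold QC.

    ``spiderweb``: the endplate is shattered into a lattice of tiny shards
    ('broken windows'), tripping both the particle-count and median-area
    heuristics. ``low_quality``: signal barely above a noisy background, so
    thresholding degenerates into speckle.
    """
    rng = np.random.default_rng(seed)
    base = nominal_spec(noise_sigma=0.0)
    shape = base.shape
    if kind == "spiderweb":
        plate = _disc(shape, (96, 96), 45)
        grid = np.zeros(shape, dtype=bool)
        grid[::5, :] = True
        grid[:, ::5] = True
        achr_structure = plate & ~grid
        spec = base
        nerve_structure = _rasterize_tree(shape, spec.tree)
        rr, cc = _draw_line(
            spec.tree.trunk_row, spec.axon.stub_cols[0],
            spec.tree.trunk_row, spec.axon.stub_cols[1],
        )
        nerve_structure[rr, cc] = True
        nerve_ch = _render_channel(nerve_structure, spec, rng)
        achr_ch = _render_channel(achr_structure, spec, rng)
    elif kind == "low_quality":
        shape_z = (base.n_slices, *shape)
        endplate, _full, nerve = render_masks(nominal_spec(noise_sigma=0.0))
        achr = np.full(shape_z, 25.0)
        achr[0][endplate.pixels] = 45.0
        achr += rng.normal(0, 18.0, size=shape_z)
        achr_ch = np.clip(achr, 0, 255).astype(np.uint8)
        nv = np.full(shape_z, 25.0)
        nv[0][nerve.pixels] = 45.0
        nv += rng.normal(0, 18.0, size=shape_z)
        nerve_ch = np.clip(nv, 0, 255).astype(np.uint8)
    else:
        raise ValueError(f"unknown failure kind {kind!r}")
    return ZStack(
        voxels=np.stack([nerve_ch, achr_ch]),
        calibration_um_per_px=base.calibration_um_per_px,
        channel_labels=["nerve", "achr"],
    )


def fixture_config(**overrides) -> RunConfig:
    """RunConfig matched to the fixture rendering (manual threshold halfway
    up the signal step, nerve on channel 0, AChR on channel 1)."""
    kwargs = dict(
        channel_map={"nerve": 0, "achr": 1},
        threshold_method="manual",
        threshold_value_nerve=FIXTURE_THRESHOLD,
        threshold_value_achr=FIXTURE_THRESHOLD,
    )
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def write_fixture(
    out_dir: str | Path, preset: str, seed: int
) -> list[Path]:
    """Materialise a preset as OME-TIFF + JSON truth sidecar (CLI helper)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_one(name: str, stack: ZStack, truth: SyntheticGroundTruth | None):
        tif = out_dir / f"{name}.ome.tif"
        write_stack(
            tif, stack.voxels, stack.calibration_um_per_px, stack.channel_labels
        )
        written.append(tif)
        if truth is not None:
            sidecar = out_dir / f"{name}.truth.json"
            payload = {
                "expected": {
                    k: v
                    for k, v in asdict(truth.expected).items()
                    if not isinstance(v, (list, tuple, dict)) or k == "qc_flags"
                },
                "axon": (
                    {
                        "line_endpoints": truth.axon_input.line_endpoints,
                        "erase_region": truth.axon_input.erase_region,
                    }
                    if truth.axon_input
                    else None
                ),
            }
            sidecar.write_text(json.dumps(payload, indent=2, default=list))
            written.append(sidecar)

    if preset in PRESETS:
        stack, truth = generate_nmj(PRESETS[preset](), seed)
        _write_one(preset, stack, truth)
    elif preset == "batch40":
        for i, (stack, truth) in enumerate(make_batch(40, seed)):
            _write_one(f"nmj{i:03d}", stack, truth)
    elif preset in ("spiderweb", "low_quality"):
        _write_one(preset, generate_failure_case(preset, seed), None)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    return written
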