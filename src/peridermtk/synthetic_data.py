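"""Synthetic fluorescence slides of suberin-stained roots with exact truth.

Real inputs are whole-slide scans of Fluorol-Yellow-stained Arabidopsis
roots: up to six gently curving root fragments mounted side by side,
hypocotyls toward one slide edge. The stain brightens suberized cell walls
in the green channel, and the two suberized tissues differ in cell shape —
the periderm (hypocotyl-proximal) shows a dense net of small irregular
cells, the endodermis (distal) long rectangular cells; short lateral-root
stubs may protrude. This module emulates exactly those features: each root
is a sinusoidally perturbed ribbon swept with a constant width, textured
with a jittered Voronoi cell net in the periderm zone and a sparse
rectangular wall grid in the endodermis zone, then Gaussian-blurred with
additive sensor noise (image only — the label mask is exact).

Ground truth is analytic: per-root centerline polylines with whole-root and
periderm arc lengths taken from the generating curve itself, so every
pipeline stage can be scored against known values. All outputs are pure
functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_formats import LabelMask, RasterImage

#: Slide canvas sizes (rows, cols): full microscope scale and the half-scale
#: default used for routine runs.
FULL_CANVAS = (14000, 10800)
HALF_CANVAS = (7000, 5400)

_BACKGROUND_LEVEL = 0.03
_INTERIOR_LEVEL = 0.35
_WALL_LEVEL = 0.92
_ENDO_WALL_LEVEL = 0.80
#: RGB weights of the green-dominant fluorescence palette.
_PALETTE = (0.38, 1.0, 0.16)


@dataclass(frozen=True)
class SyntheticRootSpec:
    """Geometry, texture and noise parameters of one synthetic root.

    Lengths are in pixels at half-scale (~1.9 um/px at full scale, twice
    that here). Defaults reflect a 14-day-old mounted root fragment: a few
    thousand px long, ~60 px wide, with the proximal third covered by
    periderm.
    """

    total_length: float = 4500.0
    width: float = 60.0
    periderm_fraction: float = 0.35
    curvature_amplitude: float = 100.0
    curvature_period: float = 2800.0
    periderm_cell_size: float = 14.0
    endoderm_cell_length: float = 90.0
    endoderm_cell_width: float = 20.0
    lateral_root_count: int = 1
    blur_sigma: float = 1.5
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_length < 10 * self.width:
            raise ValueError("total_length must be >= 10 x width")
        if not 0.0 <= self.periderm_fraction <= 1.0:
            raise ValueError("periderm_fraction must be in [0, 1]")
        if self.width < 5:
            raise ValueError("width must be >= 5 px")
        if self.curvature_amplitude < 0 or self.curvature_period <= 0:
            raise ValueError("curvature parameters must be non-negative / positive")


@dataclass
class SyntheticSlide:
    """A rendered slide with its exact mask and analytic truth table.

    ``truth`` has one row per root (root_index, periderm_px, whole_px);
    ``centerlines`` holds each root's generating polyline in slide
    coordinates, hypocotyl end first, in the same order.
    """

    image: RasterImage
    truth_mask: LabelMask
    truth: pd.DataFrame
    centerlines: list[np.ndarray]
    specs: list[SyntheticRootSpec]
    slide_id: str = "synthetic"


def _root_curve(spec: SyntheticRootSpec, phase: float) -> np.ndarray:
    """Dense (row, col) polyline of the generating curve, arc length == total_length."""
    # vertical march, 1 px in y per step; arc length accumulates faster
    # where the sinusoid bends, so overshoot generously then cut
    n = int(spec.total_length * 1.2) + 10
    y = np.arange(n, dtype=float)
    x = spec.curvature_amplitude * np.sin(2 * np.pi * y / spec.curvature_period + phase)
    pts = np.column_stack([y, x])
    steps = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    stop = int(np.searchsorted(cum, spec.total_length))
    stop = min(max(stop, 2), len(pts) - 1)
    return pts[: stop + 1]


def _polyline_cumlen(pts: np.ndarray) -> np.ndarray:
    steps = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    return np.concatenate([[0.0], np.cumsum(steps)])


def _render_root(
    spec: SyntheticRootSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Rasterize one root into a local tile.

    Returns (brightness tile float32, label tile uint8, polyline in tile
    coordinates, truth dict). Blur/noise are NOT applied here so that slides
    can be composed first and degraded once.
    """
    phase = rng.uniform(0, 2 * np.pi)
    curve = _root_curve(spec, phase)
    cum = _polyline_cumlen(curve)
    whole_px = float(cum[-1])
    periderm_px = float(spec.periderm_fraction * whole_px)

    half_w = spec.width / 2.0
    margin = int(np.ceil(half_w)) + 6
    if spec.lateral_root_count > 0:  # room for sideways stubs
        margin += int(np.ceil(3.2 * spec.width))
    r_off = margin - int(np.floor(curve[:, 0].min()))
    c_off = margin - int(np.floor(curve[:, 1].min()))
    curve = curve + np.array([r_off, c_off], dtype=float)
    H = int(np.ceil(curve[:, 0].max())) + margin + 1
    W = int(np.ceil(curve[:, 1].max())) + margin + 1

    # tangents and normals along the curve (for texture coordinates and laterals)
    tang = np.gradient(curve, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-9)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    tree = cKDTree(curve)
    rr, cc = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
    pix = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    dist, idx = tree.query(pix, k=1)
    dist = dist.reshape(H, W)
    idx = idx.reshape(H, W)
    arc = cum[idx]
    rel = pix.reshape(H, W, 2) - curve[idx]

    # flat-cut ends (the mounted fragment is scissor-cut): drop pixels whose
    # axial projection falls beyond the curve endpoints
    axial = rel[..., 0] * tang[idx][..., 0] + rel[..., 1] * tang[idx][..., 1]
    beyond = ((idx == 0) & (axial < 0)) | ((idx == len(curve) - 1) & (axial > 0))
    inside = (dist <= half_w) & ~beyond

    labels = np.zeros((H, W), dtype=np.uint8)
    labels[inside] = 2
    if periderm_px > 0:
        labels[inside & (arc <= periderm_px)] = 1

    # signed transverse offset u for the endodermis wall grid
    u = rel[..., 0] * normal[idx][..., 0] + rel[..., 1] * normal[idx][..., 1]

    bright = np.zeros((H, W), dtype=np.float32)
    bright[inside] = _INTERIOR_LEVEL

    # --- periderm texture: jittered Voronoi net of small irregular cells ---
    if periderm_px > 0:
        cell = spec.periderm_cell_size
        s_seeds = np.arange(cell / 2, periderm_px, cell)
        u_seeds = np.arange(-half_w + cell / 2, half_w, cell)
        seeds = []
        for s in s_seeds:
            i = int(np.searchsorted(cum, s))
            i = min(i, len(curve) - 1)
            for uu in u_seeds:
                jitter = rng.uniform(-0.35 * cell, 0.35 * cell, size=2)
                seeds.append(curve[i] + normal[i] * uu + jitter)
        if len(seeds) >= 2:
            seed_tree = cKDTree(np.asarray(seeds))
            peri_pix = np.argwhere(labels == 1).astype(float)
            d2, _ = seed_tree.query(peri_pix, k=2)
            wall = (d2[:, 1] - d2[:, 0]) < 1.6
            rr_p = peri_pix[wall].astype(int)
            bright[rr_p[:, 0], rr_p[:, 1]] = _WALL_LEVEL

    # --- endodermis texture: long rectangular cells ---
    endo = labels == 2
    cell_len = spec.endoderm_cell_length
    cell_w = spec.endoderm_cell_width
    s_phase = rng.uniform(0, cell_len)
    u_phase = rng.uniform(0, cell_w)
    transverse = np.mod(arc + s_phase, cell_len) < 1.6
    longitudinal = np.mod(u + half_w + u_phase, cell_w) < 1.4
    bright[endo & (transverse | longitudinal)] = _ENDO_WALL_LEVEL

    # outer wall of the whole root is strongly suberized -> bright outline
    outline = inside & (dist >= half_w - 1.8)
    bright[outline] = _WALL_LEVEL

    # --- lateral root stubs ---
    lat_margin = 0.15 * whole_px
    for _ in range(spec.lateral_root_count):
        if whole_px - periderm_px < 4 * spec.width:
            break  # no room distal of the periderm zone
        s0 = rng.uniform(periderm_px + lat_margin * 0.2, whole_px - lat_margin)
        i = min(int(np.searchsorted(cum, s0)), len(curve) - 1)
        side = rng.choice([-1.0, 1.0])
        length = rng.uniform(1.5 * spec.width, 3.0 * spec.width)
        w_lat = spec.width * 0.35
        t_lat = np.linspace(0, 1, int(length))
        stub = curve[i] + np.outer(t_lat * length, side * normal[i])
        ok = (stub[:, 0] > w_lat) & (stub[:, 0] < H - w_lat - 1)
        ok &= (stub[:, 1] > w_lat) & (stub[:, 1] < W - w_lat - 1)
        stub = stub[ok]
        if len(stub) < 2:
            continue
        stub_tree = cKDTree(stub)
        d_stub, _ = stub_tree.query(pix, k=1)
        d_stub = d_stub.reshape(H, W)
        stub_mask = (d_stub <= w_lat / 2) & (labels == 0)
        labels[stub_mask] = 3
        bright[stub_mask] = 0.55
        stub_outline = stub_mask & (d_stub >= w_lat / 2 - 1.6)
        bright[stub_outline] = _ENDO_WALL_LEVEL

    truth = {"periderm_px": periderm_px, "whole_px": whole_px}
    return bright, labels, curve, truth


def _degrade(bright: np.ndarray, blur_sigma: float, noise_sd: float,
             rng: np.random.Generator) -> np.ndarray:
    """Apply optics blur + sensor noise and convert to the RGB palette."""
    base = np.clip(bright + _BACKGROUND_LEVEL, 0, 1)
    if blur_sigma > 0:
        base = ndimage.gaussian_filter(base, blur_sigma, mode="reflect")
    out = np.empty(base.shape + (3,), dtype=np.uint8)
    for ch, weight in enumerate(_PALETTE):
        plane = base * weight * 255.0
        if noise_sd > 0:
            plane = plane + rng.normal(0.0, noise_sd, size=plane.shape)
        out[..., ch] = np.clip(np.round(plane), 0, 255).astype(np.uint8)
    return out


def generate_root(
    spec: SyntheticRootSpec, seed: int | None = None
) -> tuple[np.ndarray, LabelMask, dict]:
    """Render a single root tile with its exact mask and analytic lengths.

    Returns (RGB image tile, truth LabelMask, truth dict with
    ``periderm_px``, ``whole_px`` and the ``centerline`` polyline in tile
    coordinates). Blur and noise degrade the image only, never the mask.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    bright, labels, curve, truth = _render_root(spec, rng)
    image = _degrade(bright, spec.blur_sigma, spec.noise_sd, rng)
    truth = dict(truth, centerline=curve)
    return image, LabelMask(labels), truth


def default_slide_specs(
    n_roots: int, seed: int, canvas: tuple[int, int] = HALF_CANVAS
) -> list[SyntheticRootSpec]:
    """Draw per-root specs emulating natural variation between roots."""
    rng = np.random.default_rng(seed)
    max_len = canvas[0] - 400
    specs = []
    for k in range(n_roots):
        specs.append(
            SyntheticRootSpec(
                total_length=float(rng.uniform(0.55, 0.9) * max_len),
                width=float(rng.uniform(50, 70)),
                periderm_fraction=float(rng.uniform(0.25, 0.60)),
                curvature_amplitude=float(rng.uniform(60, 140)),
                curvature_period=float(rng.uniform(2200, 3600)),
                lateral_root_count=int(rng.integers(0, 3)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def generate_slide(
    n_roots: int = 6,
    specs: Sequence[SyntheticRootSpec] | None = None,
    seed: int = 0,
    canvas: tuple[int, int] = HALF_CANVAS,
    slide_id: str = "synthetic",
) -> SyntheticSlide:
    """Compose a whole synthetic slide of up to six non-overlapping roots.

    Roots hang from the top canvas edge (hypocotyls up), evenly spaced in
    columns left to right; root ids follow that order. Raises when the
    requested roots cannot be packed without overlap. Bit-identical output
    for identical (specs, seed).
    """
    if not 1 <= n_roots <= 6:
        raise ValueError("a slide holds between 1 and 6 roots")
    rng = np.random.default_rng(seed)
    if specs is None:
        specs = default_slide_specs(n_roots, seed, canvas)
    specs = list(specs)
    if len(specs) != n_roots:
        raise ValueError("need one spec per root")
    H, W = canvas
    slot = W / n_roots
    for spec in specs:
        if 2 * (spec.curvature_amplitude + spec.width) + 20 > slot:
            raise ValueError(
                f"infeasible packing: root needs {2 * (spec.curvature_amplitude + spec.width):.0f} px "
                f"of slot width, only {slot:.0f} available"
            )
        if spec.total_length + 200 > H:
            raise ValueError("infeasible packing: root longer than the canvas")

    bright = np.full((H, W), 0.0, dtype=np.float32)
    labels = np.zeros((H, W), dtype=np.uint8)
    rows = []
    centerlines = []
    for k, spec in enumerate(specs):
        tile_b, tile_l, curve, truth = _render_root(spec, np.random.default_rng(spec.seed))
        th, tw = tile_l.shape
        r0 = int(rng.uniform(30, 120))
        c_center = int((k + 0.5) * slot)
        c0 = c_center - tw // 2
        c0 = max(0, min(c0, W - tw))
        if r0 + th > H:
            raise ValueError("infeasible packing: root tile exceeds canvas height")
        region = (slice(r0, r0 + th), slice(c0, c0 + tw))
        paste = tile_l != 0
        if (labels[region][paste] != 0).any():
            raise ValueError("infeasible packing: roots overlap")
        labels[region][paste] = tile_l[paste]
        bright[region] = np.maximum(bright[region], tile_b)
        centerlines.append(curve + np.array([r0, c0], dtype=float))
        rows.append(
            {
                "root_index": k + 1,
                "periderm_px": truth["periderm_px"],
                "whole_px": truth["whole_px"],
            }
        )
    blur = float(np.mean([s.blur_sigma for s in specs]))
    noise = float(np.mean([s.noise_sd for s in specs]))
    image = _degrade(bright, blur, noise, rng)
    return SyntheticSlide(
        image=RasterImage(image, source_path=f"{slide_id} (synthetic)"),
        truth_mask=LabelMask(labels),
        truth=pd.DataFrame(rows),
        centerlines=centerlines,
        specs=specs,
        slide_id=slide_id,
    )


# ---------------------------------------------------------------------------
# fixture maker: planted defects for the postprocessing rule tests
# ---------------------------------------------------------------------------

def _root_arc_map(slide: SyntheticSlide, root_index: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(pixel coords, arc position, distance) of the root's labeled pixels."""
    curve = slide.centerlines[root_index - 1]
    cum = _polyline_cumlen(curve)
    spec = slide.specs[root_index - 1]
    reach = spec.width / 2 + 2
    r0 = max(0, int(curve[:, 0].min() - reach))
    r1 = min(slide.truth_mask.height, int(curve[:, 0].max() + reach) + 1)
    c0 = max(0, int(curve[:, 1].min() - reach))
    c1 = min(slide.truth_mask.width, int(curve[:, 1].max() + reach) + 1)
    window = slide.truth_mask.labels[r0:r1, c0:c1]
    coords = np.argwhere(window != 0) + np.array([r0, c0])
    dist, idx = cKDTree(curve).query(coords.astype(float), k=1)
    return coords, cum[idx], dist


def corrupt_mask(
    slide: SyntheticSlide,
    gap_spans: Sequence[tuple[int, float, float]] = (),
    hole_specs: Sequence[tuple[int, float, float]] = (),
    seed: int = 0,
) -> LabelMask:
    """Plant controlled defects in a truth mask for postprocessing tests.

    ``gap_spans`` are (root_index, start_arc_px, length_px): periderm pixels
    whose centerline arc position falls in the span are relabeled endoderm,
    simulating a mis-segmented stretch. ``hole_specs`` are (root_index,
    center_arc_px, radius_px): a disk around the centerline is relabeled
    background, simulating a small interior dropout. Spans or holes outside
    the periderm zone raise.
    """
    out = LabelMask(slide.truth_mask.labels.copy())
    for root_index, start, length in gap_spans:
        peri_end = float(slide.truth[slide.truth.root_index == root_index].periderm_px.iloc[0])
        if not (0 <= start and start + length <= peri_end):
            raise ValueError(
                f"gap span [{start}, {start + length}] outside periderm [0, {peri_end:.0f}]"
            )
        coords, arc, _ = _root_arc_map(slide, root_index)
        sel = (arc >= start) & (arc < start + length)
        sel &= out.labels[coords[:, 0], coords[:, 1]] == 1
        out.labels[coords[sel, 0], coords[sel, 1]] = 2
    for root_index, center, radius in hole_specs:
        peri_end = float(slide.truth[slide.truth.root_index == root_index].periderm_px.iloc[0])
        spec = slide.specs[root_index - 1]
        if not (radius < center < peri_end - radius):
            raise ValueError("hole is not inside the periderm zone")
        if radius + 2 > spec.width / 2:
            raise ValueError("hole radius too large to stay inside the periderm")
        coords, arc, _ = _root_arc_map(slide, root_index)
        curve = slide.centerlines[root_index - 1]
        cum = _polyline_cumlen(curve)
        center_pt = curve[min(int(np.searchsorted(cum, center)), len(curve) - 1)]
        d = np.hypot(coords[:, 0] - center_pt[0], coords[:, 1] - center_pt[1])
        sel = d <= radius
        if (out.labels[coords[sel, 0], coords[sel, 1]] != 1).any():
            raise ValueError("hole span touches non-periderm pixels")
        out.labels[coords[sel, 0], coords[sel, 1]] = 0
    return out


def make_patch_dataset(
    slides: Sequence[SyntheticSlide], patch_size: int = 1024
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Tile slides (image + truth mask) into paired training patches."""
    from .tiling import TilingConfig, tile_image

    cfg = TilingConfig(patch_size=patch_size)
    images, masks = [], []
    for slide in slides:
        _, img_patches = tile_image(slide.image, cfg)
        _, mask_patches = tile_image(slide.truth_mask, cfg)
        images.extend(img_patches)
        masks.extend(mask_patches)
    return images, masks
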