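"""Per-root cleanup of stitched prediction masks.

Periderm is biologically contiguous from the hypocotyl downwards, so the
raw model output is corrected per root:

* small gaps (up to 150 px along the centerline) between consecutive
  periderm runs are bridged — the gap is relabeled periderm;
* at the first larger gap, everything periderm distal to it is treated as
  spurious and relabeled endodermis, leaving a single periderm run anchored
  at the hypocotyl end;
* tiny non-periderm holes (area below 20 px) fully enclosed in the periderm
  region are closed.

Gap distances are measured as Euclidean arc length along the root
centerline, because the trait of interest is length along the root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from skimage.measure import label as cc_label

from .io_formats import LabelMask
from .measurement import arc_positions, compute_centerline, orient_centerline

logger = logging.getLogger(__name__)

PERIDERM, ENDODERM, LATERAL = 1, 2, 3


@dataclass(frozen=True)
class PostprocessConfig:
    """Thresholds of the mask-cleanup rules (pixels).

    ``bridge_max_gap``: largest centerline gap between periderm runs that is
    still bridged (a gap of exactly this size is bridged). ``hole_max``:
    holes strictly smaller than this are closed. ``min_root_area``: connected
    components below this area are discarded as staining debris.
    """

    bridge_max_gap: float = 150.0
    hole_max: int = 20
    min_root_area: int = 5000
    hypocotyl_edge: str = "top"

    def __post_init__(self) -> None:
        if not self.bridge_max_gap > self.hole_max > 0:
            raise ValueError("must satisfy bridge_max_gap > hole_max > 0")


@dataclass
class RootInstance:
    """One connected root: its pixels and its oriented centerline.

    ``root_id`` is 1-based, assigned left-to-right by hypocotyl position.
    ``pixel_coords`` are the (row, col) coordinates of every non-background
    pixel of the component. The centerline runs from the hypocotyl-proximal
    endpoint distally.
    """

    root_id: int
    slide_id: str
    pixel_coords: np.ndarray
    centerline: np.ndarray
    _assignment: np.ndarray | None = field(default=None, repr=False)

    @property
    def area(self) -> int:
        return len(self.pixel_coords)

    def centerline_assignment(self) -> np.ndarray:
        """Index of the nearest centerline point for each root pixel."""
        if self._assignment is None:
            tree = cKDTree(self.centerline.astype(float))
            _, idx = tree.query(self.pixel_coords.astype(float), k=1)
            self._assignment = np.asarray(idx, dtype=np.int64)
        return self._assignment


@dataclass(frozen=True)
class PeridermSegment:
    """A maximal periderm-labeled run along a root centerline (inclusive)."""

    start_index: int
    end_index: int
    length_px: float

    def __post_init__(self) -> None:
        if self.start_index > self.end_index:
            raise ValueError("segment must satisfy start <= end")


def extract_root_instances(
    mask: LabelMask,
    config: PostprocessConfig | None = None,
    slide_id: str = "",
    expected_n_roots: int | None = None,
) -> list[RootInstance]:
    """Find individual roots in a slide mask.

    8-connected components of the non-background pixels; components smaller
    than ``min_root_area`` are discarded as debris. Roots are numbered by the
    position of their hypocotyl end along the hypocotyl edge (left to right
    for top/bottom mounting). An empty mask yields an empty list.
    """
    config = config or PostprocessConfig()
    binary = mask.labels != 0
    labeled, n = cc_label(binary, connectivity=2, return_num=True)
    if n == 0:
        logger.info("slide %s: no root components found", slide_id)
        return []
    roots: list[RootInstance] = []
    areas = np.bincount(labeled.ravel())
    for comp in range(1, n + 1):
        if areas[comp] < config.min_root_area:
            continue
        coords = np.argwhere(labeled == comp)
        line = compute_centerline(labeled == comp)
        line = orient_centerline(line, config.hypocotyl_edge)
        roots.append(RootInstance(0, slide_id, coords.astype(np.int32), line))
    if expected_n_roots is not None and len(roots) != expected_n_roots:
        logger.warning(
            "slide %s: found %d roots, expected %d — check spacing/overlap",
            slide_id, len(roots), expected_n_roots,
        )
    # order by hypocotyl-end position along the mounting edge
    across_axis = 1 if config.hypocotyl_edge in ("top", "bottom") else 0
    roots.sort(key=lambda r: (r.centerline[0][across_axis], r.centerline[0][1 - across_axis]))
    for i, root in enumerate(roots, start=1):
        root.root_id = i
    return roots


def project_segments(root: RootInstance, mask: LabelMask) -> list[PeridermSegment]:
    """Project the mask onto the centerline and return periderm runs.

    Each centerline position is periderm iff the non-background pixels of
    its local cross-section (the root pixels nearest to it) are majority
    periderm (ties count as periderm). Maximal runs are returned in
    centerline order with their arc lengths.
    """
    if len(root.centerline) == 0:
        raise ValueError(f"root {root.root_id} has an empty centerline")
    labels = mask.labels[root.pixel_coords[:, 0], root.pixel_coords[:, 1]]
    assign = root.centerline_assignment()
    n = len(root.centerline)
    nonbg = labels != 0
    total = np.bincount(assign[nonbg], minlength=n)
    peri = np.bincount(assign[labels == PERIDERM], minlength=n)
    is_peri = (total > 0) & (peri * 2 >= total)
    return _runs_to_segments(is_peri, arc_positions(root.centerline))


def _runs_to_segments(is_peri: np.ndarray, cum: np.ndarray) -> list[PeridermSegment]:
    segments = []
    idx = np.flatnonzero(is_peri)
    if idx.size == 0:
        return segments
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    for s, e in zip(starts, ends):
        a, b = int(idx[s]), int(idx[e])
        segments.append(PeridermSegment(a, b, float(cum[b] - cum[a])))
    return segments


def bridge_and_relabel(
    root: RootInstance,
    segments: list[PeridermSegment],
    mask: LabelMask,
    config: PostprocessConfig | None = None,
) -> tuple[list[PeridermSegment], LabelMask]:
    """Merge near periderm runs and drop spurious distal ones.

    Scanning from the hypocotyl-proximal end: consecutive runs whose
    centerline gap is at most ``bridge_max_gap`` are merged, and the
    endoderm-labeled pixels of the gap cross-sections are relabeled
    periderm. At the first larger gap, the periderm pixels of every distal
    run are relabeled endoderm. The result is at most one periderm run,
    anchored at the hypocotyl end. Idempotent.
    """
    config = config or PostprocessConfig()
    out = LabelMask(mask.labels.copy())
    if not segments:
        return [], out
    cum = arc_positions(root.centerline)
    assign = root.centerline_assignment()
    rows, cols = root.pixel_coords[:, 0], root.pixel_coords[:, 1]

    def relabel(line_lo: int, line_hi: int, from_class: int, to_class: int) -> int:
        """Relabel pixels of cross-sections line_lo..line_hi (inclusive)."""
        sel = (assign >= line_lo) & (assign <= line_hi)
        sel &= out.labels[rows, cols] == from_class
        out.labels[rows[sel], cols[sel]] = to_class
        return int(sel.sum())

    merged_end = segments[0].end_index
    n_bridged = n_dropped = 0
    cut = None
    for seg in segments[1:]:
        gap = cum[seg.start_index] - cum[merged_end]
        if gap <= config.bridge_max_gap:
            relabel(merged_end + 1, seg.start_index - 1, ENDODERM, PERIDERM)
            merged_end = seg.end_index
            n_bridged += 1
        else:
            cut = seg.start_index
            break
    if cut is not None:
        n_dropped = relabel(cut, len(root.centerline) - 1, PERIDERM, ENDODERM)
    if n_bridged or n_dropped:
        logger.info(
            "root %s/%s: bridged %d gap(s), relabeled %d distal periderm px",
            root.slide_id, root.root_id, n_bridged, n_dropped,
        )
    start = segments[0].start_index
    run = PeridermSegment(start, merged_end, float(cum[merged_end] - cum[start]))
    return [run], out


def close_small_holes(
    mask: LabelMask, root: RootInstance, hole_max: int = 20
) -> LabelMask:
    """Fill tiny holes enclosed in the root's periderm region.

    Connected non-periderm pockets of area strictly below ``hole_max`` that
    are fully surrounded by this root's periderm are relabeled periderm;
    larger holes are left untouched. Idempotent on hole-free masks.
    """
    out = LabelMask(mask.labels.copy())
    r0, c0 = root.pixel_coords.min(axis=0)
    r1, c1 = root.pixel_coords.max(axis=0) + 1
    window = out.labels[r0:r1, c0:c1]
    peri = window == PERIDERM
    if not peri.any():
        return out
    # complement components that do not touch the window border are holes
    # (background is 4-connected, dual to the 8-connected periderm)
    holes, n = cc_label(~peri, connectivity=1, return_num=True, background=0)
    if n == 0:
        return out
    border = np.zeros_like(peri)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_ids = np.unique(holes[border & ~peri])
    areas = np.bincount(holes.ravel())
    filled = 0
    for comp in range(1, n + 1):
        if comp in border_ids or areas[comp] >= hole_max:
            continue
        window[holes == comp] = PERIDERM
        filled += int(areas[comp])
    if filled:
        logger.info("root %s/%s: filled %d hole px", root.slide_id, root.root_id, filled)
    return out


def postprocess_slide(
    mask: LabelMask,
    config: PostprocessConfig | None = None,
    slide_id: str = "",
    expected_n_roots: int | None = None,
) -> tuple[LabelMask, list[RootInstance]]:
    """Run the full cleanup over every root of a slide mask."""
    config = config or PostprocessConfig()
    roots = extract_root_instances(mask, config, slide_id, expected_n_roots)
    out = LabelMask(mask.labels.copy())
    for root in roots:
        segments = project_segments(root, out)
        _, out = bridge_and_relabel(root, segments, out, config)
        out = close_small_holes(out, root, config.hole_max)
    return out, roots
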