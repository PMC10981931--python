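"""Quality control: transition-zone inspection images and selection filtering.

Whether a root was segmented well is easiest to judge at the transition
point where the periderm run gives way to endodermis. For each root a QC
image is written: the original image and the class-colored segmentation,
cropped 1,500 px on either side of the transition point and stacked
vertically. A human inspects the crops and lists the (slide, root) pairs to
keep in a plain-text selection file; applying the selection filters the
measurement tables into the ``*_after_QC_*`` CSVs. QC never modifies masks
or measurements — it only selects rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import LabelMask, MeasurementTable, RasterImage, write_png
from .postprocess import RootInstance, project_segments

logger = logging.getLogger(__name__)

#: Class colors for rendered overlays (background, periderm, endoderm, lateral).
OVERLAY_PALETTE = np.array(
    [[0, 0, 0], [90, 200, 255], [30, 60, 200], [60, 200, 80]], dtype=np.uint8
)

DEFAULT_QC_MARGIN = 1500


@dataclass(frozen=True)
class TransitionPoint:
    """Distal end of a root's periderm run, on the centerline."""

    root_id: int
    centerline_index: int
    coordinate: tuple[int, int]  # (row, col)


@dataclass
class QCImage:
    """Original and segmented crops around one transition point, stacked."""

    root_id: int
    original_crop: np.ndarray
    segmented_crop: np.ndarray

    def stacked(self) -> np.ndarray:
        if self.original_crop.shape != self.segmented_crop.shape:
            raise ValueError("crops must have identical dimensions")
        return np.concatenate([self.original_crop, self.segmented_crop], axis=0)


def render_mask_rgb(mask: LabelMask) -> np.ndarray:
    """Color-render a label mask with the overlay palette."""
    return OVERLAY_PALETTE[mask.labels]


def find_transition(root: RootInstance, mask: LabelMask) -> TransitionPoint | None:
    """Locate the periderm-to-endodermis transition of a post-processed root.

    Returns the distal endpoint of the single periderm run, or None (and a
    log flag) when the root has no periderm at all. A fully-periderm root
    transitions at the distal centerline endpoint.
    """
    segments = project_segments(root, mask)
    if not segments:
        logger.warning(
            "root %s/%s has no periderm run; flagged for QC", root.slide_id, root.root_id
        )
        return None
    end = segments[0].end_index
    coord = tuple(int(v) for v in root.centerline[end])
    return TransitionPoint(root.root_id, end, coord)


def make_qc_image(
    original: RasterImage | np.ndarray,
    segmented: LabelMask | np.ndarray,
    point: TransitionPoint,
    margin: int = DEFAULT_QC_MARGIN,
) -> QCImage:
    """Crop a square window around the transition and stack original over mask.

    The window spans ``point +- margin`` along both slide axes, clipped at
    the image borders; both crops share the same window so their dimensions
    match.
    """
    img = original.pixels if isinstance(original, RasterImage) else np.asarray(original)
    seg = render_mask_rgb(segmented) if isinstance(segmented, LabelMask) else np.asarray(segmented)
    if img.shape[:2] != seg.shape[:2]:
        raise ValueError("original and segmented images must share dimensions")
    H, W = img.shape[:2]
    r, c = point.coordinate
    if not (0 <= r < H and 0 <= c < W):
        raise ValueError(f"transition point {point.coordinate} outside image {H}x{W}")
    r0, r1 = max(0, r - margin), min(H, r + margin + 1)
    c0, c1 = max(0, c - margin), min(W, c + margin + 1)
    return QCImage(point.root_id, img[r0:r1, c0:c1].copy(), seg[r0:r1, c0:c1].copy())


def write_qc_images(
    original: RasterImage,
    mask: LabelMask,
    roots: list[RootInstance],
    out_dir: str | Path,
    slide_id: str,
    margin: int = DEFAULT_QC_MARGIN,
) -> list[Path]:
    """Write one stacked QC PNG per root with a periderm run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for root in roots:
        point = find_transition(root, mask)
        if point is None:
            continue
        qc = make_qc_image(original, mask, point, margin)
        paths.append(write_png(qc.stacked(), out_dir / f"{slide_id}_root{root.root_id}_qc.png"))
    return paths


@dataclass
class SelectionList:
    """Retained (slide_id, root_index) pairs from human QC."""

    pairs: list[tuple[str, int]]

    @classmethod
    def read(cls, path: str | Path) -> "SelectionList":
        pairs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            slide_id, root_index = line.rsplit(",", 1)
            pairs.append((slide_id.strip(), int(root_index)))
        return cls(pairs)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("".join(f"{s},{r}\n" for s, r in self.pairs))
        return path


def apply_selection(
    measurements: MeasurementTable, selection: SelectionList
) -> MeasurementTable:
    """Filter a measurement table down to the QC-retained roots.

    Selection pairs absent from the table are ignored with a warning; the
    result is always a subset of the input with identical values and is
    flagged ``after_qc`` so it writes to the ``*_after_QC_*`` CSV names.
    """
    table_pairs = set(
        zip(measurements.data["slide_id"].astype(str), measurements.data["root_index"])
    )
    unknown = [p for p in selection.pairs if p not in table_pairs]
    if unknown:
        logger.warning("selection pairs not present in the table (ignored): %s", unknown)
    keep = set(selection.pairs) - set(unknown)
    mask = [
        (str(s), r) in keep
        for s, r in zip(measurements.data["slide_id"], measurements.data["root_index"])
    ]
    return MeasurementTable(
        measurements.data[mask].reset_index(drop=True),
        quantity=measurements.quantity,
        unit=measurements.unit,
        after_qc=True,
    )
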