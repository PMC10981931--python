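"""Reading and writing of slide images, polygon annotations, label masks and CSV outputs.

Slide images are stitched whole-slide fluorescence micrographs (TIFF or PNG,
roughly 14,000 x 10,800 px at full scale). Annotations follow the labelme
JSON dialect: a ``shapes`` list of polygons, each with a tissue-class
``label`` and a list of ``points`` in (x, y) pixel coordinates. Label masks
are per-pixel class maps over the four tissue classes.

Coordinate convention: arrays are indexed 0-based as (row, col) = (y, x);
polygon vertices are stored as (x, y) to match the annotation dialect, and
the conversion happens only inside :func:`rasterize_annotations`.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import tifffile
from PIL import Image

logger = logging.getLogger(__name__)

#: Class codes shared by every mask in the pipeline.
CLASS_MAP: dict[int, str] = {
    0: "background",
    1: "periderm",
    2: "endoderm",
    3: "lateral_root",
}

#: Inverse lookup: tissue name -> class code.
LABEL_TO_CODE: dict[str, int] = {name: code for code, name in CLASS_MAP.items()}

#: Tissue classes that annotation polygons may carry (background is implicit).
ANNOTATION_LABELS = ("periderm", "endoderm", "lateral_root")


class DecodeError(RuntimeError):
    """Raised when an image file cannot be decoded."""


@dataclass
class RasterImage:
    """An 8-bit RGB raster with provenance.

    Grayscale sources are replicated to three channels on read so that every
    downstream stage can assume H x W x 3 uint8.
    """

    pixels: np.ndarray
    source_path: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"RasterImage requires HxWx3 pixels, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("RasterImage must be at least 1x1")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class LabelMask:
    """Per-pixel tissue class map for a slide or patch."""

    labels: np.ndarray
    class_map: dict[int, str] = field(default_factory=lambda: dict(CLASS_MAP))

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValueError(f"LabelMask requires an HxW array, got shape {lab.shape}")
        if lab.size and not np.isin(np.unique(lab), list(self.class_map)).all():
            raise ValueError(
                f"LabelMask values must be in {sorted(self.class_map)}; "
                f"found {np.unique(lab).tolist()}"
            )
        self.labels = lab.astype(np.uint8, copy=False)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def class_pixel_counts(self) -> dict[int, int]:
        counts = np.bincount(self.labels.ravel(), minlength=len(self.class_map))
        return {code: int(counts[code]) for code in self.class_map}


@dataclass
class AnnotationDocument:
    """Polygonal ground-truth annotation for one slide image.

    ``polygons`` is an ordered list of ``(class_label, vertices)`` where
    vertices are (x, y) pixel coordinates. Order matters: later polygons
    overwrite earlier ones when rasterized, matching interactive annotation.
    """

    polygons: list[tuple[str, np.ndarray]]
    image_height: int
    image_width: int

    def __post_init__(self) -> None:
        clean: list[tuple[str, np.ndarray]] = []
        for label, verts in self.polygons:
            if label not in ANNOTATION_LABELS:
                raise ValueError(
                    f"unknown class label {label!r}; accepted labels: {ANNOTATION_LABELS}"
                )
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
                raise ValueError("each polygon needs >= 3 (x, y) vertices")
            clean.append((label, verts))
        self.polygons = clean


@dataclass(frozen=True)
class ScaleConfig:
    """Pixel-to-micrometer calibration, Fiji "Set Scale" style.

    ``pixel_distance`` pixels correspond to ``known_distance`` micrometers,
    i.e. micrometers_per_pixel = known_distance / pixel_distance. The default
    (0.5299 px per 1.00 um) is the calibration of the 4x objective scans the
    pipeline was designed around.
    """

    pixel_distance: float = 0.5299
    known_distance: float = 1.00
    pixel_aspect_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.pixel_distance <= 0 or self.known_distance <= 0:
            raise ValueError("pixel_distance and known_distance must be positive")
        if self.pixel_aspect_ratio != 1.0:
            raise ValueError(
                "non-square pixels (pixel_aspect_ratio != 1) are not supported"
            )

    @property
    def micrometers_per_pixel(self) -> float:
        return self.known_distance / self.pixel_distance


#: CSV quantities and units accepted by :func:`write_measurements_csv`.
_QUANTITIES = ("periderm_length", "whole_root_length")
_UNITS = ("pixels", "micrometers")


@dataclass
class MeasurementTable:
    """Per-root values of one quantity in one unit.

    Wraps a DataFrame with columns ``slide_id, root_index, value``.
    """

    data: pd.DataFrame
    quantity: str
    unit: str
    after_qc: bool = False

    def __post_init__(self) -> None:
        if self.quantity not in _QUANTITIES:
            raise ValueError(f"quantity must be one of {_QUANTITIES}")
        if self.unit not in _UNITS:
            raise ValueError(f"unit must be one of {_UNITS}")
        df = pd.DataFrame(self.data, columns=["slide_id", "root_index", "value"])
        if (df["value"] < 0).any():
            raise ValueError("measurement values must be >= 0")
        if df.duplicated(["slide_id", "root_index"]).any():
            raise ValueError("root_index must be unique per slide")
        self.data = df.reset_index(drop=True)

    @property
    def filename(self) -> str:
        qc = "_after_QC" if self.after_qc else ""
        return f"{self.quantity}{qc}_{self.unit}.csv"

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# image reading / conversion
# ---------------------------------------------------------------------------

def _decode(path: Path) -> np.ndarray:
    """Decode TIFF/PNG/JPEG into a numpy array, raising DecodeError on failure."""
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            return np.asarray(tifffile.imread(path))
        with Image.open(path) as im:
            return np.asarray(im)
    except Exception as exc:  # noqa: BLE001 - rewrap with the offending path
        raise DecodeError(f"cannot decode image file {path}: {exc}") from exc


def _to_rgb8(arr: np.ndarray, origin: str) -> np.ndarray:
    """Coerce a decoded array to HxWx3 uint8, rescaling high bit depths."""
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise DecodeError(f"unsupported image shape {arr.shape} in {origin}")
    if arr.shape[2] == 4:  # drop alpha
        arr = arr[..., :3]
    if arr.shape[2] != 3:
        raise DecodeError(f"unsupported channel count {arr.shape[2]} in {origin}")
    if arr.dtype == np.uint8:
        return arr
    # >8-bit input: linear min-max rescale to 8-bit
    arr = arr.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    logger.warning(
        "rescaling %s from %s to 8-bit via linear min-max [%g, %g]",
        origin, arr.dtype, lo, hi,
    )
    if hi > lo:
        arr = (arr - lo) / (hi - lo) * 255.0
    else:
        arr = np.zeros_like(arr)
    return np.round(arr).astype(np.uint8)


def read_image(path: str | Path) -> RasterImage:
    """Read a TIFF/PNG/JPEG image as 8-bit RGB."""
    path = Path(path)
    if not path.exists():
        raise DecodeError(f"image file does not exist: {path}")
    arr = _to_rgb8(_decode(path), str(path))
    return RasterImage(arr, source_path=str(path))


def write_png(image: RasterImage | np.ndarray, path: str | Path) -> Path:
    """Write an RGB image (or a bare array) as PNG."""
    arr = image.pixels if isinstance(image, RasterImage) else np.asarray(image)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(arr.astype(np.uint8, copy=False)).save(path, format="PNG")
    return path


def convert_to_png(src_path: str | Path, out_dir: str | Path | None = None) -> Path:
    """Convert a TIFF/JPEG slide image to lossless 8-bit RGB PNG.

    Already-PNG inputs are copied through unchanged (or returned in place
    when no ``out_dir`` is given). 16-bit inputs are linearly rescaled with
    a logged warning. Returns the path of the PNG.
    """
    src = Path(src_path)
    if not src.exists():
        raise DecodeError(f"image file does not exist: {src}")
    dest_dir = Path(out_dir) if out_dir is not None else src.parent
    dest = dest_dir / (src.stem + ".png")
    if src.suffix.lower() == ".png":
        if dest.resolve() == src.resolve():
            _decode(src)  # still validate that it decodes
            return src
        dest_dir.mkdir(parents=True, exist_ok=True)
        shutil.copyfile(src, dest)
        return dest
    image = read_image(src)
    return write_png(image, dest)


def write_mask_png(mask: LabelMask, path: str | Path) -> Path:
    """Write a label mask as a grayscale PNG of raw class codes (lossless)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(mask.labels, mode="L").save(path, format="PNG")
    return path


def read_mask_png(path: str | Path) -> LabelMask:
    """Read back a class-code grayscale PNG written by :func:`write_mask_png`."""
    with Image.open(path) as im:
        return LabelMask(np.asarray(im.convert("L")))


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path) -> AnnotationDocument:
    """Read a labelme-dialect JSON annotation file."""
    with open(path) as fh:
        doc = json.load(fh)
    polygons = []
    for shape in doc.get("shapes", []):
        if shape.get("shape_type", "polygon") != "polygon":
            logger.warning("skipping non-polygon shape %r in %s", shape.get("label"), path)
            continue
        polygons.append((shape["label"], np.asarray(shape["points"], dtype=float)))
    return AnnotationDocument(
        polygons=polygons,
        image_height=int(doc["imageHeight"]),
        image_width=int(doc["imageWidth"]),
    )


def write_annotations(doc: AnnotationDocument, path: str | Path) -> Path:
    """Write an AnnotationDocument as labelme-dialect JSON."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "version": "5.0.0",
        "flags": {},
        "shapes": [
            {
                "label": label,
                "points": np.asarray(verts, dtype=float).tolist(),
                "group_id": None,
                "shape_type": "polygon",
                "flags": {},
            }
            for label, verts in doc.polygons
        ],
        "imagePath": "",
        "imageData": None,
        "imageHeight": doc.image_height,
        "imageWidth": doc.image_width,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
    return path


def _polygon_interior(verts: np.ndarray, height: int, width: int) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    Even-odd (crossing-number) rule on pixel centers at integer (x, y)
    coordinates; handles self-intersecting polygons. Vectorized over the
    polygon's bounding box.
    """
    xs, ys = verts[:, 0], verts[:, 1]
    c0 = max(0, int(np.floor(xs.min())))
    c1 = min(width - 1, int(np.ceil(xs.max())))
    r0 = max(0, int(np.floor(ys.min())))
    r1 = min(height - 1, int(np.ceil(ys.max())))
    out = np.zeros((height, width), dtype=bool)
    if c1 < c0 or r1 < r0:
        return out
    px = np.arange(c0, c1 + 1, dtype=float)
    py = np.arange(r0, r1 + 1, dtype=float)
    X, Y = np.meshgrid(px, py)
    inside = np.zeros(X.shape, dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = xs[i], ys[i]
        x2, y2 = xs[(i + 1) % n], ys[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edge never crosses a horizontal ray test line
        cond = (Y >= min(y1, y2)) & (Y < max(y1, y2))
        x_at = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= cond & (X < x_at)
    out[r0 : r1 + 1, c0 : c1 + 1] = inside
    return out


def _is_self_intersecting(verts: np.ndarray) -> bool:
    """Naive segment-pair intersection test (polygons are small)."""

    def seg_cross(p, q, r, s) -> bool:
        def orient(a, b, c):
            return np.sign((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))

        return (
            orient(p, q, r) != orient(p, q, s)
            and orient(r, s, p) != orient(r, s, q)
            and orient(p, q, r) != 0
            and orient(p, q, s) != 0
        )

    n = len(verts)
    edges = [(verts[i], verts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through closure
            if seg_cross(*edges[i], *edges[j]):
                return True
    return False


def rasterize_annotations(doc: AnnotationDocument) -> LabelMask:
    """Rasterize annotation polygons into a label mask.

    Pixels whose centers fall inside a polygon get that polygon's class code;
    later polygons overwrite earlier ones (last drawn wins); everything else
    is background. Self-intersecting polygons are filled with the even-odd
    rule and logged.
    """
    labels = np.zeros((doc.image_height, doc.image_width), dtype=np.uint8)
    for label, verts in doc.polygons:
        if _is_self_intersecting(verts):
            logger.warning("self-intersecting %s polygon; using even-odd fill", label)
        interior = _polygon_interior(verts, doc.image_height, doc.image_width)
        labels[interior] = LABEL_TO_CODE[label]
    return LabelMask(labels)


def mask_to_annotations(mask: LabelMask) -> AnnotationDocument:
    """Trace class-region boundaries back into polygon annotations.

    Inverse of :func:`rasterize_annotations` for simply-connected regions:
    iso-contours at level 0.5 of each class's indicator image sit half a
    pixel outside the pixel centers, so re-rasterizing with the pixel-center
    even-odd rule reproduces the region.
    """
    from skimage import measure

    polygons: list[tuple[str, np.ndarray]] = []
    for code, name in CLASS_MAP.items():
        if code == 0:
            continue
        indicator = (mask.labels == code).astype(float)
        if not indicator.any():
            continue
        for contour in measure.find_contours(indicator, 0.5, fully_connected="high"):
            if len(contour) < 3:
                continue
            # find_contours yields (row, col); annotations store (x, y)
            polygons.append((name, contour[:, ::-1].copy()))
    return AnnotationDocument(polygons, mask.height, mask.width)


# ---------------------------------------------------------------------------
# measurement CSVs
# ---------------------------------------------------------------------------

def write_measurements_csv(table: MeasurementTable, out_dir: str | Path) -> Path:
    """Write a measurement table to its canonically named CSV.

    File names follow the fixed convention, e.g.
    ``periderm_length_micrometers.csv`` or
    ``periderm_length_after_QC_pixels.csv``. An empty (post-QC) table yields
    a header-only file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / table.filename
    table.data.to_csv(path, index=False, lineterminator="\r\n", float_format="%.6f")
    return path


def read_measurements_csv(path: str | Path) -> MeasurementTable:
    """Read back a canonically named measurement CSV."""
    path = Path(path)
    name = path.stem
    after_qc = "_after_QC" in name
    name = name.replace("_after_QC", "")
    for quantity in _QUANTITIES:
        if name.startswith(quantity):
            unit = name[len(quantity) + 1 :]
            break
    else:
        raise ValueError(f"cannot infer quantity/unit from file name {path.name}")
    df = pd.read_csv(path)
    return MeasurementTable(df, quantity=quantity, unit=unit, after_qc=after_qc)
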