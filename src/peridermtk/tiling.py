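"""Patch tiling of whole-slide images and stitching of predicted patch masks.

Slide scans are far too large for a segmentation model in one piece, so they
are cut into fixed-size square patches (default 1024 px) on a non-overlapping
ceiling-cover grid; right/bottom edge patches are zero-padded to full size.
Stitching discards the padding and reassembles a slide-scale mask. With
``overlap > 0`` the later patch in row-major order wins on shared pixels,
keeping the mask pipeline integer-exact (no logit averaging).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_formats import LabelMask, RasterImage


@dataclass(frozen=True)
class TilingConfig:
    patch_size: int = 1024
    pad_value: int = 0
    overlap: int = 0

    def __post_init__(self) -> None:
        if self.patch_size < 32:
            raise ValueError("patch_size must be >= 32")
        if not 0 <= self.overlap < self.patch_size:
            raise ValueError("overlap must satisfy 0 <= overlap < patch_size")


@dataclass(frozen=True)
class PatchGrid:
    """Row-major grid of patch origins covering an H x W canvas."""

    height: int
    width: int
    patch_size: int
    overlap: int
    n_rows: int
    n_cols: int

    @property
    def n_patches(self) -> int:
        return self.n_rows * self.n_cols

    def origin(self, index: int) -> tuple[int, int]:
        r, c = divmod(index, self.n_cols)
        stride = self.patch_size - self.overlap
        return r * stride, c * stride

    def origins(self) -> list[tuple[int, int]]:
        return [self.origin(i) for i in range(self.n_patches)]

    def patch_name(self, slide_id: str, index: int) -> str:
        r, c = divmod(index, self.n_cols)
        return f"{slide_id}_r{r}_c{c}.png"


def _grid_for(height: int, width: int, config: TilingConfig) -> PatchGrid:
    stride = config.patch_size - config.overlap
    n_rows = max(1, math.ceil(height / stride)) if height > config.patch_size else 1
    n_cols = max(1, math.ceil(width / stride)) if width > config.patch_size else 1
    # ensure the last patch actually reaches the edge when overlap > 0
    while (n_rows - 1) * stride + config.patch_size < height:
        n_rows += 1
    while (n_cols - 1) * stride + config.patch_size < width:
        n_cols += 1
    return PatchGrid(height, width, config.patch_size, config.overlap, n_rows, n_cols)


def tile_image(
    image: RasterImage | LabelMask | np.ndarray,
    config: TilingConfig | None = None,
) -> tuple[PatchGrid, list[np.ndarray]]:
    """Cut an image or mask into row-major patches, padding edge patches.

    A patch_size larger than both image dimensions yields a single padded
    patch. Every original pixel is covered by at least one patch (exactly
    one at overlap 0).
    """
    config = config or TilingConfig()
    if isinstance(image, RasterImage):
        arr = image.pixels
    elif isinstance(image, LabelMask):
        arr = image.labels
    else:
        arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("cannot tile an empty image")
    H, W = arr.shape[:2]
    grid = _grid_for(H, W, config)
    p = config.patch_size
    patches = []
    for r0, c0 in grid.origins():
        pad_shape = (p, p) + arr.shape[2:]
        patch = np.full(pad_shape, config.pad_value, dtype=arr.dtype)
        block = arr[r0 : min(r0 + p, H), c0 : min(c0 + p, W)]
        patch[: block.shape[0], : block.shape[1]] = block
        patches.append(patch)
    return grid, patches


def stitch_masks(grid: PatchGrid, patch_masks: list[np.ndarray | LabelMask]) -> LabelMask:
    """Reassemble per-patch masks into a slide-scale mask.

    Padding beyond the slide boundary is discarded. With overlap, the later
    patch in row-major order overwrites shared pixels.
    """
    if len(patch_masks) != grid.n_patches:
        raise ValueError(
            f"patch count mismatch: grid expects {grid.n_patches}, received {len(patch_masks)}"
        )
    out = np.zeros((grid.height, grid.width), dtype=np.uint8)
    p = grid.patch_size
    for i, patch in enumerate(patch_masks):
        arr = patch.labels if isinstance(patch, LabelMask) else np.asarray(patch)
        if arr.shape[:2] != (p, p):
            raise ValueError(f"patch {i} has shape {arr.shape}, expected ({p}, {p})")
        r0, c0 = grid.origin(i)
        h = min(p, grid.height - r0)
        w = min(p, grid.width - c0)
        out[r0 : r0 + h, c0 : c0 + w] = arr[:h, :w]
    return LabelMask(out)


#: The eight symmetries of the square used for training augmentation.
DIHEDRAL_MODES = (
    "identity",
    "rot90",
    "rot180",
    "rot270",
    "hflip",
    "vflip",
    "transpose",
    "anti_transpose",
)


def augment_patch(patch: np.ndarray, mode: str) -> np.ndarray:
    """Apply one of the eight dihedral transforms to a square patch.

    Image and mask patches must be transformed with the same mode so they
    stay aligned. Rotations/transposes of non-square patches are rejected.
    """
    arr = np.asarray(patch)
    if mode not in DIHEDRAL_MODES:
        raise ValueError(f"mode must be one of {DIHEDRAL_MODES}")
    if mode in ("rot90", "rot270", "transpose", "anti_transpose") and (
        arr.shape[0] != arr.shape[1]
    ):
        raise ValueError(f"{mode} requires a square patch, got shape {arr.shape[:2]}")
    if mode == "identity":
        return arr.copy()
    if mode == "rot90":
        return np.rot90(arr, 1).copy()
    if mode == "rot180":
        return np.rot90(arr, 2).copy()
    if mode == "rot270":
        return np.rot90(arr, 3).copy()
    if mode == "hflip":
        return arr[:, ::-1].copy()
    if mode == "vflip":
        return arr[::-1, :].copy()
    if mode == "transpose":
        return arr.swapaxes(0, 1).copy()
    # anti-transpose: flip both axes then transpose
    return arr[::-1, ::-1].swapaxes(0, 1).copy()
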