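"""Slide preprocessing: thresholding, tiling, label merging, patching.

The pipeline separates tissue from glass with a single manually chosen
global threshold (T = 210 on the grey image), lays a non-overlapping
256 x 256 grid over the foreground, merges the five raw annotation
labels into three training classes (Gleason 3/4/5 -> cancer), and crops
aligned image/mask patch pairs.

Conventions used throughout: 0-based (row, col) coordinates, top-left
origin, half-open [origin, origin + tile_size) crop windows. Partial
edge tiles are never emitted.

On polarity: the thresholding step can label *bright* pixels as
foreground (the literal textual convention) or *dark* pixels as tissue
(the physically sensible one for near-white glass and stained tissue).
Both are provided; ``dark_is_tissue`` is the default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .labels import IGNORE, MERGE_TABLE, RAW_LABELS

__all__ = ["Polarity", "ThresholdConfig", "TileGrid", "PatchPair",
           "to_grayscale", "global_threshold", "build_tile_grid",
           "merge_labels", "extract_patches", "tile_slide",
           "write_patches", "read_patch_manifest", "load_patch_pair",
           "downsample_image", "downsample_mask"]

GRAY_WEIGHTS = (0.299, 0.587, 0.114)  # ITU-R BT.601 luma


class Polarity(str, Enum):
    BRIGHT_IS_FOREGROUND = "bright_is_foreground"
    DARK_IS_TISSUE = "dark_is_tissue"


@dataclass(frozen=True)
class ThresholdConfig:
    """Global threshold T in the open interval (0, 255)."""

    T: int = 210
    polarity: Polarity = Polarity.DARK_IS_TISSUE

    def __post_init__(self):
        if not 0 < self.T < 255:
            raise ValueError(f"threshold T must satisfy 0 < T < 255, got {self.T}")
        object.__setattr__(self, "polarity", Polarity(self.polarity))


@dataclass(frozen=True)
class TileGrid:
    """Retained full-tile origins over a slide, in row-major order."""

    tile_size: int
    stride: int
    coords: tuple[tuple[int, int], ...]
    min_foreground_fraction: float
    slide_shape: tuple[int, int]

    def __len__(self):
        return len(self.coords)


@dataclass
class PatchPair:
    """One aligned 256x256 network input/target crop."""

    x: np.ndarray        # (t, t, 3) uint8 RGB
    y_raw: np.ndarray    # (t, t) uint8, raw labels {0..5}
    y: np.ndarray        # (t, t) uint8, merged {0,1,2} + IGNORE
    ignore: np.ndarray   # (t, t) bool, True where no tissue label
    origin: tuple[int, int]
    slide_id: str


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Luminance grey image (BT.601 weights), rounded half-up to uint8."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape "
                         f"{image.shape}")
    w = np.asarray(GRAY_WEIGHTS)
    grey = image.astype(np.float64) @ w
    return np.floor(grey + 0.5).clip(0, 255).astype(np.uint8)


def global_threshold(grey: np.ndarray,
                     cfg: ThresholdConfig = ThresholdConfig()) -> np.ndarray:
    """Binarise a grey image against ``cfg.T`` (strict inequality).

    Returns a uint8 {0, 1} mask; 1 marks foreground under the
    configured polarity. Pixels exactly equal to T are background under
    either polarity.
    """
    grey = np.asarray(grey)
    if grey.ndim != 2:
        raise ValueError(f"expected a single-channel image, got shape "
                         f"{grey.shape}")
    if cfg.polarity is Polarity.BRIGHT_IS_FOREGROUND:
        return (grey > cfg.T).astype(np.uint8)
    return (grey < cfg.T).astype(np.uint8)


def build_tile_grid(tissue: np.ndarray, tile_size: int = 256,
                    stride: int | None = None,
                    min_fg: float = 0.1) -> TileGrid:
    """Emit every full tile whose tissue fraction is >= ``min_fg``.

    The fraction is computed over the tile's ``tile_size**2`` pixels.
    Partial edge tiles are discarded, never padded.
    """
    tissue = np.asarray(tissue)
    stride = tile_size if stride is None else stride
    h, w = tissue.shape
    if tile_size > min(h, w):
        raise ValueError(f"tile_size {tile_size} exceeds slide dims {h}x{w}")
    if not 0.0 <= min_fg <= 1.0:
        raise ValueError(f"min_fg must be in [0, 1], got {min_fg}")
    coords = []
    area = float(tile_size * tile_size)
    for r in range(0, h - tile_size + 1, stride):
        for c in range(0, w - tile_size + 1, stride):
            frac = tissue[r:r + tile_size, c:c + tile_size].sum() / area
            if frac >= min_fg:
                coords.append((r, c))
    return TileGrid(tile_size=tile_size, stride=stride, coords=tuple(coords),
                    min_foreground_fraction=min_fg, slide_shape=(h, w))


_MERGE_LUT = np.full(256, 255, dtype=np.uint8)
for _raw, _merged in MERGE_TABLE.items():
    _MERGE_LUT[_raw] = _merged


def merge_labels(y_raw: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Map raw labels to merged classes: 1 -> stroma(0), 2 -> benign(1),
    3/4/5 -> cancer(2); raw 0 becomes IGNORE with ignore=True."""
    y_raw = np.asarray(y_raw)
    bad = np.setdiff1d(np.unique(y_raw), np.asarray(RAW_LABELS))
    if bad.size:
        raise ValueError(
            f"raw label map contains invalid value(s) {bad.tolist()}; "
            f"expected values in {list(RAW_LABELS)}")
    merged = _MERGE_LUT[y_raw]
    ignore = merged == IGNORE
    return merged, ignore


def extract_patches(slide_image: np.ndarray, mask_raw: np.ndarray,
                    grid: TileGrid, slide_id: str = "") -> list[PatchPair]:
    """Crop one PatchPair per grid coord (half-open windows, grid order)."""
    slide_image = np.asarray(slide_image)
    mask_raw = np.asarray(mask_raw)
    if slide_image.shape[:2] != mask_raw.shape:
        raise ValueError(
            f"slide {slide_image.shape[:2]} and mask {mask_raw.shape} "
            "dimensions differ")
    if slide_image.shape[:2] != grid.slide_shape:
        raise ValueError("grid was built for a different slide shape")
    t = grid.tile_size
    patches = []
    for (r, c) in grid.coords:
        x = slide_image[r:r + t, c:c + t]
        y_raw = mask_raw[r:r + t, c:c + t]
        y, ignore = merge_labels(y_raw)
        patches.append(PatchPair(x=x.copy(), y_raw=y_raw.copy(), y=y,
                                 ignore=ignore, origin=(r, c),
                                 slide_id=slide_id))
    return patches


def tile_slide(slide_image: np.ndarray, mask_raw: np.ndarray,
               threshold_cfg: ThresholdConfig = ThresholdConfig(),
               tile_size: int = 256, stride: int | None = None,
               min_fg: float = 0.1, slide_id: str = "",
               downsample: int = 1) -> tuple[TileGrid, list[PatchPair]]:
    """Full preprocessing chain for one slide: grey -> threshold ->
    grid -> patches. ``downsample`` (integer) is applied first, e.g. 2
    to move from a 20x scan to 10x analysis magnification."""
    if downsample > 1:
        slide_image = downsample_image(slide_image, downsample)
        mask_raw = downsample_mask(mask_raw, downsample)
    tissue = global_threshold(to_grayscale(slide_image), threshold_cfg)
    grid = build_tile_grid(tissue, tile_size=tile_size, stride=stride,
                           min_fg=min_fg)
    return grid, extract_patches(slide_image, mask_raw, grid, slide_id)


def downsample_image(image: np.ndarray, factor: int) -> np.ndarray:
    """Integer block-mean downsampling of an RGB image."""
    image = np.asarray(image)
    h = (image.shape[0] // factor) * factor
    w = (image.shape[1] // factor) * factor
    blocks = image[:h, :w].reshape(h // factor, factor, w // factor, factor, -1)
    return np.rint(blocks.mean(axis=(1, 3))).astype(np.uint8).squeeze()


def downsample_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    """Nearest (top-left) downsampling of a label mask."""
    mask = np.asarray(mask)
    h = (mask.shape[0] // factor) * factor
    w = (mask.shape[1] // factor) * factor
    return mask[:h:factor, :w:factor].copy()


# ---------------------------------------------------------------------------
# Patch persistence
# ---------------------------------------------------------------------------

def write_patches(patches: list[PatchPair], out_dir,
                  grid: TileGrid | None = None) -> pd.DataFrame:
    """Write per-patch PNG pairs named {slide_id}_{row}_{col}.png plus a
    manifest with foreground fraction and raw class histogram."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in patches:
        r, c = p.origin
        stem = f"{p.slide_id}_{r}_{c}"
        img_name, mask_name = f"{stem}.png", f"{stem}_mask.png"
        iio.imwrite(out_dir / img_name, p.x)
        iio.imwrite(out_dir / mask_name, p.y_raw)
        hist = {int(k): int(v) for k, v in
                zip(*np.unique(p.y_raw, return_counts=True))}
        fg = float(1.0 - p.ignore.mean())
        rows.append({"slide_id": p.slide_id, "row": r, "col": c,
                     "path_image": img_name, "path_mask": mask_name,
                     "fg_fraction": fg,
                     "class_histogram": json.dumps(hist)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "patches.csv", index=False)
    return manifest


def read_patch_manifest(patch_dir) -> pd.DataFrame:
    return pd.read_csv(Path(patch_dir) / "patches.csv")


def load_patch_pair(row, root) -> PatchPair:
    root = Path(root)
    x = np.asarray(iio.imread(root / row["path_image"]))
    y_raw = np.asarray(iio.imread(root / row["path_mask"]))
    y, ignore = merge_labels(y_raw)
    return PatchPair(x=x, y_raw=y_raw, y=y, ignore=ignore,
                     origin=(int(row["row"]), int(row["col"])),
                     slide_id=str(row["slide_id"]))
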