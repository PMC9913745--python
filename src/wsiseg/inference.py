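"""Slide-level prediction, overlay rendering, and annotation export.

A trained network sees the slide exactly the way training did: the
tissue threshold and non-overlapping 256-grid select foreground tiles,
each tile is classified per pixel, and the argmax tiles are pasted back
at their origins. Pixels no tile covers stay "background". The
auto-annotation overlay blends class colours onto the slide — white
background (left untouched), red stroma, blue benign, green cancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .labels import BENIGN, CANCER, CLASS_NAMES, IGNORE, STROMA
from .preprocessing import ThresholdConfig, TileGrid, build_tile_grid, \
    global_threshold, to_grayscale

__all__ = ["SlidePrediction", "OverlayStyle", "predict_slide",
           "render_overlay", "export_annotation"]

#: background -> white, stroma -> red, benign -> blue, cancer -> green
DEFAULT_COLORS: dict[int, tuple[int, int, int]] = {
    IGNORE: (255, 255, 255),
    STROMA: (255, 0, 0),
    BENIGN: (0, 0, 255),
    CANCER: (0, 255, 0),
}


@dataclass
class SlidePrediction:
    """Merged-class map over a slide; IGNORE where no tile predicted."""

    label_map: np.ndarray            # (H, W) uint8
    grid: TileGrid
    model_id: str = ""


@dataclass(frozen=True)
class OverlayStyle:
    colors: dict[int, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_COLORS))
    blend_alpha: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.blend_alpha <= 1.0:
            raise ValueError("blend_alpha must be in [0, 1]")
        cols = list(self.colors.values())
        if len(set(cols)) != len(cols):
            raise ValueError("overlay colors must be pairwise distinct")


def predict_slide(model, slide_image: np.ndarray,
                  threshold_cfg: ThresholdConfig = ThresholdConfig(),
                  tile_size: int = 256, min_fg: float = 0.1,
                  batch_size: int = 8, model_id: str = "") -> SlidePrediction:
    """Tile a slide, classify each tile, and stitch the argmax maps.

    ``model`` needs a ``predict_proba(x: (B,H,W,3) in [0,1]) ->
    (B,H,W,C)`` method. Deterministic given the model and inputs; warns
    and returns an all-background map when no tile passes the tissue
    threshold.
    """
    slide_image = np.asarray(slide_image)
    tissue = global_threshold(to_grayscale(slide_image), threshold_cfg)
    grid = build_tile_grid(tissue, tile_size=tile_size, min_fg=min_fg)
    h, w = grid.slide_shape
    label_map = np.full((h, w), IGNORE, dtype=np.uint8)
    if len(grid) == 0:
        import warnings
        warnings.warn("no foreground tiles found; returning an empty "
                      "prediction", stacklevel=2)
        return SlidePrediction(label_map=label_map, grid=grid,
                               model_id=model_id)
    t = tile_size
    coords = list(grid.coords)
    for start in range(0, len(coords), batch_size):
        chunk = coords[start:start + batch_size]
        x = np.stack([slide_image[r:r + t, c:c + t] for r, c in chunk])
        probs = model.predict_proba(x.astype(np.float32) / 255.0)
        pred = probs.argmax(axis=-1).astype(np.uint8)
        for (r, c), tile in zip(chunk, pred):
            label_map[r:r + t, c:c + t] = tile
    return SlidePrediction(label_map=label_map, grid=grid, model_id=model_id)


def render_overlay(slide_image: np.ndarray, prediction: SlidePrediction,
                   style: OverlayStyle = OverlayStyle()) -> np.ndarray:
    """Alpha-blend class colours onto the slide (pure function).

    Predicted pixels become ``(1-a)*slide + a*colour`` (rounded
    half-up); background pixels are returned unchanged.
    """
    slide_image = np.asarray(slide_image)
    label_map = prediction.label_map
    if slide_image.shape[:2] != label_map.shape:
        raise ValueError(
            f"slide {slide_image.shape[:2]} and prediction "
            f"{label_map.shape} dimensions differ")
    a = style.blend_alpha
    out = slide_image.astype(np.float64).copy()
    for cls, color in style.colors.items():
        if cls == IGNORE:
            continue
        sel = label_map == cls
        out[sel] = (1.0 - a) * out[sel] + a * np.asarray(color, np.float64)
    return np.floor(out + 0.5).clip(0, 255).astype(np.uint8)


def export_annotation(prediction: SlidePrediction, out_prefix) -> dict:
    """Write the label map (PNG) and a per-class region summary CSV.

    Summary fractions are of the whole slide area; background is
    excluded, so they sum to <= 1.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    label_path = Path(f"{out_prefix}_labels.png")
    iio.imwrite(label_path, prediction.label_map)
    h, w = prediction.label_map.shape
    area = float(h * w)
    rows = []
    for ci, cname in enumerate(CLASS_NAMES):
        count = int((prediction.label_map == ci).sum())
        rows.append({"class": cname, "pixel_count": count,
                     "slide_fraction": count / area})
    summary = pd.DataFrame(rows)
    summary_path = Path(f"{out_prefix}_summary.csv")
    summary.to_csv(summary_path, index=False)
    return {"label_map": label_path, "summary": summary_path,
            "summary_frame": summary}
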