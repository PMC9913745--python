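"""Synthetic H&E-like slides with Radboud-coded ground truth.

Real prostate-biopsy slides are near-white glass with darker stained
tissue: pink-dominated stroma, lighter glandular benign epithelium
(with pale lumina), and denser, darker-purple carcinoma. The generator
emulates exactly the properties the downstream pipeline relies on —

* background grey level above the T = 210 tissue threshold,
* three visually separable tissue colour families painted as random
  elliptical blobs, with raw labels 3/4/5 drawn from one "cancer"
  family in slightly different tones (the pipeline merges them),
* pixel-aligned raw label masks in {0..5}.

It deliberately does not model gland/nuclear morphology, stain
variation, or multi-resolution pyramids; blobs are region-level stand-
ins for annotated tissue regions.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse

from .labels import RAW_LABELS

__all__ = ["ClassTexture", "SlideSpec", "SyntheticSlidePair",
           "generate_slide", "generate_dataset", "read_manifest",
           "load_slide_pair", "DEFAULT_TEXTURES"]


@dataclass(frozen=True)
class ClassTexture:
    """Mean RGB colour and per-pixel gaussian jitter for one raw label."""

    mean_rgb: tuple[int, int, int]
    jitter_sigma: float = 8.0
    #: benign glands get pale lumen discs in this colour (None = no lumina)
    lumen_rgb: tuple[int, int, int] | None = None


#: Colour families: stroma pink, benign light purple with pale lumina,
#: cancer (raw 3/4/5) a dense dark-purple family in three tones. All
#: means sit well below the T = 210 luminance threshold; pairwise RGB
#: distance between the merged classes is >= 40 so a small network can
#: separate them.
DEFAULT_TEXTURES: dict[int, ClassTexture] = {
    1: ClassTexture((230, 160, 180)),
    2: ClassTexture((190, 160, 210), lumen_rgb=(196, 192, 205)),
    3: ClassTexture((120, 80, 140)),
    4: ClassTexture((105, 70, 130)),
    5: ClassTexture((90, 60, 120)),
}

DEFAULT_BLOB_COUNTS: dict[int, int] = {1: 2, 2: 2, 3: 1, 4: 1, 5: 1}


@dataclass(frozen=True)
class SlideSpec:
    """Recipe for one pseudo-slide; identical specs + seed reproduce a
    byte-identical slide."""

    width_px: int = 512
    height_px: int = 512
    background_intensity: int = 240
    blob_count_per_class: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_BLOB_COUNTS))
    blob_radius_px: tuple[int, int] = (30, 80)
    texture_params: dict[int, ClassTexture] = field(
        default_factory=lambda: dict(DEFAULT_TEXTURES))
    background_noise_sigma: float = 3.0
    pixel_spacing_um: float = 1.0
    seed: int = 0
    #: Testing hook: explicit (raw_label, (row, col), radius) discs are
    #: painted instead of random ellipses when provided.
    explicit_blobs: tuple[tuple[int, tuple[int, int], int], ...] | None = None

    def validate(self) -> None:
        if self.width_px < 256 or self.height_px < 256:
            raise ValueError(
                f"slide dimensions must be >= 256 px, got "
                f"{self.width_px}x{self.height_px}")
        if not 210 < self.background_intensity <= 255:
            raise ValueError(
                "background_intensity must exceed the 210 tissue threshold")
        for label in self.blob_count_per_class:
            if label not in RAW_LABELS or label == 0:
                raise ValueError(f"blob class {label} not a raw tissue label")
        lo, hi = self.blob_radius_px
        if not 0 < lo <= hi:
            raise ValueError(f"invalid blob radius range {self.blob_radius_px}")
        merged_means = [np.asarray(self.texture_params[c].mean_rgb, float)
                        for c in (1, 2, 3) if c in self.texture_params]
        for i in range(len(merged_means)):
            for j in range(i + 1, len(merged_means)):
                d = float(np.linalg.norm(merged_means[i] - merged_means[j]))
                if d < 40:
                    raise ValueError(
                        f"class mean colours too close (RGB distance {d:.1f} "
                        "< 40); classes would not be separable")

    def spec_hash(self) -> str:
        payload = repr((self.width_px, self.height_px,
                        self.background_intensity,
                        sorted(self.blob_count_per_class.items()),
                        self.blob_radius_px,
                        sorted((k, v.mean_rgb, v.jitter_sigma, v.lumen_rgb)
                               for k, v in self.texture_params.items()),
                        self.background_noise_sigma, self.pixel_spacing_um,
                        self.explicit_blobs))
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class SyntheticSlidePair:
    """An RGB pseudo-slide with its pixel-aligned raw label mask."""

    image: np.ndarray          # (H, W, 3) uint8
    mask: np.ndarray           # (H, W) uint8, values in {0..5}
    slide_id: str
    seed: int
    spec_hash: str

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask dimensions differ")


def _paint_region(image, mask, rr, cc, label, tex, rng) -> None:
    n = rr.size
    colors = (np.asarray(tex.mean_rgb, float)
              + rng.normal(0.0, tex.jitter_sigma, size=(n, 3)))
    image[rr, cc] = np.clip(np.rint(colors), 0, 255).astype(np.uint8)
    mask[rr, cc] = label


def generate_slide(spec: SlideSpec, slide_id: str = "slide_0000",
                   seed: int | None = None) -> SyntheticSlidePair:
    """Render one pseudo-slide deterministically from ``spec``.

    Blobs are painted in raw-label order; later blobs overwrite earlier
    ones in both the image and the mask.
    """
    spec.validate()
    seed = spec.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    h, w = spec.height_px, spec.width_px
    bg = (np.full((h, w, 3), spec.background_intensity, float)
          + rng.normal(0.0, spec.background_noise_sigma, size=(h, w, 3)))
    image = np.clip(np.rint(bg), 0, 255).astype(np.uint8)
    mask = np.zeros((h, w), dtype=np.uint8)

    if spec.explicit_blobs is not None:
        ii, jj = np.mgrid[0:h, 0:w]
        for label, (cy, cx), radius in spec.explicit_blobs:
            tex = spec.texture_params[label]
            # exact disc: pixels with squared distance <= radius**2
            rr, cc = np.nonzero((ii - cy) ** 2 + (jj - cx) ** 2
                                <= radius * radius)
            _paint_region(image, mask, rr, cc, label, tex, rng)
        return SyntheticSlidePair(image, mask, slide_id, seed,
                                  spec.spec_hash())

    lo, hi = spec.blob_radius_px
    for label in sorted(spec.blob_count_per_class):
        tex = spec.texture_params[label]
        for _ in range(spec.blob_count_per_class[label]):
            r_major = rng.integers(lo, hi + 1)
            r_minor = max(3, int(r_major * rng.uniform(0.55, 1.0)))
            cy = rng.integers(r_major, max(r_major + 1, h - r_major))
            cx = rng.integers(r_major, max(r_major + 1, w - r_major))
            rot = rng.uniform(0, np.pi)
            rr, cc = ellipse(cy, cx, r_major, r_minor, shape=(h, w),
                             rotation=rot)
            _paint_region(image, mask, rr, cc, label, tex, rng)
            if tex.lumen_rgb is not None:
                lumen_tex = ClassTexture(tex.lumen_rgb, jitter_sigma=3.0)
                for _ in range(int(rng.integers(2, 5))):
                    k = rng.integers(0, rr.size)
                    lr, lc = disk((rr[k], cc[k]), max(3, r_minor // 5),
                                  shape=(h, w))
                    keep = mask[lr, lc] == label  # stay inside the gland
                    _paint_region(image, mask, lr[keep], lc[keep], label,
                                  lumen_tex, rng)
    return SyntheticSlidePair(image, mask, slide_id, seed, spec.spec_hash())


def generate_dataset(n_slides: int, spec: SlideSpec, out_dir,
                     fmt: str = "png") -> pd.DataFrame:
    """Write ``n_slides`` image/mask pairs plus a manifest CSV.

    Slide seeds are ``spec.seed + index`` so any slide can be
    regenerated in isolation. Paths in the manifest are relative to
    ``out_dir``.
    """
    if n_slides < 1:
        raise ValueError("n_slides must be >= 1")
    if fmt not in ("png", "tiff"):
        raise ValueError(f"unsupported format {fmt!r}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_slides):
        slide_id = f"slide_{i:04d}"
        pair = generate_slide(spec, slide_id=slide_id, seed=spec.seed + i)
        img_name = f"{slide_id}.{fmt}"
        mask_name = f"{slide_id}_mask.{fmt}"
        iio.imwrite(out_dir / img_name, pair.image)
        iio.imwrite(out_dir / mask_name, pair.mask)
        rows.append({"slide_id": slide_id, "image_path": img_name,
                     "mask_path": mask_name, "width": spec.width_px,
                     "height": spec.height_px, "seed": pair.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(out_dir) -> pd.DataFrame:
    return pd.read_csv(Path(out_dir) / "manifest.csv")


def load_slide_pair(row, root) -> SyntheticSlidePair:
    """Read one manifest row's image/mask pair back from disk."""
    root = Path(root)
    image = iio.imread(root / row["image_path"])
    mask = iio.imread(root / row["mask_path"])
    return SyntheticSlidePair(np.asarray(image), np.asarray(mask),
                              str(row["slide_id"]), int(row["seed"]), "")
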