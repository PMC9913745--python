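"""Patch dataset assembly: train/val/test splits and batch streaming.

The study's split was 8100 training / 900 test patches (a 90/10
ratio), with early stopping monitored on a hold-out validation subset;
here that is a three-way (train, val, test) fractional split. Splitting
by slide (the default) keeps all patches of a slide in one part, which
prevents leakage of nearly identical neighbouring tiles across parts;
splitting by patch mirrors the study's exact patch counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import PatchPair, load_patch_pair

__all__ = ["DatasetSplit", "make_split", "load_batch", "patches_to_arrays"]


@dataclass
class DatasetSplit:
    """Disjoint manifest partitions covering the input manifest."""

    train: pd.DataFrame
    val: pd.DataFrame
    test: pd.DataFrame
    split_seed: int
    split_unit: str

    def part(self, name: str) -> pd.DataFrame:
        return {"train": self.train, "val": self.val, "test": self.test}[name]

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for name in ("train", "val", "test"):
            df = self.part(name).copy()
            df["split"] = name
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def write(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read(cls, path, split_seed: int = -1,
             split_unit: str = "unknown") -> "DatasetSplit":
        df = pd.read_csv(path)
        parts = {name: df[df["split"] == name].drop(columns="split")
                 .reset_index(drop=True) for name in ("train", "val", "test")}
        return cls(train=parts["train"], val=parts["val"], test=parts["test"],
                   split_seed=split_seed, split_unit=split_unit)


def _boundaries(n: int, fractions: tuple[float, float, float]) -> tuple[int, int]:
    f_train, f_val, _ = fractions
    i = int(round(f_train * n))
    j = int(round((f_train + f_val) * n))
    return i, j


def make_split(manifest: pd.DataFrame,
               fractions: tuple[float, float, float] = (0.81, 0.09, 0.10),
               unit: str = "by_slide", seed: int = 0) -> DatasetSplit:
    """Deterministically shuffle and partition a patch manifest.

    ``fractions`` are (train, val, test) and must be non-negative and
    sum to 1; the default carves a 10% validation subset out of a 90/10
    train/test split. With ``unit="by_slide"`` no slide contributes to
    two parts.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ValueError("fractions must be three non-negative numbers")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    if unit not in ("by_slide", "by_patch"):
        raise ValueError(f"unknown split unit {unit!r}")
    rng = np.random.default_rng(seed)
    n_parts_wanted = sum(1 for f in fractions if f > 0)

    if unit == "by_patch":
        n = len(manifest)
        if n < n_parts_wanted:
            raise ValueError(
                f"{n} patches cannot fill {n_parts_wanted} split parts")
        order = rng.permutation(n)
        i, j = _boundaries(n, fractions)
        parts = (manifest.iloc[order[:i]], manifest.iloc[order[i:j]],
                 manifest.iloc[order[j:]])
    else:
        slides = sorted(manifest["slide_id"].unique())
        if len(slides) < n_parts_wanted:
            raise ValueError(
                f"{len(slides)} slides cannot fill {n_parts_wanted} split "
                "parts")
        order = rng.permutation(len(slides))
        i, j = _boundaries(len(slides), fractions)
        groups = (set(np.asarray(slides, dtype=object)[order[:i]]),
                  set(np.asarray(slides, dtype=object)[order[i:j]]),
                  set(np.asarray(slides, dtype=object)[order[j:]]))
        parts = tuple(manifest[manifest["slide_id"].isin(g)] for g in groups)

    train, val, test = (p.reset_index(drop=True) for p in parts)
    return DatasetSplit(train=train, val=val, test=test, split_seed=seed,
                        split_unit=unit)


def patches_to_arrays(patches: list[PatchPair]):
    """Stack PatchPairs into (x, y, ignore) batch arrays.

    x is float32 in [0, 1] with shape (B, H, W, 3); y keeps merged
    integer labels; ignore is boolean.
    """
    x = np.stack([p.x for p in patches]).astype(np.float32) / 255.0
    y = np.stack([p.y for p in patches])
    ignore = np.stack([p.ignore for p in patches])
    return x, y, ignore


def load_batch(part, batch_size: int = 8, shuffle_seed: int | None = None,
               root=None):
    """Yield (x, y, ignore) batches covering ``part`` exactly once.

    ``part`` is either a list of in-memory PatchPairs or a patch
    manifest DataFrame (then ``root`` locates the PNG files). The last
    partial batch is emitted; a fixed ``shuffle_seed`` gives an
    identical ordering on every call.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    if isinstance(part, pd.DataFrame):
        items = [row for _, row in part.iterrows()]

        def fetch(row) -> PatchPair:
            try:
                return load_patch_pair(row, root)
            except FileNotFoundError as exc:
                raise IOError(f"cannot read patch file: {exc.filename}") from exc
    else:
        items = list(part)

        def fetch(p: PatchPair) -> PatchPair:
            return p

    order = np.arange(len(items))
    if shuffle_seed is not None:
        np.random.default_rng(shuffle_seed).shuffle(order)
    for start in range(0, len(items), batch_size):
        chunk = [fetch(items[k]) for k in order[start:start + batch_size]]
        yield patches_to_arrays(chunk)
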