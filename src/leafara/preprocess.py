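"""Normalization, resizing, augmentation, class balancing and splitting.

The dataset arithmetic mirrors the Plant Village study design: the
unbalanced collection is balanced to 300 images per class, each balanced
image receives four augmented variants (rotation, scaling, translation,
Gaussian noise, cycled), giving a 5x combined set, which is split
70:15:15 into train/val/test with augmented rows inheriting their parent's
split so no image leaks across splits in disguised form.

Augmentation parameter ranges: rotation 5-15 degrees either direction,
scaling 2.5-10% magnification, translation 5-20% of each axis, additive
Gaussian noise with configurable sigma.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, resize as _sk_resize, rotate as _sk_rotate, warp

from .manifest import MANIFEST_COLUMNS, validate_manifest
from .synth import SyntheticSample

__all__ = [
    "NormalizationStats",
    "TransformRecord",
    "AUG_OPS",
    "compute_stats",
    "zscore_apply",
    "resize",
    "augment_one",
    "apply_record",
    "balance_classes",
    "build_augmented_dataset",
    "split_dataset",
    "inner_split",
]

AUG_OPS = ("rotate", "scale", "translate", "noise")

ROTATE_RANGE = (5.0, 15.0)  # degrees, sign drawn separately
SCALE_RANGE = (2.5, 10.0)  # percent magnification
TRANSLATE_RANGE = (5.0, 20.0)  # percent of axis length, per axis
DEFAULT_NOISE_SIGMA = 8.0  # grey levels on the 0-255 scale


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel mean and standard deviation of the training images."""

    mean: np.ndarray
    std: np.ndarray


@dataclass
class TransformRecord:
    """The drawn parameters of one augmentation, for exact replay."""

    op: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps({"op": self.op, "params": self.params, "seed": self.seed})

    @classmethod
    def from_json(cls, s: str) -> "TransformRecord":
        d = json.loads(s)
        return cls(op=d["op"], params=d["params"], seed=d["seed"])


def compute_stats(train_images: list[np.ndarray]) -> NormalizationStats:
    """Population per-channel mean/std over the training split only."""
    if len(train_images) == 0:
        raise ValueError("need at least one training image")
    stacked = np.concatenate([np.asarray(im, float).reshape(-1, 3) for im in train_images])
    mean = stacked.mean(axis=0)
    std = stacked.std(axis=0)  # population convention
    if np.any(std <= 0):
        bad = np.nonzero(std <= 0)[0].tolist()
        raise ValueError(f"degenerate data: zero variance in channel(s) {bad}")
    return NormalizationStats(mean=mean, std=std)


def zscore_apply(image: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    """Standardize an image: (x - mean) / std per channel."""
    return (np.asarray(image, float) - stats.mean) / stats.std


def resize(image: np.ndarray, target: tuple[int, int], is_mask: bool = False) -> np.ndarray:
    """Resize to ``target`` (H, W): bilinear for images, nearest for masks.

    Masks are re-binarized after interpolation so they stay in {0, 1}.
    """
    H, W = target
    if H < 8 or W < 8:
        raise ValueError("target size must be at least 8x8")
    img = np.asarray(image)
    if img.shape[:2] == (H, W):
        return img.copy()
    if is_mask:
        out = _sk_resize(img.astype(float), (H, W), order=0, preserve_range=True, anti_aliasing=False)
        return (out > 0.5).astype(np.uint8)
    out = _sk_resize(img.astype(float), (H, W) + img.shape[2:], order=1, preserve_range=True, anti_aliasing=False)
    return out.astype(img.dtype) if np.issubdtype(img.dtype, np.integer) else out


def _draw_params(op: str, rng: np.random.Generator, noise_sigma: float) -> dict:
    if op == "rotate":
        angle = rng.uniform(*ROTATE_RANGE) * rng.choice([-1.0, 1.0])
        return {"angle_deg": float(angle)}
    if op == "scale":
        return {"magnification_pct": float(rng.uniform(*SCALE_RANGE))}
    if op == "translate":
        return {
            "shift_x_pct": float(rng.uniform(*TRANSLATE_RANGE) * rng.choice([-1.0, 1.0])),
            "shift_y_pct": float(rng.uniform(*TRANSLATE_RANGE) * rng.choice([-1.0, 1.0])),
        }
    if op == "noise":
        return {"sigma": float(noise_sigma)}
    raise ValueError(f"unknown augmentation op {op!r}")


def _warp_pair(image, mask, tform_or_angle, kind, fill):
    img = np.asarray(image, float)
    if fill == "edge":
        mode, cval = "edge", 0.0
    else:
        mode, cval = "constant", 0.0
    if kind == "rotate":
        out = _sk_rotate(img, tform_or_angle, mode=mode, cval=cval, preserve_range=True)
        m_out = None
        if mask is not None:
            m_out = _sk_rotate(mask.astype(float), tform_or_angle, order=0, mode="constant", cval=0.0, preserve_range=True)
    else:
        out = warp(img, tform_or_angle, mode=mode, cval=cval, preserve_range=True, order=1)
        m_out = None
        if mask is not None:
            m_out = warp(mask.astype(float), tform_or_angle, mode="constant", cval=0.0, preserve_range=True, order=0)
    if fill not in ("edge",) and fill is not None:
        # paint exposed border with the requested background colour
        exposed = np.all(out == 0.0, axis=-1) if out.ndim == 3 else (out == 0.0)
        if out.ndim == 3:
            out[exposed] = np.asarray(fill, float)
    if m_out is not None:
        m_out = (m_out > 0.5).astype(np.uint8)
    return out, m_out


def apply_record(
    sample: SyntheticSample, record: TransformRecord, fill="edge"
) -> SyntheticSample:
    """Replay a stored augmentation on an image (and its mask, identically)."""
    img = np.asarray(sample.image, float)
    mask = sample.mask
    H, W = img.shape[:2]
    p = record.params
    if record.op == "rotate":
        out, m_out = _warp_pair(img, mask, p["angle_deg"], "rotate", fill)
    elif record.op == "scale":
        s = 1.0 + p["magnification_pct"] / 100.0
        # magnify about the image centre
        shift = AffineTransform(translation=(-W / 2, -H / 2))
        zoom = AffineTransform(scale=(1 / s, 1 / s))
        back = AffineTransform(translation=(W / 2, H / 2))
        tform = shift + zoom + back
        out, m_out = _warp_pair(img, mask, tform.inverse, "warp", fill)
    elif record.op == "translate":
        dx = p["shift_x_pct"] / 100.0 * W
        dy = p["shift_y_pct"] / 100.0 * H
        tform = AffineTransform(translation=(-dx, -dy))
        out, m_out = _warp_pair(img, mask, tform, "warp", fill)
    elif record.op == "noise":
        rng = np.random.default_rng(record.seed)
        out = img + rng.normal(0.0, p["sigma"], size=img.shape)
        m_out = mask.copy() if mask is not None else None
    else:
        raise ValueError(f"unknown augmentation op {record.op!r}")
    out = np.clip(out, 0, 255).astype(np.uint8)
    return SyntheticSample(image=out, mask=m_out, label=sample.label, seed=record.seed)


def augment_one(
    sample: SyntheticSample, op: str, seed: int, fill="edge",
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> tuple[SyntheticSample, TransformRecord]:
    """Draw parameters for one augmentation op and apply it.

    The mask (when present) receives exactly the same geometric transform as
    the image; the returned record stores the drawn parameters for replay.
    """
    if op not in AUG_OPS:
        raise ValueError(f"unknown augmentation op {op!r}; expected one of {AUG_OPS}")
    rng = np.random.default_rng(seed)
    record = TransformRecord(op=op, params=_draw_params(op, rng, noise_sigma), seed=seed)
    return apply_record(sample, record, fill=fill), record


def balance_classes(manifest: pd.DataFrame, per_class: int = 300, seed: int = 0) -> pd.DataFrame:
    """Sample exactly ``per_class`` rows per class, without replacement."""
    validate_manifest(manifest)
    rng = np.random.default_rng(seed)
    parts = []
    for cls, grp in manifest.groupby("class", sort=True):
        if len(grp) < per_class:
            raise ValueError(
                f"class {cls!r} has only {len(grp)} rows; cannot balance to {per_class}"
            )
        take = rng.choice(len(grp), size=per_class, replace=False)
        parts.append(grp.iloc[np.sort(take)])
    return pd.concat(parts, ignore_index=True)


def build_augmented_dataset(
    manifest: pd.DataFrame,
    variants_per_image: int = 4,
    ops_cycle: tuple[str, ...] = AUG_OPS,
    seed: int = 0,
    noise_sigma: float = DEFAULT_NOISE_SIGMA,
) -> pd.DataFrame:
    """Plan ``variants_per_image`` augmented rows per real row.

    Ops are cycled over ``ops_cycle``; each augmented row stores a full
    transform record (drawn parameters + seed) so the image can be
    materialized on demand with :func:`apply_record`.  The combined manifest
    has exactly ``len(manifest) * (1 + variants_per_image)`` rows.
    """
    if variants_per_image < 1:
        raise ValueError("variants_per_image must be >= 1")
    validate_manifest(manifest)
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(manifest) * variants_per_image))
    rows = []
    for _, parent in manifest.iterrows():
        for v in range(variants_per_image):
            op = ops_cycle[v % len(ops_cycle)]
            s = int(next(children).generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(s)
            record = TransformRecord(op=op, params=_draw_params(op, rng, noise_sigma), seed=s)
            stem, dot, ext = parent["path"].rpartition(".")
            rows.append(
                {
                    "path": f"{stem or parent['path']}_aug{v}{dot}{ext}",
                    "mask_path": parent["mask_path"],
                    "class": parent["class"],
                    "split": parent["split"],
                    "provenance": "augmented",
                    "transform": record.to_json(),
                    "parent": parent["path"],
                    "seed": s,
                }
            )
    combined = pd.concat([manifest, pd.DataFrame(rows, columns=MANIFEST_COLUMNS)], ignore_index=True)
    return combined


def _allocate(n: int, ratio: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of n into three parts."""
    exact = [n * r / 100.0 for r in ratio]
    base = [math.floor(e) for e in exact]
    rem = n - sum(base)
    order = sorted(range(3), key=lambda i: exact[i] - base[i], reverse=True)
    for i in order[:rem]:
        base[i] += 1
    return tuple(base)


def split_dataset(
    manifest: pd.DataFrame,
    ratio: tuple[float, float, float] = (70, 15, 15),
    stratified: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Assign train/val/test splits, stratified by class, leakage-free.

    Splits are assigned to real (parent) rows; augmented rows inherit their
    parent's split.  Per-class counts deviate from exact proportions by at
    most one sample (largest-remainder apportionment).
    """
    if abs(sum(ratio) - 100) > 1e-9:
        raise ValueError(f"ratio must sum to 100, got {ratio}")
    validate_manifest(manifest)
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    real = out[out["provenance"] == "real"]
    groups = real.groupby("class", sort=True) if stratified else [("all", real)]
    for cls, grp in groups:
        if len(grp) == 0:
            raise ValueError(f"class {cls!r} has no rows")
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        n_tr, n_va, n_te = _allocate(len(idx), tuple(ratio))
        out.loc[idx[:n_tr], "split"] = "train"
        out.loc[idx[n_tr : n_tr + n_va], "split"] = "val"
        out.loc[idx[n_tr + n_va :], "split"] = "test"
    # children inherit the parent's split
    aug = out["provenance"] == "augmented"
    if aug.any():
        split_of = dict(zip(out.loc[~aug, "path"], out.loc[~aug, "split"]))
        out.loc[aug, "split"] = out.loc[aug, "parent"].map(split_of)
    return out


def inner_split(
    manifest: pd.DataFrame, val_fraction: float = 0.10, seed: int = 0
) -> pd.DataFrame:
    """Carve a validation subset out of the train split (e.g. 90/10).

    Used when the outer split reserved no validation share; operates on
    parent rows per class, children inheriting, like :func:`split_dataset`.
    """
    out = manifest.copy()
    rng = np.random.default_rng(seed)
    real_train = out[(out["provenance"] == "real") & (out["split"] == "train")]
    for _, grp in real_train.groupby("class", sort=True):
        idx = grp.index.to_numpy()
        rng.shuffle(idx)
        n_val = int(round(val_fraction * len(idx)))
        out.loc[idx[:n_val], "split"] = "val"
    aug = out["provenance"] == "augmented"
    if aug.any():
        split_of = dict(zip(out.loc[~aug, "path"], out.loc[~aug, "split"]))
        out.loc[aug, "split"] = out.loc[aug, "parent"].map(split_of)
    return out
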