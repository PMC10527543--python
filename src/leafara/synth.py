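"""Seeded procedural generator of diseased-leaf images with ground-truth masks.

Emulates the tomato Plant Village taxonomy: one healthy class (TH) and nine
disease phenotypes, each rendered with a distinct lesion morphology on a
smooth leaf blob (elliptical base plus low-frequency boundary noise) over a
soil-coloured background.  Every image comes with an exact binary leaf mask
and a class label, so segmentation and classification stages can be trained
and scored without any external download.  Generation is a pure function of
``(spec, size, seed)``.

The images are deliberately schematic, not photorealistic: they guarantee
that lesion statistics and hue separate the classes, which is the property
the downstream models need.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "PhenotypeSpec",
    "SyntheticSample",
    "CLASS_NAMES",
    "PLANT_VILLAGE_COUNTS",
    "phenotype_specs",
    "generate_leaf_image",
    "generate_dataset",
]

CLASS_NAMES = ["TH", "TMV", "TEB", "TLB", "TBS", "TLM", "TSLS", "TTS", "TYLCV", "TTSSM"]

#: Published per-class image counts of the tomato Plant Village collection
#: (healthy; mosaic virus; early blight; late blight; bacterial spot; leaf
#: mold; septoria leaf spot; target spot; yellow leaf curl virus; two-spotted
#: spider mite).  Used as the canonical class manifest for dataset-arithmetic
#: checks and as default weights when emulating the unbalanced collection.
PLANT_VILLAGE_COUNTS = {
    "TH": 1591,
    "TMV": 373,
    "TEB": 1000,
    "TLB": 1910,
    "TBS": 2127,
    "TLM": 952,
    "TSLS": 1771,
    "TTS": 1404,
    "TYLCV": 5357,
    "TTSSM": 1676,
}


@dataclass(frozen=True)
class PhenotypeSpec:
    """Rendering recipe for one phenotype class."""

    class_name: str
    lesion_kind: str  # none | small_spots | large_patches | mold_texture |
    #                   mottling | curl_warp | stippling
    lesion_density: float
    color_shift: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.class_name not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_name!r}")
        kinds = {
            "none",
            "small_spots",
            "large_patches",
            "mold_texture",
            "mottling",
            "curl_warp",
            "stippling",
        }
        if self.lesion_kind not in kinds:
            raise ValueError(f"unknown lesion kind {self.lesion_kind!r}")
        if self.class_name == "TH" and self.lesion_kind != "none":
            raise ValueError("healthy class TH must have lesion_kind 'none'")
        if self.class_name != "TH" and self.lesion_density <= 0:
            raise ValueError("disease classes need lesion_density > 0")


@dataclass
class SyntheticSample:
    """One generated image with its ground truth."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray  # H x W uint8, 1 = leaf
    label: str
    seed: int


# lesion morphology per class: spots for bacterial/septoria spot, large
# necrotic patches for the blights and target spot, mold texture, viral
# mottling, curl for TYLCV, mite stippling; colour shifts keep hues distinct
_SPEC_TABLE = {
    "TH": ("none", 0.0, (0.0, 0.0, 0.0)),
    "TMV": ("mottling", 0.25, (8.0, 6.0, -10.0)),
    "TEB": ("large_patches", 0.10, (6.0, -4.0, -6.0)),
    "TLB": ("large_patches", 0.16, (-4.0, -8.0, 2.0)),
    "TBS": ("small_spots", 0.055, (4.0, -6.0, -4.0)),
    "TLM": ("mold_texture", 0.22, (10.0, 8.0, -12.0)),
    "TSLS": ("small_spots", 0.035, (-6.0, 2.0, 6.0)),
    "TTS": ("large_patches", 0.07, (2.0, 2.0, -8.0)),
    "TYLCV": ("curl_warp", 0.30, (14.0, 10.0, -14.0)),
    "TTSSM": ("stippling", 0.09, (-2.0, -2.0, 10.0)),
}


def phenotype_specs(classes: list[str] | None = None) -> list[PhenotypeSpec]:
    """Default :class:`PhenotypeSpec` list for the requested classes."""
    names = CLASS_NAMES if classes is None else classes
    return [
        PhenotypeSpec(n, _SPEC_TABLE[n][0], _SPEC_TABLE[n][1], _SPEC_TABLE[n][2])
        for n in names
    ]


_BACKGROUND = np.array([121.0, 96.0, 70.0])  # dry-soil brown
_LEAF_GREEN = np.array([58.0, 128.0, 52.0])


def _leaf_mask(H: int, W: int, rng: np.random.Generator) -> np.ndarray:
    """Elliptical blob with low-frequency radial boundary noise."""
    cy, cx = H / 2 + rng.uniform(-0.04, 0.04) * H, W / 2 + rng.uniform(-0.04, 0.04) * W
    ay = H * rng.uniform(0.30, 0.38)
    ax = W * rng.uniform(0.26, 0.36)
    theta0 = rng.uniform(0, 2 * np.pi)
    n_harm = 4
    amp = rng.uniform(0.02, 0.07, size=n_harm)
    phase = rng.uniform(0, 2 * np.pi, size=n_harm)
    yy, xx = np.mgrid[0:H, 0:W]
    ang = np.arctan2(yy - cy, xx - cx)
    wobble = np.ones_like(ang)
    for k in range(n_harm):
        wobble += amp[k] * np.cos((k + 2) * (ang - theta0) + phase[k])
    r = np.sqrt(((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2)
    return (r <= wobble).astype(np.uint8)


def _smooth_noise(H: int, W: int, rng: np.random.Generator, scale: int) -> np.ndarray:
    """Low-frequency noise field in [0, 1] via bilinear upsampling."""
    h = max(2, H // scale)
    w = max(2, W // scale)
    coarse = rng.uniform(0.0, 1.0, size=(h, w))
    img = Image.fromarray((coarse * 255).astype(np.uint8))
    fine = np.asarray(img.resize((W, H), Image.BILINEAR), dtype=float) / 255.0
    return fine


def _disk(H: int, W: int, cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:H, 0:W]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def _paint_lesions(
    img: np.ndarray, mask: np.ndarray, spec: PhenotypeSpec, rng: np.random.Generator
) -> None:
    """Draw the class's lesion morphology, strictly inside the leaf mask."""
    H, W = mask.shape
    inside = mask.astype(bool)
    area = int(inside.sum())
    kind = spec.lesion_kind
    if kind == "none" or area == 0:
        return
    ys, xs = np.nonzero(inside)

    def pick_centers(n: int) -> list[tuple[int, int]]:
        idx = rng.integers(0, len(ys), size=n)
        return [(int(ys[i]), int(xs[i])) for i in idx]

    if kind == "small_spots":
        n = max(3, int(spec.lesion_density * area / 12))
        dark = np.array([70.0, 52.0, 30.0])
        for cy, cx in pick_centers(n):
            r = rng.uniform(1.0, max(1.5, 0.03 * min(H, W)))
            blob = _disk(H, W, cy, cx, r) & inside
            img[blob] = dark + rng.normal(0, 6, size=3)
    elif kind == "large_patches":
        n = max(1, int(round(spec.lesion_density * 25)))
        brown = np.array([96.0, 66.0, 34.0])
        for cy, cx in pick_centers(n):
            r = rng.uniform(0.06, 0.14) * min(H, W)
            blob = _disk(H, W, cy, cx, r) & inside
            shade = brown + rng.normal(0, 10, size=3)
            img[blob] = 0.2 * img[blob] + 0.8 * shade
    elif kind == "mold_texture":
        field = _smooth_noise(H, W, rng, scale=6)
        blot = (field > 1.0 - spec.lesion_density) & inside
        olive = np.array([150.0, 140.0, 70.0])
        img[blot] = 0.35 * img[blot] + 0.65 * olive
    elif kind == "mottling":
        field = _smooth_noise(H, W, rng, scale=8)
        light = (field > 1.0 - spec.lesion_density) & inside
        dark = (field < spec.lesion_density * 0.6) & inside
        img[light] = 0.4 * img[light] + 0.6 * np.array([170.0, 180.0, 80.0])
        img[dark] = 0.6 * img[dark] + 0.4 * np.array([30.0, 70.0, 30.0])
    elif kind == "curl_warp":
        # leaf-curl virus: strong marginal yellowing plus interior streaks
        edge = inside & ~_erode(inside, int(max(2, 0.06 * min(H, W))))
        yellow = np.array([200.0, 190.0, 60.0])
        img[edge] = 0.3 * img[edge] + 0.7 * yellow
        field = _smooth_noise(H, W, rng, scale=5)
        streak = (field > 1.0 - 0.5 * spec.lesion_density) & inside
        img[streak] = 0.5 * img[streak] + 0.5 * yellow
    elif kind == "stippling":
        n = max(10, int(spec.lesion_density * area / 6))
        pale = np.array([196.0, 200.0, 150.0])
        idx = rng.integers(0, len(ys), size=n)
        img[ys[idx], xs[idx]] = pale + rng.normal(0, 8, size=(n, 3))


def _erode(m: np.ndarray, it: int) -> np.ndarray:
    out = m.copy()
    for _ in range(it):
        shr = out.copy()
        shr[1:, :] &= out[:-1, :]
        shr[:-1, :] &= out[1:, :]
        shr[:, 1:] &= out[:, :-1]
        shr[:, :-1] &= out[:, 1:]
        out = shr
    return out


def generate_leaf_image(
    spec: PhenotypeSpec, size: tuple[int, int], seed: int
) -> SyntheticSample:
    """Render one leaf image plus exact mask for a phenotype class.

    Deterministic in ``(spec, size, seed)``.  The mask covers the leaf blob
    exactly; all lesion pixels lie inside it; foreground fraction stays
    within [5%, 95%] by construction of the blob radii.
    """
    H, W = size
    if H < 32 or W < 32:
        raise ValueError(f"canvas {H}x{W} too small; need at least 32x32")
    rng = np.random.default_rng(seed)
    mask = _leaf_mask(H, W, rng)

    img = np.empty((H, W, 3), dtype=float)
    img[:] = _BACKGROUND + rng.normal(0, 5, size=(H, W, 3))

    inside = mask.astype(bool)
    texture = _smooth_noise(H, W, rng, scale=4)  # vein-like shading field
    green = _LEAF_GREEN + np.array(spec.color_shift)
    shade = 0.82 + 0.36 * texture
    for ch in range(3):
        img[..., ch][inside] = green[ch] * shade[inside]
    img[inside] += rng.normal(0, 4, size=(int(inside.sum()), 3))

    _paint_lesions(img, mask, spec, rng)

    img = np.clip(img, 0, 255).astype(np.uint8)
    return SyntheticSample(image=img, mask=mask, label=spec.class_name, seed=seed)


def generate_dataset(
    per_class: int,
    classes: list[PhenotypeSpec],
    size: tuple[int, int],
    seed: int,
    outdir: str | None = None,
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Generate ``per_class`` samples for each phenotype and a manifest.

    Sample seeds are derived deterministically from ``seed`` so distinct
    master seeds give distinct image sets of identical shape.  When
    ``outdir`` is given, images and masks are written there as PNG and the
    manifest paths point to the files; otherwise paths are symbolic.
    """
    if per_class < 1:
        raise ValueError("per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    child = iter(ss.spawn(per_class * len(classes)))
    samples: list[SyntheticSample] = []
    rows = []
    for spec in classes:
        for k in range(per_class):
            s = int(next(child).generate_state(1)[0] % (2**31))
            sample = generate_leaf_image(spec, size, s)
            samples.append(sample)
            stem = f"{spec.class_name}_{k:05d}"
            if outdir is not None:
                cls_dir = os.path.join(outdir, spec.class_name)
                os.makedirs(cls_dir, exist_ok=True)
                img_path = os.path.join(cls_dir, stem + ".png")
                mask_path = os.path.join(cls_dir, stem + "_mask.png")
                Image.fromarray(sample.image).save(img_path)
                Image.fromarray(sample.mask * 255).save(mask_path)
            else:
                img_path = f"synthetic://{spec.class_name}/{stem}.png"
                mask_path = f"synthetic://{spec.class_name}/{stem}_mask.png"
            rows.append(
                {
                    "path": img_path,
                    "mask_path": mask_path,
                    "class": spec.class_name,
                    "split": "unassigned",
                    "provenance": "real",
                    "transform": "",
                    "parent": "",
                    "seed": s,
                }
            )
    return samples, pd.DataFrame(rows)
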