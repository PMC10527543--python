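"""Shared fixtures: synthetic datasets and trained models.

Everything is generated programmatically at test time; the heavier trained
models are session-scoped so several test modules can share one training
run.
"""

from __future__ import annotations

import numpy as np
import pytest

from leafara.classify import build_classifier, train_classifier
from leafara.preprocess import augment_one, compute_stats, zscore_apply
from leafara.synth import generate_dataset, phenotype_specs


def _stack(samples, stats):
    return np.stack(
        [zscore_apply(s.image, stats).transpose(2, 0, 1) for s in samples]
    ).astype(np.float32)


@pytest.fixture(scope="session")
def leaf_dataset_64():
    """200 synthetic 64x64 leaves (20 per class), split 140/30/30."""
    samples, manifest = generate_dataset(20, phenotype_specs(), (64, 64), seed=42)
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(samples))
    split = {"train": idx[:140], "val": idx[140:170], "test": idx[170:]}
    stats = compute_stats([samples[i].image for i in split["train"]])
    X = _stack(samples, stats)
    Y = np.stack([s.mask for s in samples])
    labels = np.array([s.label for s in samples])
    return {"samples": samples, "manifest": manifest, "X": X, "Y": Y,
            "labels": labels, "split": split, "stats": stats}


@pytest.fixture(scope="session")
def case1_data_32():
    """Balanced healthy/unhealthy 32x32 set: 60 TH + 60 diseased.

    The training split carries one noise and one rotation variant per image,
    mirroring the pipeline's augmented training condition.
    """
    specs = phenotype_specs()
    th = [s for s in specs if s.class_name == "TH"]
    disease = [s for s in specs if s.class_name != "TH"]
    th_samples, _ = generate_dataset(60, th, (32, 32), seed=7)
    dis_samples, _ = generate_dataset(7, disease, (32, 32), seed=8)
    samples = th_samples + dis_samples[:60]
    y = np.array([0 if s.label == "TH" else 1 for s in samples])
    rng = np.random.default_rng(1)
    idx = rng.permutation(len(samples))
    tr, va, te = idx[:80], idx[80:100], idx[100:]
    aug_samples, aug_y = [], []
    for j, i in enumerate(tr):
        for op in ("noise", "rotate"):
            a, _ = augment_one(samples[i], op, seed=1000 + j)
            aug_samples.append(a)
            aug_y.append(y[i])
    stats = compute_stats([samples[i].image for i in tr])
    X = _stack(samples, stats)
    Xtr = np.concatenate([X[tr], _stack(aug_samples, stats)])
    ytr = np.concatenate([y[tr], np.array(aug_y)])
    return {
        "samples": samples,
        "data": {"train": (Xtr, ytr), "val": (X[va], y[va]), "test": (X[te], y[te])},
        "test_idx": te,
        "X": X,
        "y": y,
    }


@pytest.fixture(scope="session")
def trained_case1_classifier(case1_data_32):
    """A case-1 classifier trained on the balanced 32x32 set."""
    model = build_classifier(2, width=8, seed=3)
    model, hist = train_classifier(
        model, case1_data_32["data"], epochs=8, patience=8, seed=3
    )
    return model, hist
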