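"""End-to-end orchestration of the leaf-disease analysis workflow.

Stage order: synthesize (or ingest) images -> balance / augment / split ->
train and evaluate the segmenter -> ARA hyperparameter search -> train and
evaluate the classifier -> Score-CAM visualization.  A single global seed
fans out deterministically to per-stage seeds (``stage_seed = sha256(seed,
stage) mod 2^31``), so a rerun with the same config reproduces every
artifact bit-identically on the same platform.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import preprocess as pp
from .classify import (
    build_classifier,
    case_spec,
    default_search_space,
    evaluate_metrics,
    hpo_search,
    make_proxy_objective,
    train_classifier,
)
from .manifest import write_manifest
from .scorecam import overlay, score_cam
from .synth import SyntheticSample, generate_dataset, phenotype_specs
from .unet import (
    ModifiedUNet,
    TrainConfig,
    UNetSpec,
    evaluate_segmentation,
    train_segmentation,
)

__all__ = ["PipelineConfig", "RunRecord", "run_pipeline", "stage_seed", "load_config"]

logger = logging.getLogger(__name__)

_SECTION_DEFAULTS: dict[str, dict] = {
    "synth": {"per_class": 10, "size": [32, 32], "classes": None},
    "augment": {"per_class": None, "variants_per_image": 4, "noise_sigma": 8.0},
    "split": {"ratio": [70, 15, 15]},
    "segmentation": {
        "depth": 2, "base_channels": 8, "epochs": 10, "patience": 5,
        "batch_size": 16, "learning_rate": 0.002, "loss": "NLL",
    },
    "ara": {
        "population_size": 3, "max_iterations": 2,
        "round_mode": "printed", "energy_threshold": 1.0,
    },
    "hpo": {"enabled": True, "proxy_epochs": 1, "budget": 12},
    "classify": {"case": 1, "width": 8, "epochs": 15, "patience": 5},
    "scorecam": {"n_images": 4, "colormap": "jet"},
}


@dataclass
class PipelineConfig:
    """Validated configuration; unknown sections or keys are rejected."""

    seed: int = 0
    outdir: str = "leafara_out"
    sections: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = {}
        for name, defaults in _SECTION_DEFAULTS.items():
            given = self.sections.get(name, {})
            unknown = set(given) - set(defaults)
            if unknown:
                raise ValueError(f"unknown keys in section {name!r}: {sorted(unknown)}")
            merged[name] = {**defaults, **given}
        unknown_sections = set(self.sections) - set(_SECTION_DEFAULTS)
        if unknown_sections:
            raise ValueError(f"unknown config sections: {sorted(unknown_sections)}")
        self.sections = merged

    def __getitem__(self, name: str) -> dict:
        return self.sections[name]

    def config_hash(self) -> str:
        blob = json.dumps({"seed": self.seed, "sections": self.sections}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path: str | None, seed: int | None = None, outdir: str | None = None) -> PipelineConfig:
    raw = {}
    if path:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    cfg_seed = raw.pop("seed", 0) if seed is None else seed
    cfg_out = raw.pop("outdir", "leafara_out") if outdir is None else outdir
    raw.pop("seed", None)
    raw.pop("outdir", None)
    return PipelineConfig(seed=cfg_seed, outdir=cfg_out, sections=raw)


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class RunRecord:
    stage: str
    config_hash: str
    input_hash: str
    output_hash: str
    seed: int
    started: float
    elapsed: float


def _hash_manifest(df: pd.DataFrame | None) -> str:
    if df is None:
        return ""
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def _zscore_stack(samples: list[SyntheticSample], stats=None):
    imgs = [s.image for s in samples]
    if stats is None:
        stats = pp.compute_stats(imgs)
    X = np.stack([pp.zscore_apply(im, stats).transpose(2, 0, 1) for im in imgs]).astype(np.float32)
    return X, stats


def _materialize(manifest: pd.DataFrame, by_path: dict[str, SyntheticSample]) -> None:
    """Fill in augmented samples from their parents' images."""
    for _, row in manifest.iterrows():
        if row["provenance"] == "augmented" and row["path"] not in by_path:
            parent = by_path[row["parent"]]
            record = pp.TransformRecord.from_json(row["transform"])
            by_path[row["path"]] = pp.apply_record(parent, record)


_STAGE_ORDER = ["synth", "augment", "segment", "hpo", "classify", "scorecam"]


def run_pipeline(config: PipelineConfig, until: str | None = None) -> tuple[list[RunRecord], dict]:
    """Execute the stages in order; returns run records and a metrics dict.

    ``until`` stops after the named stage (inclusive).  A failing stage
    raises an error naming the stage; outputs of completed stages are kept
    on disk under ``config.outdir``.
    """
    if until is not None and until not in _STAGE_ORDER:
        raise ValueError(f"unknown stage {until!r}; expected one of {_STAGE_ORDER}")
    last = _STAGE_ORDER.index(until) if until else len(_STAGE_ORDER) - 1
    os.makedirs(config.outdir, exist_ok=True)
    records: list[RunRecord] = []
    metrics: dict = {}
    chash = config.config_hash()

    def run_stage(name, fn, in_hash=""):
        t0 = time.time()
        try:
            out_hash = fn() or ""
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        rec = RunRecord(name, chash, in_hash, out_hash, stage_seed(config.seed, name),
                        t0, time.time() - t0)
        records.append(rec)
        logger.info("stage %s done in %.1fs", name, rec.elapsed)

    state: dict = {}

    # -- synth --------------------------------------------------------------
    def do_synth():
        sc = config["synth"]
        specs = phenotype_specs(sc["classes"])
        samples, manifest = generate_dataset(
            sc["per_class"], specs, tuple(sc["size"]), stage_seed(config.seed, "synth"),
            outdir=os.path.join(config.outdir, "images"),
        )
        # manifest paths are outdir-relative so reruns hash identically anywhere
        for col in ("path", "mask_path"):
            manifest[col] = [os.path.relpath(p, config.outdir) for p in manifest[col]]
        state["samples"] = {r["path"]: s for (_, r), s in zip(manifest.iterrows(), samples)}
        state["manifest"] = manifest
        write_manifest(manifest, os.path.join(config.outdir, "manifest_raw.csv"))
        return _hash_manifest(manifest)


    # -- augment + split ----------------------------------------------------
    def do_augment():
        ac, spl = config["augment"], config["split"]
        man = state["manifest"]
        per_class = ac["per_class"]
        if per_class:
            man = pp.balance_classes(man, per_class, stage_seed(config.seed, "balance"))
        man = pp.build_augmented_dataset(
            man, ac["variants_per_image"], seed=stage_seed(config.seed, "augment"),
            noise_sigma=ac["noise_sigma"],
        )
        man = pp.split_dataset(man, tuple(spl["ratio"]), seed=stage_seed(config.seed, "split"))
        _materialize(man, state["samples"])
        state["manifest"] = man
        write_manifest(man, os.path.join(config.outdir, "manifest.csv"))
        return _hash_manifest(man)


    def split_samples(split):
        man = state["manifest"]
        return [state["samples"][p] for p in man.loc[man["split"] == split, "path"]]

    # -- segmentation -------------------------------------------------------
    def do_segment():
        sc = config["segmentation"]
        tr, va, te = (split_samples(s) for s in ("train", "val", "test"))
        Xtr, stats = _zscore_stack(tr)
        state["stats"] = stats
        Xva, _ = _zscore_stack(va, stats)
        Xte, _ = _zscore_stack(te, stats)
        Ytr = np.stack([s.mask for s in tr])
        Yva = np.stack([s.mask for s in va])
        Yte = np.stack([s.mask for s in te])
        model = ModifiedUNet(UNetSpec(sc["depth"], sc["base_channels"],
                                      seed=stage_seed(config.seed, "segmodel")))
        tc = TrainConfig(sc["learning_rate"], sc["batch_size"], sc["epochs"],
                         min(sc["patience"], sc["epochs"]), sc["loss"])
        model, hist = train_segmentation(model, {"train": (Xtr, Ytr), "val": (Xva, Yva)},
                                         tc, stage_seed(config.seed, "segtrain"))
        seg = evaluate_segmentation(model, Xte, Yte, sc["loss"])
        metrics["segmentation"] = {"test_loss": seg.loss, "test_accuracy": seg.pixel_accuracy,
                                   "dice": seg.dice}
        pd.DataFrame(hist["train_loss"], columns=["train_loss"]).assign(
            val_loss=hist["val_loss"]
        ).to_csv(os.path.join(config.outdir, "segmentation_history.csv"), index=False)
        state["segmenter"] = model


    # -- classification data ------------------------------------------------
    case = case_spec(config["classify"]["case"])

    def class_arrays(split):
        samples = split_samples(split)
        keep = [(s, case.map_label(s.label)) for s in samples]
        keep = [(s, y) for s, y in keep if y is not None]
        X, _ = _zscore_stack([s for s, _ in keep], state["stats"])
        y = np.array([y for _, y in keep], dtype=int)
        return X, y

    # -- hpo ----------------------------------------------------------------
    def do_hpo():
        hc, ac = config["hpo"], config["ara"]
        if not hc["enabled"]:
            state["best_hp"] = None
            return
        Xtr, ytr = class_arrays("train")
        data = {"train": (Xtr[:128], ytr[:128]), "val": class_arrays("val")}  # proxy subset
        obj = make_proxy_objective(data, case.num_classes, epochs=hc["proxy_epochs"],
                                   seed=stage_seed(config.seed, "hpoobj"))
        best_hp, best_val, trace = hpo_search(
            obj, default_search_space(), ac["population_size"], ac["max_iterations"],
            seed=stage_seed(config.seed, "hpo"), budget=hc["budget"],
        )
        state["best_hp"] = best_hp
        metrics["hpo"] = {"best_proxy_val_loss": best_val, "best_hyperparams": best_hp}
        pd.DataFrame(trace.to_rows()).to_csv(
            os.path.join(config.outdir, "ara_trace.csv"), index=False)
        with open(os.path.join(config.outdir, "best_hyperparams.json"), "w") as fh:
            json.dump(best_hp, fh, indent=2)


    # -- classify -----------------------------------------------------------
    def do_classify():
        cc = config["classify"]
        hp = state.get("best_hp") or {}
        data = {"train": class_arrays("train"), "val": class_arrays("val")}
        model = build_classifier(case.num_classes, width=cc["width"],
                                 seed=stage_seed(config.seed, "clsmodel"),
                                 dropout=float(hp.get("dropout", 0.0)))
        model, hist = train_classifier(model, data, hyperparams=hp, epochs=cc["epochs"],
                                       patience=cc["patience"],
                                       seed=stage_seed(config.seed, "clstrain"))
        Xte, yte = class_arrays("test")
        pred = np.argmax(model.predict_proba(Xte), axis=1)
        m = evaluate_metrics(yte, pred, case.num_classes)
        metrics["classification"] = {
            "case": case.case_id,
            "accuracy": m.accuracy,
            "macro_precision": m.macro_precision,
            "macro_recall": m.macro_recall,
            "macro_f1": m.macro_f1,
        }
        pd.DataFrame([metrics["classification"]]).to_csv(
            os.path.join(config.outdir, f"classification_case{case.case_id}.csv"), index=False)
        state["classifier"] = model
        state["test_data"] = (Xte, yte)
        from .classify import save_classifier

        save_classifier(model, os.path.join(config.outdir, "classifier.npz"))
        stats = state["stats"]
        with open(os.path.join(config.outdir, "norm_stats.json"), "w") as fh:
            json.dump({"mean": stats.mean.tolist(), "std": stats.std.tolist()}, fh)


    # -- scorecam -----------------------------------------------------------
    def do_scorecam():
        sc = config["scorecam"]
        model = state["classifier"]
        Xte, yte = state["test_data"]
        man = state["manifest"]
        test_samples = [state["samples"][p] for p in man.loc[man["split"] == "test", "path"]]
        test_samples = [s for s in test_samples if case.map_label(s.label) is not None]
        n = min(sc["n_images"], len(Xte))
        inside_frac = []
        for i in range(n):
            cam = score_cam(model, Xte[i], int(yte[i]))
            ov = overlay(test_samples[i].image, cam.heatmap, sc["colormap"])
            Image.fromarray(ov).save(os.path.join(config.outdir, f"scorecam_{i}.png"))
            m = test_samples[i].mask.astype(bool)
            if m.any() and (~m).any():
                inside_frac.append(float(cam.heatmap[m].mean() > cam.heatmap[~m].mean()))
        if inside_frac:
            metrics["scorecam"] = {"inside_mask_localization": float(np.mean(inside_frac))}


    stages = [("synth", do_synth), ("augment", do_augment), ("segment", do_segment),
              ("hpo", do_hpo), ("classify", do_classify), ("scorecam", do_scorecam)]
    for i, (name, fn) in enumerate(stages):
        run_stage(name, fn, _hash_manifest(state.get("manifest")))
        if i == last:
            break

    with open(os.path.join(config.outdir, "metrics.json"), "w") as fh:
        json.dump(metrics, fh, indent=2, default=float)
    with open(os.path.join(config.outdir, "run_records.json"), "w") as fh:
        json.dump([asdict(r) for r in records], fh, indent=2)
    return records, metrics
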