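"""Disease classification under ARA-tuned hyperparameters.

Three case studies are supported: case 1 collapses the nine disease classes
into a single "unhealthy" label (binary task), case 2 keeps six classes
(healthy, septoria leaf spot, bacterial spot, late blight, target spot,
yellow leaf curl virus), case 3 uses all ten phenotype classes.

The classifier is the Modified-U-Net encoder followed by global average
pooling, dropout and a dense softmax head.  Hyperparameters (learning rate,
batch size, dropout, weight decay) are selected by the Artificial Rabbits
Algorithm searching the unit box, decoded through a typed
:class:`SearchSpace`; the search objective is the validation loss of a
short proxy training run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .ara import ARAConfig, ara_optimize
from .unet import EarlyStopper
from .synth import CLASS_NAMES

__all__ = [
    "CaseSpec",
    "case_spec",
    "Dimension",
    "SearchSpace",
    "default_search_space",
    "ClsMetrics",
    "LeafClassifier",
    "build_classifier",
    "evaluate_metrics",
    "train_classifier",
    "save_classifier",
    "load_classifier",
    "hpo_search",
    "make_proxy_objective",
]

CASE2_CLASSES = ["TH", "TSLS", "TBS", "TLB", "TTS", "TYLCV"]


@dataclass(frozen=True)
class CaseSpec:
    """One of the three published evaluation scenarios."""

    case_id: int
    class_names: tuple[str, ...]

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def map_label(self, phenotype: str) -> int | None:
        """Class index for a phenotype label, or None if excluded."""
        if self.case_id == 1:
            return 0 if phenotype == "TH" else 1
        if phenotype in self.class_names:
            return self.class_names.index(phenotype)
        return None


def case_spec(case_id: int) -> CaseSpec:
    if case_id == 1:
        return CaseSpec(1, ("healthy", "unhealthy"))
    if case_id == 2:
        return CaseSpec(2, tuple(CASE2_CLASSES))
    if case_id == 3:
        return CaseSpec(3, tuple(CLASS_NAMES))
    raise ValueError(f"case_id must be 1, 2 or 3; got {case_id}")


# -- hyperparameter search space -------------------------------------------


@dataclass(frozen=True)
class Dimension:
    """One typed hyperparameter dimension of the search space."""

    name: str
    kind: str  # uniform | log_uniform | integer_choice
    low: float = 0.0
    high: float = 1.0
    choices: tuple = ()

    def decode(self, u: float) -> float | int:
        u = min(max(u, 0.0), 1.0)
        if self.kind == "uniform":
            return self.low + u * (self.high - self.low)
        if self.kind == "log_uniform":
            return math.exp(math.log(self.low) + u * (math.log(self.high) - math.log(self.low)))
        if self.kind == "integer_choice":
            idx = min(int(u * len(self.choices)), len(self.choices) - 1)
            return self.choices[idx]
        raise ValueError(f"unknown dimension kind {self.kind!r}")

    def encode(self, v) -> float:
        if self.kind == "uniform":
            return (v - self.low) / (self.high - self.low)
        if self.kind == "log_uniform":
            return (math.log(v) - math.log(self.low)) / (math.log(self.high) - math.log(self.low))
        if self.kind == "integer_choice":
            return (self.choices.index(v) + 0.5) / len(self.choices)
        raise ValueError(f"unknown dimension kind {self.kind!r}")


@dataclass(frozen=True)
class SearchSpace:
    """Ordered hyperparameter dimensions with unit-box encode/decode."""

    dimensions: tuple[Dimension, ...]

    @property
    def ndim(self) -> int:
        return len(self.dimensions)

    def decode(self, position: np.ndarray) -> dict:
        return {d.name: d.decode(float(u)) for d, u in zip(self.dimensions, position, strict=True)}

    def encode(self, values: dict) -> np.ndarray:
        return np.array([d.encode(values[d.name]) for d in self.dimensions])


def default_search_space() -> SearchSpace:
    """Tunables of the classifier: lr, batch size, dropout, weight decay."""
    return SearchSpace(
        (
            Dimension("learning_rate", "log_uniform", 1e-4, 1e-1),
            Dimension("batch_size", "integer_choice", choices=(8, 16, 32)),
            Dimension("dropout", "uniform", 0.0, 0.5),
            Dimension("weight_decay", "log_uniform", 1e-6, 1e-2),
        )
    )


# -- metrics ----------------------------------------------------------------


@dataclass
class ClsMetrics:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    confusion: np.ndarray


def evaluate_metrics(y_true, y_pred, num_classes: int) -> ClsMetrics:
    """Accuracy plus macro-averaged precision/recall/F1.

    Macro averaging weights every class equally (supports are balanced by
    design here).  A class absent from ``y_true`` contributes zero to the
    averages, with a warning.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} contains labels outside [0, {num_classes})")
    cm = np.zeros((num_classes, num_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    precisions, recalls, f1s = [], [], []
    for k in range(num_classes):
        tp = cm[k, k]
        support = cm[k].sum()
        predicted = cm[:, k].sum()
        if support == 0:
            warnings.warn(f"class {k} absent from y_true; contributes 0 to macro averages")
        prec = tp / predicted if predicted else 0.0
        rec = tp / support if support else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
        precisions.append(prec)
        recalls.append(rec)
        f1s.append(f1)
    return ClsMetrics(
        accuracy=float((y_true == y_pred).mean()) if y_true.size else 0.0,
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_f1=float(np.mean(f1s)),
        confusion=cm,
    )


# -- classifier -------------------------------------------------------------


class LeafClassifier:
    """Modified-U-Net encoder + global average pooling + softmax head."""

    def __init__(self, num_classes: int, width: int = 8, depth: int = 2,
                 dropout: float = 0.0, seed: int = 0):
        if num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        rng = np.random.default_rng(seed)
        layers: list[nn.Layer] = []
        cin = 3
        for d in range(depth):
            cout = width * (2**d)
            layers += [
                nn.Conv2d(cin, cout, 3, rng),
                nn.BatchNorm2d(cout),
                nn.ReLU(),
                nn.Conv2d(cout, cout, 3, rng),
                nn.BatchNorm2d(cout),
                nn.ReLU(),
                nn.MaxPool2d(),
            ]
            cin = cout
        self.encoder = nn.Sequential(*layers)
        self.gap = nn.GlobalAvgPool()
        self.drop = nn.Dropout(dropout, rng)
        self.fc = nn.Linear(cin, num_classes, rng)
        self.num_classes = num_classes
        self.encoder_out_channels = cin

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h = self.encoder.forward(x.astype(np.float32), train)
        self._last_activation = h  # exposed for Score-CAM
        h = self.gap.forward(h, train)
        h = self.drop.forward(h, train)
        return self.fc.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.fc.backward(dlogits)
        d = self.drop.backward(d)
        d = self.gap.backward(d)
        self.encoder.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(x, train=False), axis=1)

    def encoder_activations(self, x: np.ndarray) -> np.ndarray:
        """Last encoder feature maps (N, C, H', W'), inference mode."""
        return self.encoder.forward(x.astype(np.float32), train=False)

    def _layers(self):
        return nn.collect_params([self.encoder, self.fc])


def build_classifier(num_classes: int, width: int = 8, seed: int = 0,
                     depth: int = 2, dropout: float = 0.0) -> LeafClassifier:
    return LeafClassifier(num_classes, width=width, depth=depth, dropout=dropout, seed=seed)


def _xent(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.mean(np.log(p)))


def train_classifier(
    model: LeafClassifier,
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    hyperparams: dict | None = None,
    epochs: int = 15,
    patience: int = 5,
    seed: int = 0,
) -> tuple[LeafClassifier, dict]:
    """Train with cross-entropy, early stopping on validation loss.

    ``data`` maps "train"/"val" to ``(X, y)``: X (N, 3, H, W) normalized,
    y integer class labels already mapped through the case spec.
    ``hyperparams`` may override learning_rate, batch_size, weight_decay.
    Restores the best-validation-epoch weights.
    """
    hp = {"learning_rate": 0.002, "batch_size": 16, "weight_decay": 0.0}
    hp.update(hyperparams or {})
    if "train" not in data or len(data["train"][0]) == 0:
        raise ValueError("train split is empty")
    Xtr, ytr = data["train"]
    Xva, yva = data.get("val", (Xtr, ytr))
    present = set(np.unique(ytr).tolist())
    if len(present) < 2:
        raise ValueError(f"training labels contain only classes {sorted(present)}")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model._layers(), lr=hp["learning_rate"], weight_decay=hp["weight_decay"])
    bs = int(hp["batch_size"])
    history = {"train_loss": [], "val_loss": []}
    stopper = EarlyStopper(patience)
    best_state = nn.get_state(model._layers())
    for epoch in range(1, epochs + 1):
        losses = []
        order = rng.permutation(len(Xtr))
        for i in range(0, len(order), bs):
            bi = order[i : i + bs]
            logits = model.forward(Xtr[bi], train=True)
            probs = nn.softmax(logits, axis=1)
            losses.append(_xent(probs, ytr[bi]))
            onehot = np.eye(model.num_classes, dtype=np.float32)[ytr[bi]]
            model.backward((probs - onehot) / len(bi))
            opt.step()
        val_loss = _xent(model.predict_proba(Xva), yva)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(float(val_loss))
        improved = val_loss < stopper.best_loss
        stop = stopper.update(val_loss, epoch)
        if improved:
            best_state = nn.get_state(model._layers())
        if stop:
            break
    nn.set_state(model._layers(), best_state)
    history["best_epoch"] = stopper.best_epoch
    return model, history


def save_classifier(model: LeafClassifier, path: str) -> None:
    """Checkpoint the classifier (architecture meta + weights) as .npz."""
    import json as _json

    state = nn.get_state(model._layers())
    flat = {f"l{i}__{k}": v for i, st in enumerate(state) for k, v in st.items()}
    meta = {
        "num_classes": model.num_classes,
        "width": model.encoder.layers[0].out_ch,
        "depth": sum(isinstance(l, nn.MaxPool2d) for l in model.encoder.layers),
    }
    np.savez(path, __meta__=_json.dumps(meta), **flat)


def load_classifier(path: str) -> LeafClassifier:
    import json as _json

    data = np.load(path, allow_pickle=False)
    meta = _json.loads(str(data["__meta__"]))
    model = build_classifier(meta["num_classes"], width=meta["width"], depth=meta["depth"])
    state: list[dict] = []
    for key in data.files:
        if key == "__meta__":
            continue
        i, k = key.split("__", 1)
        i = int(i[1:])
        while len(state) <= i:
            state.append({})
        state[i][k] = data[key]
    nn.set_state(model._layers(), state)
    return model


# -- HPO ---------------------------------------------------------------------


def make_proxy_objective(
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    num_classes: int,
    epochs: int = 3,
    width: int = 4,
    seed: int = 0,
):
    """Objective factory: validation loss of a short proxy training run.

    The proxy uses a narrow classifier and few epochs so one evaluation is
    cheap; the selected configuration is meant to be retrained in full.
    """

    def objective(hp: dict) -> float:
        model = build_classifier(
            num_classes, width=width, seed=seed, dropout=float(hp.get("dropout", 0.0))
        )
        _, hist = train_classifier(
            model, data, hyperparams=hp, epochs=epochs, patience=epochs, seed=seed
        )
        return float(np.min(hist["val_loss"]))

    return objective


def hpo_search(
    objective,
    space: SearchSpace,
    population_size: int = 4,
    iterations: int = 3,
    seed: int = 0,
    budget: int | None = None,
):
    """ARA search over a hyperparameter space.

    ``objective`` maps a decoded hyperparameter dict to a scalar to
    minimize (typically validation loss of a proxy run).  Total objective
    evaluations are ``population_size * (iterations + 1)``, checked against
    ``budget`` when given.  Returns ``(best_hyperparams, best_value, trace)``.
    """
    if budget is not None:
        if budget < population_size:
            raise ValueError(f"budget {budget} < population size {population_size}")
        iterations = max(1, min(iterations, budget // population_size - 1))
    config = ARAConfig(
        population_size=population_size,
        max_iterations=iterations,
        dimensions=space.ndim,
        lower_bounds=np.zeros(space.ndim),
        upper_bounds=np.ones(space.ndim),
        seed=seed,
    )
    best_pos, best_val, trace = ara_optimize(lambda u: objective(space.decode(u)), config)
    return space.decode(best_pos), float(best_val), trace
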