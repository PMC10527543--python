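"""Modified U-Net leaf/background segmenter.

An encoder-decoder CNN: each encoder block is two 3x3 convolutions with
batch normalization and ReLU followed by 2x2 stride-2 max pooling; the
decoder mirrors it with 2x2 transposed-convolution upsampling and
concatenated skip connections (the "modified" decoding path); a final 1x1
convolution maps to two channels and a per-pixel softmax yields leaf /
background probabilities.

Training supports three selectable losses (NLL on the log-softmax, BCE and
MSE on the foreground probability), early stopping on validation loss with
best-epoch weight restoration, Dice/pixel-accuracy evaluation, and
stratified k-fold cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import nn

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "SegMetrics",
    "ModifiedUNet",
    "build_modified_unet",
    "seg_loss",
    "seg_loss_grad",
    "dice_score",
    "train_segmentation",
    "evaluate_segmentation",
    "kfold_cv",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class UNetSpec:
    """Architecture of the Modified U-Net."""

    depth: int = 2  # number of encoder blocks
    base_channels: int = 8
    in_channels: int = 3
    out_classes: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class TrainConfig:
    """Training constraints (published defaults: lr 0.002, batch 16)."""

    learning_rate: float = 0.002
    batch_size: int = 16
    epochs: int = 50
    patience: int = 5  # epochs without val-loss improvement before stopping
    loss: str = "NLL"

    def __post_init__(self):
        if self.loss not in ("NLL", "BCE", "MSE"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.patience > self.epochs:
            raise ValueError("patience must not exceed epochs")


@dataclass
class SegMetrics:
    loss: float
    pixel_accuracy: float
    dice: float


def _conv_block(cin, cout, rng):
    return nn.Sequential(
        nn.Conv2d(cin, cout, 3, rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
        nn.Conv2d(cout, cout, 3, rng),
        nn.BatchNorm2d(cout),
        nn.ReLU(),
    )


class ModifiedUNet:
    """U-Net with transposed-conv upsampling and concatenated skips."""

    def __init__(self, spec: UNetSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ch = spec.base_channels
        self.enc_blocks = []
        self.pools = []
        cin = spec.in_channels
        self.enc_channels = []
        for d in range(spec.depth):
            cout = ch * (2**d)
            self.enc_blocks.append(_conv_block(cin, cout, rng))
            self.pools.append(nn.MaxPool2d())
            self.enc_channels.append(cout)
            cin = cout
        self.bottleneck = _conv_block(cin, ch * (2**spec.depth), rng)
        cin = ch * (2**spec.depth)
        self.upconvs = []
        self.dec_blocks = []
        for d in reversed(range(spec.depth)):
            skip = self.enc_channels[d]
            self.upconvs.append(nn.ConvTranspose2d(cin, skip, rng))
            self.dec_blocks.append(_conv_block(2 * skip, skip, rng))
            cin = skip
        self.head = nn.Conv2d(cin, spec.out_classes, 1, rng)

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Logits of shape (N, out_classes, H, W); H, W divisible by 2^depth."""
        H, W = x.shape[2], x.shape[3]
        f = 2**self.spec.depth
        if H % f or W % f:
            raise ValueError(f"input {H}x{W} not divisible by 2^depth={f}")
        skips = []
        h = x.astype(np.float32)
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, train)
            skips.append(h)
            h = pool.forward(h, train)
        h = self.bottleneck.forward(h, train)
        self._skip_channels = []
        for up, dec, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            h = up.forward(h, train)
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = dec.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for up, dec, c in zip(
            reversed(self.upconvs), reversed(self.dec_blocks), reversed(self._skip_channels)
        ):
            d = dec.backward(d)
            d, dskip = d[:, :-c], d[:, -c:]
            dskips.append(dskip)
            d = up.backward(d)
        d = self.bottleneck.backward(d)
        # dskips collected outermost-first; encoder backward runs innermost-first
        for blk, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = blk.backward(d + dskip)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel class probabilities (softmax over channel axis)."""
        return nn.softmax(self.forward(x, train=False), axis=1)

    def predict_mask(self, x: np.ndarray) -> np.ndarray:
        """Binary leaf mask via argmax over the two-class softmax."""
        return np.argmax(self.forward(x, train=False), axis=1).astype(np.uint8)

    def n_parameters(self) -> int:
        return sum(p.size for lay in self._layers() for p in lay.params.values())

    def _layers(self):
        return nn.collect_params(
            [self.enc_blocks, self.bottleneck, self.upconvs, self.dec_blocks, self.head]
        )


def build_modified_unet(spec: UNetSpec) -> ModifiedUNet:
    return ModifiedUNet(spec)


def _foreground_prob(predictions: np.ndarray) -> np.ndarray:
    p = np.asarray(predictions, dtype=np.float64)
    if p.ndim >= 3 and p.shape[-3] == 2:  # (..., 2, H, W) class probabilities
        return np.moveaxis(p, -3, 0)[1]
    return p


def seg_loss(predictions: np.ndarray, mask: np.ndarray, kind: str) -> float:
    """Mean per-pixel segmentation loss.

    ``predictions`` are per-pixel class probabilities with a channel axis of
    size 2 (background, foreground), or a plain foreground-probability array
    for BCE/MSE.  NLL is the mean negative log probability of the true
    class; BCE the binary cross-entropy of the foreground probability
    against the mask; MSE their mean squared difference.  Zero probabilities
    at a true-class pixel are clamped at 1e-12 (and logged).
    """
    mask = np.asarray(mask)
    p1 = _foreground_prob(predictions)
    if p1.shape != mask.shape:
        raise ValueError(f"prediction spatial shape {p1.shape} != mask {mask.shape}")
    y = mask.astype(np.float64)
    if kind == "MSE":
        return float(np.mean((p1 - y) ** 2))
    p_true = np.where(y > 0.5, p1, 1.0 - p1)
    if np.any(p_true <= _EPS):
        logger.warning("clamped %d zero probabilities at true-class pixels",
                       int(np.sum(p_true <= _EPS)))
        p_true = np.clip(p_true, _EPS, None)
    if kind == "NLL":
        return float(-np.mean(np.log(p_true)))
    if kind == "BCE":
        p1c = np.clip(p1, _EPS, 1.0 - _EPS)
        return float(-np.mean(y * np.log(p1c) + (1.0 - y) * np.log(1.0 - p1c)))
    raise ValueError(f"unknown loss kind {kind!r}")


def seg_loss_grad(logits: np.ndarray, mask: np.ndarray, kind: str) -> np.ndarray:
    """Gradient of the mean loss w.r.t. the two-channel logits."""
    probs = nn.softmax(logits, axis=1)
    p1 = probs[:, 1]
    y = mask.astype(np.float32)
    npix = y.size
    if kind == "NLL":
        onehot = np.stack([1.0 - y, y], axis=1)
        return (probs - onehot) / npix
    if kind == "BCE":
        d1 = (p1 - y) / npix  # softmax+BCE collapses to this
    elif kind == "MSE":
        d1 = 2.0 * (p1 - y) * p1 * (1.0 - p1) / npix
    else:
        raise ValueError(f"unknown loss kind {kind!r}")
    return np.stack([-d1, d1], axis=1).astype(np.float32)


def dice_score(pred_mask: np.ndarray, true_mask: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A| + |B|); two empty masks score 1."""
    a = np.asarray(pred_mask).astype(bool)
    b = np.asarray(true_mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


class EarlyStopper:
    """Stop after ``patience`` consecutive epochs without val-loss improvement.

    Tracks the best (strictly lowest) validation loss seen; callers restore
    the weights snapshotted at ``best_epoch`` when ``update`` returns True
    (stop) or the epoch budget runs out.
    """

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = 0
        self.since_best = 0

    def update(self, val_loss: float, epoch: int) -> bool:
        """Record one epoch's validation loss; True means stop now."""
        if val_loss < self.best_loss:
            self.best_loss = val_loss
            self.best_epoch = epoch
            self.since_best = 0
            return False
        self.since_best += 1
        return self.since_best >= self.patience


def _batches(n, batch_size, rng):
    idx = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield idx[i : i + batch_size]


def train_segmentation(
    model: ModifiedUNet,
    data: dict[str, tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    seed: int = 0,
) -> tuple[ModifiedUNet, dict]:
    """Train with early stopping on validation loss.

    ``data`` maps split names to ``(X, Y)`` pairs: X of shape (N, 3, H, W)
    (normalized), Y binary masks (N, H, W).  Stops when the validation loss
    has not improved for ``config.patience`` consecutive epochs, and
    restores the weights of the best-validation epoch.  Returns the model
    and a history dict with per-epoch train/val losses.
    """
    if "train" not in data or len(data["train"][0]) == 0:
        raise ValueError("train split is empty")
    if "val" not in data or len(data["val"][0]) == 0:
        raise ValueError("val split is empty")
    Xtr, Ytr = data["train"]
    Xva, Yva = data["val"]
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model._layers(), lr=config.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    stopper = EarlyStopper(config.patience)
    best_state = nn.get_state(model._layers())
    for epoch in range(1, config.epochs + 1):
        losses = []
        for bi in _batches(len(Xtr), config.batch_size, rng):
            logits = model.forward(Xtr[bi], train=True)
            probs = nn.softmax(logits, axis=1)
            losses.append(seg_loss(probs, Ytr[bi], config.loss))
            model.backward(seg_loss_grad(logits, Ytr[bi], config.loss))
            opt.step()
        val_probs = model.predict_proba(Xva)
        val_loss = seg_loss(val_probs, Yva, config.loss)
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
    history["stopped_epoch"] = epoch
    return model, history


def evaluate_segmentation(
    model: ModifiedUNet, X: np.ndarray, Y: np.ndarray, loss_kind: str = "NLL",
    batch_size: int = 16,
) -> SegMetrics:
    """Loss, pixel accuracy and mean per-image Dice on a held-out set."""
    losses, accs, dices = [], [], []
    for i in range(0, len(X), batch_size):
        xb, yb = X[i : i + batch_size], Y[i : i + batch_size]
        probs = model.predict_proba(xb)
        losses.append(seg_loss(probs, yb, loss_kind) * len(xb))
        pred = np.argmax(probs, axis=1)
        accs.append(float((pred == yb).mean()) * len(xb))
        dices.extend(dice_score(p, t) for p, t in zip(pred, yb))
    n = len(X)
    return SegMetrics(
        loss=float(np.sum(losses) / n),
        pixel_accuracy=float(np.sum(accs) / n),
        dice=float(np.mean(dices)),
    )


def kfold_cv(labels, k: int, train_eval_fn, seed: int = 0) -> dict:
    """Stratified k-fold cross-validation driver.

    ``labels`` is a per-sample class sequence (e.g. the manifest's class
    column); ``train_eval_fn(train_idx, val_idx) -> dict`` trains and
    evaluates one fold.  Every sample lands in exactly one validation fold.
    Returns ``{"folds": [...], "mean": {...}, "sd": {...}}``.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds smallest class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for tr, va in skf.split(np.zeros(len(labels)), labels):
        folds.append(dict(train_eval_fn(tr, va)))
    keys = folds[0].keys()
    mean = {key: float(np.mean([f[key] for f in folds])) for key in keys}
    sd = {key: float(np.std([f[key] for f in folds], ddof=1)) for key in keys}
    return {"folds": folds, "mean": mean, "sd": sd}
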