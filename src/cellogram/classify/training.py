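"""Training, classification and manual review of EIC images.

The protocol: mini-batches of 64, a stratified 30% validation split
held out from the training data, validation every 30 iterations, and
early stopping after five consecutive checks without improvement in
validation loss.  "No improvement" means not strictly below the best
seen; the returned model carries the best-validation-loss checkpoint,
not the last state.  Everything is driven by the config seed, so a
repeated run with the same data reproduces the training log exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .images import EICImage, RENDERER_VERSION
from .nn import MODEL_REGISTRY, CompactCNN, preprocess_images

__all__ = ["CLASSES", "SpeciesLabel", "TrainConfig", "TrainedClassifier",
           "Prediction", "train_classifier", "classify", "review_overrides"]

CLASSES = ("high_sn", "low_sn", "background")
_ENDOGENOUS = {"high_sn", "low_sn"}


@dataclass(frozen=True)
class SpeciesLabel:
    """Three-way chronogram class with its fixed binary projection."""

    cls: str

    def __post_init__(self):
        if self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}")

    @property
    def binary(self) -> str:
        return "endogenous" if self.cls in _ENDOGENOUS else "background"


@dataclass
class TrainConfig:
    batch_size: int = 64
    val_fraction: float = 0.30
    val_interval: int = 30      # iterations between validation checks
    patience: int = 5           # checks without improvement before stopping
    max_epochs: int = 60
    seed: int = 0
    lr: float = 1e-3
    class_weights: dict | None = None

    def __post_init__(self):
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class Prediction:
    """Classification of one species, with optional manual override."""

    feature_id: object
    predicted: SpeciesLabel
    scores: dict
    final: SpeciesLabel = None
    overridden: bool = False

    def __post_init__(self):
        if self.final is None:
            self.final = self.predicted


class TrainedClassifier:
    """A trained model handle: serializable, versioned to its renderer."""

    def __init__(self, model, classes=CLASSES,
                 renderer_version: str = RENDERER_VERSION,
                 log: list | None = None, best_val_loss: float = np.nan,
                 val_indices=None):
        self.model = model
        self.classes = tuple(classes)
        self.renderer_version = renderer_version
        self.log = log or []
        self.best_val_loss = best_val_loss
        #: indices (into the training input) held out for validation;
        #: also the natural held-out set for evaluation
        self.val_indices = list(val_indices) if val_indices is not None else []

    def predict_proba(self, images: list[EICImage]) -> np.ndarray:
        for img in images:
            if img.renderer_version != self.renderer_version:
                raise ValueError(
                    f"renderer version mismatch: image {img.renderer_version!r} "
                    f"vs model {self.renderer_version!r}"
                )
        x = preprocess_images(np.stack([img.pixels for img in images]))
        return self.model.predict_proba(x)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "classes": list(self.classes),
            "renderer_version": self.renderer_version,
            "best_val_loss": None if np.isnan(self.best_val_loss)
            else self.best_val_loss,
            "hyperparams": self.model.hyperparams(),
            "log": self.log,
            "val_indices": [int(i) for i in self.val_indices],
        }
        arrays = {f"param_{k}": v for k, v in self.model.get_state().items()}
        with open(path, "wb") as fh:
            np.savez(fh, meta=json.dumps(meta), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            state = {k[len("param_"):]: data[k] for k in data.files
                     if k.startswith("param_")}
        hp = meta["hyperparams"]
        factory = MODEL_REGISTRY[hp["model"]]
        model = factory(n_classes=hp["n_classes"], seed=hp["seed"], lr=hp["lr"])
        model.set_state(state)
        best = meta["best_val_loss"]
        return cls(model, classes=meta["classes"],
                   renderer_version=meta["renderer_version"],
                   log=meta["log"],
                   best_val_loss=np.nan if best is None else best,
                   val_indices=meta.get("val_indices"))


def _stratified_split(labels: np.ndarray, fraction: float,
                      rng: np.random.Generator):
    val_idx = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * idx.size)))
        val_idx.extend(idx[:n_val])
    val = np.sort(np.asarray(val_idx))
    train = np.setdiff1d(np.arange(labels.size), val)
    return train, val


def train_classifier(images: list[EICImage], labels, cfg: TrainConfig,
                     model=None) -> TrainedClassifier:
    """Train a 3-class EIC image classifier with early stopping.

    ``labels`` are class names from :data:`CLASSES` (or
    :class:`SpeciesLabel`).  A stratified ``val_fraction`` of the data
    is held out; training stops early after ``patience`` consecutive
    validation checks without a strictly better validation loss, and
    the best checkpoint is restored.
    """
    names = np.array([l.cls if isinstance(l, SpeciesLabel) else str(l)
                      for l in labels])
    present = set(names)
    unknown = present - set(CLASSES)
    if unknown:
        raise ValueError(f"unknown classes: {sorted(unknown)}")
    if len(present) < 2:
        raise ValueError("training requires at least two classes")
    if len(images) != names.size:
        raise ValueError("images and labels differ in length")

    y = np.array([CLASSES.index(n) for n in names])
    x = preprocess_images(np.stack([img.pixels for img in images]))
    renderer_versions = {img.renderer_version for img in images}
    if len(renderer_versions) != 1:
        raise ValueError("mixed renderer versions in training images")

    rng = np.random.default_rng(cfg.seed)
    train_idx, val_idx = _stratified_split(names, cfg.val_fraction, rng)
    x_train, y_train = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    if model is None:
        model = CompactCNN(n_classes=len(CLASSES), seed=cfg.seed, lr=cfg.lr)

    log = [{"event": "start",
            "class_counts": {c: int((names == c).sum()) for c in CLASSES},
            "n_train": int(train_idx.size), "n_val": int(val_idx.size)}]
    best_loss = np.inf
    best_state = model.get_state()
    bad_checks = 0
    iteration = 0
    stop = False

    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(train_idx.size)
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            loss = model.train_step(x_train[batch], y_train[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at iteration {iteration}"
                )
            iteration += 1
            if iteration % cfg.val_interval == 0:
                val_loss = model.loss(x_val, y_val)
                probs = model.predict_proba(x_val)
                val_acc = float((probs.argmax(axis=1) == y_val).mean())
                improved = val_loss < best_loss
                log.append({"event": "validation", "iteration": iteration,
                            "train_loss": round(loss, 6),
                            "val_loss": round(float(val_loss), 6),
                            "val_accuracy": round(val_acc, 6),
                            "improved": bool(improved)})
                if improved:
                    best_loss = val_loss
                    best_state = model.get_state()
                    bad_checks = 0
                else:
                    bad_checks += 1
                    if bad_checks >= cfg.patience:
                        stop = True
                        break
        if stop:
            break

    model.set_state(best_state)
    log.append({"event": "stop", "iteration": iteration,
                "best_val_loss": round(float(best_loss), 6),
                "early_stopped": stop})
    return TrainedClassifier(model, log=log, best_val_loss=float(best_loss),
                             val_indices=val_idx)


def classify(trained: TrainedClassifier, images: list[EICImage],
             feature_ids=None) -> list[Prediction]:
    """Assign a chronogram class (and binary label) per image.

    Argmax over the class scores; an exact tie involving the
    background class resolves to background — conservative, since a
    flagged species stays out of the endogenous pool until reviewed.
    """
    probs = trained.predict_proba(images)
    if feature_ids is None:
        feature_ids = list(range(len(images)))
    out = []
    bg = trained.classes.index("background")
    for fid, p in zip(feature_ids, probs):
        top = np.flatnonzero(p == p.max())
        idx = bg if bg in top else int(top[0])
        out.append(Prediction(
            feature_id=fid,
            predicted=SpeciesLabel(trained.classes[idx]),
            scores={c: float(v) for c, v in zip(trained.classes, p)},
        ))
    return out


def review_overrides(predictions: list[Prediction],
                     overrides) -> list[Prediction]:
    """Apply manual class overrides to predictions.

    ``overrides`` maps feature id to class name.  The model's original
    prediction is retained as provenance; applying the same overrides
    again is a no-op.  Unknown feature ids raise ``KeyError``.
    """
    items = overrides.items() if hasattr(overrides, "items") else overrides
    by_id = {p.feature_id: p for p in predictions}
    for fid, _cls in items:
        if fid not in by_id:
            raise KeyError(f"unknown feature id: {fid!r}")
    out = []
    override_map = dict(items)
    for p in predictions:
        if p.feature_id in override_map:
            out.append(Prediction(
                feature_id=p.feature_id,
                predicted=p.predicted,
                scores=dict(p.scores),
                final=SpeciesLabel(override_map[p.feature_id]),
                overridden=True,
            ))
        else:
            out.append(p)
    return out
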