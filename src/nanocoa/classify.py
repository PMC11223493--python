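"""Training and validation of the per-event classifier.

The classifier assigns each translocation event to a cOA stoichiometry
class (default class set: cA3/4, cA5, cA6 — cA3 and cA4 are merged because
their events are indistinguishable in this assay). Training follows a
fixed protocol: oversampling of minority classes, Adam at learning rate
0.001 for 100 epochs on the cross-entropy loss, and five random restarts
of which the one with the highest training accuracy is kept.

Validation uses trace-grouped k-fold cross-validation: events of a given
trace are never split between training and test sets, so no
trace-specific characteristics can leak into the accuracy estimate. A
k-nearest-neighbor baseline on (relative blockade, log dwell time) serves
as the conventional feature-based reference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .cnn import EventCNN

logger = logging.getLogger(__name__)

#: Default ordered class set.
DEFAULT_CLASS_ORDER = ("cA3/4", "cA5", "cA6")


def build_classifier(n_classes: int, input_width: int = 251, seed: int | None = None) -> EventCNN:
    """Untrained per-event CNN (see :class:`nanocoa.cnn.EventCNN`)."""
    return EventCNN(n_classes=n_classes, input_width=input_width, seed=seed)


def train(
    classifier: EventCNN,
    events: np.ndarray,
    labels: np.ndarray,
    epochs: int = 100,
    learning_rate: float = 1e-3,
    restarts: int = 5,
    seed: int | None = None,
    batch_size: int = 32,
    class_names: tuple[str, ...] | None = None,
) -> tuple[EventCNN, dict]:
    """Train with random restarts; keep the highest-training-accuracy run.

    *labels* are integer class indices in ``range(classifier.n_classes)``;
    every class must be present. The returned log maps each restart to its
    per-epoch loss/accuracy history plus the final training accuracy.
    """
    events = np.asarray(events, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if events.shape[0] != labels.shape[0]:
        raise ValueError("events and labels must be aligned")
    present = set(np.unique(labels).tolist())
    for c in range(classifier.n_classes):
        if c not in present:
            name = class_names[c] if class_names else str(c)
            raise ValueError(f"class {name!r} has zero events in the training set")
    if len(present) < 2:
        raise ValueError("need at least 2 classes present in the training set")

    seeds = np.random.SeedSequence(seed).spawn(restarts)
    best_state, best_acc = None, -1.0
    log: dict = {"restarts": []}
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        classifier.reinitialize(rng)
        history = classifier.fit(
            events, labels, epochs=epochs, learning_rate=learning_rate,
            batch_size=batch_size, rng=rng,
        )
        acc = classifier.accuracy(events, labels)
        log["restarts"].append({"restart": r, "history": history, "training_accuracy": acc})
        if acc > best_acc:
            best_acc = acc
            best_state = classifier.state_dict()
    classifier.load_state_dict(best_state)
    log["selected_training_accuracy"] = best_acc
    return classifier, log


@dataclass
class ConfusionMatrix:
    """Relative prediction frequencies per ground-truth class.

    ``mean`` and ``sd`` aggregate the row-normalized per-fold matrices
    (rows: truth, columns: prediction); each row of ``mean`` sums to 1.
    ``overall_accuracy`` pools the predictions of all folds into one set.
    """

    classes: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    fold_matrices: np.ndarray  # (k, C, C)
    overall_accuracy: float


@dataclass
class CVResult:
    confusion: ConfusionMatrix
    models: list[EventCNN]
    fold_of_group: dict
    predictions: np.ndarray  # merged out-of-fold predictions, aligned with input
    fold_of_event: np.ndarray


def _fold_counts(y_true, y_pred, n_classes) -> np.ndarray:
    m = np.zeros((n_classes, n_classes))
    np.add.at(m, (y_true, y_pred), 1.0)
    return m


def grouped_cross_validate(
    events: np.ndarray,
    labels: np.ndarray,
    groups: np.ndarray,
    k: int = 10,
    seed: int | None = None,
    class_names: tuple[str, ...] | None = None,
    classifier_factory=None,
    **train_kwargs,
) -> CVResult:
    """Trace-grouped k-fold cross-validation.

    Folds partition *groups* (trace identifiers), never individual events.
    If a random partition leaves some training fold without one of the
    classes, the partition is re-randomized (up to 20 attempts).
    """
    events = np.asarray(events, dtype=float)
    labels = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    n_classes = int(labels.max()) + 1
    if class_names is None:
        class_names = tuple(str(c) for c in range(n_classes))
    unique_groups = np.unique(groups)
    if unique_groups.size < k:
        raise ValueError(f"need at least k={k} traces, got {unique_groups.size}")

    rng = np.random.default_rng(seed)
    for attempt in range(20):
        shuffled = rng.permutation(unique_groups)
        folds = np.array_split(shuffled, k)
        ok = True
        for fold_groups in folds:
            train_mask = ~np.isin(groups, fold_groups)
            if set(np.unique(labels[train_mask])) != set(range(n_classes)):
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError("could not build folds with every class present in each training set")

    if classifier_factory is None:
        classifier_factory = lambda s: build_classifier(n_classes, input_width=events.shape[1], seed=s)

    fold_seeds = np.random.SeedSequence(seed).spawn(k)
    models: list[EventCNN] = []
    fold_mats = []
    predictions = np.full(labels.size, -1, dtype=int)
    fold_of_event = np.full(labels.size, -1, dtype=int)
    fold_of_group: dict = {}
    for f, fold_groups in enumerate(folds):
        for g in fold_groups:
            fold_of_group[g] = f
        test_mask = np.isin(groups, fold_groups)
        train_mask = ~test_mask
        fold_seed = int(fold_seeds[f].generate_state(1)[0] % (2**31))
        model = classifier_factory(fold_seed)
        model, _ = train(
            model, events[train_mask], labels[train_mask],
            seed=fold_seed, class_names=class_names, **train_kwargs,
        )
        models.append(model)
        y_pred = model.predict(events[test_mask])
        predictions[test_mask] = y_pred
        fold_of_event[test_mask] = f
        fold_mats.append(_fold_counts(labels[test_mask], y_pred, n_classes))

    fold_mats = np.array(fold_mats)
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = fold_mats / fold_mats.sum(axis=2, keepdims=True)
    confusion = ConfusionMatrix(
        classes=class_names,
        mean=np.nanmean(normalized, axis=0),
        sd=np.nanstd(normalized, axis=0),
        fold_matrices=normalized,
        overall_accuracy=float(np.mean(predictions == labels)),
    )
    return CVResult(
        confusion=confusion,
        models=models,
        fold_of_group=fold_of_group,
        predictions=predictions,
        fold_of_event=fold_of_event,
    )


def knn_baseline(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    k: int = 3,
) -> np.ndarray:
    """KNN on standardized (relative blockade, log dwell time) features.

    Majority vote among the k nearest neighbors (Euclidean metric after
    z-scoring each feature on the training fold); ties are broken by the
    nearest neighbor whose label is among the tied labels.
    """
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    train_labels = np.asarray(train_labels)
    if train_features.shape[0] == 0:
        raise ValueError("empty training set")
    if k > train_features.shape[0]:
        raise ValueError("k exceeds the training-set size")
    mu = train_features.mean(axis=0)
    sd = train_features.std(axis=0)
    sd[sd == 0] = 1.0
    nn = NearestNeighbors(n_neighbors=k).fit((train_features - mu) / sd)
    _, idx = nn.kneighbors((test_features - mu) / sd)
    neighbor_labels = train_labels[idx]  # (n_test, k), nearest first
    out = np.empty(test_features.shape[0], dtype=train_labels.dtype)
    for i, row in enumerate(neighbor_labels):
        values, counts = np.unique(row, return_counts=True)
        top = counts.max()
        tied = set(values[counts == top].tolist())
        if len(tied) == 1:
            out[i] = tied.pop()
        else:
            out[i] = next(lab for lab in row if lab in tied)
    return out


# ---------------------------------------------------------------------------
# persistence


def save_model(
    path,
    model: EventCNN,
    class_order: tuple[str, ...],
    duration_stats: tuple[float, float] | None = None,
) -> None:
    """Save weights plus a manifest (class order, duration-feature stats)."""
    arrays = {f"param__{k}": v for k, v in model.params.items()}
    arrays.update({f"running__{k}": v for k, v in model.running.items()})
    manifest = {
        "class_order": list(class_order),
        "duration_stats": list(duration_stats) if duration_stats is not None else None,
        "n_classes": model.n_classes,
        "input_width": model.input_width,
        "architecture": model.architecture_summary(),
    }
    arrays["manifest_json"] = np.array(json.dumps(manifest))
    np.savez(path, **arrays)


def load_model(path) -> tuple[EventCNN, dict]:
    """Load a saved model; returns (model, manifest)."""
    data = np.load(path, allow_pickle=False)
    manifest = json.loads(str(data["manifest_json"]))
    model = EventCNN(n_classes=manifest["n_classes"], input_width=manifest["input_width"])
    model.params = {k.removeprefix("param__"): data[k] for k in data.files if k.startswith("param__")}
    model.running = {k.removeprefix("running__"): data[k] for k in data.files if k.startswith("running__")}
    return model, manifest
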