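"""Evaluation: recall against a truth gene list, winner-take-all
classification accuracy, and the biomarker intersection procedure.

The classifier is a competitive (winner-take-all) network: one weight
vector per competitive unit; for each input the unit with the nearest
weight vector wins and moves toward the input; after training each unit
is labelled with the majority class of the inputs it wins.  Accuracy is
the fraction of specimens whose winning unit carries their true class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from logicmine.errors import ValidationError


def recall_rate(detected: Iterable[str], truth: Iterable[str]) -> float:
    """|detected ∩ truth| / |truth|."""
    truth_set = set(truth)
    if not truth_set:
        raise ValidationError("truth set is empty")
    return len(set(detected) & truth_set) / len(truth_set)


@dataclass
class ClassifierModel:
    weights: np.ndarray          # (units, features)
    unit_class: list[str | None]  # majority class per unit (None = dead unit)
    feature_ids: list[str]


def _inputs(m: pd.DataFrame) -> np.ndarray:
    return m.to_numpy().astype(np.float64).T  # specimens x features


def train_competitive(
    m: pd.DataFrame,
    labels: Sequence[str],
    n_units: int | None = None,
    learning_rate: float = 0.1,
    epochs: int = 50,
    rng: np.random.Generator | int | None = None,
) -> ClassifierModel:
    """Online competitive learning on the specimen columns of ``m``.

    Units default to the number of classes; weights start at randomly
    chosen specimens (seeded); the learning rate decays linearly to zero
    over the epochs.  A unit that wins no inputs is dropped with a
    warning.
    """
    X = _inputs(m)
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ValidationError("one label per specimen required")
    classes = sorted(set(labels))
    if not classes:
        raise ValidationError("no specimens")
    n_units = n_units if n_units is not None else max(len(classes), 1)
    if n_units < len(classes):
        raise ValidationError("need at least one unit per class")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    init = rng.choice(X.shape[0], size=n_units, replace=X.shape[0] < n_units)
    W = X[init].copy() + rng.normal(scale=1e-3, size=(n_units, X.shape[1]))
    for epoch in range(epochs):
        lr = learning_rate * (1.0 - epoch / epochs)
        for idx in rng.permutation(X.shape[0]):
            x = X[idx]
            winner = int(np.argmin(((W - x) ** 2).sum(axis=1)))
            W[winner] += lr * (x - W[winner])
    # label units by the majority class of the inputs they win
    wins: list[list[str]] = [[] for _ in range(n_units)]
    for idx in range(X.shape[0]):
        winner = int(np.argmin(((W - X[idx]) ** 2).sum(axis=1)))
        wins[winner].append(labels[idx])
    unit_class: list[str | None] = []
    for u, won in enumerate(wins):
        if not won:
            warnings.warn(f"competitive unit {u} won no inputs and is dropped")
            unit_class.append(None)
        else:
            vals, counts = np.unique(won, return_counts=True)
            unit_class.append(str(vals[np.argmax(counts)]))
    return ClassifierModel(weights=W, unit_class=unit_class, feature_ids=[str(i) for i in m.index])


def classification_accuracy(
    model: ClassifierModel, m: pd.DataFrame, labels: Sequence[str]
) -> float:
    """Fraction of specimens whose winning unit carries their true class."""
    if [str(i) for i in m.index] != model.feature_ids:
        raise ValidationError("matrix features do not match the model's feature set")
    X = _inputs(m)
    labels = list(labels)
    if len(labels) != X.shape[0]:
        raise ValidationError("one label per specimen required")
    live = [u for u, cls in enumerate(model.unit_class) if cls is not None]
    if not live:
        raise ValidationError("model has no live units")
    W = model.weights[live]
    correct = 0
    for idx in range(X.shape[0]):
        winner = live[int(np.argmin(((W - X[idx]) ** 2).sum(axis=1)))]
        if model.unit_class[winner] == labels[idx]:
            correct += 1
    return correct / X.shape[0]


def select_biomarkers(
    ranked_genes: Sequence[str],
    disease_related: Iterable[str],
    top_k: int,
) -> set[str]:
    """Intersection of the top-k ranked genes with a disease-related set."""
    if top_k > len(ranked_genes):
        warnings.warn(
            f"top_k={top_k} exceeds the {len(ranked_genes)} ranked genes; capped"
        )
        top_k = len(ranked_genes)
    return set(ranked_genes[:top_k]) & set(disease_related)
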