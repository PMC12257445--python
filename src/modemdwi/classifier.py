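"""Model-free signal classification (MODEM): a multilayer perceptron on
normalized diffusion signal vectors.

Each voxel (or simulated decay) is a sample whose features are the
normalized signals S(b)/S0 at the nonzero b-values.  The network has one
input layer of n neurons (n = number of nonzero b-values), six fully
connected hidden layers of n ReLU units each, and a 2-unit softmax output.
Training uses Adam on the cross-entropy loss, at most 100 epochs, with a
10% internal validation hold-out and early stopping after 10 epochs without
validation improvement.

Class imbalance in the training partition is corrected beforehand with
SMOTE: synthetic minority samples are convex combinations
x + u (x_nn - x), u ~ U(0, 1), of a minority sample and one of its k
nearest minority neighbors.  SMOTE is applied to the training partition
only, before the internal validation split, so neither the validation nor
the test data leak into oversampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier

N_HIDDEN_LAYERS = 6


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and training hyperparameters of the MODEM network."""

    n_inputs: int
    max_epochs: int = 100
    validation_fraction: float = 0.10
    early_stop_patience: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 200
    seed: int = 0

    @property
    def hidden_layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs,) * N_HIDDEN_LAYERS


@dataclass
class TrainedClassifier:
    """Fitted network plus training metadata."""

    estimator: MLPClassifier
    spec: MLPSpec
    n_epochs: int = 0
    final_validation_loss: float = float("nan")
    metadata: dict = field(default_factory=dict)


def normalize_signals(table_or_array, b_values=None) -> np.ndarray:
    """Feature vectors S(b)/S0 at the nonzero b-values.

    Accepts a signal-table DataFrame (b_* columns; b-values parsed from the
    header) or a raw (n_samples, n_b) array with an explicit ``b_values``
    grid whose first entry is 0.  Division is by the measured b = 0 column,
    so for noisy data the features are normalized by the noisy S0.
    """
    if isinstance(table_or_array, pd.DataFrame):
        cols = [c for c in table_or_array.columns if str(c).startswith("b_")]
        b = np.array([float(str(c)[2:]) for c in cols])
        order = np.argsort(b)
        b = b[order]
        arr = table_or_array[cols].to_numpy(dtype=float)[:, order]
    else:
        if b_values is None:
            raise ValueError("b_values required for array input")
        b = np.asarray(b_values, dtype=float)
        arr = np.atleast_2d(np.asarray(table_or_array, dtype=float))
    if b[0] != 0.0:
        raise ValueError("b grid must contain b = 0 as its first entry")
    s0 = arr[:, 0]
    if np.any(s0 <= 0):
        raise ValueError("nonpositive S0; cannot normalize")
    return arr[:, 1:] / s0[:, None]


def smote_balance(features: np.ndarray, labels: np.ndarray,
                  k_neighbors: int = 5, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Equalize class counts by SMOTE interpolation; originals preserved.

    Raises if either class has <= k_neighbors members (the neighbor graph
    would be degenerate) or if a class is absent.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if np.any(counts <= k_neighbors):
        raise ValueError(
            f"each class must have > {k_neighbors} members, got {counts}")
    if counts[0] == counts[1]:
        return features.copy(), labels.copy()
    minority = classes[np.argmin(counts)]
    n_new = int(abs(counts[0] - counts[1]))
    x_min = features[labels == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(x_min)
    # first neighbor is the point itself
    nbr = nn.kneighbors(x_min, return_distance=False)[:, 1:]
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(x_min), size=n_new)
    pick = nbr[base, rng.integers(0, k_neighbors, size=n_new)]
    u = rng.uniform(0.0, 1.0, size=(n_new, 1))
    synth = x_min[base] + u * (x_min[pick] - x_min[base])
    out_x = np.vstack([features, synth])
    out_y = np.concatenate([labels, np.full(n_new, minority, dtype=labels.dtype)])
    return out_x, out_y


def train_modem(features: np.ndarray, labels: np.ndarray,
                spec: MLPSpec | None = None) -> TrainedClassifier:
    """Train the MODEM network; deterministic given ``spec.seed``.

    Rows are put in a canonical (lexicographic) order before fitting so the
    internal validation split -- and hence the early-stopping epoch count --
    does not depend on the order in which training samples arrive.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training requires both classes present")
    if spec is None:
        spec = MLPSpec(n_inputs=features.shape[1])
    if spec.n_inputs != features.shape[1]:
        raise ValueError(
            f"spec.n_inputs={spec.n_inputs} != feature dim {features.shape[1]}")
    order = np.lexsort(np.vstack([features.T, labels.reshape(1, -1)]))
    x = features[order]
    y = labels[order]
    est = MLPClassifier(
        hidden_layer_sizes=spec.hidden_layer_sizes,
        activation="relu",
        solver="adam",
        learning_rate_init=spec.learning_rate,
        batch_size=min(spec.batch_size, len(x)),
        max_iter=spec.max_epochs,
        early_stopping=True,
        validation_fraction=spec.validation_fraction,
        n_iter_no_change=spec.early_stop_patience,
        random_state=spec.seed % (2 ** 31),
    )
    import warnings
    with warnings.catch_warnings():
        # hitting max_epochs without convergence is expected behavior
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        warnings.filterwarnings("ignore", category=UserWarning,
                                module="sklearn")
        est.fit(x, y)
    val_loss = float(-np.max(est.validation_scores_)) \
        if est.validation_scores_ is not None else float("nan")
    return TrainedClassifier(
        estimator=est, spec=spec, n_epochs=int(est.n_iter_),
        final_validation_loss=val_loss,
        metadata={"seed": spec.seed, "n_train": len(x)})


def predict_proba(model: TrainedClassifier, features: np.ndarray) -> np.ndarray:
    """Per-sample probability of the positive (larger-label) class."""
    features = np.asarray(features, dtype=float)
    if features.shape[1] != model.spec.n_inputs:
        raise ValueError(
            f"feature dim {features.shape[1]} != n_inputs {model.spec.n_inputs}")
    proba = model.estimator.predict_proba(features)
    return proba[:, np.argmax(model.estimator.classes_)]
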