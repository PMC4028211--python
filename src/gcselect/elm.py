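"""Extreme learning machine: SLFNs with random hidden layers and analytic output weights.

The hidden layer (input weights and biases drawn Uniform(-1, 1)) is never
trained; the output weights are the minimum-norm least-squares solution
``Wo = pinv(H) @ T`` where ``H`` is the hidden-layer output matrix under the
logistic sigmoid. With as many hidden neurons as distinct training samples the
network interpolates the training set exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .core_data import ValidationError, one_hot

#: relative singular-value cutoff for the pseudo-inverse; genes >> samples
#: scenarios make H rank-deficient routinely.
PINV_RCOND = 1e-10


@dataclass
class ELMModel:
    Wh: np.ndarray  # hidden x inputs
    b: np.ndarray  # hidden
    Wo: np.ndarray  # hidden x outputs
    n_hidden: int

    def hidden(self, X: np.ndarray) -> np.ndarray:
        """Hidden-layer activations (samples x hidden), logistic sigmoid."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.Wh.shape[1]:
            raise ValidationError(
                f"input has {X.shape[1]} features, model expects {self.Wh.shape[1]}"
            )
        return expit(X @ self.Wh.T + self.b)


def default_hidden_size(n_train: int) -> int:
    return min(n_train, 50)


def train(X: np.ndarray, T: np.ndarray, n_hidden: int, seed: int) -> ELMModel:
    """Fit an ELM on samples x features ``X`` against targets ``T``.

    Wo is the smallest-norm least-squares solution, via SVD pseudo-inverse.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(T, dtype=float)
    if n_hidden < 1:
        raise ValidationError("n_hidden must be >= 1")
    if not (np.isfinite(X).all() and np.isfinite(T).all()):
        raise ValidationError("non-finite values in training inputs")
    rng = np.random.default_rng(seed)
    Wh = rng.uniform(-1.0, 1.0, size=(n_hidden, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = expit(X @ Wh.T + b)
    Wo = np.linalg.pinv(H, rcond=PINV_RCOND) @ T
    return ELMModel(Wh=Wh, b=b, Wo=Wo, n_hidden=n_hidden)


def predict(model: ELMModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear-output scores (samples x classes) and argmax labels.

    Score ties resolve to the lowest class index.
    """
    scores = model.hidden(X) @ model.Wo
    return scores, np.argmax(scores, axis=1)


def accuracy(model: ELMModel, X: np.ndarray, y: np.ndarray) -> float:
    _, labels = predict(model, X)
    return float(np.mean(labels == np.asarray(y)))


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence(entropy=seed, spawn_key=(fold,)).generate_state(1)[0] % (2**31))


def kfold_cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    gene_subset: np.ndarray,
    n_hidden: int | None = None,
    k: int = 5,
    seed: int = 0,
) -> float:
    """Mean accuracy over k stratified folds using only ``gene_subset`` columns.

    ``X`` is samples x genes. Each fold trains a fresh ELM (fold-derived seed)
    on the remaining folds. Deterministic given ``seed``.
    """
    gene_subset = np.asarray(gene_subset, dtype=int)
    if gene_subset.size == 0:
        raise ValidationError("gene_subset must be non-empty")
    X = np.asarray(X, dtype=float)[:, gene_subset]
    y = np.asarray(y, dtype=int)
    n_classes = int(y.max()) + 1
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        nh = n_hidden if n_hidden is not None else default_hidden_size(tr.size)
        model = train(X[tr], one_hot(y[tr], n_classes), nh, _fold_seed(seed, fold))
        accs.append(accuracy(model, X[te], y[te]))
    return float(np.mean(accs))
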