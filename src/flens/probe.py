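"""Linear probing of metadata variables from frozen embeddings.

A linear probe is a single affine layer (softmax omitted at predict time,
since it is monotone) trained with softmax cross-entropy on frozen feature
vectors. Its held-out accuracy measures how linearly decodable a variable
is from the embedding space: high accuracy on a sensitive variable such as
tissue source site is evidence of a batch effect the encoder has absorbed.

Uncertainty is quantified by percentile bootstrap over the test set, and
chance agreement is corrected with Cohen's kappa, computed per bootstrap
replicate from that replicate's confusion matrix and averaged (kappa is not
a function of accuracy alone, so it cannot be derived from the accuracy
replicates).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .store import EmbeddingSet, VariableSpec, subset

__all__ = [
    "ProbeConfig",
    "ProbeResult",
    "LinearProbe",
    "train_probe",
    "evaluate_probe",
    "cohen_kappa",
    "confusion_matrix",
    "bootstrap_metrics",
    "subsample_experiment",
]


@dataclass(frozen=True)
class ProbeConfig:
    """Training/evaluation settings for a linear probe.

    Defaults follow the standard recipe for probing frozen features:
    20 epochs of mini-batch Adam (lr 1e-3, betas 0.9/0.999, batch 256),
    100 bootstrap resamples of the test set, 95% percentile intervals.
    """

    epochs: int = 20
    batch_size: int = 256
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    n_bootstrap: int = 100
    ci_level: float = 0.95
    seed: int = 0
    standardize: bool = True

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0.0 < self.ci_level < 1.0:
            raise ValueError("ci_level must be in (0, 1)")


@dataclass
class ProbeResult:
    """Evaluation of one fitted probe on one held-out test set."""

    accuracy: float
    ci_low: float
    ci_high: float
    kappa_mean: float | None
    per_class_accuracy: dict[str, float]
    confusion: np.ndarray  # rows = true class, cols = predicted class
    class_labels: list[str]
    n_train: int
    n_test: int
    n_classes: int
    seed: int
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["confusion"] = self.confusion.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeResult":
        d = dict(d)
        d["confusion"] = np.asarray(d["confusion"], dtype=np.int64)
        return cls(**d)


class LinearProbe(BaseEstimator, ClassifierMixin):
    """Single affine layer trained with mini-batch Adam on softmax CE.

    Deterministic given (data, random_state): initialization and epoch
    shuffling are drawn from one seeded generator in a fixed order.
    Features are optionally standardized per dimension using statistics
    from the training data only.

    Parameters
    ----------
    epochs : passes over the training data (exactly this many).
    batch_size : mini-batch size.
    learning_rate, beta1, beta2 : Adam hyperparameters.
    standardize : z-score features with train-split statistics before
        the affine map (stored in ``mean_`` / ``scale_``).
    random_state : seed for initialization and shuffling.

    Attributes (after fit)
    ----------------------
    classes_ : class labels in lexicographic order.
    coef_ : (n_classes, d) weight matrix; intercept_ : (n_classes,) bias.
    """

    def __init__(
        self,
        epochs: int = 20,
        batch_size: int = 256,
        learning_rate: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        standardize: bool = True,
        random_state: int = 0,
    ):
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.standardize = standardize
        self.random_state = random_state

    def fit(self, X, y) -> "LinearProbe":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=object)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one label per row")
        classes = np.array(sorted({str(v) for v in y}), dtype=object)
        if len(classes) < 2:
            raise ValueError("need >=2 classes to train a probe")
        class_index = {c: k for k, c in enumerate(classes)}
        yi = np.array([class_index[str(v)] for v in y], dtype=np.int64)
        n, d = X.shape
        m = len(classes)

        if self.standardize:
            self.mean_ = X.mean(axis=0)
            std = X.std(axis=0)
            self.scale_ = np.where(std > 0, std, 1.0)
        else:
            self.mean_ = np.zeros(d)
            self.scale_ = np.ones(d)
        Xs = (X - self.mean_) / self.scale_

        rng = np.random.default_rng(self.random_state)
        W = rng.normal(0.0, 0.01, size=(d, m))
        b = np.zeros(m)
        mW = np.zeros_like(W); vW = np.zeros_like(W)
        mb = np.zeros_like(b); vb = np.zeros_like(b)
        lr, b1, b2, eps = self.learning_rate, self.beta1, self.beta2, 1e-8
        t = 0
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                Xb, yb = Xs[idx], yi[idx]
                logits = Xb @ W + b
                logits -= logits.max(axis=1, keepdims=True)
                p = np.exp(logits)
                p /= p.sum(axis=1, keepdims=True)
                p[np.arange(len(idx)), yb] -= 1.0
                p /= len(idx)
                gW = Xb.T @ p
                gb = p.sum(axis=0)
                t += 1
                mW = b1 * mW + (1 - b1) * gW; vW = b2 * vW + (1 - b2) * gW**2
                mb = b1 * mb + (1 - b1) * gb; vb = b2 * vb + (1 - b2) * gb**2
                c1 = 1 - b1**t; c2 = 1 - b2**t
                W -= lr * (mW / c1) / (np.sqrt(vW / c2) + eps)
                b -= lr * (mb / c1) / (np.sqrt(vb / c2) + eps)

        self.classes_ = classes
        self.coef_ = W.T
        self.intercept_ = b
        self.n_features_in_ = d
        self.n_train_ = n
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=np.float64)
        return (X - self.mean_) / self.scale_ @ self.coef_.T + self.intercept_

    def predict(self, X) -> np.ndarray:
        # argmax returns the lowest index on ties -> deterministic
        scores = self.decision_function(X)
        return self.classes_[np.argmax(scores, axis=1)]


def cohen_kappa(confusion: np.ndarray) -> float | None:
    """Chance-corrected agreement from an m x m confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_o = trace/total and
    p_e = sum_k row_k * col_k / total**2. Returns ``None`` (undefined)
    when the expected agreement p_e equals 1, i.e. both marginals are
    concentrated on a single class.
    """
    C = np.asarray(confusion, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("confusion matrix must be square")
    if (C < 0).any():
        raise ValueError("confusion entries must be non-negative")
    total = C.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    p_o = np.trace(C) / total
    p_e = float(C.sum(axis=1) @ C.sum(axis=0)) / total**2
    if p_e >= 1.0 - 1e-12:
        return None
    return float((p_o - p_e) / (1.0 - p_e))


def confusion_matrix(
    y_true: Sequence[str], y_pred: Sequence[str], labels: Sequence[str]
) -> np.ndarray:
    """Count matrix, rows = true class, cols = predicted class."""
    index = {str(c): k for k, c in enumerate(labels)}
    C = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred, strict=True):
        C[index[str(t)], index[str(p)]] += 1
    return C


def bootstrap_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    labels: Sequence[str],
    n_bootstrap: int,
    seed: int,
) -> tuple[np.ndarray, list[float | None]]:
    """Accuracy and kappa over ``n_bootstrap`` resamples (with replacement)."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    n = len(y_true)
    rng = np.random.default_rng(seed)
    accs = np.empty(n_bootstrap)
    kappas: list[float | None] = []
    for r in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        C = confusion_matrix(y_true[idx], y_pred[idx], labels)
        accs[r] = np.trace(C) / n
        kappas.append(cohen_kappa(C))
    return accs, kappas


def train_probe(
    train: EmbeddingSet, variable: VariableSpec, config: ProbeConfig | None = None
) -> LinearProbe:
    """Fit a :class:`LinearProbe` predicting ``variable`` from embeddings."""
    config = config or ProbeConfig()
    y = train.variable(variable.name)
    probe = LinearProbe(
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        beta1=config.beta1,
        beta2=config.beta2,
        standardize=config.standardize,
        random_state=config.seed,
    )
    return probe.fit(train.features, y)


def evaluate_probe(
    model: LinearProbe,
    test: EmbeddingSet,
    variable: VariableSpec,
    config: ProbeConfig | None = None,
) -> ProbeResult:
    """Accuracy, bootstrap CI, averaged kappa and per-class accuracy on ``test``.

    The point estimate is computed once on the full test set; the CI is the
    percentile interval of the resampled accuracies; kappa is computed from
    each replicate's confusion matrix and averaged over the replicates where
    it is defined.
    """
    config = config or ProbeConfig()
    if test.n == 0:
        raise ValueError("empty test set")
    y_true = np.array([str(v) for v in test.variable(variable.name)], dtype=object)
    labels = [str(c) for c in model.classes_]
    unknown = sorted(set(y_true) - set(labels))
    if unknown:
        raise ValueError(f"test classes not seen in training: {unknown}")
    y_pred = model.predict(test.features)

    C = confusion_matrix(y_true, y_pred, labels)
    accuracy = float(np.trace(C) / test.n)
    per_class = {}
    for k, c in enumerate(labels):
        row = C[k].sum()
        per_class[c] = float(C[k, k] / row) if row else float("nan")

    accs, kappas = bootstrap_metrics(
        y_true, y_pred, labels, config.n_bootstrap, config.seed
    )
    alpha = (1.0 - config.ci_level) / 2.0
    ci_low = float(np.percentile(accs, 100 * alpha))
    ci_high = float(np.percentile(accs, 100 * (1 - alpha)))
    defined = [k for k in kappas if k is not None]
    kappa_mean = float(np.mean(defined)) if defined else None

    return ProbeResult(
        accuracy=accuracy,
        ci_low=ci_low,
        ci_high=ci_high,
        kappa_mean=kappa_mean,
        per_class_accuracy=per_class,
        confusion=C,
        class_labels=labels,
        n_train=getattr(model, "n_train_", -1),
        n_test=test.n,
        n_classes=len(labels),
        seed=config.seed,
        provenance={
            "variable": variable.name,
            "role": variable.role,
            "epochs": config.epochs,
            "batch_size": config.batch_size,
            "learning_rate": config.learning_rate,
            "n_bootstrap": config.n_bootstrap,
            "ci_level": config.ci_level,
            "standardized": config.standardize,
        },
    )


def _stratified_fraction(
    y: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a stratified subsample keeping round(f * n_c) per class."""
    idx_parts = []
    for c in sorted({str(v) for v in y}):
        pool = np.flatnonzero(np.array([str(v) for v in y], dtype=object) == c)
        k = int(round(fraction * len(pool)))
        if k == 0:
            raise ValueError(
                f"fraction {fraction} leaves class {c!r} empty "
                f"(class size {len(pool)})"
            )
        idx_parts.append(rng.choice(pool, size=k, replace=False))
    return np.sort(np.concatenate(idx_parts))


def subsample_experiment(
    train: EmbeddingSet,
    test: EmbeddingSet,
    variable: VariableSpec,
    fractions: Sequence[float],
    repeats: int,
    config: ProbeConfig | None = None,
    boost_epochs: int = 60,
    boost_threshold: float = 0.25,
) -> pd.DataFrame:
    """Probe accuracy as a function of training-set size.

    For each fraction f, draws ``repeats`` independent stratified subsamples
    of the training data, retrains, and evaluates on the fixed test set.
    When f <= ``boost_threshold`` the epoch count is raised to
    ``boost_epochs`` to compensate for the smaller number of gradient steps.

    Returns a table with columns ``fraction``, ``mean_accuracy``, ``sd``.
    """
    config = config or ProbeConfig()
    fractions = list(fractions)
    if fractions != sorted(fractions):
        raise ValueError("fractions must be sorted ascending")
    y = train.variable(variable.name)
    master = np.random.default_rng(config.seed)
    repeat_seeds = master.integers(0, 2**31 - 1, size=(len(fractions), repeats))
    rows = []
    for i, f in enumerate(fractions):
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction {f} not in (0, 1]")
        epochs = boost_epochs if f <= boost_threshold else config.epochs
        accs = []
        for r in range(repeats):
            seed_r = int(repeat_seeds[i, r])
            rng = np.random.default_rng(seed_r)
            idx = _stratified_fraction(y, f, rng)
            sub = subset(train, [train.ids[j] for j in idx])
            cfg = ProbeConfig(
                epochs=epochs,
                batch_size=config.batch_size,
                learning_rate=config.learning_rate,
                beta1=config.beta1,
                beta2=config.beta2,
                n_bootstrap=config.n_bootstrap,
                ci_level=config.ci_level,
                seed=seed_r,
                standardize=config.standardize,
            )
            model = train_probe(sub, variable, cfg)
            res = evaluate_probe(model, test, variable, cfg)
            accs.append(res.accuracy)
        rows.append(
            {
                "fraction": f,
                "mean_accuracy": float(np.mean(accs)),
                "sd": float(np.std(accs, ddof=1)) if repeats > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
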