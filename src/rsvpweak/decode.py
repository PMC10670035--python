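"""Single-epoch target/non-target decoding and information transfer rate.

Features are the PCA-compressed (>99% variance) channel x time values of an
epoch. Two classifiers are compared: a Fisher linear discriminant y = w'x
whose decision threshold xi is placed on the training-score ROC at the
Youden optimum (max sensitivity + specificity - 1), and a soft-margin RBF
SVM y = sum_i w_i exp(-g ||x_i - x||^2) + b (libsvm via scikit-learn).

Evaluation uses 10 repetitions of stratified 6-fold cross-validation. RSVP
epochs are 1:9 target:non-target, so by default each training fold
subsamples non-targets to 1:1 and test folds are scored by balanced accuracy
(mean of sensitivity and specificity); a raw-accuracy mode is available.
The information transfer rate converts accuracy P over N commands issued
every T seconds to bits/min.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .channels import ChannelSubset
from .preprocess import EpochSet

CV_REPS = 10
CV_FOLDS = 6

#: ITR defaults: one command = which of the N=10 digits was attended, issued
#: once per 2.0 s stimulus stream (ten 200 ms flashes).
ITR_COMMANDS = 10
ITR_PERIOD_S = 2.0


@dataclass
class LdaModel:
    """Fisher discriminant direction ``w`` and ROC threshold ``xi``."""

    w: np.ndarray
    xi: float

    def scores(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.w

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.scores(X) > self.xi


@dataclass
class SvmModel:
    """RBF-kernel SVM in explicit support-vector form."""

    support_vectors: np.ndarray
    weights: np.ndarray  # signed dual coefficients
    kernel_width: float  # g in exp(-g ||x_i - x||^2)
    bias: float
    _clf: SVC | None = field(default=None, repr=False)

    @property
    def n_support(self) -> int:
        return len(self.weights)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        d2 = ((X[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(-1)
        return np.exp(-self.kernel_width * d2) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision_function(X) > 0


@dataclass
class DecodeResult:
    """Cross-validated accuracies (%) for one condition x channel set."""

    accuracies: np.ndarray  # reps x folds
    classifier: str
    channel_set: str
    condition: str

    @property
    def mean(self) -> float:
        return float(self.accuracies.mean())

    @property
    def stderr(self) -> float:
        flat = self.accuracies.ravel()
        return float(flat.std(ddof=1) / np.sqrt(flat.size))


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Decision threshold maximizing sensitivity + specificity - 1.

    The ROC is swept over the training scores; the optimal operating point's
    threshold is returned as the midpoint between the adjacent scores so the
    strict ``score > xi`` rule reproduces the ROC point exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    fpr, tpr, thr = roc_curve(labels, scores, drop_intermediate=False)
    j = tpr - fpr
    i = int(np.argmax(j))
    t = thr[i]
    below = scores[scores < t]
    # midpoint between the lowest accepted score and the next one down
    return float((t + below.max()) / 2.0) if below.size else float(t - 1.0)


def train_lda(X: np.ndarray, labels: np.ndarray,
              reg: float | None = None) -> LdaModel:
    """Fisher direction w = Sw^-1 (mu_target - mu_nontarget), xi by ROC.

    ``reg=None`` (default) estimates the within-class covariance with
    analytic Ledoit-Wolf shrinkage — the standard small-sample stabilizer
    for single-trial ERP decoding, where the feature dimension is of the
    order of the trial count. A numeric ``reg`` instead applies diagonal
    loading reg x mean(diag(Sw)).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    Xt, Xn = X[labels], X[~labels]
    mt, mn = Xt.mean(axis=0), Xn.mean(axis=0)
    centered = np.vstack([Xt - mt, Xn - mn])
    if reg is None:
        from sklearn.covariance import ledoit_wolf

        Sw, _ = ledoit_wolf(centered, assume_centered=True)
    else:
        Sw = centered.T @ centered
        eps = reg * float(np.mean(np.diag(Sw)))
        Sw = Sw + max(eps, 1e-300) * np.eye(Sw.shape[0])
    try:
        w = np.linalg.solve(Sw, mt - mn)
    except np.linalg.LinAlgError as err:
        raise ValueError("within-class scatter is singular") from err
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("degenerate discriminant (identical class means)")
    w = w / norm
    xi = youden_threshold(X @ w, labels)
    return LdaModel(w=w, xi=xi)


def train_svm(X: np.ndarray, labels: np.ndarray, g: float | None = None,
              cost: float = 1.0) -> SvmModel:
    """Soft-margin RBF SVM; ``g`` defaults to 1 / (dim x feature variance)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if g is None:
        var = X.var()
        g = 1.0 / (X.shape[1] * var) if var > 0 else 1.0 / X.shape[1]
    if g <= 0 or cost <= 0:
        raise ValueError("kernel width and cost must be positive")
    clf = SVC(kernel="rbf", gamma=g, C=cost)
    clf.fit(X, labels)
    return SvmModel(
        support_vectors=clf.support_vectors_.copy(),
        weights=clf.dual_coef_.ravel().copy(),
        kernel_width=g,
        bias=float(clf.intercept_[0]),
        _clf=clf,
    )


def balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean of sensitivity and specificity, in percent."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    sens = y_pred[y_true].mean() if y_true.any() else np.nan
    spec = (~y_pred[~y_true]).mean() if (~y_true).any() else np.nan
    return 100.0 * float((sens + spec) / 2.0)


def _stratified_folds(labels: np.ndarray, folds: int, rng) -> list[np.ndarray]:
    idx_t = rng.permutation(np.flatnonzero(labels))
    idx_n = rng.permutation(np.flatnonzero(~labels))
    return [np.concatenate([idx_t[f::folds], idx_n[f::folds]])
            for f in range(folds)]


def cross_validate(
    epochs: EpochSet,
    channel_set: ChannelSubset | None = None,
    classifier: str = "lda",
    reps: int = CV_REPS,
    folds: int = CV_FOLDS,
    seed: int = 0,
    var_target: float = 0.99,
    balance_training: bool = True,
    balanced_scoring: bool = True,
    condition: str = "",
    svm_cost: float = 1.0,
    lda_reg: float | None = None,
) -> DecodeResult:
    """Repeated stratified k-fold CV of one classifier on one channel set.

    PCA compression is fit on training folds only; training folds are
    subsampled to 1:1 when ``balance_training``; repetition r uses seed + r.
    """
    if classifier not in ("lda", "svm"):
        raise ValueError("classifier must be 'lda' or 'svm'")
    sub = epochs if channel_set is None else epochs.pick(channel_set.channels)
    X_all = sub.data.reshape(len(sub.data), -1)
    y_all = sub.labels
    n_t, n_n = int(y_all.sum()), int((~y_all).sum())
    if min(n_t, n_n) < folds:
        raise ValueError("need at least `folds` epochs per class")

    accs = np.empty((reps, folds))
    for r in range(reps):
        rng = np.random.default_rng(seed + r)
        for f, test_idx in enumerate(_stratified_folds(y_all, folds, rng)):
            train_mask = np.ones(len(y_all), dtype=bool)
            train_mask[test_idx] = False
            tr_idx = np.flatnonzero(train_mask)
            if balance_training:
                t_idx = tr_idx[y_all[tr_idx]]
                n_idx = tr_idx[~y_all[tr_idx]]
                keep = min(len(t_idx), len(n_idx))
                tr_idx = np.concatenate([
                    rng.choice(t_idx, keep, replace=False),
                    rng.choice(n_idx, keep, replace=False),
                ])
            Xtr = X_all[tr_idx]
            # compression basis comes from the training fold only
            n_comp = var_target if var_target < 1 else None
            pca = PCA(n_components=n_comp, svd_solver="full").fit(Xtr)
            Ztr = pca.transform(Xtr)
            Zte = pca.transform(X_all[test_idx])
            if classifier == "lda":
                model = train_lda(Ztr, y_all[tr_idx], reg=lda_reg)
            else:
                model = train_svm(Ztr, y_all[tr_idx], cost=svm_cost)
            pred = model.predict(Zte)
            truth = y_all[test_idx]
            if balanced_scoring:
                accs[r, f] = balanced_accuracy(truth, pred)
            else:
                accs[r, f] = 100.0 * float((pred == truth).mean())
    name = channel_set.name if channel_set is not None else "all"
    return DecodeResult(accuracies=accs, classifier=classifier,
                        channel_set=name, condition=condition)


def itr(P: float, N: int = ITR_COMMANDS, T: float = ITR_PERIOD_S,
        clamp: bool = True) -> float:
    """Information transfer rate (bits/min) of an N-way selection at
    accuracy P issued every T seconds:

        ITR = 60/T [log2 N + P log2 P + (1-P) log2((1-P)/(N-1))]

    Zero-probability terms contribute zero. The bits expression is
    nonnegative and reaches 0 exactly at chance (P = 1/N); below chance it
    rises again because systematically wrong answers are informative, which
    is not meaningful for a BCI, so with ``clamp`` (default) below-chance
    accuracies report 0 bits/min with a warning; ``clamp=False`` returns the
    raw formula value.
    """
    if not 0 < P <= 1:
        raise ValueError("P must lie in (0, 1]")
    if N < 2:
        raise ValueError("N must be at least 2")
    if T <= 0:
        raise ValueError("T must be positive")
    bits = np.log2(N)
    bits += P * np.log2(P) if P > 0 else 0.0
    if P < 1:
        bits += (1 - P) * np.log2((1 - P) / (N - 1))
    rate = 60.0 / T * bits
    if P < 1.0 / N:
        warnings.warn("accuracy below chance (P < 1/N): ITR is not meaningful")
        if clamp:
            return 0.0
    return float(rate)
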