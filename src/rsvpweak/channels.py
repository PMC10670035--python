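"""Channel subsets and floating-forward channel selection.

Six channel sets are compared by the analysis: five fixed montage subsets
(all 62 channels; standard 32- and 16-channel caps; the 8 midline sites; a
classic 8-channel ERP set) and a sixth, subject-specific set of 6 channels
found by sequential floating forward selection (SFFS). SFFS scores a
candidate subset by a Fisher class-separability criterion: the concatenated
channel x sample features are first compressed by an adaptive PCA keeping
>99% of the variance (recomputed for every candidate subset), then
trace(Sw^-1 Sb) is evaluated on the compressed features, where Sw and Sb are
the within- and between-class scatter matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .montage import MONTAGE_62
from .preprocess import EpochSet

#: Diagonal-loading factor for Sw (x mean diagonal) before inversion.
SCATTER_REG = 1e-6

FIXED_SETS: dict[str, tuple[str, ...]] = {
    "1": MONTAGE_62,
    "2": ("FP1", "FP2", "Fz", "F3", "F4", "F7", "F8", "FC1", "FC2", "FC5",
          "FC6", "Cz", "C3", "C4", "T7", "T8", "CPz", "CP3", "CP4", "Pz",
          "P3", "P4", "P7", "P8", "POz", "PO3", "PO4", "PO7", "PO8", "Oz",
          "O1", "O2"),
    "3": ("Fz", "FC1", "FC2", "Cz", "C3", "C4", "CP1", "CP2", "Pz", "P3",
          "P4", "P7", "P8", "Oz", "O1", "O2"),
    "4": ("FPz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"),
    "5": ("Fz", "Cz", "Pz", "P3", "P4", "PO7", "PO8", "Oz"),
}

SELECTED_SET_SIZE = 6


@dataclass(frozen=True)
class ChannelSubset:
    """A named, ordered list of montage labels with an optional score."""

    name: str
    channels: tuple[str, ...]
    score: float | None = None


def fixed_sets() -> list[ChannelSubset]:
    """The five fixed channel sets (set 6 is produced by ``sffs_select``)."""
    return [ChannelSubset(name=k, channels=v) for k, v in FIXED_SETS.items()]


def compress_features(X: np.ndarray, var_target: float = 0.99):
    """PCA-compress rows of ``X`` to the smallest dimension whose cumulative
    explained variance exceeds ``var_target``.

    Returns ``(compressed, P)`` where ``P`` is the retained dimension.
    ``var_target = 1.0`` keeps every component with nonzero variance.
    """
    if not 0 < var_target <= 1:
        raise ValueError("var_target must lie in (0, 1]")
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two epochs for PCA")
    if var_target == 1.0:
        pca = PCA(svd_solver="full").fit(X)
        nz = pca.explained_variance_ > max(1e-12, 1e-9 * pca.explained_variance_[0])
        p = max(1, int(nz.sum()))
        return pca.transform(X)[:, :p], p
    pca = PCA(n_components=var_target, svd_solver="full").fit(X)
    return pca.transform(X), int(pca.n_components_)


def scatter_matrices(Z: np.ndarray, labels: np.ndarray):
    """Within- and between-class scatter of compressed features ``Z``."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    mu = Z.mean(axis=0)
    d = Z.shape[1]
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Zc = Z[labels == c]
        mc = Zc.mean(axis=0)
        D = Zc - mc
        Sw += D.T @ D
        diff = (mc - mu)[:, None]
        Sb += len(Zc) * (diff @ diff.T)
    return Sw, Sb


def fisher_criterion(data: np.ndarray, labels: np.ndarray,
                     var_target: float = 0.99, reg: float = SCATTER_REG,
                     corrected: bool = False) -> float:
    """trace(Sw^-1 Sb) on adaptively PCA-compressed channel x time features.

    ``data`` is epochs x channels x samples (already restricted to the
    candidate subset); Sw gets diagonal loading reg x mean(diag) for
    small-sample stability.

    With ``corrected`` the score gets the small-sample bias correction of
    the underlying Mahalanobis separation, ((nu - P - 1) J - P) / nu with
    nu = n - 2. The raw score inflates with the compressed dimension P, and
    P varies between candidate subsets under the adaptive compression, so
    subset comparisons (channel selection) need the corrected form; the raw
    form is the classical two-class Fisher score.
    """
    data = np.asarray(data, dtype=float)
    X = data.reshape(len(data), -1)
    Z, p = compress_features(X, var_target)
    Sw, Sb = scatter_matrices(Z, labels)
    eps = reg * float(np.mean(np.diag(Sw)))
    Sw = Sw + max(eps, 1e-300) * np.eye(Sw.shape[0])
    score = float(np.trace(np.linalg.solve(Sw, Sb)))
    if corrected:
        nu = len(X) - 2
        if nu - p - 1 <= 0:
            raise ValueError(
                f"compressed dimension {p} too large for bias correction at "
                f"n={len(X)}; use more epochs or a lower var_target")
        score = ((nu - p - 1) * score - p) / nu
    return score


def _subset_score(epochs: EpochSet, labels, subset, var_target,
                  corrected=True) -> float:
    idx = [epochs.channels.index(c) for c in subset]
    return fisher_criterion(epochs.data[:, idx, :], labels, var_target,
                            corrected=corrected)


def sffs_select(epochs: EpochSet, labels=None, k: int = SELECTED_SET_SIZE,
                var_target: float = 0.99, name: str = "6",
                corrected: bool = True) -> ChannelSubset:
    """Sequential floating forward selection of ``k`` channels.

    Channels are added greedily by the Fisher criterion (bias-corrected by
    default so candidates of different compressed dimension are comparable);
    after each addition any channel (other than the newest) whose removal
    strictly improves on the best score previously seen at the smaller size
    is dropped (the floating step). Ties prefer the lexicographically
    smallest label. The returned channels are in inclusion order with the
    subset's final score.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(epochs.channels):
        raise ValueError("k exceeds the number of channels")
    labels = epochs.labels if labels is None else np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    if k == len(epochs.channels):
        score = _subset_score(epochs, labels, epochs.channels, var_target,
                              corrected)
        return ChannelSubset(name=name, channels=tuple(epochs.channels), score=score)

    current: list[str] = []
    best: dict[int, tuple[float, tuple[str, ...]]] = {}

    def record(subset: list[str], score: float) -> None:
        size = len(subset)
        if size not in best or score > best[size][0]:
            best[size] = (score, tuple(subset))

    # overshoot past k: the floating removals on the way back down revisit
    # and often improve the recorded best at size k
    k_max = min(len(epochs.channels) - 1, k + 3)
    guard = 0
    while len(current) < k_max:
        guard += 1
        if guard > 60 * k:  # floating oscillation safety valve
            break
        # forward: best single addition (lexicographic on ties)
        candidates = sorted(c for c in epochs.channels if c not in current)
        scores = [_subset_score(epochs, labels, current + [c], var_target,
                                corrected)
                  for c in candidates]
        i = int(np.argmax(scores))
        current.append(candidates[i])
        record(current, scores[i])
        newest = current[-1]
        # floating: conditional removals that beat the smaller-size best
        while len(current) > 2:
            removable = [c for c in current if c != newest]
            r_scores = [
                _subset_score(epochs, labels, [c for c in current if c != r],
                              var_target, corrected)
                for r in removable
            ]
            j = int(np.argmax(r_scores))
            if len(current) - 1 in best and r_scores[j] > best[len(current) - 1][0]:
                current.remove(removable[j])
                record(current, r_scores[j])
            else:
                break

    while k not in best:  # only reachable via the safety valve
        candidates = sorted(c for c in epochs.channels if c not in current)
        scores = [_subset_score(epochs, labels, current + [c], var_target,
                                corrected)
                  for c in candidates]
        current.append(candidates[int(np.argmax(scores))])
        if len(current) == k:
            record(current, _subset_score(epochs, labels, current, var_target,
                                          corrected))

    score, subset = best[k]
    return ChannelSubset(name=name, channels=subset, score=score)


def selection_frequency(subsets) -> dict[str, int]:
    """How often each montage channel appears across selected subsets."""
    counts = {c: 0 for c in MONTAGE_62}
    for sub in subsets:
        chans = sub.channels if isinstance(sub, ChannelSubset) else sub
        for c in chans:
            counts[c] = counts.get(c, 0) + 1
    return counts
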