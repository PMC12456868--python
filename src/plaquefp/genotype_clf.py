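"""Genotype classification from photometry depth profiles.

Each depth profile (41 depths per penetration) is z-scored per profile,
the sample matrix is reduced to its first three principal components, and
a linear support vector machine is evaluated with the leave-one-out
procedure; performance is summarized as a confusion matrix with the
affected genotype as the positive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .stats import DegenerateInputError

AFFECTED = "affected"
CONTROL = "control"


@dataclass(frozen=True)
class ProfileMatrix:
    """Samples x depths matrix of per-profile z-scored fluorescence."""

    X: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise ValueError("X must be (n_samples, n_depths) matching labels")


@dataclass(frozen=True)
class ConfusionMatrix:
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def __post_init__(self):
        if min(self.hits, self.misses, self.false_alarms, self.correct_rejections) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejections


@dataclass(frozen=True)
class SVMConfig:
    kernel: str = "linear"
    C: float = 1.0


def build_matrix(profiles, labels) -> ProfileMatrix:
    """Stack depth profiles into a row-wise z-scored sample matrix.

    ``profiles`` may be ZProfile objects or plain arrays; all must share
    one depth grid. Each row is centered and scaled to unit sample
    standard deviation; a zero-variance profile is an error.
    """
    rows, grid = [], None
    for p in profiles:
        if hasattr(p, "dF"):
            vec = np.asarray(p.dF, dtype=float)
            g = np.asarray(p.depth_grid_um)
            if grid is None:
                grid = g
            elif g.shape != grid.shape or not np.allclose(g, grid):
                raise ValueError("all profiles must share one depth grid")
        else:
            vec = np.asarray(p, dtype=float)
            if grid is not None and len(vec) != len(grid):
                raise ValueError("all profiles must share one depth grid")
        rows.append(vec)
    X = np.vstack(rows)
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0.0):
        raise DegenerateInputError("zero-variance profile cannot be z-scored")
    X = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return ProfileMatrix(X=X, labels=tuple(labels))


def pca_reduce(matrix: ProfileMatrix | np.ndarray, k: int = 3) -> np.ndarray:
    """Scores of the top-k principal components (column-centered PCA).

    Components are ordered by explained variance with a deterministic sign
    convention: the largest-magnitude loading of each component is
    positive.
    """
    X = matrix.X if isinstance(matrix, ProfileMatrix) else np.asarray(matrix, dtype=float)
    n, d = X.shape
    if k > min(n - 1, d):
        raise ValueError(f"k={k} exceeds the maximal PCA rank {min(n - 1, d)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return (U * S)[:, :k] * flip[:k]


def loo_classify(
    scores: np.ndarray,
    labels,
    svm_config: SVMConfig = SVMConfig(),
    *,
    positive: str = AFFECTED,
) -> ConfusionMatrix:
    """Leave-one-out SVM classification tallied into a confusion matrix.

    For every sample an SVM is fitted on the remaining samples and the
    held-out sample predicted; the affected genotype is the positive class
    (hits/misses), the control genotype the negative class (correct
    rejections/false alarms). Deterministic for a fixed config.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if scores.shape[0] != n:
        raise ValueError("scores and labels must align")
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("exactly two classes are required")
    if min((labels == c).sum() for c in classes) < 2:
        raise ValueError("each class needs >= 2 samples for leave-one-out")
    hits = misses = fa = cr = 0
    for i in range(n):
        train = np.arange(n) != i
        if len(np.unique(labels[train])) < 2:
            raise ValueError(f"training fold without both classes at sample {i}")
        clf = SVC(kernel=svm_config.kernel, C=svm_config.C)
        clf.fit(scores[train], labels[train])
        pred = clf.predict(scores[i:i + 1])[0]
        if labels[i] == positive:
            hits += int(pred == positive)
            misses += int(pred != positive)
        else:
            cr += int(pred != positive)
            fa += int(pred == positive)
    return ConfusionMatrix(hits=hits, misses=misses, false_alarms=fa,
                           correct_rejections=cr)


def classify_profiles(
    profiles,
    labels,
    *,
    k: int = 3,
    svm_config: SVMConfig = SVMConfig(),
    pca_per_fold: bool = False,
) -> ConfusionMatrix:
    """Full classification chain: z-score rows, PCA to k, leave-one-out SVM.

    By default the PCA is fitted once on all samples before the
    leave-one-out loop (the published procedure; note the held-out sample
    then contributes to the projection). ``pca_per_fold=True`` refits the
    PCA inside each training fold instead, removing that leakage.
    """
    matrix = build_matrix(profiles, labels)
    lab = np.asarray(matrix.labels)
    if not pca_per_fold:
        return loo_classify(pca_reduce(matrix, k), lab, svm_config)
    n = matrix.X.shape[0]
    hits = misses = fa = cr = 0
    Xc_all = matrix.X
    for i in range(n):
        train = np.arange(n) != i
        mu = Xc_all[train].mean(axis=0, keepdims=True)
        U, S, Vt = np.linalg.svd(Xc_all[train] - mu, full_matrices=False)
        flip = np.sign(Vt[np.arange(len(S)), np.abs(Vt).argmax(axis=1)])
        flip[flip == 0] = 1.0
        W = (Vt[:k] * flip[:k, None]).T
        clf = SVC(kernel=svm_config.kernel, C=svm_config.C)
        clf.fit((Xc_all[train] - mu) @ W, lab[train])
        pred = clf.predict((Xc_all[i:i + 1] - mu) @ W)[0]
        if lab[i] == AFFECTED:
            hits += int(pred == AFFECTED)
            misses += int(pred != AFFECTED)
        else:
            cr += int(pred != AFFECTED)
            fa += int(pred == AFFECTED)
    return ConfusionMatrix(hits=hits, misses=misses, false_alarms=fa,
                           correct_rejections=cr)


def metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, hit rate and correct-rejection rate as percentages (1 dp)."""
    if cm.hits + cm.misses == 0 or cm.false_alarms + cm.correct_rejections == 0:
        raise ValueError("both classes must be represented")
    return {
        "accuracy": round(100.0 * (cm.hits + cm.correct_rejections) / cm.total, 1),
        "hit_rate": round(100.0 * cm.hits / (cm.hits + cm.misses), 1),
        "correct_rejection_rate": round(
            100.0 * cm.correct_rejections
            / (cm.correct_rejections + cm.false_alarms), 1),
    }
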