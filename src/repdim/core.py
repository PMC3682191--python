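"""Reduced-dimensional Gaussian linear classification of activity patterns.

The central object is a Gaussian linear (Fisher LDA) classifier fitted to
condition-by-run activity patterns.  The classifier is "reduced" by keeping
only the top ``d`` discriminative directions: eigenvectors of the
between-class covariance of the *pre-whitened* class means.  Cross-validated
accuracy as a function of ``d`` (the *accuracy curve*) peaks, given enough
data, at the true dimensionality of the underlying representation — a
classifier with too few dimensions misses discriminative signal, one with too
many over-fits noise.

Estimation steps:

1. class means ``mu_k`` and pooled within-class covariance ``Sigma_W``
   (regularized by adding a fraction of the mean diagonal to the diagonal);
2. whitening with the symmetric inverse square root ``Sigma_W^{-1/2}``;
3. between-class covariance of whitened means,
   ``Sigma_B* = (1/K) sum_k (mu*_k - mu*)(mu*_k - mu*)^T``;
4. its top ``K-1`` eigenvectors are the discriminative directions, ordered by
   decreasing eigenvalue.

Classification of a pattern ``y`` at dimensionality ``d`` whitens ``y``,
projects onto the first ``d`` eigenvectors and assigns the class whose
projected mean gives the largest linear discriminant (equivalently, the
nearest projected mean in squared Euclidean distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PatternDataset",
    "TrainedClassifier",
    "AccuracyCurve",
    "ProjectedConfig",
    "estimate_means",
    "estimate_within_cov",
    "whitening_transform",
    "between_class_cov_white",
    "discriminative_directions",
    "fit_classifier",
    "classify_full",
    "classify_reduced",
    "crossval_accuracy_curve",
    "project_to_feature_space",
]

#: relative floor for eigenvalues when inverting a covariance matrix
EIG_FLOOR_REL = 1e-10
#: absolute diagonal added when the within-class scatter is identically zero
ZERO_COV_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass
class PatternDataset:
    """Trials-by-units activity patterns with condition and run labels.

    Parameters
    ----------
    values
        ``(n_trials, P)`` array of activity estimates (e.g. GLM betas); one
        row per trial, one column per unit (voxel / neuron / electrode).
    condition
        Per-trial condition label.  ``K >= 2`` distinct labels are required
        and every condition must occur in every run (leave-one-run-out
        training would otherwise lack a class mean).
    run
        Per-trial fold label; one fold per imaging run.
    unit_ids
        Optional identifiers for the ``P`` columns.
    """

    values: np.ndarray
    condition: np.ndarray
    run: np.ndarray
    unit_ids: list | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D trials x units matrix")
        self.condition = np.asarray(self.condition)
        self.run = np.asarray(self.run)
        n, p = self.values.shape
        if self.condition.shape != (n,):
            raise ValueError(
                f"condition has length {self.condition.shape}, expected ({n},)"
            )
        if self.run.shape != (n,):
            raise ValueError(f"run has length {self.run.shape}, expected ({n},)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if self.unit_ids is not None and len(self.unit_ids) != p:
            raise ValueError(
                f"unit_ids has length {len(self.unit_ids)}, expected {p}"
            )
        conds = np.unique(self.condition)
        if conds.size < 2:
            raise ValueError("need at least K = 2 conditions")
        for r in np.unique(self.run):
            present = np.unique(self.condition[self.run == r])
            missing = np.setdiff1d(conds, present)
            if missing.size:
                raise ValueError(
                    f"run {r!r} is missing condition(s) {missing.tolist()}"
                )

    # -- convenience -------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_units(self) -> int:
        return self.values.shape[1]

    @property
    def conditions(self) -> np.ndarray:
        """Sorted unique condition labels."""
        return np.unique(self.condition)

    @property
    def runs(self) -> np.ndarray:
        """Sorted unique run labels."""
        return np.unique(self.run)

    @property
    def n_conditions(self) -> int:
        return self.conditions.size

    @property
    def n_runs(self) -> int:
        return self.runs.size

    def subset_units(self, index) -> "PatternDataset":
        """Return a dataset restricted to the given unit columns."""
        index = np.asarray(index)
        ids = None
        if self.unit_ids is not None:
            ids = [self.unit_ids[i] for i in index]
        return PatternDataset(self.values[:, index], self.condition.copy(),
                              self.run.copy(), ids)

    def subset_trials(self, mask) -> "PatternDataset":
        """Return a dataset restricted to the given trial rows (revalidated)."""
        mask = np.asarray(mask)
        return PatternDataset(self.values[mask], self.condition[mask],
                              self.run[mask], self.unit_ids)


@dataclass
class TrainedClassifier:
    """Gaussian linear classifier parameters fitted on a training split."""

    classes: np.ndarray          # K condition labels, sorted
    class_means: np.ndarray      # (K, P) estimated class means
    within_cov: np.ndarray       # (P, P) regularized within-class covariance
    whitener: np.ndarray         # (P, P) symmetric inverse square root
    between_cov_white: np.ndarray  # (P, P) between-class covariance, whitened
    eigvecs: np.ndarray          # (P, K-1) discriminative directions
    eigvals: np.ndarray          # (K-1,) eigenvalues, descending
    reg_fraction: float = 0.01

    @property
    def n_classes(self) -> int:
        return self.classes.size

    @property
    def n_units(self) -> int:
        return self.class_means.shape[1]


@dataclass
class AccuracyCurve:
    """Cross-validated accuracy as a function of classifier dimensionality.

    Accuracies are stored as exact counts (``n_correct`` out of
    ``n_test_trials``) so that "equal accuracy" is well defined to within
    half the resolution ``1 / n_test_trials``.
    """

    dims: np.ndarray             # classifier dimensionalities, ascending
    n_correct: np.ndarray        # correct test classifications per dim
    n_test_trials: int           # total test trials pooled over folds
    per_fold: np.ndarray | None = None   # (n_folds, n_dims) fold accuracies
    fold_sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dims = np.asarray(self.dims, dtype=int)
        self.n_correct = np.asarray(self.n_correct)
        if self.dims.shape != self.n_correct.shape:
            raise ValueError("dims and n_correct must have equal length")

    @property
    def accuracy(self) -> np.ndarray:
        return self.n_correct / self.n_test_trials

    @property
    def best_dim(self) -> int:
        """Dimensionality with the highest accuracy; ties go to the smallest d."""
        return int(self.dims[int(np.argmax(self.n_correct))])

    @property
    def full_accuracy(self) -> float:
        """Accuracy of the highest-dimensional (full) classifier in the curve."""
        return float(self.n_correct[-1] / self.n_test_trials)


@dataclass
class ProjectedConfig:
    """Condition means projected into the estimated feature space."""

    coords: np.ndarray       # (K, d) projected class means
    eigvals_used: np.ndarray  # the d eigenvalues of the projection axes
    d: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("projected coordinates are not finite")
        if self.coords.shape[1] != self.d:
            raise ValueError("coords has a different width than d")


# ---------------------------------------------------------------------------
# estimation
# ---------------------------------------------------------------------------

def _trial_mask(data: PatternDataset, trials) -> np.ndarray:
    if trials is None:
        return np.ones(data.n_trials, dtype=bool)
    trials = np.asarray(trials)
    if trials.dtype == bool:
        return trials
    mask = np.zeros(data.n_trials, dtype=bool)
    mask[trials] = True
    return mask


def estimate_means(data: PatternDataset, trials=None) -> np.ndarray:
    """Arithmetic mean pattern per condition over the selected trials.

    Returns a ``(K, P)`` matrix; row order follows ``data.conditions``.
    """
    mask = _trial_mask(data, trials)
    X = data.values[mask]
    c = data.condition[mask]
    conds = data.conditions
    means = np.empty((conds.size, data.n_units))
    for i, k in enumerate(conds):
        sel = c == k
        if not sel.any():
            raise ValueError(
                f"condition {k} has no trials in the selected subset"
            )
        means[i] = X[sel].mean(axis=0)
    return means


def estimate_within_cov(data: PatternDataset, trials=None,
                        reg_fraction: float = 0.01) -> np.ndarray:
    """Pooled within-class covariance, regularized on the diagonal.

    The pooled scatter is divided by ``sum_k (N_k - 1)`` — for balanced data
    with ``N`` trials per condition this is ``(N - 1) K``.  Regularization
    adds ``reg_fraction`` of the mean diagonal element to the diagonal, which
    keeps the estimate invertible when ``P`` exceeds the residual degrees of
    freedom (the typical case for fMRI region-of-interest data).
    """
    mask = _trial_mask(data, trials)
    X = data.values[mask]
    c = data.condition[mask]
    P = data.n_units
    scatter = np.zeros((P, P))
    dof = 0
    for k in data.conditions:
        Xk = X[c == k]
        if Xk.shape[0] == 0:
            raise ValueError(
                f"condition {k} has no trials in the selected subset"
            )
        Xc = Xk - Xk.mean(axis=0)
        scatter += Xc.T @ Xc
        dof += Xk.shape[0] - 1
    if dof == 0:
        raise ValueError(
            "within-class scatter undefined: every condition has a single trial"
        )
    cov = scatter / dof
    if reg_fraction:
        mean_diag = float(np.mean(np.diag(cov)))
        if mean_diag <= 0.0:
            warnings.warn(
                "within-class scatter is identically zero; applying an "
                f"absolute diagonal floor of {ZERO_COV_FLOOR}",
                RuntimeWarning,
            )
            cov = cov + ZERO_COV_FLOOR * np.eye(P)
        else:
            cov = cov + reg_fraction * mean_diag * np.eye(P)
    return cov


def whitening_transform(cov: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root ``Sigma^{-1/2}`` of an SPD matrix.

    Computed by symmetric eigendecomposition.  Eigenvalues below
    ``EIG_FLOOR_REL`` times the mean eigenvalue are clipped to that floor
    (with a warning); the 1% diagonal regularization normally makes the
    floor irrelevant.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be a square matrix")
    if not np.allclose(cov, cov.T, rtol=1e-8, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    vals, vecs = np.linalg.eigh(cov)
    mean_val = float(vals.mean())
    if mean_val <= 0.0:
        raise ValueError("covariance is not positive definite")
    floor = EIG_FLOOR_REL * mean_val
    if np.any(vals < floor):
        warnings.warn(
            "covariance eigenvalues below the floor were clipped before "
            "inversion",
            RuntimeWarning,
        )
        vals = np.clip(vals, floor, None)
    return (vecs / np.sqrt(vals)) @ vecs.T


def between_class_cov_white(means_white: np.ndarray) -> np.ndarray:
    """Between-class covariance of (pre-whitened) class means.

    ``(1/K) sum_k (mu*_k - mu*)(mu*_k - mu*)^T`` with ``mu*`` the unweighted
    mean over the ``K`` class means.  Rank is at most ``K - 1``.
    """
    M = np.asarray(means_white, dtype=float)
    Mc = M - M.mean(axis=0)
    return Mc.T @ Mc / M.shape[0]


def _canonical_directions(vals: np.ndarray, vecs: np.ndarray):
    """Order eigenpairs descending with deterministic tie-breaks and signs.

    Ties (relative gap below 1e-9) are ordered by the axis index of each
    eigenvector's largest-magnitude component; every eigenvector is flipped
    so that its largest-magnitude component is positive.
    """
    order = np.argsort(-vals, kind="stable")
    vals = vals[order]
    vecs = vecs[:, order]
    scale = max(abs(float(vals[0])), 1.0) if vals.size else 1.0
    tol = 1e-9 * scale
    # reorder within groups of (numerically) tied eigenvalues
    i = 0
    n = vals.size
    while i < n:
        j = i + 1
        while j < n and vals[i] - vals[j] <= tol:
            j += 1
        if j - i > 1:
            anchors = np.argmax(np.abs(vecs[:, i:j]), axis=0)
            sub = np.argsort(anchors, kind="stable")
            vecs[:, i:j] = vecs[:, i:j][:, sub]
            vals[i:j] = vals[i:j][sub]
        i = j
    # deterministic signs
    if vecs.size:
        anchors = np.argmax(np.abs(vecs), axis=0)
        signs = np.sign(vecs[anchors, np.arange(vecs.shape[1])])
        signs[signs == 0] = 1.0
        vecs = vecs * signs
    return vals, vecs


def discriminative_directions(B: np.ndarray, n_components: int | None = None):
    """Top eigenpairs of a symmetric PSD between-class covariance.

    Returns ``(eigvecs, eigvals)`` with eigenvalues descending (clipped at
    zero), orthonormal eigenvectors, and deterministic sign/tie conventions.
    ``n_components`` defaults to all ``P`` directions; pass ``K - 1`` for the
    discriminative subspace of a ``K``-class problem.
    """
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[0] != B.shape[1]:
        raise ValueError("B must be a square matrix")
    if not np.allclose(B, B.T, rtol=1e-8, atol=1e-10):
        raise ValueError("B must be symmetric")
    vals, vecs = np.linalg.eigh(B)
    vals = np.clip(vals, 0.0, None)
    vals, vecs = _canonical_directions(vals, vecs)
    if n_components is not None:
        vals = vals[:n_components]
        vecs = vecs[:, :n_components]
    return vecs, vals


def fit_classifier(data: PatternDataset, trials=None,
                   reg_fraction: float = 0.01) -> TrainedClassifier:
    """Fit class means, covariance, whitener and discriminative directions.

    The eigendecomposition of the whitened between-class covariance is
    obtained from the SVD of the ``K`` centered whitened means (exact, since
    the matrix has rank at most ``K - 1``), which avoids a ``P x P``
    eigendecomposition for large unit counts.
    """
    means = estimate_means(data, trials)
    cov = estimate_within_cov(data, trials, reg_fraction)
    whitener = whitening_transform(cov)
    mw = means @ whitener
    K = means.shape[0]
    Mc = mw - mw.mean(axis=0)
    B = Mc.T @ Mc / K
    _, svals, Vt = np.linalg.svd(Mc, full_matrices=False)
    vals = svals**2 / K
    vals, vecs = _canonical_directions(vals[: K - 1], Vt[: K - 1].T)
    return TrainedClassifier(
        classes=data.conditions,
        class_means=means,
        within_cov=cov,
        whitener=whitener,
        between_cov_white=B,
        eigvecs=vecs,
        eigvals=vals,
        reg_fraction=reg_fraction,
    )


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def _as_batch(y: np.ndarray, P: int):
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = y[None, :] if single else y
    if Y.ndim != 2 or Y.shape[1] != P:
        raise ValueError(f"pattern has {Y.shape[-1]} units, classifier expects {P}")
    return Y, single


def classify_full(model: TrainedClassifier, y: np.ndarray):
    """Assign pattern(s) to the class with the highest linear discriminant.

    ``g_k(y) = h_k y - (1/2) h_k mu_k`` with ``h_k = mu_k^T Sigma_W^{-1}``;
    constant terms independent of the class are dropped.  Ties go to the
    lowest class label.
    """
    Y, single = _as_batch(y, model.n_units)
    sigma_inv = model.whitener @ model.whitener
    H = model.class_means @ sigma_inv                      # (K, P)
    g = Y @ H.T - 0.5 * np.sum(H * model.class_means, axis=1)
    labels = model.classes[np.argmax(g, axis=1)]
    return labels[0] if single else labels


def _reduced_scores(model: TrainedClassifier, Y: np.ndarray, d: int):
    A = model.whitener @ model.eigvecs[:, :d]              # (P, d)
    Zm = model.class_means @ A                             # (K, d)
    Z = Y @ A                                              # (n, d)
    return Z @ Zm.T - 0.5 * np.sum(Zm * Zm, axis=1)


def classify_reduced(model: TrainedClassifier, y: np.ndarray, d: int):
    """Classify using only the top-``d`` discriminative directions.

    Data and class means are whitened and projected onto the first ``d``
    eigenvectors of the between-class covariance; the discriminant is then
    Euclidean in the projected space.  With ``d = K - 1`` the labels agree
    exactly with :func:`classify_full`.
    """
    K = model.n_classes
    if not 1 <= d <= K - 1:
        raise ValueError(f"d must be in 1..{K - 1}, got {d}")
    Y, single = _as_batch(y, model.n_units)
    g = _reduced_scores(model, Y, d)
    labels = model.classes[np.argmax(g, axis=1)]
    return labels[0] if single else labels


def crossval_accuracy_curve(data: PatternDataset, reg_fraction: float = 0.01,
                            dims=None) -> AccuracyCurve:
    """Leave-one-run-out accuracy for each classifier dimensionality.

    Each run serves once as the test set; the classifier (means, covariance,
    whitener, discriminative directions) is estimated on the remaining runs
    only, and every held-out trial is classified at each ``d``.  Accuracies
    are pooled over folds.
    """
    runs = data.runs
    if runs.size < 2:
        raise ValueError("cross-validation requires at least 2 runs")
    K = data.n_conditions
    dims = np.arange(1, K) if dims is None else np.asarray(dims, dtype=int)
    if dims.size == 0 or dims.min() < 1 or dims.max() > K - 1:
        raise ValueError(f"dims must lie in 1..{K - 1}")
    n_correct = np.zeros(dims.size, dtype=int)
    per_fold = np.empty((runs.size, dims.size))
    fold_sizes = np.empty(runs.size, dtype=int)
    for fi, r in enumerate(runs):
        train = data.run != r
        model = fit_classifier(data, trials=train, reg_fraction=reg_fraction)
        Y = data.values[~train]
        truth = data.condition[~train]
        fold_sizes[fi] = truth.size
        # share the projection across dims: compute at d_max, slice columns
        d_max = int(dims.max())
        A = model.whitener @ model.eigvecs[:, :d_max]
        Zm = model.class_means @ A
        Z = Y @ A
        for di, d in enumerate(dims):
            g = Z[:, :d] @ Zm[:, :d].T - 0.5 * np.sum(Zm[:, :d] ** 2, axis=1)
            pred = model.classes[np.argmax(g, axis=1)]
            c = int(np.sum(pred == truth))
            n_correct[di] += c
            per_fold[fi, di] = c / truth.size
    return AccuracyCurve(
        dims=dims,
        n_correct=n_correct,
        n_test_trials=int(fold_sizes.sum()),
        per_fold=per_fold,
        fold_sizes=fold_sizes,
    )


def project_to_feature_space(model: TrainedClassifier, d: int) -> ProjectedConfig:
    """Project the class means onto the first ``d`` discriminative directions.

    ``f_k = W^{(d)T} Sigma_W^{-1/2} mu_k``.  At ``d = K - 1`` pairwise
    Euclidean distances among the projected means equal pairwise Mahalanobis
    distances among the original means, and the per-dimension variance of the
    projected means (with ``1/K`` normalization) equals the eigenvalues.
    """
    K = model.n_classes
    if not 1 <= d <= K - 1:
        raise ValueError(f"d must be in 1..{K - 1}, got {d}")
    coords = model.class_means @ model.whitener @ model.eigvecs[:, :d]
    return ProjectedConfig(coords=coords, eigvals_used=model.eigvals[:d], d=d)
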