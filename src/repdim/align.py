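"""Procrustes alignment of projected condition configurations.

Feature-space projections are only identified up to translation, isotropic
scale, and rotation/reflection (eigenvector signs and rotations within tied
eigenvalues are arbitrary).  To compare configurations across subjects we
align them with similarity transforms: pairwise ordinary Procrustes, and a
generalized (group) Procrustes that iteratively aligns all configurations
to their evolving consensus.

Reflections are deliberately allowed — the rotation matrices are orthogonal
but not necessarily special-orthogonal — because projection axes from an
eigendecomposition have no canonical orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimilarityTransform",
    "AlignedSet",
    "procrustes_pair",
    "procrustes_group",
]


@dataclass
class SimilarityTransform:
    """x -> scale * x @ rotation + translation."""

    rotation: np.ndarray      # (d, d) orthogonal (reflections allowed)
    scale: float
    translation: np.ndarray   # (d,)

    def apply(self, X: np.ndarray) -> np.ndarray:
        return self.scale * np.asarray(X, float) @ self.rotation + self.translation


@dataclass
class AlignedSet:
    """Result of generalized Procrustes alignment."""

    configs: list              # aligned K x d configurations
    reference: np.ndarray      # K x d consensus configuration (unit norm)
    residuals: np.ndarray      # per-configuration squared misfit to consensus
    transforms: list           # SimilarityTransform per input configuration
    dispersion: np.ndarray     # (K, d, d) per-condition covariance of aligned coords
    n_iter: int


def _center(X: np.ndarray):
    mu = X.mean(axis=0)
    return X - mu, mu


def procrustes_pair(source: np.ndarray, target: np.ndarray):
    """Least-squares similarity transform of ``source`` onto ``target``.

    Minimizes ``||target - (s * source @ R + t)||_F^2`` over translation
    ``t``, orthogonal ``R`` (reflections allowed) and isotropic scale
    ``s >= 0``.  Returns ``(transform, residual)`` where the residual is the
    minimized misfit normalized by the centered target's squared norm
    (0 for a perfect fit, 1 for no fit; degenerate all-identical inputs give
    0 by convention).
    """
    S = np.asarray(source, dtype=float)
    T = np.asarray(target, dtype=float)
    if S.shape != T.shape:
        raise ValueError(f"shape mismatch: {S.shape} vs {T.shape}")
    Sc, smu = _center(S)
    Tc, tmu = _center(T)
    ns2 = float(np.sum(Sc * Sc))
    nt2 = float(np.sum(Tc * Tc))
    d = S.shape[1]
    if ns2 == 0.0 and nt2 == 0.0:
        # both configurations are a single repeated point
        tf = SimilarityTransform(np.eye(d), 0.0, tmu.copy())
        return tf, 0.0
    if ns2 == 0.0:
        tf = SimilarityTransform(np.eye(d), 0.0, tmu.copy())
        return tf, 1.0
    U, sv, Vt = np.linalg.svd(Sc.T @ Tc)
    R = U @ Vt
    scale = float(sv.sum() / ns2)
    translation = tmu - scale * smu @ R
    if nt2 == 0.0:
        # optimal scale is 0; the fit collapses onto the target point
        tf = SimilarityTransform(R, 0.0, tmu - 0.0 * smu @ R)
        return tf, 0.0
    residual = max(0.0, 1.0 - float(sv.sum()) ** 2 / (ns2 * nt2))
    return SimilarityTransform(R, scale, translation), residual


def procrustes_group(configs, max_iter: int = 100, tol: float = 1e-9) -> AlignedSet:
    """Generalized Procrustes alignment of several configurations.

    All configurations are aligned to a consensus (initialized from the
    first configuration) that is recomputed as the mean of the aligned
    configurations, re-centered and scaled to unit Frobenius norm, until it
    changes by less than ``tol``.  The per-condition dispersion of the
    aligned coordinates (a covariance matrix per condition) summarizes
    between-configuration variability, e.g. for standard-deviation ellipses.
    """
    configs = [np.asarray(c, dtype=float) for c in configs]
    if len(configs) < 2:
        raise ValueError("need at least 2 configurations")
    shape = configs[0].shape
    if any(c.shape != shape for c in configs):
        raise ValueError("all configurations must have the same K x d shape")
    ref = _center(configs[0])[0]
    norm = np.linalg.norm(ref)
    ref = ref / norm if norm > 0 else ref
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        aligned = []
        transforms = []
        for c in configs:
            tf, _ = procrustes_pair(c, ref)
            aligned.append(tf.apply(c))
            transforms.append(tf)
        new_ref = _center(np.mean(aligned, axis=0))[0]
        norm = np.linalg.norm(new_ref)
        if norm > 0:
            new_ref = new_ref / norm
        change = float(np.linalg.norm(new_ref - ref))
        ref = new_ref
        if change < tol:
            break
    # final alignment against the converged consensus
    aligned = []
    transforms = []
    residuals = []
    for c in configs:
        tf, _ = procrustes_pair(c, ref)
        a = tf.apply(c)
        aligned.append(a)
        transforms.append(tf)
        residuals.append(float(np.sum((a - ref) ** 2)))
    stack = np.stack(aligned)                      # (n_cfg, K, d)
    dev = stack - stack.mean(axis=0)
    dispersion = np.einsum("nki,nkj->kij", dev, dev) / stack.shape[0]
    return AlignedSet(
        configs=aligned,
        reference=ref,
        residuals=np.asarray(residuals),
        transforms=transforms,
        dispersion=dispersion,
        n_iter=n_iter,
    )
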