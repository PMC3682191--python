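"""Canonical Monte-Carlo experiments for validating the method.

These functions bundle the study conditions used throughout the package's
validation: K = 4 conditions, one pattern per condition per run, 8 runs,
80 units (the subspace size) for the sweep experiments, and 400-unit
regions for the random-subspace comparison.  They are thin, seedable
drivers over :mod:`repdim.simulate` and :mod:`repdim.subspace`.
"""

from __future__ import annotations


import numpy as np

from .simulate import (
    SimConfig,
    identification_rate,
    make_random_features,
    true_eigen_spectrum,
)
from .subspace import RoiExperimentResult, roi_dimensionality_experiment

__all__ = [
    "mean_random_spectrum",
    "sweep_identification",
    "roi_subspace_comparison",
]


def mean_random_spectrum(D: int, n_draws: int = 10000, K: int = 4,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Mean normalized true eigen-spectrum of random feature placements.

    Draws ``n_draws`` random K-condition feature configurations in ``D``
    dimensions, normalizes each spectrum by its largest eigenvalue, and
    averages.
    """
    if rng is None:
        rng = np.random.default_rng()
    total = np.zeros(K - 1)
    for _ in range(n_draws):
        total += true_eigen_spectrum(make_random_features(K, D, rng))
    return total / n_draws


def sweep_identification(true_Ds, n_sims: int,
                         rng: np.random.Generator | None = None,
                         P: int = 80, n_runs: int = 8):
    """Dimensionality identification across the signal-variance sweep.

    Returns the :class:`~repdim.simulate.IdentificationResult` for random
    feature spacing under the standard study conditions.
    """
    cfg = SimConfig(P=P, n_runs=n_runs)
    return identification_rate(list(true_Ds), "random", n_sims, cfg, rng)


def roi_subspace_comparison(n_per_D: int, n_draws: int,
                            rng: np.random.Generator | None = None,
                            P: int = 400, subset_size: int = 80,
                            target_accuracy: float = 0.70) -> RoiExperimentResult:
    """Full-region vs. random-subspace identification on simulated ROIs."""
    cfg = SimConfig(P=P, n_runs=8)
    return roi_dimensionality_experiment(
        n_per_D=n_per_D, true_Ds=(1, 2, 3), cfg=cfg,
        target_accuracy=target_accuracy, subset_size=subset_size,
        n_draws=n_draws, rng=rng,
    )
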