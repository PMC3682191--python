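"""Synthetic pattern datasets from latent feature spaces, and the
Monte-Carlo experiments that validate dimensionality estimation.

Generative model: condition ``k`` has a latent feature vector ``f_k`` of
length ``D`` (the true dimensionality).  Each feature dimension ``d`` is
tied to a pattern component ``u_d`` — a length-``P`` spatial pattern drawn
iid ``N(0, sigma_a^2 I)``.  A trial of condition ``k`` is

    y_{k,n} = sum_d u_d f_k^(d) + eps_{k,n},   eps ~ N(0, noise_var I).

With ``noise_var`` fixed at 1, ``sigma_a^2`` acts as the signal-to-noise
ratio of the representation.

Feature spacing modes
---------------------
``random``
    rows of ``F`` iid standard normal in ``D`` dimensions; four conditions
    placed at random in 3-D are nearly coplanar on average, so the higher
    feature dimensions carry little between-condition variance.
``even``
    built from the row-centered K x K indicator matrix (``1 - 1/K`` on the
    diagonal, ``-1/K`` elsewhere) projected onto ``D`` of its
    equal-eigenvalue eigenvectors; every feature dimension then separates
    the conditions equally (flat eigen-spectrum).
``recruitment``
    conditions differ in how many units are active at a fixed amplitude
    (nested activation), not in graded activity; despite being driven by a
    single physical variable this yields a full-rank between-class spectrum.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    PatternDataset,
    AccuracyCurve,
    _canonical_directions,
    crossval_accuracy_curve,
)

__all__ = [
    "FeatureSpec",
    "SimConfig",
    "SimulatedDataset",
    "IdentificationResult",
    "make_random_features",
    "make_even_features",
    "make_recruitment_patterns",
    "simulate_dataset",
    "simulate_from_means",
    "normalized_between_spectrum",
    "true_eigen_spectrum",
    "calibrate_sigma_sweep",
    "calibrate_sigma_to_accuracy",
    "identification_rate",
    "match_accuracy_curves",
]


@dataclass
class FeatureSpec:
    """Latent feature vectors for the K experimental conditions."""

    K: int
    D: int
    spacing: str           # {"random", "even", "recruitment"}
    F: np.ndarray          # (K, D) feature vectors, one row per condition

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (self.K, self.D):
            raise ValueError(f"F must be ({self.K}, {self.D}), got {self.F.shape}")


@dataclass
class SimConfig:
    """Simulation sizes and noise levels.

    Defaults mirror a typical fMRI run structure: one pattern estimate per
    condition per run (``N = n_runs``), 8 runs, and 80 units — the subspace
    size used throughout the random-subspace analyses.
    """

    P: int = 80
    n_runs: int = 8
    trials_per_cond_per_run: int = 1
    sigma_a2: float = 0.1
    noise_var: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.P, self.n_runs, self.trials_per_cond_per_run) < 1:
            raise ValueError("P, n_runs and trials_per_cond_per_run must be >= 1")
        if self.sigma_a2 < 0 or self.noise_var < 0:
            raise ValueError("variances must be non-negative")


@dataclass
class SimulatedDataset:
    """A generated dataset together with its true (noise-free) structure."""

    data: PatternDataset
    components: np.ndarray   # (D, P) pattern components u_d
    true_means: np.ndarray   # (K, P) noise-free condition means
    spec: FeatureSpec
    cfg: SimConfig


# ---------------------------------------------------------------------------
# feature-space constructions
# ---------------------------------------------------------------------------

def make_random_features(K: int, D: int, rng: np.random.Generator) -> FeatureSpec:
    """Draw each condition's feature vector iid from a D-dim standard normal."""
    if K < 2 or D < 1:
        raise ValueError("need K >= 2 and D >= 1")
    return FeatureSpec(K=K, D=D, spacing="random", F=rng.standard_normal((K, D)))


def make_even_features(K: int, D: int) -> FeatureSpec:
    """Equal-separation feature vectors (deterministic).

    Row-center the K x K indicator matrix and project its rows onto ``D`` of
    the resulting eigenvectors with (identical) non-zero eigenvalue.  Each of
    the ``D`` feature dimensions then carries the same between-condition
    variance; at ``D = K - 1`` the conditions form a regular simplex.
    """
    if K < 2 or D < 1:
        raise ValueError("need K >= 2 and D >= 1")
    if D > K - 1:
        raise ValueError(
            f"no {D} independent equal-separation directions exist for K={K}"
        )
    C = np.eye(K) - 1.0 / K
    vals, vecs = np.linalg.eigh(C)
    vals, vecs = _canonical_directions(vals, vecs)
    V = vecs[:, :D]                    # eigenvalue-1 eigenvectors
    return FeatureSpec(K=K, D=D, spacing="even", F=C @ V)


def make_recruitment_patterns(K: int, P: int, amplitude: float = 1.0,
                              counts=None) -> np.ndarray:
    """True mean patterns for nested recruitment coding.

    Condition ``k`` activates the first ``counts[k]`` units at a constant
    amplitude, with ``counts`` strictly increasing (default: equal steps up
    to ``P``).  Returns the ``(K, P)`` matrix of true condition means.
    """
    if counts is None:
        counts = np.round(np.arange(1, K + 1) * P / K).astype(int)
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (K,):
        raise ValueError(f"counts must have length {K}")
    if counts[0] < 1 or counts[-1] > P or np.any(np.diff(counts) <= 0):
        raise ValueError("counts must be strictly increasing within 1..P")
    means = np.zeros((K, P))
    for k, c in enumerate(counts):
        means[k, :c] = amplitude
    return means


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _assemble(true_means: np.ndarray, cfg: SimConfig,
              rng: np.random.Generator) -> PatternDataset:
    K = true_means.shape[0]
    T = cfg.trials_per_cond_per_run
    cond = np.tile(np.repeat(np.arange(1, K + 1), T), cfg.n_runs)
    run = np.repeat(np.arange(1, cfg.n_runs + 1), K * T)
    noise = rng.normal(0.0, np.sqrt(cfg.noise_var), size=(cond.size, cfg.P))
    values = true_means[cond - 1] + noise
    return PatternDataset(values=values, condition=cond, run=run)


def simulate_dataset(spec: FeatureSpec, cfg: SimConfig,
                     rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Generate a pattern dataset from a latent feature space.

    Pattern components are drawn iid ``N(0, sigma_a^2)`` per unit, and each
    trial adds iid Gaussian noise of variance ``noise_var``.  The components
    and the noise-free condition means are returned alongside the dataset.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    U = rng.normal(0.0, np.sqrt(cfg.sigma_a2), size=(spec.D, cfg.P))
    true_means = spec.F @ U
    data = _assemble(true_means, cfg, rng)
    return SimulatedDataset(data=data, components=U, true_means=true_means,
                            spec=spec, cfg=cfg)


def simulate_from_means(true_means: np.ndarray, cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> PatternDataset:
    """Generate a dataset around fixed true condition means (e.g. recruitment)."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    true_means = np.asarray(true_means, dtype=float)
    if true_means.shape[1] != cfg.P:
        raise ValueError("true_means width must equal cfg.P")
    return _assemble(true_means, cfg, rng)


# ---------------------------------------------------------------------------
# true spectra
# ---------------------------------------------------------------------------

def normalized_between_spectrum(rows: np.ndarray, n_out: int | None = None,
                                center: bool = True) -> np.ndarray:
    """Normalized eigenvalues of the 1/K scatter of ``rows``.

    With ``center=True`` (default) the rows are centered at their sample
    mean, as in the estimated between-class covariance; ``center=False``
    treats the rows as already expressed around their true mean.
    Eigenvalues are sorted descending, padded with zeros to ``n_out``
    (default ``K - 1``) and divided by the largest.  An all-zero scatter
    returns all zeros.
    """
    R = np.asarray(rows, dtype=float)
    K = R.shape[0]
    Rc = R - R.mean(axis=0) if center else R
    vals = np.linalg.eigvalsh(Rc.T @ Rc / K)[::-1]
    vals = np.clip(vals, 0.0, None)
    if n_out is None:
        n_out = K - 1
    out = np.zeros(n_out)
    m = min(n_out, vals.size)
    out[:m] = vals[:m]
    if out[0] > 0:
        out = out / out[0]
    return out


def true_eigen_spectrum(spec: FeatureSpec) -> np.ndarray:
    """Normalized true between-class eigenvalues implied by a feature spec.

    This is the large-P limit in which the pattern components are orthogonal
    up to a common scale, so the spectrum depends on the feature vectors
    alone.  The features are centered at the *true* mean of the generating
    distribution — the origin, for both the random draw and the (already
    zero-sum) even construction — not at the sample mean of the ``K`` draws.
    A 1-D space gives ``[1, 0, ...]``; even spacing gives an exactly flat
    spectrum for any ``D <= K - 1``; four conditions placed at random in 3-D
    average to roughly ``[1, 0.39, 0.09]`` because random placements are
    nearly coplanar.
    """
    return normalized_between_spectrum(spec.F, n_out=spec.K - 1, center=False)


# ---------------------------------------------------------------------------
# calibration and Monte-Carlo experiments
# ---------------------------------------------------------------------------

def _pilot_accuracies(spec: FeatureSpec, cfg: SimConfig, sigma: float,
                      rng: np.random.Generator, n_pilot: int,
                      reg_fraction: float) -> np.ndarray:
    """Full-classifier accuracies of pilot simulations at one sigma_a2."""
    cfg_s = dataclasses.replace(cfg, sigma_a2=float(sigma))
    acc = np.empty(n_pilot)
    for i in range(n_pilot):
        sp = (make_random_features(spec.K, spec.D, rng)
              if spec.spacing == "random" else spec)
        sd = simulate_dataset(sp, cfg_s, rng)
        acc[i] = crossval_accuracy_curve(sd.data, reg_fraction).full_accuracy
    return acc


def calibrate_sigma_sweep(spec: FeatureSpec, cfg: SimConfig,
                          n_levels: int = 21,
                          rng: np.random.Generator | None = None,
                          n_pilot: int = 60, perfect_fraction: float = 0.05,
                          reg_fraction: float = 0.01) -> np.ndarray:
    """Uniform sigma_a2 grid from 0 up to the 100%-accuracy level.

    The top of the grid is the smallest signal variance at which simulation
    runs start to reach 100% cross-validated accuracy with the
    full-dimensional classifier — operationalized as at least
    ``perfect_fraction`` of ``n_pilot`` pilot runs being classified
    perfectly.  (Requiring the *mean* accuracy to reach 1.0 instead would
    push the level to extreme signal variances, because with random feature
    placement there are always unlucky draws whose conditions nearly
    coincide; the sweep would then consist almost entirely of saturated
    runs.)  Located by doubling search plus bisection; for
    ``spacing == "random"`` the pilot runs redraw the feature vectors.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 grid levels")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    def reaches(sigma: float) -> bool:
        acc = _pilot_accuracies(spec, cfg, sigma, rng, n_pilot, reg_fraction)
        return float(np.mean(acc == 1.0)) >= perfect_fraction

    s = 0.05
    if reaches(s):
        lo, hi = 0.0, s
    else:
        for _ in range(40):
            s *= 2.0
            if reaches(s):
                break
        else:
            raise RuntimeError("full-classifier accuracy never reached 100%")
        lo, hi = s / 2.0, s
    for _ in range(5):
        mid = 0.5 * (lo + hi)
        if reaches(mid):
            hi = mid
        else:
            lo = mid
    return np.linspace(0.0, hi, n_levels)


def calibrate_sigma_to_accuracy(spec: FeatureSpec, cfg: SimConfig,
                                target: float,
                                rng: np.random.Generator | None = None,
                                n_pilot: int = 8, n_iter: int = 7,
                                reg_fraction: float = 0.01) -> float:
    """Signal variance at which the full classifier averages ``target`` accuracy.

    Bisection on the mean pilot accuracy; used to match the difficulty of
    simulated regions across different true dimensionalities.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    hi = 0.05
    while _pilot_accuracies(spec, cfg, hi, rng, n_pilot,
                            reg_fraction).mean() < target:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("target accuracy unreachable")
    lo = 0.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if _pilot_accuracies(spec, cfg, mid, rng, n_pilot,
                             reg_fraction).mean() >= target:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


@dataclass
class IdentificationResult:
    """Outcome of the dimensionality-identification Monte Carlo.

    ``best_counts[D]`` counts, over simulation runs with true dimensionality
    ``D``, how often each classifier dimensionality ``d = 1..K-1`` had the
    highest cross-validated accuracy (ties resolved to the smallest ``d``).
    """

    K: int
    spacing: str
    n_sims: int                      # per true dimensionality
    best_counts: dict                # D -> (K-1,) int array
    sweeps: dict                     # D -> sigma_a2 grid used

    def fraction_best(self, true_D: int, d: int) -> float:
        """Fraction of true-D runs in which the d-dim classifier was best."""
        return float(self.best_counts[true_D][d - 1] / self.n_sims)

    def correct_fraction(self, true_D: int) -> float:
        return self.fraction_best(true_D, true_D)

    def pooled_correct_fraction(self, true_Ds=None) -> float:
        """Fraction of runs (pooled over true Ds) identified correctly."""
        Ds = list(self.best_counts) if true_Ds is None else list(true_Ds)
        correct = sum(self.best_counts[D][D - 1] for D in Ds)
        return float(correct / (self.n_sims * len(Ds)))


def identification_rate(true_D_list, spacing: str, n_sims: int,
                        cfg: SimConfig,
                        rng: np.random.Generator | None = None,
                        K: int = 4, n_levels: int = 21,
                        reg_fraction: float = 0.01) -> IdentificationResult:
    """Monte-Carlo dimensionality identification over a signal-variance sweep.

    For each true dimensionality, ``n_sims`` datasets are generated with
    ``sigma_a2`` cycling uniformly over the calibrated sweep (from 0 to the
    100%-accuracy level); each dataset's accuracy curve is computed and the
    best classifier dimensionality recorded.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    best_counts: dict = {}
    sweeps: dict = {}
    for D in true_D_list:
        spec = (make_even_features(K, D) if spacing == "even"
                else make_random_features(K, D, rng))
        sweep = calibrate_sigma_sweep(spec, cfg, n_levels, rng,
                                      reg_fraction=reg_fraction)
        counts = np.zeros(K - 1, dtype=int)
        for i in range(n_sims):
            cfg_s = dataclasses.replace(cfg, sigma_a2=float(sweep[i % sweep.size]))
            sp = (make_random_features(K, D, rng) if spacing == "random"
                  else spec)
            sd = simulate_dataset(sp, cfg_s, rng)
            curve = crossval_accuracy_curve(sd.data, reg_fraction)
            counts[curve.best_dim - 1] += 1
        best_counts[int(D)] = counts
        sweeps[int(D)] = sweep
    return IdentificationResult(K=K, spacing=spacing, n_sims=n_sims,
                                best_counts=best_counts, sweeps=sweeps)


def match_accuracy_curves(observed_full_acc: float, library) -> tuple:
    """Predict lower-dimensional accuracies by matching the full accuracy.

    Selects all library accuracy curves whose full-dimensional accuracy
    equals ``observed_full_acc`` within half the accuracy resolution
    (``0.5 / n_test_trials``) and averages their accuracies per
    dimensionality.  If no run matches, the tolerance is doubled stepwise
    with a warning.

    Returns ``(dims, mean_accuracy, n_matched, tol_used)``.
    """
    library = list(library)
    if not library:
        raise ValueError("library of simulated runs is empty")
    dims = library[0].dims
    full = np.array([c.full_accuracy for c in library])
    accs = np.array([c.accuracy for c in library])
    tol = 0.5 / library[0].n_test_trials
    while True:
        sel = np.abs(full - observed_full_acc) <= tol + 1e-12
        if sel.any():
            break
        warnings.warn(
            f"no simulation run within {tol:.4g} of accuracy "
            f"{observed_full_acc:.4g}; widening the matching tolerance",
            RuntimeWarning,
        )
        tol *= 2.0
    return dims.copy(), accs[sel].mean(axis=0), int(sel.sum()), tol
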