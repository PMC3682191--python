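"""Informativeness-based unit (voxel) selection.

Selecting units by a statistic computed on *all* the data — including the
trials later used for testing — invalidates cross-validated accuracy
estimates.  Among units selected this way there are always many whose high
score is pure noise; because such units separate the conditions along
random, mutually different directions, the selected set mimics a
full-dimensional representation regardless of the truth.  The valid
alternative scores and selects units inside each cross-validation fold,
using the training runs only.

Both variants are provided: the biased whole-data selection (opt-in, with a
prominent warning, for demonstrating the artifact) and the nested selection
that preserves validity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import AccuracyCurve, PatternDataset, _trial_mask, fit_classifier

__all__ = [
    "SelectionRule",
    "unit_f_scores",
    "select_biased",
    "select_nested",
]


@dataclass
class SelectionRule:
    """Record of a selection applied to a dataset."""

    mode: str                 # {"none", "biased", "nested"}
    keep: int
    score: np.ndarray | None = None   # per-unit F statistics (if computed)


def unit_f_scores(data: PatternDataset, trials=None) -> np.ndarray:
    """One-way ANOVA F statistic across conditions, per unit.

    ``F = MS_between / MS_within`` with the usual ``K - 1`` and ``n - K``
    degrees of freedom, computed on the selected trial subset only.  Units
    that are constant across all trials score 0; units with zero
    within-condition variance but distinct condition means score ``+inf``
    (and rank first), with a warning.
    """
    mask = _trial_mask(data, trials)
    X = data.values[mask]
    c = data.condition[mask]
    conds = data.conditions
    n = X.shape[0]
    K = conds.size
    if n - K < 1:
        raise ValueError("need more trials than conditions for the F statistic")
    grand = X.mean(axis=0)
    ssb = np.zeros(data.n_units)
    ssw = np.zeros(data.n_units)
    for k in conds:
        Xk = X[c == k]
        if Xk.shape[0] < 2:
            raise ValueError(
                f"condition {k} needs >= 2 trials in the subset for an F-test"
            )
        mk = Xk.mean(axis=0)
        ssb += Xk.shape[0] * (mk - grand) ** 2
        ssw += ((Xk - mk) ** 2).sum(axis=0)
    msb = ssb / (K - 1)
    msw = ssw / (n - K)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    zero_noise = msw == 0
    F[zero_noise & (msb == 0)] = 0.0
    exploding = zero_noise & (msb > 0)
    if exploding.any():
        warnings.warn(
            f"{int(exploding.sum())} unit(s) have zero within-condition "
            "variance; their F score is +inf and they rank first",
            RuntimeWarning,
        )
        F[exploding] = np.inf
    return F


def _top_units(scores: np.ndarray, keep: int) -> np.ndarray:
    """Indices of the ``keep`` highest-scoring units; ties by unit index."""
    order = np.argsort(-scores, kind="stable")
    return np.sort(order[:keep])


def select_biased(data: PatternDataset, fraction: float = 0.15) -> PatternDataset:
    """Keep the top-scoring fraction of units, scored on ALL the data.

    .. warning::
       This selection is statistically invalid for any downstream
       cross-validated analysis: the test trials inform the selection, which
       biases accuracy upward and makes any representation look
       full-dimensional.  It exists to demonstrate that artifact.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    keep = max(1, int(round(fraction * data.n_units)))
    warnings.warn(
        "select_biased scores units on the full dataset, including future "
        "test trials; downstream cross-validated accuracies are biased and "
        "dimensionality estimates are pushed toward full rank",
        UserWarning,
    )
    scores = unit_f_scores(data)
    return data.subset_units(_top_units(scores, keep))


def select_nested(data: PatternDataset, keep: int = 80,
                  reg_fraction: float = 0.01, dims=None,
                  return_kept: bool = False):
    """Leave-one-run-out accuracy curve with fold-wise unit selection.

    Inside each fold, units are scored by the across-condition F statistic on
    the training runs only; the classifier is fitted and tested on the
    ``keep`` top-scoring units.  With ``keep = P`` this reduces to the plain
    cross-validated curve.
    """
    runs = data.runs
    if runs.size < 2:
        raise ValueError("cross-validation requires at least 2 runs")
    if not 1 <= keep <= data.n_units:
        raise ValueError(f"keep must be in 1..{data.n_units}")
    K = data.n_conditions
    dims = np.arange(1, K) if dims is None else np.asarray(dims, dtype=int)
    n_correct = np.zeros(dims.size, dtype=int)
    per_fold = np.empty((runs.size, dims.size))
    fold_sizes = np.empty(runs.size, dtype=int)
    kept_sets = []
    for fi, r in enumerate(runs):
        train = data.run != r
        scores = unit_f_scores(data, trials=train)
        idx = _top_units(scores, keep)
        kept_sets.append(idx)
        sub = data.subset_units(idx)
        model = fit_classifier(sub, trials=train, reg_fraction=reg_fraction)
        Y = sub.values[~train]
        truth = sub.condition[~train]
        fold_sizes[fi] = truth.size
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
    curve = AccuracyCurve(dims=dims, n_correct=n_correct,
                          n_test_trials=int(fold_sizes.sum()),
                          per_fold=per_fold, fold_sizes=fold_sizes)
    if return_kept:
        return curve, kept_sets
    return curve
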