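"""Reading and writing datasets, accuracy curves and projections.

A dataset on disk is a delimited numeric matrix (TSV, rows = trials,
columns = units; column order is authoritative) plus a JSON sidecar holding
the per-trial ``condition`` and ``run`` labels and optional ``unit_ids``.
Accuracy curves and projected configurations are written as TSV with a JSON
metadata sidecar.  Floats are written with 17 significant digits so that a
write/read round trip is bit-exact.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import AccuracyCurve, PatternDataset, ProjectedConfig

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_curve",
    "read_curve",
    "write_projection",
    "read_projection",
]

_FMT = "%.17g"


def _paths(path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix == ".json":
        return p.with_suffix(".tsv"), p
    if p.suffix != ".tsv":
        p = p.with_suffix(p.suffix + ".tsv") if p.suffix else p.with_suffix(".tsv")
    return p, p.with_suffix(".json")


def write_dataset(data: PatternDataset, path) -> Path:
    """Write a dataset as ``<path>.tsv`` plus ``<path>.json`` sidecar."""
    tsv, sidecar = _paths(path)
    np.savetxt(tsv, data.values, fmt=_FMT, delimiter="\t")
    meta = {
        "condition": np.asarray(data.condition).tolist(),
        "run": np.asarray(data.run).tolist(),
        "unit_ids": list(data.unit_ids) if data.unit_ids is not None else None,
    }
    sidecar.write_text(json.dumps(meta))
    return tsv


def read_dataset(path) -> PatternDataset:
    """Read a TSV matrix + JSON sidecar back into a validated dataset."""
    tsv, sidecar = _paths(path)
    if not tsv.exists():
        raise FileNotFoundError(f"dataset matrix not found: {tsv}")
    if not sidecar.exists():
        raise FileNotFoundError(f"dataset sidecar not found: {sidecar}")
    values = np.loadtxt(tsv, delimiter="\t", ndmin=2)
    meta = json.loads(sidecar.read_text())
    for key in ("condition", "run"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} lacks required field {key!r}")
        if len(meta[key]) != values.shape[0]:
            raise ValueError(
                f"sidecar field {key!r} has {len(meta[key])} entries but the "
                f"matrix has {values.shape[0]} rows"
            )
    return PatternDataset(
        values=values,
        condition=np.asarray(meta["condition"]),
        run=np.asarray(meta["run"]),
        unit_ids=meta.get("unit_ids"),
    )


def write_curve(curve: AccuracyCurve, path, meta: dict | None = None) -> Path:
    """Write an accuracy curve as TSV (one row per dimensionality) + JSON."""
    tsv, sidecar = _paths(path)
    with open(tsv, "w") as fh:
        fh.write("dim\tn_correct\tn_test_trials\taccuracy\n")
        for d, c in zip(curve.dims, curve.n_correct):
            fh.write(f"{d}\t{c}\t{curve.n_test_trials}\t"
                     f"{c / curve.n_test_trials:.17g}\n")
    payload = dict(meta or {})
    payload["n_test_trials"] = int(curve.n_test_trials)
    if curve.per_fold is not None:
        payload["per_fold"] = np.asarray(curve.per_fold).tolist()
    if curve.fold_sizes is not None:
        payload["fold_sizes"] = np.asarray(curve.fold_sizes).tolist()
    sidecar.write_text(json.dumps(payload))
    return tsv


def read_curve(path) -> AccuracyCurve:
    tsv, sidecar = _paths(path)
    rows = np.loadtxt(tsv, delimiter="\t", skiprows=1, ndmin=2)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    per_fold = np.asarray(meta["per_fold"]) if "per_fold" in meta else None
    fold_sizes = (np.asarray(meta["fold_sizes"], dtype=int)
                  if "fold_sizes" in meta else None)
    return AccuracyCurve(
        dims=rows[:, 0].astype(int),
        n_correct=rows[:, 1].astype(int),
        n_test_trials=int(rows[0, 2]),
        per_fold=per_fold,
        fold_sizes=fold_sizes,
    )


def write_projection(config: ProjectedConfig, path, conditions=None,
                     meta: dict | None = None) -> Path:
    """Write projected condition coordinates as TSV + JSON metadata."""
    tsv, sidecar = _paths(path)
    np.savetxt(tsv, config.coords, fmt=_FMT, delimiter="\t")
    payload = dict(meta or {})
    payload["d"] = int(config.d)
    payload["eigvals_used"] = np.asarray(config.eigvals_used).tolist()
    if conditions is not None:
        payload["conditions"] = np.asarray(conditions).tolist()
    sidecar.write_text(json.dumps(payload))
    return tsv


def read_projection(path) -> ProjectedConfig:
    tsv, sidecar = _paths(path)
    coords = np.loadtxt(tsv, delimiter="\t", ndmin=2)
    meta = json.loads(sidecar.read_text())
    return ProjectedConfig(
        coords=coords,
        eigvals_used=np.asarray(meta["eigvals_used"]),
        d=int(meta["d"]),
    )
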