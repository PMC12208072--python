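"""Dataset protocol: experiment-held-out splits, balancing, padding and I/O.

Solid-state nanopore experiments differ systematically (pore geometry, noise
level), so a network can learn to recognize the *experiment* rather than the
barcode.  The split protocol guards against this leak: for each label, all
experiment subsets whose share of that label's traces falls inside the
requested test-fraction bounds are enumerated, and one is drawn uniformly at
random.  The test set is the selected experiments' traces of that label;
traces of a selected experiment carrying other labels (whose own selection
did not include it) are excluded from the dataset so that no experiment
identifier ever appears on both sides of the split.

Also here: stratified validation carving, minority-class oversampling,
padding/normalization primitives, and the HDF5 + CSV dataset container.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from numpy.random import default_rng

__all__ = [
    "DatasetSplit",
    "InfeasibleSplitError",
    "split_by_experiment",
    "carve_validation",
    "oversample_balance",
    "pad_to_length",
    "normalize_to_unfolded",
    "save_dataset",
    "load_dataset",
    "write_metadata_csv",
    "save_split",
    "load_split",
]


class InfeasibleSplitError(ValueError):
    """No experiment subset satisfies the test-fraction bounds for a label."""


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test index sets plus a constraint audit."""

    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray
    constraint_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.train_ids = np.asarray(self.train_ids, dtype=np.int64)
        self.val_ids = np.asarray(self.val_ids, dtype=np.int64)
        self.test_ids = np.asarray(self.test_ids, dtype=np.int64)
        all_ids = np.concatenate([self.train_ids, self.val_ids, self.test_ids])
        if len(np.unique(all_ids)) != len(all_ids):
            raise ValueError("train/val/test index sets must be pairwise disjoint")


def split_by_experiment(labels, experiment_ids,
                        test_frac_bounds: tuple = (0.04, 0.15), seed=None,
                        max_subset_size: int = 3) -> DatasetSplit:
    """Experiment-held-out test split with per-label test-fraction bounds.

    For each label, enumerates experiment subsets (up to ``max_subset_size``
    experiments) whose share of that label's traces lies within
    ``test_frac_bounds``, then samples one uniformly at random.  Raises
    :class:`InfeasibleSplitError` naming the label if none exists.
    Deterministic under ``seed``.  Traces of a selected experiment whose own
    label did not select it are dropped (reported, never silently): keeping
    them in training would put that experiment on both sides of the split.

    The per-label draws are coupled through one shared uniform variate:
    each label's selection is still uniform over its own feasible list, but
    labels with identical feasible lists select the same experiments, which
    keeps the test-experiment union (and hence the dropped mass) small.
    """
    labels = np.asarray(labels)
    experiment_ids = np.asarray(experiment_ids)
    if labels.shape != experiment_ids.shape:
        raise ValueError("labels and experiment_ids must have the same length")
    lo, hi = test_frac_bounds
    if not 0 < lo < hi < 1:
        raise ValueError(f"bounds must satisfy 0 < lo < hi < 1, got {test_frac_bounds}")
    if len(np.unique(experiment_ids)) < 2:
        raise ValueError("need >= 2 experiments for an experiment-held-out split")
    rng = default_rng(seed)
    u = float(rng.random())  # one shared variate couples the per-label draws

    uniq_labels, label_idx = np.unique(labels, return_inverse=True)
    uniq_exps, exp_idx = np.unique(experiment_ids, return_inverse=True)
    exp_pos = {e: i for i, e in enumerate(uniq_exps.tolist())}

    selected: dict = {}
    report_labels: dict = {}
    sel_matrix = np.zeros((len(uniq_labels), len(uniq_exps)), dtype=bool)
    for li, lab in enumerate(uniq_labels):
        mask = label_idx == li
        exps, counts = np.unique(experiment_ids[mask], return_counts=True)
        total = counts.sum()
        count_of = dict(zip(exps.tolist(), counts.tolist()))
        feasible = []
        for size in range(1, min(max_subset_size, len(exps)) + 1):
            for combo in combinations(sorted(exps.tolist()), size):
                share = sum(count_of[e] for e in combo) / total
                if lo <= share <= hi:
                    feasible.append(combo)
        if not feasible:
            raise InfeasibleSplitError(
                f"label {lab}: no experiment subset (size <= {max_subset_size}) has a "
                f"trace share in [{lo}, {hi}]")
        choice = feasible[min(int(u * len(feasible)), len(feasible) - 1)]
        selected[lab] = frozenset(choice)
        for e in choice:
            sel_matrix[li, exp_pos[e]] = True
        report_labels[int(lab)] = {
            "selected_experiments": [int(e) for e in choice],
            "test_fraction": float(sum(count_of[e] for e in choice) / total),
            "n_feasible_subsets": len(feasible),
        }

    test_experiments = frozenset().union(*selected.values())
    is_test = sel_matrix[label_idx, exp_idx]
    in_test_exp = np.isin(experiment_ids, sorted(test_experiments))
    dropped = in_test_exp & ~is_test
    train_mask = ~in_test_exp

    train_ids = np.flatnonzero(train_mask)
    test_ids = np.flatnonzero(is_test)
    train_exps = set(np.unique(experiment_ids[train_ids]).tolist())
    report = {
        "per_label": report_labels,
        "test_experiments": sorted(int(e) for e in test_experiments),
        "n_dropped": int(dropped.sum()),
        "experiment_disjoint": train_exps.isdisjoint(test_experiments),
    }
    return DatasetSplit(train_ids=train_ids, val_ids=np.empty(0, np.int64),
                        test_ids=test_ids, constraint_report=report)


def carve_validation(train_ids, labels, frac: float, seed=None):
    """Carve a stratified validation set out of the training indices.

    Per-label sampling keeps validation class proportions matching the
    training set within rounding.  A label with fewer than ``1/frac`` traces
    triggers a warning and contributes at least one validation trace.
    Returns ``(train_ids, val_ids)``.
    """
    if not 0 < frac < 1:
        raise ValueError(f"frac must be in (0, 1), got {frac}")
    train_ids = np.asarray(train_ids, dtype=np.int64)
    labels = np.asarray(labels)
    rng = default_rng(seed)
    val_parts, keep_parts = [], []
    for lab in np.unique(labels[train_ids]):
        ids = train_ids[labels[train_ids] == lab]
        n_val = int(round(frac * len(ids)))
        if len(ids) < 1 / frac:
            warnings.warn(
                f"label {lab} has only {len(ids)} training traces for frac={frac}; "
                "taking at least one for validation")
            n_val = max(n_val, 1)
        chosen = rng.choice(ids, size=n_val, replace=False)
        val_parts.append(np.sort(chosen))
        keep_parts.append(np.setdiff1d(ids, chosen))
    val_ids = np.concatenate(val_parts) if val_parts else np.empty(0, np.int64)
    new_train = np.concatenate(keep_parts) if keep_parts else np.empty(0, np.int64)
    return np.sort(new_train), np.sort(val_ids)


def oversample_balance(train_ids, labels, seed=None) -> np.ndarray:
    """Oversample minority classes so every label reaches the majority count.

    All original indices are retained; minority-class indices are duplicated
    uniformly at random (with replacement) up to the majority count.  The
    result is a multiset of indices.
    """
    train_ids = np.asarray(train_ids, dtype=np.int64)
    labels = np.asarray(labels)
    labs, counts = np.unique(labels[train_ids], return_counts=True)
    missing = np.setdiff1d(np.unique(labels), labs)
    if len(labs) == 0 or missing.size:
        raise ValueError(
            f"every label must have at least one training trace (missing: {missing.tolist()})")
    target = counts.max()
    rng = default_rng(seed)
    extra = []
    for lab, c in zip(labs, counts):
        if c < target:
            ids = train_ids[labels[train_ids] == lab]
            extra.append(rng.choice(ids, size=target - c, replace=True))
    if not extra:
        return train_ids.copy()
    return np.concatenate([train_ids] + extra)


def pad_to_length(samples, L: int, pad_value: float = 0.0,
                  on_overflow: str = "error") -> np.ndarray:
    """Right-pad a trace to length ``L`` with ``pad_value``.

    Over-length input raises unless ``on_overflow='truncate'`` is requested
    explicitly (truncation is opt-in, never silent).
    """
    samples = np.asarray(samples, dtype=float)
    if len(samples) > L:
        if on_overflow == "truncate":
            return samples[:L].copy()
        raise ValueError(
            f"trace length {len(samples)} exceeds L={L}; pass on_overflow='truncate' to allow")
    out = np.full(L, pad_value, dtype=float)
    out[: len(samples)] = samples
    return out


def normalize_to_unfolded(samples, unfolded_level: float) -> np.ndarray:
    """Normalize a current trace by the experiment's unfolded-DNA level."""
    if unfolded_level == 0:
        raise ValueError("unfolded_level must be non-zero")
    return np.asarray(samples, dtype=float) / unfolded_level


# ---------------------------------------------------------------------------
# container I/O


def save_dataset(path, X, labels, experiment_ids, seed=None, spec_params=None) -> None:
    """Write the HDF5 dataset container.

    Datasets: ``traces`` (float32, N x L), ``labels`` (int8),
    ``experiment_ids`` (int32); attributes record L, the generator seed and
    the generator spec parameters (JSON).
    """
    X = np.asarray(X, dtype=np.float32)
    if X.ndim != 2:
        raise ValueError("X must be 2D (n_traces, L)")
    with h5py.File(path, "w") as f:
        f.create_dataset("traces", data=X)
        f.create_dataset("labels", data=np.asarray(labels, dtype=np.int8))
        f.create_dataset("experiment_ids", data=np.asarray(experiment_ids, dtype=np.int32))
        f.attrs["L"] = X.shape[1]
        if seed is not None:
            f.attrs["seed"] = int(seed)
        if spec_params is not None:
            f.attrs["spec_params"] = json.dumps(spec_params)


def load_dataset(path):
    """Read the HDF5 container; returns ``(X, labels, experiment_ids, attrs)``."""
    with h5py.File(path, "r") as f:
        X = f["traces"][...]
        labels = f["labels"][...]
        exps = f["experiment_ids"][...]
        attrs = dict(f.attrs)
    if "spec_params" in attrs:
        attrs["spec_params"] = json.loads(attrs["spec_params"])
    return X, labels, exps, attrs


def write_metadata_csv(path, labels, experiment_ids) -> None:
    """Companion CSV metadata table: trace index, label, experiment_id."""
    df = pd.DataFrame({
        "trace_index": np.arange(len(labels)),
        "label": np.asarray(labels, dtype=int),
        "experiment_id": np.asarray(experiment_ids, dtype=int),
    })
    df.to_csv(path, index=False)


def save_split(path, split: DatasetSplit) -> None:
    """Write a split as JSON: index lists plus the constraint report."""
    payload = {
        "train_ids": split.train_ids.tolist(),
        "val_ids": split.val_ids.tolist(),
        "test_ids": split.test_ids.tolist(),
        "constraint_report": split.constraint_report,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_split(path) -> DatasetSplit:
    d = json.loads(Path(path).read_text())
    return DatasetSplit(train_ids=np.array(d["train_ids"], np.int64),
                        val_ids=np.array(d["val_ids"], np.int64),
                        test_ids=np.array(d["test_ids"], np.int64),
                        constraint_report=d.get("constraint_report", {}))
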