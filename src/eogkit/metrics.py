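"""Confusion matrix (reversed-row convention) and recognition accuracies.

The 5×5 count matrix uses columns for the actual state in the order
(straight, up, down, left, right) and rows for the recognized state in the
*reversed* order (right, left, down, up, straight), so correct predictions
lie on the anti-diagonal: a(6−n),n.  Per-state accuracy is the column-
normalized anti-diagonal count

    Sn = a(6−n),n / Σ_i a(i,n)

and the overall accuracy is the unweighted mean 0.2·ΣSn.  Exports include a
conventional actual×predicted (diagonal) matrix as well, since downstream
tooling usually expects that orientation.
"""

from __future__ import annotations

import time
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .synth import STATES, TraceConfig, generate_dataset

#: Row order of the recognized state (reversed relative to columns).
ROW_ORDER = tuple(reversed(STATES))
#: Column order of the actual state.
COLUMN_ORDER = STATES


@dataclass
class ConfusionMatrix:
    """5×5 count matrix in the reversed-row convention."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(ROW_ORDER), len(COLUMN_ORDER)):
            raise ValueError(f"counts must be {len(ROW_ORDER)}x{len(COLUMN_ORDER)}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_conventional(self) -> pd.DataFrame:
        """Actual (rows) × predicted (columns) matrix with the diagonal correct."""
        conv = self.counts[::-1].T  # flip rows to forward order, then transpose
        return pd.DataFrame(conv, index=list(COLUMN_ORDER),
                            columns=list(COLUMN_ORDER))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(ROW_ORDER),
                            columns=list(COLUMN_ORDER))


def build_confusion(actual: Sequence[str], predicted: Sequence[str]) -> ConfusionMatrix:
    """Count (recognized, actual) pairs into the reversed-row matrix."""
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    if len(actual) == 0:
        raise ValueError("cannot build a confusion matrix from empty inputs")
    counts = np.zeros((len(ROW_ORDER), len(COLUMN_ORDER)), dtype=int)
    row_index = {s: i for i, s in enumerate(ROW_ORDER)}
    col_index = {s: i for i, s in enumerate(COLUMN_ORDER)}
    for a, p in zip(actual, predicted):
        if a not in col_index or p not in row_index:
            raise ValueError(f"invalid label pair ({a!r}, {p!r})")
        counts[row_index[p], col_index[a]] += 1
    return ConfusionMatrix(counts)


def state_accuracy(m: ConfusionMatrix, n: int) -> float:
    """Correct-recognition rate Sn of the n-th actual state (n = 1..5)."""
    if not 1 <= n <= 5:
        raise ValueError("state index n must lie in 1..5")
    column = m.counts[:, n - 1]
    denom = column.sum()
    if denom == 0:
        raise ValueError(f"no trials for state {COLUMN_ORDER[n - 1]!r} "
                         f"(column {n} sums to zero)")
    return float(column[5 - n]) / float(denom)


def overall_accuracy(m: ConfusionMatrix) -> float:
    """Unweighted mean of the five per-state accuracies."""
    return float(np.mean([state_accuracy(m, n) for n in range(1, 6)]))


def per_state_accuracies(m: ConfusionMatrix) -> Dict[str, float]:
    return {COLUMN_ORDER[n - 1]: state_accuracy(m, n) for n in range(1, 6)}


def run_benchmark(n_trials: int = 600,
                  trace_config: Optional[TraceConfig] = None,
                  pipeline_config=None,
                  split_fraction: float = 0.5,
                  seed: int = 0) -> dict:
    """Full train/test protocol on a freshly generated synthetic dataset.

    Generates ``n_trials`` balanced trials, runs the processing pipeline on
    each, performs a stratified ``split_fraction`` train/test split, trains
    the one-against-one SVM on the training half and evaluates on the test
    half.  Deterministic for a fixed seed.  Returns a JSON-serializable
    report with the confusion matrix (both conventions), per-state and
    overall accuracies, split sizes and per-stage timings.
    """
    from .classifier import predict, train
    from .pipeline import PipelineConfig, process_trace

    if trace_config is None:
        trace_config = TraceConfig()
    if pipeline_config is None:
        pipeline_config = PipelineConfig()
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must lie in (0, 1)")

    timings: Dict[str, float] = {}
    t0 = time.perf_counter()
    traces, manifest = generate_dataset(n_trials, trace_config, seed)
    timings["generate_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    features = np.vstack([process_trace(tr, pipeline_config).features
                          for tr in traces])
    timings["process_s"] = time.perf_counter() - t0
    labels = manifest["state"].to_numpy()

    idx_train, idx_test = train_test_split(
        np.arange(n_trials), train_size=split_fraction, stratify=labels,
        random_state=seed % (2 ** 32))
    idx_train.sort()
    idx_test.sort()
    for name, idx in (("training", idx_train), ("test", idx_test)):
        present = set(labels[idx])
        if present != set(STATES):
            raise ValueError(f"{name} split is missing states "
                             f"{sorted(set(STATES) - present)}")

    t0 = time.perf_counter()
    model = train(features[idx_train], labels[idx_train],
                  sigma=pipeline_config.classifier_sigma,
                  penalty=pipeline_config.classifier_penalty,
                  epsilon=pipeline_config.classifier_epsilon, seed=seed)
    timings["train_s"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    predicted = predict(model, features[idx_test])
    timings["classify_s"] = time.perf_counter() - t0

    confusion = build_confusion(list(labels[idx_test]), predicted)
    report = {
        "seed": seed,
        "n_trials": n_trials,
        "n_train": int(len(idx_train)),
        "n_test": int(len(idx_test)),
        "split_fraction": split_fraction,
        "electrode_mode": trace_config.electrode_mode,
        "accuracy": overall_accuracy(confusion),
        "per_state": per_state_accuracies(confusion),
        "confusion_reversed_rows": confusion.counts.tolist(),
        "confusion_conventional": confusion.to_conventional().values.tolist(),
        "timings": timings,
    }
    return report
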