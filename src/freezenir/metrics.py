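"""Confusion tables with a no-match column; per-class F1 and total accuracy.

The F1 convention mirrors how published fresh/frozen confusion tables tally:
precision for class c uses only the predicted-class columns (a rejection is
never a prediction *of* any class), while recall counts rejected in-class
samples as misses (row totals include the no-match column). Total accuracy
is the diagonal over all samples, no-match counting as incorrect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from freezenir.spectra_io import CLASSES, NO_MATCH
from freezenir.simca import ClassificationResult


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero at a fixed number of decimals (report style)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionTable:
    """True class (rows) x predicted class + no-match (columns) counts."""

    classes: list[str]
    counts: np.ndarray  # (C, C+1) nonnegative integers, last column = no-match

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        C = len(self.classes)
        if self.counts.shape != (C, C + 1):
            raise ValueError(
                f"counts must be {C}x{C + 1} (last column is no-match)"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_frame(self):
        import pandas as pd

        cols = [f"pred_{c}" for c in self.classes] + [NO_MATCH]
        return pd.DataFrame(self.counts, index=self.classes, columns=cols)


def build_confusion(
    true_labels: list[str], result: ClassificationResult | list[str],
    classes: list[str] | None = None,
) -> ConfusionTable:
    """Tally assignments (a ClassificationResult or a plain label list)."""
    assigned = result.assigned if isinstance(result, ClassificationResult) else list(result)
    if len(true_labels) != len(assigned):
        raise ValueError("true and predicted label lists differ in length")
    if classes is None:
        classes = [c for c in CLASSES if c in set(true_labels) | set(assigned)]
    vocab = set(classes) | {NO_MATCH}
    for lab in true_labels:
        if lab not in set(classes):
            raise ValueError(f"unknown true label {lab!r}")
    for lab in assigned:
        if lab not in vocab:
            raise ValueError(f"unknown predicted label {lab!r}")
    C = len(classes)
    counts = np.zeros((C, C + 1), dtype=int)
    col = {c: j for j, c in enumerate(classes)}
    col[NO_MATCH] = C
    for t, p in zip(true_labels, assigned):
        counts[classes.index(t), col[p]] += 1
    return ConfusionTable(classes=list(classes), counts=counts)


def f1_per_class(table: ConfusionTable, rounded: bool = False) -> np.ndarray:
    """Per-class F1 in percent.

    precision_c = diagonal / predicted-column sum (no-match column excluded);
    recall_c = diagonal / row total (no-match column included). Classes with
    an undefined precision or recall get F1 = 0 with a warning.
    """
    C = len(table.classes)
    diag = np.diag(table.counts[:, :C]).astype(float)
    col_sums = table.counts[:, :C].sum(axis=0).astype(float)
    row_sums = table.counts.sum(axis=1).astype(float)
    f1 = np.zeros(C)
    for c in range(C):
        if col_sums[c] == 0 or row_sums[c] == 0 or diag[c] == 0:
            if diag[c] == 0:
                warnings.warn(
                    f"F1 undefined or zero for class {table.classes[c]!r}; "
                    "reporting 0",
                    stacklevel=2,
                )
            f1[c] = 0.0
            continue
        precision = diag[c] / col_sums[c]
        recall = diag[c] / row_sums[c]
        f1[c] = 200.0 * precision * recall / (precision + recall)
    if rounded:
        return np.array([round_half_up(v, 1) for v in f1])
    return f1


def total_accuracy(table: ConfusionTable) -> float:
    """Percent of samples assigned to their true class (no-match = wrong)."""
    if table.n_total == 0:
        raise ValueError("empty confusion table")
    C = len(table.classes)
    return 100.0 * float(np.diag(table.counts[:, :C]).sum()) / table.n_total
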