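"""Confusion matrices and accuracy statistics (UA, PA, OA).

Accuracy conventions follow the accuracy-assessment tables this package is
designed to reproduce, in which user's accuracy is computed on the
OBSERVED-class row and producer's accuracy on the PREDICTED-class column:

    UA_c = 100 * counts[c][c] / sum_p counts[c][p]   (row basis)
    PA_c = 100 * counts[c][c] / sum_o counts[o][c]   (column basis)
    OA   = 100 * trace / total

Note this is the reverse of the most common remote-sensing convention
(where UA is the column-basis statistic); the row basis is used here
deliberately and consistently. A class absent from the denominator yields
NaN. The tree risk is the misclassification proportion 1 - OA/100 with
binomial standard error sqrt(risk*(1-risk)/N).

Reference confusion matrices from a published 311-parcel multitemporal
crop-classification accuracy assessment are shipped as package data (see
``load_reference_matrix``) so the printed statistics can be recomputed
from counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from cropclass.cart import RiskEstimate

#: Names of the shipped reference matrices: training vs testing phase,
#: per cropping system (ato/suc/wic) or over all individual crops.
REFERENCE_MATRICES = (
    "training_ato", "training_suc", "training_wic", "training_crop",
    "testing_ato", "testing_suc", "testing_wic", "testing_crop",
)


@dataclass
class ConfusionMatrix:
    """Square counts table, rows = observed class, columns = predicted."""

    classes: list[str]
    counts: np.ndarray  # shape (k, k), non-negative integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {k} classes"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def observed_totals(self) -> dict[str, int]:
        return dict(zip(self.classes, self.counts.sum(axis=1).tolist()))

    def predicted_totals(self) -> dict[str, int]:
        return dict(zip(self.classes, self.counts.sum(axis=0).tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def reorder(self, classes: Sequence[str]) -> "ConfusionMatrix":
        if sorted(classes) != sorted(self.classes):
            raise ValueError("reorder must permute the existing classes")
        idx = [self.classes.index(c) for c in classes]
        return ConfusionMatrix(list(classes), self.counts[np.ix_(idx, idx)])


def confusion(
    observed: Sequence[str],
    predicted: Sequence[str],
    classes: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Cross-tabulate observed vs predicted labels.

    The class list defaults to the sorted union of both label sets.
    """
    observed = list(observed)
    predicted = list(predicted)
    if len(observed) != len(predicted):
        raise ValueError(
            f"length mismatch: {len(observed)} observed vs {len(predicted)} predicted"
        )
    if classes is None:
        classes = sorted(set(observed) | set(predicted))
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for o, p in zip(observed, predicted):
        counts[index[o], index[p]] += 1
    return ConfusionMatrix(classes, counts)


def accuracy_stats(matrix: ConfusionMatrix) -> tuple[dict, dict, float]:
    """Per-class UA (row basis) and PA (column basis), and overall accuracy.

    All three are percentages; classes with a zero denominator get NaN.
    """
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(matrix.counts).astype(float)
    row = matrix.counts.sum(axis=1).astype(float)
    col = matrix.counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ua = np.where(row > 0, 100.0 * diag / row, np.nan)
        pa = np.where(col > 0, 100.0 * diag / col, np.nan)
    oa = 100.0 * diag.sum() / matrix.total
    return (
        dict(zip(matrix.classes, ua.tolist())),
        dict(zip(matrix.classes, pa.tolist())),
        float(oa),
    )


def risk_from_matrix(matrix: ConfusionMatrix) -> RiskEstimate:
    """Resubstitution risk (misclassification proportion) with binomial SE."""
    if matrix.total == 0:
        raise ValueError("empty confusion matrix")
    _, _, oa = accuracy_stats(matrix)
    risk = 1.0 - oa / 100.0
    se = float(np.sqrt(risk * (1.0 - risk) / matrix.total))
    return RiskEstimate(float(risk), se, "resubstitution", matrix.total)


def report(matrix: ConfusionMatrix) -> str:
    """Human-readable accuracy report (counts + UA/PA/OA + risk)."""
    ua, pa, oa = accuracy_stats(matrix)
    risk = risk_from_matrix(matrix)
    frame = matrix.to_frame()
    frame["Obs.Parcels"] = matrix.counts.sum(axis=1)
    frame["UA(%)"] = [f"{ua[c]:.1f}" if np.isfinite(ua[c]) else "-" for c in matrix.classes]
    lines = [frame.to_string()]
    pa_line = "PA(%)      " + "  ".join(
        f"{c}:{pa[c]:.1f}" if np.isfinite(pa[c]) else f"{c}:-" for c in matrix.classes
    )
    lines.append(pa_line)
    lines.append(f"OA(%) {oa:.1f}   risk {risk.risk:.2f}±{risk.se:.2f}  (N={matrix.total})")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Shipped reference tables


def _read_matrix_tsv(text: str) -> ConfusionMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    classes = header[1:]
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        if parts[0] != classes[len(rows)]:
            raise ValueError(f"row order {parts[0]!r} != column order")
        rows.append([int(x) for x in parts[1:]])
    return ConfusionMatrix(classes, np.array(rows))


def load_reference_matrix(name: str) -> ConfusionMatrix:
    """Load one of the shipped published confusion matrices by name."""
    if name not in REFERENCE_MATRICES:
        raise KeyError(f"unknown reference matrix {name!r}; "
                       f"choose from {REFERENCE_MATRICES}")
    text = resources.files("cropclass").joinpath("data", f"{name}.tsv").read_text("utf-8")
    return _read_matrix_tsv(text)


def read_confusion(path: str | Path) -> ConfusionMatrix:
    """Read a tab-delimited confusion matrix file (same layout as shipped data)."""
    return _read_matrix_tsv(Path(path).read_text(encoding="utf-8"))
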