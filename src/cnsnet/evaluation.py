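"""Partition-quality metrics against a ground truth.

All three metrics operate on the R×K contingency table n_rk = |U_r ∩ C_k|
between the true partition U and the detected partition C, and are
invariant to community relabeling and node order.

* NMI: 2·I(U;C) / (H(U) + H(C)) — mutual information normalised by the
  arithmetic mean of the two partition entropies (log base cancels).
* F-Measure: for each true community, the best harmonic mean of
  precision n_rk/|C_k| and recall n_rk/|U_r| over detected communities,
  weighted by |U_r|/|V|.
* Accuracy: fraction of nodes correctly placed under the optimal
  one-to-one matching between detected and true communities
  (maximum-weight assignment on the contingency table; surplus
  communities on either side stay unmatched).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .graph_model import Partition

logger = logging.getLogger("cnsnet")

__all__ = ["EvaluationReport", "contingency_table", "nmi", "f_measure", "accuracy", "evaluate"]


def contingency_table(truth: Partition, detected: Partition) -> pd.DataFrame:
    """R×K table of |U_r ∩ C_k|; rows = true communities, cols = detected."""
    nodes = sorted(truth.assignment)
    if sorted(detected.assignment) != nodes:
        raise ValueError("partitions cover different node sets")
    t = pd.Series({n: truth[n] for n in nodes}, name="truth")
    d = pd.Series({n: detected[n] for n in nodes}, name="detected")
    return pd.crosstab(t, d)


def nmi(truth: Partition, detected: Partition) -> float:
    """Normalized mutual information, arithmetic-mean normalisation."""
    table = contingency_table(truth, detected).to_numpy(dtype=float)
    n = table.sum()
    a = table.sum(axis=1)  # |U_r|
    b = table.sum(axis=0)  # |C_k|

    def entropy(counts: np.ndarray) -> float:
        p = counts / n
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hu, hc = entropy(a), entropy(b)
    if hu == 0.0 and hc == 0.0:
        # both partitions trivial; with a shared node set they coincide
        logger.debug("both partitions have zero entropy; NMI defined as 1")
        return 1.0
    mi = 0.0
    for r in range(table.shape[0]):
        for k in range(table.shape[1]):
            if table[r, k] > 0:
                mi += (table[r, k] / n) * np.log(n * table[r, k] / (a[r] * b[k]))
    return float(2.0 * mi / (hu + hc))


def f_measure(truth: Partition, detected: Partition) -> float:
    """|U_r|/|V|-weighted best F1 of each true community over detected ones."""
    table = contingency_table(truth, detected).to_numpy(dtype=float)
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    total = 0.0
    for r in range(table.shape[0]):
        best = 0.0
        for k in range(table.shape[1]):
            if table[r, k] == 0:
                continue
            precision = table[r, k] / b[k]
            recall = table[r, k] / a[r]
            best = max(best, 2 * precision * recall / (precision + recall))
        total += (a[r] / n) * best
    return float(total)


def accuracy(truth: Partition, detected: Partition) -> float:
    """Correctly clustered fraction under optimal one-to-one matching."""
    table = contingency_table(truth, detected).to_numpy(dtype=float)
    rows, cols = linear_sum_assignment(table, maximize=True)
    return float(table[rows, cols].sum() / table.sum())


@dataclass(frozen=True)
class EvaluationReport:
    nmi: float
    f_measure: float
    accuracy: float
    contingency: pd.DataFrame

    def as_dict(self) -> dict:
        return {
            "nmi": self.nmi,
            "f_measure": self.f_measure,
            "accuracy": self.accuracy,
            "contingency": self.contingency.to_dict(),
        }


def evaluate(truth: Partition, detected: Partition) -> EvaluationReport:
    """All three scores plus the contingency table."""
    return EvaluationReport(
        nmi=nmi(truth, detected),
        f_measure=f_measure(truth, detected),
        accuracy=accuracy(truth, detected),
        contingency=contingency_table(truth, detected),
    )
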