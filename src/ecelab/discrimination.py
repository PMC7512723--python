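"""Discrimination and calibration diagnostics: ROC/AUC and reliability tables.

These are the classical views the ECE plot is designed to complement: the
ROC curve and its AUC measure discrimination (rank separation of the two
classes, invariant under any strictly increasing transform of the scores),
while the reliability table compares stated posterior probabilities with
the empirical frequency of θ1 inside posterior bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .bayes import LRSet, PriorSpec, posterior_probability

__all__ = ["ROCCurve", "ReliabilityTable", "roc", "auc", "reliability_table"]


@dataclass(frozen=True)
class ROCCurve:
    """Operating points swept over all score thresholds.

    ``fa`` is the false-acceptance rate P(α1|θ2) (x-axis), ``ta`` the
    true-acceptance rate P(α1|θ1); θ1 is the positive class.  ``auc`` is
    the Mann–Whitney area with midrank tie handling.
    """

    fa: np.ndarray
    ta: np.ndarray
    auc: float


def auc(lr_set: LRSet) -> float:
    """Area under the ROC curve via the Mann–Whitney U statistic.

    Midranks handle ties: AUC = (R1 − N1(N1+1)/2) / (N1·N2) where R1 is the
    rank sum of the θ1 scores among all scores.  Identical to the trapezoid
    area under the threshold-swept curve.
    """
    lr_set.require_both_classes()
    ranks = rankdata(lr_set.log_lr)  # midranks; ±inf rank fine
    r1 = float(ranks[lr_set.label == 1].sum())
    n1, n2 = lr_set.n1, lr_set.n2
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n2)


def roc(lr_set: LRSet) -> ROCCurve:
    """ROC curve of the LR set (all thresholds, no point dropped)."""
    lr_set.require_both_classes()
    fa, ta, _ = _sk_roc_curve(
        lr_set.label, lr_set.log_lr, drop_intermediate=False
    )
    return ROCCurve(fa, ta, auc(lr_set))


@dataclass(frozen=True)
class ReliabilityTable:
    """Per-bin comparison of stated posteriors with observed θ1 frequency.

    Bins partition [0, 1] with equal width.  ``mean_predicted`` and
    ``frequency`` are NaN in empty bins (flagged by ``count`` = 0, never
    fabricated); counts sum to the number of trials.
    """

    bin_left: np.ndarray
    bin_right: np.ndarray
    mean_predicted: np.ndarray
    frequency: np.ndarray
    count: np.ndarray
    prior: PriorSpec = PriorSpec(0.5)
    scheme: str = "equal-width"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_left,
                "bin_right": self.bin_right,
                "mean_predicted": self.mean_predicted,
                "frequency": self.frequency,
                "count": self.count,
            }
        )


def reliability_table(
    lr_set: LRSet, prior: PriorSpec, n_bins: int = 10
) -> ReliabilityTable:
    """Bin the posteriors implied by the LRs at ``prior`` and tabulate
    per-bin mean prediction against empirical θ1 frequency.

    A well-calibrated set puts both numbers on the diagonal.  The prior is
    a parameter: calibration is typically inspected at the empirical prior
    N1/(N1+N2) of the evaluation set, but any prior is valid.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    post = np.asarray(posterior_probability(lr_set.log_lr, prior))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(post, edges[1:-1]), 0, n_bins - 1)
    count = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        mean_pred = np.bincount(idx, weights=post, minlength=n_bins) / count
        freq = (
            np.bincount(idx, weights=(lr_set.label == 1), minlength=n_bins)
            / count
        )
    return ReliabilityTable(
        edges[:-1], edges[1:], mean_pred, freq, count, prior
    )
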