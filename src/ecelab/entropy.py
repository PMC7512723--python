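"""Proper scoring rules, entropies and the empirical cross-entropy (ECE).

ECE is the prior-weighted mean logarithmic score of the posteriors implied
by a set of likelihood ratios at a given prior, in bits:

    ECE(p1) = (p1/N1) Σ_{θ1} log2(1 + 1/(LR·O1))
            + (p2/N2) Σ_{θ2} log2(1 + LR·O1),      O1 = p1/p2.

It equals the prior entropy for a neutral system (LR = 1 everywhere) and is
smaller the more informative and better calibrated the LRs are.  ECE at
prior log-odds 0 is the log-likelihood-ratio cost Cllr.

All entropies are reported in bits; log-LRs are natural-log internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .bayes import LN2, LRSet, PriorSpec

__all__ = [
    "InfiniteECEWarning",
    "ECECurve",
    "default_prior_grid",
    "logarithmic_score",
    "mean_logarithmic_score",
    "prior_entropy",
    "ece",
    "ece_curve",
    "cllr",
]


class InfiniteECEWarning(UserWarning):
    """An infinitely wrong LR (certain and incorrect) made ECE infinite.

    Carries the indices of the offending trials in ``trial_indices``.
    """

    def __init__(self, message: str, trial_indices):
        super().__init__(message)
        self.trial_indices = list(trial_indices)


def default_prior_grid() -> np.ndarray:
    """Default ECE-plot grid: prior log10-odds from −2.5 to 2.5, 501 points."""
    return np.linspace(-2.5, 2.5, 501)


def logarithmic_score(posterior_p1, label):
    """Logarithmic scoring rule in bits.

    −log2 of the probability stated for the class that turned out true:
    −log2(p) when θ1 is true, −log2(1−p) when θ2 is true.  Zero iff the
    posterior is certain and correct; +inf iff certain and wrong (a legal
    output, not an error).  Vectorized.
    """
    p = np.asarray(posterior_p1, dtype=float)
    lab = np.asarray(label)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):
        out = np.where(lab == 1, -np.log2(p), -np.log2(1.0 - p))
    return out if out.ndim else float(out)


def _class_terms(lr_set: LRSet, prior: PriorSpec):
    """Per-trial log scores in bits for each class at the given prior.

    θ1 trials score log2(1 + 1/(LR·O1)); θ2 trials score log2(1 + LR·O1).
    Computed with logaddexp so ±inf log-LRs yield the exact 0/+inf limits.
    """
    lo = prior.log_odds
    t1 = np.logaddexp(0.0, -(lr_set.llr1 + lo)) / LN2
    t2 = np.logaddexp(0.0, lr_set.llr2 + lo) / LN2
    return t1, t2


def mean_logarithmic_score(lr_set: LRSet, prior: PriorSpec):
    """Per-class mean logarithmic scores and their sum (LS), in bits.

    Posteriors are formed from the log-LRs at ``prior``.  Returns
    ``(mean_theta1, mean_theta2, ls)`` with ``ls = mean_theta1 +
    mean_theta2``; the prior-weighted combination ``p1·mean_theta1 +
    p2·mean_theta2`` is exactly :func:`ece` at the same prior.
    """
    lr_set.require_both_classes()
    t1, t2 = _class_terms(lr_set, prior)
    m1, m2 = float(t1.mean()), float(t2.mean())
    return m1, m2, m1 + m2


def prior_entropy(prior: PriorSpec) -> float:
    """Binary entropy of the prior in bits: −p1·log2 p1 − p2·log2 p2."""
    p1, p2 = prior.p1, prior.p2
    return float(-p1 * np.log2(p1) - p2 * np.log2(p2))


def ece(lr_set: LRSet, prior: PriorSpec) -> float:
    """Empirical cross-entropy of the LR set at one prior, in bits.

    A θ1 trial with log-LR = +inf contributes zero; a θ1 trial with
    log-LR = −inf (or a θ2 trial with +inf) makes the ECE infinite, which
    is returned with an :class:`InfiniteECEWarning` naming the trials —
    a wrongly-oriented certain LR is a diagnostic, not a crash.
    """
    lr_set.require_both_classes()
    t1, t2 = _class_terms(lr_set, prior)
    value = prior.p1 * float(t1.mean()) + prior.p2 * float(t2.mean())
    if np.isinf(value):
        bad = np.flatnonzero(
            ((lr_set.label == 1) & np.isneginf(lr_set.log_lr))
            | ((lr_set.label == 0) & np.isposinf(lr_set.log_lr))
        )
        warnings.warn(
            InfiniteECEWarning(
                f"ECE is infinite: {bad.size} trial(s) carry a certain LR "
                f"oriented against their true class (indices {bad.tolist()})",
                bad,
            ),
            stacklevel=2,
        )
    return value


def cllr(lr_set: LRSet) -> float:
    """Log-likelihood-ratio cost: ECE at prior log-odds 0 (prior 0.5)."""
    return ece(lr_set, PriorSpec(0.5))


@dataclass
class ECECurve:
    """ECE-plot data: the three curves over a grid of prior log10-odds.

    ``ece`` is the system curve; ``ece_min`` the PAV-calibrated reference
    (``None`` until filled, see :func:`ecelab.pav.ece_decomposition`);
    ``neutral`` the prior entropy (the LR=1-always system).  The Cllr
    summaries are the curve values at prior log10-odds exactly 0.
    """

    prior_log10_odds: np.ndarray
    ece: np.ndarray
    neutral: np.ndarray
    ece_min: np.ndarray | None = None
    name: str = ""

    def _at_zero(self, arr: np.ndarray) -> float:
        idx = int(np.argmin(np.abs(self.prior_log10_odds)))
        if self.prior_log10_odds[idx] != 0.0:
            raise ValueError("grid does not contain prior log10-odds 0")
        return float(arr[idx])

    @property
    def summary_cllr(self) -> float:
        return self._at_zero(self.ece)

    @property
    def summary_cllr_min(self) -> float:
        if self.ece_min is None:
            raise ValueError("ece_min not populated; run the PAV decomposition")
        return self._at_zero(self.ece_min)

    @property
    def summary_cllr_cal(self) -> float:
        return max(self.summary_cllr - self.summary_cllr_min, 0.0)

    @property
    def ece_cal(self) -> np.ndarray:
        """Calibration-loss curve, clipped at zero against float noise."""
        if self.ece_min is None:
            raise ValueError("ece_min not populated; run the PAV decomposition")
        return np.maximum(self.ece - self.ece_min, 0.0)


def _normalized_grid(grid) -> np.ndarray:
    g = np.asarray(default_prior_grid() if grid is None else grid, dtype=float)
    if g.size == 0:
        raise ValueError("prior grid must be nonempty")
    if np.any(np.diff(g) < 0):
        raise ValueError("prior grid must be sorted ascending")
    if not np.any(g == 0.0):  # Cllr summaries live at log-odds 0
        g = np.sort(np.append(g, 0.0))
    return g


def ece_curve(lr_set: LRSet, grid=None, with_pav: bool = True) -> ECECurve:
    """Evaluate the ECE plot's data over a grid of prior log10-odds.

    The grid defaults to :func:`default_prior_grid`; 0 is inserted if
    absent.  With ``with_pav`` (default) the PAV-calibrated reference
    curve ``ece_min`` is filled in as well.
    """
    g = _normalized_grid(grid)
    priors = [PriorSpec.from_log10_odds(lo) for lo in g]
    with warnings.catch_warnings():
        warnings.simplefilter("once", InfiniteECEWarning)
        vals = np.array([ece(lr_set, p) for p in priors])
    neutral = np.array([prior_entropy(p) for p in priors])
    curve = ECECurve(g, vals, neutral, name=lr_set.name)
    if with_pav:
        from .pav import pav_calibrated_set  # deferred: pav imports this module

        cal = pav_calibrated_set(lr_set)
        curve.ece_min = np.array([ece(cal, p) for p in priors])
    return curve
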