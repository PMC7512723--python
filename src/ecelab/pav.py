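"""Pool-adjacent-violators calibration and the ECE decomposition.

The PAV algorithm yields the monotone (isotonic) transform of the scores
whose posteriors achieve the best possible value of every proper scoring
rule on the evaluation set.  Feeding these optimally calibrated posteriors
back through the ECE machinery gives the discrimination-loss curve ECEmin;
the remainder ECEcal = ECE − ECEmin is the calibration loss:

    ECE = ECEmin + ECEcal,        Cllr = Cllrmin + Cllrcal (at prior 0.5).

ECEmin depends only on the rank order of the scores, so any strictly
increasing transform of the LRs leaves it (and ROC/AUC) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import LRSet, PriorSpec
from .entropy import ece

__all__ = [
    "IsotonicMap",
    "pav_fit",
    "apply_pav_as_lrs",
    "pav_calibrated_set",
    "ECEDecomposition",
    "ece_decomposition",
    "cllr_decomposition",
]


@dataclass(frozen=True)
class IsotonicMap:
    """A fitted PAV step function from scores to calibrated posteriors.

    ``breakpoints`` are the sorted distinct training scores; ``block_values``
    the non-decreasing fitted posterior at each (values repeat within a
    pooled block).  Each pooled block's value is the label mean of the
    trials it contains, so a block is never assigned probability 1 unless
    it holds only θ1 trials (nor 0 unless only θ2) — which keeps the
    LR-converted output finite wherever classes mix.

    ``empirical_prior_odds`` (N1/N2 of the fit set) converts calibrated
    posteriors back to likelihood ratios.
    """

    breakpoints: np.ndarray
    block_values: np.ndarray
    empirical_prior_odds: float

    def posterior(self, scores) -> np.ndarray:
        """Evaluate the step function; out-of-range scores clamp to the
        extreme blocks, scores between breakpoints take the left block."""
        s = np.atleast_1d(np.asarray(scores, dtype=float))
        idx = np.searchsorted(self.breakpoints, s, side="right") - 1
        idx = np.clip(idx, 0, self.breakpoints.size - 1)
        return self.block_values[idx]


def _pav_weighted(y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least-squares isotonic fit by pool-adjacent-violators.

    Classic stack formulation: maintain blocks of (weighted mean, weight)
    and merge backwards while the means decrease.
    """
    means = []
    weights = []
    counts = []
    for yi, wi in zip(y, w):
        cm, cw, cn = float(yi), float(wi), 1
        while means and means[-1] >= cm:
            pm, pw = means.pop(), weights.pop()
            cm = (pm * pw + cm * cw) / (pw + cw)
            cw += pw
            cn += counts.pop()
        means.append(cm)
        weights.append(cw)
        counts.append(cn)
    return np.repeat(means, counts)


def pav_fit(scores, labels) -> IsotonicMap:
    """Fit the PAV-calibrated posterior map of labels on score order.

    Trials with identical scores are pooled into one candidate block before
    fitting, so the result is a function of the score and deterministic
    regardless of input order.  Scores may include ±inf (they sort to the
    ends); both classes must be present.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels)
    if np.isnan(s).any():
        raise ValueError("NaN scores cannot be calibrated")
    n1 = int(np.sum(lab == 1))
    n2 = int(np.sum(lab == 0))
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"PAV requires trials of both classes (N1={n1}, N2={n2})"
        )
    uniq, inv = np.unique(s, return_inverse=True)
    w = np.bincount(inv, minlength=uniq.size).astype(float)
    y = np.bincount(inv, weights=(lab == 1).astype(float)) / w
    fitted = _pav_weighted(y, w)
    return IsotonicMap(uniq, fitted, n1 / n2)


def apply_pav_as_lrs(iso: IsotonicMap, scores) -> np.ndarray:
    """Convert PAV posteriors to calibrated natural-log LRs.

    The in-sample posteriors are posteriors at the empirical prior of the
    fit set, so log LRcal = logit(pcal) − log(N1/N2).  Posteriors of exactly
    0 or 1 (pure extreme blocks) map to ∓inf / ±inf log-LRs.
    """
    p = iso.posterior(scores)
    with np.errstate(divide="ignore"):
        logit = np.log(p) - np.log1p(-p)
    return logit - np.log(iso.empirical_prior_odds)


def pav_calibrated_set(lr_set: LRSet) -> LRSet:
    """The LR set recalibrated by its own in-sample PAV transform (Pcal)."""
    iso = pav_fit(lr_set.log_lr, lr_set.label)
    return LRSet(
        apply_pav_as_lrs(iso, lr_set.log_lr),
        lr_set.label,
        name=f"{lr_set.name}|pav" if lr_set.name else "pav",
    )


@dataclass(frozen=True)
class ECEDecomposition:
    """ECE split into discrimination (``ece_min``) and calibration
    (``ece_cal``) losses; scalars or per-grid-point arrays, in bits.

    ``ece_cal`` is clipped at zero; ``ece_cal_raw`` keeps the raw
    difference for diagnostics (it can be ~−1e-12 from float noise).
    """

    ece: np.ndarray | float
    ece_min: np.ndarray | float
    ece_cal: np.ndarray | float
    ece_cal_raw: np.ndarray | float


def ece_decomposition(lr_set: LRSet, prior) -> ECEDecomposition:
    """Decompose ECE at a prior (or sequence of priors) via the PAV reference.

    The PAV is fitted once on the log-LRs with the set's labels; ECEmin at
    each prior is the ECE of the PAV-recalibrated LRs, and
    ECEcal = ECE − ECEmin.
    """
    cal = pav_calibrated_set(lr_set)
    priors = [prior] if isinstance(prior, PriorSpec) else list(prior)
    e = np.array([ece(lr_set, p) for p in priors])
    emin = np.array([ece(cal, p) for p in priors])
    raw = e - emin
    ecal = np.maximum(raw, 0.0)
    if isinstance(prior, PriorSpec):
        return ECEDecomposition(float(e[0]), float(emin[0]),
                                float(ecal[0]), float(raw[0]))
    return ECEDecomposition(e, emin, ecal, raw)


def cllr_decomposition(lr_set: LRSet):
    """(Cllr, Cllr_min, Cllr_cal): the decomposition at prior 0.5."""
    d = ece_decomposition(lr_set, PriorSpec(0.5))
    return d.ece, d.ece_min, d.ece_cal
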