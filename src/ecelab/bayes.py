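"""Bayesian decision theory for likelihood-ratio classifiers.

The universal input everywhere in :mod:`ecelab` is a scored trial set: one
log-likelihood-ratio per comparison together with a binary ground-truth
label.  The label encodes the "same-source"/"target" hypothesis θ1 as 1 and
the "different-source"/"non-target" hypothesis θ2 as 0.

Log-LRs are stored in natural-log units internally; the base-10 convention
used at the file surface (and on ECE-plot axes) is converted exactly once,
in :func:`natural_from_log10` / :func:`log10_from_natural`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "LN10",
    "LN2",
    "LRSet",
    "PriorSpec",
    "CostModel",
    "CostCurve",
    "DomainError",
    "DegenerateDataError",
    "DegenerateThresholdError",
    "natural_from_log10",
    "log10_from_natural",
    "probability_to_odds",
    "odds_to_probability",
    "posterior_probability",
    "bayes_threshold",
    "decide",
    "empirical_expected_cost",
    "cost_vs_threshold_curve",
]

LN10 = float(np.log(10.0))
LN2 = float(np.log(2.0))


class DomainError(ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class DegenerateDataError(ValueError):
    """The trial set cannot support the requested operation (e.g. one class)."""


class DegenerateThresholdError(ValueError):
    """The cost model admits no finite Bayes threshold."""


def natural_from_log10(x):
    """Convert base-10 log values to natural-log units."""
    return np.asarray(x, dtype=float) * LN10


def log10_from_natural(x):
    """Convert natural-log values to base-10 log units."""
    return np.asarray(x, dtype=float) / LN10


@dataclass(frozen=True)
class LRSet:
    """A set of scored trials: natural-log LR values with ground-truth labels.

    Parameters
    ----------
    log_lr:
        Natural-log likelihood ratios, one per trial.  Values may be finite
        or exactly ±inf (oracle-like trials); NaN is rejected.
    label:
        Per-trial class indicator: 1 for θ1 ("same source"), 0 for θ2.
    name:
        Optional free-text identifier carried through reports.
    """

    log_lr: np.ndarray
    label: np.ndarray
    name: str = ""

    def __post_init__(self):
        llr = np.atleast_1d(np.asarray(self.log_lr, dtype=float))
        lab = np.atleast_1d(np.asarray(self.label))
        if llr.shape != lab.shape or llr.ndim != 1:
            raise ValueError(
                f"log_lr and label must be equal-length 1-D arrays, got shapes "
                f"{llr.shape} and {lab.shape}"
            )
        if llr.size == 0:
            raise ValueError("an LRSet must contain at least one trial")
        if np.isnan(llr).any():
            bad = np.flatnonzero(np.isnan(llr))
            raise ValueError(f"NaN log-LR at trial indices {bad.tolist()}")
        if not np.isin(lab, (0, 1)).all():
            raise ValueError("labels must be 0 (θ2) or 1 (θ1)")
        object.__setattr__(self, "log_lr", llr)
        object.__setattr__(self, "label", lab.astype(np.int8))

    def __len__(self) -> int:
        return self.log_lr.size

    @property
    def n1(self) -> int:
        """Number of θ1 (same-source / target) trials."""
        return int(self.label.sum())

    @property
    def n2(self) -> int:
        """Number of θ2 (different-source / non-target) trials."""
        return int(len(self) - self.n1)

    @property
    def llr1(self) -> np.ndarray:
        """Log-LRs of the θ1 trials."""
        return self.log_lr[self.label == 1]

    @property
    def llr2(self) -> np.ndarray:
        """Log-LRs of the θ2 trials."""
        return self.log_lr[self.label == 0]

    def require_both_classes(self) -> None:
        """Raise :class:`DegenerateDataError` unless N1 ≥ 1 and N2 ≥ 1."""
        if self.n1 == 0 or self.n2 == 0:
            raise DegenerateDataError(
                f"operation requires trials of both classes "
                f"(N1={self.n1}, N2={self.n2})"
            )


@dataclass(frozen=True)
class PriorSpec:
    """Prior probability P(θ1), strictly inside (0, 1)."""

    p1: float

    def __post_init__(self):
        p1 = float(self.p1)
        if not (0.0 < p1 < 1.0) or np.isnan(p1):
            raise DomainError(f"prior P(θ1) must lie strictly in (0,1), got {p1}")
        object.__setattr__(self, "p1", p1)

    @property
    def p2(self) -> float:
        return 1.0 - self.p1

    @property
    def odds(self) -> float:
        """Prior odds O(θ1) = p1/p2."""
        return self.p1 / self.p2

    @property
    def log_odds(self) -> float:
        """Natural-log prior odds."""
        return float(np.log(self.p1) - np.log1p(-self.p1))

    @property
    def log10_odds(self) -> float:
        """Base-10 log prior odds (ECE-plot x-axis convention)."""
        return self.log_odds / LN10

    @classmethod
    def from_log10_odds(cls, lo: float) -> "PriorSpec":
        """Build a prior from its base-10 log odds (round-trips to ~1e-12)."""
        return cls(odds_to_probability(10.0 ** float(lo)))


@dataclass(frozen=True)
class CostModel:
    """Decision costs with correct decisions costless.

    ``c_fa`` is C(α1, θ2), the cost of a false acceptance (deciding θ1 when
    θ2 is true); ``c_fr`` is C(α2, θ1), the cost of a false rejection.
    """

    c_fa: float = 1.0
    c_fr: float = 1.0

    def __post_init__(self):
        if self.c_fa < 0 or self.c_fr < 0:
            raise DomainError("decision costs must be non-negative")
        if self.c_fa == 0 and self.c_fr == 0:
            raise DomainError("at least one decision cost must be positive")


def probability_to_odds(p: float) -> float:
    """Odds O = p/(1−p) for a probability strictly inside (0, 1)."""
    p = float(p)
    if not (0.0 < p < 1.0) or np.isnan(p):
        raise DomainError(f"probability must lie strictly in (0,1), got {p}")
    return p / (1.0 - p)


def odds_to_probability(o: float) -> float:
    """Probability p = o/(1+o) for positive odds; +inf maps to 1."""
    o = float(o)
    if np.isnan(o) or o <= 0.0:
        raise DomainError(f"odds must be positive, got {o}")
    if np.isinf(o):
        return 1.0
    return o / (1.0 + o)


def posterior_probability(log_lr, prior: PriorSpec):
    """Posterior P(θ1|x) from a natural-log LR and a prior.

    Computed as LR·O(θ1) / (1 + LR·O(θ1)), evaluated in the log domain as a
    logistic of log LR + log O(θ1) so infinite log-LRs map to exact 0/1.
    Accepts scalars or arrays.
    """
    z = np.asarray(log_lr, dtype=float) + prior.log_odds
    out = expit(z)  # stable logistic; maps ±inf to exact 1/0
    return out if out.ndim else float(out)


def bayes_threshold(costs: CostModel, prior: PriorSpec) -> float:
    """Bayes threshold τB = (c_fa/c_fr)·(p2/p1) on the LR scale.

    Deciding θ1 iff LR > τB minimizes the expected cost when the LRs are
    the true likelihood ratios.
    """
    if costs.c_fr == 0:
        raise DegenerateThresholdError(
            "c_fr = 0 gives a zero threshold: θ1 is always the optimal "
            "decision and no finite Bayes threshold exists"
        )
    return (costs.c_fa / costs.c_fr) * (prior.p2 / prior.p1)


def decide(log_lr, log_threshold):
    """Bayes decision: 1 (α1) iff log LR strictly exceeds the log threshold.

    Equality decides α2 (the decision rule uses a strict inequality).
    Vectorized; NaN in either argument is rejected.
    """
    llr = np.asarray(log_lr, dtype=float)
    thr = np.asarray(log_threshold, dtype=float)
    if np.isnan(llr).any() or np.isnan(thr).any():
        raise DomainError("NaN is not a valid log-LR or threshold")
    out = (llr > thr).astype(np.int8)
    return out if out.ndim else int(out)


def empirical_expected_cost(
    lr_set: LRSet, prior: PriorSpec, costs: CostModel, log_threshold: float
) -> float:
    """Empirical expected cost of thresholding the LR set.

    Returns P(α2|θ1)·p1·c_fr + P(α1|θ2)·p2·c_fa where the conditional error
    rates are the observed fractions of trials mis-decided at the threshold.
    Requires at least one trial per class.
    """
    lr_set.require_both_classes()
    d = decide(lr_set.log_lr, log_threshold)
    p_fr = float(np.mean(d[lr_set.label == 1] == 0))
    p_fa = float(np.mean(d[lr_set.label == 0] == 1))
    return p_fr * prior.p1 * costs.c_fr + p_fa * prior.p2 * costs.c_fa


@dataclass(frozen=True)
class CostCurve:
    """Expected cost over a grid of log thresholds, one row per prior.

    ``cost[i, j]`` is the empirical expected cost of prior ``priors[i]`` at
    ``log_thresholds[j]``; ``bayes_log_threshold[i]`` marks log τB for that
    prior (the vertical lines of a cost-vs-threshold plot).
    """

    log_thresholds: np.ndarray
    priors: tuple
    cost: np.ndarray
    bayes_log_threshold: np.ndarray
    costs_model: CostModel = field(default_factory=CostModel)


def cost_vs_threshold_curve(
    lr_set: LRSet,
    priors,
    costs: CostModel,
    log_thresholds,
) -> CostCurve:
    """Expected cost swept over a threshold grid, for each prior.

    The grid must be nonempty and sorted ascending (natural-log units).
    """
    grid = np.asarray(log_thresholds, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid must be nonempty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("threshold grid must be sorted ascending")
    priors = tuple(priors)
    cost = np.empty((len(priors), grid.size))
    for i, prior in enumerate(priors):
        for j, thr in enumerate(grid):
            cost[i, j] = empirical_expected_cost(lr_set, prior, costs, thr)
    tau = np.array([np.log(bayes_threshold(costs, p)) for p in priors])
    return CostCurve(grid, priors, cost, tau, costs)
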