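"""Affine (logistic-regression / Platt-scaling) calibration of log-LRs.

Fits log LRcal = a·log LR + b on a training set by minimizing the
prior-weighted logistic log-loss of the transformed set — with the default
effective prior of 0.5 this objective is exactly the Cllr of the calibrated
scores.  The problem is convex in (a, b); a damped Newton iteration with
backtracking converges in a handful of steps.

Because the map is strictly monotone for a > 0, it changes calibration only:
rank order, ROC, AUC and the whole ECEmin curve are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .bayes import LN2, LRSet, PriorSpec

__all__ = [
    "AffineMap",
    "SeparableDataWarning",
    "NegativeScaleWarning",
    "fit_affine",
    "apply_affine",
]

#: |a·s + b| cap (natural-log units) at which fitting stops on separable data.
_PARAM_CAP = 50.0
_GRAD_TOL = 1e-9
_MAX_ITER = 200


class SeparableDataWarning(UserWarning):
    """Training classes are perfectly separable: the logistic objective has
    no finite minimizer and fitting stopped at the parameter cap."""


class NegativeScaleWarning(UserWarning):
    """The fitted scale is ≤ 0 — the score polarity is likely inverted."""


@dataclass(frozen=True)
class AffineMap:
    """A fitted calibration map log LRcal = scale·log LR + shift.

    ``objective_bits`` is the final training objective (prior-weighted
    log-loss, in bits); ``converged`` is False when the gradient tolerance
    was not reached (separable data or iteration cap).
    """

    scale: float
    shift: float
    objective_bits: float = float("nan")
    iterations: int = 0
    converged: bool = True

    def __call__(self, log_lrs):
        return apply_affine(self, log_lrs)


def apply_affine(amap: AffineMap, log_lrs):
    """Elementwise scale·s + shift on natural-log LRs."""
    out = amap.scale * np.asarray(log_lrs, dtype=float) + amap.shift
    return out if out.ndim else float(out)


def _objective_grad_hess(theta, s, sign, w):
    """Prior-weighted logistic loss (bits), its gradient and Hessian.

    ``sign`` is +1 for θ2 trials and −1 for θ1 trials so the per-trial loss
    is softplus(sign·(a·s + b + lo)) with the prior log-odds folded into
    the weights' companion offset (handled by the caller via ``s`` and the
    constant term in ``theta``).
    """
    a, b = theta
    z = a * s + b
    obj = float(np.sum(w * np.logaddexp(0.0, sign * z))) / LN2
    g = w * sign * expit(sign * z)
    grad = np.array([np.sum(g * s), np.sum(g)]) / LN2
    h = w * expit(z) * expit(-z)
    hess = np.array([
        [np.sum(h * s * s), np.sum(h * s)],
        [np.sum(h * s), np.sum(h)],
    ]) / LN2
    return obj, grad, hess


def fit_affine(
    train: LRSet,
    effective_prior: PriorSpec = PriorSpec(0.5),
    ridge: float = 0.0,
) -> AffineMap:
    """Fit the affine calibration map on a training LR set.

    Minimizes the ECE of the transformed set at ``effective_prior`` (the
    default 0.5 makes the objective the Cllr of the calibrated scores).
    Deterministic given the data; never worse than the identity map (1, 0),
    which is the starting point.

    ``ridge`` adds an optional ε·(a²+b²)/2 penalty for separable data.
    Perfectly separable training scores have no finite minimizer: fitting
    then stops once |a·s + b| exceeds 50 natural-log units over the training
    scores and returns ``converged=False`` with a
    :class:`SeparableDataWarning`.
    """
    train.require_both_classes()
    s = train.log_lr
    if not np.isfinite(s).all():
        raise ValueError("affine calibration requires finite training log-LRs")
    if np.ptp(s) == 0.0:
        raise ValueError(
            "all training scores are identical; the affine scale is "
            "unidentifiable"
        )
    lo = effective_prior.log_odds
    # perfectly separated classes admit no finite minimizer (the loss decays
    # to zero as the scale grows); fit to the parameter cap and say so
    separable = ridge == 0.0 and (
        train.llr1.min() > train.llr2.max()
        or train.llr1.max() < train.llr2.min()
    )
    sign = np.where(train.label == 1, -1.0, 1.0)
    w = np.where(
        train.label == 1,
        effective_prior.p1 / train.n1,
        effective_prior.p2 / train.n2,
    )
    # fold the prior log-odds into the shift: optimize b' = b + lo
    theta = np.array([1.0, lo])
    obj, grad, hess = _objective_grad_hess(theta, s, sign, w)
    if ridge:
        obj += 0.5 * ridge * float(theta @ theta)
        grad = grad + ridge * theta
    converged = False
    it = 0
    capped = False
    for it in range(1, _MAX_ITER + 1):
        if not separable and np.linalg.norm(grad) < _GRAD_TOL:
            converged = True
            break
        H = hess + (ridge + 1e-14) * np.eye(2)
        step = np.linalg.solve(H, -grad)
        # backtracking line search on the convex objective
        t = 1.0
        while t > 1e-12:
            cand = theta + t * step
            c_obj, c_grad, c_hess = _objective_grad_hess(cand, s, sign, w)
            if ridge:
                c_obj += 0.5 * ridge * float(cand @ cand)
                c_grad = c_grad + ridge * cand
            if c_obj <= obj:
                theta, obj, grad, hess = cand, c_obj, c_grad, c_hess
                break
            t *= 0.5
        else:
            break  # no decrease possible at float precision
        if np.max(np.abs(theta[0] * s + theta[1])) > _PARAM_CAP:
            capped = True
            break
    if separable or capped:
        warnings.warn(
            SeparableDataWarning(
                "training classes are separable; calibration stopped at the "
                "parameter cap (consider ridge > 0)"
            ),
            stacklevel=2,
        )
        converged = False
    a, b = float(theta[0]), float(theta[1] - lo)
    if a <= 0:
        warnings.warn(
            NegativeScaleWarning(
                f"fitted scale a={a:.4g} is not positive; the score polarity "
                "is likely inverted"
            ),
            stacklevel=2,
        )
    return AffineMap(a, b, objective_bits=obj, iterations=it,
                     converged=converged)
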