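# Methods

## Setting

A binary probabilistic classifier compares two items and reports a
likelihood ratio LR = p(x|θ1)/p(x|θ2) for the hypotheses θ1 ("same
source" / "target") and θ2.  A decision maker combines it with their prior
odds O(θ1) through the odds form of Bayes' rule, P(θ1|x) = LR·O/(1+LR·O),
and decides θ1 iff LR exceeds the Bayes threshold
τB = (c_fa/c_fr)·(P(θ2)/P(θ1)).  `ecelab` evaluates an *empirical set* of
such LRs with ground-truth labels; producing the LRs from raw features is
upstream of this package and out of scope.

Conventions fixed throughout: labels encode θ1 as 1 and θ2 as 0; log-LRs
are natural-log in memory and base-10 at the file surface and on plot axes
(the single conversion pair lives in `ecelab.bayes`); entropies, scores and
Cllr are in bits; ties at a decision threshold go to α2 because the
decision rule uses a strict inequality.  Log-LRs of exactly ±inf are legal
(oracle-like certainty) and propagate by limit rules; NaN is rejected at
construction.

## Empirical cross-entropy

For a prior P(θ1), each trial's implied posterior is scored with the
logarithmic proper scoring rule, and the class means are combined with
prior weights:

ECE(P) = (P/N1) Σ_{θ1} log2(1 + 1/(LR·O)) + ((1−P)/N2) Σ_{θ2} log2(1 + LR·O).

Per-trial terms are evaluated as `logaddexp(0, ∓(log LR + log O))/ln 2`, so
the identities hold at float precision: a correctly-oriented infinite LR
contributes exactly 0, and the neutral system (all LR = 1) reproduces the
binary prior entropy exactly.  A *wrongly*-oriented infinite LR makes ECE
infinite; this is returned as `inf` with a structured warning listing the
offending trials rather than raised, because such trials are a meaningful
diagnostic of a broken system, not a programming error.

The ECE curve is evaluated on a grid of prior log10-odds, by default 501
uniform points on [−2.5, 2.5] (step 0.01), which covers the prior ranges
relevant in practice while keeping a full evaluation of 10⁵ trials around a
second on one CPU; 0 is always inserted so the Cllr summaries are grid
values, never interpolations.  Cllr is ECE at prior 0.5.  The mean
logarithmic score LS of Savage/DeGroot–Fienberg is exposed with the prior
as an explicit parameter; at prior 0.5 it equals 2·Cllr.

## The PAV reference and the decomposition

The discrimination/calibration split uses the pool-adjacent-violators
(PAV) algorithm: the least-squares isotonic regression of the 0/1 labels on
the score order, which is also the monotone transform minimizing every
proper scoring rule on the set.  Implementation choices:

* Trials with identical scores are pooled into one candidate block before
  fitting, so the map is a function of the score and independent of input
  order.  The fit is the classic stack algorithm on (label-mean, count)
  blocks; block values are label means, hence never 0 or 1 for a block
  containing both classes — which keeps ECEmin finite.
* The map is applied as a right-continuous step function; scores outside
  the training range clamp to the extreme blocks (no extrapolation).
* In-sample PAV posteriors are posteriors *at the empirical prior* of the
  fit set.  To evaluate the reference at other priors they are converted to
  LRs by log LRcal = logit(pcal) − log(N1/N2) and pushed back through the
  posterior formula at each grid prior.  This is an interpretive choice —
  the natural one, since it makes the reference a set of LRs like any
  other — and it is what makes ECEmin a curve rather than a single number.
* ECEmin depends only on the rank order of the scores; ECEcal is reported
  as max(ECE − ECEmin, 0) with the raw difference (which can be ~−1e−12
  from float noise) retained in `ECEDecomposition.ece_cal_raw`.

The PAV here is fit in-sample on the evaluation set itself, by design: the
reference answers "how good could *these* scores be if optimally
recalibrated", not "how well would a recalibration generalize".

## Affine (logistic-regression / Platt) calibration

The calibration stage fits log LRcal = a·log LR + b on a training set by
minimizing the prior-weighted logistic log-loss of the transformed set at
an effective prior (default 0.5, making the objective the Cllr of the
calibrated scores — the class-balanced choice standard in this literature;
the prior is a parameter for users who want an application-weighted fit).
The objective is convex in (a, b); a damped Newton iteration with
backtracking starts at the identity (1, 0) — so the fit is deterministic
and never worse than no calibration — and stops at gradient norm < 1e−9 or
200 iterations.  Perfectly separable training scores have no finite
minimizer: separability is detected up front, fitting stops once
|a·s + b| exceeds 50 natural-log units over the training scores, and the
map is returned with `converged=False` and a warning (an optional ridge
penalty, default 1e−6 when enabled, restores a finite optimum).  A fitted
a ≤ 0 triggers a polarity warning but is not an error.  Since a > 0
preserves rank order, the map moves only the calibration loss: ECEmin, ROC
and AUC are unchanged, which the tests assert at 1e−10.

## Discrimination diagnostics

AUC is computed as the Mann–Whitney U statistic with midrank tie handling
(equal to the trapezoid area under the threshold-swept ROC); the operating
points come from a full threshold sweep with no points dropped.  The
positive class is θ1 and the x-axis is the false-acceptance rate P(α1|θ2).
Reliability tables bin the implied posteriors at a user-chosen prior
(default 10 equal-width bins) and compare per-bin mean prediction with the
observed θ1 frequency; empty bins are carried with count 0 and NaN
statistics, flagged rather than fabricated, and omitted from figures only.

## Synthetic generator

The generator draws natural-log LRs from N(+σ²/2, σ²) for θ1 trials and
N(−σ²/2, σ²) for θ2 trials — the unique equal-variance Gaussian pair whose
log density ratio at a point equals the point itself, so the scores *are*
the LRs of their own generating process and the set is calibrated by
construction.  This makes three properties provable and testable: AUC has
the closed form Φ(σ/√2); the large-sample Cllr_cal tends to 0; and the
reliability curve tends to the diagonal.  Defaults: σ² = 4 (AUC ≈ 0.92,
a realistically good but imperfect system), 10⁴ trials per class
(5·10⁴ per class in the large-sample checks, where the sampling noise of
Cllr_cal falls well below the 0.01-bit assertion).  Presets weak/medium/
strong use σ² = 1/4/9 to give visibly distinct overlaps.  Miscalibration
is modelled as an affine distortion of the log-LRs (the exact inverse of
the calibration family), with scale 2.5 and shift 1.5 in the recovery
experiments — large enough that the distorted calibration loss (~0.28
bits) dominates sampling noise.  All randomness flows from one integer
seed through `numpy` `SeedSequence` spawning; identical specs are
bit-for-bit reproducible, end to end through the CLI.

What the generator does *not* emulate: heavy-tailed or multimodal score
distributions, class-dependent variances, dataset shift between train and
test (beyond independent draws of the same process), and finite-precision
score quantization.  Passing tests therefore demonstrate correctness of
the evaluation machinery and recoverability of affine miscalibration —
they do not certify behaviour on real systems whose miscalibration is
non-affine.

## Numerical and design notes

* Probability/odds conversions validate domains strictly ((0,1) and
  (0,∞)); prior round-trips hold to 1e−12 relative error in the
  probability.
* A cost model with c_fr = 0 has no finite Bayes threshold; this raises an
  explicit degenerate-threshold error instead of silently returning 0.
* `distort(scale=0)` is permitted with a warning: it produces a degenerate
  neutral-like set, occasionally useful as a fixture.
* Plots are pure views: every figure writes a CSV sidecar with the exact
  arrays drawn, and the JSON report round-trips all numbers exactly
  (non-finite values serialized as "inf"/"-inf"/"nan" strings).
* The acceptance script uses 5·10⁴ trials per class for the generator
  soundness checks and 10⁴ per class for the recovery experiment — sizes
  at which the asserted tolerances are comfortably above sampling noise
  while a full run stays within seconds.

## Known limitations

In-sample ECEmin is optimistic for small N (the PAV adapts to noise; no
cross-validated variant is provided).  The ECE machinery is strictly
binary; multiclass extensions are out of scope.  Confidence bands on ECE,
DET curves and EER are not provided.
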