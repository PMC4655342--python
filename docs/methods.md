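# Methods

## Task model and simulator

A session is `n_blocks × trials_per_block` trials (default 6 × 160).
Stimulation is on during a fixed set of blocks (default {3, 5}). Each block
contains every cue probability level equally often — the package requires
`trials_per_block` divisible by the number of levels — in an independently
shuffled order per block. Whether the original task balanced levels within
block or only across the session is not documented anywhere we could rely
on; within-block balancing was chosen because it guarantees equal per-level
counts in both conditions, which the per-level exact tests and the
condition-wise fits both benefit from.

Per trial the simulator draws, in order: an independent Bernoulli(omission
rate) omission indicator; a Bernoulli(ψ(p)) choice using the active
condition's psychometric parameters; a Bernoulli(p) win indicator for risky
choices; and a reaction time. Omissions are modelled as trait-like and
independent of the cue — the simplest mechanism consistent with a small,
roughly constant omission fraction — with default rate 0.033.

Reaction times follow a log-normal law truncated at the deadline, sampled
by inverse CDF (no rejection loops, so the draw count per trial is fixed
and seeded streams stay aligned). Defaults: location ln(650 ms) off,
ln(680 ms) on, scale 0.15 log-ms, deadline 1000 ms. The ~30 ms on–off
location difference and the 600–800 ms operating range match the scale of
reaction-time effects this kind of session exhibits; the law itself is a
modelling choice (right-skewed, positive, deadline-respecting) made to give
the ANOVA a realistic surface, not an empirical claim.

Default agent psychometric parameters: off (m = 0.55, w = 0.1,
floor = 0.05, ceiling = 0.95), on (m = 0.35, otherwise equal) — a −0.2
threshold shift with risk sensitivity and biases held fixed, which is the
qualitative effect the analysis is designed to detect.

What the simulator does **not** emulate: feedback learning (the practice
block), within-block adaptation or drift, sequential dependencies between
trials, and any affective response to stimulation. Passing tests therefore
demonstrate correctness of the analysis pipeline under a stationary,
well-specified agent; they do not show robustness to learning dynamics or
model misspecification beyond the non-monotonicity screened by the
posterior-predictive check.

## Likelihood, priors, parameterization

The likelihood is independent Bernoulli per responded trial, aggregated to
per-level binomial counts (the two computations agree to 1e-12; omissions
are excluded as non-choices). ψ uses the scale parameterization
(p − m)/w, so w is the logistic scale: smaller w = steeper curve.

Priors are independent uniforms: m ~ U(−0.25, 1.25), w ~ U(0.01, 1),
floor ~ U(0, 0.5), ceiling ~ U(0.5, 1). They are deliberately weakly
informative: the non-overlapping floor/ceiling supports enforce
identifiability (floor < ceiling) by construction, and the threshold
support extends beyond the tested cue range so strongly shifted behaviour
is representable. Both the prior bounds and the parameterization are
configuration choices, not hard-coded constants.

## Sampler

Component-wise Gaussian random-walk Metropolis on transformed coordinates:
scaled logit for m, floor and ceiling (relative to their prior intervals),
log for w; the Jacobian of the transform is included in the target so the
chain samples the correct posterior. Chains run vectorised in lockstep.
Initialisation takes the maximum-posterior point of a coarse 11⁴ grid,
jittered per chain; a non-finite start after 100 seeded retries is an
error (unreachable under proper uniform priors).

Proposal step sizes adapt per chain and per component during warmup only,
by Robbins–Monro (γ_t = t^−0.6) toward a target acceptance rate of 0.35,
and are frozen afterwards so the retained chain is Markov; the frozen and
final scales are both stored and must be equal, which the tests assert.

Defaults: 4 chains, 1000 warmup iterations, 2000 retained draws, thin 2,
target acceptance 0.35. Thinning by 2 is deliberate: with thin 1 the
slowest-mixing parameter's effective sample size lands around 320–390,
below the 400 threshold at which this package flags a convergence failure,
so routine well-behaved fits would be spuriously flagged; thin 2 gives
ESS ≈ 540–800 at about 1.5 s per fit. Convergence reporting uses split-R̂
and bulk ESS (arviz), flagging failure at R̂ > 1.05 or ESS < 400. Deviance
(−2 log-likelihood) is stored per draw so posterior curve plots can weight
samples by fit quality.

The sampler's correctness anchor is agreement with dense-grid integration
of the same posterior: total variation of the threshold marginal within
0.05 at 128 trials per level, and mean/interval agreement for all four
parameters on smaller problems. The grid oracle lives in the test suite
and shares no code path with the sampler.

## Fit screening and threshold shift

Goodness of fit is a posterior-predictive check with the chi-square style
discrepancy T = Σ_ℓ (k_ℓ − n_ℓψ_ℓ)² / (n_ℓψ_ℓ(1 − ψ_ℓ)); the predictive p
is P(T_rep ≥ T_obs) over 500 subsampled posterior draws. Classification:
p < 0.005 → `unfittable`, p < 0.05 (or a convergence-flagged run) →
`poor_fit`, otherwise `ok`. The cutoffs operationalise "cannot be
modelled" for non-monotonic choice patterns; they are package choices, and
the discrepancy's variance floor is clipped at 1e-12 to keep saturated
levels finite.

The threshold shift is summarised from the product posterior: the off and
on fits' m draws are independently permuted (seeded), paired and
differenced. Reported: posterior mean, 5–95% interval and
P(Δm < 0) = prob_left_shift. The shift is computed whenever at least one
condition is not `unfittable`, with non-ok statuses carried as flags;
only two unfittable conditions make it unavailable. Calibration at session
scale (960 trials, 2 chains × 500 draws per fit): under a null agent the
rate of prob_left_shift > 0.95 stays within binomial slack of the nominal
5%, and a −0.2 true shift is detected in well over 80% of sessions.

## Frequentist tests

Mid-P Fisher: the hypergeometric support for the observed margins is
enumerated; two-sidedness follows the point-probability ordering, with
probabilities tied with the observed table's (relative tolerance 1e-12)
contributing half weight. A zero row or column margin leaves a single
admissible table; that degenerate case returns 0.5 with a flag. The
implementation (floating-point hypergeometric pmf) is verified against an
exact rational-arithmetic enumeration for every table with total ≤ 30
(agreement within 1e-12, and mid-P ≤ the conventional two-sided exact p
throughout). Significance tiers use strict inequalities at 0.05 / 0.01 /
0.001, uncorrected across levels by design.

Reaction-time ANOVA: ordinary least squares on responded trials with
stimulation, choice and probability as categorical factors, all
interactions, Type II sums of squares (statsmodels `anova_lm`). Probability
is categorical because the design treats it as five discrete levels; Type
II suits the near-balanced designs the simulator produces. Constant
reaction times are degenerate: every effect gets SS = 0 and p = 1. Missing
cells reduce the residual degrees of freedom; a design with no residual
degrees of freedom is an error.

## Pipeline and reproducibility

One master seed in the run configuration derives per-stage seeds through
`numpy.random.SeedSequence`, so simulation, each condition's sampler, the
draw pairing and the posterior-predictive check are all independently and
reproducibly seeded; two runs of the same configuration produce
byte-identical reports. Configurations round-trip losslessly through YAML.
Reports serialise to a versioned JSON schema (`schema_version: 1`).

## Problem sizes used in the verification suite

The structural checks use full 960-trial sessions. Omission calibration
averages 100 sessions. The grid-agreement check integrates a
120 × 60 × 40 × 40 grid against 4 chains × 10000 thinned draws. Threshold
recovery uses 50 datasets of 640 trials. Shift calibration and power use
200 sessions each at 2 chains × 500 draws. These sizes give the binomial
and Monte Carlo error bars quoted above while keeping the full suite to a
few minutes on one CPU.

## Known limitations

- The sampler is random-walk Metropolis: adequate for this 4-D posterior,
  but efficiency degrades if the posterior is strongly correlated (e.g.
  threshold far outside the tested range with few trials); no gradient
  information is used.
- Conditions are fitted independently; there is no hierarchical pooling
  across sessions or participants.
- The posterior-predictive screen targets lack of fit in the mean choice
  curve; it has no power against violations that preserve per-level means
  (e.g. trial-order dependence).
- Mid-P is reported per level without multiplicity correction,
  intentionally mirroring per-level reporting conventions.
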