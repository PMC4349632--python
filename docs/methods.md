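# Methods

## The task

Each trial of the budgeted offer task presents a sequence of 7–9 token
offers, one at a time, each worth 3, 5 or 7 tokens. The player responds
go (accept, banking the tokens) or nogo (reject) to each offer, but may
accept at most `budget` ∈ {4, 5, 6} of them; once the budget is spent
the remaining responses are enforced nogos. Offer count and budget are
drawn uniformly and independently each trial, so the player never knows
either exactly — only their generating ranges.

Offer values are governed by a contingency index `m` over three
instructed distributions on (3, 5, 7):

| m | P(3) | P(5) | P(7) | entered by |
|---|------|------|------|------------|
| 0 | 1/3  | 1/3  | 1/3  | trial onset |
| 1 | 0.50 | 0.25 | 0.25 | accepting a 5 |
| 2 | 0.90 | 0.05 | 0.05 | accepting a 7 |

The update applies only when the accept occurs after the first offer
and before three offers have been rejected; once three rejections have
accumulated, `m` is locked for the rest of the trial. The update follows
the most recent accepted offer, so by the literal rule an accepted 5 at
`m = 2` relaxes the contingency to `m = 1`. Whether that relaxation is
intended is genuinely ambiguous (the narrative motivation is a
penalty that "scales with face value"); we implement the literal rule
and expose `m_monotone=True` on the task engine and solver to forbid
improvement. All results in this repository use the literal rule.

The printed onset triple {0.33 0.33 0.33} does not sum to one; it is
implemented as exact thirds, consistent with "independent and equal
probability".

## The optimal agent

The agent's state is a pair of belief distributions — **O** over offers
remaining (onset: uniform on 7–9) and **A** over accepts remaining
(uniform on 4–6) — plus `m` and the rejection count that gates updates.
Responding shifts the relevant belief left by one and renormalizes,
dropping mass below one:

P′(c) = P(c + 1) / Σ P(c + 1).

Both beliefs are therefore deterministic functions of the number of
offers seen and accepts used, so the triple (offers_seen, n_accepted,
m) is the canonical memoization key; rejections-so-far and the
first-offer flag are derived from it. 97 states are reachable from
onset.

The state value is

SV(O, A, m) = Σ_r M_m(r) · max( P(o>1)·SV(O′, A, m),
                                r + P(o>1)·P(a>1)·SV(O′, A′, m_r) ),

the expectation over the forthcoming offer value of the better of
rejecting and accepting, with continuation probabilities P(o>1) and
P(a>1) read from the beliefs. The recursion bottoms out when either
continuation probability is zero. Two choices here deserve note:

- **max inside the expectation.** The player sees the offer value
  before responding, so the optimal decision is per-value; the
  expectation over r is over offers not yet seen.
- **contingency threading.** The accept branch uses `m_r`, the index
  after accepting value r under the eligibility rules (first offer and
  rejection lock respected), and the reject branch advances the
  rejection counter. The compact value equation alone leaves this
  bookkeeping implicit; the update rules require it.

The decision quantities at each offer are the reject value
V_R = P(o>1)·SV(O′, A, m), the future accept value
V_AF = P(o>1)·P(a>1)·SV(O′, A′, m_r), and

EV = V_AF + IR − V_R,

the long-term value of accepting an offer with face value IR. Ties
(EV = 0) are resolved toward accepting, fixed for determinism. At the
index-2, zero-rejection, uniform state the solved values are
EV(3) = −0.776, EV(5) = +0.855, EV(7) = −0.359: the optimal agent
rejects early 7-token offers despite their face value — the task's
self-control dissociation — and expects 23.71 tokens per trial from
onset.

A cache-free exhaustive tree search (`brute_force_sv`) re-derives SV by
brute force (~6^horizon nodes); the memoized program matches it to
1e-10 on every reachable state. Beliefs are not conditioned on the
budget-exhaustion signal beyond the P(a>1) bookkeeping: the modeled
agent plans over its onset uncertainty rather than updating from the
red light, matching the instructed model of the task.

## Choice models

All models pass a decision value V_A through
P(go) = 1 / (1 + exp(−τ·V_A)):

- immediate: V_A = IR − c (face value against an intercept);
- optimal: V_A = EV;
- trade1: V_A = w·EV + (1 − w)·(IR − c);
- trade3: as trade1 with a separate weight w₃/w₅/w₇ per face value.

w near 0 is impulsive (face value dominates), w near 1 is controlled.
The intercept is named `c_int` in both roles to avoid the symbol
collision between the immediate model's intercept and the trade
models' weight. Likelihoods cover every non-forced offer; forced nogos
after budget exhaustion carry no choice information and are excluded.
Per-choice probabilities are floored at 1e-12. Two exact nesting
identities hold and are tested: trade1 at w = 1 reproduces the optimal
model's likelihood at matched τ, and trade3 with equal weights
reproduces trade1.

Parameters are optimized in an unconstrained space — log τ, logit
weights, identity intercept — with analytic gradients; optimization is
boxed at |log τ| ≤ 15, |logit w| ≤ 30, |c| ≤ 100, wide enough to be
inert for any data-supported optimum while keeping the arithmetic
finite. EV values are precomputed once per solver (97 states × 3
values) and joined to the data, not recomputed per likelihood call.

## Hierarchical fitting and model comparison

Subject-level parameters are modeled as draws from independent
Gaussian group distributions in the unconstrained space (Type-II
maximum likelihood / empirical Bayes). Fitting is EM:

- **E-step** — per-subject MAP under the current group prior
  (L-BFGS-B with analytic gradients), with the local curvature from a
  central finite-difference Hessian of the penalized objective giving
  a Laplace (Gaussian) posterior approximation. Five seeded restarts
  on the first iteration; later iterations warm-start from the
  previous mode plus a prior-mean start, which preserves multi-start
  protection where the surface is still unexplored without paying for
  it at every iteration.
- **M-step** — moment matching: group mean = mean of modes, group
  variance = mean of (mode² + posterior variance) − mean².

Convergence is an absolute change below 1e-4 on every hyperparameter
(max 100 iterations); group variances are floored at 1e-6 and a flag
records when the floor binds. Because the E-step is a Laplace
approximation, the integrated-likelihood trace is monotone only up to
approximation error; the test suite asserts non-decrease within 1e-4
of the objective magnitude rather than exactly.

Models are compared by the integrated BIC,

iBIC = −2·Σᵢ log p(Dᵢ | prior) + k·log N,

with per-subject marginals by the Laplace integral over the group
prior, k = 2 hyperparameters (mean, variance) per model parameter, and
N the total free choices pooled over subjects (model comparison treats
the group as a single dataset). Goodness of fit is the Cox–Snell
pseudo-r², 1 − exp(2(ll₀ − ll₁)/n), per subject against an
intercept-only baseline whose constant accept probability is the
subject's ML accept rate; group summaries report the across-subject
mean with a 95% bootstrap CI (2000 resamples).

## Synthetic data

The generator reproduces the study design exactly: 23 subjects, three
36-trial sessions, configs drawn per trial, offers from the
contingency distributions, and choices sampled from a candidate
model's P(go) with per-subject parameters drawn from the group
distribution in unconstrained space (so every draw respects its native
domain). Sessions are statistically identical; the session column
exists for schema fidelity.

Default trade3 group settings follow the reference group medians
(τ = 2.833, c = 5.891, w₃ = 0.834, w₇ = 0.264) with spreads implied by
the interquartile ranges. The w₅ median sits at the boundary value
1.0, which a logit-Gaussian group cannot center on; the generator uses
0.95, with weights clipped to [0.025, 0.975] before the logit and
delta-method sds capped at 2.5 in transform space. The other
generators use plausible settings chosen once (trade1: w = 0.6;
optimal: τ = 2.0; immediate: τ = 1.0, c = 5.0) that produce a
realistic mix of stochastic and value-driven choice.

What the generator does **not** emulate: learning or fatigue across
sessions, reaction times, lapses, and any within-subject
non-stationarity. Passing recovery tests therefore demonstrates that
the estimation machinery is correct and that the design carries enough
information to identify the parameters — not that real subjects
satisfy the model's assumptions.

## Behavioral analyses

The acceptance grid pools free choices at uniform-contingency (m = 0)
states by (offer index, rejections so far, offer value); cells with
fewer than 15 observations are flagged excluded for display, a filter
that never touches regression inputs. The decorrelated subset is the
free choices at offer indexes 2–3 with m = 0 — the states where
immediate and long-term value are maximally decoupled; rejection
counts are left unrestricted.

The choice regression is logistic IRLS of go/nogo on IR and EV jointly
(plus intercept), per subject, with raw (unstandardized) regressors by
default and optional z-scoring. "Robust" weighting multiplies each
IRLS weight by a Tukey bisquare weight (c = 4.685) of the Pearson
residual; it is on by default and switchable to plain IRLS, which
matches the standard binomial GLM (verified against statsmodels).
Residual-based down-weighting on binary outcomes systematically
sharpens coefficients and, on near-deterministic choosers, can chase a
perfectly-classified subset to effective separation; fits whose
coefficients exceed magnitude 50 (odds ratios beyond e^200 over the
token range) are therefore flagged quasi-separated and excluded from
the group test, as are exactly separated subjects. Group inference is
a two-sided one-sample t-test of the per-subject betas against zero.

## Problem sizes and numerics

All value arithmetic is double precision with no rounding before
output (tables export at 3 decimals). The recovery studies run at the
design scale of 23 subjects × 108 trials: 10 replicates for parameter
recovery of trade3 and 5 replicates per generator (20 datasets, 80
hierarchical fits) for model recovery; analytic gradients and
precomputed EV tables keep one hierarchical fit to a few seconds.
Every stage takes a single master seed: the generator derives
per-subject streams from (seed, subject), the E-step restart draws
from (seed, iteration, subject).

## Known limitations

- The Laplace marginal can be inaccurate for subjects whose posterior
  is strongly skewed (e.g. weights piling at a boundary); iBIC
  differences of a few units should not be over-read.
- Bisquare-weighted logistic estimates are not consistent for the
  logistic ML target; they serve outlier resistance, and the plain
  path is the interpretable reference.
- With the literal most-recent-choice rule, the contingency can
  improve (2 → 1); under `m_monotone=True` the solved values differ
  slightly, and fitted EVs should be regenerated accordingly.
- The EM stopping rule halts the geometric collapse of the group
  variance early when subjects are literally identical; the variance
  approaches but does not reach the floor in finitely many iterations.
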