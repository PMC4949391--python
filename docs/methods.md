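# Methods

## The decision model

The saccadic Go/No-Go task is treated as a rapid two-alternative choice.
On each trial a single evidence accumulator starts at level `a*z` between
an implicit lower boundary at 0 (the No-Go decision) and an upper boundary
at `a` (the Go decision) and evolves as a Wiener process with drift `v`
until absorption.  Reaching the upper boundary triggers a saccade whose
latency is the first-passage time plus the non-decision time `Ter`
(stimulus encoding and motor output); reaching the lower boundary withholds
the response, which is never directly observable — a No-Go decision and a
slow undelivered Go decision look identical in the data.  Parameters per
participant:

| symbol  | meaning                               | units          | support |
|---------|---------------------------------------|----------------|---------|
| `a`     | boundary separation (caution)         | evidence       | > 0     |
| `z`     | relative starting point (Go bias)     | —              | (0, 1)  |
| `v_go`  | drift rate, Go condition              | evidence/s     | ℝ       |
| `v_nogo`| drift rate, No-Go condition           | evidence/s     | ℝ       |
| `Ter`   | non-decision time                     | s              | ≥ 0     |
| `s`     | diffusion scale                       | evidence/√s    | fixed 1 |

The scale `s` is not identifiable jointly with `a` and `v` and is fixed at
1 (the common convention in Bayesian diffusion modelling); all magnitudes
are read on that scale.  No inter-trial variability parameters are
included: the model space is exactly {a, z, v, Ter} under four constraint
variants (below).  Responses later than the 1500 ms deadline are censored
into withheld trials by the task.

## Likelihood

The first-passage density at the lower boundary is evaluated by the
standard series expansions of the Wiener FPT density, switching between
the small-time and large-time forms by comparing the number of terms each
needs for a truncation error of 1e-10 in normalized time (absolute density
error well below 1e-8 after rescaling).  The upper-boundary density uses
the mirror identity f_upper(t; v, a, z) = f_lower(t; −v, a, 1−z); the
absorption probability has the closed form
P(upper) = (1 − e^{−2vaz}) / (1 − e^{−2va}), evaluated with `expm1` and
the limit z as v → 0.

A responded trial contributes `log f_upper(latency − Ter)` with the drift
of its condition; a withheld trial contributes `log P(lower)`.  A latency
at or below `Ter` yields −∞ rather than an error so the sampler can move
away from that region.

**Deadline asymmetry.**  The generator censors Go decisions that would
land past the deadline, but the likelihood does not model that censoring:
withheld trials are scored as lower-boundary absorptions only.  At
control-like parameters the censored mass is ≲0.1% and the effect is
invisible.  At a strongly Go-biased, slow-drift parameter set
(a=1.6, z=0.73, v_go=1.7, v_nogo=−1.4, Ter=0.16) about 0.6–1.2% of
responses are censored and the posterior is pulled slightly toward faster,
less cautious dynamics; the test suite bounds the plug-in bias at that set
to |Δa| < 0.25, |Δz| < 0.06, |ΔTer| < 0.01.  This is the price of keeping
the withheld-trial likelihood in closed form, and it is shared by the
common implicit-boundary treatment of Go/No-Go data.

## Hierarchy, priors and sampler

Each free parameter carries one normal group-level distribution per
diagnostic group (PSP, PD, control): individual parameters are draws from
N(μ_{θ,g}, σ_{θ,g}²).  The starting point is modelled on the logit scale
at both levels so the hierarchy respects (0, 1).

Priors are weakly informative, covering published diffusion-model ranges:

| group mean        | prior                                  |
|-------------------|----------------------------------------|
| μ_a               | N(1.5, 1.5²) truncated to (0.1, 10)    |
| μ_logit z         | N(0, 1.5²)                             |
| μ_v (go / no-go)  | N(0, 4²)                               |
| μ_Ter             | N(0.2, 0.2²) truncated to (0, 1.5 s)   |

Group spreads get half-normal priors with scales 1 (a, logit z), 2 (v)
and 0.1 (Ter).  The μ_Ter ceiling is the response deadline, not the
minimum observed latency: one strongly Go-biased participant can produce a
minimum latency below another group's true mean non-decision time, and a
global minimum-latency ceiling was found (in recovery simulations) to jam
the control group's posterior against the bound.  Per-participant Ter
proposals are capped at that participant's minimum valid latency minus
1 ms — the likelihood is −∞ beyond it anyway, so the cap only avoids
wasted proposals and does not change the posterior.

Sampling is Metropolis-within-Gibbs.  Individual parameters take
component-wise random-walk proposals plus one joint random-walk proposal
per participant whose covariance is accumulated over the second half of
burn-in (this cuts through the strong a-v-z posterior correlations that
make purely component-wise updates crawl).  Group means are drawn exactly
from their normal-normal Gibbs conditional (redrawn on the rare prior
bound violation); group spreads take log-scale random-walk proposals with
the Jacobian term.  All step sizes and the joint covariance are adapted
every 25 iterations during burn-in (target acceptance 0.35 component-wise,
0.25 joint) and frozen afterwards, so retained chains are valid Metropolis
output and runs are bit-exactly reproducible given a seed.  Defaults are a single chain of
15,000 samples with the first 5,000 discarded; the scaled-down studies in
the test suite use 900–3,000 samples, which the recovery checks show is
adequate at those cohort sizes.  Initial values: a = 1.5, logit z = 0.2,
v = ±1.5, and Ter just below each participant's fastest valid response; a
non-finite initial likelihood triggers halving of Ter with up to eight
retries before an initialization error naming the participant.

Convergence is monitored by the Geweke diagnostic: the mean of the first
10% of the retained chain against the last 50%, studentized with
spectral-density-at-zero variance estimates (Geyer's initial positive
sequence estimator, which reduces to the plain variance for white chains);
|z| > 2 flags a quantity.  Model comparison excludes a variant from the
argmin when more than 20% of its quantities are flagged.

## Model variants and comparison

| variant | starting point | drift rates            |
|---------|----------------|------------------------|
| 1       | fixed at 0.5   | v_nogo = −v_go         |
| 2       | fixed at 0.5   | free per condition     |
| 3       | free           | v_nogo = −v_go         |
| 4       | free           | free per condition     |

Drift symmetry acts at the individual level (one underlying v per
participant).  Models are ranked by DIC = D̄ + pD with pD = D̄ − D(θ̄),
where the deviance is −2× the trial-level log-likelihood summed over
participants and D(θ̄) plugs in posterior-mean individual parameters.
The per-group decomposition restricts the deviance sums to one group's
trials within the joint fit (the alternative — separate per-group fits —
would change the hierarchy, not just the bookkeeping).  Negative pD is
reported with a warning rather than an error.

## Posterior-predictive checks

One joint posterior draw per simulation (preserving posterior
correlations) generates, for every participant, exactly the observed
number of valid trials per condition; 500 simulations by default (100 in
the scaled-down suite).  Summaries per group × condition: response rates
with Monte-Carlo percentile bands, latency histograms in 25 ms bins over
[0, 1500] ms normalized so response mass plus non-response probability
equals 1, and Go-latency deciles.  Displays follow the signed-axis
convention with correct-Go latencies on the positive axis and No-Go
commissions mirrored onto the negative axis.

## Synthetic cohorts

The generator mirrors the study design: three groups (default 19 PSP,
24 PD, 26 controls), 300 trials per participant split 50/50 between Go and
No-Go in randomized order, a 1500 ms deadline, random 1500–2500 ms
foreperiods and left/right target sides generated for realism but never
influencing latencies (the model is side-agnostic, matching the pooling of
target sides), and 5% of trials flagged invalid uniformly at random to
emulate blink/artefact rejection — a deliberate simplification of a
trace-validation stage.

Trials are simulated by Euler–Maruyama diffusion at dt = 0.2 ms with both
boundaries shrunk inward by 0.5826·s·√dt (the Broadie–Glasserman–Kou
continuity correction), which removes the leading O(√dt) first-passage
bias of discretely monitored absorption; the residual bias in recovered
parameters is below 0.03 evidence units on `a` and invisible elsewhere at
the sizes used.  The same kernel at the same step serves the
posterior-predictive simulations, and at dt = 0.1–0.2 ms with 10⁵–10⁶
paths it is the brute-force oracle against which the analytic density and
absorption probabilities are validated.

Preset magnitudes (synthetic — they encode qualitative orderings, not
estimates from any recorded cohort):

| preset      | intent                                                        |
|-------------|---------------------------------------------------------------|
| null_cohort | identical hyperparameters across groups (calibration studies) |
| paper_like  | PSP Go-bias above PD above 0.5; both patient groups with lower Go drift and shorter non-decision time than controls; boundary separation equal across groups; commission rates ≈ 6% (control) / 16% (PD) / 29% (PSP); mean Go latencies similar across groups |
| separable   | ≥ 5 group-SD gaps on z, v_go and Ter — forces near-perfect classification |

What the generator does **not** emulate: express saccades and anticipatory
responses, sequential trial-history effects, fatigue and drift of
vigilance over a session, eye-trace artefacts and the vendor validation
program, or asymmetries between leftward and rightward targets.  Passing
recovery and self-consistency tests therefore demonstrates internal
correctness of the pipeline under the model's own assumptions, not that
the model is adequate for any particular recorded dataset — that is what
the posterior-predictive machinery is for.

## Group inference

The four behavioural measures per participant (omission rate, commission
rate, mean latency of successful Go trials, mean latency of No-Go
commission trials) are computed over valid trials with sides pooled; a
mean latency with no contributing trials is NaN and the participant is
flagged.  Group statistics follow the classical reporting style for this
design: one-way ANOVA with partial η² (= SS_between / (SS_between +
SS_within) for the one-way design) and the three pairwise equal-variance
t-tests, uncorrected, with conventional degrees of freedom (N − k; some
published reports appear to count total N instead — the conventional
convention is used here and noted).  The Bayesian contrast P_p|D is the
fraction of retained posterior samples satisfying a strict directional
inequality between group-level means (or against a constant, e.g.
z > 0.5); exact ties count as not supporting (measure-zero for continuous
chains), and a batch-means Monte-Carlo standard error accompanies every
contrast.

## Classification

Features per participant are either the five posterior-mean diffusion
parameters (a, z, Ter, v_go, v_nogo) or the four behavioural measures.
A multinomial logistic-regression classifier with mild L2 regularization
(C = 1 by default, for numerical stability on ~20-participant training
folds) is evaluated by leave-one-out cross-validation; features are
standardized with training-fold statistics only.  Per class: hit rate
(true-positive rate), precision, and one-vs-rest AUC computed by the rank
formula (equivalent to the trapezoidal rule with tied probabilities
contributing their average step).  Weighted averages use class prevalence
among classified participants.  Class prediction is argmax probability
with exact ties resolved by the fixed class order PSP < PD < CONTROL.
At chance, leave-one-out is slightly pessimistic (the held-out class is
under-represented in its training fold), so calibration checks band the
weighted hit rate around — not exactly at — 1/3.

Two feature sets are compared by a permutation test: per participant,
with probability ½, the two sets' leave-one-out outcomes (predicted label
and class-probability vector move together) are swapped; each weighted
metric difference is recomputed per permutation (100,000 by default) and
the one-sided p-value is (1 + #{permuted ≥ observed}) / (n_perm + 1).
Swapping at the participant level is the natural granularity for paired
fold outcomes.  It is exact only when fold outcomes are independent
across participants; leave-one-out folds share almost all of their
training data, and that coupling makes the swap null slightly too narrow
for global rank statistics.  In calibration simulations (two feature
tables drawn as a shared base plus independent noise) the weighted
hit-rate p-value is well calibrated (≈5.5% rejections at the 5% level),
while the weighted-AUC p-value rejects ≈11–15% — the true sampling spread
of the AUC difference is about 1.3× the permutation spread.  Small AUC
p-values from this procedure should therefore be read with that ~2×
inflation of the nominal level in mind; the hit-rate comparison does not
share the problem.

## Problem sizes used by the test suite and acceptance script

Oracle checks use 1.2–1.5 × 10⁵ paths at dt = 0.2 ms per parameter set
(five sets spanning the plausible range), with binwise three-sigma
tolerances under a family-wise multiplicity correction.  Parameter
recovery uses 3 groups × 10 participants × 300 trials with 3,000/1,000
chains; model-selection recovery 3 × 3 × 150 with 2,000/800 chains over
ten replicates, ranked on raw DIC; classification studies run at the full
cohort sizes (19/24/26) with 2,000/800 chains; permutation calibration
uses 150–500 replicates at 1,000–2,000 permutations.  These sizes were chosen so each
study's Monte-Carlo error is small relative to the effects it checks.

## Known limitations

* Deadline censoring is absent from the likelihood (bounded bias, above).
* Single-chain operation by default; between-chain diagnostics such as
  split-R̂ are not computed (Geweke within-chain checks are).
* The classifier is a regularized multinomial logistic model, not a
  boosted simple-logistic variant; the metric machinery, not the
  classifier internals, is the contract.
* DIC is the only information criterion computed; WAIC/LOO-CV are out of
  scope.
* The feature-set permutation test is anti-conservative for the
  weighted-AUC metric (see the classification section); the hit-rate
  comparison is calibrated.
* The component-wise sampler mixes slowly when parameters are strongly
  correlated (notably a with v at low trial counts); chain lengths in the
  defaults are sized for the study design, and the Geweke gate guards the
  model comparison.
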