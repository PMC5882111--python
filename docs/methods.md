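# Methods

## The decision model

`rmsprt` implements a multi-hypothesis sequential probability ratio test
with delayed feedback (rMSPRT): a normative model of perceptual decision
making in which `N` competing hypotheses (saccade targets in the
random-dot-motion task) are evaluated in parallel against `C = N` streams
of sensory evidence. Each stream is a sequence of inter-spike intervals
(ISIs) with the statistics of motion-sensitive cortical neurons (area MT):
i.i.d. lognormal, with mean/SD `(mu_*, sigma_*)` when the stimulus matches
the channel's preferred direction and `(mu_0, sigma_0)` otherwise, with
`mu_* < mu_0` (preferred direction fires faster).

At each discrete step `t` the model tracks the negative log-posterior of
every hypothesis. Because the per-observation log-density ratio between
two lognormals is a quadratic in the log observation,

    log f*(u) - log f0(u) = g0 + g1 (log u)^2 + g2 log u,

the per-channel log-likelihood reduces to two running sums (of `log x` and
`(log x)^2`); the hypothesis-independent `g0` terms cancel under posterior
normalisation and are dropped ("simplified" log-likelihood). The update is
a generalized Bayes rule with feedback delay `Delta >= 1`: for `t <= Delta`
the fixed initial priors are combined with the likelihood of the full
history; for `t > Delta` the posterior from `Delta` steps in the past is
re-used as the prior, combined with the likelihood of only the last
`Delta` observations. A posterior is a sufficient statistic for the
evidence it has absorbed, so the recursive posterior equals the single-shot
batch posterior at every step and the classic non-recursive test
(`Delta -> infinity`) is a special case; for `N = 2` the statistic reduces
to Wald's sequential probability ratio test. These identities are enforced
to 1e-10 in the test suite and are also what lets the package simulate
large trial batches with cumulative sums (`DecisionEvaluator`) while the
step-by-step recursive implementation (`run_trial`) serves as the
reference path.

A decision is made the first time the smallest negative log-posterior
falls to a threshold `theta` in `(0, log N]`; the chosen hypothesis is the
arg-min (exact ties, a measure-zero event under continuous evidence, are
broken uniformly under the trial's seed).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `N` | number of alternatives | 2 or 4 | any `N >= 2` accepted |
| coherence | task difficulty (%) | — | registry levels 3.2…51.2 |
| `n` | data scaling factor | 40 | divides observations; inference-invariant |
| `delta_yb, delta_bu, delta_uy, delta_yu` | loop latencies (steps) | 1 each | recursion delay `Delta = 3` |
| `l` | constant cortical baseline | 15 | display-range only |
| `w_yu` | cortico-thalamic weight | 0.4, in `[0, 1)` | display-range only |
| `theta` | decision threshold | calibrated | per condition |
| non-decision time | sensory + motor latency | 250 ms | 200–300 ms plausible band |

The ISI registry (packaged CSV) carries, per coherence, the
preferred/null mean and SD in ms for the full-information set `omega`
(measured from MT populations) and the information-depleted sets
`omega_d_n2` / `omega_d_n4`. Lognormal shape parameters use standard
moment matching, `Theta^2 = log(sigma^2/mu^2 + 1)`,
`kappa = log mu - Theta^2/2`; `Theta^2` is invariant to `n` and `kappa`
shifts by `-log n`, which is why `n` cannot affect inference.

## Discrimination information and behavioural predictions

The information content of one observation is the Kullback–Leibler
divergence from the preferred to the null ISI density, in bits
(closed form via the log-domain normal divergence). Decision sample sizes
convert to times through the continuous-time equivalence: a spike-based
test consumes about as many ISIs in its fastest channel as the discrete
test consumes observations, so

    tau_c = (<T>_c + 0.5) mu_* n      (correct trials)
    tau_e = (<T>_e + 0.5) mu_0 n      (error trials)

with the half-ISI accounting for the wait from decision initiation to the
first spike. Reaction time adds the non-decision time. This equivalence is
asymptotic in the sample size; the package's consistency check therefore
uses its slowest condition (N = 4, 3.2% coherence, depleted set), where the
renewal-theory correction `(sigma^2/mu^2 - 1)/2 ≈ -0.3` ISIs is small
relative to the ~9-observation mean.

A note on the information bound: for the two-channel structure the
discrimination information per observation *vector* between joint
hypotheses is the symmetrised divergence `KL(f*||f0) + KL(f0||f*)`. Wald's
information inequality bounds `E[T]` from below using that quantity; the
one-directional `K` alone is used as an estimating identity
(`I_hat = <T>_c K`), not as a bound, and the estimate is expected to
overshoot — see the loss pipeline below.

## Threshold calibration

Error-rate targets are an exponential function of coherence
(`0.50 e^{-0.11 s}` for N = 2, `0.75 e^{-0.08 s}` for N = 4). Under common
random numbers the Monte Carlo error rate is an exact step function of
`theta`: per trial, only the strictly-new running minima of the
neglog-posterior-minimum trajectory can be decision points, so correctness
is piecewise constant in `theta`. The calibrator builds that step function
once and inverts it directly (no bisection re-simulation), extending the
simulated streams until the relevant threshold interval is fully covered.
The Monte Carlo sample is enlarged so that its binomial standard error is
at most half the tolerance `min(0.002, 0.15 * target)`; the near-chance
conditions need this because the mean sample size there is steeply
sensitive to the achieved error rate. The tolerance floor of
`0.15 * target` tightens (never loosens) the nominal 0.002 at small
targets such as 0.0018 (N = 2, 51.2%).

## Circuit mapping

Each step decomposes onto the cortico-basal-ganglia-thalamo-cortical loop
on a common (basal-ganglia) clock: sensorimotor cortex sums the simplified
log-likelihood, the fed-back log-prior and a baseline
`c(t) = h(t - Delta) + l`; the striatum relays a copy of the cortical
signal; the basal-ganglia output carries the fresh negative log-posteriors
(the same arithmetic as the inference core — asserted to 1e-10); the
thalamus relays the log-posterior delayed by `delta_bu` on top of the
diffuse cortico-thalamic baseline `h`, a `w_yu`-scaled average of delayed
cortical activity. Signals at or before time zero take their pre-evidence
values (likelihoods 0, posteriors = priors, `h = 0`, `c = l`), and each
trace starts with a pre-evidence step (display step −1) determined by
priors and baselines alone. Trace display steps map `s -> t = s + 1`, so
the first fed-back posterior arrives at display step `Delta`: traces ramp
together before it and fork after it, the model's signature
"ramp-and-fork". Causality of `h` requires `delta_uy + delta_yu >= 1`
(holds at the defaults; enforced otherwise). The exact linear combination
plotted per region is a convention — the loop decomposition fixes what
each region sums, not display offsets — and `h` at the final recorded
steps can require evidence beyond the horizon, where it is reported as
NaN.

Trial-averaged traces split trials into selected (chosen hypothesis) and
non-selected (mean of the rest) classes, average over trials still valid
at each aligned step, and truncate at the median termination plus 3 steps;
trials continue 3 steps past threshold crossing so termination-aligned
averages are defined there.

## Information-loss estimation and depletion

Given per-condition mean correct reaction times of a subject,
`InformationLossModel.fit` estimates how much discrimination information
the subject effectively used:

1. simulate the full-information model (`omega`) at the calibrated
   threshold; `I_hat = <T>_c K` estimates the total information needed;
2. invert the subject's reaction time into a decision sample size
   `<T_hat>_c = (rt - t_nd)/(mu_* n) - 0.5`;
3. `K_hat = I_hat / <T_hat>_c` and the loss is `(1 - K_hat/K) * 100%`;
4. *enhanced match*: because threshold overshoot makes `I_hat` an
   over-estimate, `K_hat` is rescaled by the ratio of the depleted model's
   decision time to the subject's. The package iterates this rescaling as
   a fixed point (default cap 5 iterations, stopping once the time ratio
   is within 0.5% of 1); a single step is the minimal correction, and the
   fixed point is the threshold-robust estimator;
5. *depletion*: the null-channel mean and SD are moved towards the
   preferred ones by a common proportion `gamma` (bisection to 1e-9 bits)
   until the pair carries exactly `K_hat`.

Feasibility: Monte Carlo noise can put `K_hat` slightly above the
available `K`; such estimates are clamped to `K` for the depletion step
(the enhanced-match refinement then pulls them back down). An estimate
more than 15% above `K` is treated as genuinely infeasible — the reaction
times are faster than the registry's evidence permits — and reported as a
per-condition error.

The depleted moments always lie componentwise between the preferred and
original null moments, matching the structure of the packaged depleted
sets.

## Synthetic behavioural fixture

Real subject reaction times are not distributable, so the packaged fixture
is generated by the model itself: a *secret* depleted registry (per-
coherence loss fractions 20/35/50/65/80%, both N, chosen once to emulate
the coherence-increasing loss pattern reported for macaques) is simulated
at the calibrated thresholds and 250 ms non-decision time. The recovery
test feeds the resulting reaction times and the full-information registry
back through the pipeline and requires the secret per-condition divergence
to be recovered to better than 5% relative error. What this does and does
not show: it validates the estimation pipeline end to end under the
model's own assumptions (i.i.d. lognormal evidence, constant non-decision
time, error rates on the calibration curve); it cannot certify behaviour
on real data, where those assumptions hold only approximately.

## Numerical choices and problem sizes

All posterior arithmetic is log-domain with `logsumexp`. The batch
evaluator uses float32 evidence and trajectories (Monte Carlo noise
dominates at these precisions) in 32-step chunks; exact-arithmetic checks
run on the float64 scalar path. Trials are capped at 1e5 steps with an
explicit non-termination error, which also guards degenerate registries
(preferred = null freezes the posteriors at the priors). Smoothing kernels
truncate at ±4 SD (<1e-4 mass lost); moving-rate windows are half-open and
reported only on bins fully covered by data. Random numbers derive from a
single root seed: scalar trials through one generator stream in draw
order, batch runs through one spawned child stream per condition batch.

Default study sizes mirror the primate experiments this model addresses:
per-experiment totals of 3200 (N = 2) and 4800 (N = 4) trials split
equally across the five coherences; trace experiments use 800/1200
totals. The packaged checks
use 1e4 trials per condition for calibration closure and loss recovery,
800 trials for trace averages, and 1e3 renderings for the continuous-time
consistency check.

## Known limitations

- Evidence channels are independent and i.i.d. in time; correlated or
  non-stationary streams (and `C > N` likelihoods) are out of scope.
- The error-rate calibration curve's coefficients are taken as given, not
  refitted.
- Trace magnitudes are in arbitrary units; only orderings, slopes and
  fork/peak timing are meaningful predictions.
- `I_hat` is an upper-bound-flavoured estimate; the loss percentages are
  minimum losses under the model, and the enhanced-match correction makes
  the depleted-set reaction times match, not the bound tight.
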