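# Methods

## Task model

A session is a fixed schedule of endpoint reach angles (degrees relative to
the straight-to-target direction; positive = counterclockwise). The
standard schedule is BL1 (60 trials, no rotation, never any external
noise), BL2 (60, no rotation, noise if the condition injects it), then
closed-loop blocks R1 (100 trials, ±15° rotation), washout (100, 0°), and
R2 (100, opposite rotation) — 420 trials. The 40-trial familiarization
block that precedes real sessions is excluded from every analysis and is
not simulated.

Reward rules, applied to the (possibly noise-perturbed) angle θ_noisy:

* **Baseline**: |θ_noisy − target| ≤ 5.75°, boundaries inclusive on both
  ends (a measure-zero choice; inclusivity avoids asymmetric edge
  behavior).
* **Closed-loop**: θ_noisy must lie in the closed interval from the running
  mean of the previous 10 θ_noisy values to the rotated target, extended
  5.75° beyond the target on the far side. The extension is a design
  choice: the asymptotic behavior of the zone once the mean reaches the
  target is not otherwise constrained, and without a floor the criterion
  would force ~50% reward at convergence regardless of skill. If the mean
  sits exactly on the target the zone degenerates to the symmetric
  baseline zone (an almost-surely-null event that keeps the rule
  sign-symmetric).
* The running-mean window is global over the session, so at each block
  transition it is seeded by the last 10 noisy angles of the preceding
  block, and it averages θ_noisy — the quantity feedback is actually based
  on — rather than θ_hand.
* **Clamp** (optional): reward for a correct reach is withheld whenever
  awarding it would push the accumulated session-wide rate above the
  ceiling: award iff (r+1)/(n+1) ≤ c, counting all trials from session
  start including baseline. This makes the running rate ≤ c at every
  trial by construction.

Noise injection: σ_x = √(α²−1)·σ_bl so that baseline variability and the
injected noise compose in quadrature to α·σ_bl. σ_bl defaults to the
sample SD of the session's own BL1 reach angles (a config override allows
a fixed value, e.g. a first-day estimate shared across sessions). One
standard-normal sequence covering all post-BL1 trials is drawn per seed
and reused across conditions, scaled by σ_x, so conditions differ only in
noise amplitude, not in the particular draws.

The simulated agent: x_1 = x0; per trial e ~ N(0, σ_e(prev reward)²),
m ~ N(0, σ_m²), θ_hand = x + e + m; x updates by e only after reward. The
first trial uses the rewarded-context σ_e, since sessions begin after a
practice/baseline context in which most reaches are rewarded.

## Likelihood

The filter follows the bootstrap scheme: initialize all R particles at the
BL1 mean reach angle; per trial weight by N(y_t; x_t^r, σ_m² + σ_e²) with
σ_e chosen by the previous trial's recorded reward (trial 1: rewarded
context); per-trial likelihood = mean weight; resample every trial
(multinomial by default; systematic available behind a flag); propagate
rewarded trials by drawing e from its exact Gaussian conditional given
(y_t, x_t^r): mean ρ(y_t − x_t^r), variance ρσ_m², ρ = σ_e²/(σ_e²+σ_m²).
Sampling from the conditional is the unique propagation consistent with
the generative model; a mean-only update is available as a sensitivity
option. The recorded reward sequence is exogenous data to the filter: the
fitted observable is θ_hand, and θ_noisy enters only through the rewards
it generated.

Numerics: weights are computed in log space with a max shift; if every
particle underflows, the trial contributes a floor log-density of −745 and
a warning is logged, keeping the objective finite on absurd parameter
proposals. Multinomial resampling is implemented as a single merge pass of
sorted uniforms (generated by cumulative exponential spacings) against the
cumulative weights — O(R) per trial and exactly multinomial. The core loop
is numba-compiled; the filter is deterministic given its seed. The
minimum effective sample size 1/Σŵ² across trials is reported as a
degeneracy diagnostic.

With σ_m = 0 a rewarded trial reveals e_t exactly, so x_{t+1} = y_t and
the likelihood is a product of Gaussians — the closed-form oracle used to
validate the filter (they agree to machine precision because all particles
coincide in that regime).

## Fitting and model comparison

Bounded derivative-free maximization (Nelder–Mead with bound clipping) of
the particle-filter log-likelihood with the filter seed fixed across all
evaluations (common random numbers), so the objective — and hence the
whole fit — is deterministic. Defaults: SD bounds (0.01°, 20°), spanning
plausible human values without boundary trapping; three starts at 0.25,
0.5, 0.75 of the session's overall reach-angle SD; simplex tolerances
xatol = 0.02°, fatol = 0.5 (matched to the Monte-Carlo jitter of the
objective at R = 2000). Non-convergence within the evaluation budget is
flagged on the result, not raised. The one-parameter variant (σ_m = 0) is
fit with the exact closed-form likelihood — analytically identical and free
of Monte-Carlo noise.

Summed BIC: degrees of freedom, trial counts, and log-likelihoods are
summed across sessions before BIC = k·ln(n) − 2·LL; variants are reported
as differences from the best (0 = winner).

## Behavioral metrics

Reinforcement rate (percent, optional phase filter); early learning slope
(OLS over a rotation block's first 40 trials, deg/trial); total learning
(mean of the final 40 rotation trials minus the final-40 mean of BL2);
block means over final-40 windows. All learning measures are reported in
canonical sign (countering the rotation = positive), and sessions can be
re-signed to the canonical clockwise-then-counterclockwise order (an
involution that leaves rewards untouched). The trial-to-trial analysis
assigns |θ_hand(t+1) − θ_hand(t)| to trial t's feedback × accuracy
category (Rewarded/Unrewarded × In/Out zone, judged on the noise-free
angle against the same zone state used for reward); successor pairs
spanning block boundaries are excluded because the reward rule changes at
transitions, and empty categories are reported as explicitly empty rather
than zero. Group-level inferential statistics (ANOVA, t tests) are out of
scope; summaries are exported as delimited text for external statistical
software.

## Synthetic-data generator: what it does and does not emulate

The generator reproduces the statistical structure that matters for the
model-based analysis: Gaussian baseline variability, the quadrature-scaled
shared noise sequence, reward-conditional Gaussian exploration, Gaussian
motor noise, the reward-gated estimate update, the running-mean closed-loop
zone, the block schedule, and the clamp. It does not emulate kinematics
(trajectories, movement times, repeat trials), fatigue or attention
drifts, non-Gaussian or temporally correlated noise, explicit/strategic
re-aiming, or any pathology-specific structure. Passing recovery tests
therefore shows the pipeline is correct and identifiable under the model's
own assumptions — not that real subjects satisfy them.

Default study conditions used by the test suite: agents with
σ_m = 3.5°, σ_{e,r} = 1.5°, σ_{e,u} = 3.0° (plausible human-scale values;
baseline SD then ≈ 4°); model-recovery batches generated at
(σ_m = 3.5°, σ_e = 2.0°) for the tied-exploration truth and
(σ_m = 2.0°, σ_{e,r} = 1.5°, σ_{e,u} = 3.0°) for the reward-dependent
truth. Problem sizes are chosen as the package's defaults for routine
validation: oracle-equivalence checks on 40 × 100-trial sessions at
R = 10,000; parameter recovery on 20 × 420-trial sessions at R = 2,000;
model recovery on 10 replicate batches of 10 sessions per truth at R = 250
with a capped optimizer budget; directional effects on 50 matched-seed
session pairs.

## Known limitations

* The particle-filter log-likelihood is a consistent but noisy estimator;
  common random numbers make fits reproducible, not noise-free. Reported
  maxima can sit ~1 LL unit below the true optimum at small R.
* σ_{e,r} and σ_m are separated only through the dynamics of rewarded
  updates; on single sessions the profile can be flat enough that a start
  collapses to a bound, which multi-start mitigates but does not
  eliminate.
* The closed-loop zone floor and the first-trial reward context are
  package design choices where the task description is silent; both are
  configurable in principle through the protocol/agent structures.
* No posterior state reconstruction (smoothing) and no standard errors on
  fitted parameters are provided.
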