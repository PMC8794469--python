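# Methods

`explorebandit` reimplements, as a tested pipeline, the computational
machinery used to study explore/exploit behavior on a restless two-armed
bandit: task simulation, latent-state labeling of exploration with a tied
hidden Markov model, a seven-model reinforcement-learning fitting suite,
run-length mixture analysis, Markov-dynamics energy landscapes, and
model-free behavioral metrics. This note records the models, the
assumptions behind them, and the design choices made where the design was
genuinely open.

## Task model

Each arm of the bandit carries a reward probability that drifts
independently: per trial there is a `step_prob = 0.10` chance that an
arm's probability moves by `step_size = 0.10`. Whole candidate walks are
drawn and rejected until three criteria hold: the two arms' session means
differ by at most 2 percentage points, no probability reaches 0 or 1, and
no 30-trial window has both arms below 20%.

Choices open to us and fixed here:

* **Bounds.** "Never 0% or 100%" is operationalized as *reflecting-stay*
  boundaries at 0.1 and 0.9: a proposed step that would leave [0.1, 0.9]
  is discarded and the value stays, keeping the walk on the 0.1 grid that
  ±10% steps imply.
* **Start values** are drawn uniformly from {0.2, 0.3, …, 0.8} per arm.
* Step direction is ±`step_size` with probability ½ each; arms step
  independently; the rejection budget is 10,000 candidates, after which a
  generation error names the violated constraint.

A consequence of reflecting-stay bounds worth knowing: the *unconditional*
step frequency is below 0.10 because roughly 2/9 of the time an arm sits
at a bound where half of the proposed steps are rejected. Conditional on
being at an interior value the step probability is exactly `step_prob`,
and that is what the calibration test checks.

## Explore/exploit HMM

Three latent states — explore, exploit-left, exploit-right — with fixed
emissions: explore emits either arm with probability ½ (the maximum-
entropy choice, which neither requires nor implies that exploratory
decisions are random), and each exploit state emits only its own arm.
Because a switch of exploited arm must pass through exploration, and
transitions are tied across the two exploit states, the core model
(`tied2`) has two free parameters: the explore-stay probability `a` and
the exploit-stay probability `d`:

    explore    -> [a, (1-a)/2, (1-a)/2]
    exploit_i  -> [1-d, d·δ_i]

Every session is assumed to start in the explore state; the initial
distribution is fixed rather than estimated. Two four-parameter variants
relax the core model: `io4` conditions (a, d) on the previous trial's
reward (an input-output HMM; the transition into trial *t* uses the
reward at *t−1*, so trial 1 contributes no transition), and `nt4` removes
the tying (separate explore→exploit_L/R entries and per-arm exploit-stay
probabilities).

**Fitting** is Baum-Welch with the emissions and initial distribution held
fixed, so the M-step reduces to closed-form ratios of expected transition
counts pooled across tied entries and across a subject's sessions. Each
fit uses 20 random restarts (stay parameters initialized uniform(0.5,
0.99)), a convergence tolerance of 1e-6 nats on the observed-data
log-likelihood, and at most 500 iterations; the best restart is kept.
**Decoding** is Viterbi with trial 1 constrained to explore and ties
broken toward explore (the lower-commitment label). Model comparison uses
AIC/BIC with per-subject free-parameter counts summed across subjects and
a single pooled criterion (`k = params-per-subject × n_subjects`);
`n_obs` for BIC is the total trial count.

A caution for interpretation, verified empirically during development:
per-subject AIC ranking between `tied2` and the variants that nest it is
noisy by construction (the log-likelihood gain of a nesting model on data
generated from the nested one is ~χ²/2), so parsimony recovery is
assessed on the pooled criterion, where it is decisive.

## Reinforcement-learning models

Seven likelihood models over the per-trial choices:

| id | parameters | idea |
|----|------------|------|
| `random` | b | constant side bias, P(left) = b |
| `wsls` | ε | noisy win-stay/lose-shift; stay probability 1−ε/2 after a win, ε/2 after a loss |
| `rl` | α, β | delta-rule Q learning + softmax |
| `rl_eps` | α, β, ε | softmax with lapse: P = ε + (1−2ε)·softmax |
| `rlck` | α, β, α_c, β_c | values plus a choice kernel in the softmax |
| `rlck_gamma` | + γ | learning rate γ·α on unrewarded trials |
| `rlck_eta` | + η | mixing weight η between value and kernel terms |

Q values start at 0.5 per arm (the midpoint of the reward-probability
range) and choice kernels at 0; both reset at session boundaries. Only
the chosen arm's Q updates; the kernel updates for every arm toward its
chosen indicator at rate α_c. Bounds: α, α_c, η, b ∈ [0,1]; ε ∈ [0,0.5];
β, β_c ∈ [0,20]; γ ∈ [0,2] with γ·α ≤ 1 so the effective loss learning
rate stays a valid rate while allowing both under- and over-weighting of
losses. Fitting is bounded L-BFGS-B from 10 uniform-random starts;
`fit_unit="session"` fits each session separately for the session-by-
session (meta-learning) analysis. Model agreement is the fraction of
trials on which the fitted model's higher-probability arm matches the
observed choice (ties earn half credit).

Two structural facts shape what model recovery can show. `rlck_eta` is a
strict reparameterization of `rlck` (only η·β and (1−η)·β_c are
identifiable), so data generated from it are correctly attributed to the
`rlck` family and never to the five-parameter version under AIC.
`rl` with α = 1 degenerates toward win-stay/lose-shift.

**RL-based explore labels** follow the value-deviation tradition: a trial
is exploratory iff the chosen arm's decision variable is strictly below
the unchosen arm's (equivalently, the modeled probability of the chosen
arm is < ½); ties count as exploit.

**Exploration grid.** The grid experiment simulates two-parameter `rl`
agents at random (α, β) combinations, one fresh schedule each, labels
their choices with the tied HMM, and regresses the per-agent explore
fraction on z-scored α, z-scored β, and their product (OLS; the
regression family and scaling behind the reported coefficients are not
otherwise pinned down, so only the sign pattern is treated as meaningful).
α is drawn uniformly; β is drawn *log-uniformly* over its range — β is a
scale parameter, and a log draw covers the high- and low-noise regimes
evenly. With a uniform β draw most agents sit in the value-driven regime
and the interaction term is indistinguishable from zero; the log draw is
part of the experiment's design, chosen once.

## Switch dynamics

Runs of repeated choices are extracted per session (the final, censored
run included — the bias is negligible at 300 trials; runs never span
sessions), pooled, and fit with mixtures of geometric distributions on
support {1, 2, …}, P(x|p) = (1−p)^(x−1) p, by EM with restarts. A run's
length includes its first trial, so strict alternation gives runs of
length 1 and i.i.d. coin-flip choices give mean 2. Model selection adds
components sequentially with likelihood-ratio tests (χ², df = 2 per added
component: one weight, one rate; the usual boundary caveat for mixture
LRTs applies and is inherited knowingly). Components below 3% weight are
flagged as negligible. One-component EM reaches the closed-form MLE
p = 1/mean in a single iteration, which the tests exploit as an oracle.

## Energy landscape

The stationary distribution of a fitted transition matrix (the normalized
left unit-eigenvector; non-ergodic chains raise) gives long-run state
occupancies, reported with the two exploit states collapsed. Occupancies
map to energetic depths via the Boltzmann relation E_exploit − E_explore
= ln(π_explore/π_exploit)·k_BT, and stay probabilities map to escape
barriers via the Arrhenius relation E_a = −ln(1 − stay)·k_BT with the
pre-exponential factor A = 1. k_BT and A are fixed to 1, so energies are
in natural-log units and only differences are meaningful; the absolute
placement of the barrier peak in the three-point profile (explore floor,
peak, exploit floor) is a plotting convention.

Group landscapes average *per-subject stationary distributions* within a
group — not the stationary distribution of group-mean parameters; the two
differ (Jensen), which is why group-occupancy summaries need not equal
arithmetic from group-mean stay probabilities. Barriers are computed from
group-mean stay probabilities.

## Behavioral metrics

All lagged statistics align the outcome of trial t−1 with the choice at
t and exclude each session's first trial. Win-stay/lose-shift rates
condition, in their state-split form, on the latent label of trial t−1 —
the trial whose outcome is being learned from. Conditioning sets that
never occur yield None, not 0. Conditional mutual information
I(C_t; C_{t−1} | R_{t−1}) is the plug-in estimate from the empirical
2×2×2 joint, in bits (the base is a choice; no normalized "percentage of
information" is computed because no defensible normalization presents
itself). The tetrachoric correlation between two binary label sets is
estimated by maximum likelihood (bivariate-normal thresholds from the
margins, correlation solved so the model's upper-orthant mass matches the
observed 1–1 cell), with a +0.5 continuity correction for empty cells and
an error for one-valued margins. Group separability uses the rank-based
(Mann-Whitney) AUC — oriented so 1.0 means the second group's values are
uniformly larger — with Hanley-McNeil standard errors. Response-time
structure is summarized by per-state means and by the R² of z-scored RT
on each binary label set.

## Synthetic cohorts

The generator emulates the study design: 2 groups × 16 subjects × 8
sessions × 300 trials, one fresh schedule per session. Per-subject
parameters are truncated-normal draws from group distributions. The
`hmm_tied` preset uses the fitted group means and SDs reported for this
task (explore-stay 0.921 ± 0.034 / 0.831 ± 0.168, exploit-stay
0.835 ± 0.037 / 0.797 ± 0.221 for groups M/F). The RL presets are *not*
reported numerically anywhere, so the defaults (α: F 0.45 vs M 0.30, SD
0.10; β = 3.0 ± 0.5; α_c = 0.30 ± 0.10; β_c = 1.0 ± 0.30) are fixed
choices that respect only the qualitative ordering (higher learning rate
in group F, other parameters matched) and should not be read as
estimates. The default generating model is `rlck`, the best-fitting model
family for this task.

Latencies are log-normal, parameterized by arithmetic mean and SD:
response times depend on latent state (explore 0.4 s slower) and group
(M 0.3 s slower), retrieval times are state- and group-independent
(mean 1.5 s) — mirroring the finding that exploration slows the decision,
not the reward pickup. For RL-generated agents the "true" explore state
used by the latency model is the value-deviation label under the
generating parameters.

What the generator does *not* emulate: satiety or session truncation,
within-session engagement drift, per-animal trial-count differences,
Monday re-adaptation schedules, or any within-subject parameter drift.
Passing recovery tests on these cohorts therefore shows the estimators
are correct and well-calibrated under the stated generative assumptions;
it does not certify them against misspecification in real data.

## Numerical choices

* HMM recursions are scaled (normalized forward/backward passes); the RL
  likelihood clips per-trial probabilities at 1e-12 before the log.
* EM convergence: 1e-6 nats (HMM), 1e-8 (mixture); monotonicity of the
  observed-data log-likelihood is asserted in tests.
* Viterbi ties break toward explore; exploit→other-exploit transitions
  have probability exactly 0 and never appear in decoded paths.
* Mixture components are reported sorted by mean ascending.
* Degenerate inputs raise rather than guess: absorbing/periodic chains in
  the stationary solver, zero stationary mass in the depth formula,
  stay probability 1 in the barrier formula, one-valued margins in the
  tetrachoric estimator, empty conditioning sets in state-conditioned
  WSLS (None, flagged).
* `gamma`'s feasibility wedge (γ·α ≤ 1) is enforced with a penalty during
  optimization and a hard error in direct likelihood evaluation.

## Problem sizes

The test suite exercises the estimators at reduced but statistically
meaningful sizes (e.g. 25 subjects × 2 × 300 trials for HMM parsimony
recovery, 20 replicates × 600 trials per generator for the RL confusion
matrix, a 400-agent grid for the exploration regression); the benchmark
script `scripts/acceptance.py` uses the reference sizes (24,836 run
lengths; 16 subjects × 8 × 300 trials with 20 restarts). Tolerances in
tests are 3-standard-error bands wherever a sampling distribution is
available, and fixed bands (±0.05 on stay probabilities, ±0.2 trials on
mixture means) for the recovery checks.
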