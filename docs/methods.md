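# Methods

## Model

The observed pitch of rendition *t* is modeled as

    p_t = eps_t + b_t + V_t,        V_t = p* + c_t + d_t + o_t

with iid Gaussian explorations `eps_t ~ N(0, sigma_eps^2)`, the learned
bias

    b_t = (1 - delta) b_{t-1} + alpha R_{t-1} eps_{t-1} + eta_t,

and the repertoire components: colored drift
`c_t = (1 - tau) c_{t-1} + innovation_t` with innovation variance
`sigma_innov^2`; a piecewise-linear circadian pattern
`d_t = sum_j D_j theta_j(h_t)` over hat functions on N_D + 1 equal-count
time-of-day nodes; and a history offset `o_t = O_{1 + n_h(t)}` where
`n_h(t)` counts renditions in the half-open window `(t - x, t)` seconds
(clipped to `N_h - 1`; windows never cross midnight). The bias update is
the policy-gradient ascent of an expected reward penalized by
`(delta / 2 alpha) b^2`; it is the only place reward enters — the
repertoire is deliberately reward-blind.

Reward convention: `R = -1` on hit (WN delivered), `0` on escape;
`{1, 0}` and `{1, -1}` are supported alternatives. A hit is pitch
*strictly* below (contingency `low`) or above (`high`) the threshold;
ties count as escape.

## State-space formulation and fitting

Both stages are linear-Gaussian systems `p_t = H x_t + g_t`,
`x_t = A_t x_{t-1} + d_t + q_t` with diagonal process covariance and a
fixed, tiny observation variance `G = 1e-4 Hz^2`, so explorations are
estimated as hidden-state noise rather than output noise.

**Baseline** (reward-free; the bias is absent): state `x = [c, s]` with
`s_t = m_t + eps_t`, `m_t = beta' u_t`, where `u_t` stacks the N_D + 1
circadian weights and the N_h history indicators. Free parameters:
`1 - tau`, `beta`, both noise variances. The two indicator blocks of
`u_t` each sum to one, so `beta` has a one-dimensional gauge freedom; it
is resolved after fitting by moving the rendition-weighted means of both
blocks into `p*`, which enforces zero-average circadian and history
patterns (the spec of the decomposition, not a statistical constraint).

**Feedback**: state `x = [b, c, s]`. The bias row needs
`eps_{t-1} = s_{t-1} - m_{t-1}`; since the repertoire is frozen after the
baseline fit, `m` is a known input, and the transition entries
`+-alpha R_{t-1}` make the system exactly linear with a reward-dependent
transition. (The conditioning loop makes `R_{t-1}` a function of observed
data only, so the filter and its likelihood remain exact.) Free:
`alpha`, `delta`, `sigma_eta^2`, and — re-estimated as a self-consistency
handle — `sigma_eps^2`. Model variants for comparison: *classical*
(`V = p*`, two-state system), *efference copy* (learning term
`alpha R (eps + V)`), *pitch error* (`alpha (R - Rbar)(p - p*)` with
`Rbar` the 20-rendition running mean reward, a known input).

**Estimation.** E-step: Kalman filter + fixed-interval (RTS) smoother
with exact lag-one covariances (`P_{t,t-1|T} = P_{t|T} J_{t-1}'`);
M-step: closed-form expected-complete-data updates (the bias row's two
transition coefficients solve a 2-D box-constrained quadratic;
variances have explicit forms; `beta` solves min-norm normal equations).
The initial-state prior is fixed at initialization (diffuse, data-scaled)
and excluded from the M-step, so monotonicity of the likelihood trace is
exact (asserted to 1e-8 relative). Because `alpha` and `delta` trade off
along a shallow likelihood ridge (a larger leak with a larger learning
rate yields near-identical bias paths), EM alone converges extremely
slowly along the ridge; the feedback fit therefore runs at most 150 EM
iterations and finishes with an L-BFGS-B maximization of the exact filter
likelihood over log-transformed learner parameters. Multi-start and
Nelder-Mead cross-checks confirm this reaches the ridge top. Kernels are
JIT-compiled (numba) with explicit small-matrix loops; a full
filter+smoother pass over 20,000 renditions takes ~10 ms, so a complete
two-stage fit is a few seconds.

Defaults: `tol = 1e-6` relative log-likelihood, `max_iter = 500`
(baseline), smoother jitter `1e-10`, variance floors `1e-12`.
Initialization: `sigma_eps^2` = half the sample pitch variance,
`tau = 0.01`, `beta` by least squares of pitch on `u`, `alpha = 1e-3`,
`delta = 1e-4`. Series are mean-centered internally for conditioning but
not rescaled: pitch is O(10^3) Hz and variances O(10^2) Hz^2, which is
benign in double precision, whereas rescaling to O(1) would push
variances toward the fixed `G = 1e-4 Hz^2` and worsen conditioning.
Parameters are reported in Hz.

## Diagnostics

**MAI profile.** Mutual information between a series and its lag-k copy
at 50 log-spaced integer lags in [1, 1000] (deduplicated; lags beyond T/2
dropped). Estimator: plug-in MI on an equal-frequency 2-D histogram of
rank-transformed data with `ceil(T^(1/3))` bins per axis — invariant to
monotone transforms; the surrogate normalization below makes downstream
conclusions robust to the estimator choice (which is why no kNN/kernel
estimator is offered by default). Reference level: mean MAI of 3 iid
Gaussian surrogates of the same length, pooled over lags (this pooled
level is the zero of the normalized profile; one maps to the anchor
series' raw lag-1 MAI). The *whiteness band* instead compares each lag to
the per-lag surrogate mean — the estimator's bias grows with lag as the
effective sample size T - k shrinks, and the per-lag reference shares it —
using 8 surrogates so the 3-SD band has a low family-wise false-alarm
rate over ~50 lags (measured ~5% on iid fixtures).

**Self-consistency battery** (`self_consistency_check`): whiteness band
AND Jarque-Bera normality (p >= 1e-3). The two probes are complementary:
no lag statistic can detect a non-Gaussian *marginal* on an iid series
(the MAI of iid draws sits at the white-noise level regardless of the
marginal — verified here out to kurtosis ~60), while volatility drift is
invisible to a marginal test at matched variance. Non-iid fixtures fail
the band (max |z| ~ 8-11); non-Gaussian fixtures fail normality.

**Other metrics.** MS2D: per day, the bias is linearly resampled to 1000
uniform points; the mean squared second difference is averaged over days
(days with < 3 renditions skipped). Smoothed RMSE: RMS difference of
50-rendition running means. Normalized final pitch: mean pitch of the
last feedback day mapped to 0 at the first-day threshold and 1 at the
last-day threshold. d': Cohen's d with pooled SD (the convention chosen
here; a baseline-SD-only variant is a one-line change). Autocorrelation:
biased sample estimator, lag 0 = 1.

## Generative simulator

`simulate_experiment` runs the full closed loop: schedule, repertoire,
learner, threshold policy, hit determination, reward. The synthetic-bird
defaults define the study conditions:

* `p* = 1000 Hz`, `sigma_eps = 10 Hz` (1% of p*), `alpha = 0.003`,
  `delta = 3e-4` — the scale of fitted birds; `sigma_eta^2 = 0.01 Hz^2`
  (the bias noise is an estimation device and is kept small);
* colored drift `tau = 0.01`, innovation variance 0.46 Hz^2 (stationary
  SD ~4.8 Hz); circadian coefficients an inverted U with evening decline
  (SD ~4 Hz); history offsets falling from +6 Hz (first motif of a bout)
  to -4.5 Hz, so exploration is ~60-70% of baseline pitch variance and
  the three fluctuation components split the rest roughly evenly;
* singing schedule: 300-1500 renditions/day in bouts of 1 + Poisson(1.5)
  motifs (max 6) ~0.7 s apart, bout onsets Beta(1.3, 2.0)-distributed
  over a 14-h day (morning-heavy), so 2-s history counts span 0-4;
* the bias is held at zero during baseline days (the reward-free model
  has no bias; its noise engages at feedback onset);
* the `feedback` preset uses 4 baseline + 18 feedback days, ~20,000
  renditions total — the recovery-study scale; unit tests use smaller
  birds (2 + 3 days) purely as fixture sizes.

Threshold policies: `daily_quantile(q)` (q-quantile of the previous day's
pitches, held all day — the experimenters' daily protocol),
`running_median(20)` (recomputed every rendition), `fixed`, and
`human_auto` (running median re-engaged when the escape rate over the
last 20 renditions leaves [0.05, 0.80]). Quantiles use linear
interpolation. Falsification presets replace the exploration stream:
`non_gaussian_exploration` is an iid scale mixture (10% of renditions at
5x SD, variance-matched; kurtosis ~16) and `non_iid_exploration` a
stochastic-volatility stream (log-SD an AR(0.97) with stationary SD 0.6,
variance-matched). `lesion_pair` re-simulates the bird with the
exploration channel deleted.

What the generator does *not* emulate: multi-timescale or non-stationary
drift, bout-level random effects beyond the count-indexed offset,
overnight consolidation, WN acoustics, or social-context modulation.
Consequences are visible in the model-comparison results: on this exactly
latent-RL world the classical fit's MLE is a well-behaved whitener of the
single AR(1) drift, so of the three qualitative contrasts reported for
real birds only the bias-smoothness gap (classical MS2D ~10-20x the
latent fit's) reproduces robustly; the classical lag-1-MAI excess and the
classical simulation's final-pitch undershoot are driven by repertoire
structure richer than the generator's and do not emerge here. Passing
tests therefore certify the estimation machinery and the logic of the
diagnostics, not that real repertoires are as simple as the simulated
ones.

## Design choices in open territory

* **Feedback-system inputs.** The construction uses
  `u_t = [m_t, m_{t-1}]` with `m = p* + d + o` deterministic from the
  frozen repertoire; this is the only internally consistent linear
  realization of the bias update's `eps_{t-1} = (x_{t-1})_3 - u_t(2)`.
* **Step-test proportions.** `r_A = nD_WN / n_D` (fraction of detected
  steps preceded by WN within 20 renditions) vs. `r_C = nWN / T`
  (fraction of renditions so preceded), pooled Z with variance
  `r(1-r)(1/T + 1/n_D)` — the standard two-proportion test matching the
  pooled rate and variance structure.
* **Step removal** shifts all renditions from the step index onward by
  the *signed* size `left mean - right mean`, which cancels the jump
  (an absolute-size shift would double upward steps); per iteration only
  the single largest step is removed, which resolves clusters of
  super-threshold indices naturally; magnitude ties break to the earliest
  index. Window conventions: left `[i-n_s, i)`, right `[i, i+n_s)`,
  local `[i-n_s, i+n_s]` (2 n_s + 1 renditions, taken literally).
* **History-count range** is `{0, ..., N_h - 1}` with offset index
  `1 + n_h(t)`, so the first motif of a bout (count 0) is representable;
  subjects that never reach the ceiling get `N_h = max count + 1`.
* **Equal-count circadian nodes** are exact order-statistic cuts of the
  pooled time-of-day values (counts differ by at most 1); an equal-width
  alternative is not provided since results are insensitive to binning.
* **Contingency reversals** are not handled inside one fit; fit each
  contiguous contingency block separately.
* **Overnight gaps**: both the colored-noise and the bias recursions run
  per rendition with no overnight rescaling.

## Known limitations

* `alpha` and `delta` are identified only through the within/across-day
  relaxation of the bias, so their estimates carry a heavy-tailed spread:
  at ~20,000 renditions the two-stage fit recovers `alpha` within a
  factor of 2 on ~85-90% of synthetic birds, with a ~1.4x median upward
  inflation traceable to baseline-stage estimation noise propagating
  through the frozen repertoire (fits with the true repertoire frozen
  recover `alpha` at 1.1-1.4x). `sigma_eps` (within ~1-2%) and the
  exploration fraction (within ~0.01) are far better determined.
* `tau`'s MLE is intrinsically noisy when the drift SD is half the
  exploration SD (30-70% relative error at T ~ 5000).
* `sigma_eta^2` is reported but its recovery is not asserted; at small
  `delta` it is barely identifiable from the exploration variance.
* The daily-threshold policies interact with learning speed: at the
  generator's singing rates a bird climbs ~0.5 within-day SDs per day, so
  the previous-day median realizes a hit rate near 0.3 while the
  80th-percentile policy lands near the 1/2 optimum; the clean
  policy-ordering prediction (median faster than 80th percentile) is
  realized against the continuously tracking median, which holds the hit
  rate at 1/2 by construction.
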