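# Methods

This note records the models implemented, the defaults and why they were
chosen, the numerical decisions, and what the synthetic-data tests do and do
not establish.

## Empirical mode decomposition and sifting

EMD represents a series as a sum of intrinsic mode functions (IMFs) plus a
residue. A candidate is an IMF when (i) its number of zero crossings and
number of local extrema differ by at most one, and (ii) its mean envelope —
the midpoint of natural cubic splines through the local maxima and minima —
is negligible. Condition (ii) is operationalized as
max|mean envelope| ≤ `envelope_tolerance` × half the peak-to-peak amplitude,
with `envelope_tolerance = 0.05`.

Sifting subtracts the mean envelope repeatedly. The stop rule is an
S-number rule: the candidate is accepted once the two conditions have held
at `s_number = 2` consecutive checks (checks happen before each sift, so a
candidate that already qualifies is returned untouched — sifting is a fixed
point on true IMFs), with a hard cap of `max_sifts = 10` per IMF. The cap
bounds runtime; hitting it is routine on noisy ensemble members and is
logged at debug level. Decomposition stops when the remainder has fewer
than two maxima or two minima (a constant or trend residue); a dyadic bound
of log2(n)+1 modes guards against pathological inputs.

Extrema are interior strict extrema; a plateau (run of equal values flanked
by lower/higher values) counts once, at the run's midpoint sample with left
bias — a deterministic tie-break.

## The mirror endpoint condition

Cubic-spline envelopes diverge near the series ends, where extrema are
undefined; the error then propagates inward with every sift. The mirror
method adds one reflected extremum beyond each end: at the start, if the
first interior extremum is a maximum at position p_M and the next extremum
is a minimum (p_m, v_m), a minimum is prepended at 2·p_M − p_m with value
v_m (roles swap when the first extremum is a minimum), and symmetrically at
the end. The mirrored points serve as the spline boundary knots. A
clamped-endpoint baseline (series endpoints join both extrema lists) is
kept for comparison — on pure sines the mirror rule's boundary error is
consistently no worse, and typically far smaller, than the baseline's
(measured on the outer 10% of samples). With fewer than one interior
maximum or minimum the code falls back to the clamped rule with a warning.

## Ensemble EMD

EEMD decomposes `ensemble_size` (NE, default 100) copies of the series,
each perturbed with independent Gaussian white noise of standard deviation
`noise_scale` × std(series) (default 0.05; an absolute-units mode exists
because conventions differ — the fraction-of-std reading is the standard
one), and averages the k-th IMF across members. Members with fewer modes
are padded with zero components so the ensemble mean still reconstructs the
mean perturbed signal. Member l draws from an independent child stream of
the master seed, so results are reproducible and independent of execution
order.

Because each member decomposition conserves its input exactly, the
ensemble reconstruction error equals the across-member mean of the added
noise: its RMS sits at noise·std/√NE (verified numerically), while its
pointwise maximum over n samples carries the usual √(2 ln n)
order-statistics factor on top. Averaged EEMD modes are *not* strict IMFs:
members split modes differently, and averaging breaks the extrema/
zero-crossing balance (the observation that motivates the complementary
CEEMDAN family, which is out of scope here). Sifted (single-member) IMFs do
satisfy the count condition on the interior 90% of samples; frequency
ordering (non-increasing zero-crossing count in k) holds for both EMD and
EEMD output.

## Individual forecasters

All three are one-step-ahead and strictly causal; over a held-out window
they run open loop (true lagged values fed in). Inputs to the two networks
are standardized with training-window mean and std (bandwidths and weight
training are scale-sensitive) and predictions de-standardized.

**Exponential smoothing.** x̂_{t+1} = αx_t + (1−α)x̂_t with x̂_1 = x_1.
α is chosen by in-sample one-step SSE over the grid {0.01, …, 0.99} (ties
to the smallest value — the less reactive model). α = 1 reproduces the
naive forecast exactly, a useful oracle identity.

**GRNN.** A general regression neural network is Gaussian-kernel (Nadaraya–
Watson) regression: pattern weights p_i = exp(−‖X − X_i‖²/2σ²) over the
training lag vectors, output = (Σ p_i w_i)/(Σ p_i), a convex combination of
training targets w_i. (The transposed ratio Σp/Σpw is also exposed for
comparison but is not a convex combination and is not used.) The regressor
is a lag embedding of length `grnn_lag = 5` — one working week of daily
context; σ is chosen by leave-one-out one-step SSE over a geometric grid on
the standardized scale. Kernel weights are computed with the minimum
squared distance shifted out, so the σ → 0 limit is exactly the nearest-
neighbour predictor rather than an underflow.

**NARNN.** y_t = f(y_{t−1}, …, y_{t−d}) with a single hidden layer
(`narnn_hidden = 10` tanh units, linear output), `narnn_delay = 5`. Weights
are trained by L-BFGS on mean squared error with a 1e−6 ridge term for
conditioning; the chronologically last 15% of embedding rows are a
validation split, and the parameters kept are those with the lowest
validation error along the optimization path (early stopping). Training is
deterministic given the seed. The delay/width defaults are conventional
small-network choices for sub-series of daily data, configurable and logged
in the run manifest; nothing in the method prescribes them.

## Forecast combination

Given m model forecasts x_it of x_t with errors e_it = x_t − x_it, the
fixed-weight optimal combination solves

    min_w Σ_t (Σ_i w_i e_it)²  s.t. Σ_i w_i = 1, w_i ≥ 0,

a convex QP over the probability simplex; the equal-weight special case is
the simple arithmetic mean (SAM). The IOWA combination re-ranks the model
forecasts at every t by realized accuracy a_it = 1 − |x_t − x_it|/x_t
(clipped to 0 at relative error ≥ 1) and solves the same program on the
rank-ordered error columns, so weights attach to accuracy ranks ("how much
to trust the locally best model") rather than to fixed models. Because at
a fixed t the accuracy ordering over models coincides with the ascending
|e_it| ordering, the rank ordering extends to non-positive series (IMFs
oscillate around zero) by sorting on absolute error; this is identical on
positive data except inside the zero-accuracy tie group, where ties fall
back to model index either way.

The QP is solved by an exact active-set method on the KKT system (drop the
most negative weight, release fixed weights with negative reduced cost),
with an SLSQP fallback for degenerate Gram matrices; a brute-force simplex
grid search is kept as an independent oracle for m ≤ 4 and the two agree to
1e−4 in objective on random panels. Solutions satisfy Σw = 1 to 1e−10 with
negatives clipped at 0. Equal weights on the re-ranked columns reproduce
SAM exactly (the mean is permutation-invariant), so the IOWA optimum
dominates SAM in training SSE per component by construction.

Applying rank weights out of sample needs an ordering rule. Two modes are
provided: `ex_post` re-ranks by realized test-window accuracies (the usual
way these combinations are evaluated in-literature; it uses the actuals
being forecast and therefore overstates deployable accuracy), and `ex_ante`
fixes the ordering to the mean training-window accuracy ranking (honest,
deployable). `ex_post` is the default for reproduction; the mode is
recorded in the run manifest.

## Pipeline

The hybrid run decomposes once, forecasts every IMF and the residue with
each individual model, fits one IOWA weight vector per component on the
training window, combines per component, and sums components into the
series-level forecast — additive recombination is exact by construction.
Eight variants are produced: ES, GRNN, NARNN on the raw series, their
decomposition-ensemble counterparts (summed per-component forecasts), the
equal-weight EEMD-MM-SAM and the proposed EEMD-MM-CFM. All variants share
the same decomposition object, so differences are attributable to
forecasting and combination alone. Per-component IOWA-vs-SAM training
dominance is guaranteed; the aggregated (summed-component) dominance is not
a theorem because cross-component error terms interact, but it held on all
seeded synthetic runs checked (20 seeds at reduced scale).

By default the decomposition sees the full series before the split,
matching the common evaluation protocol for decomposition-ensemble models
but leaking test-window information into the components.
`decompose_train_only=True` decomposes the training window only; test
components then do not exist, so their forecasts are extended recursively
(closed loop: each model feeds on its own predictions — ES goes flat,
networks iterate). The forecaster APIs themselves stay one-step-ahead; the
recursion is a pipeline-level device for the honest mode and is off by
default.

## Evaluation

SSE, MAE, MAPE and RMSE are the standard definitions (RMSE = √(SSE/N); MAPE
needs nonzero actuals). Mean mode accuracy (MMA) scores by health-warning
class: the fraction of days on which the forecast falls in the same AQI
class as the observation, using the six-class national breakpoint scheme on
half-open intervals (0,50] Excellent, (50,100] Good, (100,150] Light,
(150,200] Moderate, (200,300] Serious, (300,∞) Heavy — forecasts, though
real-valued, are classified on the same intervals. The improvement rate is
IR = (RMSE_benchmark − RMSE_proposed)/RMSE_benchmark, positive when the
proposed model improves.

The Diebold–Mariano test uses squared loss, g_t = (x_t − x_At)² −
(x_t − x_Bt)², long-run variance γ₀ + 2Σ_{k≤lag} γ_k from sample
autocovariances with truncation lag 0 by default (appropriate for one-step
forecasts, configurable), no small-sample correction, and a one-sided
lower-tail normal p-value: a negative statistic with small p says the
target model A beats benchmark B. (Some published tables report two-sided
p-values for the same statistic; the one-sided orientation is the stated
convention here.) Degenerate cases — identical forecasts, constant loss
differential, non-positive variance — are errors, not numbers. Type-I
calibration and power are verified by Monte Carlo in the test suite.

## Synthetic data

`gen_series` emulates what daily AQI records look like: level + slight
trend + annual and weekly sinusoids with seeded phases + AR(1) noise
(coefficient 0.5 — autocorrelated, so the decomposition yields several
meaningful fast modes rather than one white-noise mode), clipped at a small
positive floor. Defaults (level 100, slope −0.01/day, amplitudes 40 and 6,
innovation scale 10, n = 896) keep values in the realistic urban range of
roughly 20–280. `gen_panel` builds forecast panels with exactly controlled
error variances and cross-correlations around a smooth positive unit-scale
truth, which is what weight-recovery and test-calibration checks need; its
default 10% error scale is a realistic relative forecast error.

What the synthetic tests establish: exact reconstruction, noise
cancellation at the 1/√NE rate, correct tone separation, boundary-error
superiority of the mirror rule, QP optimality, combination dominance, DM
calibration, and end-to-end determinism. What they do not establish:
forecast accuracy on real AQI data — real series have regime changes,
heteroskedasticity, holiday effects and measurement artifacts that the
generator deliberately omits, and the default evaluation protocol shares
the full-series decomposition caveat above.

## Numerical choices and scales

- Splines: natural cubic through the extended extrema (`scipy` CubicSpline);
  evaluation beyond the outermost knot is the spline's natural
  extrapolation.
- Zero crossings count sign changes ignoring exact zeros.
- Reconstruction tolerance 1e−8 for plain EMD (telescoping conservation);
  sift conservation is the defining identity remainder = input − imf.
- Test and acceptance problem sizes — 512-point tone mixtures, 256-point
  series with NE = 8 for pipeline properties, one full-scale 896-point /
  NE = 100 run — were chosen to make the whole suite run in a few minutes
  on a single CPU while still exercising every stage at realistic scale.
- Seeds: one master seed per run; ensemble members and per-component
  network fits use derived child streams, so no result depends on
  execution order.

## Known limitations

- No complementary-ensemble variants (CEEMD/CEEMDAN) and no Hilbert
  spectrum; the decomposition is used for forecasting only.
- One weight vector per component, fitted once on the training window; no
  rolling re-estimation.
- Multi-step-ahead forecasting exists only as the honest mode's closed-loop
  recursion; there is no multi-horizon API.
- The GRNN stores all training patterns; cost is O(n²) in the bandwidth
  search and O(n) per prediction — fine at daily scale, not for long
  high-frequency series.
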