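# emdcombine

Hybrid decomposition–ensemble forecasting for positive, multi-scale time
series such as daily air quality index (AQI) records.

Air quality series mix slow seasonal structure with bursty high-frequency
variation, which defeats single-model forecasters. `emdcombine` implements a
hybrid scheme for one-step-ahead forecasting of such series:

1. **Decompose** the series x_t by ensemble empirical mode decomposition
   (EEMD) into intrinsic mode functions (IMFs) c_t(k), k = 1..K, ordered
   fast to slow, plus a residue r_t. Envelope splines are anchored beyond
   both series ends by the **mirror method**: a boundary minimum is added by
   reflecting the first interior minimum about the first interior maximum
   (roles swapped as needed), and symmetrically at the end, which suppresses
   the end-effect distortion of cubic-spline envelopes.
2. **Forecast** every component one step ahead with three individual models:
   exponential smoothing (x̂_{t+1} = αx_t + (1−α)x̂_t), a general regression
   neural network (Gaussian-kernel regression on a lag embedding), and a
   nonlinear autoregressive network y_t = f(y_{t−1}, …, y_{t−d}).
3. **Combine** the per-component forecasts with the IOWA (induced ordered
   weighted averaging) optimal combination: at each time point the model
   forecasts are re-ranked by realized forecasting accuracy
   a_it = 1 − |x_t − x_it|/x_t (clipped at 0), and one convex weight vector
   w′ over accuracy ranks is fitted on the training window by the quadratic
   program min Σ_t (Σ_i w′_i e′_it)² s.t. Σw′_i = 1, w′ ≥ 0.
4. **Recombine** additively: the series-level forecast is the sum of the
   per-component combined forecasts.
5. **Evaluate** against seven benchmarks (the raw individual models, the
   decomposition-ensemble individual models, and the equal-weight
   combination) with SSE/MAE/MAPE/RMSE, class-based mean mode accuracy
   (MMA), Pearson correlation, one-sided Diebold–Mariano tests and RMSE
   improvement rates.

Audience: forecasters and environmental-data analysts who want a tested,
reproducible reference implementation of decomposition-ensemble combination
forecasting, with a synthetic-data generator so every stage is verifiable
offline.

## Worked example

```python
from emdcombine import HybridForecaster, RunConfig, SiftConfig, SynthSpec, gen_series

series = gen_series(SynthSpec(n=896, seed=5))      # synthetic daily AQI
cfg = RunConfig(sift=SiftConfig(ensemble_size=100, noise_scale=0.05),
                test_length=30, seed=42)
res = HybridForecaster(series, cfg).fit()
print(res.summary())
```

prints (abridged):

```
Hybrid decomposition-ensemble forecast
======================================================
series length        896  (train 866, test 30)
decomposition        EEMD, NE=100, noise=0.05 (relative), mirror endpoints
modes                7 IMFs + residue
combination          IOWA optimal, ex_post
seed                 42

variant              RMSE      MAE     MAPE    MMA       R
----------------------------------------------------------
ES                 12.936   10.240   0.0801   0.93  0.4603
NARNN              12.505    9.988   0.0777   0.93  0.4173
EEMD-MM-NARNN       8.852    7.219   0.0568   0.97  0.7789
EEMD-MM-SAM         8.683    6.615   0.0509   0.97  0.7870
EEMD-MM-CFM         5.057    3.965   0.0319   0.97  0.9217
```

Reading the table: decomposing before forecasting roughly halves the test
RMSE of each individual model, and the IOWA optimal combination
(`EEMD-MM-CFM`) beats every benchmark — here a 42% RMSE improvement over the
equal-weight combination and test-window correlation 0.92.
`res.dm_matrix()`, `res.improvement_rates()` and `res.benchmark_table()`
give the full comparison; `res.save(outdir)` writes the decomposition,
forecasts, metrics and a run manifest.

The same pipeline is scriptable from a shell:

```bash
emdcombine simulate --n 896 --seed 5 --out series.csv
emdcombine decompose --input series.csv --ne 100 --noise 0.05 --seed 42 --out imfs.csv
emdcombine run --input series.csv --test-length 30 --seed 42 --out results/
```

## Caveats

By default the decomposition is computed on the full series before the
train/test split (the usual evaluation protocol for decomposition-ensemble
models, which leaks test-window information into the components);
`RunConfig(decompose_train_only=True)` or `emdcombine run --honest` gives
the leakage-free variant. See `docs/methods.md` for the model details,
defaults and limitations.
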