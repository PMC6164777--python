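"""End-to-end hybrid decomposition–ensemble forecasting.

:class:`HybridForecaster` wires the stages together the way the hybrid
method prescribes: (1) decompose the series by EEMD with the mirror endpoint
condition; (2) forecast every IMF and the residue one step ahead with each
individual model (ES, GRNN, NARNN); (3) per component, combine the model
forecasts by the simple arithmetic mean and by the IOWA optimal combination
fitted on the training window; (4) sum the per-component forecasts back into
series-level forecasts; (5) evaluate every variant on the held-out test
window.  Eight variants come out: the three raw individual models applied to
the undecomposed series, the three decomposition-ensemble individual models,
the equal-weight combination (EEMD-MM-SAM) and the IOWA optimal combination
(EEMD-MM-CFM).

By default the decomposition runs on the full series before splitting, which
mirrors how decomposition-ensemble studies are usually evaluated but leaks
test-window information into the components; ``decompose_train_only=True``
restricts the decomposition to the training window and extends the component
forecasts recursively (closed loop) over the test window instead.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import combiner as cb
from . import decomposition as dc
from . import evaluation as ev
from . import forecasters as fc
from .io import (
    CHINA_AQI_SCHEME,
    CombWeights,
    Decomposition,
    ForecastPanel,
    MetricsReport,
    SeriesSample,
    write_decomposition,
    write_metrics,
)

__all__ = [
    "RunConfig",
    "HybridForecaster",
    "HybridResults",
    "run_hybrid",
    "benchmark_suite",
    "VARIANTS",
]

INDIVIDUAL_MODELS = ["ES", "GRNN", "NARNN"]
VARIANTS = [
    "ES",
    "GRNN",
    "NARNN",
    "EEMD-MM-ES",
    "EEMD-MM-GRNN",
    "EEMD-MM-NARNN",
    "EEMD-MM-SAM",
    "EEMD-MM-CFM",
]


@dataclass
class RunConfig:
    """Everything one hybrid run depends on; serializes losslessly to JSON."""

    sift: dc.SiftConfig = field(default_factory=dc.SiftConfig)
    es_alpha_grid: list[float] | None = None
    grnn_lag: int = 5
    grnn_sigma_grid: list[float] | None = None
    narnn_delay: int = 5
    narnn_hidden: int = 10
    narnn_max_iter: int = 300
    combine_mode: str = "ex_post"  # "ex_post" | "ex_ante"
    test_length: int = 30
    decompose_train_only: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.combine_mode not in ("ex_post", "ex_ante"):
            raise ValueError(f"unknown combine_mode {self.combine_mode!r}")
        if isinstance(self.sift, dict):
            self.sift = dc.SiftConfig(**self.sift)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# per-component forecasting helpers


def _component_seeds(master: int, count: int) -> np.ndarray:
    """Deterministic per-component NARNN seeds derived from the master."""
    return np.random.SeedSequence(master).generate_state(count) % (2**31)


def _open_loop_forecasts(
    values: np.ndarray, split: int, warmup: int, cfg: RunConfig, narnn_seed: int
) -> np.ndarray:
    """Fit the three models on ``values[:split]`` and return their open-loop
    one-step forecasts at positions ``warmup .. N-1`` (columns ES, GRNN,
    NARNN)."""
    n = values.size
    pos = np.arange(warmup, n)

    es_model = fc.es_select_alpha(
        values[:split],
        None if cfg.es_alpha_grid is None else np.asarray(cfg.es_alpha_grid),
    )
    es_all = fc.es_forecast(values, es_model)  # forecast of position p at [p-1]
    es_col = es_all[pos - 1]

    grnn_model = fc.grnn_fit(
        values[:split],
        lag=cfg.grnn_lag,
        sigma_grid=None
        if cfg.grnn_sigma_grid is None
        else np.asarray(cfg.grnn_sigma_grid),
    )
    grnn_all = fc.grnn_forecast(grnn_model, values)  # positions lag..N-1
    grnn_col = grnn_all[pos - cfg.grnn_lag]

    narnn_model = fc.narnn_fit(
        values[:split],
        d=cfg.narnn_delay,
        hidden_units=cfg.narnn_hidden,
        seed=int(narnn_seed),
        max_iter=cfg.narnn_max_iter,
    )
    narnn_all = fc.narnn_forecast(narnn_model, values)  # positions d..N-1
    narnn_col = narnn_all[pos - cfg.narnn_delay]

    return np.column_stack([es_col, grnn_col, narnn_col])


def _closed_loop_forecasts(
    train_values: np.ndarray, horizon: int, warmup: int, cfg: RunConfig,
    narnn_seed: int,
) -> np.ndarray:
    """Honest-mode variant of :func:`_open_loop_forecasts`: open loop over
    the training window, recursive (model-fed) beyond it for ``horizon``
    steps."""
    split = train_values.size
    open_part = _open_loop_forecasts(
        train_values, split, warmup, cfg, narnn_seed
    )  # positions warmup..split-1

    es_model = fc.es_select_alpha(
        train_values,
        None if cfg.es_alpha_grid is None else np.asarray(cfg.es_alpha_grid),
    )
    es_level = fc.es_forecast(train_values, es_model)[-1]
    es_future = np.full(horizon, es_level)  # ES recursion on its own output is flat

    grnn_model = fc.grnn_fit(
        train_values,
        lag=cfg.grnn_lag,
        sigma_grid=None
        if cfg.grnn_sigma_grid is None
        else np.asarray(cfg.grnn_sigma_grid),
    )
    narnn_model = fc.narnn_fit(
        train_values,
        d=cfg.narnn_delay,
        hidden_units=cfg.narnn_hidden,
        seed=int(narnn_seed),
        max_iter=cfg.narnn_max_iter,
    )
    grnn_buf = list(train_values[-cfg.grnn_lag:])
    narnn_buf = list(train_values[-cfg.narnn_delay:])
    grnn_future, narnn_future = [], []
    for _ in range(horizon):
        g = float(fc.grnn_predict(grnn_model, np.array(grnn_buf)))
        grnn_future.append(g)
        grnn_buf = grnn_buf[1:] + [g]
        nrow = fc.narnn_forecast(narnn_model, np.array(narnn_buf + [0.0]))[-1]
        narnn_future.append(float(nrow))
        narnn_buf = narnn_buf[1:] + [float(nrow)]
    future = np.column_stack([es_future, grnn_future, narnn_future])
    return np.vstack([open_part, future])


# ---------------------------------------------------------------------------
# model / results


class HybridForecaster:
    """Decomposition-ensemble combined forecasting model for one series.

    Parameters
    ----------
    series : SeriesSample
        The full series; the final ``config.test_length`` points are held
        out for evaluation.
    config : RunConfig
        All decomposition, forecaster and combination settings.
    """

    def __init__(self, series: SeriesSample, config: RunConfig | None = None):
        self.series = series
        self.config = config or RunConfig()
        if not 0 < self.config.test_length < len(series):
            raise ValueError("test_length must be in (0, len(series))")
        warmup = max(1, self.config.grnn_lag, self.config.narnn_delay)
        split = len(series) - self.config.test_length
        if split <= warmup + self.config.narnn_hidden + 2:
            raise ValueError("training window too short for the forecasters")
        self._warmup = warmup
        self._split = split

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        value_column: str,
        date_column: str | None = None,
        config: RunConfig | None = None,
    ) -> "HybridForecaster":
        times = (
            np.arange(len(df)) if date_column is None else df[date_column].to_numpy()
        )
        sample = SeriesSample(times, df[value_column].to_numpy(float), value_column)
        return cls(sample, config)

    # -- stages ------------------------------------------------------------

    def _decompose(self) -> Decomposition:
        cfg = dataclasses.replace(self.config.sift, seed=self.config.seed)
        target = (
            self.series.values[: self._split]
            if self.config.decompose_train_only
            else self.series.values
        )
        return dc.eemd(target, cfg)

    def fit(self) -> "HybridResults":
        """Run all five stages and return the fitted results object."""
        cfg = self.config
        x = self.series.values
        n, split, warmup = x.size, self._split, self._warmup
        pos = np.arange(warmup, n)
        train_rows = pos < split

        decomp = self._decompose()
        components = decomp.components
        seeds = _component_seeds(cfg.seed, len(components) + 1)

        # stage 2: per-component individual forecasts
        comp_panels: list[ForecastPanel] = []
        for k, comp in enumerate(components):
            if cfg.decompose_train_only:
                mat = _closed_loop_forecasts(
                    comp, cfg.test_length, warmup, cfg, seeds[k]
                )
                actual = np.concatenate([comp[warmup:], np.full(cfg.test_length, np.nan)])
            else:
                mat = _open_loop_forecasts(comp, split, warmup, cfg, seeds[k])
                actual = comp[warmup:]
            comp_panels.append(
                ForecastPanel(actual, mat, model_labels=list(INDIVIDUAL_MODELS))
            )

        # stage 3: per-component combination
        comp_weights: list[CombWeights] = []
        comp_sam = np.zeros((pos.size, len(components)))
        comp_cfm = np.zeros((pos.size, len(components)))
        for k, panel in enumerate(comp_panels):
            train_panel = panel.subset(train_rows)
            w = cb.optimal_weights_iowa(train_panel)
            comp_weights.append(w)
            comp_sam[:, k] = cb.sam_combine(panel)
            if cfg.decompose_train_only or cfg.combine_mode == "ex_ante":
                order = np.argsort(
                    np.abs(train_panel.errors).mean(axis=0), kind="stable"
                )
                comp_cfm[:, k] = cb.combine(
                    panel, w, mode="ex_ante", model_order=order
                )
            else:
                comp_cfm[:, k] = cb.combine(panel, w, mode="ex_post")

        # stage 4: sum components (and fit the raw baselines)
        raw = _open_loop_forecasts(x, split, warmup, cfg, seeds[-1])
        variant_fc = {
            "ES": raw[:, 0],
            "GRNN": raw[:, 1],
            "NARNN": raw[:, 2],
        }
        for j, name in enumerate(INDIVIDUAL_MODELS):
            variant_fc[f"EEMD-MM-{name}"] = np.sum(
                [p.forecasts[:, j] for p in comp_panels], axis=0
            )
        variant_fc["EEMD-MM-SAM"] = comp_sam.sum(axis=1)
        variant_fc["EEMD-MM-CFM"] = comp_cfm.sum(axis=1)

        return HybridResults(
            model=self,
            decomposition=decomp,
            component_panels=comp_panels,
            component_weights=comp_weights,
            component_sam=comp_sam,
            component_cfm=comp_cfm,
            positions=pos,
            variant_forecasts=variant_fc,
        )


@dataclass
class HybridResults:
    """Fitted output of :class:`HybridForecaster`.

    Holds the decomposition, the per-component forecast panels and
    combination weights, and the eight series-level forecast variants,
    together with evaluation helpers over the test window.
    """

    model: HybridForecaster
    decomposition: Decomposition
    component_panels: list[ForecastPanel]
    component_weights: list[CombWeights]
    component_sam: np.ndarray
    component_cfm: np.ndarray
    positions: np.ndarray
    variant_forecasts: dict[str, np.ndarray]

    # -- window helpers ----------------------------------------------------

    @property
    def config(self) -> RunConfig:
        return self.model.config

    @property
    def _test_rows(self) -> np.ndarray:
        return self.positions >= self.model._split

    @property
    def _train_rows(self) -> np.ndarray:
        return self.positions < self.model._split

    @property
    def actual(self) -> np.ndarray:
        return self.model.series.values[self.positions]

    def test_forecast(self, variant: str) -> np.ndarray:
        return self.variant_forecasts[variant][self._test_rows]

    @property
    def test_actual(self) -> np.ndarray:
        return self.actual[self._test_rows]

    def train_sse(self, variant: str) -> float:
        err = (self.actual - self.variant_forecasts[variant])[self._train_rows]
        return float(np.sum(err**2))

    # -- evaluation --------------------------------------------------------

    def metrics(self, scheme=CHINA_AQI_SCHEME) -> dict[str, MetricsReport]:
        """Test-window metric reports for every variant."""
        out = {}
        for name in VARIANTS:
            out[name] = ev.metrics_report(
                self.test_actual, self.test_forecast(name), scheme
            )
        return out

    def dm_matrix(self, lag_truncation: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Pairwise DM statistics and one-sided p-values (row = target A,
        column = benchmark B; negative favours the row model)."""
        stat = pd.DataFrame(np.nan, index=VARIANTS, columns=VARIANTS)
        pval = pd.DataFrame(np.nan, index=VARIANTS, columns=VARIANTS)
        for a in VARIANTS:
            for b in VARIANTS:
                if a == b:
                    continue
                try:
                    res = ev.dm_test(
                        self.test_actual,
                        self.test_forecast(a),
                        self.test_forecast(b),
                        lag_truncation,
                    )
                except ValueError:
                    continue
                stat.loc[a, b] = res.statistic
                pval.loc[a, b] = res.p_value
        return stat, pval

    def improvement_rates(self, proposed: str = "EEMD-MM-CFM") -> pd.Series:
        """IR of the proposed variant over every benchmark (positive =
        the proposed variant has the lower test RMSE)."""
        reps = self.metrics(scheme=None)
        rmse_p = reps[proposed].rmse
        return pd.Series(
            {
                name: ev.improvement_rate(rmse_p, reps[name].rmse)
                for name in VARIANTS
            },
            name=f"IR vs {proposed}",
        )

    def benchmark_table(self) -> pd.DataFrame:
        """Long-format (variant, metric, value) comparison table."""
        rows = []
        for name, rep in self.metrics().items():
            for metric in ("sse", "mae", "mape", "rmse", "mma", "r"):
                rows.append(
                    {"variant": name, "metric": metric, "value": getattr(rep, metric)}
                )
        return pd.DataFrame(rows)

    def forecasts_frame(self) -> pd.DataFrame:
        data = {
            "t": self.positions,
            "window": np.where(self._test_rows, "test", "train"),
            "actual": self.actual,
        }
        for name in VARIANTS:
            data[name] = self.variant_forecasts[name]
        return pd.DataFrame(data)

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text summary of the run and the test-window comparison."""
        cfg = self.config
        lines = [
            "Hybrid decomposition-ensemble forecast",
            "=" * 54,
            f"series length        {len(self.model.series)}"
            f"  (train {self.model._split}, test {cfg.test_length})",
            f"decomposition        EEMD, NE={cfg.sift.ensemble_size}, "
            f"noise={cfg.sift.noise_scale} ({cfg.sift.noise_mode}), "
            f"{cfg.sift.extension} endpoints",
            f"modes                {self.decomposition.n_imfs} IMFs + residue",
            f"combination          IOWA optimal, {cfg.combine_mode}",
            f"seed                 {cfg.seed}",
            "",
            f"{'variant':<16}{'RMSE':>9}{'MAE':>9}{'MAPE':>9}"
            f"{'MMA':>7}{'R':>8}",
            "-" * 58,
        ]
        for name, rep in self.metrics().items():
            mma_s = "  -" if rep.mma is None else f"{rep.mma:5.2f}"
            r_s = "    -" if rep.r is None else f"{rep.r:8.4f}"
            lines.append(
                f"{name:<16}{rep.rmse:9.3f}{rep.mae:9.3f}{rep.mape:9.4f}"
                f"  {mma_s}{r_s}"
            )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> None:
        """Write imfs.csv, forecasts.csv, metrics.json, dm_matrix.csv and
        manifest.json under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_decomposition(self.decomposition, out / "imfs.csv")
        self.forecasts_frame().to_csv(out / "forecasts.csv", index=False)
        write_metrics(self.metrics(), out / "metrics.json")
        stat, pval = self.dm_matrix()
        stat.to_csv(out / "dm_matrix.csv")
        pval.to_csv(out / "dm_pvalues.csv")
        manifest = {
            "config": self.config.to_dict(),
            "series_name": self.model.series.name,
            "n_observations": len(self.model.series),
            "n_imfs": self.decomposition.n_imfs,
            "component_weights": [
                {"weights": w.weights.tolist(), "objective": w.objective}
                for w in self.component_weights
            ],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    def plot(self, ax=None):
        """Test-window actual vs the combined forecast (diagnostic plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 3))
        ax.plot(self.positions[self._test_rows], self.test_actual, label="actual")
        ax.plot(
            self.positions[self._test_rows],
            self.test_forecast("EEMD-MM-CFM"),
            label="EEMD-MM-CFM",
        )
        ax.set_xlabel("t")
        ax.set_ylabel(self.model.series.name)
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional wrappers


def run_hybrid(series: SeriesSample, config: RunConfig | None = None) -> HybridResults:
    """Fit the full hybrid pipeline; see :class:`HybridForecaster`."""
    return HybridForecaster(series, config).fit()


def benchmark_suite(
    series: SeriesSample, config: RunConfig | None = None
) -> dict[str, pd.DataFrame | pd.Series]:
    """All-variant comparison: long metric table, DM matrices and IRs."""
    res = run_hybrid(series, config)
    stat, pval = res.dm_matrix()
    return {
        "metrics": res.benchmark_table(),
        "dm_statistic": stat,
        "dm_pvalue": pval,
        "improvement_rate": res.improvement_rates(),
        "results": res,
    }
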