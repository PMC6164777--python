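"""Core domain types and CSV/JSON readers and writers.

All sample positions are 0-based integer indices into the series; time stamps
may be ISO-8601 calendar dates or plain integer ticks.  Missing values are a
hard error everywhere: the decomposition and the one-step forecasters assume a
complete, regularly sampled series.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SeriesSample",
    "Decomposition",
    "ExtremaSet",
    "EnvelopePair",
    "ForecastPanel",
    "CombWeights",
    "AQIClassScheme",
    "CHINA_AQI_SCHEME",
    "MetricsReport",
    "DMResult",
    "read_series",
    "write_series",
    "split_series",
    "read_decomposition",
    "write_decomposition",
    "write_metrics",
]


# ---------------------------------------------------------------------------
# series


@dataclass
class SeriesSample:
    """A univariate, regularly sampled time series.

    Parameters
    ----------
    times : ndarray
        Strictly increasing, regularly spaced time stamps (``datetime64`` or
        integer ticks).
    values : ndarray of float
        The observations.  Strict positivity is only *required* where a
        relative quantity (MAPE, accuracy index, AQI class) is computed;
        decomposition itself accepts any finite real series.
    name : str
        Label used in output columns.
    """

    times: np.ndarray
    values: np.ndarray
    name: str = "value"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D and equal length")
        if not np.all(np.isfinite(self.values)):
            bad = np.flatnonzero(~np.isfinite(self.values))
            raise ValueError(f"non-finite values at rows {bad.tolist()}")
        if len(self) > 1:
            steps = np.diff(self.times)
            if np.any(steps <= np.zeros(1, dtype=steps.dtype)):
                raise ValueError("times must be strictly increasing")
            if len(set(steps.tolist())) > 1:
                # irregular spacing is reported, not fatal: calendar data with
                # a missing day should be caught by the caller
                import warnings

                warnings.warn(
                    f"irregular time spacing in series '{self.name}'",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def is_positive(self) -> bool:
        return bool(np.all(self.values > 0))

    def require_positive(self) -> None:
        if not self.is_positive:
            bad = np.flatnonzero(self.values <= 0)
            raise ValueError(
                f"series '{self.name}' must be strictly positive; "
                f"non-positive at rows {bad.tolist()[:10]}"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.times, self.name: self.values})


def read_series(
    path: str | Path, date_column: str | int = 0, value_column: str | int = 1
) -> SeriesSample:
    """Read a two-column (date, value) CSV into a :class:`SeriesSample`.

    The header row is required.  Dates are parsed as ISO-8601 when possible,
    otherwise kept as integer ticks.  Missing or unparsable values raise with
    the offending 0-based data row numbers.
    """
    df = pd.read_csv(path)
    date_col = df.columns[date_column] if isinstance(date_column, int) else date_column
    value_col = (
        df.columns[value_column] if isinstance(value_column, int) else value_column
    )
    raw = pd.to_numeric(df[value_col], errors="coerce")
    if raw.isna().any():
        bad = np.flatnonzero(raw.isna().to_numpy())
        raise ValueError(f"missing or non-numeric values at rows {bad.tolist()}")
    dates = df[date_col]
    try:
        times = pd.to_datetime(dates, format="ISO8601").to_numpy()
    except (ValueError, TypeError):
        times = pd.to_numeric(dates).to_numpy()
    if len(times) > 1 and np.any(np.diff(times) <= np.zeros(1, np.diff(times).dtype)):
        raise ValueError("dates are not strictly increasing")
    return SeriesSample(times=times, values=raw.to_numpy(float), name=str(value_col))


def write_series(sample: SeriesSample, path: str | Path) -> None:
    sample.to_frame().to_csv(path, index=False)


def split_series(s: SeriesSample, test_length: int) -> tuple[SeriesSample, SeriesSample]:
    """Chronological train/test split; the test set is the final block."""
    if not 0 < test_length < len(s):
        raise ValueError(
            f"test_length must be in (0, {len(s)}), got {test_length}"
        )
    cut = len(s) - test_length
    train = SeriesSample(s.times[:cut], s.values[:cut], s.name)
    test = SeriesSample(s.times[cut:], s.values[cut:], s.name)
    return train, test


# ---------------------------------------------------------------------------
# decomposition containers


@dataclass
class Decomposition:
    """An ordered set of IMFs (highest frequency first) plus a residue."""

    imfs: list[np.ndarray]
    residue: np.ndarray
    ensemble_size: int = 1
    noise_scale: float = 0.0
    seed: int | None = None

    @property
    def n_imfs(self) -> int:
        return len(self.imfs)

    @property
    def components(self) -> list[np.ndarray]:
        """IMFs followed by the residue."""
        return [*self.imfs, self.residue]

    @property
    def component_labels(self) -> list[str]:
        return [f"imf{k + 1}" for k in range(self.n_imfs)] + ["residue"]

    def reconstruct(self) -> np.ndarray:
        out = self.residue.copy()
        for c in self.imfs:
            out = out + c
        return out

    def to_frame(self) -> pd.DataFrame:
        data = {"t": np.arange(len(self.residue))}
        for lab, comp in zip(self.component_labels, self.components):
            data[lab] = comp
        return pd.DataFrame(data)


def write_decomposition(d: Decomposition, path: str | Path) -> None:
    d.to_frame().to_csv(path, index=False)


def read_decomposition(path: str | Path) -> Decomposition:
    df = pd.read_csv(path)
    imf_cols = [c for c in df.columns if c.startswith("imf")]
    imf_cols.sort(key=lambda c: int(c[3:]))
    return Decomposition(
        imfs=[df[c].to_numpy(float) for c in imf_cols],
        residue=df["residue"].to_numpy(float),
    )


@dataclass
class ExtremaSet:
    """Interior local extrema of a series, in 0-based sample coordinates.

    After boundary extension the position arrays may contain indices outside
    ``[0, n-1]``; ``extended`` records that the set already carries the padded
    boundary extrema (making the extension idempotent).
    """

    max_positions: np.ndarray
    max_values: np.ndarray
    min_positions: np.ndarray
    min_values: np.ndarray
    extended: bool = False

    def __post_init__(self) -> None:
        self.max_positions = np.asarray(self.max_positions, dtype=float)
        self.max_values = np.asarray(self.max_values, dtype=float)
        self.min_positions = np.asarray(self.min_positions, dtype=float)
        self.min_values = np.asarray(self.min_values, dtype=float)
        for pos in (self.max_positions, self.min_positions):
            if pos.size > 1 and np.any(np.diff(pos) <= 0):
                raise ValueError("extrema positions must be strictly increasing")

    @property
    def n_max(self) -> int:
        return len(self.max_positions)

    @property
    def n_min(self) -> int:
        return len(self.min_positions)


@dataclass
class EnvelopePair:
    upper: np.ndarray
    lower: np.ndarray

    @property
    def mean(self) -> np.ndarray:
        return 0.5 * (self.upper + self.lower)


# ---------------------------------------------------------------------------
# forecast combination containers


@dataclass
class ForecastPanel:
    """Aligned actuals and per-model one-step forecasts over a window.

    ``errors`` is always ``actual - forecast`` (positive when the model under-
    predicts); ``accuracies`` follows the relative-accuracy index, defined only
    for strictly positive actuals.
    """

    actual: np.ndarray
    forecasts: np.ndarray  # shape (N, m)
    model_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.actual = np.asarray(self.actual, dtype=float)
        self.forecasts = np.atleast_2d(np.asarray(self.forecasts, dtype=float))
        if self.forecasts.shape[0] != self.actual.shape[0]:
            self.forecasts = self.forecasts.T
        if self.forecasts.shape[0] != self.actual.shape[0]:
            raise ValueError("forecasts must align with actual along time")
        if not self.model_labels:
            self.model_labels = [f"model{i + 1}" for i in range(self.n_models)]
        if len(self.model_labels) != self.n_models:
            raise ValueError("one label per forecast column required")

    @property
    def n_obs(self) -> int:
        return self.actual.shape[0]

    @property
    def n_models(self) -> int:
        return self.forecasts.shape[1]

    @property
    def errors(self) -> np.ndarray:
        return self.actual[:, None] - self.forecasts

    @property
    def accuracies(self) -> np.ndarray:
        from .combiner import accuracy_index

        return np.column_stack(
            [accuracy_index(self.actual, self.forecasts[:, i]) for i in range(self.n_models)]
        )

    def subset(self, idx: slice | np.ndarray) -> "ForecastPanel":
        return ForecastPanel(
            self.actual[idx], self.forecasts[idx], list(self.model_labels)
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"t": np.arange(self.n_obs), "actual": self.actual}
        for j, lab in enumerate(self.model_labels):
            data[lab] = self.forecasts[:, j]
        return pd.DataFrame(data)


@dataclass
class CombWeights:
    """Convex combination weights, either attached to models (``fixed``) or to
    per-time accuracy ranks (``accuracy_ordered``)."""

    weights: np.ndarray
    ordering: str = "fixed"  # "fixed" | "accuracy_ordered"
    objective: float = np.nan

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.ordering not in ("fixed", "accuracy_ordered"):
            raise ValueError(f"unknown ordering {self.ordering!r}")
        if np.any(self.weights < -1e-12):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-10:
            raise ValueError("weights must sum to 1")


# ---------------------------------------------------------------------------
# evaluation containers


@dataclass(frozen=True)
class AQIClassScheme:
    """Six ordered AQI classes on half-open intervals ``(lo, hi]``.

    The national scheme partitions (0, inf) as (0,50] Excellent, (50,100]
    Good, (100,150] Light pollution, (150,200] Moderate pollution, (200,300]
    Serious pollution and (300, inf) Heavy pollution.
    """

    upper_bounds: tuple[float, ...] = (50.0, 100.0, 150.0, 200.0, 300.0)
    labels: tuple[str, ...] = (
        "Excellent",
        "Good",
        "Light pollution",
        "Moderate pollution",
        "Serious pollution",
        "Heavy pollution",
    )

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.upper_bounds) + 1:
            raise ValueError("need exactly one more label than finite bound")
        if np.any(np.diff(self.upper_bounds) <= 0):
            raise ValueError("upper bounds must be strictly increasing")

    @property
    def n_classes(self) -> int:
        return len(self.labels)

    def classify(self, values: np.ndarray | float) -> np.ndarray | int:
        """Map positive values to class indices 1..6 (scalar in, scalar out)."""
        arr = np.asarray(values, dtype=float)
        if np.any(arr <= 0):
            raise ValueError("AQI class is undefined for non-positive values")
        idx = np.searchsorted(np.asarray(self.upper_bounds), arr, side="left") + 1
        return int(idx) if np.isscalar(values) else idx

    def label_of(self, value: float) -> str:
        return self.labels[self.classify(value) - 1]


CHINA_AQI_SCHEME = AQIClassScheme()


@dataclass
class DMResult:
    """One-sided Diebold–Mariano comparison of two forecasts under squared
    loss; a negative statistic favours the target model A."""

    statistic: float
    p_value: float
    lag_truncation: int
    n_obs: int
    mean_loss_diff: float


@dataclass
class MetricsReport:
    sse: float
    mae: float
    mape: float
    rmse: float
    mma: float | None = None
    r: float | None = None
    dm: dict[str, DMResult] = field(default_factory=dict)
    ir: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out


def write_metrics(reports: dict[str, MetricsReport], path: str | Path) -> None:
    payload = {name: rep.to_dict() for name, rep in reports.items()}
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
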