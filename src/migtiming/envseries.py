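"""Regular environmental logger series (10-min water temperature / level)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EnvSeries:
    """A regularly sampled environmental time series.

    Parameters
    ----------
    variable : str
        ``"temperature"`` (degC) or ``"level"`` (m).
    start : pd.Timestamp
        Timestamp of the first sample.
    values : np.ndarray
        Sample values on the regular grid.
    step_min : int
        Sampling interval in minutes (nominally 10).
    """

    variable: str
    start: pd.Timestamp
    values: np.ndarray
    step_min: int = 10

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-d array")
        if self.step_min <= 0:
            raise ValueError("step_min must be positive")
        if np.isnan(self.values).any():
            raise ValueError("environmental series contains NaN inside the analysis span")

    def __len__(self) -> int:
        return self.values.size

    @property
    def step_h(self) -> float:
        return self.step_min / 60.0

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(np.arange(len(self)) * self.step_min, unit="min")

    @property
    def end(self) -> pd.Timestamp:
        """Timestamp one step past the last sample (half-open span end)."""
        return self.start + pd.Timedelta(minutes=self.step_min * len(self))

    def hours_since_start(self, when: pd.Timestamp) -> float:
        return (pd.Timestamp(when) - self.start) / pd.Timedelta(hours=1)

    def to_frame(self) -> pd.DataFrame:
        col = "temperature_c" if self.variable == "temperature" else "level_m"
        return pd.DataFrame({"timestamp": self.times, col: self.values})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, variable: str) -> "EnvSeries":
        col = "temperature_c" if variable == "temperature" else "level_m"
        ts = pd.to_datetime(frame["timestamp"])
        if len(ts) < 2:
            raise ValueError("need at least two samples")
        steps = np.diff(ts.values).astype("timedelta64[s]").astype(float) / 60.0
        step = steps[0]
        if not np.allclose(steps, step):
            raise ValueError("irregular sampling: gaps detected in environmental series")
        return cls(variable=variable, start=ts.iloc[0], values=frame[col].to_numpy(),
                   step_min=int(round(step)))
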