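"""Hourly soil-profile series and period-24 seasonal differencing.

A soil monitoring station logs temperature (°C) and volumetric moisture (%)
on a strict one-hour grid at several depths.  Both variables carry a strong
diurnal cycle, so before any stochastic modelling each series is seasonally
differenced at period ``S`` (24 hours by default):

    y_t = (1 - B^S) x_t = x_t - x_{t-S}

which removes any pattern that repeats exactly daily.  The differenced
series is the modelling substrate for the stationarity tests, VAR fits,
impulse responses and Granger tests in the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta

import numpy as np

__all__ = [
    "HourlySeries",
    "DeseasonalizedSeries",
    "seasonal_difference",
    "align_pair",
    "SeriesError",
]

#: Instrument range for soil temperature probes, °C.
TEMPERATURE_RANGE = (-20.0, 60.0)
#: Physical range for volumetric moisture content, %.
MOISTURE_RANGE = (0.0, 100.0)

_VALID_VARIABLES = ("temperature", "moisture")


class SeriesError(ValueError):
    """Raised when a series violates the hourly-grid or range contracts.

    ``kind`` is a short machine-readable tag: ``"gap"``, ``"duplicate"``,
    ``"format"``, ``"too-short"``, ``"disjoint"``, ``"range"``.
    """

    def __init__(self, kind: str, message: str):
        self.kind = kind
        super().__init__(f"{kind}: {message}")


@dataclass(frozen=True)
class HourlySeries:
    """One variable (temperature or moisture) at one depth on an hourly grid.

    Parameters
    ----------
    variable : {"temperature", "moisture"}
        Physical quantity; temperature in °C, moisture in volumetric %.
    depth : int
        Sensor depth below the surface in cm (positive).
    start : datetime
        Timestamp of the first value, at hour resolution.
    values : ndarray
        Ordered observations at strict one-hour spacing.
    label : str
        Free-text identifier, e.g. ``"ST10"`` or ``"MC30"``.
    """

    variable: str
    depth: int
    start: datetime
    values: np.ndarray
    label: str = ""

    def __post_init__(self):
        if self.variable not in _VALID_VARIABLES:
            raise SeriesError("format", f"unknown variable {self.variable!r}")
        if self.depth <= 0:
            raise SeriesError("format", f"depth must be positive, got {self.depth}")
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.ndim != 1:
            raise SeriesError("format", "values must be one-dimensional")
        if not np.all(np.isfinite(vals)):
            i = int(np.flatnonzero(~np.isfinite(vals))[0])
            raise SeriesError("format", f"non-finite value at index {i}")
        lo, hi = TEMPERATURE_RANGE if self.variable == "temperature" else MOISTURE_RANGE
        if vals.size and (vals.min() < lo or vals.max() > hi):
            i = int(np.flatnonzero((vals < lo) | (vals > hi))[0])
            raise SeriesError(
                "range",
                f"{self.variable} value {vals[i]:g} at {self.time(i)} outside [{lo}, {hi}]",
            )
        if not self.label:
            prefix = "ST" if self.variable == "temperature" else "MC"
            object.__setattr__(self, "label", f"{prefix}{self.depth}")

    def __len__(self) -> int:
        return self.values.size

    def time(self, i: int) -> datetime:
        """Timestamp of observation ``i``."""
        return self.start + timedelta(hours=int(i))

    @property
    def end(self) -> datetime:
        """Timestamp of the last observation."""
        return self.time(len(self) - 1)

    def timestamps(self) -> list[datetime]:
        return [self.time(i) for i in range(len(self))]


@dataclass(frozen=True)
class DeseasonalizedSeries:
    """Period-``S`` seasonal difference of an :class:`HourlySeries`.

    ``values[t] = parent[t + S] - parent[t]``; the start shifts forward by
    ``S`` hours and the length shrinks by ``S``.  The parent's first ``S``
    values (``head``) are retained so the original series can be
    reconstructed exactly.
    """

    variable: str
    depth: int
    start: datetime
    values: np.ndarray
    label: str
    period: int = 24
    head: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.head is not None:
            object.__setattr__(self, "head", np.asarray(self.head, dtype=float))

    def __len__(self) -> int:
        return self.values.size

    def time(self, i: int) -> datetime:
        return self.start + timedelta(hours=int(i))

    @property
    def end(self) -> datetime:
        return self.time(len(self) - 1)

    def reconstruct(self) -> np.ndarray:
        """Invert the differencing using the retained leading values.

        Returns the parent value array: ``x_t = y_t + x_{t-S}`` applied
        recursively from the stored head.
        """
        if self.head is None:
            raise SeriesError("format", "no retained head values; cannot reconstruct")
        S = self.period
        out = np.empty(len(self) + S)
        out[:S] = self.head
        for t in range(len(self)):
            out[S + t] = self.values[t] + out[t]
        return out


def seasonal_difference(series: HourlySeries, period: int = 24) -> DeseasonalizedSeries:
    """Apply the seasonal difference ``y_t = x_t - x_{t-period}``.

    Parameters
    ----------
    series : HourlySeries
    period : int
        Seasonal span in hours; 24 removes the diurnal cycle.

    Raises
    ------
    SeriesError
        ``"too-short"`` if the series has no more than ``period`` values.
    """
    if period < 1:
        raise SeriesError("format", f"period must be >= 1, got {period}")
    x = series.values
    if x.size <= period:
        raise SeriesError(
            "too-short",
            f"series {series.label} has {x.size} values, need > {period}",
        )
    return DeseasonalizedSeries(
        variable=series.variable,
        depth=series.depth,
        start=series.start + timedelta(hours=period),
        values=x[period:] - x[:-period],
        label=f"{series.label}SD" if not series.label.endswith("SD") else series.label,
        period=period,
        head=x[:period].copy(),
    )


def align_pair(
    a: DeseasonalizedSeries, b: DeseasonalizedSeries
) -> tuple[DeseasonalizedSeries, DeseasonalizedSeries]:
    """Restrict two deseasonalized series to their common timestamp range.

    Both inputs must share the same seasonal period.  Returns the trimmed
    pair with identical start and length.

    Raises
    ------
    SeriesError
        ``"disjoint"`` if the time ranges do not overlap.
    """
    if a.period != b.period:
        raise SeriesError("format", f"period mismatch: {a.period} vs {b.period}")
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    if end < start:
        raise SeriesError(
            "disjoint",
            f"{a.label} ends {a.end} / {b.label} starts {b.start}: no overlap",
        )

    def crop(s: DeseasonalizedSeries) -> DeseasonalizedSeries:
        i0 = int((start - s.start).total_seconds() // 3600)
        n = int((end - start).total_seconds() // 3600) + 1
        if i0 == 0 and n == len(s):
            return s
        return replace(s, start=start, values=s.values[i0 : i0 + n], head=None)

    return crop(a), crop(b)
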