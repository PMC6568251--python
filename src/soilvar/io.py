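"""Reading and writing delimited hourly soil-series tables.

Two table dialects are supported:

* **long** — one row per observation with timestamp, depth, variable and
  value columns (column names configurable through a column map);
* **wide** — a timestamp column plus one column per series label such as
  ``ST10`` or ``MC30`` (temperature/moisture prefix + depth in cm).

Timestamps are parsed as time-zone-naive local station time; only the
one-hour spacing matters downstream.  Missing hours are rejected by
default; short gaps (at most ``max_gap`` consecutive hours) can be filled
by linear interpolation when explicitly allowed.
"""

from __future__ import annotations

import logging
import re
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .series import DeseasonalizedSeries, HourlySeries, SeriesError

__all__ = ["read_hourly_table", "write_deseasonalized", "read_deseasonalized"]

log = logging.getLogger(__name__)

#: Default column map for long tables.
DEFAULT_COLUMN_MAP = {
    "timestamp": "timestamp",
    "depth": "depth",
    "variable": "variable",
    "value": "value",
}

_LABEL_RE = re.compile(r"^(ST|MC)(SD)?(\d+)$", re.IGNORECASE)

_VARIABLE_ALIASES = {
    "temperature": "temperature",
    "temp": "temperature",
    "st": "temperature",
    "soil_temperature": "temperature",
    "moisture": "moisture",
    "mc": "moisture",
    "soil_moisture": "moisture",
    "water_content": "moisture",
}


def _parse_times(raw: pd.Series, path) -> pd.Series:
    parsed = pd.to_datetime(raw, format="ISO8601", errors="coerce")
    if parsed.isna().any():
        parsed = pd.to_datetime(raw, format="%Y-%m-%d %H:%M", errors="coerce")
    if parsed.isna().any():
        row = int(np.flatnonzero(parsed.isna().to_numpy())[0])
        raise SeriesError("format", f"{path}: unparseable timestamp at data row {row + 1}")
    return parsed


def _to_hourly(
    times: pd.Series,
    values: pd.Series,
    *,
    variable: str,
    depth: int,
    label: str,
    path,
    interpolate_gaps: bool,
    max_gap: int,
) -> HourlySeries:
    order = np.argsort(times.to_numpy())
    times = times.iloc[order].reset_index(drop=True)
    vals = pd.to_numeric(values.iloc[order], errors="coerce").to_numpy(dtype=float)
    if np.isnan(vals).any():
        row = int(np.flatnonzero(np.isnan(vals))[0])
        raise SeriesError("format", f"{path}: unparseable value for {label} at data row {row + 1}")

    dup = times.duplicated()
    if dup.any():
        raise SeriesError("duplicate", f"{path}: duplicate timestamp {times[dup.idxmax()]} for {label}")

    t0, t1 = times.iloc[0], times.iloc[-1]
    full = pd.date_range(t0, t1, freq="h")
    if len(full) != len(times):
        present = pd.Series(vals, index=pd.DatetimeIndex(times))
        regular = present.reindex(full)
        missing = regular.index[regular.isna()]
        # length of the longest run of consecutive missing hours
        run = longest = 0
        prev = None
        for ts in missing:
            run = run + 1 if prev is not None and ts - prev == timedelta(hours=1) else 1
            longest = max(longest, run)
            prev = ts
        if not interpolate_gaps or longest > max_gap:
            raise SeriesError("gap", f"{path}: missing hour {missing[0]} in {label}")
        log.warning(
            "%s: interpolated %d missing hour(s) in %s (longest run %d h)",
            path, len(missing), label, longest,
        )
        vals = regular.interpolate(method="linear").to_numpy()
        times = pd.Series(full)
    elif (times.diff().iloc[1:] != timedelta(hours=1)).any():
        bad = times.diff().iloc[1:].ne(timedelta(hours=1)).idxmax()
        raise SeriesError("gap", f"{path}: irregular spacing before {times[bad]} in {label}")

    return HourlySeries(
        variable=variable,
        depth=depth,
        start=times.iloc[0].to_pydatetime(),
        values=vals,
        label=label,
    )


def _label_to_variable_depth(label: str):
    m = _LABEL_RE.match(label.strip())
    if not m:
        return None
    variable = "temperature" if m.group(1).upper() == "ST" else "moisture"
    return variable, int(m.group(3))


def read_hourly_table(
    path,
    column_map: dict | None = None,
    *,
    delimiter: str | None = None,
    interpolate_gaps: bool = False,
    max_gap: int = 2,
) -> dict[tuple[str, int], HourlySeries]:
    """Read a delimited hourly table into :class:`HourlySeries` objects.

    The dialect (long vs wide) is detected from the header: a table with a
    resolvable value column is read as long; otherwise every non-timestamp
    column whose name parses as a series label (``ST10``, ``MCSD30``, ...)
    becomes one series.

    Parameters
    ----------
    path : path-like
        CSV/TSV file, UTF-8, decimal point.
    column_map : dict, optional
        Maps the roles ``timestamp``/``depth``/``variable``/``value`` to
        actual column names (long dialect only).
    interpolate_gaps : bool
        Fill missing-hour runs of at most ``max_gap`` hours by linear
        interpolation instead of rejecting the file.

    Returns
    -------
    dict
        ``{(variable, depth): HourlySeries}``, one entry per pair.
    """
    cmap = {**DEFAULT_COLUMN_MAP, **(column_map or {})}
    df = pd.read_csv(path, sep=delimiter, engine="python", comment="#")
    if df.empty:
        raise SeriesError("format", f"{path}: no data rows")
    cols_lower = {c.lower(): c for c in df.columns}

    ts_col = cols_lower.get(cmap["timestamp"].lower())
    if ts_col is None:
        for cand in ("timestamp", "time", "datetime", "date"):
            if cand in cols_lower:
                ts_col = cols_lower[cand]
                break
    if ts_col is None:
        raise SeriesError("format", f"{path}: no timestamp column (have {list(df.columns)})")
    times = _parse_times(df[ts_col], path)

    kwargs = dict(path=path, interpolate_gaps=interpolate_gaps, max_gap=max_gap)
    out: dict[tuple[str, int], HourlySeries] = {}

    if cmap["value"].lower() in cols_lower:  # long dialect
        val_col = cols_lower[cmap["value"].lower()]
        dep_col = cols_lower.get(cmap["depth"].lower())
        var_col = cols_lower.get(cmap["variable"].lower())
        if dep_col is None or var_col is None:
            raise SeriesError("format", f"{path}: long table needs depth and variable columns")
        for (var_raw, depth), grp in df.groupby([var_col, dep_col]):
            variable = _VARIABLE_ALIASES.get(str(var_raw).strip().lower())
            if variable is None:
                raise SeriesError("format", f"{path}: unknown variable {var_raw!r}")
            depth = int(depth)
            label = ("ST" if variable == "temperature" else "MC") + str(depth)
            out[(variable, depth)] = _to_hourly(
                times.loc[grp.index], grp[val_col],
                variable=variable, depth=depth, label=label, **kwargs,
            )
    else:  # wide dialect: one column per label
        for col in df.columns:
            if col == ts_col:
                continue
            parsed = _label_to_variable_depth(str(col))
            if parsed is None:
                log.warning("%s: skipping unrecognised column %r", path, col)
                continue
            variable, depth = parsed
            out[(variable, depth)] = _to_hourly(
                times, df[col],
                variable=variable, depth=depth, label=str(col).strip(), **kwargs,
            )
        if not out:
            raise SeriesError("format", f"{path}: no series columns recognised")
    return out


def write_deseasonalized(series: DeseasonalizedSeries, path) -> None:
    """Write a deseasonalized series as two-column CSV (timestamp, value).

    A leading comment records the parent label and seasonal period so the
    file is self-describing.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# label={series.label} period={series.period} "
                 f"variable={series.variable} depth={series.depth}\n")
        fh.write("timestamp,value\n")
        for i, v in enumerate(series.values):
            fh.write(f"{series.time(i):%Y-%m-%d %H:%M},{v:.10g}\n")


def read_deseasonalized(path) -> DeseasonalizedSeries:
    """Read a file produced by :func:`write_deseasonalized`."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    if first.startswith("#"):
        meta = dict(tok.split("=", 1) for tok in first[1:].split() if "=" in tok)
    df = pd.read_csv(path, comment="#")
    times = _parse_times(df["timestamp"], path)
    if (times.diff().iloc[1:] != timedelta(hours=1)).any():
        raise SeriesError("gap", f"{path}: deseasonalized file is not hourly")
    return DeseasonalizedSeries(
        variable=meta.get("variable", "moisture"),
        depth=int(meta.get("depth", 0) or 1),
        start=times.iloc[0].to_pydatetime(),
        values=df["value"].to_numpy(dtype=float),
        label=meta.get("label", "series"),
        period=int(meta.get("period", 24)),
    )


def ingest_deseasonalized_table(
    path, *, period: int = 24, column_map: dict | None = None, delimiter: str | None = None
) -> dict[tuple[str, int], DeseasonalizedSeries]:
    """Read a table of already-deseasonalized series (wide or long).

    Used for deposited supplementary data that were differenced upstream;
    physical-range validation is skipped because differenced values are
    deviations, not levels.
    """
    df = pd.read_csv(path, sep=delimiter, engine="python", comment="#")
    cols_lower = {c.lower(): c for c in df.columns}
    ts_col = None
    for cand in ("timestamp", "time", "datetime", "date"):
        if cand in cols_lower:
            ts_col = cols_lower[cand]
            break
    if column_map and "timestamp" in column_map:
        ts_col = cols_lower.get(column_map["timestamp"].lower(), ts_col)
    if ts_col is None:
        raise SeriesError("format", f"{path}: no timestamp column")
    times = _parse_times(df[ts_col], path)
    if (times.diff().iloc[1:] != timedelta(hours=1)).any():
        bad = times.diff().iloc[1:].ne(timedelta(hours=1)).idxmax()
        raise SeriesError("gap", f"{path}: missing hour before {times[bad]}")
    out: dict[tuple[str, int], DeseasonalizedSeries] = {}
    for col in df.columns:
        if col == ts_col:
            continue
        parsed = _label_to_variable_depth(str(col))
        if parsed is None:
            continue
        variable, depth = parsed
        out[(variable, depth)] = DeseasonalizedSeries(
            variable=variable,
            depth=depth,
            start=times.iloc[0].to_pydatetime(),
            values=pd.to_numeric(df[col], errors="raise").to_numpy(dtype=float),
            label=str(col).strip(),
            period=period,
        )
    if not out:
        raise SeriesError("format", f"{path}: no series columns recognised")
    return out
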