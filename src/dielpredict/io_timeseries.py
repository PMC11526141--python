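"""Reading, regularizing and summarizing environmental logger time series.

Coastal loggers record water temperature (°C) and dissolved oxygen
(% air saturation) every few minutes, typically at a 10-min cadence.
Spectral analysis downstream requires a gap-free, evenly sampled series,
so this module handles parsing delimited text, snapping records onto an
exact time grid, interpolating short dropouts, linear detrending and the
daily min/mean/max summaries used for the daily-range analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal, stats

VARIABLES = ("temperature", "oxygen_saturation")
DEFAULT_UNITS = {"temperature": "degC", "oxygen_saturation": "% air saturation"}


@dataclass
class EnvSeries:
    """One regularly sampled environmental variable at a site.

    Parameters
    ----------
    site_id : str
        Site label (e.g. ``"cold_temperate"``).
    variable : str
        ``"temperature"`` or ``"oxygen_saturation"``.
    unit : str
        Physical unit of ``x`` (°C or % air saturation).
    t : pandas.DatetimeIndex
        Strictly increasing timestamps; after :func:`regularize` they sit on
        an exact ``dt`` grid.
    x : numpy.ndarray
        Values, same length as ``t``.
    gaps_filled : list of (Timestamp, Timestamp)
        Intervals whose values were interpolated.
    """

    site_id: str
    variable: str
    unit: str
    t: pd.DatetimeIndex
    x: np.ndarray
    gaps_filled: list = field(default_factory=list)

    def __post_init__(self):
        self.t = pd.DatetimeIndex(self.t)
        self.x = np.asarray(self.x, dtype=float)
        if self.variable not in VARIABLES:
            raise ValueError(f"unknown variable {self.variable!r}; expected one of {VARIABLES}")
        if len(self.t) != len(self.x):
            raise ValueError("t and x must have equal length")
        if len(self.t) < 2:
            raise ValueError("EnvSeries needs at least 2 samples")
        if not self.t.is_monotonic_increasing or self.t.has_duplicates:
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def dt(self) -> float:
        """Sampling step in seconds (nan if the grid is irregular)."""
        steps = np.diff(self.t.asi8) / 1e9
        if steps.size and np.all(steps == steps[0]):
            return float(steps[0])
        return float("nan")

    @property
    def is_regular(self) -> bool:
        return np.isfinite(self.dt)

    def replace(self, **kw) -> "EnvSeries":
        return dataclasses.replace(self, **kw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.t, self.variable: self.x}).set_index("time")


@dataclass
class DailyStats:
    """Per-calendar-day summary: mean, min, max and diel range (max - min)."""

    date: object  # datetime.date
    mean: float
    min: float
    max: float
    range: float

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValueError(f"day {self.date}: min <= mean <= max violated")
        if abs(self.range - (self.max - self.min)) > 1e-9:
            raise ValueError(f"day {self.date}: range != max - min")


def daily_stats_frame(days: list) -> pd.DataFrame:
    """DailyStats list -> DataFrame with columns date, mean, min, max, range."""
    return pd.DataFrame(
        [(d.date, d.mean, d.min, d.max, d.range) for d in days],
        columns=["date", "mean", "min", "max", "range"],
    )


def read_env_csv(path, schema: dict | None = None):
    """Read a delimited logger file into one :class:`EnvSeries` per variable.

    ``schema`` keys (all optional): ``timestamp`` (column name, default
    ``"time"``), ``format`` (strptime format for the timestamp), ``variables``
    (mapping of variable name -> column name, default
    ``{"temperature": "temp_C", "oxygen_saturation": "do_pct"}``), ``timezone``
    (IANA name; naive timestamps are localized to it), ``site_id``, ``sep``.

    Returns ``(series_list, qc)`` where ``qc`` maps each variable to the number
    of rows dropped because the timestamp or value failed to parse.
    """
    schema = dict(schema or {})
    ts_col = schema.get("timestamp", "time")
    var_map = schema.get(
        "variables", {"temperature": "temp_C", "oxygen_saturation": "do_pct"}
    )
    site_id = schema.get("site_id", "unknown")
    tz = schema.get("timezone")

    try:
        df = pd.read_csv(path, sep=schema.get("sep", ","))
    except OSError as exc:
        raise OSError(f"cannot read logger file {path}: {exc}") from exc
    if ts_col not in df.columns:
        raise ValueError(f"no timestamp column {ts_col!r} in {path} (columns: {list(df.columns)})")

    t = pd.to_datetime(df[ts_col], format=schema.get("format"), errors="coerce")
    if tz is not None:
        t = t.dt.tz_localize(tz, ambiguous="NaT", nonexistent="NaT")

    series, qc = [], {}
    for variable, col in var_map.items():
        if col not in df.columns:
            continue
        x = pd.to_numeric(df[col], errors="coerce")
        good = t.notna() & x.notna()
        qc[variable] = int((~good).sum())
        sub = pd.DataFrame({"t": t[good], "x": x[good]}).sort_values("t")
        sub = sub.drop_duplicates(subset="t", keep="first")
        if len(sub) < 2:
            raise ValueError(
                f"{path}: variable {variable!r} has fewer than 2 valid rows after QC"
            )
        series.append(
            EnvSeries(
                site_id=site_id,
                variable=variable,
                unit=DEFAULT_UNITS[variable],
                t=pd.DatetimeIndex(sub["t"]),
                x=sub["x"].to_numpy(float),
            )
        )
    if not series:
        raise ValueError(f"{path}: no known variable columns found ({list(var_map.values())})")
    return series, qc


def write_env_csv(path, series_list, schema: dict | None = None) -> None:
    """Write EnvSeries back to the same CSV dialect read_env_csv accepts."""
    schema = dict(schema or {})
    ts_col = schema.get("timestamp", "time")
    var_map = schema.get(
        "variables", {"temperature": "temp_C", "oxygen_saturation": "do_pct"}
    )
    frames = []
    for s in series_list:
        frames.append(pd.Series(s.x, index=s.t, name=var_map.get(s.variable, s.variable)))
    df = pd.concat(frames, axis=1)
    df.index.name = ts_col
    df.to_csv(path)


def _grid_positions(t: pd.DatetimeIndex, dt: float):
    """Map timestamps to integer positions on the grid anchored at t[0]."""
    rel = (t.asi8 - t.asi8[0]) / 1e9
    pos = np.rint(rel / dt).astype(np.int64)
    ok = np.abs(rel - pos * dt) <= dt / 2 + 1e-9
    return pos, ok


def regularize(series: EnvSeries, dt: float = 600.0, max_gap: float = 6 * 3600.0,
               strategy: str = "linear") -> EnvSeries:
    """Resample onto an exact ``dt`` grid, filling short gaps.

    Internal gaps no longer than ``max_gap`` seconds are filled — linearly by
    default, or with ``strategy="nearest_day"`` by copying the value at the
    same clock time from the nearest day that has one. Filled intervals are
    recorded in ``gaps_filled``. If any gap exceeds ``max_gap`` the longest
    contiguous gap-free stretch is returned instead (the discarded spans are
    recorded on the result as ``discarded_spans``).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if strategy not in ("linear", "nearest_day"):
        raise ValueError(f"unknown gap-fill strategy {strategy!r}")
    t, x = series.t, series.x
    native = float(np.median(np.diff(t.asi8) / 1e9))
    if native > 1.5 * dt:
        raise ValueError(
            f"dt={dt}s is incompatible with the data density "
            f"(native sampling ~{native:.0f}s would leave most grid cells empty)"
        )

    pos, ok = _grid_positions(t, dt)
    # keep the first sample landing on each grid cell
    pos, x_keep = pos[ok], x[ok]
    pos, uniq_idx = np.unique(pos, return_index=True)
    x_keep = x_keep[uniq_idx]
    if len(pos) < 2:
        raise ValueError(
            f"dt={dt}s is incompatible with the data density: fewer than 2 samples land on the grid"
        )

    n_grid = int(pos[-1]) + 1
    grid_t = t[0] + pd.to_timedelta(np.arange(n_grid) * dt, unit="s")
    grid_x = np.full(n_grid, np.nan)
    grid_x[pos] = x_keep

    missing = np.isnan(grid_x)
    max_gap_steps = int(np.floor(max_gap / dt))

    # identify runs of missing cells
    runs = []
    i = 0
    while i < n_grid:
        if missing[i]:
            j = i
            while j < n_grid and missing[j]:
                j += 1
            runs.append((i, j))  # [i, j)
            i = j
        else:
            i += 1

    long_runs = [(a, b) for a, b in runs if b - a > max_gap_steps]
    if long_runs:
        # split into gap-free-after-fill segments separated by the long runs
        bounds = [0] + [e for run in long_runs for e in run] + [n_grid]
        segments = [(bounds[k], bounds[k + 1]) for k in range(0, len(bounds) - 1, 2)]
        seg = max(segments, key=lambda ab: ab[1] - ab[0])
        discarded = [
            (grid_t[a], grid_t[b - 1]) for a, b in segments if (a, b) != seg
        ]
        sub = series.replace(
            t=grid_t[seg[0]:seg[1]], x=grid_x[seg[0]:seg[1]], gaps_filled=[]
        )
        out = regularize(sub, dt=dt, max_gap=max_gap, strategy=strategy)
        out.discarded_spans = discarded  # type: ignore[attr-defined]
        return out

    gaps_filled = list(series.gaps_filled)
    if runs:
        s = pd.Series(grid_x, index=grid_t)
        if strategy == "linear":
            s = s.interpolate(method="time", limit_area="inside")
        else:
            day = int(round(86400.0 / dt))
            vals = s.to_numpy()
            for a, b in runs:
                for k in range(a, b):
                    for off in range(1, n_grid // day + 2):
                        for cand in (k - off * day, k + off * day):
                            if 0 <= cand < n_grid and not np.isnan(vals[cand]):
                                vals[k] = vals[cand]
                                break
                        else:
                            continue
                        break
            s = pd.Series(vals, index=grid_t)
        grid_x = s.to_numpy()
        gaps_filled += [(grid_t[a], grid_t[b - 1]) for a, b in runs]

    out = series.replace(t=grid_t, x=grid_x, gaps_filled=gaps_filled)
    out.discarded_spans = []  # type: ignore[attr-defined]
    return out


def detrend_linear(series: EnvSeries) -> EnvSeries:
    """Remove the least-squares straight line over the whole segment.

    A single global line (not per-window) is removed; a constant series maps
    to all zeros.
    """
    x = series.x
    if np.allclose(x, x[0]):
        return series.replace(x=np.zeros_like(x))
    return series.replace(x=signal.detrend(x, type="linear"))


def percentile_transform(series: EnvSeries) -> EnvSeries:
    """Replace values by their average rank divided by (n + 1).

    The transform is monotone and maps into (0, 1); ties share the average
    rank (a constant series maps to all 0.5). It robs the spectrum of
    amplitude information but stabilizes heavy-tailed logger records before
    wavelet analysis.
    """
    r = stats.rankdata(series.x, method="average")
    return series.replace(x=r / (series.n + 1))


def daily_summaries(series: EnvSeries, completeness: float = 0.8):
    """Per-calendar-day mean/min/max/range in site-local time.

    A day qualifies only if at least ``completeness`` of its expected samples
    (86400 / dt) are present, so partial first/last days do not bias the
    min/max. Returns a list of :class:`DailyStats`.
    """
    if series.n == 0:
        return []
    if not series.is_regular:
        raise ValueError("daily_summaries requires a regularized series")
    expected = 86400.0 / series.dt
    s = pd.Series(series.x, index=series.t)
    out = []
    for date, day in s.groupby(s.index.date):
        if len(day) < completeness * expected:
            continue
        mn, mx = float(day.min()), float(day.max())
        out.append(DailyStats(date=date, mean=float(day.mean()), min=mn, max=mx,
                              range=mx - mn))
    return out
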