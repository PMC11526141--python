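"""The diel-predictability index and supporting daily-scale relations.

Predictability of a logger series is defined here as the fraction of the
monitored period — excluding the cone of influence at the 24 h scale —
during which the 24 h periodicity is statistically significant against the
red-noise null. Both a pointwise (fraction of timestamps) and a day-count
(days whose significant fraction exceeds a threshold, out of all days with
valid timestamps) version are reported, mirroring how such indices are
tabulated per site and variable.

Also provided: full-resolution lagged Pearson correlation between two
series (e.g. oxygen vs temperature, to locate the diel lag), and the
ordinary least-squares relation between daily dissolved-oxygen range and
daily mean temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_timeseries import (DailyStats, EnvSeries, daily_stats_frame,
                            detrend_linear, percentile_transform)
from .spectral import WaveletResult, cwt_morlet, red_noise_significance


@dataclass
class BandMask:
    """Per-timestamp significance of one target period, with COI validity."""

    t: object
    target_period: float          # hours
    valid: np.ndarray             # bool: coi_period >= target_period
    significant: np.ndarray       # bool: sig_ratio > 1 at the nearest scale
    scale_period: float           # the Fourier period actually used, hours


@dataclass
class PredictabilityReport:
    """One table row: how often the 24 h cycle of a series is significant."""

    site_id: str
    variable: str
    n_days_significant: int
    n_days_total: int
    fraction_time: float
    fraction_days: float
    alpha: float
    day_rule_threshold: float

    def __post_init__(self):
        if not (0 <= self.n_days_significant <= self.n_days_total):
            raise ValueError("day counts inconsistent")
        for f in (self.fraction_time, self.fraction_days):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class LaggedCorrelation:
    lags: np.ndarray      # seconds (signed: positive = second series lags)
    r: np.ndarray
    p: np.ndarray
    best_lag: float       # seconds


@dataclass
class RangeTempFit:
    """OLS of daily DO range on daily mean temperature, with a 95% band."""

    slope: float
    intercept: float
    se_slope: float
    r2: float
    n: int
    ci95_band: object = field(repr=False, default=None)  # callable temp -> (lo, hi)


def band_significance_mask(result: WaveletResult, target_period: float = 24.0) -> BandMask:
    """Classify each timestamp at the scale nearest ``target_period`` hours.

    A timestamp is *valid* iff its cone-of-influence period reaches the
    target period, and *significant* iff the red-noise ``sig_ratio`` exceeds
    1 there. The single nearest scale (geometric distance) is used, not a
    band average.
    """
    if result.sig_ratio is None:
        raise ValueError("run red_noise_significance before extracting a band mask")
    if not (result.period.min() <= target_period <= result.period.max()):
        raise ValueError(
            f"target period {target_period} h outside computed range "
            f"[{result.period.min():.2f}, {result.period.max():.2f}] h"
        )
    idx = int(np.argmin(np.abs(np.log(result.period / target_period))))
    valid = result.coi_period >= target_period
    significant = result.sig_ratio[idx] > 1.0
    return BandMask(t=result.t, target_period=target_period, valid=valid,
                    significant=significant, scale_period=float(result.period[idx]))


def predictability_index(mask: BandMask, day_rule_threshold: float = 0.5,
                         site_id: str = "", variable: str = "",
                         alpha: float = 0.05) -> PredictabilityReport:
    """Aggregate a band mask into the per-series predictability statistics.

    ``fraction_time`` is significant/valid timestamps pointwise. A calendar
    day counts as significant iff more than ``day_rule_threshold`` of its
    valid timestamps are significant; days with no valid timestamps are
    excluded from the denominator.
    """
    valid = np.asarray(mask.valid)
    sig = np.asarray(mask.significant) & valid
    if valid.sum() == 0:
        raise ValueError("no timestamps outside the cone of influence at the target period")

    dates = pd.DatetimeIndex(mask.t).date
    df = pd.DataFrame({"date": dates, "valid": valid, "sig": sig})
    per_day = df.groupby("date").sum()
    per_day = per_day[per_day["valid"] > 0]
    if per_day.empty:
        raise ValueError("no day has valid timestamps outside the cone of influence")
    day_sig = (per_day["sig"] / per_day["valid"]) > day_rule_threshold

    return PredictabilityReport(
        site_id=site_id,
        variable=variable,
        n_days_significant=int(day_sig.sum()),
        n_days_total=int(len(per_day)),
        fraction_time=float(sig.sum() / valid.sum()),
        fraction_days=float(day_sig.sum() / len(per_day)),
        alpha=alpha,
        day_rule_threshold=day_rule_threshold,
    )


def diel_predictability(series: EnvSeries, alpha: float = 0.05,
                        percentile: bool = True, detrend: bool = True,
                        day_rule_threshold: float = 0.5,
                        target_period: float = 24.0,
                        dj: float = 1.0 / 12) -> PredictabilityReport:
    """Detrend, (optionally) percentile-transform, and score one series.

    Convenience pipeline producing one table row from a regular series.
    """
    s = detrend_linear(series) if detrend else series
    if percentile:
        s = percentile_transform(s)
    res = cwt_morlet(s, dj=dj)
    res = red_noise_significance(res, s, alpha=alpha)
    mask = band_significance_mask(res, target_period=target_period)
    return predictability_index(mask, day_rule_threshold=day_rule_threshold,
                                site_id=series.site_id, variable=series.variable,
                                alpha=alpha)


def reports_frame(reports: list) -> pd.DataFrame:
    """PredictabilityReport rows -> tabular form (one row per series)."""
    rows = []
    for r in reports:
        rows.append({
            "site_id": r.site_id, "variable": r.variable,
            "days_significant": r.n_days_significant, "days_total": r.n_days_total,
            "fraction_days": r.fraction_days, "fraction_time": r.fraction_time,
            "alpha": r.alpha, "day_rule_threshold": r.day_rule_threshold,
        })
    return pd.DataFrame(rows)


def lagged_crosscorrelation(a: EnvSeries, b: EnvSeries, max_lag: float,
                            step: float | None = None) -> LaggedCorrelation:
    """Pearson correlation of ``b`` against ``a`` over a grid of time lags.

    Positive lag means ``b`` is shifted later, i.e. ``b`` lagging ``a``: if
    ``b(t) = a(t - L)`` the peak |r| sits at lag ``+L``. p-values use the
    t transform with (overlap - 2) dof. Lags with fewer than 10 overlapping
    samples are dropped with a warning.
    """
    if len(a.t) != len(b.t) or not (a.t == b.t).all():
        raise ValueError("lagged correlation requires identical timestamp grids")
    dt = a.dt
    if not np.isfinite(dt):
        raise ValueError("series must be regularized")
    span = a.n * dt
    if max_lag > 0.25 * span:
        raise ValueError(f"max_lag {max_lag}s exceeds 25% of the series span {span}s")
    step = dt if step is None else step
    kstep = max(1, int(round(step / dt)))
    kmax = int(round(max_lag / dt))

    lags, rs, ps = [], [], []
    for k in range(-kmax, kmax + 1, kstep):
        if k >= 0:
            xa, xb = a.x[: a.n - k] if k else a.x, b.x[k:]
        else:
            xa, xb = a.x[-k:], b.x[: b.n + k]
        if len(xa) < 10:
            warnings.warn(f"lag {k * dt:.0f}s dropped: overlap {len(xa)} < 10 samples")
            continue
        r, p = stats.pearsonr(xa, xb)
        lags.append(k * dt)
        rs.append(r)
        ps.append(p)
    lags, rs, ps = map(np.asarray, (lags, rs, ps))
    best = float(lags[np.argmax(np.abs(rs))])
    return LaggedCorrelation(lags=lags, r=rs, p=ps, best_lag=best)


def daily_range_vs_temperature(do_daily: list, temp_daily: list) -> RangeTempFit:
    """OLS of daily dissolved-oxygen range on daily mean temperature.

    Days are matched by calendar-date intersection; at least 3 matched days
    are required. The returned ``ci95_band`` callable evaluates the 95%
    confidence band of the mean response at given temperatures.
    """
    do = daily_stats_frame(do_daily).set_index("date")
    te = daily_stats_frame(temp_daily).set_index("date")
    common = do.index.intersection(te.index)
    if len(common) < 3:
        raise ValueError(f"only {len(common)} matched days; need >= 3")
    y = do.loc[common, "range"].to_numpy()
    x = te.loc[common, "mean"].to_numpy()
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()

    def band(temp):
        pred = fit.get_prediction(sm.add_constant(np.atleast_1d(np.asarray(temp, float)),
                                                  has_constant="add"))
        ci = pred.conf_int(alpha=0.05)
        return ci[:, 0], ci[:, 1]

    return RangeTempFit(slope=float(fit.params[1]), intercept=float(fit.params[0]),
                        se_slope=float(fit.bse[1]), r2=float(fit.rsquared),
                        n=int(len(common)), ci95_band=band)
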