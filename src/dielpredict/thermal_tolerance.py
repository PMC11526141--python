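"""LT50 estimation from ramped-mortality assays and thermal safety margins.

In a thermal-ramp assay, animals are warmed stepwise (e.g. 1 °C every
30 min) and mortality is checked at each step, under one of two dissolved-
oxygen treatments: full saturation (97 ± 2%) or supersaturation (140 ± 3%).
Each individual's death temperature is therefore interval-censored between
consecutive checkpoints. The LT50 is the temperature at which half the
population dies; it is estimated here by maximum likelihood for a logistic
(default) or normal death-temperature distribution, parametrized on the
logit/probit scale as ``link(F) = b0 + b1*T`` so that LT50 = -b0/b1 and
the delta method gives its standard error.

Derived per-species quantities: ΔLT50 (supersaturation minus full
saturation LT50 — the oxygen-driven gain in heat tolerance) and the thermal
safety margin, TSM = LT50 minus the mean of daily maximum habitat
temperatures. The species-level regression of ΔLT50 on TSM is ordinary
least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .io_timeseries import DailyStats

OXYGEN_LEVELS = ("full_saturation", "supersaturation")


@dataclass
class RampAssay:
    """Checkpointed mortality of one species at one oxygen treatment.

    ``checkpoints`` is an ordered list of (temperature °C, n_newly_dead,
    n_at_risk) triples; ``n_at_risk`` counts animals alive entering the
    checkpoint.
    """

    species: str
    site_id: str
    oxygen_level: str
    checkpoints: list          # (temp_C, n_newly_dead, n_at_risk)
    n_total: int

    def __post_init__(self):
        if self.oxygen_level not in OXYGEN_LEVELS:
            raise ValueError(f"oxygen_level must be one of {OXYGEN_LEVELS}")
        temps = [c[0] for c in self.checkpoints]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("checkpoint temperatures must be strictly increasing")
        deaths = [c[1] for c in self.checkpoints]
        risks = [c[2] for c in self.checkpoints]
        if any(d < 0 for d in deaths) or sum(deaths) > self.n_total:
            raise ValueError("death counts inconsistent with n_total")
        if any(b > a for a, b in zip(risks, risks[1:])):
            raise ValueError("n_at_risk must be nonincreasing")

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([c[0] for c in self.checkpoints], float)

    @property
    def deaths(self) -> np.ndarray:
        return np.array([c[1] for c in self.checkpoints], int)

    @property
    def ramp_step(self) -> float:
        t = self.temperatures
        return float(np.median(np.diff(t))) if len(t) > 1 else 1.0


@dataclass
class LT50Estimate:
    lt50: float
    se: float
    slope: float               # logit (or probit) units per °C
    n: int
    method: str
    convergence: bool


@dataclass
class SpeciesRecord:
    """Per-species covariates feeding the cross-species analyses."""

    species: str
    site_id: str
    lt50_full: float
    lt50_super: float
    delta_lt50: float
    tsm_super: float
    tsm_full: float
    mean_daily_max_temp: float
    temp_fluctuation: float = np.nan    # 24 h FFT amplitude, °C
    oxy_fluctuation: float = np.nan     # 24 h FFT amplitude, % air saturation
    temp_predictability: float = np.nan
    oxy_predictability: float = np.nan

    def __post_init__(self):
        if abs(self.delta_lt50 - (self.lt50_super - self.lt50_full)) > 1e-9:
            raise ValueError("delta_lt50 != lt50_super - lt50_full")
        if abs(self.tsm_super - (self.lt50_super - self.mean_daily_max_temp)) > 1e-9:
            raise ValueError("tsm_super != lt50_super - mean_daily_max_temp")


@dataclass
class LinearFit:
    intercept: float
    slope: float
    se_slope: float
    F: float
    adj_r2: float
    p: float
    n: int
    ci95_slope: tuple = field(default=(np.nan, np.nan))


def read_assay_csv(path) -> list:
    """Read assays from CSV columns species,oxygen_level,temperature_C,n_newly_dead,n_at_risk.

    One RampAssay per (species, oxygen_level) group; optional site_id column.
    """
    df = pd.read_csv(path)
    required = {"species", "oxygen_level", "temperature_C", "n_newly_dead", "n_at_risk"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    assays = []
    for (species, level), g in df.groupby(["species", "oxygen_level"], sort=False):
        g = g.sort_values("temperature_C")
        site = str(g["site_id"].iloc[0]) if "site_id" in g else "unknown"
        cps = list(zip(g["temperature_C"].astype(float),
                       g["n_newly_dead"].astype(int), g["n_at_risk"].astype(int)))
        assays.append(RampAssay(species=str(species), site_id=site, oxygen_level=str(level),
                                checkpoints=cps, n_total=int(g["n_at_risk"].iloc[0])))
    return assays


def write_assay_csv(path, assays: list) -> None:
    rows = []
    for a in assays:
        for temp, dead, risk in a.checkpoints:
            rows.append((a.species, a.site_id, a.oxygen_level, temp, dead, risk))
    pd.DataFrame(rows, columns=["species", "site_id", "oxygen_level",
                                "temperature_C", "n_newly_dead", "n_at_risk"]).to_csv(
        path, index=False)


def _interval_nll(beta, temps, deaths, n_surv, cdf):
    b0, b1 = beta
    F = cdf(b0 + b1 * temps)
    pint = np.diff(np.concatenate([[0.0], F]))  # death in (T_{j-1}, T_j]
    nll = 0.0
    mask = deaths > 0
    if np.any(pint[mask] <= 0):
        return 1e10
    nll -= np.sum(deaths[mask] * np.log(pint[mask]))
    if n_surv > 0:
        tail = 1.0 - F[-1]
        if tail <= 0:
            return 1e10
        nll -= n_surv * np.log(tail)
    return nll


def fit_lt50(assay: RampAssay, link: str = "logit") -> LT50Estimate:
    """Maximum-likelihood LT50 from interval-censored checkpoint mortality.

    Each individual contributes one term: the probability of dying in its
    observed checkpoint interval (or of surviving past the last checkpoint).
    With ``link="logit"`` the death-temperature distribution is logistic;
    ``"probit"`` fits a normal. If the deaths are completely separated (all
    in one interval) the midpoint of that interval is returned with the
    interval half-width as SE and ``convergence=False``.
    """
    cdf = {"logit": stats.logistic.cdf, "probit": stats.norm.cdf}.get(link)
    if cdf is None:
        raise ValueError(f"unknown link {link!r}")
    temps, deaths = assay.temperatures, assay.deaths
    total_dead = int(deaths.sum())
    n_surv = assay.n_total - total_dead
    if deaths[0] >= assay.n_total:
        raise ValueError("LT50 outside tested range: all individuals dead at the first checkpoint")
    if total_dead == 0:
        raise ValueError("LT50 outside tested range: no deaths by the last checkpoint")

    step = assay.ramp_step
    nonzero = np.nonzero(deaths)[0]
    if len(nonzero) == 1:
        j = nonzero[0]
        lo = temps[j - 1] if j > 0 else temps[j] - step
        return LT50Estimate(lt50=float((lo + temps[j]) / 2), se=float((temps[j] - lo) / 2),
                            slope=np.inf, n=assay.n_total, method=link, convergence=False)

    # moment start: mean/sd of interval midpoints weighted by deaths
    mids = temps - step / 2
    mu0 = np.average(mids, weights=deaths)
    sd0 = max(np.sqrt(np.average((mids - mu0) ** 2, weights=deaths)), step / 4)
    scale0 = sd0 * (np.sqrt(3) / np.pi if link == "logit" else 1.0)
    beta0 = np.array([-mu0 / scale0, 1.0 / scale0])

    res = optimize.minimize(_interval_nll, beta0, args=(temps, deaths, n_surv, cdf),
                            method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
    b0, b1 = res.x
    converged = bool(res.success) and b1 > 0 and abs(b1) < 1e3 / step
    lt50 = -b0 / b1
    if not converged:
        # separation-like failure: bracket the 50% mortality crossing
        cum = np.cumsum(deaths) / assay.n_total
        j = int(np.searchsorted(cum, 0.5))
        lo = temps[j - 1] if j > 0 else temps[j] - step
        return LT50Estimate(lt50=float((lo + temps[j]) / 2), se=float((temps[j] - lo) / 2),
                            slope=float(b1), n=assay.n_total, method=link, convergence=False)

    H = numdiff.approx_hess(res.x, _interval_nll, args=(temps, deaths, n_surv, cdf))
    try:
        cov = np.linalg.inv(H)
        grad = np.array([-1.0 / b1, b0 / b1**2])  # d(lt50)/d(b0, b1)
        se = float(np.sqrt(grad @ cov @ grad))
    except np.linalg.LinAlgError:
        se = float(step / 2)
    if not np.isfinite(se) or se <= 0:
        se = float(step / 2)
    return LT50Estimate(lt50=float(lt50), se=se, slope=float(b1), n=assay.n_total,
                        method=link, convergence=True)


def build_species_record(full: LT50Estimate, super_: LT50Estimate,
                         temp_daily: list, species: str = "", site_id: str = "",
                         temp_fluctuation: float = np.nan,
                         oxy_fluctuation: float = np.nan,
                         temp_predictability: float = np.nan,
                         oxy_predictability: float = np.nan) -> SpeciesRecord:
    """Combine the two oxygen-level fits with site environmental summaries.

    ``mean_daily_max_temp`` is the arithmetic mean of the daily maxima over
    the monitored period of the site's temperature logger; both TSM variants
    are computed (supersaturation for the primary analysis, full saturation
    for comparison — the latter may be negative for tropical species whose
    habitat maxima exceed their normoxic tolerance).
    """
    if full is None or super_ is None:
        raise ValueError("both oxygen levels are required to build a species record")
    if not temp_daily:
        raise ValueError("temp_daily must contain at least one day")
    mdm = float(np.mean([d.max for d in temp_daily]))
    return SpeciesRecord(
        species=species, site_id=site_id,
        lt50_full=full.lt50, lt50_super=super_.lt50,
        delta_lt50=super_.lt50 - full.lt50,
        tsm_super=super_.lt50 - mdm, tsm_full=full.lt50 - mdm,
        mean_daily_max_temp=mdm,
        temp_fluctuation=temp_fluctuation, oxy_fluctuation=oxy_fluctuation,
        temp_predictability=temp_predictability, oxy_predictability=oxy_predictability,
    )


def records_frame(records: list) -> pd.DataFrame:
    cols = ["species", "site_id", "lt50_full", "lt50_super", "delta_lt50",
            "tsm_super", "tsm_full", "mean_daily_max_temp",
            "temp_fluctuation", "oxy_fluctuation",
            "temp_predictability", "oxy_predictability"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records])


def tsm_delta_regression(records: list, margin: str = "super") -> LinearFit:
    """OLS of ΔLT50 (response) on the chosen thermal safety margin (predictor)."""
    if margin not in ("super", "full"):
        raise ValueError("margin must be 'super' or 'full'")
    if len(records) < 3:
        raise ValueError("need at least 3 species records")
    x = np.array([r.tsm_super if margin == "super" else r.tsm_full for r in records])
    y = np.array([r.delta_lt50 for r in records])
    if np.ptp(x) == 0:
        raise ValueError("thermal safety margin is constant across records")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ci = fit.conf_int(alpha=0.05)
    return LinearFit(intercept=float(fit.params[0]), slope=float(fit.params[1]),
                     se_slope=float(fit.bse[1]), F=float(fit.fvalue),
                     adj_r2=float(fit.rsquared_adj), p=float(fit.f_pvalue),
                     n=len(records), ci95_slope=(float(ci[1, 0]), float(ci[1, 1])))
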