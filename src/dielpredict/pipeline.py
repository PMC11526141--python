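"""End-to-end orchestration: loggers -> spectra -> predictability -> tolerance -> path model."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig, derive_seed, load_preset
from .io_timeseries import (daily_stats_frame, daily_summaries, detrend_linear,
                            read_env_csv, regularize)
from .path_model import PathModelSpec, fit_path_model, standardize_table
from .predictability import (daily_range_vs_temperature, diel_predictability,
                             lagged_crosscorrelation, reports_frame)
from .spectral import cross_wavelet, fft_amplitude_24h
from .synthetic import (AssaySimParams, EnvSimParams, SpeciesSimParams,
                        simulate_env_pair, simulate_ramp_assay, simulate_species_table)
from .thermal_tolerance import fit_lt50, records_frame, tsm_delta_regression

log = logging.getLogger("dielpredict")

DEFAULT_MODEL = """\
tsm_super ~ temp_predictability + oxy_predictability
delta_lt50 ~ tsm_super
temp_predictability ~~ oxy_predictability
temp_predictability ~~ temp_fluctuation
oxy_predictability ~~ oxy_fluctuation
temp_fluctuation ~~ oxy_fluctuation
"""


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage, write outputs under ``config.outdir``, return the manifest.

    Deterministic given (config, seed): the manifest records the package
    version, a config hash and a checksum per stage output.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"package": "dielpredict", "version": __version__,
                "config_hash": config.digest(), "seed": config.seed, "outputs": {}}

    def record(stage, path):
        manifest["outputs"][stage] = {"path": str(path), "sha256": _checksum(Path(path))}

    def timed(stage):
        t0 = time.perf_counter()
        return lambda: log.info("stage %-16s %.2fs", stage, time.perf_counter() - t0)

    # stage 1: environmental series
    done = timed("env")
    try:
        if config.temperature_csv and config.oxygen_csv:
            schema_t = dict(config.schema, variables={"temperature": config.schema.get(
                "variables", {}).get("temperature", "temp_C")})
            schema_o = dict(config.schema, variables={"oxygen_saturation": config.schema.get(
                "variables", {}).get("oxygen_saturation", "do_pct")})
            (temp,), _ = read_env_csv(config.temperature_csv, schema_t)
            (oxy,), _ = read_env_csv(config.oxygen_csv, schema_o)
        else:
            preset = load_preset(config.preset or "warm_temperate")
            preset.update(config.synthetic)
            preset["seed"] = derive_seed(config.seed, 0)
            temp, oxy = simulate_env_pair(EnvSimParams(**preset))
        temp = regularize(temp, dt=config.dt, max_gap=config.max_gap)
        oxy = regularize(oxy, dt=config.dt, max_gap=config.max_gap)
        env_df = pd.DataFrame({"time": temp.t, "temp_C": temp.x})
        oxy_df = pd.DataFrame({"time": oxy.t, "do_pct": oxy.x})
        _write_csv(env_df.merge(oxy_df, on="time", how="inner"), out / "env_series.csv")
        record("env", out / "env_series.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'env' failed: {exc} (check input paths/preset name)") from exc
    done()

    # stage 2: daily summaries + daily-range regression + lagged correlation
    done = timed("daily")
    try:
        td, od = daily_summaries(temp), daily_summaries(oxy)
        _write_csv(daily_stats_frame(td), out / "daily_temperature.csv")
        _write_csv(daily_stats_frame(od), out / "daily_oxygen.csv")
        record("daily_temperature", out / "daily_temperature.csv")
        record("daily_oxygen", out / "daily_oxygen.csv")
        fit = daily_range_vs_temperature(od, td)
        dt_t, dt_o = detrend_linear(temp), detrend_linear(oxy)
        lc = lagged_crosscorrelation(dt_t, dt_o, max_lag=6 * 3600.0, step=3600.0)
        daily_json = {
            "range_vs_temp": {"slope": fit.slope, "intercept": fit.intercept,
                              "se_slope": fit.se_slope, "r2": fit.r2, "n": fit.n},
            "lagged_correlation": {"best_lag_hours": lc.best_lag / 3600.0,
                                   "r_at_best": float(lc.r[np.argmax(np.abs(lc.r))])},
        }
        (out / "daily_relations.json").write_text(json.dumps(daily_json, indent=2))
        record("daily_relations", out / "daily_relations.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'daily' failed: {exc}") from exc
    done()

    # stage 3: predictability reports
    done = timed("predictability")
    try:
        reports = [diel_predictability(s, alpha=config.alpha, percentile=config.percentile,
                                       day_rule_threshold=config.day_rule_threshold,
                                       dj=config.dj)
                   for s in (temp, oxy)]
        _write_csv(reports_frame(reports), out / "predictability.csv")
        record("predictability", out / "predictability.csv")
    except Exception as exc:
        raise RuntimeError(f"stage 'predictability' failed: {exc} "
                           "(series may be too short for the 24 h scale)") from exc
    done()

    # stage 4: cross-wavelet summary + diel FFT amplitudes
    done = timed("xwt")
    try:
        xwt = cross_wavelet(detrend_linear(temp), detrend_linear(oxy), dj=config.dj)
        i24 = int(np.argmin(np.abs(np.log(xwt.period / 24.0))))
        ok = (xwt.coi_period >= 24.0) & (xwt.sig_ratio[i24] > 1)
        mean_phase = float(np.angle(np.mean(np.exp(1j * xwt.phase[i24][ok])))) if ok.any() else float("nan")
        amp_t, amp_o = fft_amplitude_24h(detrend_linear(temp)), fft_amplitude_24h(detrend_linear(oxy))
        xwt_json = {
            "mean_phase_24h_rad": mean_phase,
            "significant_fraction_24h": float(ok.sum() / max((xwt.coi_period >= 24.0).sum(), 1)),
            "fft_amplitude_24h_temp": amp_t.amplitude,
            "fft_amplitude_24h_oxygen": amp_o.amplitude,
        }
        (out / "xwt_summary.json").write_text(json.dumps(xwt_json, indent=2))
        record("xwt", out / "xwt_summary.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'xwt' failed: {exc}") from exc
    done()

    # stage 5: simulated assays -> LT50 fits -> species records -> TSM regression
    done = timed("thermal")
    try:
        records = simulate_species_table(SpeciesSimParams(
            n_species=config.n_species, seed=derive_seed(config.seed, 4)))
        # one worked pair of simulated assays, fitted, as a demonstration row
        ap = AssaySimParams(n_individuals=50, seed=derive_seed(config.seed, 5))
        est_full = fit_lt50(simulate_ramp_assay(ap, "full_saturation"), link=config.lt50_link)
        est_super = fit_lt50(simulate_ramp_assay(ap, "supersaturation"), link=config.lt50_link)
        _write_csv(records_frame(records), out / "species_records.csv")
        record("species_records", out / "species_records.csv")
        reg = tsm_delta_regression(records, margin=config.tsm_margin)
        thermal_json = {
            "example_lt50_full": est_full.lt50, "example_lt50_super": est_super.lt50,
            "example_delta_lt50": est_super.lt50 - est_full.lt50,
            "tsm_regression": {"intercept": reg.intercept, "slope": reg.slope,
                               "se_slope": reg.se_slope, "F": reg.F,
                               "adj_r2": reg.adj_r2, "p": reg.p, "n": reg.n},
        }
        (out / "thermal.json").write_text(json.dumps(thermal_json, indent=2))
        record("thermal", out / "thermal.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'thermal' failed: {exc}") from exc
    done()

    # stage 6: path model on the standardized species table
    done = timed("path_model")
    try:
        spec = PathModelSpec.from_string(config.model or DEFAULT_MODEL)
        table = standardize_table(records_frame(records), spec.variables)
        fit = fit_path_model(spec, table)
        path_json = {
            "chi2": fit.chi2, "dof": fit.dof, "cfi": fit.cfi, "rmsea": fit.rmsea,
            "converged": fit.converged,
            "coefficients": {f"{r}~{p}": {"est": e, "se": s, "p": pv}
                             for (r, p), (e, s, pv) in fit.coefficients.items()},
        }
        (out / "path_model.json").write_text(json.dumps(path_json, indent=2))
        record("path_model", out / "path_model.json")
    except Exception as exc:
        raise RuntimeError(f"stage 'path_model' failed: {exc}") from exc
    done()

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
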