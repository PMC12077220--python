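"""Cross-species statistics and end-to-end orchestration.

Trait correlations (e.g. maximum swimming speed R_max against thermal
optimum T_opt, cell width or aspect ratio) are ordinary least squares
fits with exact small-sample inference; the swimming-vs-photosynthesis
T_opt comparison asks whether the 95 % CI of the slope contains 1.  A
per-replicate slope check summarizes the stability of control swimming
speed over time (the simple, transparent reduction of a random-slope
mixed model).  ``run_pipeline`` chains simulate → track → metrics → TPC
into a reproducible report bundle.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import __version__
from .metrics import duration_scaled_threshold, population_summary, track_metrics
from .simulate import SimConfig, simulate_tracks
from .tpc import ThermalPerformanceModel
from .tracking import LinkConfig, filter_tracks, link_tracks, tracks_from_spot_table

CRYOPHILIC_TOPT_MAX_C = 10.0
MESOPHILIC_TOPT_MIN_C = 20.0


def thermal_class(topt_C: float) -> str:
    """Thermal class of a species by swimming T_opt (°C)."""
    if topt_C < CRYOPHILIC_TOPT_MAX_C:
        return "cryophilic"
    if topt_C > MESOPHILIC_TOPT_MIN_C:
        return "mesophilic"
    return "intermediate"


@dataclass(frozen=True)
class LinearFitResult:
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r_squared: float
    p_value: float
    ci95_slope: tuple
    n: int

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["ci95_slope"] = list(self.ci95_slope)
        return d


def linear_fit(x, y) -> LinearFitResult:
    """OLS of y on x with t-based p-value and 95 % CI for the slope."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; slope undefined")
    model = sm.OLS(y, sm.add_constant(x))
    res = model.fit()
    ci = res.conf_int(alpha=0.05)
    return LinearFitResult(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        ci95_slope=(float(ci[1, 0]), float(ci[1, 1])),
        n=int(x.size),
    )


def slope_vs_one_test(fit: LinearFitResult) -> dict:
    """Is the fitted slope statistically distinguishable from 1?

    Follows the CI criterion: consistent with slope 1 iff the 95 % CI
    for the slope contains 1.0.
    """
    lo, hi = fit.ci95_slope
    consistent = bool(lo < 1.0 < hi)
    return {
        "consistent_with_slope_1": consistent,
        "decision": "consistent with slope 1" if consistent else "differs from slope 1",
        "ci95_slope": [lo, hi],
    }


def ramp_slope_check(times_s, speeds_um_s, replicates) -> dict:
    """Per-replicate OLS slopes of speed vs time, pooled with a t-CI.

    Used as a stability check of control swimming speed over time: the
    pooled mean slope's 95 % CI including 0 indicates no drift.
    """
    df = pd.DataFrame({"t": times_s, "v": speeds_um_s, "rep": replicates})
    slopes = {}
    for rep, g in df.groupby("rep"):
        slopes[rep] = linear_fit(g["t"], g["v"]).slope
    vals = np.array(list(slopes.values()))
    mean = float(vals.mean())
    if vals.size > 1:
        se = float(vals.std(ddof=1) / np.sqrt(vals.size))
        tcrit = stats.t.ppf(0.975, vals.size - 1)
        ci = (mean - tcrit * se, mean + tcrit * se)
    else:
        se, ci = float("nan"), (float("nan"), float("nan"))
    return {
        "per_replicate_slopes": {str(k): float(v) for k, v in slopes.items()},
        "pooled_mean_slope": mean,
        "pooled_se": se,
        "ci95": [ci[0], ci[1]],
        "stable": bool(ci[0] <= 0.0 <= ci[1]) if np.isfinite(ci[0]) else None,
    }


def plot_correlation(fit: LinearFitResult, x, y, ax=None, xlabel="", ylabel=""):
    """Scatter with the OLS line and its 95 % confidence band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ax.scatter(x, y, color="k", zorder=3)
    grid = np.linspace(x.min(), x.max(), 100)
    pred = fit.intercept + fit.slope * grid
    # exact t-based mean-prediction band
    resid_var = np.var(y - (fit.intercept + fit.slope * x), ddof=2)
    se = np.sqrt(resid_var * (1.0 / x.size + (grid - x.mean()) ** 2 / np.sum((x - x.mean()) ** 2)))
    tcrit = stats.t.ppf(0.975, x.size - 2)
    ax.plot(grid, pred, color="C0")
    ax.fill_between(grid, pred - tcrit * se, pred + tcrit * se, alpha=0.2, color="C0")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"slope={fit.slope:.2f}, R²={fit.r_squared:.2f}, p={fit.p_value:.3g}")
    return ax


def welch_ttest(a, b) -> dict:
    """Two-sample Welch t-test (ramp-rate comparisons of TPC parameters)."""
    t, p = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return {"t_stat": float(t), "p_value": float(p)}


# ---------------------------------------------------------------------------
# Orchestration


DEFAULT_PIPELINE = {
    "species": "synthetic",
    "temperatures_C": [0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0],
    "n_replicates": 3,
    "n_cells": 120,
    "motile_fraction": 0.7,
    "noise_cv": 0.10,
    "true_tpc": {"model": "thomas2", "a": 40.0, "b": 0.08, "c": 5.0, "d": 0.35, "e_coef": 0.26},
    "fit_models": ["pawar", "thomas2"],
    "n_boot": 200,
    "relink": True,
    "seed": 0,
}


def _true_params(spec: dict):
    from . import tpc as _tpc

    spec = dict(spec)
    model = spec.pop("model")
    cls = {"pawar": _tpc.PawarParams, "thomas2": _tpc.Thomas2Params,
           "weibull": _tpc.WeibullParams}[model]
    return cls(**spec)


def run_pipeline(config: dict | None = None, outdir=None) -> dict:
    """End-to-end: simulate per-temperature replicates from a known TPC,
    (re-)link tracks, compute motility metrics and motile fractions, fit
    TPC models to the per-temperature motile mean speeds, and select by
    AIC.  Deterministic given the config seed.

    Returns the report bundle as a dict; when ``outdir`` is given, also
    writes summary CSVs, fit JSON and a provenance record there.
    """
    from .tpc import fit_tpc, model_select_aic

    cfg = dict(DEFAULT_PIPELINE)
    cfg.update(config or {})
    rng = np.random.default_rng(cfg["seed"])
    true_params = _true_params(cfg["true_tpc"])
    link_cfg = LinkConfig()

    rows = []
    samples = []
    for temp in cfg["temperatures_C"]:
        for rep in range(cfg["n_replicates"]):
            rate = float(np.asarray(true_params.rate(temp)))
            rate = max(rate, 0.0)
            n_mot = int(rng.binomial(cfg["n_cells"], cfg["motile_fraction"])) if rate > 0 else 0
            n_rest = cfg["n_cells"] - n_mot
            sim_cfg = SimConfig(
                arena_width_um=max(1500.0, 80.0 * np.sqrt(cfg["n_cells"])),
                arena_height_um=max(1500.0, 80.0 * np.sqrt(cfg["n_cells"])),
                n_motile=n_mot,
                n_drifting=n_rest // 2,
                n_stationary=n_rest - n_rest // 2,
                speed_mean_um_s=rate,
                speed_sd_um_s=rate * cfg["noise_cv"],
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            spots, _ = simulate_tracks(sim_cfg)
            if cfg["relink"]:
                raw = spots.copy()
                raw["TRACK_ID"] = np.nan
                tracks = filter_tracks(link_tracks(raw, link_cfg), link_cfg.min_track_frames)
            else:
                tracks = tracks_from_spot_table(spots)
            mets = [track_metrics(t) for t in tracks]
            sample = population_summary(
                mets, cfg["species"], temp, f"r{rep+1}",
                distance_threshold_um=duration_scaled_threshold(sim_cfg.duration_s),
            )
            samples.append(sample)
            rows.append(sample.to_row())
    summary = pd.DataFrame(rows)

    # per-temperature replicate means -> TPC dataset (motile speeds only)
    agg = (
        summary.dropna(subset=["motile_mean_speed"])
        .groupby("temperature_C")["motile_mean_speed"]
        .agg(["mean", "std", "count"])
        .reset_index()
        .rename(columns={"mean": "rate", "std": "sd", "count": "n"})
    )
    agg = agg[(agg["n"] >= 2) & (agg["sd"] > 0)]
    fits = [
        fit_tpc(agg, model=m, n_boot=cfg["n_boot"], seed=int(rng.integers(0, 2**31 - 1)))
        for m in cfg["fit_models"]
    ]
    best = model_select_aic(fits)

    bundle = {
        "config": cfg,
        "population_summary": summary,
        "tpc_dataset": agg,
        "fits": {f.model: f.to_dict() for f in fits},
        "best_model": best.model,
        "topt_C": best.topt_C,
        "rmax": best.rmax,
        "ci_topt": list(best.ci_topt),
        "ci_rmax": list(best.ci_rmax),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        summary.to_csv(outdir / "population_summary.csv", index=False)
        agg.to_csv(outdir / "tpc_dataset.csv", index=False)
        best.curve().to_csv(outdir / "tpc_curve.csv", index=False)
        with open(outdir / "tpc_fits.json", "w") as fh:
            json.dump(bundle["fits"], fh, indent=2)
        provenance = {
            "package": "snowmotility",
            "version": __version__,
            "python": platform.python_version(),
            "seed": cfg["seed"],
            "config": cfg,
        }
        with open(outdir / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2)
    return bundle
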