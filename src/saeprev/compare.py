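"""Precision and consistency diagnostics across the three estimator families.

Aligns per-district direct, area-level (FH) and unit-level (EBP) estimates and
computes the comparison battery: coefficients of variation with the <20%
reliability rule, OLS bias regressions of model-based on direct estimates,
MSE-ratio precision gains, and seven-number summary tables.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "coefficient_of_variation",
    "bias_regression",
    "precision_gain",
    "reliability_classification",
    "summary_table",
    "align_estimates",
    "comparison_report",
    "plot_comparison",
]


def coefficient_of_variation(estimate, se):
    """CV% = 100*se/estimate; NaN (with a logged count) where estimate <= 0."""
    est = np.asarray(estimate, dtype=float)
    se = np.asarray(se, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(est > 0, 100.0 * se / est, np.nan)
    n_bad = int(np.sum(~(est > 0)))
    if n_bad:
        logger.warning("CV undefined for %d non-positive estimates", n_bad)
    return float(cv) if cv.ndim == 0 else cv


def bias_regression(model_estimates, direct_estimates):
    """OLS of model-based on direct estimates: returns (slope, intercept, r2).

    A slope below 1 is the shrinkage signature; r2 measures consistency.
    """
    x = np.asarray(direct_estimates, dtype=float)
    y = np.asarray(model_estimates, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 aligned districts")
    if np.ptp(x) == 0:
        raise ValueError("direct estimates have zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(res.rsquared) if np.ptp(y) > 0 else 0.0  # constant model series
    return float(res.params[1]), float(res.params[0]), r2


def precision_gain(mse_direct, mse_model):
    """Percent MSE reduction 100*(1 - mse_model/mse_direct) per district + mean."""
    md = np.asarray(mse_direct, dtype=float)
    mm = np.asarray(mse_model, dtype=float)
    if np.any(md <= 0):
        raise ValueError("mse_direct must be positive")
    per = 100.0 * (1.0 - mm / md)
    return per, float(np.mean(per))


def reliability_classification(cv_series, threshold: float = 20.0) -> dict:
    """Count/fraction of districts with CV strictly below the threshold.

    NaN CVs (undefined estimates) count as not reliable.
    """
    cv = np.asarray(cv_series, dtype=float)
    n = len(cv)
    ok = int(np.sum(cv < threshold))  # NaN compares False
    return {"n": n, "n_reliable": ok, "pct_reliable": 100.0 * ok / n if n else np.nan}


def summary_table(series_by_method: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean, SD, min, max and quartiles (linear interpolation) per method."""
    rows = {}
    for name, s in series_by_method.items():
        s = np.asarray(s, dtype=float)
        s = s[np.isfinite(s)]
        if len(s) == 0:
            raise ValueError(f"series '{name}' is empty")
        q1, q2, q3 = np.quantile(s, [0.25, 0.5, 0.75])
        rows[name] = {
            "mean": s.mean(),
            "sd": s.std(ddof=1) if len(s) > 1 else 0.0,
            "min": s.min(), "max": s.max(),
            "q1": q1, "q2": q2, "q3": q3,
        }
    return pd.DataFrame(rows).T


def align_estimates(
    direct: pd.DataFrame, fh: pd.DataFrame, ebp: pd.DataFrame
) -> pd.DataFrame:
    """Merge the three estimate tables on district_id (outer; gaps stay NaN).

    Expected columns: direct (p_hat, se, n), fh (p_fh, mse_p), ebp
    (p_ebp, mse_boot). Emits estimate/rmse/cv columns per method.
    """
    out = (
        direct[["district_id", "n", "p_hat", "se"]]
        .merge(fh[["district_id", "p_fh", "mse_p"]], on="district_id", how="outer")
        .merge(ebp[["district_id", "p_ebp", "mse_boot"]], on="district_id", how="outer")
        .sort_values("district_id")
        .reset_index(drop=True)
    )
    out["rmse_fh"] = np.sqrt(out["mse_p"])
    out["rmse_ebp"] = np.sqrt(out["mse_boot"])
    out["cv_direct"] = coefficient_of_variation(out["p_hat"], out["se"])
    out["cv_fh"] = coefficient_of_variation(out["p_fh"], out["rmse_fh"])
    out["cv_ebp"] = coefficient_of_variation(out["p_ebp"], out["rmse_ebp"])
    n_gap = int(out[["p_hat", "p_fh", "p_ebp"]].isna().any(axis=1).sum())
    if n_gap:
        logger.info("%d districts missing at least one estimate", n_gap)
    return out


def comparison_report(aligned: pd.DataFrame, cv_threshold: float = 20.0) -> dict:
    """Full diagnostic battery on an aligned estimate table."""
    est_summary = summary_table(
        {
            "direct": aligned["p_hat"].to_numpy(),
            "area_level": aligned["p_fh"].to_numpy(),
            "unit_level": aligned["p_ebp"].to_numpy(),
        }
    )
    cv_summary = summary_table(
        {
            "direct": aligned["cv_direct"].to_numpy(),
            "area_level": aligned["cv_fh"].to_numpy(),
            "unit_level": aligned["cv_ebp"].to_numpy(),
        }
    )
    report: dict = {
        "estimate_summary": est_summary,
        "cv_summary": cv_summary,
        "reliability": {
            m: reliability_classification(aligned[f"cv_{k}"], cv_threshold)
            for m, k in (("direct", "direct"), ("area_level", "fh"), ("unit_level", "ebp"))
        },
    }
    for name, col in (("area_level", "p_fh"), ("unit_level", "p_ebp")):
        try:
            slope, intercept, r2 = bias_regression(aligned[col], aligned["p_hat"])
            report[f"bias_regression_{name}"] = {
                "slope": slope, "intercept": intercept, "r2": r2,
            }
        except ValueError as exc:
            logger.warning("bias regression (%s) skipped: %s", name, exc)
    # direct-estimator MSE taken as its variance (design-unbiasedness assumed)
    mask = (
        aligned[["se", "mse_p", "mse_boot"]].notna().all(axis=1)
        & (aligned["se"] > 0)
    )
    sub = aligned[mask]
    if len(sub):
        # ratio analysis of the *mean* MSE: robust to near-zero direct SEs
        mse_d = float(np.mean(sub["se"] ** 2))
        report["precision_gain_pct"] = {
            "area_level": 100.0 * (1.0 - float(np.mean(sub["mse_p"])) / mse_d),
            "unit_level": 100.0 * (1.0 - float(np.mean(sub["mse_boot"])) / mse_d),
        }
    return report


def plot_comparison(aligned: pd.DataFrame, path) -> None:
    """Scatter of model vs direct estimates and CV-by-sample-size profiles."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    ax = axes[0]
    lim = float(np.nanmax(aligned[["p_hat", "p_fh", "p_ebp"]].to_numpy())) * 1.05
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    ax.scatter(aligned["p_hat"], aligned["p_fh"], s=14, label="area-level")
    ax.scatter(aligned["p_hat"], aligned["p_ebp"], s=14, label="unit-level")
    ax.set_xlabel("direct estimate")
    ax.set_ylabel("model-based estimate")
    ax.legend()
    ax = axes[1]
    srt = aligned.sort_values("n")
    for col, lab in (("cv_direct", "direct"), ("cv_fh", "area-level"),
                     ("cv_ebp", "unit-level")):
        ax.plot(srt["n"], srt[col], marker=".", lw=0.7, label=lab)
    ax.axhline(20.0, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("district sample size")
    ax.set_ylabel("CV (%)")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
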