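"""Fay-Herriot area-level model on the logit scale.

Sampling model  theta_hat_i = theta_i + e_i,  e_i ~ N(0, psi_i), psi_i known.
Linking model   theta_i = z_i' beta + v_i,    v_i ~ N(0, sigma_v^2).

The EBLUP is the convex combination

    theta_fh_i = gamma_i * theta_hat_i + (1 - gamma_i) * z_i' beta,
    gamma_i    = sigma_v^2 / (sigma_v^2 + psi_i),

with sigma_v^2 estimated by REML (default) or ML via the one-dimensional
profile likelihood, truncated at zero. The MSE of the EBLUP follows the
Prasad-Rao decomposition g1 + g2 + 2*g3, with the Datta-Lahiri bias
correction when sigma_v^2 is estimated by ML. Prevalence-scale output uses
the delta method; confidence intervals are symmetric on the logit scale and
back-transformed, hence always inside (0, 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import expit
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "FHFit",
    "FHConvergenceError",
    "fit_variance_ml",
    "gls_beta",
    "eblup",
    "fh_mse",
    "back_transform",
    "fit_fh",
    "select_model_aic",
    "profile_loglik",
]

_LOG2PI = np.log(2.0 * np.pi)


class FHConvergenceError(RuntimeError):
    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class FHFit:
    district_id: np.ndarray
    beta: pd.Series
    beta_cov: np.ndarray
    sigma_v2: float
    gamma: np.ndarray
    theta_fh: np.ndarray
    mse_logit: np.ndarray
    p_fh: np.ndarray
    mse_p: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    loglik: float
    aic: float
    converged: bool
    method: str
    covariates: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "district_id": self.district_id,
                "theta_fh": self.theta_fh,
                "gamma": self.gamma,
                "mse_logit": self.mse_logit,
                "p_fh": self.p_fh,
                "mse_p": self.mse_p,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def summary(self) -> dict:
        return {
            "beta": {k: float(v) for k, v in self.beta.items()},
            "sigma_v2": float(self.sigma_v2),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "method": self.method,
            "converged": bool(self.converged),
        }


def _check_design(Z: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # locate columns involved in the collinearity via QR pivoting
        _, r = np.linalg.qr(Z)
        diag = np.abs(np.diag(r))
        bad = [names[j] for j in range(len(names)) if diag[j] < 1e-10 * diag.max()]
        raise ValueError(f"design matrix rank deficient; collinear columns: {bad}")


def gls_beta(
    theta: np.ndarray, psi: np.ndarray, Z: np.ndarray, sigma_v2: float,
    names: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """GLS coefficients with weights 1/(sigma_v^2 + psi_i); returns (beta, cov)."""
    names = names or [f"z{j}" for j in range(Z.shape[1])]
    _check_design(Z, names)
    w = 1.0 / (sigma_v2 + psi)
    A = Z.T @ (w[:, None] * Z)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ (Z.T @ (w * theta))
    return beta, Ainv


def profile_loglik(
    sigma_v2: float, theta: np.ndarray, psi: np.ndarray, Z: np.ndarray,
    method: str = "REML",
) -> float:
    """Profile (restricted) Gaussian log-likelihood of the FH model in sigma_v^2."""
    v = sigma_v2 + psi
    if (v <= 0).any():  # boundary with psi_i = 0: density degenerate
        return -np.inf
    w = 1.0 / v
    A = Z.T @ (w[:, None] * Z)
    try:
        beta = np.linalg.solve(A, Z.T @ (w * theta))
    except np.linalg.LinAlgError:  # numerically degenerate weighting
        return -np.inf
    r = theta - Z @ beta
    ll = -0.5 * (len(theta) * _LOG2PI + np.sum(np.log(v)) + np.sum(r * r * w))
    if method.upper() == "REML":
        p = Z.shape[1]
        ll += 0.5 * (p * _LOG2PI - np.linalg.slogdet(A)[1])
    return float(ll)


def fit_variance_ml(
    theta: np.ndarray, psi: np.ndarray, Z: np.ndarray,
    method: str = "REML", tol: float = 1e-10, max_iter: int = 200,
) -> float:
    """Maximize the profile likelihood over sigma_v^2 >= 0.

    Bounded scalar maximization; if the interior optimum does not beat the
    boundary, the estimate is truncated at 0.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    p = Z.shape[1]
    if len(theta) < p + 2:
        raise ValueError(f"need at least {p + 2} districts to fit {p} coefficients")
    upper = max(10.0 * float(np.var(theta)), 10.0 * float(np.max(psi)), 1e-3)
    res = minimize_scalar(
        lambda s: -profile_loglik(s, theta, psi, Z, method),
        bounds=(0.0, upper), method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    if not res.success:
        raise FHConvergenceError(
            f"variance optimization did not converge: {res.message}", trace=res
        )
    s_hat = float(res.x)
    if profile_loglik(0.0, theta, psi, Z, method) >= -res.fun:
        s_hat = 0.0
    return s_hat


def eblup(
    theta: np.ndarray, psi: np.ndarray, Z: np.ndarray,
    beta: np.ndarray, sigma_v2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """EBLUP theta_fh = gamma*theta_hat + (1-gamma)*z'beta; returns (theta_fh, gamma).

    Districts with missing theta_hat (NaN) receive the synthetic part with
    gamma = 0.
    """
    synth = Z @ beta
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(
            np.isnan(theta), 0.0,
            np.where(psi + sigma_v2 > 0, sigma_v2 / (sigma_v2 + psi), 1.0),
        )
    theta_fh = np.where(np.isnan(theta), synth, gamma * np.nan_to_num(theta) + (1 - gamma) * synth)
    return theta_fh, gamma


def fh_mse(
    psi: np.ndarray, Z: np.ndarray, sigma_v2: float,
    beta_cov: np.ndarray, method: str = "REML",
    missing: np.ndarray | None = None,
) -> np.ndarray:
    """Prasad-Rao MSE g1 + g2 + 2*g3 of the EBLUP on the logit scale.

    g1 = gamma*psi (shrinkage variance), g2 = leverage term for beta
    estimation, g3 = variance-estimation term using the asymptotic variance
    of sigma_v^2-hat; the ML estimator additionally gets the Datta-Lahiri
    bias-correction term. Districts flagged ``missing`` (no direct estimate)
    get the synthetic-prediction MSE sigma_v^2 + z' cov(beta) z instead.
    """
    v = sigma_v2 + psi
    with np.errstate(invalid="ignore", divide="ignore"):
        gamma = np.where(v > 0, sigma_v2 / v, 1.0)
    g1 = gamma * psi
    g2 = (1.0 - gamma) ** 2 * np.einsum("ij,jk,ik->i", Z, beta_cov, Z)
    inv2 = np.nansum(1.0 / v[~missing] ** 2) if missing is not None else np.sum(1.0 / v**2)
    var_s = 2.0 / inv2 if inv2 > 0 else 0.0
    g3 = psi**2 / v**3 * var_s
    mse = g1 + g2 + 2.0 * g3
    if method.upper() == "ML":
        # asymptotic downward bias of the ML variance estimator
        keep = (~missing if missing is not None else np.ones(len(v), bool)) & (v > 0)
        W = np.zeros(len(v))
        W[keep] = 1.0 / v[keep]
        tr = float(np.trace(beta_cov @ (Z.T @ ((W**2)[:, None] * Z))))
        bias = -tr / inv2 if inv2 > 0 else 0.0
        mse = mse - bias * (1.0 - gamma) ** 2
    if missing is not None and missing.any():
        synth_var = sigma_v2 + np.einsum("ij,jk,ik->i", Z, beta_cov, Z)
        mse = np.where(missing, synth_var, mse)
    return np.maximum(mse, 0.0)


def back_transform(
    theta_fh: np.ndarray, mse_logit: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Prevalence scale: p = expit(theta); delta-method MSE; logit-symmetric CI."""
    p = expit(theta_fh)
    mse_p = mse_logit * (p * (1.0 - p)) ** 2
    z = norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(mse_logit)
    return p, mse_p, expit(theta_fh - half), expit(theta_fh + half)


def _design_from_inputs(
    inputs: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[str]]:
    names = ["intercept"] + list(covariates)
    Z = np.column_stack(
        [np.ones(len(inputs))] + [inputs[c].to_numpy(float) for c in covariates]
    )
    return Z, names


def fit_fh(
    inputs: pd.DataFrame,
    covariates: list[str],
    method: str = "REML",
    alpha: float = 0.05,
) -> FHFit:
    """Fit the area-level model from a per-district input table.

    ``inputs`` needs columns district_id, theta_hat, psi and the covariate
    columns. Rows with NaN theta_hat (districts excluded at the direct stage)
    are left out of estimation and receive synthetic predictions.
    """
    inputs = inputs.sort_values("district_id").reset_index(drop=True)
    Z, names = _design_from_inputs(inputs, covariates)
    theta_all = inputs["theta_hat"].to_numpy(float)
    psi_all = inputs["psi"].to_numpy(float)
    missing = ~np.isfinite(theta_all) | ~np.isfinite(psi_all)
    if (psi_all[~missing] < 0).any():
        raise ValueError("psi must be >= 0")
    theta, psi, Zf = theta_all[~missing], psi_all[~missing], Z[~missing]
    _check_design(Zf, names)
    sigma_v2 = fit_variance_ml(theta, psi, Zf, method=method)
    beta, beta_cov = gls_beta(theta, psi, Zf, sigma_v2, names)
    theta_fh, gamma = eblup(theta_all, psi_all, Z, beta, sigma_v2)
    mse_logit = fh_mse(
        np.where(missing, 0.0, psi_all), Z, sigma_v2, beta_cov,
        method=method, missing=missing,
    )
    p_fh, mse_p, lo, hi = back_transform(theta_fh, mse_logit, alpha)
    ll_ml = profile_loglik(sigma_v2, theta, psi, Zf, "ML")
    ll = profile_loglik(sigma_v2, theta, psi, Zf, method)
    aic = -2.0 * ll_ml + 2.0 * (len(beta) + 1)
    return FHFit(
        district_id=inputs["district_id"].to_numpy(),
        beta=pd.Series(beta, index=names),
        beta_cov=beta_cov,
        sigma_v2=sigma_v2, gamma=gamma, theta_fh=theta_fh, mse_logit=mse_logit,
        p_fh=p_fh, mse_p=mse_p, ci_low=lo, ci_high=hi,
        loglik=ll, aic=aic, converged=True, method=method.upper(),
        covariates=list(covariates),
    )


def select_model_aic(
    inputs: pd.DataFrame, candidates: list[list[str]]
) -> tuple[pd.DataFrame, list[str]]:
    """Rank candidate covariate sets by ML AIC; ties go to fewer parameters.

    AIC = -2*loglik_ML + 2*(p+1), the +1 counting sigma_v^2. All candidates
    are fit by ML so likelihoods are comparable.
    """
    if not candidates:
        raise ValueError("need at least one candidate covariate set")
    rows = []
    fits: list = []
    for cand in candidates:
        try:
            fit = fit_fh(inputs, cand, method="ML")
            rows.append({"covariates": tuple(cand), "n_params": len(cand) + 2,
                         "loglik": fit.loglik, "aic": fit.aic, "converged": True})
            fits.append(fit)
        except (FHConvergenceError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            logger.warning("candidate %s failed: %s", cand, exc)
            rows.append({"covariates": tuple(cand), "n_params": len(cand) + 2,
                         "loglik": np.nan, "aic": np.inf, "converged": False})
            fits.append(None)
    table = pd.DataFrame(rows)
    if not table["converged"].any():
        raise FHConvergenceError("no candidate model converged")
    table = table.sort_values(["aic", "n_params"], kind="stable").reset_index(drop=True)
    best = list(table.iloc[0]["covariates"])
    return table, best
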