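"""Unit-level logistic mixed model, EBP district prevalence, bootstrap MSE.

Model:  logit P(y_ij = 1 | x_ij, v_i) = x_ij' beta + v_i,  v_i ~ N(0, sigma_v^2),
with y_ij conditionally independent Bernoulli. The marginal likelihood
integrates the random intercept out per district with adaptive Gauss-Hermite
quadrature centred at the posterior mode. Survey weights are deliberately NOT
used in fitting: the working model is the unweighted population model, so on
an unequal-probability sample the fit is model-based, not design-based —
users of informative designs should be aware of this.

The district prevalence predictor is the empirical best predictor (EBP)

    p_hat_i = ( sum_{j in S} y_ij + sum_{j in S'} p_hat_ij ) / N_i,

summing observed outcomes over the sampled set S and plugged-in predicted
probabilities p_hat_ij = expit(x_ij' beta_hat + v_hat_i) over the non-sampled
set S', with v_hat_i the empirical-Bayes mode (0 for districts absent from
the fitting sample). Its MSE comes from a finite-population parametric
bootstrap: regenerate every unit's outcome from the fitted model, refit on
the same sampled units, recompute the EBP, and average the squared error
against each replicate's realized finite-population prevalence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp

from .design import build_design

logger = logging.getLogger(__name__)

__all__ = [
    "UnitModelFit",
    "DistrictFrame",
    "EBPEstimate",
    "SeparationError",
    "fit_logistic_mixed",
    "predict_units",
    "ebp_prevalence",
    "bootstrap_mse",
    "make_district_frames",
]

_LOG2PI = np.log(2.0 * np.pi)
_MIN_LOG_SIGMA = np.log(1e-4)
_MAX_LOG_SIGMA = np.log(10.0)


class SeparationError(ValueError):
    """A covariate level perfectly predicts the outcome."""


@dataclass
class UnitModelFit:
    beta: pd.Series
    sigma_v2: float
    v_hat: pd.Series  # EB modes indexed by district_id (fitting sample only)
    loglik: float
    converged: bool
    covariates: list[str]
    levels: dict
    n_quad: int

    def summary(self) -> dict:
        return {
            "beta": {k: float(v) for k, v in self.beta.items()},
            "sigma_v2": float(self.sigma_v2),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_quad": self.n_quad,
        }


@dataclass
class DistrictFrame:
    """Population bookkeeping for one district: N_i = |S| + |S'|.

    ``nonsampled`` may also be a covariate subsample standing in for S' (an
    auxiliary-survey frame); EBP computation then scales its mean prediction
    up to the N_i - n_i non-sampled individuals.
    """

    district_id: int
    N: int
    sampled: pd.DataFrame  # covariates + y
    nonsampled: pd.DataFrame  # covariates only

    def __post_init__(self):
        if self.N < len(self.sampled):
            raise ValueError(
                f"district {self.district_id}: N={self.N} smaller than sample"
            )

    @property
    def is_full_frame(self) -> bool:
        return len(self.sampled) + len(self.nonsampled) == self.N


@dataclass
class EBPEstimate:
    district_id: int
    p_ebp: float
    mse_boot: float
    ci: tuple[float, float]
    n: int
    N: int


# ---------------------------------------------------------------------------
# marginal likelihood by adaptive Gauss-Hermite quadrature


class _QuadCore:
    """Sorted-by-district arrays + quadrature machinery for one design."""

    def __init__(self, X: np.ndarray, y: np.ndarray, district: np.ndarray,
                 n_quad: int = 15):
        codes, counts = np.unique(district, return_counts=True)
        self.district_ids = codes
        self.m = len(codes)
        order = np.argsort(district, kind="stable")
        self.order = order
        self.X = np.ascontiguousarray(X[order])
        self.y = np.asarray(y, dtype=float)[order]
        self.codes = np.searchsorted(codes, district[order])
        self.starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        t, w = hermgauss(n_quad)
        self.t = t
        self.logw_t2 = np.log(w) + t**2
        self._v_warm = np.zeros(self.m)

    def set_outcomes(self, y: np.ndarray) -> None:
        self.y = np.asarray(y, dtype=float)[self.order]

    def modes(self, eta0: np.ndarray, sigma_v2: float,
              tol: float = 1e-10, max_iter: int = 100):
        """Posterior modes v_hat_i and curvatures h_i (strictly concave)."""
        v = self._v_warm.copy()
        ysum = np.add.reduceat(self.y, self.starts)
        for _ in range(max_iter):
            p = expit(eta0 + v[self.codes])
            g = ysum - np.add.reduceat(p, self.starts) - v / sigma_v2
            h = np.add.reduceat(p * (1.0 - p), self.starts) + 1.0 / sigma_v2
            step = np.clip(g / h, -4.0, 4.0)
            v += step
            if np.max(np.abs(step)) < tol:
                break
        p = expit(eta0 + v[self.codes])
        h = np.add.reduceat(p * (1.0 - p), self.starts) + 1.0 / sigma_v2
        self._v_warm = v
        return v, h

    def loglik_grad(self, beta: np.ndarray, sigma_v2: float,
                    with_grad: bool = True):
        """Marginal log-likelihood, and its gradient in (beta, log sigma).

        The gradient applies the Fisher identity — the posterior-weighted
        complete-data score — on the same adaptive quadrature nodes.
        """
        eta0 = self.X @ beta
        v, h = self.modes(eta0, sigma_v2)
        s = 1.0 / np.sqrt(h)
        vk = v[:, None] + np.sqrt(2.0) * s[:, None] * self.t[None, :]  # (m,K)
        eta = eta0[:, None] + vk[self.codes]  # (n,K)
        sgn = 2.0 * self.y - 1.0
        ll_unit = -np.logaddexp(0.0, -sgn[:, None] * eta)
        dsum = np.add.reduceat(ll_unit, self.starts, axis=0)  # (m,K)
        log_phi = -0.5 * (_LOG2PI + np.log(sigma_v2)) - vk**2 / (2.0 * sigma_v2)
        a = self.logw_t2[None, :] + dsum + log_phi
        logL = 0.5 * np.log(2.0) + np.log(s) + logsumexp(a, axis=1)
        ll = float(np.sum(logL))
        if not with_grad:
            return ll, None, v
        wpost = np.exp(a - (logL - 0.5 * np.log(2.0) - np.log(s))[:, None])  # (m,K)
        p = expit(eta)
        resid = self.y - np.sum(wpost[self.codes] * p, axis=1)
        g_beta = self.X.T @ resid
        # d/d(sigma^2) log phi = v^2/(2 sig^4) - 1/(2 sig^2); chain to log sigma
        dsig2 = np.sum(wpost * (vk**2 / (2.0 * sigma_v2**2) - 0.5 / sigma_v2))
        g_logsig = dsig2 * 2.0 * sigma_v2
        return ll, np.concatenate([g_beta, [g_logsig]]), v


def _check_separation(X: np.ndarray, names: list[str], y: np.ndarray) -> None:
    for j, nm in enumerate(names):
        if nm == "intercept":
            continue
        col = X[:, j]
        for val in (0.0, 1.0):
            mask = col == val
            if mask.any() and mask.sum() < len(y):
                sub = y[mask]
                if sub.min() == sub.max() and not (y.min() == y.max()):
                    if len(np.unique(col)) <= 2:
                        raise SeparationError(
                            f"level '{nm}'={int(val)} perfectly predicts y={int(sub[0])}"
                        )


def _start_values(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plain logistic IRLS for starting coefficients."""
    beta = np.zeros(X.shape[1])
    beta[0] = np.log((y.mean() + 1e-6) / (1.0 - y.mean() + 1e-6))
    for _ in range(25):
        p = expit(X @ beta)
        w = np.maximum(p * (1.0 - p), 1e-6)
        try:
            delta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (y - p))
        except np.linalg.LinAlgError:
            break
        beta += np.clip(delta, -5.0, 5.0)
        if np.max(np.abs(delta)) < 1e-8:
            break
    return beta


def _fit_core(core: _QuadCore, start: np.ndarray, max_iter: int = 200):
    def nll(params):
        ll, grad, _ = core.loglik_grad(params[:-1], np.exp(2.0 * params[-1]))
        return -ll, -grad

    bounds = [(None, None)] * (len(start) - 1) + [(_MIN_LOG_SIGMA, _MAX_LOG_SIGMA)]
    res = minimize(
        nll, start, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-6},
    )
    return res


def fit_logistic_mixed(
    records: pd.DataFrame,
    covariates: list[str],
    n_quad: int = 15,
    max_iter: int = 200,
) -> UnitModelFit:
    """ML fit of the random-intercept logistic model.

    ``records`` needs district_id, y, and the covariate columns. Raises
    :class:`SeparationError` when a binary covariate level perfectly predicts
    the outcome, and ``RuntimeError`` (with the optimizer result attached) on
    non-convergence.
    """
    if records["district_id"].nunique() < 2:
        raise ValueError("need at least 2 districts")
    y = records["y"].to_numpy(float)
    if y.min() == y.max():
        raise ValueError("outcome is constant; model not identifiable")
    X, names, levels = build_design(records, covariates)
    _check_separation(X, names, y)
    core = _QuadCore(X, y, records["district_id"].to_numpy(), n_quad)
    start = np.concatenate([_start_values(X, y), [np.log(0.3)]])
    res = _fit_core(core, start, max_iter)
    if not res.success and "ABNORMAL" in str(res.message):
        err = RuntimeError(f"GLMM fit did not converge: {res.message}")
        err.trace = res
        raise err
    beta = res.x[:-1]
    sigma_v2 = float(np.exp(2.0 * res.x[-1]))
    ll, _, v = core.loglik_grad(beta, sigma_v2, with_grad=False)
    return UnitModelFit(
        beta=pd.Series(beta, index=names),
        sigma_v2=sigma_v2,
        v_hat=pd.Series(v, index=pd.Index(core.district_ids, name="district_id")),
        loglik=ll,
        converged=bool(res.success),
        covariates=list(covariates),
        levels=levels,
        n_quad=n_quad,
    )


def loglik_trapezoid(
    records: pd.DataFrame, covariates: list[str],
    beta: np.ndarray, sigma_v2: float,
    n_points: int = 201, half_width_sd: float = 10.0,
) -> float:
    """Brute-force per-district likelihood by trapezoid integration over v.

    Independent check of the quadrature: integrates exp(loglik_i(v)) phi(v)
    on a wide uniform grid centred at the posterior mode.
    """
    X, _, _ = build_design(records, covariates)
    y = records["y"].to_numpy(float)
    core = _QuadCore(X, y, records["district_id"].to_numpy(), 15)
    eta0 = core.X @ np.asarray(beta, float)
    v, h = core.modes(eta0, sigma_v2)
    s = 1.0 / np.sqrt(h)
    total = 0.0
    for i in range(core.m):
        lo = core.starts[i]
        hi = core.starts[i + 1] if i + 1 < core.m else len(y)
        grid = np.linspace(v[i] - half_width_sd * s[i], v[i] + half_width_sd * s[i],
                           n_points)
        eta = eta0[lo:hi, None] + grid[None, :]
        sgn = 2.0 * core.y[lo:hi] - 1.0
        ll = np.sum(-np.logaddexp(0.0, -sgn[:, None] * eta), axis=0)
        ll += -0.5 * (_LOG2PI + np.log(sigma_v2)) - grid**2 / (2.0 * sigma_v2)
        dv = grid[1] - grid[0]
        wts = np.full(n_points, dv)
        wts[[0, -1]] = dv / 2.0
        total += logsumexp(ll + np.log(wts))
    return float(total)


def predict_units(fit: UnitModelFit, frame: pd.DataFrame) -> np.ndarray:
    """Plug-in probabilities expit(x'beta_hat + v_hat_i) for frame rows.

    Districts absent from the fitting sample use v_hat = 0. Unseen covariate
    levels raise :class:`~saeprev.design.UnseenLevelError`.
    """
    X, _, _ = build_design(frame, fit.covariates, levels=fit.levels)
    v = fit.v_hat.reindex(frame["district_id"]).fillna(0.0).to_numpy()
    return expit(X @ fit.beta.to_numpy() + v)


def ebp_prevalence(fit: UnitModelFit, frame: DistrictFrame) -> float:
    """EBP district prevalence (sum of observed y + predicted probabilities)/N."""
    if frame.N == 0:
        raise ValueError(f"district {frame.district_id}: N is 0")
    n_i = len(frame.sampled)
    ysum = float(frame.sampled["y"].sum()) if n_i else 0.0
    n_ns = frame.N - n_i
    if n_ns == 0 or len(frame.nonsampled) == 0:
        pred_sum = 0.0 if n_ns == 0 else np.nan
    else:
        ns = frame.nonsampled.copy()
        if "district_id" not in ns.columns:
            ns["district_id"] = frame.district_id
        p = predict_units(fit, ns)
        # scale a partial auxiliary frame up to the N - n non-sampled units
        pred_sum = float(p.sum()) if frame.is_full_frame else n_ns * float(p.mean())
    return (ysum + pred_sum) / frame.N


def make_district_frames(pop, sample: "pd.DataFrame | object") -> dict[int, DistrictFrame]:
    """Build full-population DistrictFrames from a synthetic population and its
    drawn sample (S' = every population unit not in the sample)."""
    records = getattr(sample, "records", sample)
    sampled_ids = set(records["unit_id"])
    covs = [c for c in pop.units.columns if c not in ("eta", "y")]
    frames = {}
    for d, sub in pop.units.groupby("district_id"):
        in_s = sub["unit_id"].isin(sampled_ids)
        frames[d] = DistrictFrame(
            district_id=d,
            N=len(sub),
            sampled=records[records["district_id"] == d].copy(),
            nonsampled=sub.loc[~in_s, covs].copy(),
        )
    return frames


def bootstrap_mse(
    fit: UnitModelFit,
    frames: dict[int, DistrictFrame],
    B: int = 200,
    seed: int | None = None,
    max_fail: float = 0.2,
) -> pd.DataFrame:
    """Finite-population parametric bootstrap MSE of the EBP.

    Per replicate: draw fresh district effects v* ~ N(0, sigma_v2_hat),
    regenerate Bernoulli outcomes for every unit (sampled and non-sampled),
    record the replicate's finite-population truth p*_i, refit the model on
    the original sampled units (fixed design, random outcomes), recompute the
    EBP, and accumulate (p_ebp* - p*)^2. Returns a per-district frame with
    columns district_id, mse_boot, n_boot.
    """
    if B < 2:
        raise ValueError("B must be >= 2")
    rng = np.random.default_rng(seed)
    dlist = sorted(frames)
    m = len(dlist)
    beta_hat = fit.beta.to_numpy()
    sig_hat = np.sqrt(fit.sigma_v2)

    # fixed design pieces, concatenated across districts
    Xs_parts, ys_codes, Xns_parts, ns_codes = [], [], [], []
    scale = np.zeros(m)  # weight of each S' unit toward the district total
    N = np.zeros(m)
    n_s = np.zeros(m, dtype=int)
    for k, d in enumerate(dlist):
        fr = frames[d]
        N[k] = fr.N
        n_s[k] = len(fr.sampled)
        if n_s[k]:
            X, _, _ = build_design(fr.sampled, fit.covariates, levels=fit.levels)
            Xs_parts.append(X)
            ys_codes.append(np.full(n_s[k], k))
        n_ns_units = len(fr.nonsampled)
        if n_ns_units:
            ns = fr.nonsampled
            X, _, _ = build_design(ns, fit.covariates, levels=fit.levels)
            Xns_parts.append(X)
            ns_codes.append(np.full(n_ns_units, k))
            scale[k] = (fr.N - n_s[k]) / n_ns_units
    Xs = np.vstack(Xs_parts)
    cs = np.concatenate(ys_codes)
    Xns = np.vstack(Xns_parts) if Xns_parts else np.zeros((0, Xs.shape[1]))
    cns = np.concatenate(ns_codes) if ns_codes else np.zeros(0, dtype=int)
    eta_s0 = Xs @ beta_hat
    eta_ns0 = Xns @ beta_hat

    core = _QuadCore(Xs, np.zeros(len(cs)), cs, fit.n_quad)
    start = np.concatenate([beta_hat, [np.log(max(sig_hat, 1e-3))]])

    acc = np.zeros(m)
    n_ok = 0
    n_fail = 0
    for b in range(B):
        v_star = rng.normal(0.0, sig_hat, m)
        ys = (rng.random(len(cs)) < expit(eta_s0 + v_star[cs])).astype(float)
        yns = (rng.random(len(cns)) < expit(eta_ns0 + v_star[cns])).astype(float)
        truth = (np.bincount(cs, ys, m) + scale * np.bincount(cns, yns, m)) / N
        if ys.min() == ys.max():
            n_fail += 1
            continue
        core.set_outcomes(ys)
        core._v_warm = np.zeros(core.m)
        try:
            res = _fit_core(core, start, max_iter=200)
        except (np.linalg.LinAlgError, FloatingPointError):  # pragma: no cover
            n_fail += 1
            continue
        if not np.isfinite(res.fun):
            n_fail += 1
            continue
        beta_b = res.x[:-1]
        sig2_b = float(np.exp(2.0 * res.x[-1]))
        _, _, v_b = core.loglik_grad(beta_b, sig2_b, with_grad=False)
        v_full = np.zeros(m)  # districts absent from S keep v_hat* = 0
        v_full[core.district_ids] = v_b
        p_ns = expit(Xns @ beta_b + v_full[cns])
        ebp_b = (np.bincount(cs, ys, m) + scale * np.bincount(cns, p_ns, m)) / N
        acc += (ebp_b - truth) ** 2
        n_ok += 1
    if n_fail > max_fail * B:
        raise RuntimeError(
            f"bootstrap refit failure rate {n_fail / B:.0%} exceeds {max_fail:.0%}"
        )
    return pd.DataFrame(
        {"district_id": dlist, "mse_boot": acc / n_ok, "n_boot": n_ok}
    )


def ebp_estimates(
    fit: UnitModelFit,
    frames: dict[int, DistrictFrame],
    B: int = 200,
    seed: int | None = None,
    alpha: float = 0.05,
    skip_unsampled: bool = False,
) -> pd.DataFrame:
    """EBP point estimates plus bootstrap MSEs and truncated normal CIs.

    ``skip_unsampled`` drops districts with no sampled units (as one would
    when no auxiliary survey covers them) instead of predicting with v_hat=0.
    """
    from scipy.stats import norm

    use = {
        d: fr for d, fr in frames.items()
        if not (skip_unsampled and len(fr.sampled) == 0)
    }
    mse = bootstrap_mse(fit, use, B=B, seed=seed).set_index("district_id")
    z = norm.ppf(1.0 - alpha / 2.0)
    rows = []
    for d in sorted(use):
        fr = use[d]
        p = ebp_prevalence(fit, fr)
        mb = float(mse.loc[d, "mse_boot"])
        half = z * np.sqrt(mb)
        rows.append(
            dict(district_id=d, p_ebp=p, mse_boot=mb,
                 ci_low=max(p - half, 0.0), ci_high=min(p + half, 1.0),
                 n=len(fr.sampled), N=fr.N)
        )
    return pd.DataFrame(rows)
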