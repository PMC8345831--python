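"""Design-weighted direct district prevalence with linearization SEs.

The direct estimator is the Hájek ratio p_hat_i = sum(w*y)/sum(w) over the
district's sampled records. Its variance is estimated by Taylor linearization
with clusters (PSUs) as the with-replacement resampling unit within the
district stratum. The logit transform theta_hat = logit(p_hat) with
delta-method sampling variance psi = se^2 / (p_hat(1-p_hat))^2 feeds the
area-level model, which treats psi as known.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logit
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "DirectEstimate",
    "SinglePSUError",
    "direct_prevalence",
    "linearization_se",
    "logit_transform",
    "direct_estimates",
    "DIRECT_COLUMNS",
]

DIRECT_COLUMNS = [
    "district_id",
    "n",
    "p_hat",
    "se",
    "ci_low",
    "ci_high",
    "cv_pct",
    "theta_hat",
    "psi",
    "fh_eligible",
]


class SinglePSUError(ValueError):
    """Variance is not estimable from a single PSU."""


@dataclass
class DirectEstimate:
    district_id: int
    p_hat: float
    se: float
    ci: tuple[float, float]
    n: int
    cv_pct: float
    theta_hat: float
    psi: float
    fh_eligible: bool


def direct_prevalence(y: np.ndarray, weights: np.ndarray) -> float:
    """Hájek ratio sum(w*y)/sum(w); invariant to the weight scale."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if y.size == 0:
        raise ValueError("no records")
    if (w <= 0).any():
        raise ValueError("weights must all be positive")
    b = w.sum()
    return float(w @ y / b)


def _psu_linearized_totals(y, w, psu) -> tuple[np.ndarray, float]:
    """PSU totals of the linearized ratio scores z = w*(y - p_hat)/B."""
    p_hat = direct_prevalence(y, w)
    b = np.asarray(w, dtype=float).sum()
    z = np.asarray(w, dtype=float) * (np.asarray(y, dtype=float) - p_hat) / b
    totals = pd.Series(z).groupby(pd.Series(np.asarray(psu))).sum().to_numpy()
    return totals, p_hat


def linearization_se(
    y: np.ndarray, weights: np.ndarray, psu: np.ndarray
) -> float:
    """Taylor-linearized SE of the Hájek ratio, PSUs with replacement.

    Uses the single-stratum form n_psu/(n_psu-1) * sum((Z_c - Z_bar)^2) on the
    PSU totals of the linearized scores.
    """
    totals, _ = _psu_linearized_totals(y, weights, psu)
    n_psu = len(totals)
    if n_psu < 2:
        raise SinglePSUError("variance not estimable: district has a single PSU")
    var = n_psu / (n_psu - 1) * np.sum((totals - totals.mean()) ** 2)
    return float(np.sqrt(max(var, 0.0)))


def _collapsed_se(totals: np.ndarray, n_other: int) -> float:
    """SE for a single-PSU district collapsed with a neighbour stratum.

    The neighbour's PSUs carry zero linearized score for this district's
    domain, so only their count enters the degrees of freedom.
    """
    z = np.concatenate([totals, np.zeros(n_other)])
    n_psu = len(z)
    var = n_psu / (n_psu - 1) * np.sum((z - z.mean()) ** 2)
    return float(np.sqrt(max(var, 0.0)))


def logit_transform(p_hat: float, se: float) -> tuple[float, float]:
    """theta = logit(p); psi = se^2 / (p(1-p))^2 by the delta method."""
    if not 0.0 < p_hat < 1.0:
        raise ValueError("logit transform requires 0 < p_hat < 1")
    return float(logit(p_hat)), float(se**2 / (p_hat * (1.0 - p_hat)) ** 2)


def direct_estimates(
    records: pd.DataFrame,
    alpha: float = 0.05,
    on_single_psu: str = "collapse",
) -> pd.DataFrame:
    """Per-district direct estimates from a survey-record table.

    ``records`` needs columns district_id, cluster_id, weight, y. Districts
    with p_hat of exactly 0 or 1 keep their estimate and truncated CI but are
    flagged ``fh_eligible=False`` (psi undefined). Single-PSU districts have
    their variance computed against a neighbouring district's PSUs
    (``on_single_psu="collapse"``) or raise (``"error"``).
    """
    for col in ("district_id", "cluster_id", "weight", "y"):
        if col not in records.columns:
            raise ValueError(f"records missing column '{col}'")
    if not records["y"].isin([0, 1]).all():
        raise ValueError("y must be binary 0/1")
    if (records["weight"] <= 0).any():
        raise ValueError("weights must all be positive")
    zcrit = norm.ppf(1.0 - alpha / 2.0)
    grouped = dict(tuple(records.groupby("district_id", sort=True)))
    districts = sorted(grouped)
    psu_counts = {d: grouped[d]["cluster_id"].nunique() for d in districts}
    rows = []
    for pos, d in enumerate(districts):
        sub = grouped[d]
        y, w, psu = sub["y"].to_numpy(), sub["weight"].to_numpy(), sub["cluster_id"]
        totals, p_hat = _psu_linearized_totals(y, w, psu)
        if len(totals) >= 2:
            n_psu = len(totals)
            var = n_psu / (n_psu - 1) * np.sum((totals - totals.mean()) ** 2)
            se = float(np.sqrt(max(var, 0.0)))
        elif on_single_psu == "collapse" and len(districts) > 1:
            neigh = districts[pos + 1] if pos + 1 < len(districts) else districts[pos - 1]
            logger.warning(
                "district %s has a single PSU; collapsing with district %s "
                "for variance estimation", d, neigh
            )
            se = _collapsed_se(totals, psu_counts[neigh])
        else:
            raise SinglePSUError(
                f"district {d} has a single PSU; variance not estimable"
            )
        ci = (max(p_hat - zcrit * se, 0.0), min(p_hat + zcrit * se, 1.0))
        if 0.0 < p_hat < 1.0:
            theta, psi = logit_transform(p_hat, se)
            eligible = True
        else:
            theta, psi, eligible = np.nan, np.nan, False
            logger.warning("district %s has p_hat=%s; excluded from FH input", d, p_hat)
        cv = 100.0 * se / p_hat if p_hat > 0 else np.nan
        rows.append(
            dict(
                district_id=d, n=len(sub), p_hat=p_hat, se=se,
                ci_low=ci[0], ci_high=ci[1], cv_pct=cv,
                theta_hat=theta, psi=psi, fh_eligible=eligible,
            )
        )
    return pd.DataFrame(rows, columns=DIRECT_COLUMNS)
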