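"""Categorical design-matrix construction shared by the generator and the models.

Treatment (reference-cell) coding with the first listed category as the
reference level: age 15-19, male, no education, single, 0 partners.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from pandas.api.types import is_numeric_dtype

#: Canonical level order per covariate; the first level is the reference.
CATEGORY_ORDERS: dict[str, list[str]] = {
    "sex": ["male", "female"],
    "age_group": ["15-19", "20-24", "25-34", "35-44", "45-64"],
    "education": [
        "none",
        "incomplete_primary",
        "primary",
        "incomplete_secondary",
        "complete_secondary_plus",
    ],
    "marital": ["single", "married", "previously_married"],
    "partners": ["0", "1", "2plus"],
}


class UnseenLevelError(ValueError):
    """A covariate level appears in prediction data but not in the fit."""


def resolve_levels(values: pd.Series, name: str) -> list[str]:
    """Order the observed levels of one covariate, reference first."""
    observed = set(values.astype(str).unique())
    order = CATEGORY_ORDERS.get(name, sorted(observed))
    levels = [lv for lv in order if lv in observed]
    levels += sorted(observed - set(order))
    return levels


def build_design(
    df: pd.DataFrame,
    covariates: list[str],
    levels: dict[str, list[str] | None] | None = None,
) -> tuple[np.ndarray, list[str], dict[str, list[str] | None]]:
    """Build an intercept + dummy design matrix.

    Parameters
    ----------
    df : frame holding the covariate columns.
    covariates : column names to include, in order.
    levels : per-covariate level lists from a previous fit (``None`` value =
        numeric passthrough). When given, any level in ``df`` outside the
        stored list raises :class:`UnseenLevelError`; when omitted, levels are
        inferred from the data via :func:`resolve_levels`.

    Returns
    -------
    (X, column_names, levels) with ``X`` of shape (n, 1 + n_dummies).
    """
    n = len(df)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    out_levels: dict[str, list[str] | None] = {}
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate column '{cov}' not found")
        s = df[cov]
        fixed = levels.get(cov, "infer") if levels is not None else "infer"
        if fixed is None or (fixed == "infer" and is_numeric_dtype(s)):
            cols.append(np.asarray(s, dtype=float))
            names.append(cov)
            out_levels[cov] = None
            continue
        vals = s.astype(str)
        if fixed == "infer":
            lvls = resolve_levels(vals, cov)
        else:
            lvls = list(fixed)
            unseen = sorted(set(vals.unique()) - set(lvls))
            if unseen:
                raise UnseenLevelError(
                    f"covariate '{cov}' has level(s) {unseen} not present in the fit"
                )
        arr = vals.to_numpy()
        for lv in lvls[1:]:
            cols.append((arr == lv).astype(float))
            names.append(f"{cov}={lv}")
        out_levels[cov] = lvls
    return np.column_stack(cols), names, out_levels
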