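"""Synthetic finite populations and two-stage cluster survey samples.

Emulates the structure of a national HIV-prevalence setting: ~70 districts,
district random effects on the logit scale, individual risk covariates drawn
from published marginal distributions, a two-stage sample (PPS selection of
clusters, simple random sampling of individuals within cluster), and a biased
noisy district-level proxy of true prevalence standing in for antenatal-care
(ANC) surveillance prevalence.

Everything downstream (direct estimation, the area-level model, the unit-level
model) can be exercised and validated against the known simulated truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import CATEGORY_ORDERS, build_design

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationConfig",
    "Population",
    "SurveySample",
    "generate_population",
    "draw_two_stage_sample",
    "compute_anc_covariate",
    "lqas_style_frame",
    "DEFAULT_MARGINALS",
    "DEFAULT_BETA",
    "SAMPLE_COLUMNS",
]


def _normalized(d: dict[str, float]) -> dict[str, float]:
    tot = sum(d.values())
    return {k: v / tot for k, v in d.items()}


#: Population covariate marginals: survey-weighted respondent percentages
#: (sex, five age bands, five education levels, marital status with
#: widowed/divorced/separated collapsed, sexual partners in the last year),
#: renormalized so each map sums to exactly 1.
DEFAULT_MARGINALS: dict[str, dict[str, float]] = {
    "sex": _normalized({"male": 0.479, "female": 0.521}),
    "age_group": _normalized(
        {"15-19": 0.239, "20-24": 0.186, "25-34": 0.252, "35-44": 0.163, "45-64": 0.144}
    ),
    "education": _normalized(
        {
            "none": 0.078,
            "incomplete_primary": 0.437,
            "primary": 0.162,
            "incomplete_secondary": 0.240,
            "complete_secondary_plus": 0.083,
        }
    ),
    "marital": _normalized(
        {"single": 0.311, "married": 0.557, "previously_married": 0.133}
    ),
    "partners": _normalized({"0": 0.141, "1": 0.702, "2plus": 0.156}),
}

#: Logit-scale coefficients of the data-generating outcome model, keyed by
#: design-matrix column (reference levels carry no coefficient). The intercept
#: is set so the population prevalence lands near 6% under the default
#: random-effect variances (marginalizing the district and cluster effects
#: raises the mean above expit of the mean logit), with risk gradients in the
#: directions reported for adult HIV in East Africa: higher for women, rising
#: with age, higher after marital dissolution and with multiple partners.
DEFAULT_BETA: dict[str, float] = {
    "intercept": -4.9,
    "sex=female": 0.50,
    "age_group=20-24": 0.60,
    "age_group=25-34": 1.10,
    "age_group=35-44": 1.30,
    "age_group=45-64": 1.20,
    "education=incomplete_primary": 0.20,
    "education=primary": 0.10,
    "education=incomplete_secondary": -0.10,
    "education=complete_secondary_plus": -0.30,
    "marital=married": 0.20,
    "marital=previously_married": 0.80,
    "partners=1": 0.30,
    "partners=2plus": 0.70,
}

#: Column order of the survey-sample CSV emitted by :meth:`SurveySample.to_csv`.
SAMPLE_COLUMNS = [
    "district_id",
    "cluster_id",
    "weight",
    "y",
    "sex",
    "age_group",
    "education",
    "marital",
    "partners",
]

COVARIATES = list(DEFAULT_MARGINALS)


@dataclass
class PopulationConfig:
    """Parameters of the synthetic finite population.

    district_sizes of ``None`` means sizes are drawn log-uniformly on
    ``size_range`` (districts span roughly an order of magnitude in
    population, as real districts do).
    """

    n_districts: int = 70
    district_sizes: np.ndarray | list[int] | None = None
    size_range: tuple[int, int] = (2000, 20000)
    clusters_per_district: int = 20
    cluster_size_cv: float = 0.5  # log-scale SD of cluster sizes
    beta_true: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BETA))
    sigma_v_true: float = 0.25
    #: SD of a logit-scale cluster (enumeration-area) random effect: household
    #: clusters correlate strongly in HIV risk (fishing villages, transport
    #: corridors), giving district design effects around 2-3 as population
    #: HIV surveys exhibit. 0 disables clustering.
    sigma_cluster: float = 0.9
    covariate_marginals: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARGINALS.items()}
    )
    #: Dirichlet concentration for district-level covariate composition:
    #: each district's category shares are drawn ~ Dirichlet(c * national
    #: shares), so districts differ demographically (as real districts do)
    #: while the expected composition matches the configured marginals.
    #: ``None`` gives every district the identical national composition.
    composition_concentration: float | None = 10.0
    anc_bias: float = 0.3
    anc_noise_sd: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        if self.n_districts < 1:
            raise ValueError("n_districts must be >= 1")
        if self.sigma_v_true < 0:
            raise ValueError("sigma_v_true must be >= 0")
        if self.sigma_cluster < 0:
            raise ValueError("sigma_cluster must be >= 0")
        if self.clusters_per_district < 1:
            raise ValueError("clusters_per_district must be >= 1")
        if self.district_sizes is not None:
            sizes = np.asarray(self.district_sizes)
            if len(sizes) != self.n_districts:
                raise ValueError("district_sizes length must equal n_districts")
            if (sizes < 1).any():
                raise ValueError("district_sizes must all be >= 1")
        for cov, probs in self.covariate_marginals.items():
            tot = sum(probs.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"marginals for '{cov}' sum to {tot}, not 1")
            if any(p < 0 for p in probs.values()):
                raise ValueError(f"marginals for '{cov}' contain negatives")
        for val in self.beta_true.values():
            if not np.isfinite(val):
                raise ValueError("beta_true contains non-finite values")
        if self.composition_concentration is not None and (
            self.composition_concentration <= 0
        ):
            raise ValueError("composition_concentration must be positive or None")


@dataclass
class Population:
    """A realized finite population with known truth."""

    units: pd.DataFrame  # unit_id, district_id, cluster_id, covariates, eta, y
    district_effects: pd.Series  # v_i indexed by district_id
    true_prevalence: pd.Series  # finite-population mean of y per district
    config: PopulationConfig

    @property
    def district_sizes(self) -> pd.Series:
        return self.units.groupby("district_id").size()


@dataclass
class SurveySample:
    """A drawn two-stage sample; district is the stratum, cluster the PSU."""

    records: pd.DataFrame  # SAMPLE_COLUMNS plus unit_id

    def to_csv(self, path) -> None:
        self.records[["unit_id"] + SAMPLE_COLUMNS].to_csv(path, index=False)


def generate_population(config: PopulationConfig) -> Population:
    """Draw a finite population from the unit-level outcome model.

    Per district ``i`` a random effect ``v_i ~ N(0, sigma_v_true^2)`` is drawn;
    each individual receives independent categorical covariates from
    ``covariate_marginals`` and an outcome ``y ~ Bernoulli(expit(x'beta + v_i))``.
    The finite-population true prevalence is the realized mean of ``y``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_districts
    if config.district_sizes is None:
        lo, hi = config.size_range
        sizes = np.exp(rng.uniform(np.log(lo), np.log(hi), m)).astype(int)
        sizes = np.maximum(sizes, 1)
    else:
        sizes = np.asarray(config.district_sizes, dtype=int)
    n_total = int(sizes.sum())
    district_id = np.repeat(np.arange(m), sizes)

    # cluster structure: sizes log-normal around N_i / C so PPS is non-trivial
    cluster_id = np.empty(n_total, dtype=int)
    offset = 0
    for d in range(m):
        n_d = sizes[d]
        c = min(config.clusters_per_district, n_d)
        raw = rng.lognormal(mean=0.0, sigma=config.cluster_size_cv, size=c)
        counts = _allocate(raw, n_d)
        cluster_id[offset : offset + n_d] = d * 10_000 + np.repeat(
            np.arange(c), counts
        )
        offset += n_d

    data = {"unit_id": np.arange(n_total), "district_id": district_id,
            "cluster_id": cluster_id}
    conc = config.composition_concentration
    starts = np.concatenate([[0], np.cumsum(sizes)])
    for cov, probs in config.covariate_marginals.items():
        levels = [lv for lv in CATEGORY_ORDERS.get(cov, sorted(probs)) if lv in probs]
        levels += [lv for lv in probs if lv not in levels]
        p = np.array([probs[lv] for lv in levels])
        if conc is None:
            draws = rng.choice(len(levels), n_total, p=p)
        else:
            # district-specific composition around the national marginals
            district_p = rng.dirichlet(conc * np.maximum(p, 1e-12), size=m)
            draws = np.empty(n_total, dtype=int)
            for d in range(m):
                draws[starts[d] : starts[d + 1]] = rng.choice(
                    len(levels), sizes[d], p=district_p[d]
                )
        data[cov] = np.array(levels, dtype=object)[draws]
    units = pd.DataFrame(data)

    covs = list(config.covariate_marginals)
    X, names, _ = build_design(units, covs)
    unknown = sorted(set(config.beta_true) - set(names))
    if unknown:
        raise ValueError(f"beta_true has keys outside the design: {unknown}")
    beta = np.array([config.beta_true.get(nm, 0.0) for nm in names])
    v = rng.normal(0.0, config.sigma_v_true, m)
    eta = X @ beta + v[district_id]
    if config.sigma_cluster > 0:
        cluster_codes, cluster_idx = np.unique(cluster_id, return_inverse=True)
        u = rng.normal(0.0, config.sigma_cluster, len(cluster_codes))
        eta = eta + u[cluster_idx]
    if not np.isfinite(eta).all():
        raise ValueError("non-finite linear predictor; rejecting config")
    units["eta"] = eta
    units["y"] = (rng.random(n_total) < expit(eta)).astype(int)

    idx = pd.Index(np.arange(m), name="district_id")
    return Population(
        units=units,
        district_effects=pd.Series(v, index=idx, name="v"),
        true_prevalence=units.groupby("district_id")["y"].mean().rename("p_true"),
        config=config,
    )


def _allocate(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder integer allocation of `total` proportional to weights,
    each share at least 1."""
    c = len(weights)
    if total <= c:
        out = np.zeros(c, dtype=int)
        out[:total] = 1
        return out
    share = weights / weights.sum() * (total - c)
    base = np.floor(share).astype(int)
    rem = total - c - base.sum()
    order = np.argsort(-(share - base))
    base[order[:rem]] += 1
    return base + 1


def _pps_systematic(sizes: np.ndarray, n_sel: int, rng: np.random.Generator):
    """Systematic PPS without replacement with certainty selections.

    Returns (selected indices, inclusion probabilities for those indices).
    Clusters whose size share exceeds 1/n_sel are taken with certainty and the
    rest are sampled systematically in random order.
    """
    k = len(sizes)
    if n_sel > k:
        raise ValueError("cannot select more clusters than exist")
    certain: list[int] = []
    remaining = list(range(k))
    a = n_sel
    while a > 0:
        tot = sizes[remaining].sum()
        big = [i for i in remaining if a * sizes[i] >= tot]
        if not big or a == len(remaining):
            if a == len(remaining):
                certain += remaining
                remaining, a = [], 0
            break
        certain += big
        remaining = [i for i in remaining if i not in big]
        a -= len(big)
    sel = list(certain)
    pi = {i: 1.0 for i in certain}
    if a > 0:
        order = rng.permutation(remaining)
        sz = sizes[order].astype(float)
        tot = sz.sum()
        step = tot / a
        points = rng.uniform(0, step) + step * np.arange(a)
        cum = np.cumsum(sz)
        picked = np.searchsorted(cum, points, side="right")
        for j in np.unique(picked):
            i = int(order[j])
            sel.append(i)
            pi[i] = a * sizes[i] / tot
    return sel, pi


def draw_two_stage_sample(
    pop: Population,
    clusters_per_district: int | dict[int, int],
    units_per_cluster: int,
    seed: int | None = None,
) -> SurveySample:
    """Two-stage sample: PPS-by-size clusters, then SRS of individuals.

    The design weight is the inverse overall inclusion probability
    ``1 / (pi_cluster * n_taken / M_cluster)``; when a selected cluster holds
    fewer than ``units_per_cluster`` individuals it is taken in full.
    """
    rng = np.random.default_rng(seed)
    frames = []
    grouped = pop.units.groupby("district_id", sort=True)
    for d, sub in grouped:
        csizes = sub.groupby("cluster_id").size()
        n_clusters = len(csizes)
        a = (
            clusters_per_district[d]
            if isinstance(clusters_per_district, dict)
            else clusters_per_district
        )
        if a > n_clusters:
            raise ValueError(
                f"district {d} has only {n_clusters} clusters; {a} requested"
            )
        sel, pi = _pps_systematic(csizes.to_numpy(), a, rng)
        cluster_ids = csizes.index.to_numpy()
        by_cluster = sub.groupby("cluster_id").indices
        for i in sel:
            cid = cluster_ids[i]
            rows = by_cluster[cid]
            m_c = len(rows)
            take = min(units_per_cluster, m_c)
            chosen = rng.choice(rows, size=take, replace=False)
            rec = sub.iloc[np.sort(chosen)].copy()
            rec["weight"] = m_c / (pi[i] * take)
            frames.append(rec)
    records = pd.concat(frames, ignore_index=True)
    records = records.drop(columns=["eta"])
    return SurveySample(records=records)


def compute_anc_covariate(
    pop: Population,
    anc_bias: float | None = None,
    anc_noise_sd: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Biased noisy area-level proxy of true prevalence on the logit scale.

    ``z_i = logit(p_i) + anc_bias + N(0, anc_noise_sd^2)`` — emulating routine
    ANC surveillance prevalence, which is systematically shifted relative to
    general-population prevalence and measured with error.
    """
    bias = pop.config.anc_bias if anc_bias is None else anc_bias
    noise = pop.config.anc_noise_sd if anc_noise_sd is None else anc_noise_sd
    p = pop.true_prevalence.to_numpy()
    if ((p <= 0) | (p >= 1)).any():
        bad = pop.true_prevalence.index[(p <= 0) | (p >= 1)].tolist()
        raise ValueError(f"true prevalence in {{0,1}} for districts {bad}; logit undefined")
    rng = np.random.default_rng(seed)
    z = logit(p) + bias + rng.normal(0.0, noise, len(p))
    return pd.DataFrame(
        {"district_id": pop.true_prevalence.index.to_numpy(), "anc_logit": z}
    )


def lqas_style_frame(
    pop: Population, per_district_n: int, seed: int | None = None
) -> pd.DataFrame:
    """Per-district simple random subsample of units, outcome stripped.

    Emulates a small fixed-size auxiliary survey carrying risk covariates only,
    usable as the unit-level prediction frame.
    """
    rng = np.random.default_rng(seed)
    keep = []
    for d, rows in pop.units.groupby("district_id").indices.items():
        if per_district_n > len(rows):
            raise ValueError(
                f"district {d} has {len(rows)} units; {per_district_n} requested"
            )
        keep.append(rng.choice(rows, size=per_district_n, replace=False))
    frame = pop.units.iloc[np.sort(np.concatenate(keep))].copy()
    return frame[["unit_id", "district_id"] + COVARIATES].reset_index(drop=True)
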