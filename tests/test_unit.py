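"""Unit-level GLMM: likelihood oracles, EBP arithmetic, bootstrap contracts."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from saeprev import (
    DistrictFrame,
    bootstrap_mse,
    ebp_prevalence,
    fit_logistic_mixed,
    make_district_frames,
    predict_units,
)
from saeprev.design import UnseenLevelError, build_design
from saeprev.unit import (
    SeparationError,
    UnitModelFit,
    _QuadCore,
    ebp_estimates,
    loglik_trapezoid,
)


def _toy_fit(beta, sigma_v2, v_hat=None, covariates=("x",), levels=None):
    names = ["intercept"] + list(covariates)
    return UnitModelFit(
        beta=pd.Series(beta, index=names[: len(beta)]),
        sigma_v2=sigma_v2,
        v_hat=pd.Series(v_hat or {}, dtype=float).rename_axis("district_id"),
        loglik=np.nan,
        converged=True,
        covariates=list(covariates),
        levels=levels or {c: None for c in covariates},
        n_quad=15,
    )


def test_sigma_zero_limit_matches_plain_logistic(glmm_data):
    """With no district heterogeneity the GLMM collapses to ordinary logistic
    regression (statsmodels GLM as the oracle)."""
    rng = np.random.default_rng(1)
    d = np.repeat(np.arange(40), 80)
    x = rng.integers(0, 2, len(d)).astype(float)
    y = (rng.random(len(d)) < expit(-2.0 + 0.6 * x)).astype(int)
    df = pd.DataFrame({"district_id": d, "x": x, "y": y})
    fit = fit_logistic_mixed(df, ["x"])
    X = sm.add_constant(x)
    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    assert fit.sigma_v2 < 0.01
    assert fit.beta["intercept"] == pytest.approx(glm.params[0], abs=5e-3)
    assert fit.beta["x"] == pytest.approx(glm.params[1], abs=5e-3)


def test_quadrature_gradient_matches_finite_differences(glmm_data):
    X, _, _ = build_design(glmm_data, ["x"])
    core = _QuadCore(X, glmm_data["y"].to_numpy(float),
                     glmm_data["district_id"].to_numpy(), 15)
    p0 = np.array([-1.8, 0.4, np.log(0.45)])
    _, grad, _ = core.loglik_grad(p0[:-1], np.exp(2 * p0[-1]))
    eps = 1e-6
    for i in range(3):
        hi, lo = p0.copy(), p0.copy()
        hi[i] += eps
        lo[i] -= eps
        f_hi, _, _ = core.loglik_grad(hi[:-1], np.exp(2 * hi[-1]), with_grad=False)
        f_lo, _, _ = core.loglik_grad(lo[:-1], np.exp(2 * lo[-1]), with_grad=False)
        assert grad[i] == pytest.approx((f_hi - f_lo) / (2 * eps), rel=1e-4, abs=1e-4)


def test_quadrature_matches_trapezoid_integration():
    """Adaptive 50-node quadrature vs 201-point trapezoid on a 5-district toy."""
    rng = np.random.default_rng(2)
    d = np.repeat(np.arange(5), 30)
    x = rng.integers(0, 2, 150).astype(float)
    v = rng.normal(0, 0.5, 5)
    y = (rng.random(150) < expit(-1.5 + 0.5 * x + v[d])).astype(int)
    df = pd.DataFrame({"district_id": d, "x": x, "y": y})
    X, _, _ = build_design(df, ["x"])
    core = _QuadCore(X, y.astype(float), d, 50)
    beta = np.array([-1.5, 0.5])
    ll_quad, _, _ = core.loglik_grad(beta, 0.25, with_grad=False)
    ll_trap = loglik_trapezoid(df, ["x"], beta, 0.25)
    assert ll_quad == pytest.approx(ll_trap, abs=1e-6)


def test_separation_error_names_level():
    df = pd.DataFrame(
        {
            "district_id": [0, 0, 1, 1] * 5,
            "g": (["a", "b"] * 10),
            "y": [1 if g == "a" else 0 for g in ["a", "b"] * 10],
        }
    )
    with pytest.raises(SeparationError, match="g="):
        fit_logistic_mixed(df, ["g"])


def test_constant_outcome_rejected():
    df = pd.DataFrame({"district_id": [0, 0, 1, 1], "x": [0, 1, 0, 1.0],
                       "y": [1, 1, 1, 1]})
    with pytest.raises(ValueError, match="constant"):
        fit_logistic_mixed(df, ["x"])


def test_predict_units_plug_in():
    fit = _toy_fit([0.0, 0.0], 0.1)
    frame = pd.DataFrame({"district_id": [9, 9], "x": [0.0, 0.0]})
    p = predict_units(fit, frame)  # X=0, absent district -> v=0 -> expit(b0)
    assert np.allclose(p, 0.5)
    # hand-computed eta for 3 printed rows
    fit = _toy_fit([-2.0, 0.7], 0.1, v_hat={1: 0.3})
    frame = pd.DataFrame({"district_id": [1, 1, 2], "x": [0.0, 1.0, 1.0]})
    p = predict_units(fit, frame)
    expected = expit(np.array([-2.0 + 0.3, -2.0 + 0.7 + 0.3, -2.0 + 0.7]))
    assert np.allclose(p, expected, atol=1e-12)
    assert np.all((p > 0) & (p < 1))


def test_predict_rejects_unseen_level():
    fit = _toy_fit([0.0, 0.5], 0.1, covariates=("g",), levels={"g": ["a", "b"]})
    frame = pd.DataFrame({"district_id": [1], "g": ["zzz"]})
    with pytest.raises(UnseenLevelError, match="zzz"):
        predict_units(fit, frame)


def test_ebp_toy_arithmetic():
    """N=4, sampled y={1,0}, two non-sampled with p_hat=0.5 -> p=0.5."""
    fit = _toy_fit([0.0, 0.0], 0.1)
    frame = DistrictFrame(
        district_id=3, N=4,
        sampled=pd.DataFrame({"district_id": [3, 3], "x": [0.0, 0.0], "y": [1, 0]}),
        nonsampled=pd.DataFrame({"district_id": [3, 3], "x": [0.0, 0.0]}),
    )
    assert ebp_prevalence(fit, frame) == pytest.approx(0.5)


def test_ebp_census_and_empty_sample_cases():
    fit = _toy_fit([-1.0, 0.5], 0.2)
    census = DistrictFrame(
        district_id=1, N=3,
        sampled=pd.DataFrame({"district_id": [1] * 3, "x": [0, 1, 0.0],
                              "y": [1, 0, 1]}),
        nonsampled=pd.DataFrame({"district_id": [], "x": []}),
    )
    assert ebp_prevalence(fit, census) == pytest.approx(2 / 3)
    empty_s = DistrictFrame(
        district_id=2, N=2,
        sampled=pd.DataFrame({"district_id": [], "x": [], "y": []}),
        nonsampled=pd.DataFrame({"district_id": [2, 2], "x": [0.0, 1.0]}),
    )
    expected = (expit(-1.0) + expit(-0.5)) / 2
    assert ebp_prevalence(fit, empty_s) == pytest.approx(expected)
    with pytest.raises(ValueError):
        DistrictFrame(district_id=9, N=1,
                      sampled=census.sampled, nonsampled=census.nonsampled)


def test_ebp_partial_frame_scales_up():
    """An auxiliary subsample standing in for S' is scaled to N - n."""
    fit = _toy_fit([0.0, 0.0], 0.1)
    frame = DistrictFrame(
        district_id=1, N=10,
        sampled=pd.DataFrame({"district_id": [1, 1], "x": [0.0, 0.0], "y": [1, 1]}),
        nonsampled=pd.DataFrame({"district_id": [1], "x": [0.0]}),  # 1 of 8
    )
    assert ebp_prevalence(fit, frame) == pytest.approx((2 + 8 * 0.5) / 10)


@pytest.fixture(scope="module")
def boot_setup():
    rng = np.random.default_rng(5)
    m, N, n = 10, 80, 30
    d = np.repeat(np.arange(m), N)
    x = rng.integers(0, 2, m * N).astype(float)
    v = rng.normal(0, 0.5, m)
    y = (rng.random(m * N) < expit(-1.5 + 0.5 * x + v[d])).astype(int)
    units = pd.DataFrame({"unit_id": np.arange(m * N), "district_id": d,
                          "x": x, "y": y})
    sampled_idx = np.concatenate(
        [rng.choice(np.where(d == i)[0], n, replace=False) for i in range(m)]
    )
    records = units.iloc[np.sort(sampled_idx)]
    fit = fit_logistic_mixed(records, ["x"])
    frames = {}
    for i in range(m):
        sub = units[units["district_id"] == i]
        in_s = sub["unit_id"].isin(records["unit_id"])
        frames[i] = DistrictFrame(
            district_id=i, N=N,
            sampled=sub[in_s][["district_id", "x", "y"]],
            nonsampled=sub[~in_s][["district_id", "x"]],
        )
    return fit, frames


def test_bootstrap_deterministic_and_nonnegative(boot_setup):
    fit, frames = boot_setup
    a = bootstrap_mse(fit, frames, B=20, seed=7)
    b = bootstrap_mse(fit, frames, B=20, seed=7)
    pd.testing.assert_frame_equal(a, b)
    assert (a["mse_boot"] >= 0).all()
    c = bootstrap_mse(fit, frames, B=20, seed=8)
    assert not np.allclose(a["mse_boot"], c["mse_boot"])


def test_bootstrap_census_district_has_zero_mse(boot_setup):
    fit, frames = boot_setup
    census = {
        0: DistrictFrame(
            district_id=0, N=len(frames[0].sampled),
            sampled=frames[0].sampled,
            nonsampled=frames[0].nonsampled.iloc[:0],
        ),
        1: frames[1],
    }
    out = bootstrap_mse(fit, census, B=20, seed=3).set_index("district_id")
    assert out.loc[0, "mse_boot"] == pytest.approx(0.0, abs=1e-12)
    assert out.loc[1, "mse_boot"] > 0


def test_ebp_estimates_table(boot_setup):
    fit, frames = boot_setup
    out = ebp_estimates(fit, frames, B=20, seed=1)
    assert len(out) == len(frames)
    assert ((out["p_ebp"] >= 0) & (out["p_ebp"] <= 1)).all()
    assert ((out["ci_low"] >= 0) & (out["ci_high"] <= 1)).all()
    assert (out["ci_low"] <= out["p_ebp"]).all()


def test_make_district_frames(small_pop, small_sample):
    frames = make_district_frames(small_pop, small_sample)
    sizes = small_pop.district_sizes
    for d, fr in frames.items():
        assert fr.N == sizes[d]
        assert len(fr.sampled) + len(fr.nonsampled) == fr.N
        assert fr.is_full_frame
        assert "y" not in fr.nonsampled.columns


def test_matches_lme4_glmer():
    """Cross-implementation check against R lme4 on a small fixture."""
    rng = np.random.default_rng(6)
    m, n = 20, 60
    d = np.repeat(np.arange(m), n)
    x = rng.integers(0, 2, m * n).astype(float)
    v = rng.normal(0, 0.6, m)
    y = (rng.random(m * n) < expit(-1.2 + 0.5 * x + v[d])).astype(int)
    df = pd.DataFrame({"district_id": d, "x": x, "y": y})
    fit = fit_logistic_mixed(df, ["x"], n_quad=25)

    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        csv = Path(tmp) / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(
            f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            fit <- glmer(y ~ x + (1|district_id), data=d, family=binomial, nAGQ=25)
            co <- fixef(fit)
            cat(co[1], co[2], unlist(VarCorr(fit))[1], as.numeric(logLik(fit)), sep="\\n")
            """
        )
        try:
            out = subprocess.run(
                ["Rscript", "-e", script], capture_output=True, text=True,
                timeout=300, check=True,
            )
        except (FileNotFoundError, subprocess.CalledProcessError) as exc:
            pytest.fail(f"lme4 oracle unavailable: {exc}")
    b0, b1, s2, ll = map(float, out.stdout.strip().split("\n"))
    assert fit.beta["intercept"] == pytest.approx(b0, abs=2e-3)
    assert fit.beta["x"] == pytest.approx(b1, abs=2e-3)
    assert fit.sigma_v2 == pytest.approx(s2, abs=5e-3)
    assert fit.loglik == pytest.approx(ll, abs=1e-2)
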