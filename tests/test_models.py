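import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from hostmet.models import (
    MassScalingModel,
    fit_lmm,
    lrt,
    pairwise_contrasts_tukey,
    wald_chi2_tests,
)


# ------------------------------------------------------------ mass scaling
def test_noiseless_power_law_is_recovered_exactly():
    mass = np.linspace(0.02, 0.4, 30)
    rate_ml_h = 0.43 * mass**0.84
    df = pd.DataFrame({"host": "Urtica", "mass_g": mass,
                       "vco2_ml_min": rate_ml_h / 60.0})
    m = MassScalingModel().fit(df)
    assert m.exponent_b_ == pytest.approx(0.84, abs=1e-10)
    assert m.coefficients_a_["Urtica"] == pytest.approx(0.43, rel=1e-10)


def test_two_points_give_the_secant_slope():
    df = pd.DataFrame({"host": ["Urtica"] * 2, "mass_g": [0.1, 0.4],
                       "vco2_ml_min": [1e-3, 3e-3]})
    m = MassScalingModel().fit(df)
    secant = (np.log(3e-3) - np.log(1e-3)) / (np.log(0.4) - np.log(0.1))
    assert m.exponent_b_ == pytest.approx(secant, rel=1e-12)


def test_interaction_lrt_has_host_minus_one_df(default_metrics):
    larvae = default_metrics[default_metrics["stage"].isin(["instar3", "instar4"])]
    m = MassScalingModel().fit(larvae)
    assert m.interaction_lrt_["df"] == 2
    assert m.interaction_lrt_["chi2"] >= 0
    assert 0 <= m.interaction_lrt_["p"] <= 1
    assert set(m.coefficients_a_) == {"Urtica", "Salix", "Ribes"}


def test_too_few_points_per_host_is_degenerate():
    df = pd.DataFrame({"host": ["Urtica"] * 3 + ["Salix"] * 2,
                       "mass_g": [0.1, 0.2, 0.3, 0.1, 0.2],
                       "vco2_ml_min": [1e-3] * 5})
    with pytest.raises(ValueError, match="at least 3"):
        MassScalingModel().fit(df)


# ------------------------------------------------------------------- LRT
def test_lrt_of_a_model_against_itself_is_null():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"x": rng.normal(size=50)})
    df["y"] = 1 + df.x + rng.normal(size=50)
    fit = smf.ols("y ~ x", df).fit()
    res = lrt(fit, fit)
    assert res == {"chi2": 0.0, "df": 0, "p": 1.0}


def test_lrt_rejects_different_data_and_reversed_nesting():
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"x": rng.normal(size=60), "g": list("ab") * 30})
    df["y"] = df.x + rng.normal(size=60)
    full = smf.ols("y ~ x + g", df).fit()
    red = smf.ols("y ~ x", df).fit()
    with pytest.raises(ValueError):
        lrt(red, full)  # reversed
    with pytest.raises(ValueError):
        lrt(full, smf.ols("y ~ x", df.iloc[:30]).fit())  # different data


def test_lrt_null_rejection_rate_is_calibrated():
    """No-interaction truth: the interaction LRT rejects at ~alpha."""
    rej = 0
    n_rep = 200
    for s in range(n_rep):
        rng = np.random.default_rng(1000 + s)
        n = 150
        df = pd.DataFrame({"x": rng.normal(size=n),
                           "g": rng.choice(list("abc"), n)})
        df["y"] = (1.0 + 0.5 * df.x + df.g.map({"a": 0, "b": 0.3, "c": -0.2})
                   + rng.normal(size=n))
        full = smf.ols("y ~ x * g", df).fit()
        red = smf.ols("y ~ x + g", df).fit()
        rej += lrt(full, red)["p"] < 0.05
    lo, hi = stats.binom.interval(0.95, n_rep, 0.05)
    assert lo <= rej <= hi


# ------------------------------------------------------------ mixed model
def test_zero_family_variance_reduces_to_ols():
    rng = np.random.default_rng(1)
    n_fam, per = 12, 10
    fam = np.repeat([f"f{i}" for i in range(n_fam)], per)
    host = np.tile(["Urtica", "Salix", "Ribes"], n_fam * per // 3)
    df = pd.DataFrame({"host": host, "family_id": fam})
    mu = df.host.map({"Urtica": 1.0, "Salix": 1.5, "Ribes": 2.0}).to_numpy()
    resid = rng.normal(size=n_fam * per)
    # remove all between-family residual variation: the REML estimate of
    # the family variance hits the zero boundary and GLS collapses to OLS
    resid -= pd.Series(resid).groupby(fam).transform("mean").to_numpy()
    df["y"] = mu + resid
    lmm = fit_lmm(df, "y ~ host")
    ols = smf.ols("y ~ host", df).fit()
    assert lmm.random_variances_["family"] == pytest.approx(0.0, abs=1e-8)
    assert np.allclose(lmm.fixed_effects_["estimate"].to_numpy(),
                       np.asarray(ols.params), atol=1e-6)


def test_balanced_noiseless_design_recovers_group_means_exactly():
    df = pd.DataFrame({
        "g": np.repeat(["a", "b"], 8),
        "family_id": np.tile([f"f{i}" for i in range(4)], 4),
    })
    df["y"] = df.g.map({"a": 2.0, "b": 5.0})
    m = fit_lmm(df, "y ~ g")
    est = dict(zip(m.fixed_effects_["term"], m.fixed_effects_["estimate"]))
    assert est["Intercept"] == pytest.approx(2.0, abs=1e-8)
    assert est["g[T.b]"] == pytest.approx(3.0, abs=1e-8)


def test_family_variance_component_is_recovered():
    """family_sd = 0.3 (variance 0.09), 30 families: the median REML
    estimate over 100 simulated datasets lands within +-50%."""
    estimates = []
    for s in range(100):
        rng = np.random.default_rng(500 + s)
        n_fam, per = 30, 20
        fam = np.repeat(np.arange(n_fam), per)
        y = rng.normal(0, 0.3, n_fam)[fam] + rng.normal(0, 0.5, n_fam * per)
        df = pd.DataFrame({"y": y, "family_id": fam})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_lmm(df, "y ~ 1")
        estimates.append(m.random_variances_["family"])
    assert 0.045 <= np.median(estimates) <= 0.135


def test_nested_random_effect_is_exposed(default_metrics):
    from hostmet.pipeline import fit_vco2_model

    m = fit_vco2_model(default_metrics)
    assert {"family", "individual", "residual"} <= set(m.random_variances_)
    assert all(v >= 0 for v in m.random_variances_.values())


# ------------------------------------------------------------- Wald tests
def test_single_binary_predictor_wald_equals_squared_z():
    rng = np.random.default_rng(4)
    n = 80
    df = pd.DataFrame({"g": rng.choice(["a", "b"], n)})
    df["y"] = (df.g == "b") * 0.5 + rng.normal(size=n)
    fit = smf.ols("y ~ g", df).fit()
    table = wald_chi2_tests(fit).set_index("term")
    z = fit.params["g[T.b]"] / fit.bse["g[T.b]"]
    assert table.loc["g", "chi2"] == pytest.approx(z**2, rel=1e-10)
    assert table.loc["g", "df"] == 1
    assert table.loc["g", "p"] == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-10)


def test_type_two_matches_sequential_sums_in_balanced_design():
    """In a balanced orthogonal two-way design, Type II and Type I tests
    coincide: chi2 = SS_typeI / residual variance for every term."""
    rng = np.random.default_rng(5)
    a = np.repeat(["a1", "a2"], 40)
    b = np.tile(np.repeat(["b1", "b2"], 20), 2)
    df = pd.DataFrame({"A": a, "B": b})
    df["y"] = ((df.A == "a2") * 0.8 + (df.B == "b2") * 0.5
               + ((df.A == "a2") & (df.B == "b2")) * 0.4
               + rng.normal(size=80))
    fit = smf.ols("y ~ A * B", df).fit()
    mine = wald_chi2_tests(fit).set_index("term")["chi2"]
    anova1 = sm.stats.anova_lm(fit, typ=1)
    for term in ("A", "B", "A:B"):
        assert mine[term] == pytest.approx(
            anova1.loc[term, "sum_sq"] / fit.scale, rel=1e-8
        )


def test_null_wald_p_values_are_uniform():
    """A predictor absent from the truth yields uniform p-values."""
    pvals = []
    for s in range(500):
        rng = np.random.default_rng(3000 + s)
        n = 120
        df = pd.DataFrame({"x": rng.normal(size=n),
                           "g": rng.choice(list("abc"), n)})
        df["y"] = 1.0 + 0.5 * df.x + rng.normal(size=n)
        fit = smf.ols("y ~ x + g", df).fit()
        pvals.append(wald_chi2_tests(fit).set_index("term").loc["g", "p"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# ---------------------------------------------------------- Tukey contrasts
def test_two_level_tukey_equals_unadjusted():
    rng = np.random.default_rng(6)
    df = pd.DataFrame({"g": np.repeat(["a", "b"], 25)})
    df["y"] = (df.g == "b") * 0.3 + rng.normal(size=50)
    fit = smf.ols("y ~ g", df).fit()
    out = pairwise_contrasts_tukey(fit, "g", df)
    assert len(out) == 1
    assert out.loc[0, "p_tukey"] == pytest.approx(out.loc[0, "p_unadjusted"],
                                                  rel=1e-9)


def test_identical_noiseless_means_have_unit_p():
    df = pd.DataFrame({"y": [1.0] * 9, "g": ["a", "b", "c"] * 3})
    fit = smf.ols("y ~ g", df).fit()
    out = pairwise_contrasts_tukey(fit, "g", df)
    assert (out["p_tukey"] == 1.0).all()


def test_adjusted_p_never_below_unadjusted(default_metrics):
    from hostmet.pipeline import fit_growth_cost

    m = fit_growth_cost(default_metrics)
    out = m.contrasts("host")
    assert len(out) == 3  # 3 hosts -> 3 pairwise contrasts
    assert (out["p_tukey"] >= out["p_unadjusted"] - 1e-12).all()


def test_tukey_p_matches_monte_carlo_studentized_range():
    """Three balanced groups: the adjusted p for a pair agrees with a
    simulated studentized-range null within 0.005."""
    rng = np.random.default_rng(7)
    n = 2000
    df = pd.DataFrame({"g": np.repeat(["a", "b", "c"], n)})
    df["y"] = rng.normal(size=3 * n)
    fit = smf.ols("y ~ g", df).fit()
    out = pairwise_contrasts_tukey(fit, "g", df).set_index("contrast")
    sim = np.random.default_rng(123).normal(size=(100_000, 3))
    q_null = sim.max(axis=1) - sim.min(axis=1)  # range of 3 std normals
    for contrast in out.index:
        q_obs = abs(out.loc[contrast, "z"]) * np.sqrt(2.0)
        p_mc = float(np.mean(q_null > q_obs))
        assert out.loc[contrast, "p_tukey"] == pytest.approx(p_mc, abs=0.005)


def test_factor_absent_from_model_is_an_error():
    rng = np.random.default_rng(8)
    df = pd.DataFrame({"x": rng.normal(size=30),
                       "g": rng.choice(["a", "b"], 30)})
    df["y"] = df.x + rng.normal(size=30)
    fit = smf.ols("y ~ x", df).fit()
    with pytest.raises(ValueError):
        pairwise_contrasts_tukey(fit, "g", df)
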