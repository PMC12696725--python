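"""Allometric mass-scaling and host-effect mixed models.

The metabolic rate of the larvae is modelled as an allometric power law
``rate = a_host * mass^b`` with a common mass-scaling exponent ``b`` and
host-specific coefficients ``a`` — fitted as a common-slope regression of
ln(rate) on ln(mass) with host intercepts, after a likelihood-ratio test
confirms the host x mass interaction (host-specific slopes) is not
needed. Host effects on growth rate, metabolic rate and growth cost are
Gaussian linear mixed models with a family random intercept (optionally
individual nested in family), assessed by Type-II Wald chi-square tests
and Tukey-adjusted pairwise contrasts of estimated marginal means.

Contrast p-values use the large-sample (z / chi-square) reference
distribution; with hundreds of observations the difference from a
finite-df reference is negligible.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats
from sklearn.base import BaseEstimator

from .config import HOSTS

__all__ = [
    "lrt",
    "wald_chi2_tests",
    "estimated_marginal_means",
    "pairwise_contrasts_tukey",
    "MassScalingModel",
    "LinearMixedModel",
    "fit_mass_scaling",
    "fit_lmm",
]


# ----------------------------------------------------------------------
# generic helpers over statsmodels results (OLS and MixedLM)

def _fixed_parts(result):
    """(beta, cov, exog, design_info) for the fixed/mean part of a fit."""
    model = result.model
    design_info = getattr(model.data, "design_info", None)
    if hasattr(result, "fe_params"):  # MixedLM: fixed effects lead cov_params
        beta = np.asarray(result.fe_params, dtype=float)
        k = beta.size
        cov = np.asarray(result.cov_params())[:k, :k]
    else:
        beta = np.asarray(result.params, dtype=float)
        cov = np.asarray(result.cov_params())
    return beta, cov, np.asarray(model.exog, dtype=float), design_info


def _n_mean_params(result):
    return (result.fe_params if hasattr(result, "fe_params") else result.params).shape[0]


def lrt(model_full, model_reduced) -> dict:
    """Likelihood-ratio test of nested fits (both by maximum likelihood).

    chi2 = 2 (ll_full - ll_reduced), clamped at zero; df is the
    difference in mean-parameter counts; p from the chi-square upper tail.
    """
    if int(model_full.nobs) != int(model_reduced.nobs):
        raise ValueError("LRT requires models fitted to the same data")
    df = _n_mean_params(model_full) - _n_mean_params(model_reduced)
    if df < 0:
        raise ValueError("model_full has fewer parameters than model_reduced")
    delta = 2.0 * (model_full.llf - model_reduced.llf)
    if delta < -1e-6:
        raise ValueError(
            "reduced model has higher likelihood: models are not nested"
        )
    chi2 = max(delta, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return {"chi2": float(chi2), "df": int(df), "p": p}


def wald_chi2_tests(result, typ: str = "II") -> pd.DataFrame:
    """Per-term Wald chi-square table respecting marginality (Type II).

    For a term T with higher-order relatives R (terms whose factor sets
    strictly contain T's) and remaining terms O, the tested quantity is
    the coefficient T would take in the model containing only O and T:
    L beta with L = [0_O, I_T, A_R], A = (X_T' M_O X_T)^+ X_T' M_O X_R,
    where M_O projects out the columns of O. Without relatives this is
    the ordinary Wald test of T's coefficients; in balanced orthogonal
    designs it coincides with the sequential (Type I) test.
    """
    if typ != "II":
        raise ValueError("only Type II tests are implemented")
    beta, cov, X, design_info = _fixed_parts(result)
    if design_info is None:
        raise ValueError("model must be formula-based (no design information)")
    slices = design_info.term_slices
    rows = []
    for term in design_info.terms:
        if not term.factors:  # intercept
            continue
        fset = set(term.factors)
        cols_T = np.arange(*slices[term].indices(beta.size))
        cols_R: list[int] = []
        cols_O: list[int] = []
        for other in design_info.terms:
            if other == term:
                continue
            idx = list(range(*slices[other].indices(beta.size)))
            if fset < set(other.factors):
                cols_R.extend(idx)
            else:
                cols_O.extend(idx)
        L = np.zeros((cols_T.size, beta.size))
        L[:, cols_T] = np.eye(cols_T.size)
        if cols_R:
            X_O = X[:, cols_O]
            X_T = X[:, cols_T]
            X_R = X[:, np.asarray(cols_R)]
            if X_O.size:
                coef, *_ = np.linalg.lstsq(X_O, np.column_stack([X_T, X_R]),
                                           rcond=None)
                X_T = X_T - X_O @ coef[:, : X_T.shape[1]]
                X_R = X_R - X_O @ coef[:, X_T.shape[1]:]
            A, *_ = np.linalg.lstsq(X_T, X_R, rcond=None)
            L[:, np.asarray(cols_R)] = A
        estimate = L @ beta
        lvl = L @ cov @ L.T
        try:
            chi2 = float(estimate @ np.linalg.solve(lvl, estimate))
            df = cols_T.size
            p = float(stats.chi2.sf(chi2, df))
        except np.linalg.LinAlgError:
            chi2, df, p = np.nan, cols_T.size, np.nan
        rows.append({"term": design_info.term_names[
            design_info.terms.index(term)], "chi2": chi2, "df": df, "p": p})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# estimated marginal means and Tukey-adjusted contrasts

def _model_variables(design_info, data):
    """Split model variables into categorical (with levels) and numeric
    (at their data means). Formulas must use plain column names."""
    categorical: dict[str, list] = {}
    numeric: dict[str, float] = {}
    for factor, info in design_info.factor_infos.items():
        name = factor.code
        if name not in data.columns:
            raise ValueError(
                f"variable {name!r} not a column of the data; use plain "
                "column names in the model formula"
            )
        if info.type == "categorical":
            categorical[name] = list(info.categories)
        else:
            numeric[name] = float(np.asarray(data[name], dtype=float).mean())
    return categorical, numeric


def estimated_marginal_means(result, factor: str, data: pd.DataFrame) -> pd.DataFrame:
    """Marginal means of a factor, averaged over the levels of the other
    factors with numeric covariates held at their means."""
    beta, cov, _, design_info = _fixed_parts(result)
    categorical, numeric = _model_variables(design_info, data)
    if factor not in categorical:
        raise ValueError(f"{factor!r} is not a categorical term of the model")
    levels = categorical[factor]
    others = {k: v for k, v in categorical.items() if k != factor}
    combos = list(itertools.product(*others.values())) or [()]
    L = np.zeros((len(levels), beta.size))
    for i, level in enumerate(levels):
        rows = []
        for combo in combos:
            rec = {factor: [level]}
            rec.update({k: [v] for k, v in zip(others, combo)})
            rec.update({k: [v] for k, v in numeric.items()})
            (m,) = build_design_matrices([design_info], rec)
            rows.append(np.asarray(m)[0])
        L[i] = np.mean(rows, axis=0)
    emm = L @ beta
    emm_cov = L @ cov @ L.T
    se = np.sqrt(np.clip(np.diag(emm_cov), 0.0, None))
    out = pd.DataFrame({"level": levels, "emmean": emm, "se": se})
    out.attrs["L"] = L
    out.attrs["cov"] = emm_cov
    return out


def pairwise_contrasts_tukey(result, factor: str, data: pd.DataFrame) -> pd.DataFrame:
    """All pairwise differences of the factor's marginal means.

    The adjusted p-value uses the studentized-range distribution with
    k = number of levels (Tukey's method) on the asymptotic (infinite-df)
    reference; with two levels it reduces to the unadjusted z-test.
    """
    emms = estimated_marginal_means(result, factor, data)
    k = len(emms)
    if k < 2:
        raise ValueError("factor must have at least 2 levels")
    emm_cov = emms.attrs["cov"]
    # an interpolating (residual-variance ~ 0) fit leaves both the
    # differences and their SEs at rounding-error size; treat those 0/0
    # ratios as exact ties rather than dividing noise by noise
    tie_tol = 1e-10 * max(1.0, float(np.max(np.abs(emms["emmean"]))))
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = emms["emmean"][i] - emms["emmean"][j]
        var = emm_cov[i, i] + emm_cov[j, j] - 2.0 * emm_cov[i, j]
        se = float(np.sqrt(max(var, 0.0)))
        if abs(diff) < tie_tol and se < tie_tol:
            z = 0.0
        elif se == 0.0:
            z = np.inf * np.sign(diff)
        else:
            z = diff / se
        p_unadj = float(2.0 * stats.norm.sf(abs(z)))
        p_tukey = float(stats.studentized_range.sf(abs(z) * np.sqrt(2.0), k, np.inf))
        rows.append(
            {
                "contrast": f"{emms['level'][i]} - {emms['level'][j]}",
                "estimate": float(diff),
                "se": se,
                "z": float(z),
                "p_unadjusted": min(p_unadj, 1.0),
                "p_tukey": min(max(p_tukey, p_unadj if se else p_tukey), 1.0),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
@dataclass
class AllometryFit:
    """Summary of the common-slope mass-scaling fit."""

    exponent_b: float
    coefficients_a: dict[str, float]
    interaction_lrt: dict
    host_test: dict
    slope_test: dict
    n_obs: int
    n_excluded: int


class MassScalingModel(BaseEstimator):
    """Common-slope allometric regression of ln(rate) on ln(mass).

    Fits ``ln(rate) ~ ln(mass) + host`` by maximum likelihood (OLS) and
    the host-specific-slope alternative, reports the interaction LRT
    (df = n_hosts - 1), the common exponent ``b`` and the back-transformed
    per-host coefficients ``a = exp(host intercept)``.

    Parameters
    ----------
    rate_unit : {"ml_min", "ml_h"}
        Unit of the rate column. Coefficients are always reported on the
        package convention (mL h^-1 at 1 g), so rates in mL min^-1 are
        converted internally.
    """

    def __init__(self, host_col: str = "host", mass_col: str = "mass_g",
                 rate_col: str = "vco2_ml_min", rate_unit: str = "ml_min"):
        self.host_col = host_col
        self.mass_col = mass_col
        self.rate_col = rate_col
        self.rate_unit = rate_unit

    def fit(self, X: pd.DataFrame, y=None):
        if self.rate_unit not in ("ml_min", "ml_h"):
            raise ValueError("rate_unit must be 'ml_min' or 'ml_h'")
        for col in (self.host_col, self.mass_col, self.rate_col):
            if col not in X.columns:
                raise ValueError(f"missing column {col!r}")
        rate = X[self.rate_col].to_numpy(dtype=float)
        if self.rate_unit == "ml_min":
            rate = rate * 60.0
        mass = X[self.mass_col].to_numpy(dtype=float)
        host = X[self.host_col].to_numpy()
        ok = np.isfinite(rate) & (rate > 0) & np.isfinite(mass) & (mass > 0)
        self.n_excluded_ = int((~ok).sum())
        hosts_present = [h for h in HOSTS if h in set(host[ok])]
        if not hosts_present:  # hosts outside the standard panel
            hosts_present = sorted(set(host[ok]))
        d = pd.DataFrame(
            {
                "ln_rate": np.log(rate[ok]),
                "ln_mass": np.log(mass[ok]),
                "host": pd.Categorical(host[ok], categories=hosts_present),
            }
        )
        counts = d["host"].value_counts()
        if len(counts) >= 2 and (counts < 3).any():
            raise ValueError("need at least 3 observations per host")
        if len(counts) >= 2:
            additive = smf.ols("ln_rate ~ ln_mass + host", d).fit()
            interaction = smf.ols("ln_rate ~ ln_mass * host", d).fit()
            self.interaction_lrt_ = lrt(interaction, additive)
            wald = wald_chi2_tests(additive)
            self.host_test_ = wald.set_index("term").loc["host"].to_dict()
        else:
            additive = smf.ols("ln_rate ~ ln_mass", d).fit()
            self.interaction_lrt_ = {"chi2": 0.0, "df": 0, "p": 1.0}
            wald = wald_chi2_tests(additive)
            self.host_test_ = {"chi2": np.nan, "df": 0, "p": np.nan}
        self.slope_test_ = wald.set_index("term").loc["ln_mass"].to_dict()
        self.exponent_b_ = float(additive.params["ln_mass"])
        intercept = additive.params["Intercept"]
        coeffs = {}
        for h in hosts_present:
            key = f"host[T.{h}]"
            eta = intercept + (additive.params[key] if key in additive.params else 0.0)
            coeffs[h] = float(np.exp(eta))
        self.coefficients_a_ = coeffs
        self.result_ = additive
        self.n_obs_ = int(ok.sum())
        self.summary_ = AllometryFit(
            exponent_b=self.exponent_b_,
            coefficients_a=dict(coeffs),
            interaction_lrt=dict(self.interaction_lrt_),
            host_test=dict(self.host_test_),
            slope_test=dict(self.slope_test_),
            n_obs=self.n_obs_,
            n_excluded=self.n_excluded_,
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Predicted rate a_host * mass^b, in the configured rate unit."""
        a = np.array([self.coefficients_a_[h] for h in X[self.host_col]])
        out = a * X[self.mass_col].to_numpy(dtype=float) ** self.exponent_b_
        return out / 60.0 if self.rate_unit == "ml_min" else out


class LinearMixedModel(BaseEstimator):
    """Gaussian linear mixed model with a family random intercept.

    Thin estimator around REML fitting with, optionally, an individual
    intercept nested within family (as a variance component). Exposes the
    Type-II Wald table and Tukey-adjusted pairwise contrasts.

    Parameters
    ----------
    formula : str
        Fixed-effects formula, e.g. ``"growth_cost_ml_per_g ~ host"``.
        Use plain column names (transform covariates beforehand).
    groups : str
        Grouping column for the random intercept (the family).
    nested : str, optional
        Column identifying individuals; adds an individual-within-family
        intercept variance component.
    reml : bool
        REML (default) or maximum likelihood.
    """

    def __init__(self, formula: str, groups: str = "family_id",
                 nested: str | None = None, reml: bool = True):
        self.formula = formula
        self.groups = groups
        self.nested = nested
        self.reml = reml

    def fit(self, X: pd.DataFrame, y=None):
        response = self.formula.split("~")[0].strip()
        cols = [c for c in X.columns
                if c in self.formula or c in (self.groups, self.nested)]
        if response not in X.columns:
            raise ValueError(f"response {response!r} not in data")
        data = X.dropna(subset=[c for c in cols if X[c].isna().any()])
        self.n_dropped_ = len(X) - len(data)
        vc = None
        if self.nested is not None:
            vc = {"individual": f"0 + C({self.nested})"}
        model = smf.mixedlm(
            self.formula, data, groups=data[self.groups], re_formula="1",
            vc_formula=vc,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            result = model.fit(reml=self.reml)
            # the default optimizer occasionally stalls on weakly
            # identified variance ratios; retry with derivative-free
            # methods before reporting non-convergence
            for method in ("powell", "cg"):
                if getattr(result, "converged", True):
                    break
                result = model.fit(reml=self.reml, method=method, maxiter=2000)
        self.fit_warnings_ = [str(w.message) for w in caught]
        self.converged_ = bool(getattr(result, "converged", True))
        self.result_ = result
        self._data = data
        k = result.fe_params.shape[0]
        se = np.sqrt(np.diag(np.asarray(result.cov_params()))[:k])
        self.fixed_effects_ = pd.DataFrame(
            {
                "term": list(result.fe_params.index),
                "estimate": np.asarray(result.fe_params, dtype=float),
                "se": se,
            }
        )
        variances = {"family": float(np.asarray(result.cov_re)[0, 0])}
        for name, v in zip(model.exog_vc.names if vc else [], result.vcomp):
            variances[name] = float(v)
        variances["residual"] = float(result.scale)
        self.random_variances_ = variances
        self.wald_table_ = wald_chi2_tests(result)
        return self

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise ValueError("model is not fitted")

    def emmeans(self, factor: str) -> pd.DataFrame:
        self._check_fitted()
        return estimated_marginal_means(self.result_, factor, self._data)

    def contrasts(self, factor: str) -> pd.DataFrame:
        self._check_fitted()
        return pairwise_contrasts_tukey(self.result_, factor, self._data)

    def refit_ml(self):
        """Refit by plain maximum likelihood (for fixed-effect LRTs)."""
        self._check_fitted()
        clone = LinearMixedModel(self.formula, self.groups, self.nested, reml=False)
        return clone.fit(self._data)


def fit_mass_scaling(table: pd.DataFrame, **params) -> MassScalingModel:
    """Functional wrapper: fit and return a :class:`MassScalingModel`."""
    return MassScalingModel(**params).fit(table)


def fit_lmm(table: pd.DataFrame, formula: str, groups: str = "family_id",
            nested: str | None = None, reml: bool = True) -> LinearMixedModel:
    """Functional wrapper: fit and return a :class:`LinearMixedModel`."""
    return LinearMixedModel(formula, groups=groups, nested=nested, reml=reml).fit(table)
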