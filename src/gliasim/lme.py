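"""Linear mixed-effects analysis of the response tables.

Each hypothesis has a fixed-effect polynomial in its swept parameters and
network-specific random effects with *independent* components (diagonal
random-effect covariance), estimated by REML:

* removal (H1):  phi(Z) = mu + Delta * removed + u_net + eps, phi = log.
  The average percent reduction is delta_rem = 100 * (1 - exp(Delta)).
* ATP (H2):      log Z = (mu + u_mu) + (b_a + u_a) y_Astro + b_a2 y_Astro^2 + eps
* glutamate (H3): Z = (mu + u_mu) + (b_f + u_f) w_f + (b_g + u_g) w_g
                      + b_f2 w_f^2 + b_g2 w_g^2 + (b_fg + u_fg) w_f w_g + eps
* weights (H4):  Z = mu + b_in y_in + b_ex y_ex + b_in2 y_in^2 + b_ex2 y_ex^2
                     + b_inex y_in y_ex + gamma_net + eps

Fixed-effect confidence intervals are Wald; variance-component intervals
come from a seeded parametric bootstrap; the removal p-value is a
likelihood-ratio test (ML fits) of the removal fixed effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.regression.mixed_linear_model import MixedLM

__all__ = [
    "LMEFit",
    "RemovalContrast",
    "fit_lme",
    "removal_contrast",
    "fit_h2",
    "fit_h3",
    "fit_h4",
    "hypothesis_fits",
    "response_surface",
    "bootstrap_sd_cis",
]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class LMEFit:
    """REML fit summary with Wald CIs for the fixed effects."""

    fixed: dict                      # name -> estimate
    fixed_ci: dict                   # name -> (lo, hi)
    sd: dict                         # random-effect SDs + "residual"
    sd_ci: dict = field(default_factory=dict)  # optional bootstrap CIs
    transform: str = "identity"
    response: str = ""
    llf_ml: float = np.nan           # ML log-likelihood (for LRTs)
    boundary: bool = False           # a variance component hit ~0
    converged: bool = True
    n_obs: int = 0
    _spec: dict = field(default_factory=dict, repr=False)

    def predict_fixed(self, df: pd.DataFrame) -> np.ndarray:
        """Evaluate the fixed-effect polynomial (stochastic terms at 0)."""
        import patsy

        rhs = self._spec["formula"].split("~", 1)[1]
        X = patsy.dmatrix(rhs, df, return_type="dataframe")
        beta = np.array([self.fixed[c] for c in X.columns])
        return X.to_numpy() @ beta


@dataclass
class RemovalContrast:
    delta_rem_pct: float             # average reduction, percent
    delta_rem_ci: tuple              # 95 % CI (lo, hi), percent
    p_value: float                   # LRT of the removal fixed effect
    mu_hat: float                    # mean transformed response, intact nets
    sigma_rem_norm_pct: float        # 100 * sigma_rem / mu_hat
    sigma_norm_pct: float            # 100 * sigma_resid / mu_hat
    fit: LMEFit = None


def _apply_transform(y: pd.Series, transform: str, response: str) -> pd.Series:
    if transform == "identity":
        return y
    if transform == "log":
        bad = np.flatnonzero(~(y > 0))
        if bad.size:
            raise ValueError(
                f"log transform of {response!r} undefined for rows {bad.tolist()[:10]}"
                f"{'...' if bad.size > 10 else ''} (non-positive values)"
            )
        return np.log(y)
    raise ValueError(f"unknown transform: {transform!r}")


def fit_lme(
    data: pd.DataFrame,
    response: str,
    formula_rhs: str,
    groups: str,
    re_formula: str | None = None,
    vc_formula: dict | None = None,
    transform: str = "identity",
    sd_names: dict | None = None,
) -> LMEFit:
    """REML mixed-model fit with independent variance components.

    ``vc_formula`` entries give diagonal (mutually independent) random
    effects; ``re_formula``="1" adds a plain random intercept.  Degenerate
    data with (numerically) zero residual variance fall back to ordinary
    least squares with all random-effect SDs reported as 0 and the
    ``boundary`` flag set.
    """
    df = data.copy()
    if df[groups].nunique() < 2:
        raise ValueError("grouping factor needs at least 2 levels")
    df["_y"] = _apply_transform(df[response], transform, response)
    formula = f"_y ~ {formula_rhs}"

    # degenerate (noise-free) data: REML is ill-posed; OLS recovers the
    # fixed-effect polynomial exactly
    ols = smf.ols(formula, df).fit()
    if np.var(ols.resid.to_numpy()) < 1e-16 * max(1.0, float(np.var(df["_y"]))):
        fixed = dict(ols.params)
        ci = {k: (v, v) for k, v in fixed.items()}
        sd = {name: 0.0 for name in (sd_names or {}).values()}
        sd["residual"] = 0.0
        return LMEFit(fixed, ci, sd, transform=transform, response=response,
                      boundary=True, n_obs=len(df),
                      _spec={"formula": formula})

    kwargs = {"groups": df[groups]}
    if vc_formula:
        kwargs["vc_formula"] = vc_formula
        kwargs["re_formula"] = re_formula if re_formula is not None else "0"
    elif re_formula is not None:
        kwargs["re_formula"] = re_formula

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(formula, df, **kwargs)
        res = _robust_fit(model, reml=True)
        try:
            # derivative-free polish: tightens the variance-parameter optimum
            polished = model.fit(reml=True, method="powell",
                                 start_params=res.params_object)
            if np.isfinite(polished.llf):
                res = polished
        except Exception:
            pass
        res_ml = _robust_fit(model, reml=False)

    fixed = dict(res.fe_params)
    # Wald intervals with group-level degrees of freedom: the normal
    # quantile undercovers when the grouping factor has few levels
    dof = max(df[groups].nunique() - len(fixed), 3)
    tcrit = stats.t.ppf(0.975, dof)
    fixed_ci = {
        k: (fixed[k] - tcrit * res.bse_fe[k], fixed[k] + tcrit * res.bse_fe[k])
        for k in fixed
    }

    sd = {}
    names = sd_names or {}
    if kwargs.get("re_formula") not in (None, "0") and res.cov_re.shape[0]:
        sd[names.get("intercept", "sd_net")] = float(np.sqrt(res.cov_re.iloc[0, 0]))
    for i, vc_name in enumerate(model.exog_vc.names if vc_formula else []):
        sd[names.get(vc_name, f"sd_{vc_name}")] = float(np.sqrt(res.vcomp[i]))
    sd["residual"] = float(np.sqrt(res.scale))
    boundary = any(v < 1e-6 for k, v in sd.items() if k != "residual")

    return LMEFit(
        fixed, fixed_ci, sd,
        transform=transform, response=response,
        llf_ml=float(res_ml.llf), boundary=boundary,
        converged=bool(res.converged), n_obs=len(df),
        _spec={
            "formula": formula, "groups": groups, "re_formula": re_formula,
            "vc_formula": vc_formula, "sd_names": sd_names,
        },
    )


def _robust_fit(model, reml):
    last_err = None
    for method in ("lbfgs", "bfgs", "cg", "powell", "nm"):
        try:
            res = model.fit(reml=reml, method=method)
            if np.isfinite(res.llf):
                return res
        except Exception as err:  # singular fits near variance boundaries
            last_err = err
    raise RuntimeError(f"mixed-model fit failed with every optimizer: {last_err}")


def _loglike_ml(data, response, formula_rhs, groups, transform, **kwargs):
    df = data.copy()
    df["_y"] = _apply_transform(df[response], transform, response)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(f"_y ~ {formula_rhs}", df, groups=df[groups], **kwargs)
        return float(_robust_fit(model, reml=False).llf)


def removal_contrast(
    table: pd.DataFrame,
    response: str,
    condition_col: str = "condition",
    reduced_tag: str = "astro_removed",
    instance_col: str = "instance",
) -> RemovalContrast:
    """Percent reduction of one response due to cell removal.

    Fits log(Z) with a removal indicator fixed effect and a random
    intercept per network instance, contrasts reduced against intact
    networks, and back-transforms the effect to a percent reduction.
    """
    df = table[table[condition_col].isin(["default", reduced_tag])].copy()
    if not (df[condition_col] == "default").any():
        raise ValueError("no default (intact) rows in the table")
    if not (df[condition_col] == reduced_tag).any():
        raise ValueError(f"no rows tagged {reduced_tag!r}")
    df["removed"] = (df[condition_col] == reduced_tag).astype(float)

    fit = fit_lme(
        df, response, "removed", groups=instance_col, re_formula="1",
        transform="log", sd_names={"intercept": "sd_rem"},
    )
    delta = fit.fixed["removed"]
    lo, hi = fit.fixed_ci["removed"]
    delta_pct = 100.0 * (1.0 - np.exp(delta))
    ci = (100.0 * (1.0 - np.exp(hi)), 100.0 * (1.0 - np.exp(lo)))

    llf_full = fit.llf_ml
    llf_null = _loglike_ml(df, response, "1", instance_col, "log", re_formula="1")
    lrt = max(0.0, 2.0 * (llf_full - llf_null))
    p = float(stats.chi2.sf(lrt, df=1))

    mu = fit.fixed["Intercept"]
    return RemovalContrast(
        delta_rem_pct=float(delta_pct),
        delta_rem_ci=ci,
        p_value=p,
        mu_hat=float(mu),
        sigma_rem_norm_pct=100.0 * fit.sd.get("sd_rem", 0.0) / abs(mu),
        sigma_norm_pct=100.0 * fit.sd["residual"] / abs(mu),
        fit=fit,
    )


def fit_h2(table: pd.DataFrame, response: str) -> LMEFit:
    """ATP experiment: log response, random intercept and y_Astro slope."""
    df = table.copy()
    df["ya"] = df["y_astro"]
    df["ya2"] = df["y_astro"] ** 2
    return fit_lme(
        df, response, "ya + ya2", groups="network",
        vc_formula={"mu": "1", "a": "0 + ya"},
        transform="log",
        sd_names={"mu": "sd_mu", "a": "sd_a"},
    )


def fit_h3(table: pd.DataFrame, response: str) -> LMEFit:
    """Glutamate experiment: identity response, diagonal random effects."""
    df = table.copy()
    df["wf2"] = df["w_f"] ** 2
    df["wg2"] = df["w_g"] ** 2
    df["wfg"] = df["w_f"] * df["w_g"]
    return fit_lme(
        df, response, "w_f + w_g + wf2 + wg2 + wfg", groups="network",
        vc_formula={"mu": "1", "f": "0 + w_f", "g": "0 + w_g", "fg": "0 + wfg"},
        sd_names={"mu": "sd_mu", "f": "sd_f", "g": "sd_g", "fg": "sd_fg"},
    )


def fit_h4(table: pd.DataFrame, response: str) -> LMEFit:
    """Weight-bound experiment: identity response, random network intercept."""
    df = table.copy()
    df["yin2"] = df["y_in"] ** 2
    df["yex2"] = df["y_ex"] ** 2
    df["yinex"] = df["y_in"] * df["y_ex"]
    return fit_lme(
        df, response, "y_in + y_ex + yin2 + yex2 + yinex", groups="network",
        re_formula="1",
        sd_names={"intercept": "sd_net"},
    )


_H_FITTERS = {"H2": fit_h2, "H3": fit_h3, "H4": fit_h4}


def hypothesis_fits(table: pd.DataFrame, hypothesis: str) -> dict[str, LMEFit]:
    """One fit per response variable, in report-table layout."""
    fitter = _H_FITTERS[hypothesis]
    return {resp: fitter(table, resp) for resp in ("Z_spike", "Z_burst", "Z_astro")}


def fits_to_table(fits: dict[str, LMEFit]) -> pd.DataFrame:
    """Est / CI2.5 / CI97.5 columns per response, SDs then fixed effects."""
    rows = []
    for resp, fit in fits.items():
        for name, v in fit.sd.items():
            lo, hi = fit.sd_ci.get(name, (np.nan, np.nan))
            rows.append({"response": resp, "parameter": name, "Est": v,
                         "CI2.5": lo, "CI97.5": hi})
        for name, v in fit.fixed.items():
            lo, hi = fit.fixed_ci[name]
            rows.append({"response": resp, "parameter": name, "Est": v,
                         "CI2.5": lo, "CI97.5": hi})
    return pd.DataFrame(rows)


def response_surface(fit: LMEFit, grid: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect predicted response on a parameter grid.

    The grid must contain the swept parameter columns (e.g. w_f and w_g);
    derived polynomial columns are added automatically.  Values outside the
    fitted range are still computed, with a warning.
    """
    df = grid.copy()
    for col, expr in (
        ("wf2", lambda d: d["w_f"] ** 2 if "w_f" in d else None),
        ("wg2", lambda d: d["w_g"] ** 2 if "w_g" in d else None),
        ("wfg", lambda d: d["w_f"] * d["w_g"] if "w_f" in d else None),
        ("yin2", lambda d: d["y_in"] ** 2 if "y_in" in d else None),
        ("yex2", lambda d: d["y_ex"] ** 2 if "y_ex" in d else None),
        ("yinex", lambda d: d["y_in"] * d["y_ex"] if "y_in" in d else None),
        ("ya", lambda d: d["y_astro"] if "y_astro" in d else None),
        ("ya2", lambda d: d["y_astro"] ** 2 if "y_astro" in d else None),
    ):
        val = expr(df)
        if val is not None:
            df[col] = val
    pred = fit.predict_fixed(df)
    out = grid.copy()
    out["predicted"] = pred
    return out


def bootstrap_sd_cis(
    table: pd.DataFrame,
    fit: LMEFit,
    n_boot: int = 500,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Seeded parametric bootstrap CIs for the random-effect / residual SDs.

    Data are re-simulated from the fitted model (fixed effects + Gaussian
    random effects and residuals), re-fitted, and the SDs collected;
    intervals are the empirical (1-level)/2 quantiles.
    """
    spec = fit._spec
    rng = np.random.default_rng(seed)
    df = table.copy()
    groups_col = spec["groups"]
    mean = fit.predict_fixed(df)
    labels = df[groups_col].to_numpy()
    uniq = pd.unique(labels)

    # design values multiplying each variance component
    vc_design = {}
    if spec.get("vc_formula"):
        import patsy
        for name, f in spec["vc_formula"].items():
            vc_design[name] = np.asarray(
                patsy.dmatrix(f, df, return_type="dataframe")
            ).ravel()
    sd_names = spec.get("sd_names") or {}

    draws = {k: [] for k in fit.sd}
    for _ in range(n_boot):
        y = mean.copy()
        if spec.get("re_formula") in ("1",):
            name = sd_names.get("intercept", "sd_net")
            u = rng.normal(0.0, fit.sd.get(name, 0.0), size=uniq.size)
            y = y + u[pd.Categorical(labels, categories=uniq).codes]
        for vc_name, design in vc_design.items():
            name = sd_names.get(vc_name, f"sd_{vc_name}")
            u = rng.normal(0.0, fit.sd.get(name, 0.0), size=uniq.size)
            y = y + design * u[pd.Categorical(labels, categories=uniq).codes]
        y = y + rng.normal(0.0, fit.sd["residual"], size=len(df))

        boot = df.copy()
        resp = fit.response
        boot[resp] = np.exp(y) if fit.transform == "log" else y
        try:
            refit = fit_lme(
                boot, resp, spec["formula"].split("~", 1)[1], groups_col,
                re_formula=spec.get("re_formula"),
                vc_formula=spec.get("vc_formula"),
                transform=fit.transform, sd_names=sd_names,
            )
        except Exception:
            continue
        for k in draws:
            draws[k].append(refit.sd.get(k, np.nan))

    alpha = (1.0 - level) / 2.0
    out = {}
    for k, vals in draws.items():
        vals = np.asarray([v for v in vals if np.isfinite(v)])
        if vals.size:
            out[k] = (float(np.quantile(vals, alpha)), float(np.quantile(vals, 1 - alpha)))
    return out
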