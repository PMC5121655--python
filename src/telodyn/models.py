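"""Mixed models for cross-sectional RTL and RTL change.

Two core fits: (1) RTL on sex, age, age² (optionally age³ with an
automatic drop when non-significant), body mass, reproductive activity
and day of year; (2) RTL at time t on the same covariates plus RTL at
t−1 and the sampling interval.  Conditioning the change model on the
previous measurement is the regression-to-the-mean adjustment; the
equivalent residual-based correction is provided as
:func:`rtm_residual_correction`.

Animal and qPCR plate enter as crossed random intercepts, implemented
as variance components inside a single grouping super-set (the
standard trick for crossed factors in ``statsmodels`` MixedLM).
Fixed-effect p-values use the normal approximation to the Wald
statistic; Satterthwaite degrees of freedom are not available in this
backend, which matters only at very small group counts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "MixedModelFit",
    "fit_rtl_model",
    "fit_change_model",
    "rtm_residual_correction",
    "aicc",
    "compare_random_structures",
]

RTL_FIXED_TERMS = (
    "C(sex)",
    "age",
    "I(age**2)",
    "body_mass",
    "reproductive_active",
    "day_of_year",
)


@dataclass
class MixedModelFit:
    """Coefficients, random-effect SDs and fit statistics of one model."""

    coefficients: pd.DataFrame  # index term; columns estimate, se, stat, p
    random_effect_sds: dict
    n_obs: int
    n_subjects: int
    loglik: float
    k_params: int
    aic: float
    aicc: float
    r2_full: float
    r2_random: float
    residuals: np.ndarray
    fitted: np.ndarray
    formula: str
    backend: str = "statsmodels-MixedLM"
    pvalue_method: str = "normal-approximation"
    converged: bool = True
    notes: list = field(default_factory=list)

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.coefficients.loc[term, "se"])

    def p(self, term: str) -> float:
        return float(self.coefficients.loc[term, "p"])


def _prepare_vc(df: pd.DataFrame, vc_factors: tuple[str, ...]) -> dict[str, str]:
    """Variance-component formulas, dropping degenerate (<2 level) factors."""
    vc = {}
    for col in vc_factors:
        name = col.replace("_id", "")
        if df[col].nunique() >= 2:
            vc[name] = f"0 + C({col})"
        else:
            logger.warning("random factor %s has a single level; variance set to 0", col)
    return vc


def _fit_mixed(
    df: pd.DataFrame,
    formula: str,
    vc_factors: tuple[str, ...] = ("animal_id", "plate_id"),
    reml: bool = True,
) -> MixedModelFit:
    """Fit a linear mixed model with crossed random intercepts.

    Falls back to OLS when the data are noise-free (zero residual
    variance breaks the profiled-likelihood optimiser) or when every
    random factor is degenerate.
    """
    df = df.reset_index(drop=True)
    y_name = formula.split("~")[0].strip()
    n = len(df)
    n_subjects = df["animal_id"].nunique() if "animal_id" in df else n
    vc = _prepare_vc(df, vc_factors)
    notes = []

    ols = smf.ols(formula, df).fit()
    tss = float(((df[y_name] - df[y_name].mean()) ** 2).sum())
    if not vc or ols.ssr <= 1e-12 * max(tss, 1.0):
        # degenerate / noise-free data: exact linear algebra
        if ols.ssr <= 1e-12 * max(tss, 1.0):
            notes.append("noise-free response: fixed-effects-only fit")
        else:
            notes.append("no usable random factors: fixed-effects-only fit")
        coeffs = pd.DataFrame(
            {
                "estimate": ols.params,
                "se": ols.bse,
                "stat": ols.tvalues,
                "p": ols.pvalues,
            }
        )
        k = len(ols.params) + 1
        fitted = np.asarray(ols.fittedvalues)
        obs = df[y_name].to_numpy()
        return MixedModelFit(
            coefficients=coeffs,
            random_effect_sds={f.replace("_id", ""): 0.0 for f in vc_factors},
            n_obs=n,
            n_subjects=n_subjects,
            loglik=float(ols.llf),
            k_params=k,
            aic=float(ols.aic) + 2,
            aicc=aicc(float(ols.aic) + 2, k, n),
            r2_full=_corr_r2(fitted, obs),
            r2_random=0.0,
            residuals=np.asarray(ols.resid),
            fitted=fitted,
            formula=formula,
            backend="statsmodels-OLS",
            notes=notes,
        )

    groups = np.ones(n)
    model = smf.mixedlm(formula, df, groups=groups, vc_formula=vc, re_formula="0")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=reml, method=["lbfgs", "powell"])
        except (np.linalg.LinAlgError, ValueError) as err:
            notes.append(f"mixed fit failed ({err}); refit as fixed-effects model")
            return _fit_mixed(df, formula, vc_factors=(), reml=reml)

    params = res.fe_params
    coeffs = pd.DataFrame(
        {
            "estimate": params,
            "se": res.bse_fe,
            "stat": params / res.bse_fe,
            "p": 2 * stats.norm.sf(np.abs(params / res.bse_fe)),
        }
    )
    vc_names = list(vc)
    re_sds = {name: float(np.sqrt(v)) for name, v in zip(vc_names, res.vcomp)}
    for f in vc_factors:
        re_sds.setdefault(f.replace("_id", ""), 0.0)
    re_sds["residual"] = float(np.sqrt(res.scale))

    obs = df[y_name].to_numpy()
    fitted = np.asarray(res.fittedvalues)  # X*beta + Z*bhat
    fixed_part = model.exog @ params.to_numpy()
    random_part = fitted - fixed_part
    resid = obs - fitted

    k = len(params) + len(vc_names) + 1  # fixed + variance components + residual
    ll = float(res.llf)
    aic = 2 * k - 2 * ll
    return MixedModelFit(
        coefficients=coeffs,
        random_effect_sds=re_sds,
        n_obs=n,
        n_subjects=n_subjects,
        loglik=ll,
        k_params=k,
        aic=aic,
        aicc=aicc(aic, k, n),
        r2_full=_corr_r2(fitted, obs),
        r2_random=_corr_r2(random_part, obs),
        residuals=resid,
        fitted=fitted,
        formula=formula,
        converged=bool(res.converged),
        notes=notes,
    )


def _corr_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    if np.std(pred) == 0 or np.std(obs) == 0:
        return 0.0
    return float(np.corrcoef(pred, obs)[0, 1] ** 2)


def fit_rtl_model(
    data: pd.DataFrame,
    extra_terms: tuple[str, ...] = (),
    include_cubic: str | bool = "auto",
    reml: bool = True,
) -> MixedModelFit:
    """Cross-sectional RTL model with quadratic (optionally cubic) age.

    ``include_cubic='auto'`` fits the cubic term first and drops it
    when p >= 0.05, keeping the quadratic — the fit-and-drop rule for
    higher-order age terms.
    """
    if len(data) < 2:
        raise ValueError("need at least 2 observations")
    terms = list(RTL_FIXED_TERMS) + list(extra_terms)
    base = "rtl ~ " + " + ".join(terms)
    if include_cubic is True:
        return _fit_mixed(data, base + " + I(age**3)", reml=reml)
    if include_cubic == "auto":
        full = _fit_mixed(data, base + " + I(age**3)", reml=reml)
        if full.p("I(age ** 3)") < 0.05:
            full.notes.append("cubic age term significant and retained")
            return full
        fit = _fit_mixed(data, base, reml=reml)
        fit.notes.append("cubic age term not significant (p >= 0.05); dropped")
        return fit
    return _fit_mixed(data, base, reml=reml)


def fit_change_model(
    data: pd.DataFrame,
    extra_terms: tuple[str, ...] = (),
    reml: bool = True,
) -> MixedModelFit:
    """RTL-change model: RTL_t on RTL_{t−1}, age, age² and covariates.

    ``data`` is a change table (one row per consecutive within-subject
    pair, e.g. from :func:`telodyn.synthetic.make_change_table`).
    Conditioning on ``rtl_prev`` adjusts for regression to the mean.
    """
    need = {"rtl", "rtl_prev", "interval_days"}
    if not need.issubset(data.columns):
        raise ValueError(f"change table must contain {sorted(need)}")
    n0 = len(data)
    data = data.dropna(subset=["rtl_prev"])
    if n0 - len(data):
        logger.info("dropped %d rows without a previous measurement", n0 - len(data))
    terms = ["rtl_prev"] + list(RTL_FIXED_TERMS) + ["interval_days"] + list(extra_terms)
    formula = "rtl ~ " + " + ".join(terms)
    return _fit_mixed(data, formula, reml=reml)


def rtm_residual_correction(
    initial_rtl: np.ndarray, rtl_loss: np.ndarray
) -> np.ndarray:
    """Regression-to-the-mean-corrected change scores.

    Returns the residuals of an ordinary least-squares regression of
    RTL loss on initial RTL.  Equivalent, up to an additive constant,
    to the numerical part-whole correlation correction of change
    scores; conditioning on the initial value inside the mixed model
    (``fit_change_model``) gives the same age-term inference when
    random effects are absent.
    """
    x = np.asarray(initial_rtl, dtype=float)
    y = np.asarray(rtl_loss, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired (initial, loss) values")
    if np.ptp(x) == 0:
        warnings.warn(
            "initial RTL is constant; slope undefined, returning mean-centred losses"
        )
        return y - y.mean()
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def aicc(aic: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: AIC + 2k(k+1)/(n−k−1)."""
    if n <= k + 1:
        return float("inf")
    return float(aic + 2 * k * (k + 1) / (n - k - 1))


def compare_random_structures(
    data: pd.DataFrame,
    candidate_structures: dict[str, tuple[str, ...]],
    formula: str | None = None,
    reml: bool = True,
) -> pd.DataFrame:
    """Rank random-intercept structures by AICc (same fixed effects).

    ``candidate_structures`` maps a label to a tuple of grouping
    columns, e.g. ``{"animal+plate": ("animal_id", "plate_id"),
    "animal+plate+year": ("animal_id", "plate_id", "year")}``.
    Candidates whose AICc is undefined (n <= k+1) are excluded with a
    warning.  Ties are broken in favour of fewer parameters.
    """
    formula = formula or ("rtl ~ " + " + ".join(RTL_FIXED_TERMS))
    rows = []
    for name, factors in candidate_structures.items():
        fit = _fit_mixed(data, formula, vc_factors=tuple(factors), reml=reml)
        if not np.isfinite(fit.aicc):
            warnings.warn(f"structure {name!r}: AICc undefined (n <= k+1); excluded")
            continue
        rows.append({"structure": name, "k": fit.k_params, "aicc": fit.aicc,
                     "loglik": fit.loglik})
    if not rows:
        raise ValueError("no candidate structure with a defined AICc")
    tab = pd.DataFrame(rows).sort_values(["aicc", "k"], kind="mergesort")
    tab["delta_aicc"] = tab["aicc"] - tab["aicc"].min()
    return tab.reset_index(drop=True)
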