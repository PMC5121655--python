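"""Age dependence of female reproduction and litter size.

The yearly probability that a female reproduces is modelled as a
logistic mixed model with age as the fixed predictor and random
intercepts for study year and for animal (animals repeat within and
across years).  The age effect is tested by a likelihood-ratio
chi-square between the Laplace log-likelihoods with and without age.
Litter size is tested against age with a Gaussian mixed model (animal
random intercept); the litter-size distribution is summarised by its
sample mean and SD.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats

from .glmm import GlmmFit, FirthFit, fit_logistic_glmm, firth_logistic

logger = logging.getLogger(__name__)

__all__ = ["LogisticFit", "fit_reproduction_model", "test_litter_size_vs_age"]


@dataclass
class LogisticFit:
    """Reproduction-probability model summary."""

    intercept: float
    age_slope: float
    intercept_se: float
    age_slope_se: float
    random_sds: dict
    chi_sq_age: float
    p_value: float
    prediction_curve: pd.DataFrame  # age, probability (population-averaged)
    n_obs: int
    n_animals: int
    method: str  # "pql-laplace" | "firth"
    separation_detected: bool
    glmm: GlmmFit | None = None
    fallback: FirthFit | None = None


def _codes(values: pd.Series) -> np.ndarray:
    return pd.Categorical(values).codes.astype(int)


def fit_reproduction_model(
    records: pd.DataFrame,
    age_grid: np.ndarray | None = None,
) -> LogisticFit:
    """Mixed-effects logistic regression of reproduction on age.

    ``records`` needs columns ``animal_id, study_year, age,
    reproduced``.  Returns the fitted model with a population-averaged
    prediction curve over ``age_grid`` (default: the observed integer
    age range).  If the fixed-effect estimates diverge (complete or
    quasi-complete separation), the fit falls back to bias-reduced
    (Firth) logistic regression without random effects, with a
    warning.
    """
    if records["study_year"].nunique() < 2:
        raise ValueError("need >= 2 study years")
    y = records["reproduced"].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    age = records["age"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(age), age])
    groups = {
        "year": _codes(records["study_year"]),
        "animal": _codes(records["animal_id"]),
    }

    fit = fit_logistic_glmm(X, y, groups)
    # LRT for the age term
    fit0 = fit_logistic_glmm(X[:, :1], y, groups)
    chi2 = max(2.0 * (fit.loglik - fit0.loglik), 0.0)
    p = float(stats.chi2.sf(chi2, df=1))

    method = "pql-laplace"
    fallback = None
    separation = fit.separation
    if separation:
        warnings.warn(
            "separation detected in the reproduction model; "
            "falling back to bias-reduced (Firth) logistic regression"
        )
        fallback = firth_logistic(X, y)
        method = "firth"

    if age_grid is None:
        age_grid = np.arange(int(age.min()), int(age.max()) + 1, dtype=float)
    Xg = np.column_stack([np.ones_like(age_grid), age_grid])
    if method == "firth":
        eta = Xg @ fallback.beta
        prob = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        icpt, slope = fallback.beta
        icpt_se, slope_se = fallback.beta_se
    else:
        prob = fit.predict_marginal(Xg)
        icpt, slope = fit.beta
        icpt_se, slope_se = fit.beta_se
    curve = pd.DataFrame({"age": age_grid, "probability": prob})

    return LogisticFit(
        intercept=float(icpt),
        age_slope=float(slope),
        intercept_se=float(icpt_se),
        age_slope_se=float(slope_se),
        random_sds=fit.random_sds,
        chi_sq_age=float(chi2),
        p_value=p,
        prediction_curve=curve,
        n_obs=len(records),
        n_animals=records["animal_id"].nunique(),
        method=method,
        separation_detected=separation,
        glmm=fit,
        fallback=fallback,
    )


def test_litter_size_vs_age(records: pd.DataFrame) -> dict:
    """Likelihood-ratio test of an age effect on litter size.

    Restricted to records with a litter; fits Gaussian mixed models of
    litter size with an animal random intercept, with and without age
    (ML, so the likelihoods are comparable), and returns the LRT
    chi-square, its p-value and the sample mean and SD of litter size.
    """
    litters = records.dropna(subset=["litter_size"]).copy()
    if len(litters) < 10:
        raise ValueError("need >= 10 litters")
    litters["litter_size"] = litters["litter_size"].astype(float)
    mean = float(litters["litter_size"].mean())
    sd = float(litters["litter_size"].std(ddof=1))
    if sd == 0:
        warnings.warn("all litters identical; age effect untestable (zero variance)")
        return {"chi_sq": 0.0, "p": 1.0, "mean": mean, "sd": sd, "n": len(litters)}

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m1 = smf.mixedlm(
            "litter_size ~ age", litters, groups=litters["animal_id"]
        ).fit(reml=False)
        m0 = smf.mixedlm(
            "litter_size ~ 1", litters, groups=litters["animal_id"]
        ).fit(reml=False)
    chi2 = max(2.0 * (m1.llf - m0.llf), 0.0)
    p = float(stats.chi2.sf(chi2, df=1))
    return {"chi_sq": float(chi2), "p": p, "mean": mean, "sd": sd, "n": len(litters)}
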