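"""Within-subject centering and the mean-age change-point search.

Age is decomposed into each subject's mean age (the between-subject
predictor) and the deviation from it (the within-subject predictor),
so that cross-sectional differences between animals and longitudinal
change within animals get separate coefficients.  Because the
within-subject age effect switches sign over the lifespan, segment
models are fitted separately to subjects below and above a mean-age
split, and the split is chosen by minimising the combined residual sum
of squares over all candidate partitions of subjects by mean age.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import MixedModelFit, _fit_mixed

logger = logging.getLogger(__name__)

__all__ = [
    "CenteredDesign",
    "ChangePointResult",
    "center_within_subjects",
    "fit_centered_model",
    "search_changepoint",
]


@dataclass
class CenteredDesign:
    """Observation table augmented with the centering decomposition.

    ``data`` carries per row: ``mean_age_c`` (subject mean age),
    ``delta_age`` (age − mean age) and ``initial_rtl`` (the subject's
    first measured RTL, the adjustment for initial telomere length).
    """

    data: pd.DataFrame
    response: str = "rtl"
    n_dropped_single_obs: int = 0

    @property
    def subjects(self) -> pd.DataFrame:
        return (
            self.data.groupby("animal_id")
            .agg(mean_age=("mean_age_c", "first"), n_obs=("delta_age", "size"))
            .reset_index()
        )


@dataclass
class ChangePointResult:
    """RSS-minimising mean-age split with per-segment within-subject fits."""

    split_age: float
    candidate_grid: np.ndarray
    combined_rss_by_candidate: np.ndarray
    young_fit: MixedModelFit
    old_fit: MixedModelFit
    n_young_subjects: int
    n_old_subjects: int
    supported: bool
    rss_improvement: float
    pooled_rss: float
    bootstrap_splits: np.ndarray | None = None

    @property
    def young_slope(self) -> float:
        return self.young_fit.coef("delta_age")

    @property
    def old_slope(self) -> float:
        return self.old_fit.coef("delta_age")

    def profile(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"candidate_split": self.candidate_grid,
             "combined_rss": self.combined_rss_by_candidate}
        )


def center_within_subjects(
    trajectories: pd.DataFrame, response: str = "rtl"
) -> CenteredDesign:
    """Decompose age into subject mean age and within-subject deviation.

    Subjects with fewer than 2 observations are dropped (their within
    deviation is identically zero) and counted.  The decomposition is
    exact: ``age == mean_age_c + delta_age`` row by row.
    """
    df = trajectories.copy()
    counts = df.groupby("animal_id")["age"].transform("size")
    dropped = int((counts < 2).sum())
    if dropped:
        logger.info("dropping %d single-observation rows", dropped)
    df = df[counts >= 2].copy()
    if df.empty:
        raise ValueError("no subject has >= 2 observations")
    g = df.groupby("animal_id")
    df["mean_age_c"] = g["age"].transform("mean")
    df["delta_age"] = df["age"] - df["mean_age_c"]
    order = df.sort_values(["animal_id", "age"]).groupby("animal_id")[response].first()
    df["initial_rtl"] = df["animal_id"].map(order)
    return CenteredDesign(data=df, response=response, n_dropped_single_obs=dropped)


def fit_centered_model(
    design: CenteredDesign,
    include_interaction: bool = False,
    adjust_initial: bool = True,
    mode: str = "mixed",
) -> MixedModelFit:
    """Between/within age-effect model on a centered design.

    response ~ mean_age_c + delta_age (+ mean_age_c:delta_age)
    (+ initial_rtl), with a random intercept per animal in ``mode
    'mixed'`` or plain least squares in ``mode 'ols'``.  The
    ``delta_age`` coefficient is the within-subject slope (RTL/year);
    ``mean_age_c`` the between-subject slope.
    """
    terms = ["mean_age_c", "delta_age"]
    if include_interaction:
        terms.append("mean_age_c:delta_age")
    if adjust_initial:
        terms.append("initial_rtl")
    formula = f"{design.response} ~ " + " + ".join(terms)
    vc = ("animal_id",) if mode == "mixed" else ()
    return _fit_mixed(design.data, formula, vc_factors=vc)


def _segment_fits(
    design: CenteredDesign, split: float, mode: str, adjust_initial: bool
) -> tuple[MixedModelFit, MixedModelFit, float]:
    young = CenteredDesign(
        design.data[design.data["mean_age_c"] <= split], design.response
    )
    old = CenteredDesign(
        design.data[design.data["mean_age_c"] > split], design.response
    )
    fy = fit_centered_model(young, adjust_initial=adjust_initial, mode=mode)
    fo = fit_centered_model(old, adjust_initial=adjust_initial, mode=mode)
    rss = float((fy.residuals**2).sum() + (fo.residuals**2).sum())
    return fy, fo, rss


def search_changepoint(
    trajectories: pd.DataFrame,
    response: str = "rtl",
    min_group_subjects: int = 5,
    mode: str = "ols",
    adjust_initial: bool = True,
    improvement_threshold: float = 0.01,
    bootstrap: int = 0,
    seed: int | None = 0,
) -> ChangePointResult:
    """Find the mean-age split minimising combined segment RSS.

    Candidate splits are the midpoints between consecutive distinct
    subject mean ages (any split between the same two subjects yields
    the identical partition).  Candidates leaving either segment with
    fewer than ``min_group_subjects`` subjects are skipped.  Segment
    models are plain regressions by default: their residual sums of
    squares are directly comparable across candidate partitions,
    whereas mixed-model residuals involve partition-dependent BLUP
    shrinkage (``mode='mixed'`` is available).  The result
    is flagged unsupported when the best split improves the RSS of the
    single pooled model by less than ``improvement_threshold``
    (relative), i.e. when the data carry no evidence of a break.

    With ``bootstrap`` > 0, subjects are resampled with replacement and
    the split re-estimated, giving an uncertainty distribution for the
    split age.
    """
    design = center_within_subjects(trajectories, response=response)
    subj = design.subjects
    if len(subj) < 2 * min_group_subjects:
        raise ValueError("need at least 2*min_group_subjects subjects")

    mean_ages = np.sort(subj["mean_age"].unique())
    grid = (mean_ages[:-1] + mean_ages[1:]) / 2.0
    counts = subj["mean_age"].value_counts().sort_index()
    cum = counts.cumsum()

    candidates, rss_values, fits = [], [], []
    for cand in grid:
        n_young = int(cum[cum.index <= cand].iloc[-1]) if (cum.index <= cand).any() else 0
        n_old = len(subj) - n_young
        if n_young < min_group_subjects or n_old < min_group_subjects:
            continue
        fy, fo, rss = _segment_fits(design, cand, mode, adjust_initial)
        candidates.append(cand)
        rss_values.append(rss)
        fits.append((fy, fo))
    if not candidates:
        raise ValueError("no admissible candidate split (min_group_subjects too large)")

    candidates = np.asarray(candidates)
    rss_values = np.asarray(rss_values)
    best = int(np.argmin(rss_values))
    fy, fo = fits[best]
    split = float(candidates[best])

    pooled = fit_centered_model(design, adjust_initial=adjust_initial, mode=mode)
    pooled_rss = float((pooled.residuals**2).sum())
    improvement = 1.0 - rss_values[best] / pooled_rss if pooled_rss > 0 else 0.0
    # Evidence for a break: the split model pays for its extra
    # parameters (both segments' coefficients plus the searched split
    # location) under BIC; a raw RSS-improvement floor alone cannot
    # separate signal from selection noise, because maximising over
    # candidates inflates the improvement under the null.
    n_rows = len(design.data)
    k_pooled = len(pooled.coefficients)
    k_split = len(fy.coefficients) + len(fo.coefficients) + 1
    bic_pooled = n_rows * np.log(max(pooled_rss, 1e-300) / n_rows) + k_pooled * np.log(n_rows)
    bic_split = n_rows * np.log(max(rss_values[best], 1e-300) / n_rows) + k_split * np.log(n_rows)
    supported = (bic_split < bic_pooled) and improvement >= improvement_threshold

    boot = None
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        ids = subj["animal_id"].to_numpy()
        boot_list = []
        for _ in range(bootstrap):
            take = rng.choice(ids, size=ids.size, replace=True)
            parts = []
            for j, aid in enumerate(take):
                part = trajectories[trajectories["animal_id"] == aid].copy()
                part["animal_id"] = f"{aid}#b{j}"
                parts.append(part)
            bdf = pd.concat(parts, ignore_index=True)
            try:
                res = search_changepoint(
                    bdf, response=response, min_group_subjects=min_group_subjects,
                    mode=mode, adjust_initial=adjust_initial,
                    improvement_threshold=improvement_threshold,
                    bootstrap=0, seed=None,
                )
                boot_list.append(res.split_age)
            except ValueError:
                continue
        boot = np.asarray(boot_list)

    n_young = int((subj["mean_age"] <= split).sum())
    return ChangePointResult(
        split_age=split,
        candidate_grid=candidates,
        combined_rss_by_candidate=rss_values,
        young_fit=fy,
        old_fit=fo,
        n_young_subjects=n_young,
        n_old_subjects=len(subj) - n_young,
        supported=supported,
        rss_improvement=float(improvement),
        pooled_rss=pooled_rss,
        bootstrap_splits=boot,
    )
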