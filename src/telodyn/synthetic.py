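"""Synthetic cohorts, qPCR plates and reproduction histories.

The generators run the analysis models forward so that every downstream
stage (quantification, mixed models, change-point search, reproduction
GLMM) can be exercised and validated by parameter recovery.  The default
parameterisation emulates a long-term capture–mark–recapture study of
edible dormice (*Glis glis*): 49 subjects sampled 2–5 times at ~178-day
intervals, entering the study at ages 1–8 years, with relative telomere
length (RTL) showing a quadratic cross-sectional age profile and a
two-regime within-subject drift (shortening below a mean age of 5.3
years, elongation above it).

Observed RTL for subject *i* at observation *j* is

    rtl_ij = baseline + b1 * mbar_i + b2 * mbar_i**2 + u_i
             + s(mbar_i) * (age_ij - mbar_i) + p_{plate(ij)} + e_ij

where ``mbar_i`` is the subject's mean age over its own observations,
``s(m)`` is ``slope_young`` for ``m <= split_age`` and ``slope_old``
above, and u, p, e are Gaussian subject, plate and residual effects.
The between-subject part is quadratic in mean age and the within-subject
part is piecewise linear in the deviation from mean age, which makes the
within-subject centering decomposition an exactly well-posed estimand.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrajectoryGenConfig",
    "QpcrGenConfig",
    "ReproGenConfig",
    "generate_trajectories",
    "make_change_table",
    "generate_qpcr_plate",
    "generate_reproduction",
]

DAYS_PER_YEAR = 365.25

# First-capture age distribution of the emulated cohort: number of
# subjects entering at ages 1..8.
DEFAULT_ENTRY_AGE_COUNTS = (15, 20, 1, 4, 4, 2, 1, 2)
# Number of subjects with 2, 3, 4 and 5 repeat samples.
DEFAULT_OBS_COUNTS = {2: 15, 3: 15, 4: 12, 5: 7}


@dataclass
class TrajectoryGenConfig:
    """Parameters of the longitudinal RTL cohort generator.

    SDs are in RTL units; slopes in RTL per year.  Defaults are
    calibrated to the emulated dormouse cohort (see module docstring).
    """

    n_subjects: int = 49
    obs_per_subject_range: tuple[int, int] = (2, 5)
    obs_count_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_OBS_COUNTS)
    )
    age_at_entry_weights: tuple[float, ...] = DEFAULT_ENTRY_AGE_COUNTS
    entry_ages: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    mean_sampling_interval_days: float = 178.3
    interval_jitter_days: float = 30.0
    beta_age: float = -0.14
    beta_age2: float = 0.019
    split_age: float = 5.3
    slope_young: float = -0.097
    slope_old: float = 0.410
    sd_subject: float = 0.10
    sd_plate: float = 0.05
    sd_resid: float = 0.22
    baseline_rtl: float = 1.0
    plate_capacity: int = 30
    start_year: int = 2012
    selective_disappearance: bool = False
    disappearance_strength: float = 0.0
    seed: int | None = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.obs_per_subject_range
        if not (2 <= lo <= hi):
            raise ValueError("obs_per_subject_range must satisfy 2 <= min <= max")
        for sd in (self.sd_subject, self.sd_plate, self.sd_resid):
            if sd < 0:
                raise ValueError("random-effect SDs must be >= 0")
        if self.mean_sampling_interval_days <= 0:
            raise ValueError("mean_sampling_interval_days must be > 0")
        ages = np.asarray(self.entry_ages, dtype=float)
        if not (ages.min() < self.split_age < ages.max() + 3):
            raise ValueError("split_age must lie inside the simulated age range")
        if len(self.age_at_entry_weights) != len(self.entry_ages):
            raise ValueError("age_at_entry_weights must match entry_ages")

    def replace(self, **kw) -> "TrajectoryGenConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class QpcrGenConfig:
    """Parameters of the raw amplification-curve generator.

    Efficiencies are per-cycle amplification factors in (1, 2]; defaults
    match the emulated assay (telomere 1.9630, single-copy reference
    gene 1.9486).  Fluorescence is on an arbitrary scale with plateau
    ~1.0.
    """

    efficiency_telomere: float = 1.9630
    efficiency_reference: float = 1.9486
    noise_sd_fluorescence: float = 0.002
    baseline_level: float = 0.05
    baseline_drift: float = 0.0
    plateau: float = 1.0
    q0_reference: float = 1e-7
    pipetting_sd_log: float = 0.003
    n_cycles: int = 40
    replicates: int = 3
    threshold_fraction: float = 0.2
    seed: int | None = 0

    def validate(self) -> None:
        for e in (self.efficiency_telomere, self.efficiency_reference):
            if not (1.0 < e <= 2.0):
                raise ValueError("efficiencies must lie in (1, 2]")
        if self.n_cycles < 15:
            raise ValueError("n_cycles must be >= 15")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not (0 < self.threshold_fraction < 1):
            raise ValueError("threshold_fraction must be in (0, 1)")
        if self.noise_sd_fluorescence < 0 or self.pipetting_sd_log < 0:
            raise ValueError("noise SDs must be >= 0")

    def replace(self, **kw) -> "QpcrGenConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class ReproGenConfig:
    """Parameters of the female reproduction-history generator.

    The yearly probability of reproducing follows a logistic curve in
    age with year and animal random intercepts on the log-odds scale;
    above ``saturation_age`` the probability is clamped to 1 (the
    emulated population reproduces every year once old).  Litter sizes
    are drawn, independently of age, from a discretised normal
    truncated at 1 pup.
    """

    n_animal_years: int = 1529
    logistic_intercept: float = -2.8
    logistic_slope: float = 1.4
    saturation_age: float = 5.0
    saturate: bool = True
    sd_year: float = 1.0
    sd_animal: float = 0.5
    litter_mean: float = 5.49
    litter_sd: float = 2.14
    n_years: int = 9
    start_year: int = 2006
    annual_survival: float = 0.65
    max_age: int = 9
    seed: int | None = 0

    def validate(self) -> None:
        if self.n_animal_years < 1:
            raise ValueError("n_animal_years must be >= 1")
        if self.n_years < 2:
            raise ValueError("need >= 2 study years")
        if not (0 < self.annual_survival < 1):
            raise ValueError("annual_survival must be in (0, 1)")
        for sd in (self.sd_year, self.sd_animal, self.litter_sd):
            if sd < 0:
                raise ValueError("SDs must be >= 0")
        if self.litter_mean < 1:
            raise ValueError("litter_mean must be >= 1")

    def replace(self, **kw) -> "ReproGenConfig":
        return dataclasses.replace(self, **kw)


def _rng(seed) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_trajectories(cfg: TrajectoryGenConfig) -> pd.DataFrame:
    """Simulate a longitudinal RTL cohort.

    Returns a tidy observation table with one row per capture:
    ``animal_id, plate_id, date, age, sex, body_mass, reproductive_active,
    day_of_year, rtl`` plus the latent bookkeeping columns ``mean_age``
    (generator truth) and ``true_rtl`` (RTL before plate and residual
    noise).  Deterministic for a fixed seed.
    """
    cfg.validate()
    rng = _rng(cfg.seed)
    n = cfg.n_subjects

    entry_w = np.asarray(cfg.age_at_entry_weights, dtype=float)
    entry_ages = rng.choice(
        np.asarray(cfg.entry_ages, dtype=float), size=n, p=entry_w / entry_w.sum()
    )
    lo, hi = cfg.obs_per_subject_range
    counts = np.array(sorted(k for k in cfg.obs_count_weights if lo <= k <= hi))
    if counts.size == 0:
        raise ValueError("obs_count_weights has no entry inside obs_per_subject_range")
    cw = np.array([cfg.obs_count_weights[k] for k in counts], dtype=float)
    n_obs = rng.choice(counts, size=n, p=cw / cw.sum())

    sexes = rng.choice(np.array(["f", "m"]), size=n)
    u_subject = rng.normal(0.0, cfg.sd_subject, size=n)

    rows = []
    for i in range(n):
        k = int(n_obs[i])
        jit = rng.uniform(-cfg.interval_jitter_days, cfg.interval_jitter_days, size=k - 1)
        intervals = cfg.mean_sampling_interval_days + jit
        # entry somewhere in the April–October active season
        entry_doy = rng.uniform(91, 304)
        t_days = np.concatenate([[0.0], np.cumsum(intervals)])
        ages = entry_ages[i] + t_days / DAYS_PER_YEAR
        mean_age = ages.mean()
        slope = cfg.slope_young if mean_age <= cfg.split_age else cfg.slope_old
        between = (
            cfg.baseline_rtl
            + cfg.beta_age * mean_age
            + cfg.beta_age2 * mean_age**2
        )
        true_rtl = between + u_subject[i] + slope * (ages - mean_age)
        if cfg.selective_disappearance and cfg.disappearance_strength > 0:
            # optional scenario: subjects with low RTL drop out early
            p_keep = 1.0 / (1.0 + np.exp(-cfg.disappearance_strength * u_subject[i]))
            keep = rng.random(k) < np.concatenate([[1.0], np.full(k - 1, p_keep)])
            keep = np.logical_or.accumulate(keep[::-1])[::-1] & keep
            if keep.sum() < 2:
                keep[:2] = True
        mass = rng.normal(120.0, 20.0, size=k).round(0)
        repro = rng.random(k) < 0.4
        doy = (entry_doy + t_days) % DAYS_PER_YEAR
        date = (
            np.datetime64(f"{cfg.start_year}-01-01")
            + np.round(entry_doy + t_days).astype("timedelta64[D]")
        )
        for j in range(k):
            rows.append(
                {
                    "animal_id": f"A{i + 1:03d}",
                    "date": date[j],
                    "age": ages[j],
                    "sex": sexes[i],
                    "body_mass": mass[j],
                    "reproductive_active": bool(repro[j]) if sexes[i] == "f" else bool(rng.random() < 0.6),
                    "day_of_year": float(doy[j]),
                    "mean_age": mean_age,
                    "true_rtl": true_rtl[j],
                }
            )
    df = pd.DataFrame(rows)

    # qPCR plates: observations are randomised across plates to avoid
    # confounding plate with age, mirroring good assay design.
    n_obs_total = len(df)
    order = rng.permutation(n_obs_total)
    plate_idx = np.empty(n_obs_total, dtype=int)
    plate_idx[order] = np.arange(n_obs_total) // cfg.plate_capacity
    df["plate_id"] = [f"P{p + 1:02d}" for p in plate_idx]
    p_effect = rng.normal(0.0, cfg.sd_plate, size=plate_idx.max() + 1)
    resid = rng.normal(0.0, cfg.sd_resid, size=n_obs_total)
    df["rtl"] = df["true_rtl"] + p_effect[plate_idx] + resid
    # RTL is a positive ratio; at calibrated noise the floor is never hit
    df["rtl"] = df["rtl"].clip(lower=1e-3)
    cols = [
        "animal_id", "plate_id", "date", "age", "sex", "body_mass",
        "reproductive_active", "day_of_year", "rtl", "mean_age", "true_rtl",
    ]
    return df[cols]


def make_change_table(trajectories: pd.DataFrame) -> pd.DataFrame:
    """Consecutive within-subject observation pairs.

    One row per (t-1, t) pair: current RTL, previous RTL, interval in
    days and covariates at time t.  Subjects with a single observation
    contribute no rows.
    """
    df = trajectories.sort_values(["animal_id", "age"], kind="mergesort")
    g = df.groupby("animal_id", sort=False)
    out = df.copy()
    out["rtl_prev"] = g["rtl"].shift(1)
    prev_date = g["date"].shift(1)
    out["interval_days"] = (out["date"] - prev_date).dt.days.astype(float)
    out = out.dropna(subset=["rtl_prev"]).reset_index(drop=True)
    return out


def generate_qpcr_plate(
    samples: list[tuple[str, float]], cfg: QpcrGenConfig, run_id: str = "R1"
) -> pd.DataFrame:
    """Simulate raw amplification curves for one qPCR run.

    ``samples`` is a list of (sample_id, true_rtl); exactly one entry
    should be the reference standard with true_rtl == 1 (by convention
    sample_id ``"STD"``).  Each sample is amplified in ``replicates``
    wells per target.  Per well,

        F(c) = baseline + drift*c + min(q0 * E**c, plateau) + noise(c)

    with the telomere-target starting quantity proportional to the
    sample's true RTL and the reference-gene quantity constant across
    samples.  Returns a long-format curve table (run_id, well,
    sample_id, target, cycle, fluorescence).
    """
    cfg.validate()
    rng = _rng(cfg.seed)
    for sid, r in samples:
        if not r > 0:
            raise ValueError(f"true_rtl must be > 0 (sample {sid!r})")
    cycles = np.arange(1, cfg.n_cycles + 1)
    rows = []
    well_no = 0
    for target, eff in (("telomere", cfg.efficiency_telomere),
                        ("reference", cfg.efficiency_reference)):
        for sid, true_rtl in samples:
            q0 = cfg.q0_reference * (true_rtl if target == "telomere" else 1.0)
            for _rep in range(cfg.replicates):
                well_no += 1
                q0_w = q0 * np.exp(rng.normal(0.0, cfg.pipetting_sd_log))
                signal = np.minimum(q0_w * eff**cycles.astype(float), cfg.plateau)
                f = (
                    cfg.baseline_level
                    + cfg.baseline_drift * cycles
                    + signal
                    + rng.normal(0.0, cfg.noise_sd_fluorescence, size=cfg.n_cycles)
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "run_id": run_id,
                            "well": f"W{well_no:03d}",
                            "sample_id": sid,
                            "target": target,
                            "cycle": cycles,
                            "fluorescence": f,
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


def _litter_latent_params(mean: float, sd: float, kmax: int = 40) -> tuple[float, float]:
    """Latent normal (mu, sigma) whose round-then-truncate-at-1
    discretisation has the requested mean and SD.

    Rounding and truncation shift the moments of a naive normal draw
    (by about +0.06 pups at the default calibration), so the latent
    parameters are solved for rather than used directly.
    """
    from scipy import optimize, stats as st

    ks = np.arange(1, kmax + 1)

    def moments(params):
        mu, sig = params
        upper = st.norm.cdf((ks + 0.5 - mu) / sig)
        lower = st.norm.cdf((ks - 0.5 - mu) / sig)
        p = upper - lower
        p = p / p.sum()
        m = float(p @ ks)
        v = float(p @ (ks - m) ** 2)
        return np.array([m - mean, np.sqrt(v) - sd])

    sol = optimize.root(moments, x0=np.array([mean, sd]), method="hybr")
    mu, sig = sol.x
    if not sol.success or sig <= 0:  # pragma: no cover - defensive
        return mean, sd
    return float(mu), float(sig)


def generate_reproduction(cfg: ReproGenConfig) -> pd.DataFrame:
    """Simulate female animal-year reproduction records.

    Animals enter at age 1 in a random study year and survive each
    subsequent year with probability ``annual_survival`` (a geometric
    lifespan capped at ``max_age``), until ``n_animal_years`` records
    accumulate.  Reproduction is Bernoulli on a logistic age curve with
    year and animal intercepts; litter size is drawn for reproducers
    only, independent of age.
    """
    cfg.validate()
    rng = _rng(cfg.seed)
    litter_mu, litter_sigma = _litter_latent_params(cfg.litter_mean, cfg.litter_sd)
    year_effects = rng.normal(0.0, cfg.sd_year, size=cfg.n_years)
    rows = []
    animal = 0
    while len(rows) < cfg.n_animal_years:
        animal += 1
        a_eff = rng.normal(0.0, cfg.sd_animal)
        entry_year = int(rng.integers(0, cfg.n_years))
        age = 1
        year = entry_year
        while year < cfg.n_years and age <= cfg.max_age:
            eta = (
                cfg.logistic_intercept
                + cfg.logistic_slope * age
                + year_effects[year]
                + a_eff
            )
            p = 1.0 / (1.0 + np.exp(-eta))
            if cfg.saturate and age >= cfg.saturation_age:
                p = 1.0
            reproduced = bool(rng.random() < p)
            litter = np.nan
            if reproduced:
                while True:
                    ls = int(np.rint(rng.normal(litter_mu, litter_sigma)))
                    if ls >= 1:
                        litter = ls
                        break
            rows.append(
                {
                    "animal_id": f"F{animal:04d}",
                    "study_year": cfg.start_year + year,
                    "age": age,
                    "reproduced": reproduced,
                    "litter_size": litter,
                }
            )
            if rng.random() > cfg.annual_survival:
                break
            age += 1
            year += 1
    df = pd.DataFrame(rows[: cfg.n_animal_years])
    return df
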