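"""Mixed models: exact recovery on noise-free data, null recovery,
the regression-to-the-mean correction, and AICc model ranking."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from telodyn.models import (
    aicc,
    compare_random_structures,
    fit_change_model,
    fit_rtl_model,
    rtm_residual_correction,
)
from telodyn.models import _fit_mixed
from telodyn.synthetic import TrajectoryGenConfig, generate_trajectories, make_change_table


class TestRtlModel:
    def test_noise_free_coefficients_exact(self, noisefree_cfg):
        # response constructed as the exact quadratic of observed age,
        # no noise anywhere: recovery is exact linear algebra
        cfg = noisefree_cfg
        df = generate_trajectories(cfg)
        df = df.assign(rtl=1.0 + cfg.beta_age * df["age"] + cfg.beta_age2 * df["age"] ** 2)
        fit = fit_rtl_model(df, include_cubic=False)
        assert fit.backend == "statsmodels-OLS"
        assert fit.coef("age") == pytest.approx(cfg.beta_age, abs=1e-6)
        assert fit.coef("I(age ** 2)") == pytest.approx(cfg.beta_age2, abs=1e-6)

    def test_default_cohort_quadratic_within_two_se(self):
        # replicate the default design; the mean estimate must sit
        # within two (single-fit) standard errors of the generating
        # quadratic
        ests, ses = [], []
        for s in range(10):
            df = generate_trajectories(TrajectoryGenConfig(seed=1000 + s))
            f = fit_rtl_model(df, include_cubic=False)
            ests.append([f.coef("age"), f.coef("I(age ** 2)")])
            ses.append([f.se("age"), f.se("I(age ** 2)")])
        mean = np.mean(ests, axis=0)
        se = np.median(ses, axis=0)
        assert abs(mean[0] - (-0.14)) < 2 * se[0]
        assert abs(mean[1] - 0.019) < 2 * se[1]

    def test_cubic_dropped_when_not_significant(self, default_cohort):
        fit = fit_rtl_model(default_cohort, include_cubic="auto")
        assert "I(age ** 3)" not in fit.coefficients.index
        assert any("cubic" in n for n in fit.notes)

    def test_single_plate_fit_succeeds_with_zero_variance(self, default_cohort):
        df = default_cohort.copy()
        df["plate_id"] = "P01"
        fit = fit_rtl_model(df, include_cubic=False)
        assert fit.random_effect_sds["plate"] == 0.0
        assert np.isfinite(fit.coef("age"))

    def test_r2_bounds(self, default_cohort):
        fit = fit_rtl_model(default_cohort, include_cubic=False)
        assert 0 <= fit.r2_random <= fit.r2_full <= 1

    def test_matches_lme4_fixed_effects(self, default_cohort, tmp_path):
        """Independent oracle: the same crossed random-intercept model
        fitted by lme4 (REML) must give the same fixed effects."""
        df = default_cohort.copy()
        df["sex"] = (df["sex"] == "m").astype(int)
        df["repro"] = df["reproductive_active"].astype(int)
        csv = tmp_path / "cohort.csv"
        df.to_csv(csv, index=False)
        rscript = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(rtl ~ sex + age + I(age^2) + body_mass + repro +
                      day_of_year + (1|animal_id) + (1|plate_id), data=d)
            cat(fixef(m)[["age"]], fixef(m)[["I(age^2)"]], sep="\\n")
        """)
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        r_age, r_age2 = (float(v) for v in out.stdout.split())
        fit = _fit_mixed(
            df,
            "rtl ~ sex + age + I(age**2) + body_mass + repro + day_of_year",
        )
        assert fit.coef("age") == pytest.approx(r_age, abs=2e-4)
        assert fit.coef("I(age ** 2)") == pytest.approx(r_age2, abs=2e-5)


class TestChangeModel:
    def test_null_drift_gives_null_age_terms(self):
        cfg = TrajectoryGenConfig(slope_young=0.0, slope_old=0.0,
                                  beta_age=0.0, beta_age2=0.0, seed=8)
        ch = make_change_table(generate_trajectories(cfg))
        fit = fit_change_model(ch)
        assert abs(fit.coef("age")) < 2 * fit.se("age")
        assert abs(fit.coef("I(age ** 2)")) < 2 * fit.se("I(age ** 2)")

    def test_default_cohort_quadratic_within_two_se(self):
        ests, ses = [], []
        for s in range(10):
            ch = make_change_table(
                generate_trajectories(TrajectoryGenConfig(seed=2000 + s))
            )
            f = fit_change_model(ch)
            ests.append([f.coef("age"), f.coef("I(age ** 2)")])
            ses.append([f.se("age"), f.se("I(age ** 2)")])
        mean = np.mean(ests, axis=0)
        se = np.nanmedian(ses, axis=0)  # rare singular vc fits yield NaN SEs
        assert abs(mean[0] - (-0.18)) < 2 * se[0]
        assert abs(mean[1] - 0.022) < 2 * se[1]

    def test_prev_rtl_coefficient_below_one_on_pure_noise(self):
        # regression to the mean: with no true change, the slope of
        # RTL_t on RTL_{t-1} is attenuated below 1
        rng = np.random.default_rng(5)
        n = 400
        latent = rng.normal(1.0, 0.15, n)
        df = pd.DataFrame(
            {
                "animal_id": [f"A{i}" for i in range(n)],
                "plate_id": rng.choice(["P1", "P2", "P3"], n),
                "rtl": latent + rng.normal(0, 0.2, n),
                "rtl_prev": latent + rng.normal(0, 0.2, n),
                "age": rng.uniform(1, 8, n),
                "sex": rng.choice(["f", "m"], n),
                "body_mass": rng.normal(120, 20, n),
                "reproductive_active": rng.random(n) < 0.5,
                "day_of_year": rng.uniform(90, 300, n),
                "interval_days": np.full(n, 178.0),
            }
        )
        fit = fit_change_model(df)
        assert fit.coef("rtl_prev") < 1 - 2 * fit.se("rtl_prev")


class TestRtmCorrection:
    def test_perfectly_linear_losses_become_zero(self):
        x = np.array([0.8, 1.0, 1.2, 1.5])
        y = 0.4 - 0.3 * x
        assert np.allclose(rtm_residual_correction(x, y), 0.0)

    def test_corrected_values_sum_to_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(1, 0.2, 200)
        y = rng.normal(0, 0.1, 200)
        assert rtm_residual_correction(x, y).sum() == pytest.approx(0.0, abs=1e-10)

    def test_uncorrelated_with_initial_on_null_data(self):
        rng = np.random.default_rng(7)
        n = 500
        latent = rng.normal(1, 0.15, n)
        first = latent + rng.normal(0, 0.2, n)
        second = latent + rng.normal(0, 0.2, n)
        corrected = rtm_residual_correction(first, first - second)
        assert abs(np.corrcoef(first, corrected)[0, 1]) < 0.05

    def test_constant_initial_warns_and_centres(self):
        with pytest.warns(UserWarning):
            out = rtm_residual_correction(np.ones(5), np.arange(5.0))
        assert out.sum() == pytest.approx(0.0)

    def test_equivalent_to_conditioning_in_fixed_effects_fit(self):
        # Frisch–Waugh: the age coefficient from the joint OLS of loss
        # on initial RTL and age equals the slope of the corrected
        # losses on initial-RTL-residualised age
        rng = np.random.default_rng(3)
        n = 300
        initial = rng.normal(1, 0.2, n)
        age = 2 + 0.5 * initial + rng.uniform(0, 5, n)  # correlated with initial
        loss = 0.2 - 0.4 * initial + 0.05 * age + rng.normal(0, 0.1, n)
        X = np.column_stack([np.ones(n), initial, age])
        joint = np.linalg.lstsq(X, loss, rcond=None)[0][2]
        corrected = rtm_residual_correction(initial, loss)
        age_resid = rtm_residual_correction(initial, age)
        via_resid = np.linalg.lstsq(
            np.column_stack([np.ones(n), age_resid]), corrected, rcond=None
        )[0][1]
        assert via_resid == pytest.approx(joint, rel=1e-10)


class TestAicc:
    def test_closed_form(self):
        assert aicc(100.0, 3, 10) == pytest.approx(104.0)

    def test_undefined_when_sample_too_small(self):
        assert aicc(100.0, 9, 10) == np.inf

    def test_identical_structures_tie(self, default_cohort):
        tab = compare_random_structures(
            default_cohort,
            {"a": ("animal_id", "plate_id"), "b": ("animal_id", "plate_id")},
        )
        assert tab["aicc"].nunique() == 1

    def test_structure_without_spurious_year_effect_wins(self):
        # data generated without year effects: the structure omitting
        # the year random intercept should win most replicates
        wins = 0
        reps = 30
        for s in range(reps):
            df = generate_trajectories(TrajectoryGenConfig(seed=3000 + s))
            df = df.assign(year=df["date"].dt.year.astype(str))
            tab = compare_random_structures(
                df,
                {
                    "animal+plate": ("animal_id", "plate_id"),
                    "animal+plate+year": ("animal_id", "plate_id", "year"),
                },
            )
            wins += tab.iloc[0]["structure"] == "animal+plate"
        assert wins / reps >= 0.8
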