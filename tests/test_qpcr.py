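"""Quantification: efficiency estimation, the RTL ratio, replicate QC
and inter-run calibration, checked against analytic oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from telodyn.qpcr import (
    AmplificationCurve,
    QuantParams,
    RtlInputs,
    aggregate_replicates,
    compute_rtl,
    curves_from_frame,
    estimate_well_efficiency,
    inter_run_calibration,
    quantify_run,
)
from telodyn.synthetic import QpcrGenConfig, generate_qpcr_plate


def exp_curve(e=2.0, q0=1e-7, n=40, baseline=0.05, plateau=1.0, drift=0.0):
    c = np.arange(1, n + 1, dtype=float)
    return baseline + drift * c + np.minimum(q0 * e**c, plateau)


class TestEfficiency:
    def test_exact_exponential_recovered_to_machine_precision(self):
        curve = AmplificationCurve("R", "W1", "S", "telomere", exp_curve(e=2.0))
        w = estimate_well_efficiency(curve)
        assert w.efficiency == pytest.approx(2.0, abs=1e-6)
        assert w.r_squared == pytest.approx(1.0, abs=1e-9)
        assert not w.qc_flags

    @pytest.mark.parametrize("e", [1.9486, 1.9630])
    def test_assay_efficiency_recovered_under_noise(self, e):
        rng = np.random.default_rng(4)
        ests = []
        for _ in range(6):
            f = exp_curve(e=e) + rng.normal(0, 0.002, 40)
            w = estimate_well_efficiency(
                AmplificationCurve("R", "W", "S", "reference", f)
            )
            ests.append(w.efficiency)
        assert np.mean(ests) == pytest.approx(e, abs=0.02)

    def test_flat_curve_flags_no_amplification(self):
        curve = AmplificationCurve("R", "W", "S", "telomere", np.full(40, 0.05))
        w = estimate_well_efficiency(curve)
        assert "no_amplification" in w.qc_flags
        assert math.isnan(w.efficiency)

    def test_baseline_shift_invariance(self):
        f = exp_curve(e=1.9)
        w0 = estimate_well_efficiency(AmplificationCurve("R", "W", "S", "telomere", f))
        w1 = estimate_well_efficiency(
            AmplificationCurve("R", "W", "S", "telomere", f + 0.37)
        )
        assert w1.efficiency == pytest.approx(w0.efficiency, abs=1e-9)

    def test_linear_drift_removed_when_fitted(self):
        f = exp_curve(e=1.95, drift=0.002)
        w = estimate_well_efficiency(
            AmplificationCurve("R", "W", "S", "telomere", f),
            QuantParams(fit_baseline_drift=True),
        )
        assert w.efficiency == pytest.approx(1.95, abs=1e-6)

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            AmplificationCurve("R", "W", "S", "telomere", np.ones(10))


class TestComputeRtl:
    def test_standard_against_itself_is_one(self):
        assert compute_rtl(RtlInputs(2.0, 2.0, 21.0, 21.0, 19.0, 19.0)) == 1.0

    def test_one_cycle_doubling(self):
        assert compute_rtl(RtlInputs(2.0, 2.0, 20.0, 21.0, 19.0, 19.0)) == 2.0

    def test_mixed_efficiencies_match_direct_arithmetic(self):
        # independent arithmetic oracle: E_T^0.5 * E_C^0.25
        got = compute_rtl(RtlInputs(1.9630, 1.9486, 20.5, 21.0, 19.25, 19.0))
        expected = math.pow(1.9630, 0.5) * math.pow(1.9486, 0.25)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_non_amplifying_efficiency_rejected(self):
        with pytest.raises(ValueError):
            compute_rtl(RtlInputs(0.99, 2.0, 20.0, 21.0, 19.0, 19.0))

    @given(
        k=st.integers(min_value=-5, max_value=5),
        e=st.floats(min_value=1.5, max_value=2.0),
    )
    def test_scale_consistency(self, k, e):
        # multiplying starting quantity by E^k shifts Ct by -k and
        # multiplies RTL by E^k; the standard itself stays at 1
        base = RtlInputs(e, e, 20.0, 20.0, 18.0, 18.0)
        shifted = RtlInputs(e, e, 20.0 - k, 20.0, 18.0, 18.0)
        assert compute_rtl(base) == pytest.approx(1.0, rel=1e-12)
        assert compute_rtl(shifted) == pytest.approx(e**k, rel=1e-9)


class TestReplicates:
    def test_identical_triplicates_have_zero_cv(self):
        mean, cv, n, flags = aggregate_replicates(np.array([20.0, 20.0, 20.0]))
        assert (mean, cv, n) == (20.0, 0.0, 3)
        assert not flags

    def test_outlier_excluded_by_median_rule(self):
        mean, cv, n, flags = aggregate_replicates(
            np.array([20.0, 20.1, 23.0]), outlier_ct_cutoff=0.5
        )
        assert mean == pytest.approx(20.05)
        assert n == 2
        assert "outlier_replicate" in flags

    def test_noise_free_plate_cvs_are_tiny(self):
        cfg = QpcrGenConfig(noise_sd_fluorescence=0.0, seed=9)
        df = generate_qpcr_plate([("STD", 1.0), ("A", 1.3)], cfg)
        meas, _ = quantify_run(curves_from_frame(df))
        for m in meas:
            assert m.cv_telomere < 1e-3  # intra-assay CV of order 1e-4
            assert m.cv_reference < 1e-3


class TestPipelineIdentity:
    def test_zero_noise_rtl_recovery_exact(self):
        cfg = QpcrGenConfig(noise_sd_fluorescence=0, pipetting_sd_log=0, seed=0)
        truth = {"STD": 1.0, "A": 0.5, "B": 1.2, "C": 1.9}
        df = generate_qpcr_plate(list(truth.items()), cfg)
        meas, wtab = quantify_run(curves_from_frame(df))
        eff = wtab.groupby("target")["efficiency"].mean()
        assert abs(eff["telomere"] - cfg.efficiency_telomere) < 1e-6
        assert abs(eff["reference"] - cfg.efficiency_reference) < 1e-6
        for m in meas:
            assert m.rtl == pytest.approx(truth[m.sample_id], rel=1e-3)

    def test_default_noise_rtl_rmse_under_five_percent(self):
        cfg = QpcrGenConfig(seed=21)
        truth = {"STD": 1.0}
        rng = np.random.default_rng(12)
        truth.update({f"S{i}": float(r) for i, r in enumerate(rng.uniform(0.5, 2, 12))})
        df = generate_qpcr_plate(list(truth.items()), cfg)
        meas, _ = quantify_run(curves_from_frame(df))
        rel = np.array([m.rtl / truth[m.sample_id] - 1 for m in meas])
        assert np.sqrt((rel**2).mean()) < 0.05


class TestInterRun:
    def _tab(self, vals):
        return pd.DataFrame(
            {"sample_id": [f"S{i}" for i in range(len(vals))], "rtl": vals}
        )

    def test_identical_runs(self):
        a = self._tab([0.8, 1.0, 1.4, 1.9])
        r, slope = inter_run_calibration(a, a.copy())
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.0)

    def test_constructed_scaling_slope(self):
        a = self._tab([0.8, 1.0, 1.4, 1.9])
        b = a.copy()
        b["rtl"] *= 1.12
        r, slope = inter_run_calibration(a, b)
        assert r == pytest.approx(1.0)
        assert slope == pytest.approx(1.12)

    def test_duplicate_noisy_runs_correlate(self):
        truth = [("STD", 1.0)] + [
            (f"S{i}", v) for i, v in enumerate(np.linspace(0.5, 2.0, 10))
        ]
        tabs = []
        for seed in (31, 32):
            df = generate_qpcr_plate(truth, QpcrGenConfig(seed=seed))
            meas, _ = quantify_run(curves_from_frame(df))
            tabs.append(
                pd.DataFrame(
                    {"sample_id": [m.sample_id for m in meas],
                     "rtl": [m.rtl for m in meas]}
                )
            )
        r, slope = inter_run_calibration(*tabs)
        assert r >= 0.9

    def test_too_few_shared_samples(self):
        a = self._tab([1.0, 1.2])
        with pytest.raises(ValueError):
            inter_run_calibration(a, a.copy())
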