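"""Seeded, manifest-producing pipeline over the analysis stages.

Stages: ``generate`` (synthetic cohort, qPCR curves, reproduction
records), ``quantify`` (curves → RTL table), ``model`` (cross-sectional
and change models), ``changepoint`` (mean-age split search),
``reproduction`` (logistic GLMM + litter-size test).  Every output file
is recorded in a JSON manifest with its SHA-256 hash and the config
snapshot; rerunning with the same config reproduces identical bytes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic, qpcr, models, centering, reproduction as repro

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("generate", "quantify", "model", "changepoint", "reproduction")
FLOAT_FORMAT = "%.10g"


@dataclasses.dataclass
class PipelineConfig:
    """Paths, stage list, generator settings and the master seed."""

    outdir: str = "telodyn_out"
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    trajectory: dict = dataclasses.field(default_factory=dict)
    qpcr_gen: dict = dataclasses.field(default_factory=dict)
    repro_gen: dict = dataclasses.field(default_factory=dict)
    quant: dict = dataclasses.field(default_factory=dict)
    changepoint: dict = dataclasses.field(default_factory=dict)
    n_qpcr_samples: int = 20
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in order and return the manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    sub_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    manifest: dict = {"config": config.to_dict(), "outputs": {}, "stages_run": []}

    def record(name: str, path: Path):
        manifest["outputs"][name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    stages = [s for s in ALL_STAGES if s in config.stages]

    traj = rtl_curves = repro_df = None
    if "generate" in stages:
        tcfg = synthetic.TrajectoryGenConfig(**{"seed": sub_seed[0], **config.trajectory})
        traj = synthetic.generate_trajectories(tcfg)
        _write_csv(traj, out / "trajectories.csv")
        record("trajectories", out / "trajectories.csv")

        qcfg = synthetic.QpcrGenConfig(**{"seed": sub_seed[1], **config.qpcr_gen})
        rng = np.random.default_rng(sub_seed[1])
        n = config.n_qpcr_samples
        sample_rtls = [("STD", 1.0)] + [
            (f"S{i:03d}", float(r)) for i, r in enumerate(rng.uniform(0.5, 2.0, n), 1)
        ]
        rtl_curves = synthetic.generate_qpcr_plate(sample_rtls, qcfg)
        _write_csv(rtl_curves, out / "qpcr_curves.csv")
        record("qpcr_curves", out / "qpcr_curves.csv")
        _write_csv(
            pd.DataFrame(sample_rtls, columns=["sample_id", "true_rtl"]),
            out / "qpcr_truth.csv",
        )
        record("qpcr_truth", out / "qpcr_truth.csv")

        rcfg = synthetic.ReproGenConfig(**{"seed": sub_seed[2], **config.repro_gen})
        repro_df = synthetic.generate_reproduction(rcfg)
        _write_csv(repro_df, out / "reproduction.csv")
        record("reproduction", out / "reproduction.csv")
        manifest["stages_run"].append("generate")

    if "quantify" in stages:
        if rtl_curves is None:
            rtl_curves = pd.read_csv(out / "qpcr_curves.csv")
            manifest["outputs"]["qpcr_curves_input"] = {
                "path": str(out / "qpcr_curves.csv"),
                "sha256": _sha256(out / "qpcr_curves.csv"),
            }
        params = qpcr.QuantParams(**config.quant)
        rtl_tab, well_tab = qpcr.quantify_curves(rtl_curves, params)
        _write_csv(rtl_tab, out / "rtl_measurements.csv")
        record("rtl_measurements", out / "rtl_measurements.csv")
        qc = {
            "n_samples": int(len(rtl_tab)),
            "n_flagged": int((rtl_tab.qc_flags != "").sum()),
            "mean_cv_telomere": float(rtl_tab.cv_telomere.mean()),
            "mean_cv_reference": float(rtl_tab.cv_reference.mean()),
            "mean_efficiency": well_tab.groupby("target")["efficiency"]
            .mean()
            .to_dict(),
        }
        _write_json(qc, out / "qc_report.json")
        record("qc_report", out / "qc_report.json")
        manifest["stages_run"].append("quantify")

    if {"model", "changepoint"} & set(stages) and traj is None:
        traj = pd.read_csv(out / "trajectories.csv", parse_dates=["date"])

    if "model" in stages:
        fit = models.fit_rtl_model(traj)
        _write_csv(
            fit.coefficients.reset_index(names="term"), out / "rtl_model_coefficients.csv"
        )
        record("rtl_model_coefficients", out / "rtl_model_coefficients.csv")
        changes = synthetic.make_change_table(traj)
        cfit = models.fit_change_model(changes)
        _write_csv(
            cfit.coefficients.reset_index(names="term"),
            out / "change_model_coefficients.csv",
        )
        record("change_model_coefficients", out / "change_model_coefficients.csv")
        report = {
            name: {
                "n_obs": f.n_obs,
                "n_subjects": f.n_subjects,
                "aicc": f.aicc,
                "r2_full": f.r2_full,
                "r2_random": f.r2_random,
                "random_effect_sds": f.random_effect_sds,
                "notes": f.notes,
            }
            for name, f in (("rtl", fit), ("change", cfit))
        }
        _write_json(report, out / "model_report.json")
        record("model_report", out / "model_report.json")
        manifest["stages_run"].append("model")

    if "changepoint" in stages:
        cp = centering.search_changepoint(
            traj, seed=sub_seed[3], **config.changepoint
        )
        _write_csv(cp.profile(), out / "rss_profile.csv")
        record("rss_profile", out / "rss_profile.csv")
        cp_json = {
            "split_age": cp.split_age,
            "supported": cp.supported,
            "rss_improvement": cp.rss_improvement,
            "n_young_subjects": cp.n_young_subjects,
            "n_old_subjects": cp.n_old_subjects,
            "young_slope": cp.young_slope,
            "young_slope_se": cp.young_fit.se("delta_age"),
            "young_slope_p": cp.young_fit.p("delta_age"),
            "old_slope": cp.old_slope,
            "old_slope_se": cp.old_fit.se("delta_age"),
            "old_slope_p": cp.old_fit.p("delta_age"),
        }
        if cp.bootstrap_splits is not None and cp.bootstrap_splits.size:
            cp_json["bootstrap_split_ci"] = [
                float(np.percentile(cp.bootstrap_splits, 2.5)),
                float(np.percentile(cp.bootstrap_splits, 97.5)),
            ]
        _write_json(cp_json, out / "changepoint.json")
        record("changepoint", out / "changepoint.json")
        manifest["stages_run"].append("changepoint")

    if "reproduction" in stages:
        if repro_df is None:
            repro_df = pd.read_csv(out / "reproduction.csv")
        fit = repro.fit_reproduction_model(repro_df)
        litter = repro.test_litter_size_vs_age(repro_df)
        _write_csv(fit.prediction_curve, out / "reproduction_curve.csv")
        record("reproduction_curve", out / "reproduction_curve.csv")
        _write_json(
            {
                "intercept": fit.intercept,
                "age_slope": fit.age_slope,
                "age_slope_se": fit.age_slope_se,
                "random_sds": fit.random_sds,
                "chi_sq_age": fit.chi_sq_age,
                "p_value": fit.p_value,
                "method": fit.method,
                "litter": litter,
            },
            out / "reproduction_fit.json",
        )
        record("reproduction_fit", out / "reproduction_fit.json")
        manifest["stages_run"].append("reproduction")

    _write_json(manifest, out / "manifest.json")
    return manifest
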