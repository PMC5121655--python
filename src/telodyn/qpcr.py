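"""Raw amplification curves → relative telomere length (RTL).

Implements efficiency-corrected relative quantification against a
standard sample: a window-of-linearity efficiency estimator in the
LinRegPCR tradition (baseline subtraction from pre-amplification
cycles, best-R² log-linear window, E = 10**slope), interpolated Ct
calling at a run-constant threshold, replicate aggregation with
outlier exclusion, and the RTL ratio

    RTL = E_T**(Ct_ST - Ct_T) / E_C**(Ct_SC - Ct_C)

where T/ST are telomere reactions of the target and standard samples
and C/SC the corresponding single-copy reference-gene reactions.  The
standard sample has RTL = 1 by definition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AmplificationCurve",
    "WellQuant",
    "RtlInputs",
    "RtlMeasurement",
    "QuantParams",
    "estimate_well_efficiency",
    "compute_rtl",
    "aggregate_replicates",
    "curves_from_frame",
    "rtl_from_ct_table",
    "quantify_run",
    "quantify_curves",
    "inter_run_calibration",
]


@dataclass
class AmplificationCurve:
    """One well's raw fluorescence-by-cycle trace."""

    run_id: str
    well: str
    sample_id: str
    target: str  # "telomere" | "reference"
    fluorescence: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.fluorescence, dtype=float)
        if f.ndim != 1 or f.size < 15:
            raise ValueError("curve needs >= 15 cycles")
        if not np.all(np.isfinite(f)):
            raise ValueError("fluorescence must be finite")
        if self.target not in ("telomere", "reference"):
            raise ValueError("target must be 'telomere' or 'reference'")
        self.fluorescence = f

    @property
    def n_cycles(self) -> int:
        return self.fluorescence.size


@dataclass
class WellQuant:
    """Per-well efficiency, Ct and QC summary."""

    run_id: str
    well: str
    sample_id: str
    target: str
    efficiency: float
    ct: float
    window: tuple[int, int]
    r_squared: float
    plateau: float
    qc_flags: set = field(default_factory=set)

    @property
    def ok(self) -> bool:
        return "no_amplification" not in self.qc_flags


@dataclass
class RtlInputs:
    """Efficiencies and Cts entering the RTL ratio."""

    e_t: float
    e_c: float
    ct_t: float
    ct_st: float
    ct_c: float
    ct_sc: float

    def validate(self) -> None:
        for name in ("e_t", "e_c"):
            e = getattr(self, name)
            if not np.isfinite(e) or e <= 1.0:
                raise ValueError(f"{name} = {e}: a non-amplifying assay (E <= 1)")
            if e > 2.2:
                raise ValueError(f"{name} = {e} exceeds plausible range (1, 2.2]")
        for name in ("ct_t", "ct_st", "ct_c", "ct_sc"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive cycle number")


@dataclass
class RtlMeasurement:
    """One sample's RTL with replicate CVs and QC flags."""

    sample_id: str
    run_id: str
    rtl: float
    cv_telomere: float
    cv_reference: float
    n_replicates_used: int
    qc_flags: set = field(default_factory=set)


@dataclass
class QuantParams:
    """Tunables of the quantification pipeline.

    baseline_cycles: 1-based inclusive cycle range whose mean estimates
    the pre-amplification baseline; window widths are the candidate
    log-linear window sizes; the Ct threshold is a fixed fraction of
    the run's median plateau fluorescence, constant within a run.
    """

    baseline_cycles: tuple[int, int] = (3, 8)
    fit_baseline_drift: bool = False
    window_widths: tuple[int, ...] = (4, 5, 6)
    min_signal_factor: float = 10.0
    plateau_exclude_fraction: float = 0.95
    min_r_squared: float = 0.98
    threshold_fraction: float = 0.2
    outlier_ct_cutoff: float = 0.5
    per_well_efficiency: bool = False
    standard_id: str = "STD"


def _baseline_correct(
    f: np.ndarray, params: QuantParams, signal: np.ndarray | None = None
) -> tuple[np.ndarray, float]:
    """Estimate and subtract the pre-amplification baseline.

    ``signal``, when given, is a model of the amplification signal to
    remove from the baseline cycles first (iterative reconstruction:
    early exponential growth otherwise inflates the baseline mean).
    """
    lo, hi = params.baseline_cycles
    cyc = np.arange(1, f.size + 1, dtype=float)
    idx = slice(lo - 1, hi)
    resid = f if signal is None else f - signal
    if params.fit_baseline_drift:
        A = np.vstack([np.ones(hi - lo + 1), cyc[idx]]).T
        coef, *_ = np.linalg.lstsq(A, resid[idx], rcond=None)
        base = coef[0] + coef[1] * cyc
        noise = float(np.std(resid[idx] - A @ coef))
    else:
        base = np.full(f.size, resid[idx].mean())
        noise = float(np.std(resid[idx]))
    return f - base, noise


def estimate_well_efficiency(
    curve: AmplificationCurve,
    params: QuantParams | None = None,
    threshold: float | None = None,
) -> WellQuant:
    """Estimate amplification efficiency and Ct from one raw curve.

    The baseline (mean of the pre-amplification cycles, optionally with
    a fitted linear drift) is subtracted; the exponential phase is the
    4–6 cycle window of maximal R² for log10(fluorescence) vs cycle,
    restricted to cycles well above baseline noise and below the
    plateau; E = 10**slope.  Ct is the log-interpolated cycle at which
    the corrected signal crosses ``threshold`` (if None, a per-curve
    threshold at ``threshold_fraction`` of this curve's plateau).

    Flat or plateau-only curves get the ``no_amplification`` flag with
    efficiency and Ct undefined (NaN).
    """
    params = params or QuantParams()
    f = curve.fluorescence
    cyc = np.arange(1, f.size + 1, dtype=float)

    def failed(plateau=float("nan")):
        return WellQuant(
            curve.run_id, curve.well, curve.sample_id, curve.target,
            float("nan"), float("nan"), (0, 0), float("nan"), plateau,
            {"no_amplification"},
        )

    # Iterative baseline reconstruction: the fitted exponential is
    # extrapolated into the baseline cycles and removed before the
    # baseline is re-estimated, so early signal growth cannot bias it.
    signal_model = None
    best = None
    corrected = f
    plateau = float("nan")
    for _ in range(6):
        corrected, noise = _baseline_correct(f, params, signal_model)
        plateau = float(corrected.max())
        floor = max(params.min_signal_factor * noise, 1e-4 * max(plateau, 0.0), 1e-12)
        usable = (corrected > floor) & (
            corrected < params.plateau_exclude_fraction * plateau
        )
        if plateau <= 0 or usable.sum() < min(params.window_widths):
            return failed(plateau)
        logf = np.full(f.size, np.nan)
        pos = corrected > 0
        logf[pos] = np.log10(corrected[pos])
        new_best = None  # ((r2, width, start), slope, intercept, window)
        for width in params.window_widths:
            for start in range(f.size - width + 1):
                sl = slice(start, start + width)
                if not usable[sl].all():
                    continue
                x, y = cyc[sl], logf[sl]
                xm, ym = x.mean(), y.mean()
                sxx = ((x - xm) ** 2).sum()
                sxy = ((x - xm) * (y - ym)).sum()
                syy = ((y - ym) ** 2).sum()
                if sxx == 0 or syy == 0:
                    continue
                slope = sxy / sxx
                r2 = (sxy * sxy) / (sxx * syy)
                # prefer higher R^2; near-ties (clean exponentials) go
                # to wider, later (higher-signal) windows
                key = (round(r2, 10), width, start)
                if slope > 0 and (new_best is None or key > new_best[0]):
                    new_best = (key, slope, ym - slope * xm, (start + 1, start + width))
        if new_best is None:
            return failed(plateau)
        converged = (
            best is not None
            and new_best[3] == best[3]
            and abs(new_best[1] - best[1]) < 1e-14
        )
        best = new_best
        if converged:
            break
        _key, slope, icpt, _win = best
        signal_model = 10.0 ** np.minimum(icpt + slope * cyc, np.log10(plateau))

    flags: set = set()
    (r2, _w, _s), slope, _icpt, window = best
    eff = 10.0 ** slope
    if r2 < params.min_r_squared:
        flags.add("poor_linearity")

    thr = threshold if threshold is not None else params.threshold_fraction * plateau
    ct = _call_ct(corrected, thr)
    if not np.isfinite(ct):
        flags.add("no_amplification")
    return WellQuant(
        curve.run_id, curve.well, curve.sample_id, curve.target,
        float(eff), float(ct), window, float(r2), plateau, flags,
    )


def _call_ct(corrected: np.ndarray, threshold: float) -> float:
    """First threshold crossing, interpolated on the log-signal scale."""
    above = np.nonzero(corrected >= threshold)[0]
    if above.size == 0 or threshold <= 0:
        return float("nan")
    i = above[0]
    if i == 0:
        return 1.0
    f0, f1 = corrected[i - 1], corrected[i]
    if f0 <= 0:
        frac = (threshold - f0) / (f1 - f0)
    else:
        frac = (np.log(threshold) - np.log(f0)) / (np.log(f1) - np.log(f0))
    return float(i + frac)  # cycles are 1-based: crossing between cycle i and i+1


def compute_rtl(inputs: RtlInputs) -> float:
    """Efficiency-corrected RTL ratio relative to the standard sample."""
    inputs.validate()
    return float(
        inputs.e_t ** (inputs.ct_st - inputs.ct_t)
        / inputs.e_c ** (inputs.ct_sc - inputs.ct_c)
    )


def aggregate_replicates(
    cts: np.ndarray, outlier_ct_cutoff: float = 0.5
) -> tuple[float, float, int, set]:
    """Mean Ct and CV over replicate wells with median-outlier exclusion.

    A replicate deviating from the replicate median by more than
    ``outlier_ct_cutoff`` cycles is flagged and excluded.  CV is the
    sample SD over surviving replicate Cts divided by their mean.
    """
    cts = np.asarray(cts, dtype=float)
    cts = cts[np.isfinite(cts)]
    flags: set = set()
    if cts.size == 0:
        return float("nan"), float("nan"), 0, {"no_amplification"}
    med = np.median(cts)
    keep = np.abs(cts - med) <= outlier_ct_cutoff
    if not keep.all():
        flags.add("outlier_replicate")
    kept = cts[keep]
    mean = float(kept.mean())
    cv = float(kept.std(ddof=1) / mean) if kept.size > 1 else 0.0
    return mean, cv, int(kept.size), flags


def curves_from_frame(df: pd.DataFrame) -> list[AmplificationCurve]:
    """Long-format curve table → AmplificationCurve objects."""
    out = []
    for (run, well), sub in df.groupby(["run_id", "well"], sort=True):
        sub = sub.sort_values("cycle")
        out.append(
            AmplificationCurve(
                run_id=str(run),
                well=str(well),
                sample_id=str(sub["sample_id"].iloc[0]),
                target=str(sub["target"].iloc[0]),
                fluorescence=sub["fluorescence"].to_numpy(dtype=float),
            )
        )
    return out


def quantify_run(
    curves: list[AmplificationCurve], params: QuantParams | None = None
) -> tuple[list[RtlMeasurement], pd.DataFrame]:
    """Quantify one run: wells → efficiencies/Cts → per-sample RTL.

    The Ct threshold is run-constant (``threshold_fraction`` of the
    run's median well plateau).  Eq. uses the run-mean efficiency per
    assay across unflagged wells unless ``per_well_efficiency`` is set,
    in which case each sample's replicate-mean efficiency is used.
    Returns the RTL measurements and the per-well quantification table.
    """
    params = params or QuantParams()
    if not curves:
        raise ValueError("no curves supplied")
    run_id = curves[0].run_id

    prelim = [estimate_well_efficiency(c, params) for c in curves]
    plateaus = [w.plateau for w in prelim if w.ok]
    if not plateaus:
        raise ValueError(f"run {run_id}: no amplifying wells")
    thr = params.threshold_fraction * float(np.median(plateaus))
    wells = [estimate_well_efficiency(c, params, threshold=thr) for c in curves]
    wtab = pd.DataFrame(
        {
            "run_id": [w.run_id for w in wells],
            "well": [w.well for w in wells],
            "sample_id": [w.sample_id for w in wells],
            "target": [w.target for w in wells],
            "efficiency": [w.efficiency for w in wells],
            "ct": [w.ct for w in wells],
            "r_squared": [w.r_squared for w in wells],
            "qc_flags": [";".join(sorted(w.qc_flags)) for w in wells],
        }
    )

    mean_eff = {
        t: float(np.mean([w.efficiency for w in wells if w.ok and w.target == t]))
        for t in ("telomere", "reference")
    }

    # replicate aggregation per sample x target
    agg: dict[tuple[str, str], tuple[float, float, int, set]] = {}
    eff_sample: dict[tuple[str, str], float] = {}
    for (sid, t), grp in wtab.groupby(["sample_id", "target"]):
        ok = grp[~grp.qc_flags.str.contains("no_amplification")]
        mean_ct, cv, n_used, flags = aggregate_replicates(
            ok["ct"].to_numpy(), params.outlier_ct_cutoff
        )
        agg[(sid, t)] = (mean_ct, cv, n_used, flags)
        eff_sample[(sid, t)] = float(ok["efficiency"].mean()) if len(ok) else float("nan")

    std = params.standard_id
    if (std, "telomere") not in agg or (std, "reference") not in agg:
        raise ValueError(f"run {run_id}: standard sample {std!r} missing")
    ct_st = agg[(std, "telomere")][0]
    ct_sc = agg[(std, "reference")][0]

    out = []
    for sid in sorted(wtab.sample_id.unique()):
        ct_t, cv_t, n_t, fl_t = agg.get((sid, "telomere"), (np.nan, np.nan, 0, {"no_amplification"}))
        ct_c, cv_c, n_c, fl_c = agg.get((sid, "reference"), (np.nan, np.nan, 0, {"no_amplification"}))
        flags = set(fl_t) | set(fl_c)
        if params.per_well_efficiency:
            e_t, e_c = eff_sample[(sid, "telomere")], eff_sample[(sid, "reference")]
        else:
            e_t, e_c = mean_eff["telomere"], mean_eff["reference"]
        if n_t == 0 or n_c == 0 or not np.isfinite(ct_t) or not np.isfinite(ct_c):
            flags.add("no_amplification")
            rtl = float("nan")
        else:
            rtl = compute_rtl(RtlInputs(e_t, e_c, ct_t, ct_st, ct_c, ct_sc))
        out.append(RtlMeasurement(sid, run_id, rtl, cv_t, cv_c, min(n_t, n_c), flags))
    return out, wtab


def quantify_curves(
    df: pd.DataFrame, params: QuantParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a long-format curve table, run by run.

    Returns (RTL table, per-well table).
    """
    meas, wtabs = [], []
    for run_id, sub in df.groupby("run_id", sort=True):
        m, w = quantify_run(curves_from_frame(sub), params)
        meas.extend(m)
        wtabs.append(w)
    rtl = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meas],
            "run_id": [m.run_id for m in meas],
            "rtl": [m.rtl for m in meas],
            "cv_telomere": [m.cv_telomere for m in meas],
            "cv_reference": [m.cv_reference for m in meas],
            "n_replicates_used": [m.n_replicates_used for m in meas],
            "qc_flags": [";".join(sorted(m.qc_flags)) for m in meas],
        }
    )
    return rtl, pd.concat(wtabs, ignore_index=True)


def rtl_from_ct_table(df: pd.DataFrame, standard_id: str = "STD") -> pd.DataFrame:
    """RTL from a pre-quantified table (sample_id, run_id, target, ct,
    efficiency) for users without raw curves."""
    out = []
    for run_id, sub in df.groupby("run_id", sort=True):
        eff = sub.groupby("target")["efficiency"].mean()
        ct = sub.set_index(["sample_id", "target"])["ct"]
        ct_st = ct[(standard_id, "telomere")]
        ct_sc = ct[(standard_id, "reference")]
        for sid in sorted(sub.sample_id.unique()):
            rtl = compute_rtl(
                RtlInputs(eff["telomere"], eff["reference"],
                          ct[(sid, "telomere")], ct_st, ct[(sid, "reference")], ct_sc)
            )
            out.append({"sample_id": sid, "run_id": run_id, "rtl": rtl})
    return pd.DataFrame(out)


def inter_run_calibration(
    run_a: pd.DataFrame, run_b: pd.DataFrame
) -> tuple[float, float]:
    """Inter-run agreement: Pearson R and OLS slope of run B on run A.

    Both inputs are RTL tables with ``sample_id`` and ``rtl``; at least
    3 shared samples are required.
    """
    merged = run_a[["sample_id", "rtl"]].merge(
        run_b[["sample_id", "rtl"]], on="sample_id", suffixes=("_a", "_b")
    ).dropna()
    if len(merged) < 3:
        raise ValueError("fewer than 3 shared samples between runs")
    x = merged["rtl_a"].to_numpy()
    y = merged["rtl_b"].to_numpy()
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1))
    return r, slope
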