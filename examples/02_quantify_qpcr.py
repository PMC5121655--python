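"""Quantify relative telomere length from raw amplification curves.

Simulates one qPCR run (triplicate telomere and reference-gene wells
per sample, fluorescence-by-cycle), then recovers per-well
efficiencies by the window-of-linearity method and computes RTL with
the efficiency-corrected ratio against the standard sample.
"""

import numpy as np

from telodyn import QpcrGenConfig, generate_qpcr_plate, quantify_run
from telodyn.qpcr import curves_from_frame

truth = {"STD": 1.0, "S01": 0.62, "S02": 0.95, "S03": 1.38, "S04": 1.80}
cfg = QpcrGenConfig(seed=7)  # efficiencies 1.9630 (telomere) / 1.9486 (reference)
curves = generate_qpcr_plate(list(truth.items()), cfg)
print(f"simulated {curves['well'].nunique()} wells x {cfg.n_cycles} cycles")

measurements, wells = quantify_run(curves_from_frame(curves))

eff = wells.groupby("target")["efficiency"].mean()
print(f"estimated run efficiencies: telomere {eff['telomere']:.4f} "
      f"(truth {cfg.efficiency_telomere}), reference {eff['reference']:.4f} "
      f"(truth {cfg.efficiency_reference})")
print()
print(f"{'sample':8} {'RTL':>7} {'truth':>7} {'CV tel %':>9} {'CV ref %':>9}")
for m in sorted(measurements, key=lambda m: m.sample_id):
    print(f"{m.sample_id:8} {m.rtl:7.3f} {truth[m.sample_id]:7.2f} "
          f"{100 * m.cv_telomere:9.3f} {100 * m.cv_reference:9.3f}")
err = [m.rtl / truth[m.sample_id] - 1 for m in measurements]
print(f"\nRMS relative error {100 * np.sqrt(np.mean(np.square(err))):.1f}% — "
      "the assay noise floor at the default noise settings.")
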