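"""Separate between- and within-animal age effects and locate the
mean-age split.

Age is decomposed into each animal's mean age (between-subject) and
the deviation from it (within-subject).  Segment models adjusted for
initial RTL are fitted separately to animals below and above each
candidate split, and the split minimising the combined residual sum of
squares is reported with both within-subject slopes.
"""

from telodyn import TrajectoryGenConfig, generate_trajectories, search_changepoint

cohort = generate_trajectories(TrajectoryGenConfig(seed=42))
res = search_changepoint(cohort, bootstrap=100, seed=1)

print(f"candidate splits evaluated: {len(res.candidate_grid)}")
print(f"best split: mean age {res.split_age:.2f} y "
      f"({res.n_young_subjects} young / {res.n_old_subjects} old animals)")
print(f"young-segment within-subject slope: {res.young_slope:+.3f} "
      f"RTL/y (SE {res.young_fit.se('delta_age'):.3f}, p {res.young_fit.p('delta_age'):.3f})")
print(f"old-segment within-subject slope:   {res.old_slope:+.3f} "
      f"RTL/y (SE {res.old_fit.se('delta_age'):.3f}, p {res.old_fit.p('delta_age'):.3f})")
print(f"RSS improvement over single model: {100 * res.rss_improvement:.1f}% "
      f"(break supported: {res.supported})")
lo, hi = (res.bootstrap_splits.min(), res.bootstrap_splits.max())
print(f"bootstrap split range (100 resamples): {lo:.2f}-{hi:.2f} y")
print()
print("A negative young slope with a positive old slope reproduces the")
print("two-regime pattern: telomere attrition early in life, elongation")
print("in animals whose mean age exceeds the split.")
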