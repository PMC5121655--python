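# telodyn

Longitudinal telomere dynamics for wild-animal field studies: from raw
qPCR fluorescence curves to relative telomere length (RTL), and from
repeated RTL measurements to within-individual attrition/elongation
rates, a mean-age change point, and the age dependence of
reproduction.

The package is built around the analysis design of long-term
capture–mark–recapture studies of the edible dormouse (*Glis glis*),
a hibernating rodent in which telomeres shorten within young animals
but *elongate* within old ones. Because such field data are rarely
deposited, `telodyn` ships a first-class synthetic-data generator
that runs the analysis models forward, so every stage of the pipeline
is testable by parameter recovery.

## What it computes

**RTL from raw qPCR curves.** Per-well amplification efficiency `E`
is estimated by the window-of-linearity method (iterative baseline
reconstruction, best-R² log-linear window of 4–6 cycles,
`E = 10^slope`); Ct is interpolated at a run-constant threshold.
Replicates are aggregated with a median-deviation outlier rule, and
RTL follows the efficiency-corrected ratio against a standard sample
(RTL ≡ 1):

```
RTL = E_T^(Ct_ST − Ct_T) / E_C^(Ct_SC − Ct_C)
```

with T/ST the telomere reactions of the target and standard samples
and C/SC the single-copy reference-gene (c-myc) reactions.

**Mixed models of RTL and RTL change.** `RTL ~ sex + age + age² +
body mass + reproductive activity + day of year` with crossed random
intercepts for animal and qPCR plate; a cubic age term is tried and
dropped when non-significant. The change model regresses `RTL_t` on
`RTL_{t−1}` (the regression-to-the-mean adjustment), the age terms
and the sampling interval. The equivalent residual-based correction
(`rtm_residual_correction`) and AICc-based random-structure
comparison are included.

**Within-subject centering and the change-point search.** Age is
split into each animal's mean age (between-subject) and the deviation
from it (within-subject). Segment models adjusted for initial RTL are
fitted separately to animals below/above every candidate mean-age
split (midpoints of consecutive distinct mean ages); the split
minimising the combined residual sum of squares yields the two
within-subject slopes.

**Reproduction.** A logistic mixed model (penalised
quasi-likelihood + Laplace likelihood, written in-package) of the
yearly probability that a female reproduces, with year and animal
random intercepts, a likelihood-ratio test for age, bias-reduced
(Firth) fallback under separation, and a Gaussian mixed-model test of
litter size against age.

## Worked example

```python
from telodyn import TrajectoryGenConfig, generate_trajectories, search_changepoint

cohort = generate_trajectories(TrajectoryGenConfig(seed=42))   # 49 animals, 143 captures
res = search_changepoint(cohort, bootstrap=100, seed=1)
print(res.split_age, res.young_slope, res.old_slope)
```

Running `python examples/04_changepoint.py` (the same computation,
annotated) prints:

```
candidate splits evaluated: 40
best split: mean age 5.37 y (42 young / 7 old animals)
young-segment within-subject slope: -0.046 RTL/y (SE 0.050, p 0.357)
old-segment within-subject slope:   +0.488 RTL/y (SE 0.075, p 0.000)
RSS improvement over single model: 21.9% (break supported: True)
```

The split near 5.3 years and the sign pattern (attrition in young
animals, significant elongation in old ones) is the generator's
configured truth re-discovered by the estimation pipeline; single
cohorts of 49 animals scatter around the generating slopes of −0.097
and +0.410 RTL/year. `examples/` contains one such narrative script
per capability (cohort generation, qPCR quantification, mixed models,
change point, reproduction), and the `telodyn` CLI (`generate`,
`quantify`, `model`, `changepoint`, `reproduction`, `run-all`) runs
the same stages as a seeded pipeline writing CSV/JSON outputs plus a
hash manifest.

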