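# coda24

Compositional analysis of 24-hour time use — sitting, standing, light
physical activity (LPA), moderate-to-vigorous physical activity (MVPA) and
sleeping — against cardiometabolic and glycaemic risk markers, for
epidemiologists working with posture-sensing activity monitor (e.g.
activPAL) data.

A day is a *composition*: five strictly positive durations that always sum
to 1440 min, so only their relative sizes carry information. The package
implements the full compositional-data-analysis (CoDA) workflow around that
constraint:

* **ilr pivot coordinates.** A five-part composition **x** maps to four
  isometric log-ratio coordinates; the first contrasts a lead behaviour
  against the geometric mean of the rest:

  ```
  ilr1 = sqrt(4/5) * ln( sitting / (standing * LPA * MVPA * sleeping)^(1/4) )
  ```

  Reordering which behaviour leads (the *permutation principle*) rotates
  the coordinates but leaves every fit and prediction unchanged.
* **Outcome construction.** Six analysis outcomes as z-scores: waist
  circumference; fasting plasma glucose (FPG), 2-h post-load glucose and
  HbA1c on the natural-log scale; the Matsuda insulin-sensitivity index
  `ISI-M = 10000 / sqrt(FPG * FPI * meanG * meanI)`; and a clustered
  cardiometabolic risk score `CMR = (z(waist) + z(ln FPG) + z(ln TG)
  - z(ln HDL) + z(meanBP)) / 5`. Glycaemic status (NGM / IGM / T2D) follows
  the WHO 2006 OGTT cut-points with a medication override.
* **Compositional regression.** OLS of each outcome on the four ilr
  coordinates plus covariates (age, sex, education, smoking, diet score,
  diabetes status), with stratified fits and composition-by-stratum
  interaction F-tests.
* **Isotemporal substitution.** The predicted outcome difference when 30 min
  move from one behaviour to another, starting at the sample's compositional
  geometric mean, with t-based confidence intervals.
* **Optimal-zone grid search.** Every 10-min-lattice composition inside the
  empirical footprint (1st–99th percentile band per behaviour) is scored by
  the fitted model; the best 5% (direction-aware) form each outcome's
  optimal zone, and their cross-outcome intersection — escalated towards the
  top 10% when needed — is the overlapping optimal zone, summarised by its
  compositional centre and ranges and exportable as tetrahedron coordinates.
* **Synthetic cohort.** Because the motivating cohort is private, a
  generator draws a fully synthetic three-stratum population (logistic-normal
  compositions, realistic covariates and raw marker panels) with a recorded
  ground truth, so every stage is testable end to end.
* **Wear-day aggregation.** Day-level monitor summaries are screened (first
  day dropped, short last day dropped, ≥14 h waking required), stepping is
  split at 100 steps/min into LPA/MVPA, and valid days average into one
  daily composition per participant.

## Worked example

```python
import coda24 as c
from coda24.composition import minutes_to_hmm

table, truth = c.generate_cohort(seed=1)          # synthetic 2388-row cohort
bundle = c.analyse(table, c.PipelineOptions(footprint=c.MAASTRICHT_FOOTPRINT))

sub = bundle.substitutions.query(
    "outcome == 'waist' and stratum == 'overall' and `from` == 'sitting'")
for r in sub.itertuples():
    print(f"30 min sitting -> {r.to:9s}: {r.estimate:+.3f} z "
          f"[{r.ci_low:+.3f}, {r.ci_high:+.3f}]")

zone = bundle.zones.overlap
print(f"overlap at top {bundle.zones.overlap_fraction:.0%}, centre:")
for part, m in zip(c.PARTS, zone.centre_rounded):
    print(f"  {part:9s} {minutes_to_hmm(m)}")
```

prints

```
30 min sitting -> standing : -0.034 z [-0.048, -0.020]
30 min sitting -> lpa      : -0.006 z [-0.041, +0.028]
30 min sitting -> mvpa     : -0.077 z [-0.104, -0.050]
30 min sitting -> sleeping : +0.005 z [-0.015, +0.025]
overlap at top 5%, centre:
  sitting   6:00
  standing  7:20
  lpa       2:20
  mvpa      1:40
  sleeping  6:50
```

Reading: replacing 30 min of sitting with MVPA is associated with a 0.077 SD
lower waist circumference in this synthetic cohort; the compositions in the
best 5% for *all six* outcomes simultaneously centre on roughly 6 h sitting
and 4 h of physical activity. The magnitudes reflect the synthetic
generator's effect sizes, not estimates for any real population.

The same pipeline is scriptable from the shell:

```sh
coda24 simulate --seed 1 --out-dir data/
coda24 run --participants data/participants.csv --out-dir reports/
```

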