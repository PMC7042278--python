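# floodring

Dendroecology of flood-pulse forests: a tested, reusable pipeline for
cross-dated ring-width chronologies, climate–growth correlation, sigmoidal
age–diameter growth modelling, population age-structure reconstruction and
flood-duration estimation from river-gauge records.

The package targets studies of monodominant floodplain stands (its built-in
synthetic study emulates an *Erythrina fusca* population on the Paraguay
River floodplain): a few dozen trees are cored or felled, their annual rings
measured at 0.01 mm, cross-dated into a master chronology, correlated with
monthly climate and ENSO indices, and used to fit a growth model that
converts the diameters of a whole plot inventory into ages — which, combined
with per-plot flood durations derived from water marks and a daily gauge
record, lets one ask whether recruitment tracks the flood pulse.

## Methods at a glance

* **Cross-dating** — Gleichläufigkeit (GLK, the % of year-to-year intervals
  in which two series move in the same direction, with the classical ½-score
  for one-sided ties) and the Baillie–Pilcher t-value
  `t = r·√((n−2)/(1−r²))`, where r is the Pearson correlation of 5-year
  moving-average-indexed, log-transformed overlapping segments. Series are
  admitted to the chronology by iterative leave-one-out rejection against
  the mean of the others (defaults GLK ≥ 60, t ≥ 2.0).
* **Chronology** — growth index = ring width / centred 5-year moving average
  (shrinking windows at the edges); unweighted mean across trees with
  per-year sample depth; mean sensitivity
  `MS = mean |2(xᵢ−xᵢ₋₁)/(xᵢ+xᵢ₋₁)|`, flagged "high" above 0.40.
* **Climate–growth correlation** — Pearson r of the chronology against each
  (variable, month) cell over a 24-month window from October(−1) to
  September(+1); two-sided significance via
  `r_crit = t_crit/√(n−2+t_crit²)` at α = 0.05, no multiple-testing
  correction (a deliberate, documented per-cell screen).
* **Growth model** — `DBH(age) = β₀ / (1 + (β₁/age)^β₂)` fitted by nonlinear
  least squares to the mean cumulative diameter curve (curves rescaled
  proportionally to field DBH), inverted in closed form
  `age = β₁/(β₀/DBH − 1)^{1/β₂}`; tree height as `H = a·DBH/(b+DBH)`.
* **Population structure** — DBH classes by Sturges' rule
  `K = round(1 + 3.3·log₁₀N)` with equal width `(max−min)/K`; recruitment
  compared between flood categories with a Pearson chi-square; environmental
  history across establishment cohorts with one-way ANOVA + Tukey HSD.
* **Flooding** — plot elevation = annual gauge maximum − water mark
  (flat-terrain assumption); flood duration = mean days/year the gauge
  exceeds that elevation over a 10-year window; plots split at the midpoint
  of the observed gradient; annual-minima change tested with Welch's t.

## Worked example

Simulate the default synthetic study (34-year chronology, 36 trees, 153-tree
inventory in 24 plots spanning a 42–117 days/yr flood gradient) and run
every stage:

```python
from floodring import SimConfig, run_synthetic_study

report = run_synthetic_study(SimConfig(seed=1))
print(report["crossdating"]["n_admitted"])                      # 32
print(round(report["chronology"]["mean_sensitivity_series_mean"], 3))  # 0.443
print(round(report["growth_model"]["beta0_cm"], 1))             # 76.6
print(round(report["flooding"]["chi2"], 2))                     # 19.01
```

Reading the numbers: 32 of the 36 simulated series pass the GLK/t admission
thresholds; the admitted series have a mean sensitivity of 0.443 (above the
0.40 "high" convention, as designed); the fitted asymptotic DBH β₀ is
76.6 cm against a planted truth of 80 cm (the chronology only reaches
cambial age 34, well short of the asymptote); and the category × class
chi-square of 19.01 (p = 0.008) detects the recruitment deficit planted in
the short-flood plots. The correlation screen recovers the planted climate
signals: December(−1) precipitation r = +0.67 and Niño 1+2 / Niño 3
January–February r ≈ −0.47 to −0.48, all beyond the r_crit(34) = 0.339
significance line.

The same run is available from the shell:

```bash
floodring simulate --seed 1 --outdir study    # RWL + CSV inputs + truth.json
floodring crossdate study/rings.rwl           # admission report
floodring run-all config.yaml                 # full report.json bundle
```

where `config.yaml` can be as small as `{mode: synthetic, sim: {seed: 1}}`.

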