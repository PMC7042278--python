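# Methods

This note documents the models, numerical choices and known limitations of
the package, and what its synthetic study does and does not demonstrate.

## Ring calendar and data model

A ring is labelled by the calendar year in which its growth season starts
(the season starts around October; wood formation begins December–January).
Ring widths are radial increments in mm at 0.01 mm resolution; `RingSeries`
carries the first measured year, an optional pith offset (estimated count of
unmeasured innermost rings) and the sampling method (stem disc vs core).
The Tucson/RWL reader accepts both common dialects (sentinel 999 → 0.01 mm,
−9999 → 0.001 mm) and the writer emits the 0.01 mm dialect, matching the
measuring-bench precision the data model assumes.

## Cross-dating

GLK scores each year-to-year interval 1 if both series move in the same
direction, 0 if opposite, ½ if exactly one is unchanged (Eckstein–Bauch
convention; both-unchanged counts as agreement). The t-value follows the
Baillie–Pilcher recipe: each series is indexed by its centred 5-year moving
average, log-transformed, and the Pearson r of the aligned overlap converted
to Student-t; t is capped at ±100 as r → 1, and zero variance raises rather
than returning a silent value.

Admission to the chronology uses iterative leave-one-out rejection: each
series is scored (GLK and t) against the mean index chronology of the
others; while any series falls below the thresholds the worst offender is
dropped and scores recomputed. Defaults GLK ≥ 60 %, t ≥ 2.0, minimum
overlap 10 years — conventional working values, exposed as configuration
because the classical literature fixes no universal cut-offs. The lag
search ranks shifts by GLK with t as tie-break, then deterministically
toward smaller |lag| (the more negative lag among equal magnitudes).
Missing inner rings are estimated as round-half-up(pith distance / mean of
the 5 innermost widths); the divisor count is configurable.

## Chronology and sensitivity

Indexing divides each width by its centred 5-year moving average; at the
series edges the window shrinks (3- and 4-term means) so no years are lost —
a truncating rule is available by option. The chronology is the unweighted
per-year arithmetic mean of the available indices (Tukey biweight offered,
off by default), with sample depth recorded per year. Mean sensitivity is
reported both for the mean chronology and as the average over raw series;
the "high" flag uses the conventional 0.40 threshold. MDI (mean diameter
increment) is twice the mean radial width.

## Climate–growth screen

Ring year t is paired with climate months over a 24-month window
October(t−1) … September(t+1). Each (variable, month) cell gets the Pearson
r over the overlapping years and a two-sided significance flag from the
critical value r_crit = t_crit/√(n−2+t_crit²) at α = 0.05
(r_crit ≈ 0.339 at n = 34). No multiple-testing correction is applied: the
screen is intentionally per-cell and therefore liberal — with ~200 cells,
roughly ten false positives are expected under the null, which is why the
synthetic-study tests judge the screen by the planted cells and by its
aggregate false-positive rate, not by individual unplanted cells.

A known artefact of moving-average detrending: the index of year t carries
a small negative weight on its neighbours, so a signal planted in year t±1
leaks into year t cells with opposite sign. On the default study this can
push a few off-target ENSO cells past the significance line; the planted
cells dominate in magnitude.

## Growth model

Cumulative diameter at cambial age a is twice the running sum of radial
widths, rescaled multiplicatively so the final value equals the field DBH
(this absorbs bark thickness and off-centre pith bias; an additive rule was
rejected because it can produce negative early diameters). Ages are offset
by the pith offset. The sigmoid DBH = β₀/(1+(β₁/age)^β₂) is fitted by
Levenberg–Marquardt-style least squares (scipy curve_fit, positive bounds)
to the per-age mean curve by default (pooled-point fitting available);
initialisation β₀ ← 1.2·max DBH, β₁ ← age whose mean DBH is nearest β₀/2,
β₂ ← 1. Both r² values (mean-curve and pooled) are reported because the two
can differ substantially and either may be the quantity a reader wants.
The increment maximum is located on a 0.01-year grid of the analytic
derivative with first-index (smallest-age) tie-break; for β₂ ≤ 1 the
increment is monotone decreasing and the boundary result is flagged.
Inversion is exact: age = β₁/(β₀/DBH−1)^{1/β₂}, undefined at DBH ≥ β₀;
inventory records above the fitted asymptote are flagged and assigned the
age of the oldest invertible DBH rather than dropped.

The height model H = a·DBH/(b+DBH) is a saturating hyperbola — the
literature this pipeline follows cites a non-linear DBH–height fit without
printing its equation, so the simplest two-parameter saturating form is
adopted and made swappable.

## Population structure and flooding

Sturges' count K = 1 + 3.3·log₁₀N is rounded half-up (N = 153 → K = 8);
classes are half-open [lo, hi) except the last, closed at the maximum, so
counts always partition N. Class → establishment-year spans invert the
class DBH boundaries through the growth model (boundaries at/above the
asymptote clamped just below it). The chi-square on the category × class
table pools classes with expected count < 1 into their neighbour (logged).
ANOVA/Tukey compares annual maximum flood level, minimum flood level and
total precipitation across the first five cohorts (each required to hold
more than five trees); grouping letters use a compact-letter-display
insertion algorithm. The CBH ≥ 15 cm inclusion rule is applied before
classing; for bifurcated stems the convention is one record per tree with
the largest stem's DBH.

Plot elevation = survey-year gauge maximum − mean water mark, under the
stated flat-terrain, no-tributary assumption. Flood days count gauge
readings above plot elevation over the 10 years preceding the survey; gaps
of ≤ 5 days are linearly interpolated, longer gaps are removed from the
denominator and the count rescaled to a full year. The category boundary is
the midpoint of [min, max] flood days, boundary plots joining the lower
category. The annual-minima change uses Welch's t (the comparison in the
emulated design is 26 vs 9 years; no specific test is canonical, so the
variance-robust choice is made).

## Synthetic study: what is emulated, and what is not

The generator plants known truth at the emulated field design: a 1981–2014
chronology of 36 trees (7 discs, 29 cores, germination skewed early so the
window is fully spanned), a 153-tree inventory in 24 plots of 250 m²
(0.6 ha) across a 42–117 days/yr flood gradient, monthly climate from 1968
and a daily monomodal flood pulse.

* Climate: Niño indices load on a shared AR(1) ENSO factor (φ = 0.7
  monthly; SOI loads negatively, PDO is independent and slow);
  precipitation is a Pantanal-like seasonal profile × lognormal noise,
  reduced in proportion to the positive part of the ENSO factor, so El Niño
  years are dry.
* Rings: expected radial width = growth-model annual increment ×
  exp(b_precip·z_Dec(−1) + b_enso·z_JanFeb + b_flood·z_wet) × lognormal
  noise. Defaults b_precip = +0.22, b_enso = −0.18, b_flood = 0,
  noise σ = 0.30. These effect sizes were set, together with the noise, so
  that (i) series mean sensitivity lands in the "high" regime (~0.44–0.48)
  that motivates climate work on such stands, (ii) nearly all series pass
  the admission thresholds, and (iii) the planted cells clear the n = 34
  significance line with comfortable power. b_flood = 0 encodes the
  emulated finding that growth is climate- not flood-driven.
* Growth truth: β₀ = 80 cm, β₁ = 20 yr, β₂ = 1.8 — a fast floodplain
  pioneer reaching ~58 cm DBH by age 34 with maximum diameter increment
  ~2.5 cm/yr around age 10.
* Population: standing-cohort ages follow steady recruitment thinned by
  exponential survivorship (e-folding 15 yr, maximum age 54); trees
  established in the final 9 years join short-flood plots with probability
  downweighted by the decline factor 0.10 — a spatial reallocation at fixed
  N, sized by a design simulation to give the category × class chi-square
  ≈ 90 % power at α = 0.05 (and ≈ 5 % rejection with the factor at 1).
  DBH adds 1 cm Gaussian noise and the CBH-15 cm threshold filter.
* Gauge: sinusoidal pulse (base 250 cm, amplitude 160 cm, peak ~1 March)
  plus AR(1) noise; after 2007 the low-water trough is lowered by 60 cm,
  planting the annual-minima decline.

Every generator draws from a named substream of the seed, so outputs are
bit-identical per seed and independent of call order.

Not emulated: false/wedging rings and locally absent rings (pith offsets
are the only dating defect), spatial autocorrelation between neighbouring
trees, hydraulic routing between gauge and plots, bark growth, mortality
dynamics, and observation error in water marks. Passing tests therefore
demonstrate that the statistical machinery recovers known structure under
the stated noise model — not that the machinery is robust to every field
pathology.

## Problem sizes and tolerances

Oracle-equivalence tests use ≥ 1000 random small instances per statistic;
growth-model recovery uses noiseless exactness to 0.1 % and 100 noisy
replicates (σ = 5 % of β₀, n = 200 points, median relative bias < 2 %);
the correlation screen's false-positive rate is measured over 1000 null
replicates, and the recruitment chi-square over 500 replicate populations
each for the planted and null cases. Mutual-inverse identities are held to
1e−9 relative tolerance; the increment-curve grid step is 0.01 yr against
a 0.001 yr brute-force check.
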