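# Methods

## Measurement model

The plate reports one frame per sampling tick: eight kilogram-equivalent
readings, one per load cell, keyed by (foot, fore/rear half,
medial/lateral side). All analog conditioning (amplification, ADC,
voltage→kg conversion) is assumed to have happened upstream; the only
place voltage appears in this package is the calibration fit, which
regresses known weights on sensor voltage by ordinary least squares and
reports R² = 1 − SSres/SStot.

A *measurement* is the per-cell mean of a window of tare-corrected frames
(default 50 frames, mirroring 50-repeat bench stability testing; the
window is configurable because real firmware averaging intervals vary).
Tare offsets are per-cell means over empty-plate frames; the residual
noise is the pooled per-cell sample SD, and taring fails when it exceeds
a tolerance (default 0.1 kg) — the start-up self-check. Readings down to
−0.05 kg after taring are clipped to zero (normal tare over-subtraction);
anything lower is rejected as a fault rather than silently clipped.

Quadrants are the sum of their two cells; this cell→quadrant mapping
(medial + lateral of the same foot-half) is the only one consistent with
two sensors under each corner of each foot. Aggregates are sums of two
quadrants, so the three conservation identities hold by construction and
are verified to 1e−9 relative tolerance throughout the tests (observed
worst case ≈ 4e−16, i.e. float64 rounding only).

## Percentage scales

`compute_percentages` expresses every region as percent of total body
weight, so quadrants sum to 100 and each aggregate pair (left+right,
toes+heel) sums to 100. The shipped population threshold table, however,
is printed on the device's *chart scale*: each of the eight displayed
regions normalized by the sum over all eight region weights. That sum is
three times body weight (each cell appears in one quadrant and two
aggregates), so the chart scale is exactly the body-weight percentage
divided by three, and the printed grid sums to ~100 as a whole. On this
scale the printed setpoints are physiologically sensible — heel 20.2
corresponds to 60.6% of body weight on the heels, left 16.8 to 50.4% on
the left foot. `to_chart_scale` performs the conversion and the
`screen_frames` pipeline applies it before classification. Derived tables
carry whatever scale their input averages were on; callers must keep
table and observation scales consistent.

The printed table ships verbatim rather than being recomputed from the
quadrant setpoints: its aggregate rows were averaged independently and
display-rounded, which is why toes prints 13.1 while its quadrants sum to
12.8. Derived tables are self-consistent (setpoint always the midpoint of
its bounds). Display rounding is one decimal place for kg and percent;
full precision is kept internally.

## Screening algorithm

Margins are percentage *points* on the table's scale — ±1.5 pp for
quadrant regions, ±3 pp for aggregates; only this reading reproduces the
printed bounds (9.8 ± 1.5 → 8.3/11.3). Bounds are warning-inclusive
(≥ upper → red, ≤ lower → blue) per the printed ≥/≤ rules; green is the
open interval. The "two cells on the same side" rule is carried by the
aggregate regions themselves — an aggregate is the sum of its two
quadrants and its ±3 pp band encodes the two-cell condition, so no
separate conjunction test exists.

Point scoring: 1 per red/blue quadrant, 2 per red/blue aggregate
(maximum 12 per color). Level precedence is above > below > average: the
printed level rules overlap (a report can satisfy both "blue > 2" and
"red < 2 or blue ≤ 2"), so a fixed precedence is required; putting
overload first is the conservative triage choice and is exercised by an
exhaustive truth-table test over all point pairs.

## Synthetic data

The subject generator emulates a static standing subject: quadrant load
= total_weight × share + drift × t, split medial/lateral by a fixed
fraction (default 0.5), plus i.i.d. Gaussian noise per cell per frame
(default SD 0.05 kg, in the 0.1–1 kg device-deviation range after
window averaging). Drift is linear (sensor creep or slow sway); the
default frame interval is 20 ms. Default shares are the population
quadrant setpoints renormalized. What it does **not** emulate: dynamic
sway spectra, center-of-pressure trajectories, cell cross-talk,
temperature drift, or foot-placement error — passing tests demonstrate
the arithmetic and screening logic, not robustness to those real-world
effects.

The cohort generator draws arch types from a categorical distribution
(defaults 31% high / 54% medium / 15% low — the medium frequency being
the complement of the two reported classes), heights and weights from a
correlated bivariate normal (170 ± 8 cm, 65 ± 10 kg, ρ = 0.5 — typical
young-adult anthropometry), plantar pressures from linear models on
weight and height plus Gaussian noise (means 45/55 kPa, slopes chosen to
give weak correlations of magnitude ≈ 0.1–0.2 — no population pressure
means are available, so these are free choices fixed once), and per-bag
torso/pelvis posture shifts from a bivariate normal built by the latent
construction pelvis_z = ρ·torso_z + √(1−ρ²)·ε (defaults ρ = 0.82
backpack, 0.49 tote, 0.94 sling; shifts in abstract chart units,
mean 4/3, SD 2). One global integer seed fans out to per-component
generators keyed by a CRC of the component name, so adding a component
never perturbs another's stream.

## Statistics

Repeatability is the sample SD (n−1). The unpaired comparison defaults to
Welch's t (no equal-variance assumption is defensible across different
scanners); paired data uses the paired t, and a paired arm with
zero-variance differences is reported as degenerate rather than as an
infinite statistic. Association is Pearson's r with the OLS line of y on
x; no rank alternative and no multiple-testing correction are offered,
matching the analysis style the screening targets. Significance is
flagged at 0.05.

## Numerical and testing choices

Stochastic tests assert against bounds computed analytically in advance
and frozen: exact binomial 99% intervals for class counts at n = 1034,
the χ²(49) 99% interval for a sample SD at n = 50, and Fisher-z ±4·SE
bands for the mean correlation of 200 replicates at n = 54. Problem
sizes (10,000 conservation frames, 500-frame CLT checks, 200-replicate
correlation means) keep the whole suite under a few seconds on one core
while leaving the Monte-Carlo bounds comfortably tight.

## Limitations

The screening is a triage aid, not a diagnosis; thresholds derive from a
single population average and the shipped table inherits its printing
artifacts. The session store is a local append-only JSONL file with no
concurrency control. The simulator's Gaussian/linear structure is the
simplest model consistent with the stated conditions; none of the
package's validation statistics on synthetic cohorts say anything about
a physical device beyond the correctness of the computations.
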