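# enp — eight-cell balance-plate screening toolkit

`enp` implements the software side of a point-of-care body-balance
screening plate: a bathroom-scale-like platform with **eight load cells**,
two under each quadrant of the stance (left/right foot × fore/rear half,
medial + lateral). It is aimed at people building or validating such
devices — and at anyone who needs a fully synthetic, hardware-free test
bed for plantar-load screening pipelines: every stage from raw frames to
color-coded reports can be driven by the built-in simulator.

## The model

A validated frame assigns a weight `w_c ≥ 0` (kg) to each cell `c`. Cells
aggregate into four **quadrants** (L.toe, R.toe, L.heel, R.heel — the two
cells sharing a foot and a fore/rear half) and four **aggregates**
(Left, Right, Toes, Heel — sums of two quadrants), with the conservation
identities

```
Left + Right = Toes + Heel = ΣL.toe + L.heel + R.toe + R.heel = Total
```

Screening compares each region's body-weight share against a population
**setpoint** with a symmetric warning band: ±1.5 percentage points for
quadrants, ±3 for aggregates. Shares at/above the upper bound code **red**
(overload), at/below the lower bound **blue** (underload), strictly inside
**green**. Red warnings score 1 point per quadrant and 2 per aggregate
(blue likewise), and the totals set the overall level:
`red ≥ 2 → above-average`, else `blue > 2 → below-average`, else
`average`.

The shipped population table lives on the device's *chart scale*, where
each of the eight displayed regions is normalized by the sum over all
eight (three times body weight, since every cell feeds one quadrant and
two aggregates); `enp.to_chart_scale` converts body-weight percentages to
it, and the grid's setpoints sum to ~100 as a whole.

Alongside the screening core the package provides tare self-calibration,
voltage→kg calibration fits (OLS with R²), repeatability SD and Welch/
paired *t* comparisons for device validation, a synthetic cohort generator
(foot-arch classes, plantar pressures, correlated torso/pelvis posture
shifts per bag type) with Pearson/OLS analytics, and a JSONL session
store with longitudinal trend summaries.

## Worked example

Simulate a 77.7 kg subject leaning onto the left heel, then screen:

```bash
enp simulate --frames 50 --seed 42 --weight 77.7 --noise-sd 0.1 \
    --shares '{"L.toe":0.20,"R.toe":0.16,"L.heel":0.40,"R.heel":0.24}' \
    --out lean.csv
enp screen lean.csv --format text
```

```
Total weight: 77.7 kg
region    share %  color
L.toe         6.7  green
toes         12.0  green
R.toe         5.3  green
left         20.0  red
right        13.3  blue
L.heel       13.3  red
heel         21.3  green
R.heel        8.0  blue
Red points: 3  Blue points: 3
Level: above-average
warning: left share 20.0% at or above upper bound 19.8% (overload)
warning: right share 13.3% at or below lower bound 13.5% (underload)
warning: L.heel share 13.3% at or above upper bound 11.6% (overload)
warning: R.heel share 8.0% at or below lower bound 8.3% (underload)
```

The subject puts 60% of body weight on the left foot, so on the chart
scale the left aggregate (20.0) breaches its 19.8 upper bound and the
right (13.3) its 13.5 lower bound; the left heel quadrant overloads and
the right heel underloads. Red points 2+1 = 3 ≥ 2 set the overall level
to above-average — the left-lean early-warning pattern. A balanced
subject (default shares) screens all-green at level `average`.

Other verbs: `enp cohort` / `enp cohort-stats` (synthetic study tables
and their frequencies/correlations), `enp validate` (repeatability SD and
reference-scale *t* comparison), `enp thresholds show|derive`,
`enp trend` (longitudinal per-region deltas from a `--store` JSONL file).
Exit codes: 0 ok, 1 usage, 2 data error, 3 calibration failure.

## File formats

* **Frames CSV** — long (`timestamp,foot,region,side,kg`) or wide
  (`timestamp,L_fore_med,…,R_rear_lat`); the reader auto-detects by
  header.
* **Threshold table / tare model / calibration fit / screening report** —
  versioned JSON (`schema_version` field).
* **Session store** — line-delimited JSON, one session per line.
* **Cohort table** — CSV with columns `id, age, height_cm, weight_kg,
  shoe_size, arch_type, forefoot_kpa, rearfoot_kpa,
  torso_shift_<bag>, pelvis_shift_<bag>`.

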