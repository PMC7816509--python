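# Methods

## Scope and model

`netrd` computes a single resistance-to-damage (RD) score for a bed-net
fabric from four laboratory textile tests, on the premise that a net whose
measured strengths exceed the forces a human user can physically exert on
it will resist hole formation during normal household use. Two scoring
algorithms are provided (continuous proximity-to-target, and a tiered KPI
score matrix), together with the WHO proportionate hole index (PHI) used
to grade retrieved field nets, the force/pressure arithmetic behind the
aspirational targets, and the association statistics linking lab RD to
field PHI.

## Method 1: proximity to aspirational values

Each strength parameter contributes `λ/η · 25` points, where η is the
aspirational target, plus a quarter of the 0–100 hole-enlargement score
σ_H. Defaults (overridable via a JSON config):

| parameter | symbol | aspirational default | rationale |
|---|---|---|---|
| bursting strength | η_B | 700 kPa | upper-limit explosive pull (~500 N) over the 7.3 cm² burst diaphragm is 685 kPa; rounded up as a safety margin for smaller contact areas |
| snag strength | η_S | 200 N | above the maximum most users in the target populations can exert in an underhand pull |
| abrasion resistance | η_A | 400 rubs | scaled down from the 1000-rub pass level used for much heavier woven fabrics |
| hole enlargement | σ_H max | 100 | final hole ≤ 5 mm (the WHO recording threshold) with no secondary damage |

σ_H is a base score per final-hole-size band (≤5 mm: 100, 6–20 mm: 80,
>20 mm: 40) times a damage multiplier (none 1.0, laddering 0.8,
unravelling 0.5, tearing combined with either 0.4); the products
reproduce the full published 4×3 grid. Totals are deliberately not
clamped: exceeding a target scores above 100, which rewards
over-engineered products.

## Method 2: KPI score matrix

Strength values are binned into tiers. Bursting and snag have 11 tiers
(scores 1, 2.5, …, 25) with lower edges every 50 kPa from 250 and every
20 N from 20 respectively; abrasion has 9 tiers (scores 1, 3, 6, 9, 13,
16, 19, 22, 25) with lower edges 25, 75, 125, 175, 250, 300, 350, 400.
The hole term is σ_H ∈ {25, 20, 10} by size band, minus the penalty
ρ_H = penalty(damage) · σ_H / 100 with penalties {laddering 10,
unravelling 20, tearing-combined 30, none 0}. The attainable range is
[10, 100].

Numerical conventions where the published tier tables are ambiguous:

- Tiers are contiguous half-open intervals `[edge, next edge)`; printed
  integer ranges like 250–299 extend naturally to real-valued inputs.
- The abrasion row is published with gaps (e.g. 50–75): a value falling
  in a gap takes the score of the tier below it (greatest lower bound),
  the only gap-free monotone reading.
- Hole-size bands are ≤5 mm, (5, 20], >20 mm under both methods,
  consistent with the WHO 5 mm recording threshold.
- Scores are carried at full precision; the report writer rounds RD to
  1 dp and hole indices to integers.

Both methods accept one summary value per net and parameter; replicate
aggregation (e.g. a 15-specimen abrasion protocol) is the caller's
responsibility upstream.

## WHO hole index

PHI is the weighted hole count H_i = 1·N₁ + 23·N₂ + 196·N₃ + 576·N₄ over
the four WHO size bands (assumed radii 0.625, 3, 8.75 and 15 cm). Weights
are the squared ratios of band radii to the size-1 radius, rounded to the
nearest integer — sizes 3 and 4 are exactly 14² and 24², size 2 rounds
from 23.04. The alternative convention of dividing rounded band areas by
the rounded size-1 area (1.23 cm²) gives 574.8 → 575 for size 4 and is
rejected: only the exact-ratio rule reproduces all four published weights.
Band areas are reported with the reference value π = 3.142 by default
(reproducing the published 1.23, 28.28, 240.56, 706.95 cm²); exact π is a
config switch affecting reported areas only, never weights. Raw diameters
classify into half-open bands [0.5, 2], (2, 10], (10, 25], (25, ∞) cm so
every recordable hole lands in exactly one band; the published ranges
leave 2–2.5 cm unassigned and this convention closes the gap. Brand-level
PHI is the arithmetic mean of per-net indices (the aggregation level is
otherwise unspecified in the WHO guidance used here).

## Human-factors constants and conversions

The packaged tables carry maximal isometric limb forces (EN 1005-3:2002,
professional and domestic populations), explosive under/overhand pulling
force ranges for adults aged 21–60, and mean adult body weights in
malaria-endemic countries. `force_to_pressure` implements
p [kPa] = F [N] / (A [cm²]·10⁻⁴) / 1000 and returns full precision; the
published worked values mix rounding conventions (274 and 685 round,
421 and 843 truncate), so comparisons are made at ±1 kPa.

## Association statistics

Lab-vs-field association is the squared Pearson correlation of raw
(RD, PHI) pairs — no transform is applied — with the two-sided t test on
n − 2 degrees of freedom and the ordinary-least-squares line of PHI on
RD (for simple regression the slope test is identical to the correlation
test). At least 3 pairs are required and constant series are rejected.
Between-method agreement adds the Spearman rank correlation, since
procurement decisions rest on product ranking. Excluding non-mechanical
field damage (cuts, seam failure, rodents, burns) from PHI is the
caller's responsibility; the module never filters.

## Synthetic data generator

No public dataset pairs per-net lab values with field censuses, so the
generator defines the study conditions for all statistical tests:

- Panels default to 16 products with strengths uniform over ranges that
  span every score-matrix tier (bursting 100–900 kPa, snag 10–250 N,
  abrasion 10–450 rubs), hole-outcome cells drawn with probabilities
  (≤5 mm: 0.35, 6–20 mm: 0.40, >20 mm: 0.25) × (none 0.35, laddering
  0.30, unravelling 0.20, tearing-combined 0.15) — chosen once as a
  plausible spread for a mixed procurement panel.
- Field data follow E[H_i] = max(0, 900 − 8·RD₁) plus Gaussian noise
  (default sd 60): a mid-panel net at RD 50 expects an index of 500, an
  aspirational net near 100, matching the direction and rough magnitude
  of the lab-field link. Negative targets clip to zero.
- Each target index is realized as a band census by greedy decomposition
  (largest weight first, remainder as size-1 holes), exact for integer
  targets and within one weight unit of any real target; small holes
  dominate the count, as in retrieved nets.
- One `numpy.random.Generator` drives everything; the field draw uses
  seed + 1 so lab and field noise are independent but jointly
  reproducible.

What the generator does **not** emulate: damage accumulation over time,
attrition/survivorship, brand-level clustering of fabric properties,
measurement error on the lab tests, and non-mechanical damage. Passing
tests therefore demonstrate the correctness and statistical behaviour of
the scoring and association machinery under a known link — not that any
particular real-world lab-field correlation holds.

## Problem sizes and checks

The test and acceptance runs use a 16-net panel for between-method rank
agreement (Spearman ≥ 0.9), n = 200 for recovery of a known generating
r² = 0.8 (tolerance ±0.08, the Monte-Carlo spread of r̂² at that size),
and 100 replicates at n = 200 for slope-recovery bias (< 15%; zero-
clipping of PHI attenuates the slope slightly). All quantities printed by
the acceptance script are computed at run time from these conditions.

## Known limitations

- The tier-edge and band-boundary conventions above are choices where the
  published tables are ambiguous; alternative readings would change
  scores only for values landing exactly in gaps or on edges.
- Method 2 is coarse by design: products differing within one tier score
  identically.
- The force tables are reference constants for populations studied under
  lab conditions; they bound, rather than measure, field forces.
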