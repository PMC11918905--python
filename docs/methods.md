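# Methods

## Data model and inclusion

A panel cohort holds Likert item scores for 62 items — 30 IDS (0–3),
21 BAI (0–3), 11 PSWQ (0–4) — at up to five assessment waves (years 0, 2,
4, 6, 9), per-wave anxiety-disorder (AD) and major-depressive-disorder
(MDD) diagnosis flags (the wave-0 flag encodes lifetime diagnosis before
baseline), and participant covariates: age in years, sex (0/1), education
(ordinal 0/1/2).

A wave is *complete* only when all 62 items are present. Participants are
retained only with ≥ 4 complete waves; incomplete waves of retained
participants are dropped wholly, never imputed. Standardization happens
after exclusion, on the analyzed sample: each item is z-scored with its
mean and sample SD (n−1 denominator) pooled over all retained participants
and complete waves. Items with zero pooled SD map to z = 0 and are
flagged, not dropped, so all downstream distances stay defined.
Per-participant raw item means — the severity covariates used later — are
computed before standardization.

## DTW distances

For one participant, an item pair gives two aligned series of length
T ∈ {4, 5} (their complete waves; waves are treated as ordinal steps, the
calendar spacing is metadata only). The local cost is the absolute
difference of the two z-scores (squared difference available by option).
The accumulated cost uses the symmetric2 step pattern

    D(i, j) = min(D(i−1, j) + c, D(i−1, j−1) + 2c, D(i, j−1) + c),
    D(1, 1) = 2·c(1, 1),

restricted to the Sakoe-Chiba band |i − j| ≤ 1 — the warping path never
aligns scores more than one assessment apart, which matters when
assessments are years apart. The normalized distance divides by
T_a + T_b, which makes 4- and 5-wave participants directly comparable
(a constant-offset pair of either length has normalized distance equal to
the offset). Equal-cost predecessor ties during path backtracking are
broken diagonal → vertical → horizontal; this affects only the reported
path, never the distance.

The dynamic program is validated against exhaustive enumeration of every
band-admissible warping path (`brute_force_dtw`), which is feasible
because T ≤ 5. A batch implementation runs the same recursion vectorized
over hundreds of thousands of pairs with two DP rows in memory; it is the
engine behind the cohort pipeline and all simulation studies, and is
checked for exact agreement with the scalar version.

Each participant yields (62² − 62)/2 = 1,891 unique distances. Distances
for participants with 4 complete waves use the native 4×4 cost matrix —
no padding — because the normalization already puts them on the common
scale. The stacked long table (participant, item_i, item_j, distance,
pair mean raw score) is the unit of analysis downstream; distances are
never re-standardized, all adjustment happens through model covariates.

## Edge test

An edge is drawn when a pair's mean distance is significantly *smaller*
than that of all remaining pairs (one-sided), default α = 10⁻⁴ with no
multiplicity correction (Bonferroni/BH offered as options). Two modes:

- `ttest`: pooled-variance independent-samples t-test of the focal pair's
  distances against all other pairs' distances.
- `adjusted` (default): per focal pair, OLS of distance on the focal-pair
  indicator plus a raw-score covariate, with participant intercepts. Item
  pairs whose scores both sit near the scale floor produce trivially
  small distances; the covariate guards against crowning those as edges.
  Because the design is balanced (every participant contributes every
  pair), the participant intercepts are absorbed exactly by
  within-participant centering, and the per-pair coefficient, SE, and
  one-sided p-value follow from Frisch–Waugh projection. This is
  numerically identical to OLS with participant dummies (verified against
  statsmodels in the tests) but runs for all 1,891 pairs in a handful of
  array operations. A true random-intercept fit is a needless extra here:
  with a balanced design the fixed-effects projection gives the same
  within-participant contrast.

The covariate coding is configurable: the pair's mean raw score
(default), or the two member items' raw means as separate covariates —
the choice is logged with each run.

The edge "effect" reported (and used for edge width in plots) is the
model coefficient of the focal-pair indicator (mean difference in ttest
mode); significance additionally requires the effect to be negative.

A calibration caveat that the test suite makes explicit: "all items
pairwise independent" is *not* sufficient for the null edge rate to equal
α. Items on different response scales (0–3 vs 0–4) or with different
baseline levels have systematically different distance distributions, so
some pairs are genuinely, reproducibly closer than the rest even with
zero coupling. Type-I calibration is therefore assessed on cohorts of
exchangeable items (a single-scale catalog), where the adjusted test's
empirical rate matches α within binomial bounds.

## Centrality, inversion, density

Distances are mapped to a "connectedness" scale by linear inversion,
`reference − d`, with the reference defaulting to the largest observed
distance; the reciprocal `1/d` is available by option. The linear default
is deliberate: group contrasts and the quadratic stability regression are
invariant to any affine choice, whereas the reciprocal is not.

Centrality of an item is the mean inverted distance to its connected
(significant-edge) neighbours; isolated items get centrality 0 and a
flag. A z-standardized centrality supports ranked bar plots.

A participant's network density is their mean inverted distance over all
1,891 pairs. Adjusted group densities come from OLS of density on mean
symptom severity (grand mean of the 62 raw item scores), age, sex,
education, and group indicators; the reported group estimates are
predictions at the grand covariate means with delta-method SEs, plus all
pairwise group contrasts. With one density record per participant a
random intercept is degenerate, so the fixed-effects fit is the exact
counterpart of the residualize-then-contrast description. Groups with
fewer than 2 participants are excluded with a warning.

## Networks and layout

The whole-group network fixes the node layout (Fruchterman–Reingold via
networkx's spring layout, seeded, fixed iteration count) and the
edge-weight scale; subgroup networks inherit both bit-identically so
plots are directly comparable — in subgroup plots only edge width, not
node proximity, carries information. Exports: edge/node tables, GraphML,
JSON (with layout), optional matplotlib rendering with node size ∝
centrality and color by scale.

## Disease-state stability

The stability score counts the diagnostic assessments (5 per participant:
baseline-lifetime plus four follow-up intervals) with an active AD and/or
MDD diagnosis. It is a count, deliberately order-insensitive: reversing
the assessment sequence leaves it unchanged. Scores 0–1 are labelled
stable health, 2–3 unstable, 4–5 stable disease, and the labelled
categorical is exported alongside the raw score. Score 0 coincides with
the control subgroup by construction.

The density–stability relation is fit in two steps, literally: (1)
residualize per-participant density on severity, age, sex, education;
(2) regress the residuals on the stability score with linear and
quadratic terms. A joint single-model option exists; the two differ
slightly because step 1 also absorbs covariate–score overlap, and the
two-step form is the package default. Collinear covariates abort with the
offending column named. Adjusted mean densities per score level (with
SEs) accompany the coefficients.

## Synthetic cohort generator

The generator exists so that every pipeline stage has testable ground
truth. It emulates the *statistical structure* of a naturalistic
depression/anxiety cohort, not its clinical calibration:

- **Subgroups** control / AD-only / MDD-only / comorbid with default
  sizes 120/53/88/289 (the 360/158/265/866 proportions of a large
  published cohort scaled by 1/3 — large enough for stable adjusted
  densities, small enough that full-cohort replicates run in ~1 s).
- **Latent factors** mood, cognitive anxiety, somatic arousal, worry,
  sleep; items map to factors deterministically in catalog proportion
  (PSWQ entirely to worry). An item's series is
  `y = √c·f + √(1−c)·u` with `f` (factor) and `u` (item noise)
  independent stationary AR(1) paths (coefficient 0.4), so `c` is the
  variance share of the shared factor.
- **Coupling defaults** 0.08 / 0.45 / 0.48 / 0.75 encode the generating
  density order control < AD ≈ MDD < comorbid. Worry items weight their
  factor ×1.35 (they cluster hardest), sleep ×0.8 (they sit at the
  periphery). Per-item factor assignments and coupling weights can be
  overridden, which is how the engineered-cluster and hub scenarios for
  the recovery tests are built.
- **Scores** are fixed-threshold discretizations: round(base + latent +
  severity) clipped to the item's Likert range — deterministic given the
  latent draw, no probit sampling. Scale bases (IDS 1.2, BAI 1.1,
  PSWQ 1.8) sit mid-range so that range-censoring is mild and roughly
  symmetric across subgroups. This is a deliberate departure from real
  control groups, whose items pile up at zero: heavy floor/ceiling
  censoring flattens series and inflates density in a way that a linear
  severity adjustment only partly removes, and with strong censoring the
  coupling signal the recovery tests target would be confounded with a
  censoring artifact. Passing recovery tests therefore demonstrate
  coupling recovery under mild censoring, not robustness to the extreme
  floor effects of real control data — the severity covariates exist for
  exactly that reason, but their adequacy on strongly censored data is
  not something these simulations establish.
- **Severity** adds subgroup offsets (0 / 0.20 / 0.22 / 0.35), a
  baseline-only extra (0.2) producing the initial post-baseline drop, and
  a boost (0.15) while a diagnosis is active.
- **Disease chains**: patient subgroups start diagnosis-positive at
  baseline (lifetime diagnosis) and follow per-subgroup Markov
  (onset, remission) probabilities — AD (0.10, 0.55), MDD (0.08, 0.65),
  comorbid (0.40, 0.30) — chosen to land mean stability scores near
  2.0 / 1.7 / 3.5, mirroring the ordering reported for such cohorts.
- **Covariates** age ~ N(41.5, 13.2²) clipped to 18–65, sex
  Bernoulli(0.664), education (0.033, 0.554, 0.413) — identical across
  subgroups, so covariate adjustment is exercised but subgroup covariate
  confounding is not emulated.
- 15% of participants lose one random follow-up wave, exercising the
  4-wave normalization path.

The stability scenario builder draws stability scores from a fixed 0–5
distribution, constructs flags with exactly that many positive
assessments, and sets each participant's coupling by their score. The
default inverted-U profile (0.10, 0.33, 0.58, 0.62, 0.33, 0.12) peaks at
mid scores; the flat profile (all 0.35) is its null.

Everything is driven by one seed through a single `numpy` generator;
regeneration is bit-identical.

## Problem sizes in tests and the acceptance script

Simulation studies are sized to give decisive answers at interactive
runtimes: null calibration uses 200 replicates of 300 participants × 20
exchangeable items at α = 0.01 (38,000 tests, binomial 99% band ±0.0013);
cluster/hub recovery 500 participants, 5 replicates; density ordering 50
replicates at the default 550-participant cohort; quadratic recovery 100
replicates of 800 participants × 20 items. The acceptance script repeats
the same computations at reduced replicate counts (its own output states
the `n` used for each number). The full test suite runs in about a
minute; the acceptance script in about twenty seconds.

## Known limitations

- The band width (1) and step pattern (symmetric2) are fixed defaults,
  not tuned; nothing here says they are optimal for a given wave spacing.
- The edge test's rest-of-pairs reference makes edges *relative*: adding
  strongly coupled items to the catalog can push previously significant
  edges below threshold.
- Reciprocal inversion changes group contrasts (it is not affine);
  results using it are not comparable to the linear default.
- The generator does not emulate item-level response styles, informative
  dropout, subgroup covariate imbalance, or treatment effects; claims
  about those cannot be supported by its recovery tests.
- α defaults to 10⁻⁴ for edge display; the choice is a display threshold
  inherited from practice in this literature, not an error-rate
  guarantee across the 1,891 correlated tests.
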