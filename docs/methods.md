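# Methods

This note documents the models behind `dormscreen`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
tests do and do not demonstrate about real screening data.

## Dormancy categories and classification rules

Primary (physiological) dormancy is screened with hormone germination
assays scored at day 7.  Categories are ordered ND(1) < WD(2) < MD(3) <
SD(4).  Two rounds feed the rules:

* **Initial round** (no treatment + 0.1/1/10 µM ABA, 3 technical
  replicates of 10 seeds): SD when every arm's mean germination is below
  0.25; ND when every arm exceeds 0.75 and the variety shows no
  significant ABA response; MD when no-treatment germination is below 0.50
  with a non-increasing ABA dose response dropping ≥ 5 points in total; WD
  when no-treatment germination exceeds 0.50 with an ABA response.
* **Refined round** (NT + 10 µM ABA + 10 µM GA, 3 biological × 3 technical
  replicates), for everything not initially ND: SD when NT and ABA stay
  below 0.25 and GA below 0.30; MD when GA reaches ≥ 0.50 while NT stays
  below 0.50 with an ABA response; WD when germination exceeds 0.50
  without hormone **or** with GA, with an ABA response.

Inequalities follow the screening protocol's wording literally: "0–24%"
is strict (< 0.25), "50% or greater" is inclusive, "above 50%"/"above
75%" are strict.  Rules are evaluated most-restrictive-first (SD, ND, MD,
WD initially; SD, MD, WD refined).  Several rule boundaries do not tile
the input space, so inputs satisfying no rule receive the **nearest**
rule's category — smallest total threshold violation in percentage points,
with a fixed 100-point penalty for a mismatched responsiveness requirement
— and an `ambiguous` flag.  Ties prefer the less dormant category; together
with the rule structure this makes calls monotone: raising every
germination mean never moves a call toward SD (property-tested).  In the
refined fallback, the distance to WD is measured to its no-hormone branch
only, because the GA branch overlaps the MD region, which has precedence.

Design choices worth flagging:

* "Responsive to ABA" is operationalised as: ABA10 mean below NT mean and
  a pooled-variance t-test on the arcsine scale rejecting at α = 0.05,
  with a fallback for zero-variance replicates (drop ≥ 20 points).  The
  transform is plain arcsin √p without small-sample correction.
* The ND rule requires *absence* of a statistically significant ABA
  response.  High-germinating varieties (> 75% everywhere) with a small
  but significant ABA drop are therefore called WD, which is the dominant
  residual error mode on synthetic panels (see Recovery below).
* A stricter ND variant additionally requiring > 95% no-treatment
  germination is available (`ClassifierConfig(strict_nd=True)`).

### Viability decision tree

Varieties still SD/MD after the refined round are after-ripened one month
(AR) and re-assayed; scarification (SCR) is consulted only when AR seeds
failed to germinate (max of NT/GA below 0.50), and a three-month
after-ripening round (LAR) when scarification also fails.  Decision
order: (1) AR NT or GA ≥ 0.75 → dormancy released, embryo-imposed,
viable; (2) significant AR gain with NT still < 0.50 → slow
after-ripener, embryo-imposed (after-ripening responsiveness implies a
physiological mechanism), viable; (3) scarified germination ≥ 0.50 and
significantly above the refined baseline → seed-coat-imposed, viable;
(4) LAR release → embryo-imposed (long after-ripening), viable; (5) only
LAR scarification rescues → seed-coat-imposed, viable; (6) otherwise a
viability concern.  "Significantly above" is a t-test on the arcsine
scale at α = 0.05.  The maturity category is retained — the tree explains
the mechanism, it does not reclassify strength.

## Germination statistics

One-way fixed-effects ANOVA on arcsine-transformed replicate fractions,
with Tukey(–Kramer) HSD p-values from the studentized-range distribution
at the residual degrees of freedom.  Replicates are treated as
exchangeable within a treatment (the bio × tech nesting is not modelled;
the screening analysis is a one-way layout).  Compact letters use the
insert-and-absorb procedure over groups sorted by descending mean (ties
broken lexicographically), so groups sharing a letter are never a
significant pair.  Residual variance is declared zero below a relative
tolerance (1e-14 on the squared data scale); unequal means then report
p → 0 with a `zero_variance` warning flag, identical groups share one
letter.

## Synthetic panel generator

The generator defines the study conditions for all tests.  Defaults: 189
varieties in proportions 141/27/9/12 (ND/WD/MD/SD) apportioned by
largest-remainder rounding (exact counts, deterministic); a quarter of SD
varieties carry seed-coat-imposed dormancy (the screen confirmed 2–3 of
12 such varieties; 3/12 after rounding); 3 × 3 replicates of 10 seeds;
seed 42.  Every generator is a pure function of (config, seed), with
per-variety substreams keyed by variety index so panels extend without
reshuffling.

Germination follows a closed-form dose-response: baseline germinability
g₀, Hill-type ABA inhibition g₀/(1 + (C/IC₅₀)^h), a multiplicative GA
boost g + b·(1−g), and release terms for after-ripening (per-month
fraction, compounding as 1−(1−r)^k) and scarification, each moving the
baseline toward 1.  Replicate counts are Binomial(10, p).  Class-
conditional parameter ranges are chosen so SD expectations stay below
0.25 in-assay and ND expectations above 0.75 (enforced invariants), with
within-class spread comparable to the replicate error bars of real
hormone screens; embryo-imposed SD releases through after-ripening
(r ∈ [0.80, 0.95] per month) while seed-coat-imposed SD releases only
through scarification (r ∈ [0.80, 0.95], after-ripening ≤ 0.05 — dry
storage does not soften a seed coat).  Within-variety replicate variance
is purely binomial; real assays add plate effects, so recovery rates
measured here are an upper bound on field performance.

Traits are class-conditional: strongly dormant varieties draw thicker
seed coats (mean 0.065 mm vs 0.040 mm for ND, truncated normal on
0.02–0.12 mm) and a narrower, lower eccentricity range (truncated
exponential on 0.36–0.49 vs 0.34–0.84 for ND) by construction, matching
the qualitative association between coat thickness, roundness and
dormancy strength; means remain similar across categories, as observed.
Major/minor axes are derived from area and eccentricity assuming an
elliptical seed; the tabulated perimeter carries a 5–18% roughness factor
over the Ramanujan ellipse perimeter because real seeds are not smooth
ellipses.  Coat colors are multinomial per category using the observed
color-by-category frequencies smoothed 15% toward the pooled marginal so
that no color is exclusive to one category by construction (exclusive
levels would be quasi-separated in the ordinal regression).

Spectra are a low-rank factor model (rank 5, smooth sinusoidal loadings)
plus isotropic noise on the 950–1650 nm grid at 5 nm (141 wavelengths);
outliers draw inflated factor scores (×3) and noise (×5) and their
indices are recorded.  Rendered scans place dark ellipses on a light
background with analytic ground truth (area πab, Ramanujan perimeter,
eccentricity √(1−(b/a)²), solidity 1) converted at 25.4/dpi mm per pixel.

## Morphometrics

Grayscale by standard luminance; polarity auto-detected from the border
median (seeds darker than the scanner bed); Otsu global threshold; hole
filling; removal of components below 0.1 mm²; 8-connected labeling;
touching seeds split by watershed on the Euclidean distance transform
seeded at h-maxima with suppression depth 10% of the maximum distance.
Distance-transform plateaus can shatter into nearby unconnected maxima
pixels, so peaks are dilated by a 3-px disk before marker labeling —
small enough never to merge distinct seeds at 1200 dpi.  Descriptors use
the moment-equivalent ellipse for axis lengths and the 4-direction
Crofton estimate for perimeter (lower bias than pixel-edge counting on
smooth shapes).  Eccentricity is reported as √(1−(b/a)²) — the convention
matching reported ranges where values near zero are round seeds — with
the raw axis ratio b/a also emitted for users of the other convention.
Single-pixel/degenerate regions are flagged and excluded from sample
means.  Measured accuracy on rendered truth: eccentricity within 0.02,
area within 2%, < 1% drift when doubling dpi, < 2% under rotation.

## NIR quality control

Filters run in the fixed order range → Mahalanobis → adjustment.  The
centroid uses calibration spectra only; the covariance is the sample
covariance (n−1) of the pooled experimental + calibration rows — the
pooled convention is deliberate, matching instrument practice of
including experimental spectra in the covariance.  The squared distance
d² is compared against the χ² quantile at 1−α (α = 0.001) with df equal
to the wavelength count (141); a config switch compares the unsquared
distance against the root of the quantile instead (identical decisions,
different reported scale).  When the pooled row count is small relative
to 141 dimensions the covariance is near-singular; a ridge of
1e-8·trace(Σ)/p is added to the diagonal when the condition number
exceeds 1e12 (both configurable).  Dry-matter adjustment is
value·100/(100−moisture), the standard as-is → dry-basis conversion.

## FAMD

Quantitative columns are standardised with the population (1/n) standard
deviation; each categorical level becomes an indicator divided by √p and
centred.  One SVD of the encoded matrix scaled by 1/√n yields
eigenvalues (squared singular values), row principal coordinates
(√n·U·s, so the mass-weighted mean squared coordinate equals λ), percent
and cumulative inertia, loadings and per-column contributions.  Total
inertia is K_quant + Σ(levels−1), conserved to 1e-10; with no categorical
variables the analysis is exactly correlation-matrix PCA, with a single
categorical variable it reproduces the correspondence analysis of the
indicator matrix (both oracle-tested).  Signs are fixed by making each
dimension's largest-magnitude loading positive.  Rows with missing cells
are dropped and counted, not imputed — ordination runs on the
complete-case subset, as the QC chain naturally produces one.  A factor
map over the first d dimensions is declared supported only when their
cumulative inertia reaches 50%; the pipeline evaluates the rule on 2
dimensions by default.

The four standard variable sets are: all traits + coat color + dormancy;
coat thickness + coat color + dormancy; shape traits + dormancy; protein
+ moisture + dormancy.  Dormancy enters as an active categorical
variable.

## Proportional-odds regression

logit P(Y ≤ j | x) = θⱼ − xβ with logistic F.  Newton–Raphson on the
unconstrained parameterisation (θ₁, log-gaps) with analytic gradient and
Hessian and step-halving, which guarantees a non-decreasing
log-likelihood; convergence requires the gradient max-norm in the natural
parameterisation to fall below 1e-8 (max 100 iterations).  Cut-points
initialise at marginal cumulative-proportion logits, β = 0.  Standard
errors come from the inverse observed information at the optimum;
p-values use the two-sided normal approximation 2(1−Φ(|t|)).  Predictors
are **not** standardised — coefficients are reported per raw unit (a
seed-coat-thickness effect is per mm, hence numerically large), and
categorical predictors are dummy-coded against a baseline (beige for coat
color, the most prevalent).  Separation is diagnosed on the scale-free
effect |βⱼ|·sd(xⱼ): values above 20 log-odds per SD are unreachable for
overlapping categories and raise a diagnostic error instead of silently
diverging.  Quasi-separated sparse dummies (a level observed in one
category only) converge to large finite coefficients with very large
standard errors, matching standard reference implementations; the
pipeline's color model additionally pools levels rarer than 5 varieties
into an `other` dummy.  The three standard models are thickness + color,
protein + moisture, and the six shape traits.

Simulation calibration (1,000 replicates, re-run by the acceptance
script): Wald type-I error at n = 200 within the Monte-Carlo band of 5%,
95% interval coverage at n = 500 within [0.93, 0.97], slope bias < 0.01.

## Pipeline and problem sizes

The driver chains simulate → germination statistics → classify →
morphometrics → NIR QC → trait assembly → FAMD ×4 → OLR ×3 → report,
logging rows in/out at every stage; the accounting table asserts that
excluded rows plus reported rows equal input rows.  The NIR stage
predicts protein/moisture from the trait table, injects a 4% spectral
outlier fraction and uses deliberately interior calibration ranges
(protein 12–19.5, moisture 7.4–9.0 g/100 g) so both filters act; the
analysis table is the QC-kept complete-case subset (typically ~175 of
189 varieties).  Demonstration scans render 24 seeds for 2 varieties at
1200 dpi.  Reported floats use 6 significant digits, regression estimates
8 decimals.

Test and acceptance problem sizes were chosen to make Monte-Carlo bands
tight while keeping the default suite fast: 10,000 draws for binomial and
null-exclusion checks, 1,000 replicates for regression calibration, 100
random tables for inertia conservation, 20–100 random instances for
oracle-agreement checks.

## Known limitations

* Recovery rates are measured under binomial-only replicate noise;
  plate/batch effects, dormancy loss during storage and scoring
  subjectivity in real assays will lower them.
* The watershed splitter is validated on moderately overlapping convex
  seeds; clusters of three or more strongly overlapping seeds can
  under-segment.
* The NIR stage implements only the exclusion filters and the dry-matter
  adjustment; the instrument's calibration model that produces predicted
  constituents is out of scope, so synthetic predictions stand in for it.
* FAMD support is a heuristic screening rule on cumulative inertia, not a
  significance test; no cluster inference is performed.
* The ordinal model assumes proportional odds; no partial or multinomial
  fallback is provided.
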