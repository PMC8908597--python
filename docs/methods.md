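# Methods

## Statistical model and procedure

**Weighted UniFrac.** For two communities in relative-abundance form,
each branch b of the rooted phylogeny contributes ℓ_b·|A_b − B_b|,
where A_b, B_b are the fractions of each community descending from b.
The implementation builds a branches × taxa membership matrix once per
tree and evaluates all pairs as a length-weighted L1 distance between
branch-fraction vectors; the normalized variant divides by
Σ_j d_j(A_j + B_j) with d_j the root-to-leaf depth, bounding the value
in [0, 1]. The unnormalized form is the default, matching the common
default of reference implementations; the variant is a flag because the
upstream 16S tooling does not pin one down.

**PCoA.** Gower double centering of −d²/2 followed by a symmetric
eigendecomposition. Negative eigenvalues (UniFrac is not Euclidean) are
excluded from coordinates and their absolute mass reported; no
Cailliez/Lingoes correction is applied — the simplest defensible
choice, left as a documented extension. Axis signs are canonicalized
(the largest-magnitude coordinate on each axis is positive) so PCo1 has
a stable direction across runs; mediation results are invariant to this
choice (flipping the mediator flips a and b but not a·b), which the
test suite checks explicitly.

**PERMANOVA.** Sequential (Type-I) sums of squares on the
Gower-centered matrix: SS of term i is tr((H_i − H_{i−1})G) for the
cumulative hat matrices of the ordered design, pseudo-F uses the
residual SS, and p-values come from permutations with the add-one
convention p = (1 + exceedances)/(1 + B), so p ≥ 1/(B+1) always. Two
permutation schemes are exposed: `free` (any sample permutation, the
common adonis usage) and `subjects` (subjects exchanged as whole units
with timepoints pinned, the default for group×time models because it
respects within-subject dependence). For n ≤ 8 an exact mode enumerates
all n! permutations; the small-instance tests compare it against an
independent enumeration oracle built from the classic within-group
squared-distance identity.

**Convergence.** For each arm at month six,
Δ = mean between-group − mean within-group dissimilarity; the null
redraws group labels (sizes preserved), and the one-sided p asks for
Δ at least as large as observed. The statistic is evaluated for all
label draws in vectorized chunks (one D·Z product per chunk), so the
default B = 10⁵ runs in seconds on a 90-subject matrix; B is a
parameter, and the Monte-Carlo summary (null mean, sd, quantiles) is
reported with every p.

**Change matrix.** Per subject, log2((rel_t6 + ε)/(rel_t0 + ε)) with
ε defaulting to half the smallest nonzero relative abundance in the
table (scale-adaptive; a fixed ε can be supplied). A taxon absent at
both timepoints gives exactly 0. Subjects missing one timepoint are
dropped with a logged reason; duplicate timepoints are an error.

**Core/non-core.** Prevalence is the fraction of samples with a
nonzero value. The core cutoff is *strictly* greater than 50%: the
boundary case is assigned to the non-core (rare, person-specific)
fraction, since the source definitions ("> 50%" and "< 50%") leave
exactly-50% unassigned. The abundance filter (relative abundance
≥ 1e−5 in ≥ 5% of samples) is inclusive on both thresholds.

**Adherence.** Intakes are normalized to grams per kcal, medians are
taken over the pooled cohort (an "adherence relative to the study
population" reading; per-arm medians are an option), beneficial
components score 1 at or above the median, meats score 1 strictly
below. Ties follow that literal wording, which has the visible
consequence that a component consumed by fewer than half the cohort
(median 0) awards its point to everyone if beneficial.

**Per-feature differential change.** Abundances are total-sum scaled
and logged with a half-minimum pseudocount. With exactly two timepoints
and a subject-level random intercept, the mixed model
`feature ~ group + time + group:time + (1|subject)` reduces
algebraically to regressing the per-subject change score on group; the
implementation takes the change-score path and the test suite verifies
coefficient-level equality against an explicit mixed-model fit. The
interaction p is the joint F over the group contrasts; features
constant after transformation are flagged with p = 1. BH correction is
applied across features with the study-wide q < 0.25 target.

**Trend and correlation tests.** Kendall tau-b treats the arms as a
ranked variable (1 = HDG, 2 = MED, 3 = Green-MED); the p-value is exact
when scipy's rule allows (small n, no ties — note the rank variable is
itself tied, so the tie-corrected normal approximation is the usual
path, and its null calibration is verified empirically). Spearman maps
are computed as Pearson correlation on midranks with the t
approximation, matching scipy on every grid cell.

**Mediation.** The single-mediator estimator fits M ~ X and
Y ~ X + M by OLS and draws coefficient vectors from their estimated
sampling distributions (quasi-Bayesian simulation; a bootstrap is not
provided). For linear models without exposure–mediator interaction the
potential-outcome contrasts collapse to ACME = a·b and ADE = c′ per
draw; percentile intervals come from the draws. The proportion mediated
is a ratio of noisy quantities, so it is reported only when the
total-effect CI excludes zero and flagged unstable otherwise. The
high-dimensional estimator screens taxa to the top ⌈n/log n⌉ by
exposure-adjusted outcome association, selects mediators by
cross-validated lasso on exposure-residualized data (an L1 stand-in for
the minimax-concave penalty of the cited approach — acceptance is
truth-recovery, not coefficient equality), and tests each selected
taxon by joint significance, p = max(p_a, p_b), with BH across the
selected set; the per-taxon proportion mediated is a·b divided by the
total effect.

## The synthetic cohort generator

The generator emulates a 3-arm, two-timepoint trial and is the
package's acceptance surface. Counts are Dirichlet-multinomial:
subject-level latent compositions (global lognormal taxon weights ×
subject jitter × a Bernoulli occupancy mask on rare taxa) are
resampled per timepoint with concentration `overdispersion` (default
300) and multinomial library sizes (Poisson, default mean 20 000). All
randomness flows through named sub-streams of one seed; identical spec
+ seed gives bit-identical output.

Planted structure, all recorded in a truth object:

* **Core/rare split** — the first `n_core_taxa` taxa carry
  `core_mass` = 0.70 of expected abundance; rare taxa are present in a
  subject with probability `occupancy` = 0.4. Core mass 0.70 (rather
  than a more top-heavy split) keeps rare-taxon Dirichlet weights large
  enough that rare-fraction effects are quantifiable rather than buried
  in sampling noise.
* **Arm-graded shift** — responder taxa (default 20, three-quarters
  rare) multiplied by exp(shift × ±1) at t6, shifts defaulting to
  (0, 0.5, 1.0) natural-log units across HDG/MED/Green-MED.
* **Convergence** — the Green-MED arm's rare-fraction composition is
  mixed toward one shared attractor with weight `convergence_strength`.
  At strength 1 the *latent* rare compositions are identical within the
  arm (the degenerate limit tested on the truth record); observed
  counts always retain sampling noise.
* **Adherence and intake** — component intakes rise (green items) or
  fall (meats) stepwise across arms around subject propensities, so the
  computed Green-MED score orders the arms; the score computed from the
  generated intake *is* the exposure used for mediation planting.
* **Mediation** — each of the (default 3) mediator taxa carries an
  independent path M_k = a·Ã + ε_k (Ã the standardized score), shifting
  the taxon by exp(1.2·±M_k); the planted outcome's percent change is
  b·mean(M_k) + c′·Ã + measurement noise, so the analytic proportion
  mediated is a·b/(a·b + c′) regardless of the number of paths. Three
  deliberate choices make per-taxon recovery well-posed: independent
  path noises (a single shared latent makes the taxa collinear in the
  joint outcome model and defeats joint significance), mediator taxa in
  the upper-middle of the core abundance range (abundant enough for
  low counting noise, not so dominant that multiplicative shifts
  saturate under compositional closure), and alternating shift signs
  (so the trio's total mass does not co-swing with adherence, which
  would inject a large shared closure term into every taxon's change).

**What the generator does not emulate:** taxonomic correlation
structure beyond the phylogeny's role in UniFrac, sequencing-run batch
effects, antibiotic perturbations, dropout/attrition, non-linear
diet–taxon dose response, and measured-confounder structure for the
mediation models. Passing tests therefore demonstrate statistical
correctness and power under a clean compositional model, not
performance on real 16S data.

**Compositional closure caveat.** Because relative abundances sum to
one, planting large shifts on abundant taxa genuinely changes every
other taxon's relative abundance; "non-responder" features are then not
null, and apparent false-discovery proportions against the planted
labels overstate the error rate. FDR-control checks therefore use
closure-light configurations (rare-only responders, balanced
directions), and detection checks score recovery on the core
responders, whose changes are quantified reliably at the default
library sizes.

## Problem sizes and numerical choices

The test suite's simulation studies use cohorts scaled to the
statistics they probe, chosen as the smallest sizes at which the
planted effects are identifiable: null calibration runs 200 cohorts of
8 subjects/arm × 40 taxa with B = 99–199; planted-shift recovery runs
50 cohorts of 30/arm × 120 taxa with B = 199; high-dimensional
mediation runs 50 cohorts of 50/arm × 200 taxa. The full pipeline on a
90-subject, 300-taxon cohort with B = 999 (PERMANOVA) and B = 10⁴
(convergence) completes in a few seconds on one CPU.

Other conventions: permutation p-values are never 0 (add-one); exact
PERMANOVA enumeration tolerates F ties with a relative 1e−9 slack;
QR-based rank detection guards singular designs; the lasso CV fold
count is 5 with the random state derived from the caller's seed;
percent change with a zero baseline is flagged missing rather than
±∞; zero-sum samples are rejected by name.

## Known limitations

* PCo1 is a crude one-axis summary of microbiome change: with
  multi-directional planted paths it captures only part of the mediated
  signal, so summary-level proportions mediated are systematically
  smaller than the planted path-level truth (the same caveat applies to
  any single-coordinate mediator in real data).
* High-dimensional mediation needs on the order of 150 subjects under
  the default effect sizes; at 90 subjects the screen-and-select stages
  lose the planted taxa more often than not.
* The convergence Δ statistic responds to *any* shared within-arm
  shift, not only attractor dynamics; interpreting a significant Δ as
  convergence assumes the arm-level mean shift has been considered.
* No correction for negative PCoA eigenvalues; proportions explained
  are relative to the positive spectrum only.
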