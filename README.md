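# dietshift

Analysis pipeline for gut-microbiome shifts under graded dietary
interventions: did the intervention change community composition, which
taxa carried the change, did the strongest arm's microbiomes *converge*,
and how much of the diet's cardiometabolic benefit is *mediated* by the
microbiome change?

The package targets the design of a three-arm weight-loss trial —
healthy dietary guidance (HDG), Mediterranean diet (MED), and a
polyphenol-enriched, meat-depleted "green" Mediterranean diet
(Green-MED) — with stool 16S ASV profiles, food-frequency data and
cardiometabolic biomarkers at baseline (t0) and month six (t6). All of
its statistics are general-purpose and work on any samples × features
count table with a rooted phylogeny.

## What it computes

* **Community shift** — weighted UniFrac distances
  (d(A,B) = Σ_b ℓ_b·|A_b − B_b| over branches), PCoA, and PERMANOVA
  with sequential (Type-I) terms `group + time + group:time`, where a
  significant interaction means the arms' compositions moved
  differently over time. Subjects are permuted as whole units by
  default so repeated measures stay intact; leave-one-out group-pair
  contrasts are BH-corrected.
* **Per-subject change space** — the log2 change matrix
  `log2((rel_t6 + ε)/(rel_t0 + ε))` per subject and taxon, its Euclidean
  distance matrix, and the variance in it explained by biomarker or
  adherence changes (single-covariate PERMANOVA R²).
* **Core vs non-core** — taxa partitioned at >50% sample prevalence;
  all community tests can be stratified on either fraction.
* **Convergence** — for each arm, Δ = mean between-group −
  mean within-group dissimilarity at t6, against a label-permutation
  null: a large Δ means that arm's members grew alike.
* **Green-MED adherence score** — 9-item median-split index on
  calorie-normalized intake: 7 beneficial components (walnuts,
  vegetables, legumes, fruits, fish, green tea, Mankai) score 1 at or
  above the cohort median, red and processed meat score 1 strictly
  below it; range 0–9.
* **Per-feature tests** — group×time interaction per taxon via
  change-score regression (algebraically the two-timepoint linear mixed
  model with subject random intercept), Kendall tau-b trends across the
  ranked arms, Spearman taxon-biomarker maps, all BH-controlled with a
  q < 0.25 discovery target.
* **Mediation** — adherence → microbiome change → biomarker change:
  quasi-Bayesian single-mediator estimation (ACME, direct and total
  effects, proportion mediated with percentile CIs) using PCo1 of the
  change matrix as the summary mediator, plus high-dimensional
  per-taxon mediation (sure-independence screening to ⌈n/log n⌉
  candidates, cross-validated L1 selection, joint-significance
  p = max(p_a, p_b), BH across selected taxa).
* **Synthetic cohorts** — a fully seeded generator
  (Dirichlet-multinomial counts over a random phylogeny, core/rare
  prevalence structure, arm-graded shifts, a rare-fraction attractor,
  intake tables and mediated biomarkers) whose planted truth makes
  every stage testable without any data download.

## Worked example

```python
from dietshift import (CohortSpec, generate_cohort, to_relative,
                       weighted_unifrac, interaction_permanova,
                       log2_change, euclidean_distances, pcoa,
                       greenmed_score, mediate_summary, percent_change)

cohort = generate_cohort(CohortSpec(n_subjects_per_arm=30, n_taxa=300,
                                    n_core_taxa=60, convergence_strength=0.5,
                                    seed=1))
rel = to_relative(cohort.counts)
dm = weighted_unifrac(rel, cohort.tree)
res = interaction_permanova(dm, rel.meta, n_perm=999, seed=1)
print(res.table.loc["group:time", ["R2", "p"]])
score = greenmed_score(cohort.intake).scores
print(score.groupby(cohort.truth.groups).mean())
```

prints

```
R2    0.012559
p        0.001
Name: group:time, dtype: object
group
GreenMED    6.8
HDG         1.6
MED         5.1
```

— the planted group×time interaction is detected (p = 0.001 at B = 999,
R² ≈ 1.3%), and the adherence score rises stepwise across the arms, as
planted. The same objects feed the downstream stages, e.g.
`mediate_summary(score, pcoa(euclidean_distances(log2_change(rel)), 2).pc1,
percent_change(cohort.biomarkers)["weight"])`.

The command line drives the same stages end to end:

```bash
dietshift simulate --seed 1 --out cohort/
dietshift run --config config.yaml        # writes report.json + TSVs
dietshift score-adherence --intake cohort/intake.tsv
```

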