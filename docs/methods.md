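# Methods

This note documents the models, numerical choices and known limits of
`dbscreen`. It covers what the package computes and why each default is
what it is; no number here is claimed beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model

A cohort is a protein × sample matrix of raw quantification intensities
with a peptide-evidence count per protein, plus sample metadata (group:
healthy_newborn / healthy_adult / patient; disease and causative gene for
patients). Two absent-value states are kept distinct end to end:

* **missing** — the protein was not quantified in that sample (any
  reason);
* **below LOD** — the value was censored at the detection limit. A
  below-LOD cell is an *observation* for screening purposes: it always
  flags, and reports print it as such rather than dropping it.

Protein identifiers are gene symbols (the clinical tables, gene sets and
panels are all symbol-keyed).

## Preprocessing

1. **Evidence filter.** Keep proteins with ≥ 2 identified peptides
   (default `min_peptides=2`) that are quantified in *every*
   healthy-newborn sample. Requiring completeness in the reference group
   guarantees every kept protein has a well-defined reference interval.
   The filter is idempotent and order-preserving.
2. **%β-actin normalization.** value = 100 · intensity / ACTB intensity
   per sample. β-actin is an abundant cytoskeletal protein present in
   every blood cell, making it a stable within-sample anchor; the 100×
   scale matches the clinical reference tables (e.g. a healthy-newborn
   Munc13-4 mean of 10.9 %β-actin). The anchor must be quantified in every
   sample — a hard error otherwise.
3. **log₂ transform.** Intensities are strictly positive and
   right-skewed; tests and clustering run on the log scale.
4. **Downshift imputation** (width = 0.3, downshift = 2.4, per sample
   column). Absent cells of a column are drawn from
   N(m − 2.4·s, (0.3·s)²), with m and s the observed mean and sample SD of
   that column *across proteins*. Because s includes the between-protein
   abundance spread, imputed values land deep in the low-abundance tail —
   the intended behaviour for left-censored (missing-not-at-random) data:
   a protein censored in patients but observed in controls will surface as
   strongly down-regulated. The statistics can optionally be taken from
   the whole matrix (`per_column=False`); per-column is the default
   convention. A column with fewer than 3 observed values is an error.
   Imputation never alters observed cells and is fully seed-determined.
5. **z-scoring** for clustering/PCA, per protein row by default, sample SD
   (ddof = 1; group sizes are small). Zero-variance rows are a hard error.

The default pipeline imputes before both the clustering stages and the
group tests; a caller who wants tests on observed values only can run the
stages individually.

## Reference intervals and screening flags

For each protein the healthy-newborn reference is (mean, sample SD,
minimum, n) of its %β-actin values. The default flag rule is
**below-group-minimum**: flag a sample for protein p iff its value is
strictly below the healthy minimum, or censored. The minimum is the
natural operationalization when the reference table publishes a "Min"
column; a z-score rule (flag iff z < −3) is available as the alternative.
A protein with no reference interval (below detection in every healthy
sample, as for the common γ chain) returns *not evaluable* rather than a
flag, and screening falls back to phenotype panels.

Phenotype panels score cell-population reductions as the mean z-score of
panel members against the healthy-newborn reference: T-cell (CD2, CD3D,
CD3E, CD5, CD247), platelet (ITGA2B/CD41, GP1BA/CD42b), neutrophil
(ITGAM/CD11b, ITGB2/CD18, CD33, CEACAM8/CD66b). Members without a value or
reference are skipped; a panel with no scorable member is an error.

Note the %β-actin denominator induces positive correlation between all
proteins of a sample (a low anchor draw inflates every ratio), so
single-sample panel z-scores of ±1–2 occur in healthy samples; the
below-minimum rule absorbs this because the reference minimum is taken
over the same normalized values.

## Differential expression

Per-protein two-sided two-sample t-tests (Student by default — the common
"multiple t tests" convention; Welch by flag) on log₂ values. Proteins
with zero variance in both groups get p = 1 when the means agree and p = 0
otherwise.

FDR control is the Benjamini–Krieger–Yekutieli adaptive two-stage linear
step-up at α = 0.05: stage 1 runs the step-up at α′ = α/(1+α); its
rejection count r₁ estimates the number of true nulls m₀ = m − r₁; stage 2
reruns the step-up at α′·m/m₀ (r₁ = 0 → nothing, r₁ = m → everything).
Reported q-values are BH-adjusted p-values scaled by m₀/m and (1+α),
capped at 1, so q ≤ α reproduces the discovery set; they are specific to
the α they were computed at. The implementation is cross-checked against
an independent two-stage implementation on random p-vectors in the test
suite.

A protein is a DEP when q < 0.01 **and** its linear fold change is ≥ 2 in
either direction. The fold change defaults to the ratio of arithmetic
means of the linear %β-actin values (`fold_change_basis="linear_means"`);
the geometric version (2^Δlog₂) is available. The log₂ fold change column
is always the log-scale mean difference.

Multi-group comparisons of single proteins use the tie-corrected
Kruskal–Wallis H with the χ²(k−1) approximation (all-identical input
returns H = 0, p = 1 instead of erroring), followed by Dunn's
multiple-comparisons test: pairwise z from mean-rank differences with
tie-corrected variance S² = N(N+1)/12 − Σ(t³−t)/(12(N−1)), two-sided
normal p multiplied by the number of compared pairs and capped at 1. At
very small N (≤ 9) the χ² p deviates from the exact permutation p by up to
~0.1; the test suite therefore validates the H statistic itself
exhaustively rather than pretending the asymptotic p is exact there.

## Secondary-marker discovery

Over-representation of a DEP list in a gene-set collection is the
upper-tail hypergeometric probability P(X ≥ k) for universe size N, set
size K (after intersection with the universe), query size n and overlap k,
BH-adjusted across sets. The universe defaults to all proteins surviving
the evidence filter; an explicit background list is accepted. Zero-overlap
sets are reported with p = 1 (or skipped by flag) and are never counted as
enriched.

The dual-control procedure asks for changes beyond age-dependent
variation: run the DEP stage patient-vs-newborn and patient-vs-adult, rank
each comparison's enriched terms (adjusted p ascending, ties by larger
overlap then name, zero-overlap terms excluded), intersect the top-10
lists ("commonly altered pathways"), and report the proteins that are
same-direction DEPs in both comparisons and belong to a common pathway.
Enlarging top-N never removes a marker (monotonicity is tested). The
adult control group is small (n = 8 in the study design), so moderate
co-reductions (×0.2–0.3) do not always clear q < 0.01 against it — the
dual-control requirement trades sensitivity for robustness to age effects,
and the demo output shows this honestly.

## Mutation-based loss prediction

Missense alleles: predicted loss iff the precomputed FoldX total-energy
change exceeds 1.58 kcal/mol (strictly greater; the threshold is
configurable). Frameshift/nonsense alleles: predicted loss under an NMD
annotation; NMD-escaping is indeterminate. Splicing, exon-skip, in-frame
deletion, transcriptional-dysregulation and synonymous-splice alleles have
no principled predictor and are always indeterminate — never guessed. The
benchmark restricts to missense alleles with a definite observed-loss
label; "reduced but detectable" rows are excluded unless a flag maps them
to loss, and undefined ratios (0/0) are reported as undefined, not zero.
On the bundled clinical allele table this yields TP=8, FN=2, FP=3, TN=0.

## Synthetic cohorts

The generator emulates the study design: 40 healthy newborns, 8 healthy
adults by default. Per protein a log₂ baseline is drawn from N(20, 3)
(arbitrary MS-intensity units) and per-cell noise from N(0, 0.5) —
the 0.5 log₂ within-group scatter reproduces within-group Pearson
correlations ≈ 0.95, comparable to real DBS cohorts. Named proteins
(disease targets, partners, panel members, age-shifted proteins) draw
baselines from the upper abundance range, modelling the screen's target
class of consistently quantifiable blood proteins; generic filler proteins
span the full range and exercise the censoring and evidence-filter
machinery. The β-actin anchor sits 4 SD above the baseline mean and is
never censored or missing.

Injected structure: newborn-vs-adult log₂ shifts (fetal-hemoglobin-like
proteins +2.5–3, coagulation/immunoglobulin-like −1.5–2.5); disease
conditions multiply the causative protein (default ×0.05), optional
partner proteins (e.g. a p22/p91-phox-like pair), and whole phenotype
panels (cytopenias). Cells below the `lod_quantile` (default 0.05) of the
intensity distribution are censored (MNAR by construction, matching the
imputation model); a small MCAR rate (1%) hits only generic proteins. A
knockdown factor of 0 produces exact zero intensities, censored by any
positive detection limit. Every draw is determined by the seed; the
truth table records every injected effect and censored cell.

What the generator does **not** emulate: peptide-level effects (shared
peptides, modified forms, truncated proteins still detected by N-terminal
peptides — the main real-world cause of missed losses), batch/storage
effects, age-continuous trends, or realistic protein-protein correlation
beyond the shared anchor. Passing the synthetic suite therefore
demonstrates the statistical machinery and decision rules, not assay-level
performance on real spots.

## Monte-Carlo evaluation (study conditions)

* **Null error control** — cohorts with no effects and no censoring (the
  sampling-noise-only global null; the MNAR path is excluded here because
  downshifted imputed values are designed to register as reductions, and
  are exercised by the recovery experiments instead): mean false-discovery
  proportion of the two-stage procedure at α = 0.05 over 500 seeds, and
  the fraction of q/fold-change DEP calls.
* **Knockdown recovery** — SCID-like cohorts (causative ×0.1, 5 patients,
  T-cell panel ×0.1, 300 proteins): per-sample flag sensitivity,
  specificity on healthy samples, and recovery of CD3E through the
  dual-control marker report, over 100 seeds; plus knockdown-only cohorts
  (×0.05) where the causative protein should top the down-regulated
  ranking (q, then log₂ fold change), over 200 seeds.

Problem sizes (300–500 proteins, study-sized sample groups, 100–500
seeds) keep the full evaluation under a minute while leaving the group
designs exactly as in the study.

## Deposited-cohort replication

`dbscreen.pipeline.cohort_summary` reproduces full-cohort summary numbers
(evidence-filter yield, newborn-vs-adult DEP counts, within-newborn
correlation range) from a measured quantification table in the package's
TSV layout. The measured tables themselves are not redistributable here;
the corresponding test states the expected values and runs when the tables
are placed under `data/external/`.

## Known limitations

* The below-minimum flag rule depends on the reference cohort's size: with
  40 newborns the minimum is a ~2.5th-percentile estimate and tightens as
  the cohort grows.
* q-values from the adaptive procedure are α-specific; comparing them
  across α levels is not meaningful.
* Dunn's adjustment multiplies by the number of compared pairs
  (conservative for many groups).
* The stability threshold (1.58 kcal/mol) is a published operating point,
  not optimized here; the benchmark deliberately reports its failure modes
  (on the bundled table: specificity 0).
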