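# Methods

## The problem

MicroRNAs (miRNAs) repress mRNAs post-transcriptionally, mostly through
3′-UTR binding. Sequence-based target prediction alone produces many
false positives, while any single perturbation experiment is noisy and
platform-limited. `mirscore` integrates four independent lines of
evidence into one composite target-prediction score per miRNA–mRNA pair,
annotates each gene and miRNA with cancer-relevance statistics, and
provides enrichment and query machinery on top of the score table.

## The composite score

Each evidence category contributes a *partial score*: the percentage of
its datasets supporting the pair under a strict threshold.

| category | support rule | default cutoff |
|---|---|---|
| ectopic miRNA expression | fold change (treated/control) below cutoff | `fc_down = 0.8` |
| miRNA knockout/knockdown | fold change above cutoff | `fc_up = 1.25` |
| tumour expression correlation | Pearson r below cutoff | `r_cut = -0.1` |
| prediction algorithms | fraction of the algorithm complement calling the pair | complement size 10 |

All comparisons are strict. The fold-change cutoffs encode "repressed by
more than 1.25-fold" (1/1.25 = 0.8) and "induced by more than
1.25-fold": datasets are frequently unreplicated, so a biologically
motivated fold-change rule replaces per-dataset significance testing.
The composite is the equally weighted mean of the partial scores of the
categories that have data for the pair, so the ceiling is 100: sum/4
with all four categories, and sum/2 when only correlation and prediction
data exist (the case of miRNAs without any perturbation study). When
exactly one experimental category is missing we generalise to the mean
of the three present categories; the availability mask (`EKCP` letters)
in every output row lets consumers filter on this. Missing cells —
a dataset that did not measure a gene — are excluded from both numerator
and denominator, so platform coverage is not penalised.

A pair with no fold-change measurement, no correlation cell and zero
positive prediction calls is omitted rather than scored 0, keeping
"no data" distinct from "contradicting data". For any pair that carries
other evidence, zero prediction calls score 0 over the full complement
(the denominator is always the configured complement, never the count of
calls).

Ranks are assigned within each miRNA (`mirna_rank`, 1 = best target) and
within each gene (`mrna_rank`, 1 = best regulator) by descending
composite; ties break on the lexicographically smaller identifier, which
makes the ranking a bijection onto 1..N and invariant to input row
order.

## Clinical annotation

**Differential expression** uses a two-group empirical-Bayes moderated
t-statistic: gene-wise pooled variances are shrunk towards a prior
fitted by moment matching on the log variances (trigamma inversion for
the prior degrees of freedom; when the observed variances are less
dispersed than a chi-square the prior is infinitely strong and its scale
is the arithmetic mean of the variances; total degrees of freedom are
capped at the pooled residual df). The implementation agrees with the
standard R reference implementation to machine precision on both
branches (checked in the test suite via `Rscript`). Direction calls
(`up_in_tumor` / `down_in_tumor`) use BH-adjusted p < α (default 0.05;
a switch allows raw p). Features with constant expression or zero
median are reported `undetermined` — the operationalisation of "could
not be determined due to low expression".

**Survival association** dichotomises expression at the cutoff
maximising the standardised log-rank statistic over unique expression
values between the 10th and 90th percentiles, requiring each group to
hold at least 10 % of the cohort. The reported p is the naive log-rank
p at the selected cutoff. Because the cutoff is chosen to maximise the
statistic, this p is anti-conservative under the null — the test suite
asserts the inflation as a property instead of hiding it, and no
multiplicity correction is applied across the scan, faithfully matching
common optimal-cutoff practice. The hazard ratio comes from a
one-covariate Cox partial-likelihood fit (Newton iterations on the
scalar log-HR, Breslow tie handling, β clipped at ±10 to absorb
separation). Both the log-rank machinery and the Cox fit are implemented
directly on cumulative risk-set sums so that screening tens of thousands
of feature×entity combinations stays fast; they are cross-checked
against lifelines in the tests.

**Dependency**: a gene is dependent in a cancer type when at least 10 %
(inclusive) of that type's cell lines show a gene-effect score strictly
below −0.5; effects below −1 feed a separate essentiality fraction.
CRISPR and RNAi screens are called independently. **Druggability** is
membership in a user-supplied curated gene list.

## Target summary scores

For each miRNA the top-k targets by composite score (k = 1000 by
default) are extracted; per entity each target contributes +1/−1/0 by
its significant DE direction (tumour/normal score) or survival direction
(overall-survival score). Genes without an evaluable record contribute
0 rather than being dropped, so scores remain comparable across miRNAs
(the sum always runs over a fixed-size set). Strongly positive scores
mean the miRNA's predicted targets behave like oncogenes — the signature
expected for a tumour-suppressive miRNA.

## Enrichment

**Preranked GSEA** uses the weighted Kolmogorov–Smirnov running sum with
weight exponent 1; the ES is the larger signed excursion (exact ties
resolve to the positive excursion so the sign is deterministic, and
ranking ties are pre-broken by gene identifier). P-values come from
gene-label permutations of set membership with +1 smoothing — hence
p ≥ 1/(n_perm+1) — using the sign-matched tail; NES divides the ES by
the mean |permuted ES| of matching sign. The implementation is verified
against a literal prefix-sum oracle to 1e-12 and calibrated against
uniform on null draws. The validated-target benchmark runs this GSEA
per miRNA for every miRNA with at least 10 luciferase-validated targets
present in its ranking, with BH correction across miRNAs.

**ORA** is the one-sided hypergeometric tail P[X ≥ k] with BH FDR across
sets; the universe defaults to all genes in the score table because no
canonical universe is prescribed. User-list→miRNA enrichment is ORA of
the list against every miRNA's top-k target set.

## Queries

Candidate filters (DE direction, survival direction, dependency,
druggability, rank/score cutoffs) compose as set intersection and are
evaluated either in a single entity or as "in at least X % of cancer
types", where the denominator counts entities with *evaluable* data for
that criterion — differential expression is typically available for
fewer entities than survival, so a fixed denominator would silently
penalise criteria with sparser coverage. Dependency satisfies with
either screen by default (switchable to both). The per-pair detail
report serialises the scores, every raw evidence datum and all
annotations into one JSON document.

## Synthetic data generator

The generator emulates the structure of the real corpus at roughly 1/50
scale: defaults are 20 miRNAs × 2000 genes × 10 entities with 4 ectopic
and 3 knockout studies per miRNA (matching the per-miRNA study counts of
the real compilations) and a 10-algorithm prediction complement. A
planted 5 % of pairs per miRNA are true targets: ectopic fold changes
log-normal around 0.5, knockout around 2.0, correlations Fisher-z
jittered around −0.4, prediction support Binomial(10, 0.8); decoys draw
the same noise centred on no effect (decoy call probability 0.05).
Noise levels (log-σ 0.2, z-σ 0.15) were chosen once as values a
curated-microarray compilation plausibly shows, and favour closed-form
expectations in tests.

Each miRNA carries a clinical class (¼ suppressive, ¼ oncogenic, rest
neutral). Targets of suppressive miRNAs are planted with the oncogene
constellation — up in tumours (log2FC +1.5), poor survival, dependent in
20 % of cell lines, druggable with probability 0.3 — and vice versa.
Survival uses a latent patient risk score with exponential event times
(baseline rate 0.1, unit log-hazard loading) and uniform censoring over
the follow-up window; planted features' expression loads on the risk
score, which lets thousands of features share one coherent cohort. The
ground-truth ledger records every planted choice and round-trips through
JSON, so tests recompute expected summaries from it.

What the generator does **not** emulate: transcriptome-wide covariance,
batch and platform effects, miRNA-family seed sharing, non-exponential
hazards, and realistic missingness (its matrices are dense). Passing
tests therefore demonstrate correctness of the machinery and
recoverability of planted signal under idealised noise — not performance
on real corpora.

## Numerical choices and problem sizes

* Strict inequalities at every threshold; boundary cases (fold change
  exactly 0.8 or 1.25, r exactly −0.1, effect exactly −0.5) count as
  non-support. The dependency flag is inclusive at exactly 10 %.
* Rank and ORA ties break lexicographically; GSEA excursion ties break
  positive.
* The dependency-fraction comparison `k/n >= 0.10` is exact in double
  precision for every k, n ≤ 50 (verified exhaustively).
* Permutation p-values are smoothed (+1) and seeded; every stochastic
  step flows from a single integer seed.
* Test and calibration runs use deliberately small systems (hundreds of
  genes, tens of seeds) chosen so the full suite completes in minutes
  while keeping Monte-Carlo margins comfortable; the default-preset
  end-to-end pipeline (simulate → score → annotate → target-scores →
  benchmark → query) runs in under two minutes on one CPU.

## Known limitations

* The optimal-cutoff survival p is anti-conservative by construction
  (documented above); downstream consumers should treat survival
  direction calls as screening hints, not confirmatory inference.
* Identifier handling is purely lexical (case-insensitive symbols); no
  alias resolution is attempted, so upstream inputs must use consistent
  nomenclature.
* The two-category composite fallback makes scores of pairs with and
  without experimental evidence numerically comparable but statistically
  different animals; the availability mask is the intended guard.
* Swapping survival event codes does not mirror the dataset (censoring
  carries no group information), so no symmetry is claimed or tested for
  that operation; the exact symmetry — inverting the high/low group
  reciprocates the hazard ratio — is tested instead.
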