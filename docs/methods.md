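# Methods

This note documents the statistical procedures the package implements, the
defaults it ships, and the design choices made where the design was
genuinely open.

## Overlap annotation and coordinate conventions

All coordinates are GRCh37, 1-based, fully closed; chromosome names are
stored without a `chr` prefix (an alias map resolves VCF contig naming).
Overlap between a germline variant and a hotspot mutation is defined in two
modes:

- **nucleotide** (default): exact (chrom, pos, ref, alt) match;
- **residue_change**: identical (gene, residue, ref_aa, alt_aa), which
  groups distinct nucleotide substitutions producing the same amino-acid
  change.

Tumor-sample counts (samples with the exact change; samples with any change
at the residue) are copied from the matched hotspot onto the germline
record and are zero for non-overlapping variants. Missing scores are
represented as missing, never 0, because 0 is a legitimate REVEL/phyloP
value. VCF queries match at the allele level after decomposing
multi-allelic records; site-level matches with a different alternate
allele are not overlaps.

## Contingency scenarios and effect estimation

With a = overlap ∧ LP/P, b = overlap ∧ comparator, c = no-overlap ∧ LP/P,
d = no-overlap ∧ comparator, three nested comparator definitions are
provided: LB/B only; LB/B with VUS folded in (every VUS treated as if
benign); and additionally folding in variants with conflicting
interpretations. A gene-restricted variant of the second scenario supports
subgroup analyses (e.g. genes whose Mendelian disease mechanism is
concordant with the cancer mechanism). The scenarios are deliberately
conservative in sequence: each one dilutes the comparator with variants
that may in truth be pathogenic, so the resulting odds ratio can only be
biased toward the null.

The odds ratio is the cross-product ad/bc. The confidence interval uses
Woolf's log method, exp(ln OR ± z·√(1/a+1/b+1/c+1/d)) with z = 1.959964
at 95%; this choice reproduces published interval bounds from the
published counts exactly at printed precision. When a cell is zero the
Haldane–Anscombe correction (+0.5 to every cell) is applied and flagged —
the standard remedy; it is never applied otherwise. The p-value uses the
chi-square test with Yates continuity correction by default; Fisher's
exact test is available by option. Published sources often report only
bounds (p < 0.001), which either test satisfies, so the default was chosen
for speed on large tables.

The positive likelihood ratio of the overlap flag for LP/P status is
LR⁺ = [a/(a+c)] / [b/(b+d)]. An empty comparator-overlap cell (b = 0) with
non-zero sensitivity yields an infinite LR⁺, returned as `math.inf` rather
than an arbitrary capped value.

## Evidence-strength calibration

The exponential point scale assigns a band worth p points the odds of
pathogenicity O^(p/8), p ∈ {1, 2, 4, 8} for supporting / moderate /
strong / very strong. Two calibrations of O are shipped: 350 (the original
framework, moderate threshold 350^(1/4) ≈ 4.33) and 1124 (the later
computational-evidence calibration, moderate threshold ≈ 5.79). A
likelihood ratio maps to the strongest band whose threshold it meets.

The ACMG/AMP combining engine implements the 2015 guideline table for
pathogenic, likely pathogenic, benign and likely benign, with duplicate
code identifiers collapsing to one line of evidence, contradictory
evidence (both sides satisfied) resolving to uncertain, and everything
else uncertain. The upgrade simulation appends one additional code (e.g. a
new moderate criterion representing hotspot overlap) to each
currently-uncertain variant and counts re-classifications to likely
pathogenic or stronger; variants already carrying the added code are
excluded from the denominator with a warning.

In-silico score binning uses ClinGen-style supporting-level cutoffs,
REVEL ≥ 0.644 toward pathogenicity (PP3) and ≤ 0.290 toward benign-ness
(BP4), both overridable; a configuration whose BP4 cutoff is not strictly
below its PP3 cutoff is rejected.

## Training-set construction

Records are grouped by (gene, residue, ref_aa, alt_aa). When grouped
nucleotide variants disagree, the label follows the precedence
LP/P > LB/B > VUS (prefer the expert-reviewed assertion of pathogenicity),
the maximum REVEL is kept, and any overlapping member marks the group as
overlapping. VUS with REVEL above 0.29 — the upper bound of
benign-supporting evidence — are excluded; the remainder are re-labelled
benign with prior weight 1 − REVEL, so a VUS with REVEL 0.05 counts nearly
as a full benign example while one at 0.29 counts as 0.71 of one. True
LB/B and LP/P examples have weight 1. VUS without a REVEL score cannot be
weighted and are dropped with a counted reason. Genes are restricted to a
whitelist defaulting to the genes carrying at least one overlapping
grouped variant (how the restriction is defined in the source protocol);
the construction report telescopes: every step's output count is the next
step's input count.

## Models

**Logistic regression (LRM).** Weighted maximum-likelihood fit (IRLS via
statsmodels GLM/Binomial with frequency weights) on eight predictors:
overlap flag, gene factor (treatment contrasts, alphabetically first gene
as reference), the two tumor-sample counts, and four conservation scores
(phyloP and phastCons, 20-way mammalian and 7-way vertebrate). Prior
weights multiply the Bernoulli log-likelihood, so integer weights are
exactly equivalent to row replication (asserted in tests). Diagnostics:
AIC and McFadden pseudo-R² = 1 − ℓ_model/ℓ_null against the weighted
intercept-only null. Prediction for a gene outside the trained levels is
an explicit error — the model is only defined on its training genes. A
feature-subset parameter supports the conservation-score ablation.

**Random forest (RFM).** 350 trees, 4 candidate variables per split
(scikit-learn), gene factor excluded so the model generalises across
genes. The reported probability is the fraction of trees voting
pathogenic (not averaged leaf probabilities), and the out-of-bag error is
computed from out-of-bag votes only. Example weights are ignored by
default, matching the reference forest implementation the protocol used;
a flag can pass them as sample weights. All stochastic fits take explicit
seeds and are bit-reproducible under a fixed seed.

## Evaluation

PR and ROC curves use every unique score value as a threshold (predict
pathogenic iff score ≥ t). AUPRC is average precision, Σ(R_k − R_{k−1})P_k
over descending thresholds — step interpolation avoids the optimism of
connecting PR points linearly; a trapezoidal option exists because
third-party tooling sometimes integrates the curve directly. AUROC is the
rank-sum identity U/(n₁n₀) with ties at half credit, and the tests assert
its equality with trapezoidal curve integration. The F1-optimal threshold
breaks ties toward the larger threshold (fewer false positives).
Cross-validation is unstratified k-fold with a recorded fold seed
(mirroring the fold-creation default in the protocol's tooling); folds are
redrawn, up to a cap, if a held-out fold is single-class or contains a
gene missing from its training folds; per-fold F1 uses the fixed 0.5
threshold. Comparator-tool benchmarking deletes missing scores pairwise
per tool (counts reported) and normalises score direction through an
orientation map (SIFT-style scores, where lower means damaging, are
negated).

## Synthetic data generator

The generator emulates the structure of the real inputs: per-gene variant
counts from a negative binomial (default mean 238, dispersion 1.2, ~216
genes ≈ 51k variants, echoing the ClinVar-scale dataset); class
proportions defaulting to 6.13% LP/P, 88.50% VUS, 5.37% LB/B (the printed
composition 3,149/45,442/2,755); REVEL from class-conditional Beta
distributions; four conservation scores driven by a shared latent
constraint draw per variant so they are positively correlated; and
zero-truncated geometric tumor counts, with the geometric parameter
divided by a multiplier (default 4) for pathogenic overlapping variants.

Overlap enrichment is parameterised on the odds scale: non-LP/P variants
overlap with probability r (default 0.0055) and LP/P variants with the
probability whose odds are e^θ times greater (θ defaults to ln 28.3), so
the population log odds ratio equals θ exactly and odds-ratio recovery is
unbiased in expectation. A small fraction of variants (2%) receive a
second nucleotide representation of the same amino-acid change to
exercise grouping. The hotspot catalogue contains every overlapping
variant plus 2.5× as many hotspots absent from the germline table.

What the generator does **not** emulate: tumor-type composition,
sequencing error, per-gene heterogeneity in the overlap effect,
correlation between REVEL and the conservation scores beyond class
membership, and the curation noise of real ClinVar assertions. Passing
parameter-recovery tests therefore demonstrate the estimators and
pipeline plumbing are correct under the stated model, not that real-data
effect sizes will match.

### Parameter recovery and the identifiable estimand

The recovery suite asserts that generate → annotate → build training set →
weighted logistic fit returns the configured log odds ratio. The fit used
for this assertion is the overlap-only weighted logit: in the full
8-predictor model the tumor-count features are non-zero only for
overlapping variants (collinear with the flag) and logistic coefficients
are non-collapsible, so the marginal log-OR is not the full model's
estimand. Because overlap is assigned conditionally on LP/P status only,
and the VUS REVEL filter and 1 − REVEL weights are independent of overlap
within the non-LP/P stratum, the overlap-only coefficient equals the
marginal log odds ratio in expectation. The suite uses 20 seeded cohorts
of ≈ 50,000 variants and requires the mean estimate within ±0.15 of the
target; a 100-replicate check additionally requires the Woolf 95% CI to
cover the target odds ratio in ≥ 90 replicates.

## Numerical and degenerate-input choices

- Contingency scenarios with an empty margin, single-class ROC/PR inputs,
  empty rank-sum groups, and whitelists with no genes raise errors rather
  than returning conventional values.
- ROC over heavily tied integer counts uses the rank-sum tie convention
  (half credit); the single operating point is chosen by the Youden index,
  the standard criterion when none is otherwise specified.
- The COSMIC-style recurrence filter uses a strict `> min_samples`
  inequality and tests absence from the hotspot catalogue at the
  (gene, protein-change) level, matching how hotspots are defined.
- Table parsing is total: each row becomes a record or an enumerated
  rejection, and the two always sum to the input row count.

## Known limitations

- The logistic model cannot score genes absent from its training set; use
  the forest for out-of-gene prediction.
- Evidence calibration maps likelihood ratios to bands only; no
  prior-dependent posterior probability of pathogenicity is computed.
- The spreadsheet reader requires an explicit column mapping and never
  guesses headers.
- One record per variant is assumed; collapsing multiple transcript
  annotations is out of scope.
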