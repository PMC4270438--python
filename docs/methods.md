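# Methods

This note documents the statistical models implemented in `prelsc`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about behaviour on real data.

## Single-hit Poisson limiting-dilution model

Engraftment of a transplanted inoculum is modelled as requiring at least
one functional stem cell: with frequency *f* (stem cells per transplanted
cell) and dose *d*, P(negative) = exp(−*f·d*). A dilution cohort —
per-dose counts *k·/n·* of engrafted/tested recipients — gives the
binomial log-likelihood

ℓ(f) = Σᵢ [ kᵢ log(1 − e^(−f·dᵢ)) − (nᵢ − kᵢ) f·dᵢ ].

ℓ is concave in *f*, so the MLE is found as the unique root of the score
function by bracketed root-finding (Brent) on [10⁻⁹, 1] per cell, with
relative tolerance 10⁻¹⁵; for a single dose this reproduces the closed
form −ln(k_neg/n)/d to floating-point accuracy. Confidence intervals
invert the likelihood-ratio statistic at the χ²(1) quantile
(profile-likelihood intervals), solved on the log-frequency axis. Boundary
cohorts are flagged rather than silently extrapolated: all-negative
cohorts return f̂ = 0 with an upper bound only (ℓ is linear there, so the
bound is χ²/2 ÷ Σnᵢdᵢ in closed form); all-positive cohorts return f̂ at
the upper search bound with a lower bound only.

Positivity of a recipient is strict: reconstitution > 1% (configurable).

**Frequency ratios.** The fold-change between two genotypes is
f̂ₐ/f̂_b. Each profile interval is converted to a log-scale standard error
(half-width over the normal quantile) and the two are combined in
quadrature, treating cohorts as independent. This normal-on-log
approximation is simple and symmetric; simulation at the transplantation
design shows its 95% interval covers true 5-, 20- and 60-fold differences
in ≈94–96% of replicates.

**Calibration caveat.** Likelihood-ratio intervals on discrete engraftment
counts are slightly anti-conservative when only two or three doses are
informative: at the standard design (doses 10⁷…10², 7 recipients per dose)
and a true frequency of 10⁻⁵ the 95% interval's true coverage is ≈93.5%.
The acceptance checks therefore measure coverage with a large replicate
count (20,000 cohorts) so the estimate reflects the method rather than
Monte-Carlo noise.

**RU / CRU / MAS.** RU = donor-derived cells ÷ competitor host cells in
the recipient thymus; both counts are caller-supplied because the gating
of "competitor" cells is a lab convention. CRU is defined per inoculum:
an inoculum of *N* cells contains *N·f̂* CRU (the literature speaks of
"~1 CRU" doses; the package exposes both the per-cell frequency and the
per-inoculum CRU). MAS = RU / CRU exactly.

## Transition fold changes and trajectory profiles

Expression matrices are linear-scale, genes × ordered stages, optionally
with replicate columns per stage. Replicates are averaged per stage before
the ratio, so fc(g, t) = mean(stage t+1)/mean(stage t); fold changes
telescope exactly across consecutive transitions. Up-regulation is strict:
fc > 1.3 by default, so a gene at exactly 1.3-fold is not counted. A gene
set's trajectory profile is the percentage of its *detected* members
(set ∩ expression universe — the denominator choice matters for sets with
absent members) above threshold at each transition, with the same statistic
over the whole universe as background.

The detection filter replaces probe-level absent/present calls with an
intensity floor: a gene is kept iff its mean exceeds the floor in at least
one condition. It is order-preserving and idempotent. Probe-level
microarray preprocessing (RMA/MAS5) is out of scope; matrices are accepted
already normalised.

## Rank Products

For groups with n_a and n_b replicates, all n_a × n_b pairwise
comparisons are ranked by fold change (rank 1 = most changed in the tested
direction; up and down are analysed separately) and combined as the
geometric mean RP(g). The permutation null shuffles gene labels
independently **within each replicate array** and recomputes every
comparison's ranks. This matters: comparisons share arrays, so their ranks
are positively correlated, and a null that draws independent ranks per
comparison underestimates the tail of small rank products, inflating
significance (we measured ~3% of null genes at pfp < 0.01 under that
simplification, versus ≲0.1% with array-wise permutation). With E(g) the
average number of null rank products at or beyond RP(g) per permutation,
pfp(g) = E(g)/position(g) where position is the gene's 1-based rank-product
order. The exactness of this scheme is verified against a full enumeration
of the array-permutation null on a 5-gene, 1-vs-2-replicate fixture.
Default 10⁴ permutations; a seed is mandatory in the CLI.

## ΔΔCt and RPKM correlation

Relative RT-qPCR expression is 2^(−ΔΔCt) with
ΔΔCt = (Ct_target,test − Ct_ref,test) − (Ct_target,ctrl − Ct_ref,ctrl),
the reference being a housekeeping gene such as β-actin. RPKM correlations
are Pearson on log2(x + 1)-transformed values by default (pseudocount 1.0
— the convention is not universal, so it is a parameter); cross-sample
normalisation is left to the caller (default none).

## Promoter-window peak assignment

BED intervals are 0-based half-open throughout; GFF3 (1-based inclusive)
is converted on read, with the TSS at `start` on + and `end` on − strands.
A gene is a regulator's target iff at least one peak intersects the
**closed** window [TSS − w, TSS + w], default w = 2000 bp. The window is
symmetric and strand-agnostic (strand only locates the TSS); a nearest
edge at 2,000 bp is in, 2,001 bp is out. Boundary inclusivity at exactly
w is a convention — closed was chosen and is documented here. One primary
TSS per gene (first annotated wins; alternatives are logged). Assignment
uses an interval tree per chromosome and is verified against an all-pairs
distance scan.

Multi-dataset merging: interval union pools peaks before assignment;
gene-level intersection assigns per dataset and intersects the target
sets (the "peaks common in two cell lines" rule). Intersection is defined
on gene sets rather than base pairs because the downstream unit is the
gene list; it is commutative and associative.

## GSEA

The ranking metric is caller-supplied scores (for two-condition designs
without replicates, log2 fold change is the natural choice, and gene-label
permutation is used because phenotype permutation is impossible at n = 1).
Hit increments are |score|^w normalised over hits (w = 1 default; w = 0
gives the classic Kolmogorov–Smirnov statistic), miss decrements uniform;
ES is the running sum's signed extremum, |ES| ≤ 1. When the number of
same-size placements C(N, k) does not exceed the permutation budget the
null is enumerated exhaustively and the p-value is exact; otherwise random
subsets are drawn with the add-one estimator. FDR across a collection is
Benjamini–Hochberg on the permutation p-values.

## Hypergeometric overlap

One-sided tail P(X ≥ overlap) for each compendium set, BH-adjusted across
the compendium; "enriched" is strict adjusted p < 0.05. Zero overlap gives
p = 1 under this tail convention.

## Candidate intersection filter

Steps: (1) regulator-bound ∩ pathway-responsive; (2) strict fold gate at a
named transition; (3) membership in the union of self-renewal resources
(union because no AND semantics is implied by "present in resources"; a
flag can require all); (4) optional stage exclusion: drop a gene whose
mean expression at a named refractory stage (DP) is ≥ 0.8 × its own
trajectory maximum. The 0.8 fraction is configurable; the exclusion of
candidates that stay high in DP cells is inherently qualitative, and this
rule is its declared, reproducible form. Survivor sets are asserted to be
nested at every step.

## Synthetic data: what it emulates, and what it does not

* **Dilution cohorts** follow the exact single-hit Bernoulli model on the
  standard schedule (10⁷, 10⁶, 10⁵, 10⁴, 10³, 10² cells; 7 recipients per
  dose). Positive recipients draw reconstitution uniform(5, 90)%, negative
  uniform(0, 1)% — only the >1% dichotomy matters downstream. Real
  experiments add litter effects, irradiation variability and
  dose-preparation error that the simulator omits, so passing coverage
  checks validate the estimator under its own model, not robustness to
  model violation.
* **Stage matrices**: planted sets multiply by 1.5 per transition up to a
  DN3a peak, then by 0.5 per transition (the rise-then-fall shape of
  NOTCH-driven targets across thymocyte differentiation); background genes
  are flat at 100 intensity units; noise is multiplicative log-normal,
  independent per gene × column (no gene–gene correlation, no
  stage-specific variance). Effect 1.5 sits comfortably above the 1.3
  screening threshold; noiseless runs must recover planted sets exactly.
* **Peaks**: targets receive one 200 bp peak wholly inside the ±2 kb
  window; decoys sit at least one window-width outside it.
* **RPKM tables**: planted pairs are bivariate normal on the log2 scale
  (mean 5, sd 1) with the requested correlation, exponentiated.

All generators are pure functions of (parameters, seed).

## Problem sizes and numerical choices

The verification scripts use: 20,000 simulated cohorts for CI coverage
(Monte-Carlo sd ≈ 0.18 percentage points) at true frequency 10⁻⁵; 400
cohort pairs per fold level (5/20/60) for ratio recovery; 10⁴ permutations
against the exact 5-gene Rank Products enumeration plus 50 null runs of 20
genes × 3+3 replicates at 10³ permutations; all C(6,2) GSEA placements;
1,000 × 1,000 peak/gene fixtures for assignment; 400-gene noiseless
matrices for end-to-end filter recovery; 3,000-gene background matrices
(noise sd 0.3, natural-log scale) against the analytic log-normal tail
P(fc > t) = 1 − Φ(ln t / (σ√2)).

Root-finding tolerances: score root at rtol 10⁻¹⁵; profile bounds at
xtol 10⁻¹³ on the log axis. Ties in ranks use average ranks. Degenerate
inputs (zero tested recipients, non-positive stage means, zero-variance
correlation, empty gene sets, mixed-regulator merges) raise typed input
errors; statistical boundaries (ratios or MAS of boundary estimates) raise
a distinct boundary error that the CLI maps to exit code 3.

## Known limitations

* The ratio CI is a normal approximation on the log scale; exact
  profile-likelihood ratio intervals would be preferable at very small
  cohorts but need a joint profile over both cohorts.
* Rank Products pfp is a point estimate; no uncertainty on pfp itself.
* GSEA FDR is BH on permutation p-values, not the ES-distribution FDR of
  the original GSEA software; with few sets the two can differ.
* One TSS per gene ignores alternative promoters; genes whose relevant
  promoter is not the first annotated one can be missed.
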