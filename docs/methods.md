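# Methods

## The lineage model

Each scored hemisegment (A2–A8, left and right) is modeled as two
independent lineages:

* **Svp lineage.** An early division produces `k` Svp progenitors:
  `k = 2` with probability `1 − r_early`, and `k = 1` or `k = 3` with
  probability `r_early/2` each (the one-or-three-progenitor failure mode).
  Each progenitor then divides asymmetrically: with probability
  `1 − r_asym` it yields one Svp-CC and one Svp-PC; with probability
  `r_asym` it fails, choosing a mode from `asym_mode_weights`:
  two CCs and no PC, two PCs and no CC, or — karyokinesis failure — a
  single undivided cell scored as one enlarged Svp-CC and no PC.
* **Tin lineage.** Two progenitors in A2–A7, one in A8. Each yields two
  Tin-CCs with probability `1 − r_sym`; a failure yields one cell
  (no division) or three (an extra division) per `sym_mode_weights`.

Hemisegments are independently unscoreable with probability `r_dropout`;
unscoreable hemisegments carry no counts and never enter a denominator.

Parameters are per-division probabilities in [0, 1]. Defaults are all
zero (wild-type); the mode weights default to uniform, since the relative
frequencies of the failure modes are not characterized — analyses that
depend on them should vary the weights. Two analytic identities are used
throughout testing and calibration: the earlier-defect frequency equals
`r_early` exactly, and the probability that a hemisegment deviates from the
(2 CC, 2 PC, 0 enlarged) pattern is
`π(r) = 1 − (1 − r_asym)² − 2 r_asym² w_cc w_pc`
(the second term is the one configuration of two simultaneous failures —
one both-CC, one both-PC — that restores the wild-type counts).
`asym_rate_for_defect_prob` inverts this quadratic so cohorts can be built
with exactly additive, or exactly super-additive, per-hemisegment defect
probabilities.

### Assumptions and what the generator does not emulate

* The scored region is A2–A8 only (14 hemisegments per embryo); anterior
  heart segments are not modeled. The wild-type A8 pericardial complement
  is assumed to be two, matching A2–A7; only the Tin complement is
  truncated there.
* Division errors are independent across progenitors, hemisegments and
  embryos; dropout is uniform. Real unscoreable hemisegments may be
  systematically located, and real error rates may vary between embryos
  (staging, genetic background) — such overdispersion would widen the
  embryo-level response distribution, which the permutation tests tolerate
  but the analytic rate identities do not describe.
* Cell positions, nuclear-size measurement error, and fate-switching
  between Svp and Tin identities are out of scope. Passing tests therefore
  demonstrate correctness of the scoring and inference machinery under the
  lineage model, not robustness to segmentation or staining artifacts.

### Reproducibility

All randomness derives from one integer seed. Each hemisegment draws from
its own substream keyed by (seed, CRC-32 of the genotype label, embryo
index, hemisegment index), so cohorts are bit-reproducible and independent
of generation order, and adding a genotype to a design does not perturb
the others.

## Defect classification

The Tin rule is direct: a hemisegment is symmetric-defective iff its
Tin-CC count differs from the segment expectation (4 in A2–A7, 2 in A8).

The Svp rule reasons over lineage histories. For an observed triple
(n_svp_cc, n_svp_pc, n_enlarged), all histories with `k ∈ {1, 2, 3}`
progenitors and per-progenitor outcomes in {normal, both-CC, both-PC,
karyokinesis failure} are enumerated; those reproducing the triple are the
consistent explanations. Each explanation's error weight is
`|k − 2|` plus the number of failed asymmetric divisions, and only the
minimal-weight explanations inform the call — the most parsimonious
mechanization of expert scoring. Then:

* `earlier` is true iff every minimal explanation has `k ≠ 2`, false iff
  none does, and UNKNOWN when they disagree;
* `asymmetric` likewise from the presence of failed outcomes;
* `svp_lineage` is true whenever the minimal weight is positive (any
  anomaly, attributed or not);
* an empty explanation set (e.g. (2, 1, 0) under strict marker semantics,
  or any triple requiring `k ≥ 4`) is flagged `inconsistent`, which also
  counts as an Svp-lineage anomaly.

`enlarged_marker_reliable` (default true) requires the number of
karyokinesis failures in an explanation to equal the observed enlarged-CC
count. When false — for microscopy that may miss enlarged nuclei —
explanations with at least the observed number are admitted, which makes
triples like (2, 1, 0) explainable as a missed karyokinesis failure.

Without pericardial visualization, attribution is impossible by
construction: the CC-only classifier flags `svp_lineage` iff the Svp-CC
count differs from two and leaves `asymmetric`/`earlier` UNKNOWN.

Per-embryo summaries divide flagged hemisegments by scoreable
hemisegments per category. UNKNOWN never counts toward `asymmetric` or
`earlier`, but the underlying anomaly still counts toward `svp_lineage`
and `any`; a hemisegment defective in both lineages contributes to both
category numerators. Embryos with zero scoreable hemisegments are excluded
with a logged warning.

## Permutation inference

Defect proportions are bounded, tie-heavy and heteroscedastic, so
coefficients are tested by permutation rather than t/F statistics, with
`p = (n + 1)/(N + 1)` and the exceedance rule counting permutation
estimates that **equal or exceed** the observed one (ties count; the
"less" and "two-sided" alternatives use the analogous rules). The default
`N = 10⁶` is overridable; the sampled test is validated against exhaustive
enumeration of all label assignments on small designs.

* **Two-group.** `Y_j = β0 + β1 I_j + ε_j`; β1 is the difference of group
  means; permutations shuffle genotype labels with group sizes preserved.
* **Interaction (synergy).** `Y_j = β1 Ip_j + β2 Iq_j + β3 Ip_j Iq_j + ε_j`
  without intercept, fit over the two single-heterozygote groups and the
  double-heterozygote group only. With those three groups the model is
  saturated: β1 and β2 are the single-het means and β3 is the double-het
  mean minus the additive expectation β1 + β2. Wild-type embryos do not
  enter the fit: a (0,0) group would unsaturate the no-intercept model and
  force the wild-type baseline to zero defects, changing the meaning of
  every coefficient. An optional intercept mode exists for sensitivity
  analysis. The default alternative is "greater" for both tests (a defect
  excess, and synergy as excess over additivity).

**Smith procedure.** The interaction column `Ip·Iq` is orthogonalized
against the main-effect columns, `Z_res = Z − X(XᵀX)⁻¹XᵀZ`, and the
observed statistic is the coefficient on `Z_res` — identical to the OLS β3
by Frisch–Waugh. Permutations shuffle the entries of `Z_res` while Y, Ip
and Iq stay fixed, and each shuffled column's coefficient is computed
against the nuisance-residualized response at the column's original scale,
`β3* = ⟨Z*_res, Y_res⟩ / ⟨Z_res, Z_res⟩`. Under the additive null the
nuisance-projected response is exchangeable against the shuffled column,
so this variant is exact; the alternative of re-fitting the full OLS per
shuffle re-residualizes the permuted column, systematically shrinking its
norm and inflating permuted |β3*|, which makes that variant measurably
conservative (size ≈ 0.023 at α = 0.05 under a Gaussian additive null,
versus ≈ 0.049 for the variant used here).

### Numerical choices

* Exceedance comparisons use a tie tolerance of `1e-9` times the
  statistic's scale. Proportion responses live on a lattice, exact ties
  are the norm, and the vectorized recomputation of a tied statistic can
  round a few ulps to either side; without the tolerance, dropped ties
  make the test anticonservative. The tolerance is far below the smallest
  non-tied statistic spacing (≈ 1/(14·14) for 14-embryo cohorts).
* A permuted interaction column that lands in the span of the main
  effects has no coefficient; its NaN statistic never counts as an
  exceedance.
* Permutations are sampled in vectorized blocks of 50 000 from a seeded
  generator; the seed is recorded in every result.

### Calibration and power (operating characteristics)

`cardiodiv.calibration` measures rejection rates over replicate simulated
cohorts run through the full pipeline. At the study design — 14 vs 14
embryos, N = 2000 permutations, α = 0.05 — the measured type-I error is
≈ 0.033 for the two-group test (r_sym = 0.05 in both groups) and ≈ 0.039
for the Smith test under exactly additive per-hemisegment defect
probabilities (0.05, 0.08, 0.13). Both sit slightly below nominal, the
expected discreteness cost of the equals-or-exceeds rule on tie-heavy
proportions; the acceptance checks bound the size within [0.03, 0.07]
with a two-standard-error Monte-Carlo allowance on the estimate. Power to
detect r_asym = 0.25 vs 0.02 in the Svp-lineage category at the same
design is ≈ 1. Replicate counts (2000 for size in the test suite, 500 in
the acceptance script, 200 for power) balance Monte-Carlo error against
runtime.

## Expression screening

Gating uses strict inequalities throughout — activated:
`log2FC < −threshold`, repressed: `log2FC > threshold`, both with
`FDR < 0.1`; boundary values are excluded. The sign convention is the
mutant-vs-wild-type contrast (negative fold change = activated by the
regulator); a flag flips it for contrasts coded the other way. The
low-expression exclusion removes the `⌊fraction·n⌋` lowest-log2CPM records
(default fraction 0.30) with ties broken by stable input order.
2^−ΔΔCT averages technical replicates on the CT scale before computing
ΔCT — a common convention where no aggregation rule is stated — and Welch
one-tailed t-tests (Welch–Satterthwaite degrees of freedom) assess
significance. The packaged 21-row table carries the published
log2FC/p/FDR values of the phenotypically screened genes; it has no
log2CPM column, so the low-expression filter applies only to full DE
tables.

## Target triage

Coordinates are 0-based half-open (BED convention); GFF3 input is
converted on read, and strand is ignored for territory construction. A
gene's search territory is its introns (span minus exons) plus the two
intergenic intervals bounded by its immediate neighbors; abutting
neighbors contribute no interval, and gene models without exon structure
fall back to the whole gene body with a warning (a conservative superset
of the introns). Peaks partially overlapping the territory count as
inside. Two peaks are clustered when the gap between them is at most
`max_gap` bases (overlap = gap 0). No clustering distance is established
for this criterion in the literature, so the default is `max_gap = 0`
(required overlap) — the strictest reading — with the gap configurable
and recorded in the output; direct calls are monotone non-decreasing in
`max_gap` by construction. A gene is `direct` when a focal-TF peak
clusters with ≥ 1 partner-TF peak in the territory, `jumu_only` when the
focal peak is isolated, `no_jumu_peak` otherwise.

## Known limitations

* UNKNOWN category attributions are recorded but unresolvable without
  pericardial data; studies needing the asymmetric/earlier split must
  score with the lineage reporter.
* The interaction model assumes the three genotype groups share the
  no-intercept parameterization; heteroscedasticity across groups is
  handled by the permutation scheme's exchangeability argument only under
  the null, as with all such tests.
* The simulator's independence assumptions make its analytic rate
  identities exact; real data with embryo-level rate variation will show
  overdispersed proportions, for which the per-embryo response (rather
  than pooled hemisegment counts) is precisely the defensible unit of
  analysis.
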