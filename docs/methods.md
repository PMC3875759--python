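# Methods

## Relative quantification

The comparative-Ct model assumes ideal (doubling-per-cycle) amplification:
RQ = 2^−ΔΔCt with ΔCt = Ct_target − mean(Ct of reference genes) within a
sample and ΔΔCt differenced between a patient's tumor and normal samples.
No amplification-efficiency correction is applied; if probe efficiencies
deviate from 2, fold changes are biased multiplicatively and should be
calibrated upstream.  Reference genes are declared by the caller (the
dataset carries them explicitly); ΔCt uses their per-sample arithmetic mean.

**Aggregation.** Per-gene fold changes are summarized as the median RQ
across informative pairs.  For an odd number of pairs this equals
2^−median(ΔΔCt) (the median commutes with the monotone transform); for even
counts the midpoint is taken on the RQ scale, which differs from
exponentiating the midpoint ΔΔCt — the RQ scale is the reported quantity, so
the midpoint is computed there.  The signed-fold display transform maps
RQ < 1 to −1/RQ so that magnitudes are always ≥ 1-fold and the sign encodes
direction.

**Censoring.** A Ct that never crossed threshold ("undetermined") is imputed
at `max_cycles` (default 40, the last cycle) when the other member of the
pair amplified; this caps the fold change at the detection limit instead of
producing an infinite estimate, while preserving direction.  If both members
are undetermined the pair is non-informative for that gene, and a gene with
zero informative pairs is excluded as not evaluable.  An undetermined
*reference* gene is a hard error: the normalization anchor is meaningless
and imputation there would bias every gene in the sample.

**Classification.** Genes with median RQ strictly above the fold threshold
(default 4) are "up", strictly below the reciprocal "down", otherwise
unchanged; boundary values are deliberately unchanged (strict inequality).
Inhibitors are classified but excluded from protease list statistics;
non-protease homologues count as proteases.  Ranked lists order by
|signed fold| descending with an alphabetical tie-break for determinism.

## Sample QC

Pairs are excluded when either member's RNA Integrity Number falls below
`rin_min` (default 7, inclusive: RIN = 7.0 is retained).  The design is
paired, so one bad member removes the whole pair.  Missing RIN values pass
with a warning — absence of a quality score is not evidence of degradation,
and callers can require the column upstream if they disagree.

## Exact statistics

Implemented from first principles in `stats.py`, with log-gamma factorials
throughout (no factorial tables, no overflow at array-scale counts):

* **Hypergeometric pmf** in log space; out-of-support k returns 0.
* **Fisher exact**: one-sided sums the upper tail of cell `a` (enrichment);
  two-sided sums every same-margin table whose probability is ≤ the observed
  table's, with a 1+1e−7 tolerance factor guarding float equality at ties —
  the convention of mainstream implementations.  Zero-margin tables are
  untestable and return p = 1 with a warning.
* **Mann–Whitney–Wilcoxon** (the default, unpaired rank-sum variant —
  appropriate because the group sizes in proliferation and validation
  comparisons differ): exact p from the rank-sum counting recurrence when
  the pooled size is ≤ `exact_limit` (default 12) and there are no ties,
  otherwise a normal approximation with tie-corrected variance and
  continuity correction.  The one-sided p is the tail in the observed
  direction; two-sided doubles it (the null distribution is symmetric).
  A paired signed-rank variant is provided but is not the default.
* **Two-proportion z** (pooled variance, one-sided) with the companion
  one-sided Fisher p reported alongside, because at n = 50 per list the
  exact test is the natural check on the normal approximation.  A degenerate
  pooled variance (0% or 100% in both groups) yields z = 0, p = 0.5.

The test suite holds these to independent oracles: exhaustive
exact-fraction enumeration of all 2×2 tables with total ≤ 12, full labeling
enumeration for rank-sum samples with m+n ≤ 10, scipy equivalents, and a
10,000-replicate null simulation confirming the Fisher test's conservatism.

## Enrichment and cross-referencing

The enrichment table is [[list_EC, list_IC], [bg_EC − list_EC, bg_IC −
list_IC]]: the list is subtracted from the background row so the rows are
disjoint, the standard contingency construction when the list is a subset of
the probe universe.  The default background is the array content (266
extracellular / 264 intracellular probes); the tissue-expressed background
(219/255) is selectable.  EC-S and EC-TM collapse to one extracellular
compartment.

Cross-referencing intersects a ranked top-n list with a mutation catalog
(set semantics, case-insensitive) and reports the hit proportion on the
*declared* n — even when fewer than n list members are known.  The shipped
top-50 fixtures are partial reconstructions (24/50 up, 36/50 down: the
published table prints only genes above the 4-fold threshold, plus four
members named in prose), and the n = 50 denominator keeps the proportions on
the published 7/50 = 14% and 2/50 = 4% arithmetic.  The direction comparison
is one-sided (down > up), reporting both the pooled z and the exact Fisher
p; which exact variant produced the published down-list enrichment p is not
stated in the source, so both are always recorded in reports.

## Xenograft growth model

Response: log(volume + 1) for caliper series (tolerates zero volumes before
palpable tumors), log for photon flux and normalized ratios.  Model: fixed
effects intercept, day, group, group×day; a random intercept per flank;
independent residuals.  Flank is the unit of analysis (each mouse
contributes two flanks); a mouse-level random effect is deliberately
omitted — at 4–8 flanks per group it is not identifiable, and random slopes
are likewise unsupported by the design.  The fit maximizes the marginal
likelihood by profiling out the variance ratio λ = σ²_flank/σ²_resid: for
fixed λ the covariance is block diagonal (I + λJ per flank), so GLS reduces
to per-flank sums via the Woodbury identity and the profile is optimized by
scalar search over log λ with the λ = 0 (OLS) boundary checked explicitly.
Agreement with an established general mixed-model implementation is verified
in the tests to ~1e−6 on fixed effects and the likelihood-ratio statistic.

The group effect is the 2-df likelihood-ratio test of the group and
group×day terms.  The chi-square reference is asymptotic; the
permutation variant re-randomizes flank-to-group assignments (≥999 by
default) and uses the same statistic, with p = (1 + #{perm ≥ obs})/(1 +
n_perm), exact under exchangeability of flanks.

## Synthetic-data generator

The paired-Ct generator emulates the study design it is meant to test: 14
tumor/normal pairs, a ~600-gene panel with designated reference genes,
per-gene baseline ΔCt uniform on 4–12 cycles (moderate-to-low expression),
tumor ΔCt shifted by the spiked log2 fold, Gaussian technical noise on every
Ct (default sd 0.5 cycles), and censoring of Ct values beyond cycle 40.
Per-sample effects cancel by construction through reference normalization in
the paired design; a patient-specific tumor-effect sd (default 0.3 cycles)
models biological heterogeneity that does not cancel.  Spiked |log2 fold|
magnitudes follow a shifted exponential (min 1 + Exp(1.5)) so some spikes
straddle the 4-fold threshold and exercise boundary behavior.  Mutation
catalogs include true-down genes with probability 0.14 and true-up genes
with 0.04, mirroring the proportions the cross-referencing stage should
recover.  Ground truth is returned as a separate object and never written
into the data files the pipeline reads.

What the generator does *not* model: amplification curves (Ct is atomic),
probe efficiency variation, plate/batch effects, RNA-quality gradients
correlated with expression, and inter-gene correlation.  Passing recovery
tests therefore demonstrates correctness of the estimator arithmetic and
calibration of the tests under the stated noise model — not robustness to
efficiency artifacts or batch structure in real plates.

## Problem sizes and numerical choices

* Spike-recovery check: 600 genes (40 up / 60 down spikes at |lfc| ≥ 3), 14
  pairs, sd 0.5, 100 seeds — large enough for stable sensitivity estimates
  while keeping the default test run fast.
* Permutation null calibration: 500 simulated null experiments at 6 flanks
  per group, 5 time points, 199 permutations each; 199 gives a p-value grid
  of 1/200, ample for checking the rejection rate against a [0.03, 0.07]
  band.  The API default remains 999 permutations for single analyses.
* Mixed-model profile search: bounded scalar optimization over log λ ∈
  [−12, 12], xatol 1e−8; residual sum of squares floored at 1e−300; LRT
  statistics clipped at 0 (boundary fits can come out negative by rounding).
* Fisher two-sided tie tolerance 1+1e−7; p-values clipped into (0, 1].
* Median over an even number of pairs: midpoint on the RQ scale (documented
  above).  Ties in ranked lists: alphabetical.

## Known limitations

* No multiple-testing correction anywhere: the workflow is a fold-threshold
  screen with single confirmatory tests, not a genome-wide FDR analysis.
* The ideal-efficiency 2^−ΔΔCt form; no standard-curve calibration.
* The top-50 list fixtures are partial (see above); analyses of new data
  supply complete ranked lists and do not inherit this limitation.
* The mixed model assumes a common residual variance across groups and
  days; strong heteroscedasticity (e.g., near-zero early volumes) is only
  partially absorbed by the log1p transform.
* Mutation catalogs are user-supplied gene lists; no retrieval from COSMIC
  or TCGA is attempted.
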