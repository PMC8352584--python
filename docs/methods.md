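# Methods

## The experiment being modelled

A pooled library of barcoded high-copy overexpression plasmids (one ORF per
plasmid, ~4,900 genes) is transformed into a yeast strain and grown
competitively for 10 generations under plasmid selection. Sequencing the
plasmid barcodes at generation 0 and generation 10, in 2–3 biological
replicates per strain, measures each gene's relative fitness effect when
amplified. Repeating the screen across a panel of ~15 genetically diverse
strains asks which amplification effects are universal and which depend on
genetic background.

## Normalization and imputation

Counts are normalized to reads per million within each sample (count /
column total × 10⁶). Library-size normalization is deliberately the only
between-sample adjustment: the screens have large, real composition shifts
(many genes deplete), which violate the assumptions of TMM-style methods.

A barcode present in the starting pool but absent from an end-point sample
carries real signal (extreme depletion), not missing data. The imputation
rule: per strain, a gene with normalized generation-0 count ≥
`min_norm_count` (default 20) in **all** replicates, but with zero raw
reads in a generation-10 sample, receives a pseudocount of 1 in that
sample. The affected columns are renormalized afterwards so the
column-sum invariant holds exactly (the perturbation is ≤ 1 ppm).
Loader-level `NA` cells are folded to 0 with a recorded mask; for
imputation a zero count and a masked cell are equivalent, since a zero in
count data means "no reads observed". The rule is evaluated per end-point
sample, so a gene detected in one replicate and missing in another is
imputed only where missing. The threshold applies to all available
replicates (panels include duplicate-only strains).

## Fitness scores

Replicate score = `log2(RPM_gen10 / RPM_gen0)` per (strain, replicate)
pair; the mean score averages the defined replicate scores. A replicate
score is defined only when both normalized counts are positive: a zero
starting count gives no baseline, and a zero end-point count that did not
qualify for imputation would yield −∞. `n_replicates_measured` counts
defined scores and feeds the enrichment-background rule. QC reports the
mean pairwise Pearson correlation between replicate score vectors per
strain, computed over genes defined in both replicates (≥ 10 required).
With shared true effects and independent replicate noise this correlation
estimates `var(true) / (var(true) + σ²)`.

## The negative-binomial generation test

Counts are modelled as NB with `Var = μ + φμ²`. The test is intentionally
self-contained rather than a wrapper around an external count-model
package:

1. **Dispersions.** Counts are rescaled to the mean library size; within
   each generation group the raw per-gene dispersion is
   `max(0, (v − μ)/μ²)` from the group mean and sample variance, pooled
   across groups with df weights. The common dispersion is a 5%-trimmed
   mean over genes; tagwise values shrink toward it with weight
   `n₀/(n₀ + r)` (prior weight `n₀` = 10, `r` = residual df), so small
   designs shrink harder.
2. **Effect and test.** `log2fc = log2((S₁₀/L₁₀)/(S₀/L₀))` from group
   count sums and raw library-size totals, with a Haldane 0.5 added to
   both count sums when either is zero. The delta-method standard error is
   `sqrt(1/S₀ + φΣL₀ⱼ²/L₀² + 1/S₁₀ + φΣL₁₀ⱼ²/L₁₀²)/ln 2`, and the Wald
   statistic is referred to the normal. Genes with zero counts at both
   generations are untestable (p = 1, log2fc = 0, flagged).
3. **FDR.** Benjamini–Hochberg step-up per strain; significance at
   FDR < 0.05. Direction comes from the sign of `log2fc`.

At the screen's depths (mean count ≥ ~500) the normal reference is
accurate; the test is calibrated on null simulations (≤ 1% of genes flagged
at FDR < 0.05) and recovers planted effects (≥ 80% detection of
|log2fc| ∈ [1,2] at depth 10⁶ with 3+3 replicates). The delta-method
standard error is itself checked against the empirical estimator spread.
Note an intrinsic precision limit: with 3+3 replicates at dispersion φ the
estimator's sd is `≈ sqrt(2(φ + 1/μ)/3)/ln 2` — about 0.27 log2 units at
φ = 0.05 — so point estimates carry ~±0.5 (2σ) uncertainty regardless of
depth; detection, sign and ranking are the reliable outputs.

## Gene-set taxonomy

- *Deleterious / beneficial* per strain: FDR < 0.05 and `log2fc` < 0 / > 0.
- *Commonly deleterious*: deleterious in ≥ `ceil(0.66 × S)` strains
  (10 of 15). `ceil` keeps the 15-strain case consistent.
- *Strain-specific*: significant in the focal strain and in ≤ 2 other
  strains. Other-strain significance counts either direction by default
  ("fitness effect" is direction-neutral); a direction-restricted mode is
  available. Strain exclusions (e.g. low-powered duplicate-only strains)
  are a caller choice, not hard-coded.
- *Backgrounds*: per-strain enrichment background = genes with FDR > 0.1
  and ≥ 2 measured replicates (confidently insignificant); panel-wide
  background = all measured genes.
- *Histogram*: genes binned by the exact number of strains where
  deleterious; bins partition the union of deleterious sets.

## Enrichment

Hypergeometric upper-tail p-values for term over-representation (lower
tail reported for depletion), computed in log space with `gammaln` +
`logsumexp`; full-support tails return exactly 1. Wilcoxon rank-sum for
continuous features compares the query against background-minus-query
with midranks for ties: exact by enumeration of all
`C(n+m, n)` assignments when `min(n,m) ≤ 8` and `n+m ≤ 20`, otherwise a
tie-corrected normal approximation with continuity correction. Because
functional terms overlap heavily, the primary significance rule is raw
`p < 5×10⁻⁴`; BH values across terms are reported as annotation only.
`exclude_translation` applies the same removal to query and background so
re-tests remain coherent.

## Assays

qPCR: technical-replicate Cts are averaged on the Ct scale; the
marker/reference ratio is `efficiency^(Ct_ref − Ct_target)` with
efficiency 2.0 (100%) by default, and copy number scales that ratio
through an internal-control strain of known copy number. Error
propagation note: one ΔΔCt chain with Ct noise σ has log2-copy sd
`2σ/√3` (technical triplicates); averaging ≥ 4 biological replicates is
what brings a ±20% claim to ~2σ coverage, matching the assay's design.
RPKM is `reads × 10⁹ / (length_bp × total_reads)`. Doubling time is
`1/slope` of a least-squares `log2(OD)` vs time fit over points with OD in
[0.05, 0.5] (the log-phase window the cultures are held in; ≥ 3 points
required, positive slope enforced). Relative growth is the per-replicate
ratio of doubling times. The paired t-test uses `t = mean(d)/(sd(d)/√n)`,
df = n−1; one-tailed p on a named side; zero-variance differences are
flagged degenerate.

## Synthetic-data generator

Defaults are the study conditions: 4,871 genes; 15 strains (13 triplicate,
2 duplicate-only); generations 0 and 10; NB dispersion φ = 0.1; library
sizes log-normal around 7.5×10⁶ reads (σ = 0.25); starting abundances
Dirichlet with concentration 5 (engineered pools are fairly even);
per-strain effect fraction 0.2 with private effect magnitudes uniform on
[0.5, 2.5] log2 units, 30% beneficial.

The planted commonly-deleterious set (30% of a strain's effect genes) has
gene-intrinsic deleterious effects drawn from uniform [1.5, 2.5], applied
in every strain scaled by the strain's sensitivity. The strong lower bound
is a design requirement, not a convenience: with 3+3 replicates at φ = 0.1
the per-strain log2fc estimator has sd ≈ 0.37, so a gene with a 0.5-unit
effect is detected in well under half the strains and cannot be "commonly
deleterious" in any operational sense; genes that the panel can agree on
are precisely the strongly deleterious ones. End-point barcodes whose
expected abundance falls below 20 cpm are zeroed with probability 0.5 and
masked, which makes the dropout/imputation path carry real weight in
end-to-end runs (imputed genes surface as extreme depletions, as in real
screens). Annotations are co-generated: a planted term samples genes with
a 20:1 odds ratio favouring the planted set, and continuous features
(interaction count, disorder, SNP count) are shifted between planted and
other genes.

What the generator does **not** emulate: PCR amplification bias,
read-level error, barcode cross-mapping, batch effects between replicates,
and correlated gene effects (each gene's effect is independent given the
planted structure). Passing recovery tests therefore demonstrates the
statistics are correctly implemented and calibrated under the assumed
model — not that the model captures every artifact of real screens. A
log-normal count-model option exists for robustness checks against NB
misspecification.

A strain "sensitivity" scalar multiplies all of a strain's true effects,
emulating globally stronger/weaker selection in some backgrounds,
distinct from gene-specific private effects.

## Numerical choices and degenerate inputs

- Normalized column sums are exact to 10⁻⁹ relative, including after
  imputation.
- Zero-total columns, single-replicate groups, empty backgrounds/queries,
  p-values outside [0,1], non-positive growth slopes: hard errors with the
  offending entity named.
- BH is vectorized `min`-accumulate over the sorted vector; ties are
  handled by stable sort and are exactly reproduced by the brute-force
  step-up.
- Problem sizes used by the test suite and acceptance script (2,000-gene
  single-strain simulations, 20 seeds; 20 full 15-strain end-to-end
  seeds) were chosen so the whole suite completes in a few minutes while
  keeping Monte-Carlo error well inside the asserted margins.

## Known limitations

- The Wald test loses calibration below ~20 counts per group; the screens
  analysed here are far above that, and the Haldane correction only
  stabilises the boundary cases.
- Dispersion shrinkage uses a fixed prior weight rather than estimating
  the prior from the data; with 2–3 replicates there is little information
  to do better.
- One barcode per gene is assumed; collapsing multiple barcodes per gene
  is upstream of this package.
- The imputation rule treats any zero end-point cell of a well-represented
  gene as a dropout; it cannot distinguish technical loss from true
  extinction — by design, both should be scored as strong depletion.
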