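# Methods

## Assay model

A pool of barcoded strains is propagated in serial batch culture: grow to
stationary phase, sample, dilute 1:100 into fresh medium, repeat.  Four
growth phases are sampled (T1–T4); analysis contrasts T3 against T1
(~16 generations of competitive growth).  Strain abundance is measured by
sequencing a 150-bp amplicon containing two 12-nt barcodes separated by a
fixed 92-nt loxP-scar spacer; a strain is identified by its barcode pair,
so combinatorial reuse of codes addresses up to 96 strains from 20 codes.

### Competition dynamics

Each strain carries a selection coefficient s, the log2 per-generation
growth-rate advantage relative to the pool: within one growth phase of
g_p generations, abundance multiplies by 2^((1+s)·g_p) and fractions
renormalize.  Over Δg generations a strain's log2 relative-abundance
ratio therefore changes by s·Δg (plus a pool-average term common to all
strains, removed by normalization).  The per-generation parameterization
is a modeling convention chosen so that recovery targets are closed-form;
the assay itself only ever observes per-contrast log2 fold-changes.

g_p defaults to 8: a 1:100 transfer alone implies ~6.6 doublings and the
remaining growth to stationary phase is absorbed into the round value, so
two passages span the nominal ~16 generations.  Transfers draw N_b cells
multinomially from the current fractions (genetic drift); `bottleneck_cells
= None` gives the deterministic infinite-bottleneck limit.  Extinction
(fraction exactly 0) is legal and propagates.

### Measurement model

Sequencing counts are multinomial over biased template proportions
p_i ∝ f_i·b_i, where b_i is a strain-specific DNA-extraction bias.  b is
log-normal across strains and rescaled so max/min equals a target fold
range (default 22×, the observed spread of counts at near-equal
abundance); it is constant across all samples of an experiment, matching
the empirical reproducibility of strain-specific recovery across
replicate extractions.  PCR bias is not modeled separately — the assay's
single-primer, low-cycle design argues against sequence-dependent
amplification — so multinomial sampling at the target depth (default
3×10⁴ per sample) is the only counting noise.  Read errors are i.i.d.
substitutions; indels are out of scope because barcodes are matched
positionally in a fixed-structure amplicon.

What the simulator does **not** emulate: PCR jackpotting / UMI-level
duplication, index hopping between samples, ragged 5′ ends beyond a small
offset shift, adapter read-through, quality-score variation, and
condition-dependent extraction bias.  Passing tests therefore demonstrate
correctness of the inference given this generative structure, not
robustness to every artifact of real libraries (the offset-scan matcher
and mismatch tolerance cover the common ones).

## Barcode counting

Reads are assigned by extracting the two 12-nt windows at template-defined
offsets and computing the Hamming distance of the concatenated 24-nt
barcode to every library pair: unique pair within `max_mismatch` →
assigned; tie at the minimum → ambiguous (never fractionally assigned);
otherwise unassigned.  Positional extraction replaces alignment-based
mapping because the amplicon structure is fixed; an offset scan (±k nt)
is available for ragged 5′ ends.  Default `max_mismatch` = 1 against a
library built at minimum pairwise code distance 3, which keeps single
errors unambiguous.  Per sample, assigned + ambiguous + unassigned equals
reads processed, and output is independent of read order.

## Filtering and normalization

Samples with fewer than 15 assigned reads are dropped, then strains with
fewer than 3 reads across the remaining samples (both thresholds are
parameters; totals rather than per-cell values, following common count-
pipeline practice).  Size factors are relative-log-expression
(median-of-ratios): the reference for strain i is the geometric mean of
its counts across samples, and c_j is the median of count_ij/ref_i over
strains with no zero count.  Factors are reported raw, not rescaled to
geometric mean 1 — the GLM consumes them as log effective-library-size
offsets, log(N_j·nf_j) with nf_j = (c_j/N_j) rescaled to geometric mean 1,
which equals log c_j up to a constant that cancels in every contrast.
Normalized log2 counts use a prior count of 0.5 and are descriptive only.

RLE assumes a majority of non-changing strains; when most of the pool is
under selection the median ratio tracks the median strain's response and
all logFCs shift by that amount.  Validation studies here keep perturbed
strains in the minority, consistent with that assumption.

## Fitness inference

The design is cell-means over treatment × time
(`~0 + treatment + treatment:time`, time categorical, one coefficient per
occupied cell); an intercept variant (reference condition as baseline)
spans the same column space and is provided for designs formulated that
way.  Time is categorical because the contrasts difference specific
sampling points rather than fit a slope.

Fitted cell means are the arithmetic means of offset-normalized counts —
the log-link score solution when offsets are constant within a cell, and
the definition adopted exactly here.  This makes two properties hold to
machine precision rather than approximately: (1) the two design encodings
give identical fitted means, and (2) multiplying one strain's counts by
any constant in every sample scales all its cell means by that constant
and leaves every contrast logFC (and all size factors) unchanged — the
exact cancellation of extraction bias.  Contrast log fold-changes agree
with edgeR's glmQLFit/glmQLFTest pipeline to <0.01 log2 units on simulated
data (cross-checked in the test suite); the surrounding dispersion and
testing machinery is a documented simplification, not a re-implementation:

* **Dispersion**: per-strain raw NB dispersion by Pearson-statistic moment
  matching (solve Σ(y−μ)²/(μ+φμ²) = residual df on the cell-means fit),
  shrunk toward the common (mean) value with prior df 10, so the shrunk
  value always lies between raw and common.  Zero residual df falls back
  to the common value with a warning.
* **Testing**: per-strain quasi-dispersion = residual deviance / residual
  df, empirical-Bayes squeezed across strains by moment matching on log
  variances (the standard scaled-inverse-chi-square hyperparameter
  estimator, with trigamma inversion by Newton iteration); the 1-df
  contrast statistic F = (cᵀβ)² / (cᵀ(XᵀWX)⁻¹c · s²_post) is referred to
  F(1, residual df + prior df).  Null simulations show the resulting
  p-values are uniform (pooled KS ≈ 0.03 over 12 seeds) and FDR<0.05 calls
  stay below 5% under the global null.

Strains with an all-zero occupied cell are flagged: their log-scale cell
coefficient is not estimable, the reported logFC falls back to
prior-count (0.5) cell means, and p is NA (excluded from the BH
denominator).  Multiple testing uses Benjamini–Hochberg within each
contrast; the significance threshold for downstream classification is
FDR < 0.05.

## Downstream reporting

* **OD calibration**: log10(cells) = a·log10(abs) + b with defaults
  a = 1.011, b = 7.489; `fit_calibration` is OLS on the log-log points
  (two distinct points give the exact line).
* **Tolerance calls**: a strain is tolerant (sensitive) in a condition
  group when ≥ `min_support` (default 2) of the group's contrasts are
  significant with positive (negative) logFC; mixed-sign significance is
  unclassified.  The rule is monotone: tightening fdr or support never
  classifies a previously unclassified strain.  A mean-logFC-based rule is
  not provided as a default because replicated-support is the stated
  classification criterion; mean ± SD of the group's logFCs is reported
  alongside for inspection.
* **Clustering**: agglomerative Ward on Euclidean distances (the ward.D2
  convention: input distances not pre-squared) on both axes via scipy's
  nearest-neighbor-chain implementation, which is deterministic with a
  documented tie-break; missing values are imputed as 0 (neutral) with a
  count of imputations reported.
* **Cross-batch correlation**: Spearman rho of reference-condition fitness
  on the strains shared by each batch pair; pairs sharing fewer than 3
  strains give NA with a warning.

## Numerical choices and validation sizes

Conservation of fractions is enforced to 1e-9; bias-cancellation and
reparameterization invariances are asserted at 1e-9 on fixed fixtures
(observed ~1e-15).  Validation studies use 80 strains × 3 replicates at
depth 3×10⁴ with the 22× bias model: selection-coefficient recovery
averages 40 replicate simulations per grid value s ∈ {−0.2, …, 0.2}
(minority of strains perturbed, 8 per value), and null calibration pools
5 seeds (400 strain-tests).  These sizes give standard errors comfortably
below the stated tolerances (0.15 log2 units for recovery; 5% for the
null positive rate) while keeping the full suite fast.

## Known limitations

* Agreement with edgeR is on logFC; moderated statistics and p-values
  differ in detail (different dispersion estimators and prior-df choices).
* Very low-abundance strains (expected counts of a few reads) show the
  usual downward Jensen bias in log-scale estimates; the simulator
  reproduces this regime at strong negative selection.
* The simulator's conditions are abstract labels with per-strain s values;
  no dose-response or medium-chemistry model is included.
* Continuous-time growth modeling (fitness per OD-hour, spline fits) is
  out of scope; fitness is defined per sampled contrast.
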