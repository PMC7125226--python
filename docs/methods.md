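# Methods

## The screen and its data model

`barfit` analyses pooled fitness screens of randomly barcoded transposon
(RB-TnSeq) libraries read out by barcode sequencing (BarSeq). Each insertion
mutant carries a unique DNA barcode; the library is sampled once before
treatment (T0), and again after outgrowth under a selective condition and a
non-selective control, typically in several independent experiments. The
entry point is a barcode × sample table of read counts together with a pool
map (barcode → locus tag, insertion coordinate) and a sample sheet
(sample → experiment, condition ∈ {T0, control, selective}). Barcode
extraction from raw reads is out of scope; established BarSeq counters
produce these tables.

## Barcode curation

Three filters are applied, in this order, before any modeling:

1. **Position.** Only barcodes inserted within the middle 80% of the coding
   sequence are kept (fractional position in [0.1, 0.9], bounds inclusive;
   `middle_fraction` configurable). Insertions near a gene's ends often leave
   function intact. Fractional position is measured from the start codon, so
   strand matters; GFF3 coordinates are treated as 1-based inclusive.
2. **T0 depth.** A barcode must have at least 15 reads summed over all T0
   samples (`min_t0_reads`). The threshold is applied per barcode, not per
   gene: a per-gene reading would make the next filter order-dependent.
3. **Representation.** A gene must retain at least 3 barcodes at distinct
   insertion coordinates (`min_barcodes_per_gene`), so no fitness value rests
   on a single insertion event.

Intergenic barcodes (null locus tag) are dropped up front but are preserved
in raw files. Curation is idempotent and monotone in all three thresholds;
both properties are tested.

## Normalization

Counts are transformed to

    value(i, s) = log2( (c(i, s) + 1) · D_ref / D_s ),

with `D_s` the library size of sample *s* (column sum) and `D_ref` the median
library size. The pseudocount keeps zeros finite and is added before depth
scaling. The median was chosen over the mean as the reference so one
unusually deep lane does not shift every sample. The T0 baseline is then
removed per experiment: for each barcode and each non-T0 sample, the mean of
that experiment's T0 log2 values is subtracted. With a single T0 sample per
experiment (the usual design) the mean is exact. The result *y* is the log2
abundance change of each mutant relative to the starting pool; for counts
well above the pseudocount it is invariant to common depth rescaling.

## Per-gene model, fitness, and significance

For each gene *g* the values y_{i,j,k} (barcode *i*, condition *j*, sample
*k*, experiments pooled) follow a Gaussian random-intercept model:

    full:  y_{i,j,k} = μ_g + C_j + B_i + ε_{i,j,k}
    null:  y_{i,j,k} = μ_g        + B_i + ε_{i,j,k}

with B_i ~ iid N(0, ς_g²) capturing insertion-specific effects shared across
a barcode's samples, and ε ~ iid N(0, σ_g²). Both models are fitted by
maximum likelihood (not REML: the two models differ in their fixed effects,
and only ML log-likelihoods are comparable across fixed-effect structures).
The condition term is coded sum-to-zero (selective = +½, control = −½), so
its coefficient is directly the **fitness**: the expected log2 abundance
change under selection relative to control. Loss of a gene required for
survival of the selection gives negative fitness; loss that improves it gives
positive fitness.

**Optimization.** For a fixed variance ratio λ = ς²/σ² the model is
generalized least squares with per-barcode compound-symmetric blocks
W_i = I + λJ, and both the fixed effects and σ² have closed forms through the
Woodbury identity, so the profiled log-likelihood is a function of λ alone.
It is maximized by evaluating λ = 0 exactly plus a 49-point log-spaced grid
on [10⁻⁶, 10⁶], then refining the best interior point with bounded scalar
minimization (tolerance 10⁻¹⁰ on log λ). This is deterministic, cannot miss
the ς² = 0 boundary, and agrees with generic 4-parameter numerical
maximization of the dense Gaussian likelihood to |Δloglik| < 10⁻⁶ (tested on
100 random genes against an independent brute-force oracle, and
cross-checked against statsmodels' MixedLM). A residual-variance floor of
10⁻¹² guards exactly degenerate data.

**T-value.** The per-gene confidence statistic is the Wald statistic of the
condition effect: estimate divided by the standard error from the observed
information at the ML variance estimates (σ̂²(XᵀW⁻¹X)⁻¹). In the ς² → 0,
balanced limit this reduces to the classical two-sample t statistic up to
the ML √(n/(n−2)) degrees-of-freedom factor.

**Likelihood-ratio test.** Gene significance is 2(ℓ_full − ℓ_null) referred
to the upper tail of χ²(1); round-off negatives are clamped at zero. When
ς̂² sits on its zero boundary the χ²(1) reference for the fixed-effect test
is only approximate; null simulations show the raw p < 0.05 rate lands near
0.05–0.07, which is why the calibration test accepts [0.03, 0.08]. P-values
are adjusted across genes by Benjamini–Hochberg step-up (via statsmodels),
and hits are called at |fitness| > 1, |T| > 4, q < 0.001 by default —
negative hits are genes required under selection, positive hits genes whose
loss improves it. All three cutoffs are strict inequalities.

## Synthetic screens

`barfit.simulate` generates screens with exactly the structure the model
assumes, plus ground truth, so every stage is testable without external
data. Per barcode, an initial relative abundance is drawn log-normal(0, 1);
per non-T0 sample, abundance is multiplied by 2^(C_j + B_i + ε) with
C_control = 0, C_selective the gene's true fitness, B_i ~ N(0, ς²) drawn
once per barcode, and ε ~ N(0, σ²) per observation; reads are then drawn
multinomially at a fixed per-sample depth. Multinomial sampling (rather than
independent Poisson) reproduces pooled sequencing's compositional
constraint and therefore stresses the depth normalization. Insertion
positions are uniform along the gene body so curation has realistic work to
do. An optional confounder plants genes at near-zero T0 abundance — mimicking
mutants that die before selection for unrelated reasons — to verify the T0
filter excludes them rather than letting them surface as spurious calls.

Defaults describe a desk-scale version of a three-experiment screen: 500
genes, 10 barcodes per gene, one T0/control/selective sample per experiment,
10⁶ reads per sample, ς² = 0.1 and σ² = 0.3 (log2² units, typical of
barcode-level heterogeneity in such screens), 10% of genes non-null with
fitness in {−4, −2, +2}. What the generator does **not** emulate: PCR
amplification bias, barcode sequencing errors and chimeras, growth-rate
(rather than survival) selection dynamics, and correlated depth differences
between conditions — so passing recovery tests demonstrates correctness of
the estimator under its own assumptions, not robustness to those artifacts.

Problem sizes in the test suite and acceptance script (500-gene null
calibration, 120-gene recovery grid at depth 10⁶ with 5 barcodes/gene,
200-gene sensitivity screen with 10% of genes at fitness −3) keep a full run
in the low minutes on one CPU while leaving Monte-Carlo error well inside
the tested tolerances.

## Assay calculators

* **Cosinor phase.** Peak expression time of a circadian gene is estimated
  by least squares on Y(t) = M + A·cos(2π(t − φ)/P) via the linear
  reparameterization M + a·cos(ωt) + b·sin(ωt); A = √(a² + b²) ≥ 0,
  φ = (P/2π)·atan2(b, a) wrapped to [0, P). The period defaults to 24 h and
  stays a parameter. A mesor term M is included: without it a constant
  (arrhythmic) series could not resolve to the degenerate A = 0 answer that
  the fit reports (with a flag) for flat data. The fit is exact on noiseless
  model data; single harmonic only — no multi-harmonic period estimation.
* **Transformation efficiency.** Resistant colonies per CFU plated without
  selection, each count back-multiplied by its dilution factor; the shared
  plated volume cancels. Colony counting itself is upstream image analysis
  and out of scope.
* **Relative qPCR expression.** 2^−ΔΔCt with
  ΔΔCt = (Ct_target − Ct_ref)_treatment − (Ct_target − Ct_ref)_baseline. No
  amplification-efficiency correction (Pfaffl) is applied.

## Known limitations

* Experiments are pooled into one model per gene with no experiment term;
  between-experiment variation is absorbed by the barcode and residual
  variances.
* The χ²(1) LRT reference is anti-conservative at the ς² = 0 boundary (see
  calibration above); the stringent default FDR cutoff (0.001) absorbs this
  in practice.
* Genes whose mutants are nearly absent from the T0 pool are excluded by
  curation, so a true competence requirement of such a gene is undetectable
  by design — the screen has no information about it.
* The Wald T uses the plug-in ML variance and carries no small-sample
  degrees-of-freedom correction; with the default ≥3 barcodes × 6 samples it
  is adequate, but T-values from genes with few observations should be read
  with care.
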