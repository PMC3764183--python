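# Methods

This note records the models behind each stage, the defaults and why, the
numerical choices, and what the synthetic studies can and cannot show.

## Gel-lane sizing (telquant)

**Model.** Migration of restriction fragments in an agarose gel is treated
as log-linear: log₁₀(size in bp) = a·position + b. With exactly two marker
bands (2044 and 779 bp in the reference assay) the calibration is the line
through the two (position, log₁₀ size) points — exact at both anchors by
construction, order-invariant, and equivalent to geometric-mean
interpolation (the positional midpoint of the markers maps to
√(2044·779) ≈ 1261.9 bp). With more than two markers the natural extension
is least squares in log space; this is out of scope while inputs carry two.

**Smear summary.** Telomeric signal is a smear, not a band. After
subtracting the intensity quantile (default 0.1) as background, the smear
is the maximal contiguous interval around the global peak with intensity
≥ 0.2 of the peak (both thresholds exposed as parameters). The reported
length is the fragment size at the *intensity-weighted centroid position*
of that interval; the interval's ends map to `smear_lo`/`smear_hi`. The
centroid is exact for symmetric bands and degrades gracefully for skewed
smears; whether the original instrument software summarized by centroid,
mode or median is not documented, so centroid is recorded here as this
package's own choice. Sizing refuses to extrapolate: a smear reaching
outside the marker-bracketed range is an error, not a guess.

**Accuracy.** On profiles generated from the same forward model (Gaussian
band on a flat baseline, additive noise up to 5% of peak amplitude),
recovery is well inside 2% of truth; the acceptance script reports the
maximum relative error over 100 draws.

## Differential expression (expression_de)

**Filter.** A gene is kept iff at most half of its detection calls are
Absent (strict `>` for removal, so exactly half keeps the gene); Marginal
counts as present. The filter is idempotent and independent of expression
values.

**Statistic.** Two-class SAM: dᵢ = (mean_stress − mean_control)/(sᵢ + s₀),
with sᵢ the pooled standard error of the mean difference. At s₀ = 0 this is
exactly the pooled-variance two-sample t (asserted against an independent
implementation in the tests). s₀ is selected by scanning the
0, 5, …, 100 percentiles of {sᵢ} and minimizing the coefficient of
variation of the MAD of d across sᵢ-quantile bins — the value that makes
the spread of d flattest in the gene's standard error, decoupling
significance from expression-level variance.

**FDR.** With 4 control and 3 stress samples only C(7,3) = 35 distinct
label assignments exist, so they are enumerated exhaustively (the sampler
with a seed takes over only when the distinct count exceeds `n_perm`).
For each gene's threshold |dᵢ|, q = (median over assignments of the count
of permuted |d*| at or above the threshold) / (observed count admitted),
clipped to [0, 1] and forced monotone nonincreasing in |d|; ties in |d| at
a threshold admit all tied genes. The working set is q < 0.01.

**Calibration and power.** On null data the median number of significant
genes over 100 runs is 0. Two honest caveats:

- The *median* false-count estimator is anticonservative for very small
  significant sets: whenever the observed maximum |d| happens to rank above
  about half of the 35 permuted maxima, the top gene's q is 0, so a
  substantial minority of null runs declare 1–3 flukes. The 90th-percentile
  estimator (`estimator="q90"`) controls the any-hit rate to < 10% and is
  the right choice when any false set matters more than power.
- Recall of planted effects at FDR 0.01 is bounded by the design, not the
  estimator. At the default study conditions (1000 genes, 4 vs 3 samples,
  effect 3σ), the mean-difference separation is 3/√(1/4+1/3) ≈ 3.9 standard
  errors; flagging 80% of 50 planted genes would require a cut near z ≈ 3.1,
  where ~950 null genes contribute ≈ 1.9 expected false calls per
  permutation and any FDR estimate sits near 5%. The achievable recall at
  a true FDR of 1% is ~0.6 for *any* correctly calibrated procedure
  (Benjamini–Hochberg on exact t p-values does far worse here because the
  5-df t tails are heavy; the fudge factor is what keeps SAM near the
  ceiling). The acceptance script reports the measured recall (~0.59)
  rather than pretending otherwise.

**Set algebra.** specific(s) = DE(s) \ ∪ₜ≠ₛ DE(t); direction-specific sets
(genes DE under every stress of one direction group — elongating /
shortening / neutral — and none outside it) are provided alongside, since
either reading of "stress-specific" can be wanted downstream; the per-stress
difference is what the proximity stage consumes by default.

## Network proximity (network_proximity)

**Test.** dist_a = multiset of pairwise unweighted shortest-path lengths
within the stress-specific DE TLM set; dist_b, by default, the same within
the remaining TLM genes ("other TLM genes"); the alternative reading — all
TLM pairs not entirely inside the specific set — is selectable
(`b_definition="all_other_tlm_pairs"`), since the phrase is ambiguous.
The comparison is a one-sided Wilcoxon rank-sum (specific set closer):
exact by full enumeration when |a|+|b| ≤ 16 with no ties, otherwise the
normal approximation with tie-corrected variance and continuity correction.
Distances are BFS path lengths (checked against an exhaustive all-pairs
relaxation oracle on small random graphs). Unreachable pairs are *excluded
and counted*, never imputed: an unweighted distance across components is
undefined, and imputing diameter+1 would manufacture proximity signal; an
imputation mode is deliberately not provided.

**Specificity control.** The same comparison on the full network between
specific DE TLM genes and specific DE non-TLM genes. An empty non-TLM
comparison set is an error, not a silent pass. Each stress is tested
separately against its own background.

**Synthetic networks.** A stochastic block model (default 300 nodes, 6
blocks, p_in = 0.3, p_out = 0.01) with ~15% TLM nodes; when planted, 15
TLM+DE nodes sit inside one block (mutually proximal). Non-TLM nodes are
flagged DE at a background rate of 0.1 — a parameter beyond the minimal
generator contract, needed so the specificity control has a non-empty
comparison set. Planted recovery gives p < 0.01 in ≥ 95/100 seeds;
unplanted networks give p consistent with uniform, with the caveat that
rank-sum p-values on small integer-valued distance multisets are discrete,
so exact uniformity is only approached.

## Responsiveness screen (responsiveness_screen)

**Fit.** Δlength is regressed on initial length by iteratively reweighted
least squares with Tukey bisquare weights (tuning constant 4.685, ~95%
Gaussian efficiency), residual scale 1.4826·MAD (re-estimated each
iteration), OLS start, convergence at relative coefficient change < 1e-8 or
50 iterations (non-convergence is reported, not raised). This matches the
classical robustfit-style default and is cross-checked in the tests against
an independent IRLS implementation (statsmodels RLM).

**Outlier call.** Residuals are assumed normal; mutants are flagged in the
most extreme 5% of that distribution — |z| > 1.96 at α = 0.05, 2.5% per
side. Two open choices are exposed:

- *Standardization scale.* Default is the classical SD of the residuals
  (a normal fitted to all residuals, ddof = 2). Gross outliers inflate this
  scale, so only points far outside the bulk are flagged — high precision
  on contaminated screens, recall preserved when shifts are large (the
  8σ-shift regime the screen targets). The robust MAD scale
  (`scale_estimator="robust"`) keeps the cut calibrated to the clean bulk
  instead; it trades precision (~0.5 by construction at 5% contamination,
  since it flags a full α of clean points) for sensitivity to subtler
  outliers. On clean data both flag ≈ α of points.
- *Rule form.* The normal-quantile cut is the default; a literal rank-based
  most-extreme-round(αn) variant (`method="rank"`) is available.

Direction: under an elongating stress a positive residual is
over-responsive; under a shortening stress a negative one is.

**Correlation.** Pearson r with the two-sided t-transform p (n−2 df),
refusing constant inputs.

## ChIP quantification (chip_quant)

fold = (tel_IP/ARO1_IP)/(tel_input/ARO1_input) on linear-scale quantities —
degree-0 homogeneous, so common rescaling (amount of chromatin, PCR
efficiency common to a sample) cancels. Replicates are summarized by the
geometric mean (folds are ratio-scale; the arithmetic mean is available
behind a flag), spread as the SD of log₂ folds; condition effects are
ratios of summarized folds (0.5 = two-fold depletion). A convenience
converter from qPCR Ct values (quantity = efficiency^(−Ct), default
efficiency 2.0) is provided; amplification-curve processing is not.

## Synthetic data: what it does and does not emulate

Defaults are the study conditions: 4 control vs 3 stress arrays per
contrast; 1000 genes; 5% planted DE at effect 3σ on the normalized log
scale with σ = 0.5; Absent calls i.i.d. at rate 0.1, independent of DE
status; screen initial lengths uniform on [150, 450] bp of telomeric
repeat (wild type ≈ 350 bp), bracketing short and long maintenance
mutants; outliers shifted ±8σ with fair-coin sign; lanes from the
two-marker log-linear model with Gaussian bands; ChIP quadruples with
~10% lognormal noise per quantity around a planted fold.

Deliberate simplifications, hence limits on what passing tests show about
real data: expression noise is i.i.d. Gaussian on the log scale (real
arrays have correlated, intensity-dependent variance and the true variance
structure is unknown — the Gaussian choice is a stand-in); detection calls
are independent of expression level; the interaction network is a clean
block model, not a scale-free PPI graph; screen noise is homoscedastic;
lanes are 1-D profiles (no lane-finding, no 2-D gel artifacts, no probe
kinetics). Recovery on these generators demonstrates correctness of the
procedures, not field performance on raw instrument data.

## Determinism and numerics

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); identical parameters and seed give
byte-identical outputs, including the full pipeline's result tables
(asserted in the tests). Degenerate inputs fail loudly with the offending
field named: zero-variance genes at s₀ = 0, coincident markers, smears
outside the marker range, empty comparison sets, non-positive ChIP
quantities, scale-zero fits. Ties: average ranks in the rank-sum test; |d|
ties at a SAM threshold admit all tied genes; the s₀ scan breaks ties
toward the smaller candidate.
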