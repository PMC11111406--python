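# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical and design choices made where the design was
genuinely open.

## Pooled-barcode screen processing

The screen model assumes each well's readout is a per-barcode median
fluorescence intensity (MFI) proportional to the abundance of that
barcode's cell line, distorted multiplicatively by well-level
amplification/detection efficiency. Ten spike-in control barcodes at
fixed, strictly increasing abundances are present in every well and carry
the well-level distortion but no treatment signal, which makes them a
per-well calibration ladder.

Processing steps, in order:

1. **Reference profile** — per plate, the median log2(MFI) of each
   spike-in across negative-control (vehicle) wells. Medians are robust to
   an aberrant control well; a control well missing a spike-in is an error
   naming the well.
2. **Well calibration** — a monotone map g from the well's ten spike-in
   levels to the reference profile, applied to every cell barcode. g is a
   shape-preserving cubic (PCHIP) through the ten pairs with linear
   extrapolation beyond the data range using the endpoint slopes. The
   reference values are isotonic-regressed before interpolation so g is
   non-decreasing even when noise reorders the pairs; tied well levels are
   collapsed to their mean reference, and fewer than four usable pairs is
   an error. A penalized monotone spline would also fit this contract; the
   contract actually relied on — monotonicity, smoothness, identity on
   undistorted wells, exact inversion of affine distortions — is what the
   tests pin down, and PCHIP satisfies it without free smoothing
   parameters.
3. **Control separability** — per (cell line, plate): the error rate of
   the best single-threshold classifier (values below the threshold called
   positive-control-like), minimized over midpoints between adjacent
   distinct values plus ±∞, and the dynamic range μ− − μ+ of the median
   calibrated controls. Midpoints between *distinct* values never coincide
   with a sample, which resolves the below/above ambiguity a threshold on
   a data value would create. Inclusion requires error ≤ 0.05, DR ≥ 1.74
   (boundary values pass) and at least two passing replicates. The μ±
   statistics are computed per cell line × plate; the calibrated log2(MFI)
   is used as the "normalized" signal.
4. **Log-viability** — calibrated log2(MFI) minus the per-plate, per-line
   median of the negative controls, so vehicle wells sit at 0 by
   construction and −1 means half the control signal. For curve fitting
   the linear fraction 2^LV is clipped to [0, 1.2], since the 4PL
   constraints are expressed on the viability-fraction scale.
5. **Batch correction** — a parametric empirical-Bayes location–scale
   adjustment: per feature, data are standardized against the sample-size
   weighted grand mean and pooled variance; per batch, additive and
   multiplicative effects are estimated, shrunk toward across-batch
   moment-matched priors by the standard iterative posterior-mean solve,
   and divided out. Afterward each feature is recentred so its grand mean
   is preserved exactly (the plain algorithm preserves it only
   approximately, and downstream AUCs should not shift in aggregate).
   Cell lines are the samples and their pool/culture label the batch; a
   single batch passes through unchanged, a singleton batch gets a
   location-only adjustment (its scale is not estimable), and
   zero-variance features are left untouched.
6. **Collapse** — median log-viability per (line, treatment, dose) across
   replicates.

On noiseless input the full chain is exact: well offsets are affine in
log2 and inverted exactly by the monotone map, and the per-plate
negative-control normalization cancels plate- and batch-level shifts that
affect treatment and control wells alike.

## Dose–response

The 4PL is f(x) = b + (a − b)/(1 + e^{s·ln(x/EC50)}), natural log; s > 0
gives viability decreasing with dose (any log base is absorbed into s).
Constraints: a ∈ [0.99, 1.01] (upper asymptote pinned to the vehicle
level), b ∈ [0, 1.01], direction not enforced, initialization a = 1,
b = 0.5, s = 1, EC50 at the median tested dose. Fitting is bounded
trust-region least squares in (a, b, s, log EC50); when it fails, a
soft-L1 robust refit from the last iterate is reported and flagged. EC50
is allowed up to four decades outside the tested window so flat or shifted
curves converge at a boundary rather than erroring.

- **AUC** — mean fitted viability over the tested log10-dose window,
  ∫f(10^u)du normalized by the window width, integrated to ≤ 1e-6
  absolute. Untreated = 1; lower = more sensitive. AUC on the fitted curve
  is the default; the raw-point trapezoid over log10-dose is the obvious
  alternative and can be computed directly from the collapsed table.
- **IC50** — closed-form inversion of the logistic at 0.5, reported only
  when the crossing lies inside the tested window; a curve with floor
  above 0.5 has no IC50 (undefined, not an error).
- **PK–PD sigmoid** — r(C) = bottom + (1 − bottom)/(1 + (C/EC50)^h) with
  the top fixed at 1, since responses are vehicle-normalized; fixing the
  bottom at 0 instead is available by flag. A flat response profile
  returns an unconverged fit with EC50 = NaN rather than an arbitrary
  number.
- **Exposure** — trapezoidal AUC over the sampled window; terminal
  half-life by log-linear regression on the longest strictly-declining
  suffix (≥ 3 points, else NaN); Kp = AUC_tissue/AUC_blood on matched
  timepoints.
- **Tumour response** — percent volume change from the first (baseline)
  volume, best response as the minimum over follow-up, and an exponential
  growth rate as the least-squares slope of ln V against time.

## Sparse copy-number pipeline

Inputs are per-bin read counts with per-bin GC fraction, 0-based half-open
coordinates. The desk-scale default genome is one synthetic chromosome of
2,000 bins of 100 kb; a full-scale 20,000-bin genome is a config change
(`n_bins`), at quadratic cost in the segmentation scan.

- **GC correction** divides each count by the LOWESS trend of count
  against GC (span 0.3 by default, floored at a small positive value) and
  rescales so the genome mean is preserved exactly. It assumes a smooth
  bias; it will not remove bin-specific mappability artifacts, which is
  why real studies use mappability-derived variable bins. This package
  uses fixed-width bins (the simulator provides matching ones) and accepts
  arbitrary user-supplied bins, since mappability computation needs a
  reference genome.
- **Normalization** is relative to the mean of the genome — ratios, not
  absolute copy states, deliberately: microdissected tumour material
  retains stromal contamination that shifts absolute levels.
- **CBS** treats each interval as a circle and scans *all* breakpoint
  pairs (i, j) for the maximal mean-shift statistic
  T = |mean_in − mean_out| / (sd·√(1/k + 1/(n−k))), with the interval's
  overall sd as scale. The split is accepted when the within-interval
  permutation p-value (p = (1+exceed)/(1+B), B = 1,000 by default) is
  ≤ α = 0.01, and recursion continues on the pieces. Because the overall
  sd is permutation-invariant, the permutation null needs only cumulative
  sums; the scan is vectorized over permutation chunks and stops early
  once significance is no longer attainable, so null intervals cost a few
  dozen permutations. Complementary arcs ([0, j) vs [j, n)) carry equal
  statistics and induce the same partition; ties break to the first pair
  in lexicographic order. Adjacent segments whose means differ by less
  than `min_seg_delta` = 0.1 are merged. Segmentation runs on linear
  ratios by default (log2 by flag) — at the ratio amplitudes of interest
  (±0.5 around 1) the two scales behave near-identically, and linear
  ratios keep segment means directly interpretable against the 1.5 gain
  threshold.
- **Focal gains** require segment mean ratio strictly above 1.5 and
  physical extent at most 20 Mb (≈ 200 bins at 100 kb); gains longer than
  that are classified broad. The length cutoff is this package's
  operational definition of "focal" — large enough for multi-megabase
  amplicons, small enough to exclude arm-level events — and is exposed as
  `focality_limit`. The threshold applies to the segment mean, not to
  bin-level ratios.
- **Cohort comparison** is the standard two-sided Fisher exact test
  (hypergeometric tables with point probability ≤ observed).

## Association testing

Per gene with ≥ 4 mutant lines (and ≥ 2 wild-type — the wild-type floor is
this package's choice), Welch's t-test compares AUC between mutant and
wild-type lines; the pooled-variance test is a flag. Three cohorts are
run: all lines, excluding KRAS mutants, excluding KRAS or NRAS mutants.
Constant-and-equal groups return t = 0, p = 1 (no evidence) instead of the
NaN a textbook t-test would produce. Raw p-values are the primary output;
a Benjamini–Hochberg column is added per cohort as a convenience and is
not part of the original analysis design.

## Synergy and signatures

Bliss excess is computed on the inhibition scale with viability clipped to
[0, 1] first; the expectation is eA + eB − eA·eB from the zero-dose
margins, excess is observed minus expected (positive = synergy), and the
mean over nonzero dose pairs is the matrix score. When replicate matrices
exist, excess is computed per replicate and then averaged. The z-score
signature is (x − mean_ctrl)/sd_ctrl per gene with the sample sd (ddof 1,
≥ 2 controls); zero-variance genes are flagged NaN rather than ±∞.
Consensus integration uses Stouffer's z (Σz/√k over signatures with
defined values per gene); plain averaging is a flag.

## Synthetic-data generators

The generators define the study conditions under which everything is
tested:

- **Screen**: 8-point, 3-fold dilution series from 1 µM, triplicate, ten
  spike-ins ~2× apart, lognormal multiplicative MFI noise (default cv
  0.1, i.e. additive Gaussian ≈ 0.14 log2 units), per-well additive log2
  offsets (sd 0.3) carried by all barcodes, positive-control viability
  0.05 (not 0, keeping log-viability finite). The MFI noise model is an
  assumption about the readout, not an inference about the instrument.
  Pool/batch effects are injected into cell barcodes of treatment wells
  only — effects that also shifted a line's own negative controls would
  cancel in the per-plate normalization and be invisible downstream, so
  the injected structure is exactly the residual the empirical-Bayes
  corrector is asked to remove.
- **CNV**: Poisson counts with mean depth × copy ratio × smooth GC bias
  (polynomial in GC, normalized to mean 1), default depth 100 reads/bin.
  True segment tables are emitted for round-trips. Read-level artifacts
  (duplicates, mappability, WGA chimeras) are not simulated.
- **Dose matrices**: combined inhibition eA + eB − eA·eB + interaction,
  clipped to [0, 1]; the interaction term is recovered exactly by the
  Bliss scorer in the noiseless case unless clipping saturates a cell.
- **PK–PD**: one-compartment oral model
  C(t) = D·ka/(V(ka−ke))·(e^{−ke t} − e^{−ka t}) with the ka → ke limit
  handled analytically, linked to r = 1/(1 + (C/EC50)^h).

Passing tests on these generators shows the chain is correct under its own
model assumptions — monotone well distortions, lognormal noise, smooth GC
bias, Poisson counts. They do not establish robustness to real-data
pathologies: barcode cross-hybridization, non-monotone detection
saturation, mappability structure, or heavy-tailed expression noise.

## Problem sizes and determinism

The test and acceptance workloads use desk-scale sizes chosen to exercise
every code path at comfortable statistical power: 200 simulated lines for
4PL recovery, 100 seeded runs for CBS step localization and null
specificity at 200 bins, 10 replicate 47-sample cohorts at 300 bins for
the resistance-genomics chain, and 1,000 label permutations for
association calibration. All generators and the CBS permutation test take
explicit seeds; identical seed and config give bit-identical outputs.

## Known limitations

- CBS is O(n²) per interval scan; 20,000-bin genomes work but are slow —
  the design target is the few-hundred-to-few-thousand-bin regime.
- The empirical-Bayes corrector assumes roughly balanced, multi-sample
  batches; heavily unbalanced designs reduce shrinkage quality.
- No absolute copy-number, ploidy or purity estimation, by design.
- IC50 is reported only within the tested dose window; extrapolated
  potency is deliberately not produced.
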