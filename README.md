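# preclin

Analytics for the computational backbone of a preclinical oncology
pharmacology study: processing a pooled-barcode cell-line viability screen,
fitting constrained dose–response curves, calling focal copy-number gains
from sparse whole-genome sequencing, scoring drug-combination synergy,
summarizing PK–PD exposure–response, testing mutation–sensitivity
associations, and building z-score expression signatures. Every stage can
be exercised end to end on synthetic data with known ground truth, so the
whole pipeline is testable without any external download.

It is written for computational biologists who need the analysis chain
behind a RAS-inhibitor-style preclinical study — multiplexed PRISM-type
viability screens, resistance genomics on relapsed tumours, combination
rescue experiments — as a library first, with a thin CLI for batch use.

## The methods at the core

**Screen processing.** Each well of a pooled screen carries ten spike-in
control barcodes at fixed increasing abundances. Per plate, a reference
profile is the median log2(MFI) of each spike-in across negative-control
wells; each well is mapped onto that reference with a monotone smooth
curve through its ten spike-in pairs, correcting amplification and
detection artifacts. Per cell line and plate, control separability is the
error rate of the optimal single-threshold classifier between positive and
negative controls, Error = (FP + FN)/n, plus the dynamic range
DR = μ− − μ+; lines with error > 0.05, DR < 1.74 or fewer than two passing
replicates are dropped. Log-viability is log2(x) − log2(μ−) against the
per-plate negative-control median; residual pool/condition batch effects
are removed with a parametric empirical-Bayes location–scale adjustment
(ComBat-style) and replicates are collapsed by the median.

**Dose–response.** A robust four-parameter logistic

&nbsp;&nbsp;&nbsp;&nbsp;f(x) = b + (a − b) / (1 + e^{s·ln(x/EC50)})

is fitted per line with the upper asymptote constrained to [0.99, 1.01],
the lower to [0, 1.01], direction unconstrained, initialization at
(a, b) = (1, 0.5), and a soft-L1 refit when the plain fit fails. AUC is
the mean fitted viability over the tested log10-dose window (untreated =
1); IC50 is the closed-form 50%-viability crossing, defined only for
curves that drop below 50%. PK–PD uses a three-parameter sigmoid (top
fixed at 1) for EC50, trapezoidal AUC, terminal-phase half-life, and
Kp = AUC_tissue / AUC_blood.

**Copy number.** Binned read counts are corrected for GC content with
LOWESS, normalized relative to the mean of the genome (relative copy
number only — no ploidy/purity), segmented with circular binary
segmentation (exhaustive circular breakpoint pairs, permutation p ≤ 0.01),
and segments with mean ratio > 1.5 and sub-chromosomal extent (≤ 20 Mb)
are called focal gains. Cohort gain frequencies are compared with the
two-sided Fisher exact test.

**Synergy and signatures.** Excess over Bliss on the inhibition scale,
e_obs − (eA + eB − eA·eB), averaged over nonzero dose pairs; per-gene
z-scores of treated samples against vehicle controls, integrated across
lines by Stouffer's method.

## A worked example

```sh
python examples/screen_pipeline.py
```

simulates a 6-plate, 8-line screen with 10% lognormal MFI noise, processes
it and refits each line:

```
QC: 8/8 lines pass (error rate <= 0.05, dynamic range >= 1.74, >= 2 replicates)

cell_line  auc_fit  auc_true  ic50_nM  ec50_true_nM
   CL0000    0.740     0.704    79.04         42.51
   CL0003    0.348     0.372     4.39          4.73
   CL0006    0.315     0.301     1.90          1.41
   ...
```

AUC near 1 means unaffected viability across the tested doses; sensitive
lines (true EC50 in the low-nanomolar range) land near 0.3 and get an
IC50. The other scripts in `examples/` walk through copy-number calling
(`cnv_pipeline.py`), Bliss scoring (`synergy_scoring.py`), PK–PD
summaries (`pkpd_summary.py`), association testing
(`mutation_association.py`) and signatures (`expression_signatures.py`).
`preclin demo --seed 7 --out out/` runs the whole stack and writes a
summary report.

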