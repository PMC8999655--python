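# ybrca1

Validation and data-integration of yeast-based functional assays for
classifying BRCA1 missense variants.

Rare BRCA1 missense variants often cannot be classified from genetic
evidence and remain variants of uncertain significance (VUS). Four
yeast assays give an orthogonal functional readout: expressing a
loss-of-function variant raises intra-chromosomal homologous
recombination (HIS3 colonies / 10⁴ cells), inter-chromosomal HR (ADE2
colonies / 10⁵ cells) and gene reversion (ILV1 colonies / 10⁶ cells),
and relieves the growth inhibition imposed by wild-type BRCA1 (small
colony phenotype, scored as cells per colony). This package is for
groups running such assay panels: it turns replicate-level readouts
into calibrated per-assay classifiers and one integrated
benign/pathogenic call per variant.

## Method

For each assay, per-variant replicates are summarized by their median
(HR/GR as fold of the wild-type-control median; SCP raw), and a cut-off
*c* is fitted on variants with known prior labels by maximizing the
Youden index

    J(c) = sensitivity(c) + specificity(c) − 1

over midpoints between consecutive distinct medians; `median > c` calls
a variant pathogenic. Each (variant, assay) pair then gets a functional
impact FI ∈ {pathogenic, benign} and a prediction score

    PS = #{bootstrap medians > c} / B,   clamped to [1/B, 1 − 1/B],

with B = 4000 resamples by default. The n assays are combined by
equal-weight majority voting: pathogenic votes PV = number of
pathogenic FI calls, pathogenic prediction score PPS = PV/n, final
label pathogenic iff PPS > 0.5 (a 2-of-4 tie is benign). Combined
performance is reported as accuracy with an exact (Clopper–Pearson)
95% CI, sensitivity, specificity, PPS-ranked AUROC, MCC and Cohen's κ.

Raw replicate data for the original 46-variant benchmark (23
pathogenic, 23 benign) plus 10 VUS were never deposited, so the package
includes a synthetic generator with log-normal replicate noise, and a
benchmark-structured panel that plants the published per-assay
false-positive/false-negative pattern. See `docs/methods.md` for the
model, defaults, and design choices.

## Worked example

Calibrate on the benchmark-structured synthetic panel, then classify:

```sh
ybrca1 validate --paper-like 1 --out cal
ybrca1 classify --paper-like 1 --calibration cal/calibration.json --seed 1 --out calls
```

`cal/calibration_summary.tsv` holds the per-assay performance:

```
assay     sensitivity  specificity  accuracy  auroc  youden_index  best_cutoff
intra_hr  0.957        0.783        0.87      0.749  0.739         1.932
inter_hr  0.87         0.913        0.891     0.794  0.783         2.004
gr        0.913        0.87         0.891     0.794  0.783         1.844
scp       1.0          0.913        0.957     0.913  0.913         19.431
```

Each assay recovers its published confusion structure — e.g. intra-HR
misses one pathogenic variant (p.R71K) and flags five benign ones,
giving sensitivity 22/23 = 0.957 and specificity 18/23 = 0.783. The
cut-offs are in fold-of-control units (SCP in cells per colony) and are
properties of the synthetic readouts, not of the unpublished raw data.

`calls/calls.tsv` has one row per variant with per-assay (PS, FI)
pairs, then PV, PPS and the final label:

```
variant_id  intra_hr_ps  intra_hr_fi  ...  pv  pps   ybrca1
p.R71K      0.00025      benign       ...  1   0.25  benign
p.R1699W    0.99975      pathogenic   ...  3   0.75  pathogenic
```

p.R71K — pathogenic by prior label but functionally silent in three of
four assays — collects only one vote and is the integrated method's
false negative. `calls/performance.tsv` summarizes the integration:

```
accuracy             0.9565
accuracy_ci95_low    0.8516
accuracy_ci95_high   0.9947
sensitivity          0.9565
specificity          0.9565
mcc                  0.913
cohen_kappa          0.913
concordant_all_assays  35
```

i.e. 44 of 46 prior-classified variants correct (only p.R71K and
p.I1275V missed), 35 of 46 called correctly by every single assay, and
the 10 VUS split 6 pathogenic / 4 benign.

The same stages are available as library functions
(`generate_paper_like_panel`, `calibrate_panel`, `score_panel`,
`integrate_panel`, `combined_performance`) on any
`AssayPanel`, including ones read from your own long-format TSV/CSV
(`read_panel`; columns `variant_id, prior_label, assay,
replicate_index, value, is_control`).

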