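# Methods

## The problem

Rare BRCA1 missense variants are hard to classify from genetic evidence
alone, and most end up annotated as variants of uncertain significance
(VUS). Yeast-based functional assays offer an orthogonal readout:
expressing a loss-of-function BRCA1 variant in *S. cerevisiae* raises
the frequency of intra- and inter-chromosomal homologous recombination
(HR) and of gene reversion (GR), and relieves the growth inhibition
that wild-type BRCA1 imposes (the small colony phenotype, SCP). Each
assay is an imperfect binary classifier; the yBRCA1 method calibrates
each one on a panel of variants with known prior labels and then
combines the four calls by equal-weight majority voting.

## Per-assay calibration

For each variant in one assay, the replicate readouts (5–15 independent
experiments) are reduced to a median and interquartile range. HR and GR
frequencies are normalized as **fold of the wild-type-control median**
before summarizing; SCP stays in raw cells per colony (its decision
scale is far from fold-1). Both modes are configurable per assay, since
a fold-normalized SCP is also well defined.

Classification orientation is fixed: *higher readout ⇒ pathogenic*, in
all four assays. There is no automatic orientation detection — a
data-driven sign flip on a small panel can lock in a spurious
orientation, and the biology determines the sign here.

The cut-off is chosen by maximizing the Youden index
`J = sensitivity + specificity − 1` over candidate thresholds placed at
the midpoints between consecutive distinct medians (published cut-offs
fall between variant values, not on them). Ties in `J` break toward the
higher-specificity candidate, then toward the smaller threshold. Calls
use a strict inequality (`median > cutoff` ⇒ pathogenic), so a median
exactly at the cut-off is benign. With a single distinct median the
cut-off degenerates to that value and everything is called benign.

The ROC curve sweeps thresholds over the distinct medians, entering
tied variants atomically; the trapezoidal area then equals the
normalized Mann–Whitney U statistic with 0.5 tie credit, which is what
the test suite checks it against (brute-force pairwise comparisons and
`scipy.stats.mannwhitneyu` as independent routes).

Quartiles use linear interpolation between order statistics. They feed
only the waterfall export (box positions), never the calls.

## Prediction scores

Each (variant, assay) pair gets a binary functional impact FI (median
vs. cut-off) and a prediction score PS in (0, 1). PS is a **bootstrap
exceedance probability**: resample the replicates with replacement
B times and report the fraction of bootstrap medians strictly above the
cut-off, clamped to `[1/B, 1 − 1/B]`. The default `B = 4000` puts
scores on a 1/4000 = 0.00025 grid with extremes 0.00025 and 0.99975 —
the granularity the published per-variant score tables show, which is
why this interpretation and this default were adopted. The original
scoring tool's internals are not documented; no other resampling scheme
(per-experiment blocks, posterior draws) is attempted. `B < 100` is
rejected as unstably coarse.

FI drives the votes, not `PS > 0.5`. The published per-variant tables
count calls with FI = pathogenic but PS < 0.5 as pathogenic votes, so
the FI reading is the one consistent with all printed rows; the literal
`PS > 0.5` rule is still available as the `ps_votes` mode. The two modes
differ only for low-confidence calls whose median and bootstrap mass
straddle the cut-off.

One shared seed drives all bootstrap draws of a run (calls are produced
in panel order, assay-major), and the CLI logs seed, B, clamp bounds
and vote mode, so classification outputs are exactly reproducible.

## Majority voting

With `n` assays (configurable, ≥ 2; the benchmark uses 4), a variant's
pathogenic votes PV count its pathogenic calls; the pathogenic
prediction score is `PPS = PV/n`; the final label is pathogenic iff
`PPS > 0.5`. The tie `PPS = 0.5` resolves to **benign** — the published
integration treats 2-of-4 as benign — so the classifier is deliberately
conservative toward pathogenicity at the tie.

Combined performance on the classified (non-VUS) variants reports
accuracy with an exact Clopper–Pearson 95% binomial interval
(`statsmodels.stats.proportion.proportion_confint(method="beta")`),
sensitivity, specificity, an AUROC that ranks variants by PPS (five
distinct values, 0.5 tie credit), the Matthews correlation coefficient
and Cohen's kappa from the 2×2 confusion matrix. MCC and kappa are
computed from their definitions and cross-checked against scikit-learn
in the tests. Note that for any 2×2 table with
sensitivity = specificity = 44/46 on a balanced 23+23 panel, MCC and
kappa are both 0.913 by identity; the pipeline reports what the
formulas give.

## Synthetic data

Raw per-variant frequencies were never published, so the generator is
first-class pipeline code rather than a test fixture. Replicates are
log-normal, `value = L·f·exp(σZ)` with `σ = sqrt(log(1 + CV²))`, so the
distribution median is exactly `L·f`: fold-shifts act on the median,
the scale all downstream statistics use. Defaults mirror the benchmark
design: 23 pathogenic + 23 benign + 10 VUS, 5 replicates (the
experimental minimum), pathogenic fold 3, benign fold 1, CV 0.3.
Control locations are typical readouts in each assay's units (intra-HR
2 per 10⁴, inter-HR 3 per 10⁵, GR 2 per 10⁶ plated cells; SCP 10 cells
per colony). No dispersion estimates were published; CV = 0.3 is a
modeling choice typical of colony-count assays, fixed once. Controls
are pooled per assay (one wild-type series attached to every
measurement); the data model also accepts per-measurement controls,
since batch-matching practice was left open. VUS behave pathogenic in
an assay with probability 0.5, independently per assay, and the
realized behaviour is returned alongside the panel so recovery tests
can score VUS calls.

The **benchmark-structured panel** plants the published discordance
pattern: each assay's false-positive benign variants are elevated in
exactly that assay, its false-negative pathogenic variants stay low,
and VUS follow their published per-assay impact labels. Planted false
positives sit at 1.3× the pathogenic fold (above the pathogenic
cluster) and planted false negatives at fold 0.75 (below the control
cluster). This placement is deliberate: if a planted variant sat
*inside* a cluster, a threshold splitting the cluster just below/above
it would achieve a higher Youden index with non-negligible probability,
and the published confusion sets would not be recovered at every seed.
Outside the clusters, with replicate CV ≤ 0.05 (the panel's default),
the cluster gap is tens of log-scale standard errors wide and recovery
is deterministic at any seed. One side effect: because planted false
positives outrank every true positive, this panel's per-assay AUROCs
are *lower* than the published ones — it reproduces the confusion sets
and everything downstream of them, not the within-cluster ranking.

What passing on synthetic panels does **not** show: the generator has
no batch effects, no heavy-tailed outlier replicates, no correlation
between assays beyond the planted labels, and benign/pathogenic classes
are unimodal. Real panels may violate all of these; the published
cut-off magnitudes (1.535, 1.32, 1.077 fold; 25.833 cells/colony) and
per-assay AUROCs depend on the unpublished raw data and are therefore
*not* reproduction targets — the pipeline reproduces the published
confusion structure, integration results and VUS calls, and its
statistical machinery is property-tested against independent oracles.

## Problem sizes and numerics

The reconstruction stages are desk-scale (46×4 call matrix, exact
arithmetic). Property suites run 200 random instances (n ≤ 50) against
brute-force oracles; bootstrap scores are checked against exact
enumeration of the resample-median distribution (full `n^n` enumeration
at n = 5, the binomial closed form at n = 7). The parameter-recovery
study uses 50 seeds at the default design. All metrics are kept at full
precision internally and rounded (3–4 decimals) only in report tables.

## Known limitations

- Two-class voting only; no weighted or learned ensemble (equal weights
  are the method's design).
- The bootstrap PS treats replicates as exchangeable; replicate-level
  batch structure would need a block bootstrap.
- External annotation columns (other classifiers' calls) are
  pass-through only; no re-implementation of those methods.
- With very few replicates the bootstrap median distribution is coarse;
  the pipeline warns below 5 replicates rather than refusing.
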