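"""Calibration statistics: summaries, ROC sweep vs the pairwise
(Mann-Whitney) oracle, Youden cut-off vs exhaustive enumeration,
confusion-metric formulas on the published confusion lists."""

import numpy as np
import pytest
import scipy.stats

import ybrca1 as yb
from ybrca1.validation import candidate_cutoffs

from conftest import make_measurement


def _summaries(medians, assay=yb.Assay.GR):
    """VariantSummaries with the given median values (degenerate IQR)."""
    return [
        yb.VariantSummary(variant_id=f"p.V{i}", assay=assay, median_value=float(m),
                          q1=float(m), q3=float(m), n_replicates=5)
        for i, m in enumerate(medians)
    ]


def _labels(truth):
    return {
        f"p.V{i}": yb.PriorLabel.PATHOGENIC if t else yb.PriorLabel.BENIGN
        for i, t in enumerate(truth)
    }


# ---------------------------------------------------------------------------
# summarize
# ---------------------------------------------------------------------------


@pytest.mark.filterwarnings("ignore::ybrca1.errors.FewReplicatesWarning")
def test_summarize_fold_normalization_hand_example():
    m = make_measurement((2.0, 4.0, 6.0), controls=(2.0, 2.0, 2.0))
    s = yb.summarize(m, yb.Normalization.FOLD_OF_CONTROL_MEDIAN)
    assert (s.q1, s.median_value, s.q3) == (1.5, 2.0, 2.5)


def test_summarize_identity_at_control_level():
    m = make_measurement((3.0,) * 5, controls=(3.0,) * 5)
    assert yb.summarize(m, "fold_of_control_median").median_value == 1.0


@pytest.mark.filterwarnings("ignore::ybrca1.errors.FewReplicatesWarning")
def test_summarize_raw_mode_ignores_control():
    m = make_measurement((10.0, 20.0, 30.0), controls=())
    assert yb.summarize(m, yb.Normalization.RAW).median_value == 20.0


def test_summarize_large_sample_fold_recovery(rng):
    """Monte-Carlo: 1000 log-normal replicates at fold 3, CV 0.3 give a
    median within 3 +/- 0.2."""
    sigma = np.sqrt(np.log1p(0.3**2))
    reps = 3.0 * np.exp(sigma * rng.standard_normal(1000))
    m = make_measurement(reps, controls=(1.0,) * 5)
    assert yb.summarize(m, "fold_of_control_median").median_value == pytest.approx(3.0, abs=0.2)


def test_summarize_zero_control_median_is_degenerate():
    m = make_measurement((1.0,) * 5, controls=(0.0,) * 5)
    with pytest.raises(yb.DegenerateControlError):
        yb.summarize(m, "fold_of_control_median")
    with pytest.raises(yb.DegenerateControlError):
        yb.summarize(make_measurement((1.0,) * 5, controls=()), "fold_of_control_median")


# ---------------------------------------------------------------------------
# roc_sweep
# ---------------------------------------------------------------------------


def test_roc_perfect_separation():
    points, auroc = yb.roc_sweep(_summaries([1, 2, 3, 10, 11, 12]),
                                 _labels([False] * 3 + [True] * 3))
    assert auroc == 1.0
    assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)


def test_roc_identical_medians_is_chance():
    _, auroc = yb.roc_sweep(_summaries([2.0] * 8), _labels([0, 1, 0, 1, 1, 0, 1, 0]))
    assert auroc == 0.5


def test_roc_single_class_undefined():
    with pytest.raises(yb.UndefinedMetricError):
        yb.roc_sweep(_summaries([1, 2, 3]), _labels([True, True, True]))


def _auroc_pairwise_oracle(medians, truth):
    """Brute-force pairwise comparisons with 0.5 tie credit."""
    pos = [m for m, t in zip(medians, truth) if t]
    neg = [m for m, t in zip(medians, truth) if not t]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def test_auroc_equals_mann_whitney_oracle_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(2, 50))
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            continue
        medians = np.round(rng.random(n) * 10, int(rng.integers(0, 3)))  # induces ties
        _, auroc = yb.roc_sweep(_summaries(medians), _labels(truth))
        assert auroc == pytest.approx(_auroc_pairwise_oracle(medians, truth), abs=1e-12)
        # independent third route: scipy's U statistic
        u = scipy.stats.mannwhitneyu(medians[truth], medians[~truth]).statistic
        assert auroc == pytest.approx(u / (truth.sum() * (~truth).sum()), abs=1e-12)


def test_roc_points_monotone(paper_like_panel, paper_like_calibrations):
    for cal in paper_like_calibrations.values():
        fprs = [p[0] for p in cal.roc_points]
        tprs = [p[1] for p in cal.roc_points]
        assert fprs == sorted(fprs) and tprs == sorted(tprs)
        assert cal.roc_points[0] == (0.0, 0.0) and cal.roc_points[-1] == (1.0, 1.0)


# ---------------------------------------------------------------------------
# best_cutoff
# ---------------------------------------------------------------------------


def test_best_cutoff_toy_example():
    cutoff, cal = yb.best_cutoff(_summaries([1, 2, 3, 4]), _labels([0, 0, 1, 1]))
    assert cutoff == 2.5
    assert cal.youden_index == 1.0


def _best_cutoff_oracle(medians, truth):
    """Exhaustive enumeration over midpoint thresholds, pure-python."""
    distinct = sorted(set(medians))
    cands = (
        [distinct[0]]
        if len(distinct) == 1
        else [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    )
    best_key, best_c = None, None
    n_pos, n_neg = sum(truth), len(truth) - sum(truth)
    for c in cands:
        tp = sum(m > c and t for m, t in zip(medians, truth))
        tn = sum(m <= c and not t for m, t in zip(medians, truth))
        sens, spec = tp / n_pos, tn / n_neg
        key = (sens + spec - 1, spec, -c)
        if best_key is None or key > best_key:
            best_key, best_c = key, c
    return best_c, best_key[0]


def test_best_cutoff_equals_exhaustive_oracle_on_random_instances(rng):
    for _ in range(100):
        n = int(rng.integers(2, 50))
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            continue
        medians = np.round(rng.random(n) * 10, int(rng.integers(0, 3)))
        cutoff, cal = yb.best_cutoff(_summaries(medians), _labels(truth))
        oracle_c, oracle_yi = _best_cutoff_oracle(list(medians), list(truth))
        assert cutoff == pytest.approx(oracle_c, abs=1e-12)
        assert cal.youden_index == pytest.approx(oracle_yi, abs=1e-12)


def test_relabel_and_negate_symmetry(rng):
    """Swapping the classes and negating the orientation leaves the
    optimal Youden index unchanged."""
    for _ in range(25):
        n = int(rng.integers(4, 30))
        truth = rng.random(n) < 0.5
        if truth.all() or not truth.any():
            continue
        medians = rng.random(n) * 10
        _, cal = yb.best_cutoff(_summaries(medians), _labels(truth))
        _, cal_flip = yb.best_cutoff(_summaries(-medians), _labels(~truth))
        assert cal.youden_index == pytest.approx(cal_flip.youden_index, abs=1e-12)


def test_single_distinct_median_degenerates_to_no_call():
    cutoff, cal = yb.best_cutoff(_summaries([2.0, 2.0]), _labels([0, 1]))
    assert cutoff == 2.0
    assert cal.youden_index == 0.0


def test_candidate_cutoffs_are_midpoints():
    assert candidate_cutoffs([1.0, 3.0, 2.0, 3.0]) == [1.5, 2.5]


# ---------------------------------------------------------------------------
# confusion_metrics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "counts, sens, spec, acc, yi",
    [
        # published per-assay confusion lists, 23 pathogenic + 23 benign truth
        (yb.ConfusionCounts(tp=22, fp=5, tn=18, fn=1), 0.957, 0.783, 0.870, 0.739),  # intra-HR
        (yb.ConfusionCounts(tp=20, fp=2, tn=21, fn=3), 0.870, 0.913, 0.891, 0.783),  # inter-HR
        (yb.ConfusionCounts(tp=21, fp=3, tn=20, fn=2), 0.913, 0.870, 0.891, 0.783),  # GR
        (yb.ConfusionCounts(tp=23, fp=2, tn=21, fn=0), 1.000, 0.913, 0.957, 0.913),  # SCP
    ],
)
def test_confusion_metrics_reproduce_published_assay_performance(counts, sens, spec, acc, yi):
    m = yb.confusion_metrics(counts)
    assert round(m.sensitivity, 3) == sens
    assert round(m.specificity, 3) == spec
    assert round(m.accuracy, 3) == acc
    assert round(m.youden_index, 3) == yi


def test_confusion_metrics_perfect_classifier():
    m = yb.confusion_metrics(yb.ConfusionCounts(tp=7, fp=0, tn=7, fn=0))
    assert (m.sensitivity, m.specificity, m.accuracy, m.youden_index) == (1, 1, 1, 1)


def test_confusion_metrics_empty_class_undefined():
    with pytest.raises(yb.UndefinedMetricError):
        yb.confusion_metrics(yb.ConfusionCounts(tp=3, fp=0, tn=0, fn=2))
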