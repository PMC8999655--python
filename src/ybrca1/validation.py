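"""Per-assay calibration: normalization, waterfall summaries, ROC sweep,
Youden-index best cut-off, confusion metrics.

Orientation is fixed for all four assays: a *higher* readout calls the
variant pathogenic (HR and GR frequencies increase, and SCP colonies
grow larger, when BRCA1 function is lost). A variant is called
pathogenic when its median readout is strictly above the cut-off;
a median exactly at the cut-off is benign.

Normalization policy: HR and GR readouts are expressed as fold of the
wild-type-control median; SCP is kept in raw cells-per-colony. Both
modes are exposed per assay.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateControlError, UndefinedMetricError
from .panel_io import Assay, AssayMeasurement, AssayPanel, PriorLabel


class Normalization(str, enum.Enum):
    """How replicate readouts are scaled before summarizing."""

    FOLD_OF_CONTROL_MEDIAN = "fold_of_control_median"
    RAW = "raw"


#: Default per-assay normalization policy: frequencies as fold of the
#: wild-type control median, SCP in raw cells per colony.
DEFAULT_NORMALIZATION: dict[Assay, Normalization] = {
    Assay.INTRA_HR: Normalization.FOLD_OF_CONTROL_MEDIAN,
    Assay.INTER_HR: Normalization.FOLD_OF_CONTROL_MEDIAN,
    Assay.GR: Normalization.FOLD_OF_CONTROL_MEDIAN,
    Assay.SCP: Normalization.RAW,
}


@dataclass(frozen=True)
class VariantSummary:
    """Median and interquartile range of one variant's replicates in one assay."""

    variant_id: str
    assay: Assay
    median_value: float
    q1: float
    q3: float
    n_replicates: int

    def __post_init__(self) -> None:
        if not self.q1 <= self.median_value <= self.q3:
            raise ValueError(
                f"quartiles out of order for {self.variant_id}: "
                f"q1={self.q1}, median={self.median_value}, q3={self.q3}"
            )


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts against the prior labels."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class ConfusionMetrics:
    sensitivity: float
    specificity: float
    accuracy: float
    youden_index: float


@dataclass
class AssayCalibration:
    """Fitted cut-off, ROC curve, and performance metrics for one assay."""

    assay: Assay
    best_cutoff: float
    roc_points: list[tuple[float, float]]
    auroc: float
    sensitivity: float
    specificity: float
    accuracy: float
    youden_index: float
    fp_variants: list[str]
    fn_variants: list[str]
    counts: ConfusionCounts
    normalization: Normalization = Normalization.FOLD_OF_CONTROL_MEDIAN


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def normalized_values(
    measurement: AssayMeasurement, normalization: Normalization | str
) -> np.ndarray:
    """Replicate readouts on the analysis scale (fold of control median, or raw)."""
    normalization = Normalization(normalization)
    values = np.asarray(measurement.replicates, dtype=float)
    if normalization is Normalization.RAW:
        return values
    if len(measurement.control_replicates) == 0:
        raise DegenerateControlError(
            f"{measurement.variant_id}/{measurement.assay.value}: fold normalization "
            "requested but no control replicates present"
        )
    ctrl_median = float(np.median(measurement.control_replicates))
    if ctrl_median == 0.0:
        raise DegenerateControlError(
            f"{measurement.variant_id}/{measurement.assay.value}: control median is zero"
        )
    return values / ctrl_median


def summarize(
    measurement: AssayMeasurement, normalization: Normalization | str
) -> VariantSummary:
    """Median and quartiles (linear interpolation) of the normalized replicates."""
    values = normalized_values(measurement, normalization)
    q1, med, q3 = np.percentile(values, [25.0, 50.0, 75.0], method="linear")
    return VariantSummary(
        variant_id=measurement.variant_id,
        assay=measurement.assay,
        median_value=float(med),
        q1=float(q1),
        q3=float(q3),
        n_replicates=len(values),
    )


def summarize_panel(
    panel: AssayPanel,
    assay: Assay,
    normalization: Normalization | str | None = None,
) -> list[VariantSummary]:
    """Summaries for every variant measured in ``assay``, in panel order."""
    if normalization is None:
        normalization = DEFAULT_NORMALIZATION[assay]
    return [
        summarize(panel.measurements[(v.id, assay)], normalization)
        for v in panel.variants
        if (v.id, assay) in panel.measurements
    ]


# ---------------------------------------------------------------------------
# ROC and cut-off
# ---------------------------------------------------------------------------


def _split_classes(
    summaries: Sequence[VariantSummary], labels: Mapping[str, PriorLabel]
) -> tuple[np.ndarray, np.ndarray]:
    """(medians, is_pathogenic) over the classified variants, VUS excluded."""
    medians, truth = [], []
    for s in summaries:
        label = labels[s.variant_id]
        if label is PriorLabel.VUS:
            continue
        medians.append(s.median_value)
        truth.append(label is PriorLabel.PATHOGENIC)
    medians_arr = np.asarray(medians, dtype=float)
    truth_arr = np.asarray(truth, dtype=bool)
    if truth_arr.sum() == 0 or (~truth_arr).sum() == 0:
        raise UndefinedMetricError(
            "ROC requires at least one pathogenic and one benign variant"
        )
    return medians_arr, truth_arr


def roc_sweep(
    summaries: Sequence[VariantSummary], labels: Mapping[str, PriorLabel]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and AUROC for the "median > threshold" classifier.

    The threshold sweeps over all distinct median values; variants tied
    at one value enter the curve atomically, so the trapezoidal AUROC
    credits ties 0.5 and equals the normalized Mann-Whitney U statistic.
    Points run from (0, 0) to (1, 1).
    """
    medians, truth = _split_classes(summaries, labels)
    n_pos = int(truth.sum())
    n_neg = int((~truth).sum())

    points = [(0.0, 0.0)]
    # descending distinct thresholds: at each, call pathogenic all medians >= v
    for v in np.unique(medians)[::-1]:
        called = medians >= v
        tpr = float((called & truth).sum()) / n_pos
        fpr = float((called & ~truth).sum()) / n_neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):  # pragma: no cover - last threshold includes all
        points.append((1.0, 1.0))

    fprs = np.array([p[0] for p in points])
    tprs = np.array([p[1] for p in points])
    auroc = float(np.trapezoid(tprs, fprs))
    return points, auroc


def _confusion_at(
    medians: np.ndarray, truth: np.ndarray, cutoff: float
) -> ConfusionCounts:
    called = medians > cutoff
    return ConfusionCounts(
        tp=int((called & truth).sum()),
        fp=int((called & ~truth).sum()),
        tn=int((~called & ~truth).sum()),
        fn=int((~called & truth).sum()),
    )


def confusion_metrics(counts: ConfusionCounts) -> ConfusionMetrics:
    """Sensitivity, specificity, accuracy, and Youden index.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/(TP+FN+TN+FP), YI = sensitivity + specificity - 1.
    Full precision; rounding happens only at report time.
    """
    if counts.tp + counts.fn == 0 or counts.tn + counts.fp == 0:
        raise UndefinedMetricError("confusion metrics undefined without both classes")
    sens = counts.tp / (counts.tp + counts.fn)
    spec = counts.tn / (counts.tn + counts.fp)
    acc = (counts.tp + counts.tn) / counts.n
    return ConfusionMetrics(
        sensitivity=sens, specificity=spec, accuracy=acc, youden_index=sens + spec - 1.0
    )


def candidate_cutoffs(medians: Iterable[float]) -> list[float]:
    """Candidate thresholds: midpoints between consecutive distinct medians.

    Published best cut-offs fall between variant values rather than on
    them, hence midpoints. A single distinct median yields itself as the
    only candidate (everything called benign).
    """
    distinct = np.unique(np.asarray(list(medians), dtype=float))
    if len(distinct) == 1:
        return [float(distinct[0])]
    return [float(m) for m in (distinct[:-1] + distinct[1:]) / 2.0]


def best_cutoff(
    summaries: Sequence[VariantSummary],
    labels: Mapping[str, PriorLabel],
    normalization: Normalization | str | None = None,
) -> tuple[float, AssayCalibration]:
    """Cut-off maximizing the Youden index, with the full calibration record.

    Ties in YI are broken toward higher specificity, then the smaller
    threshold. VUS are excluded from the fit by :func:`_split_classes`.
    """
    medians, truth = _split_classes(summaries, labels)
    assay = summaries[0].assay
    if normalization is None:
        normalization = DEFAULT_NORMALIZATION[assay]

    best: tuple[float, float, float] | None = None  # (yi, specificity, -cutoff) to maximize
    best_c: float | None = None
    for c in candidate_cutoffs(medians):
        m = confusion_metrics(_confusion_at(medians, truth, c))
        key = (m.youden_index, m.specificity, -c)
        if best is None or key > best:
            best, best_c = key, c
    assert best_c is not None

    counts = _confusion_at(medians, truth, best_c)
    metrics = confusion_metrics(counts)
    roc_points, auroc = roc_sweep(summaries, labels)

    classified = [
        s for s in summaries if labels[s.variant_id] is not PriorLabel.VUS
    ]
    fp_variants = [
        s.variant_id
        for s in classified
        if labels[s.variant_id] is PriorLabel.BENIGN and s.median_value > best_c
    ]
    fn_variants = [
        s.variant_id
        for s in classified
        if labels[s.variant_id] is PriorLabel.PATHOGENIC and s.median_value <= best_c
    ]

    calibration = AssayCalibration(
        assay=assay,
        best_cutoff=float(best_c),
        roc_points=roc_points,
        auroc=auroc,
        sensitivity=metrics.sensitivity,
        specificity=metrics.specificity,
        accuracy=metrics.accuracy,
        youden_index=metrics.youden_index,
        fp_variants=fp_variants,
        fn_variants=fn_variants,
        counts=counts,
        normalization=Normalization(normalization),
    )
    return float(best_c), calibration


def calibrate_panel(
    panel: AssayPanel,
    normalization: Mapping[Assay, Normalization] | None = None,
) -> dict[Assay, AssayCalibration]:
    """Fit the best cut-off for every assay present in the panel."""
    policy = dict(DEFAULT_NORMALIZATION)
    if normalization:
        policy.update(normalization)
    labels = panel.labels()
    out = {}
    for assay in panel.assays:
        summaries = summarize_panel(panel, assay, policy[assay])
        _, out[assay] = best_cutoff(summaries, labels, policy[assay])
    return out


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def export_waterfall(
    summaries: Sequence[VariantSummary],
    labels: Mapping[str, PriorLabel],
    cutoff: float,
    path: str | Path,
) -> Path:
    """One TSV row per variant, ordered by descending median — enough to
    redraw the waterfall distribution with the cut-off line."""
    rows = [
        {
            "variant_id": s.variant_id,
            "assay": s.assay.value,
            "prior_label": labels[s.variant_id].value,
            "median": s.median_value,
            "q1": s.q1,
            "q3": s.q3,
            "n_replicates": s.n_replicates,
            "call": "pathogenic" if s.median_value > cutoff else "benign",
            "above_cutoff": int(s.median_value > cutoff),
        }
        for s in sorted(summaries, key=lambda s: -s.median_value)
    ]
    df = pd.DataFrame(rows)
    df["cutoff"] = cutoff
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def export_calibration_summary(
    calibrations: Mapping[Assay, AssayCalibration], path: str | Path, digits: int = 3
) -> Path:
    """Per-assay performance table (sensitivity/specificity/accuracy/AUROC/YI,
    cut-off, FP and FN variant lists), rounded at report time only."""
    rows = [
        {
            "assay": a.value,
            "sensitivity": round(c.sensitivity, digits),
            "specificity": round(c.specificity, digits),
            "accuracy": round(c.accuracy, digits),
            "auroc": round(c.auroc, digits),
            "youden_index": round(c.youden_index, digits),
            "best_cutoff": round(c.best_cutoff, digits),
            "normalization": c.normalization.value,
            "fp_variants": " ".join(c.fp_variants),
            "fn_variants": " ".join(c.fn_variants),
        }
        for a, c in calibrations.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return Path(path)
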