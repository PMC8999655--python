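"""Majority-voting integration of per-assay calls into the final yBRCA1
classification, plus combined-performance statistics.

Each assay is one classifier with equal weight. A variant's pathogenic
votes PV count its pathogenic calls across assays; the pathogenic
prediction score is PPS = PV / n_assays; the final label is pathogenic
iff PPS > 0.5. A tie (PPS exactly 0.5, e.g. 2 of 4 assays) resolves to
benign.

Two voting modes exist: ``fi_votes`` counts FI labels (median vs
cut-off) — the mode consistent with the published per-variant tables —
and ``ps_votes`` counts assays with PS > 0.5, the literal
prediction-score reading. They differ only for low-confidence calls
whose median and bootstrap mass fall on opposite sides of the cut-off.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from math import sqrt
from typing import Mapping, Sequence

from statsmodels.stats.proportion import proportion_confint

from .errors import ConsistencyError, UndefinedMetricError
from .panel_io import Assay, PriorLabel
from .scoring import ImpactCall
from .validation import ConfusionCounts, confusion_metrics


class VoteMode(str, enum.Enum):
    FI_VOTES = "fi_votes"
    PS_VOTES = "ps_votes"


@dataclass(frozen=True)
class IntegratedCall:
    """Final majority-vote classification of one variant."""

    variant_id: str
    pv: int
    pps: float
    label: PriorLabel

    def __post_init__(self) -> None:
        if self.label is PriorLabel.VUS:
            raise ValueError("integrated label must be pathogenic or benign")


@dataclass(frozen=True)
class CombinedPerformance:
    accuracy: float
    accuracy_ci95: tuple[float, float]
    sensitivity: float
    specificity: float
    auroc: float
    mcc: float
    kappa: float
    counts: ConfusionCounts


def integrate(
    calls: Sequence[ImpactCall],
    n_assays: int,
    mode: VoteMode | str = VoteMode.FI_VOTES,
) -> IntegratedCall:
    """Combine one variant's per-assay calls by equal-weight majority vote."""
    mode = VoteMode(mode)
    if not calls:
        raise ConsistencyError("no per-assay calls given")
    vid = calls[0].variant_id
    if any(c.variant_id != vid for c in calls):
        raise ConsistencyError("calls describe different variants")
    assays = {c.assay for c in calls}
    if len(calls) != n_assays or len(assays) != n_assays:
        raise ConsistencyError(
            f"variant {vid}: expected one call per each of {n_assays} assays, "
            f"got {len(calls)} calls over {len(assays)} assays"
        )
    if mode is VoteMode.FI_VOTES:
        pv = sum(c.fi is PriorLabel.PATHOGENIC for c in calls)
    else:
        pv = sum(c.ps > 0.5 for c in calls)
    pps = pv / n_assays
    label = PriorLabel.PATHOGENIC if pps > 0.5 else PriorLabel.BENIGN
    return IntegratedCall(variant_id=vid, pv=pv, pps=pps, label=label)


def integrate_panel(
    per_assay: Sequence[ImpactCall],
    n_assays: int | None = None,
    mode: VoteMode | str = VoteMode.FI_VOTES,
) -> list[IntegratedCall]:
    """Integrate every variant present in a flat list of per-assay calls."""
    by_variant: dict[str, list[ImpactCall]] = {}
    for c in per_assay:
        by_variant.setdefault(c.variant_id, []).append(c)
    if n_assays is None:
        n_assays = len({c.assay for c in per_assay})
    return [integrate(calls, n_assays, mode) for calls in by_variant.values()]


# ---------------------------------------------------------------------------
# Combined performance
# ---------------------------------------------------------------------------


def _pps_auroc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Pairwise-comparison AUROC of PPS as a ranking score (0.5 tie credit).

    PPS takes few distinct values, so the rank-sum form with explicit
    tie credit is simpler and exact."""
    pos = [s for s, t in zip(scores, truth) if t]
    neg = [s for s, t in zip(scores, truth) if not t]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def combined_performance(
    integrated: Sequence[IntegratedCall],
    truth: Mapping[str, PriorLabel],
    alpha: float = 0.05,
) -> CombinedPerformance:
    """Performance of the integrated classifier on the classified variants.

    Accuracy CI is the exact (Clopper-Pearson) binomial interval. AUROC
    ranks variants by PPS. MCC and Cohen's kappa come from the 2x2
    confusion matrix.
    """
    classified = [c for c in integrated if truth[c.variant_id] is not PriorLabel.VUS]
    if not classified:
        raise UndefinedMetricError("no classified (non-VUS) variants to evaluate")
    is_path = [truth[c.variant_id] is PriorLabel.PATHOGENIC for c in classified]
    called_path = [c.label is PriorLabel.PATHOGENIC for c in classified]
    if all(is_path) or not any(is_path):
        raise UndefinedMetricError("combined performance requires both truth classes")

    counts = ConfusionCounts(
        tp=sum(c and t for c, t in zip(called_path, is_path)),
        fp=sum(c and not t for c, t in zip(called_path, is_path)),
        tn=sum(not c and not t for c, t in zip(called_path, is_path)),
        fn=sum(not c and t for c, t in zip(called_path, is_path)),
    )
    m = confusion_metrics(counts)
    correct = counts.tp + counts.tn
    lo, hi = proportion_confint(correct, counts.n, alpha=alpha, method="beta")

    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0

    po = m.accuracy
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / counts.n**2
    kappa = (po - pe) / (1.0 - pe) if pe != 1.0 else 1.0

    auroc = _pps_auroc([c.pps for c in classified], is_path)

    return CombinedPerformance(
        accuracy=m.accuracy,
        accuracy_ci95=(float(lo), float(hi)),
        sensitivity=m.sensitivity,
        specificity=m.specificity,
        auroc=auroc,
        mcc=mcc,
        kappa=kappa,
        counts=counts,
    )


def concordance_report(
    call_matrix: Mapping[str, Mapping[Assay, bool]],
    truth: Mapping[str, PriorLabel],
) -> tuple[int, dict[str, dict[Assay, str]]]:
    """Count variants called correctly by *every* assay.

    ``call_matrix[variant][assay]`` is True for a pathogenic call.
    Returns ``(n_all_correct, discordant)`` where ``discordant`` maps
    each remaining variant to its per-assay error annotation
    ("false_positive" / "false_negative").
    """
    n_all_correct = 0
    discordant: dict[str, dict[Assay, str]] = {}
    assay_set: set[Assay] | None = None
    for vid, calls in call_matrix.items():
        label = truth[vid]
        if label is PriorLabel.VUS:
            continue
        is_path = label is PriorLabel.PATHOGENIC
        if assay_set is None:
            assay_set = set(calls)
            if not assay_set:
                raise ConsistencyError(f"variant {vid}: empty call matrix row")
        if set(calls) != assay_set:
            raise ConsistencyError(f"variant {vid}: incomplete call matrix row")
        errors = {
            a: ("false_negative" if is_path else "false_positive")
            for a, called in calls.items()
            if called is not is_path
        }
        if errors:
            discordant[vid] = errors
        else:
            n_all_correct += 1
    return n_all_correct, discordant
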