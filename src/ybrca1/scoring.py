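"""Per-variant, per-assay functional-impact calls and bootstrap
prediction scores.

FI (functional impact) is the binary call: pathogenic iff the variant's
median normalized readout is strictly above the assay's best cut-off.

PS (prediction score) quantifies confidence in the pathogenic direction
as a bootstrap exceedance probability: replicates are resampled with
replacement B times and PS is the fraction of bootstrap medians
strictly above the cut-off, clamped to [1/B, 1 - 1/B] so the score is
never exactly 0 or 1. The default B = 4000 gives scores on a 0.00025
grid with extremes 0.00025 and 0.99975. FI is determined by the
observed median, never by PS, so FI = pathogenic with PS < 0.5 is a
legitimate (low-confidence) state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .panel_io import Assay, AssayMeasurement, AssayPanel, PriorLabel
from .validation import (
    AssayCalibration,
    Normalization,
    VariantSummary,
    normalized_values,
    summarize,
)

DEFAULT_BOOTSTRAP_B = 4000
MIN_BOOTSTRAP_B = 100


@dataclass(frozen=True)
class ImpactCall:
    """One variant's call in one assay: FI label plus bootstrap PS."""

    variant_id: str
    assay: Assay
    fi: PriorLabel
    ps: float
    n_bootstrap: int

    def __post_init__(self) -> None:
        if self.fi is PriorLabel.VUS:
            raise ValueError("functional impact must be pathogenic or benign")
        if not 0.0 < self.ps < 1.0:
            raise ValueError(f"ps must lie strictly inside (0, 1), got {self.ps}")


def functional_impact(summary: VariantSummary, cutoff: float) -> PriorLabel:
    """Pathogenic iff the median is strictly above the cut-off; a median
    exactly at the cut-off is benign."""
    return PriorLabel.PATHOGENIC if summary.median_value > cutoff else PriorLabel.BENIGN


def bootstrap_ps(
    measurement: AssayMeasurement,
    cutoff: float,
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int | np.random.Generator = 0,
    normalization: Normalization | str = Normalization.FOLD_OF_CONTROL_MEDIAN,
) -> float:
    """Bootstrap exceedance probability of the median over the cut-off.

    ``seed`` may be an integer or an already-initialized Generator (the
    latter lets one shared stream govern all draws in a run).
    """
    if B < MIN_BOOTSTRAP_B:
        raise ConfigError(f"B must be >= {MIN_BOOTSTRAP_B} for stable scores, got {B}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = normalized_values(measurement, normalization)
    n = len(values)
    idx = rng.integers(0, n, size=(B, n))
    boot_medians = np.median(values[idx], axis=1)
    ps = float(np.count_nonzero(boot_medians > cutoff)) / B
    return float(np.clip(ps, 1.0 / B, 1.0 - 1.0 / B))


def score_panel(
    panel: AssayPanel,
    calibrations: Mapping[Assay, AssayCalibration],
    B: int = DEFAULT_BOOTSTRAP_B,
    seed: int = 0,
    assays: Sequence[Assay] | None = None,
) -> list[ImpactCall]:
    """FI and PS for every variant (VUS included) in every calibrated assay.

    One shared seed governs all bootstrap draws; calls are produced in
    panel order, assay-major within variant, so a run is reproducible
    from (panel, calibrations, B, seed) alone.
    """
    rng = np.random.default_rng(seed)
    if assays is None:
        assays = [a for a in Assay if a in calibrations]
    calls: list[ImpactCall] = []
    for v in panel.variants:
        for assay in assays:
            m = panel.measurements[(v.id, assay)]
            cal = calibrations[assay]
            s = summarize(m, cal.normalization)
            calls.append(
                ImpactCall(
                    variant_id=v.id,
                    assay=assay,
                    fi=functional_impact(s, cal.best_cutoff),
                    ps=bootstrap_ps(m, cal.best_cutoff, B=B, seed=rng, normalization=cal.normalization),
                    n_bootstrap=B,
                )
            )
    return calls
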