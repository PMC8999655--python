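"""Synthetic assay-panel generator.

Generates :class:`~ybrca1.panel_io.AssayPanel` objects with the
statistical structure the downstream analysis assumes, so that every
stage of the pipeline is testable without access to raw laboratory
data.

Model
-----
Replicate readouts are log-normal: colony-count-derived frequencies are
strictly positive and right-skewed, and a multiplicative error model is
the natural choice. Each replicate for a variant with fold-shift *f* in
an assay with control location *L* is drawn as::

    value = L * f * exp(sigma * Z),   Z ~ N(0, 1),
    sigma = sqrt(log(1 + cv^2))

so the *median* of the distribution is exactly ``L * f`` — fold shifts
act on the median, matching the median-based statistics used downstream.
Control replicates are drawn with fold 1 and pooled per assay (one
wild-type control series per assay, attached to every measurement).

Benign variants sit at the control location (fold 1 by default);
pathogenic variants are shifted upward (default 3-fold). The SCP assay
is generated in cells-per-colony units with the same machinery —
pathogenic variants relieve the growth inhibition imposed by wild-type
BRCA1, so colonies are *larger* — which keeps the "higher readout means
pathogenic" orientation uniform across all four assays. VUS behave
pathogenic in an assay with probability ``vus_mixture_prob``,
independently per assay; the realized behaviour is available from
:func:`generate_panel_with_truth` so parameter-recovery tests can score
VUS calls.

Not modelled: plating/colony Poisson sampling, survival fractions,
galactose-induction kinetics, or between-batch control drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import reference
from .errors import ConfigError
from .panel_io import Assay, AssayMeasurement, AssayPanel, PriorLabel, VariantRecord

#: Typical wild-type control readouts, in each assay's own units
#: (HR/GR: recombinant or revertant colonies per 10^4 / 10^5 / 10^6
#: plated cells; SCP: cells per colony).
DEFAULT_CONTROL_LOCATIONS: dict[Assay, float] = {
    Assay.INTRA_HR: 2.0,
    Assay.INTER_HR: 3.0,
    Assay.GR: 2.0,
    Assay.SCP: 10.0,
}


@dataclass(frozen=True)
class AssayParams:
    """Generator parameters for one assay.

    control_location
        Median readout of the wild-type control, in assay units.
    replicate_cv
        Coefficient of variation of the log-normal replicate noise on
        the natural scale.
    pathogenic_fold
        Median fold-shift of pathogenic variants relative to control.
    benign_fold
        Median fold-shift of benign variants (1.0 = at control).
    vus_mixture_prob
        Probability that a VUS behaves pathogenic in this assay.
    """

    control_location: float
    replicate_cv: float = 0.3
    pathogenic_fold: float = 3.0
    benign_fold: float = 1.0
    vus_mixture_prob: float = 0.5

    def __post_init__(self) -> None:
        for name in ("control_location", "replicate_cv", "pathogenic_fold", "benign_fold"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not 0.0 <= self.vus_mixture_prob <= 1.0:
            raise ConfigError(f"vus_mixture_prob must be in [0, 1], got {self.vus_mixture_prob!r}")

    @property
    def sigma(self) -> float:
        """Log-scale standard deviation implied by the natural-scale CV."""
        return float(np.sqrt(np.log1p(self.replicate_cv**2)))


def default_assay_params(**overrides: float) -> dict[Assay, AssayParams]:
    return {
        a: AssayParams(control_location=DEFAULT_CONTROL_LOCATIONS[a], **overrides) for a in Assay
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Full panel-generation configuration.

    Defaults mirror the benchmark study design: 23 pathogenic + 23
    benign + 10 VUS variants, 5 replicates each (the experimental
    minimum), 3-fold pathogenic shift, CV 0.3.
    """

    n_pathogenic: int = 23
    n_benign: int = 23
    n_vus: int = 10
    n_replicates: int = 5
    seed: int = 0
    assays: dict[Assay, AssayParams] = field(default_factory=default_assay_params)

    def __post_init__(self) -> None:
        for name in ("n_pathogenic", "n_benign", "n_vus"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if not self.assays:
            raise ConfigError("at least one assay block required")


def config_from_dict(tree: dict) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` from a plain key tree (YAML/JSON)."""
    tree = dict(tree)
    assay_tree = tree.pop("assays", None)
    if assay_tree is not None:
        assays = {}
        for token, block in assay_tree.items():
            assay = Assay(token) if not isinstance(token, Assay) else token
            block = dict(block)
            block.setdefault("control_location", DEFAULT_CONTROL_LOCATIONS[assay])
            assays[assay] = AssayParams(**block)
        tree["assays"] = assays
    return GeneratorConfig(**tree)


def _lognormal(rng: np.random.Generator, median: float, sigma: float, n: int) -> tuple[float, ...]:
    return tuple(float(x) for x in median * np.exp(sigma * rng.standard_normal(n)))


def generate_panel_with_truth(
    config: GeneratorConfig,
) -> tuple[AssayPanel, dict[str, dict[Assay, bool]]]:
    """Generate a panel plus the generator's ground truth.

    Returns ``(panel, behaviour)`` where ``behaviour[variant][assay]``
    is True when the generator made that variant behave pathogenic in
    that assay (for classified variants this follows the prior label;
    for VUS it is the realized per-assay mixture draw).
    """
    rng = np.random.default_rng(config.seed)
    variants = (
        [(f"p.PAT{i:03d}", PriorLabel.PATHOGENIC) for i in range(1, config.n_pathogenic + 1)]
        + [(f"p.BEN{i:03d}", PriorLabel.BENIGN) for i in range(1, config.n_benign + 1)]
        + [(f"p.VUS{i:03d}", PriorLabel.VUS) for i in range(1, config.n_vus + 1)]
    )

    behaviour: dict[str, dict[Assay, bool]] = {vid: {} for vid, _ in variants}
    measurements: dict[tuple[str, Assay], AssayMeasurement] = {}
    for assay, params in config.assays.items():
        controls = _lognormal(rng, params.control_location, params.sigma, config.n_replicates)
        for vid, label in variants:
            if label is PriorLabel.VUS:
                is_path = bool(rng.random() < params.vus_mixture_prob)
            else:
                is_path = label is PriorLabel.PATHOGENIC
            behaviour[vid][assay] = is_path
            fold = params.pathogenic_fold if is_path else params.benign_fold
            reps = _lognormal(rng, params.control_location * fold, params.sigma, config.n_replicates)
            measurements[(vid, assay)] = AssayMeasurement(
                variant_id=vid, assay=assay, replicates=reps, control_replicates=controls
            )

    panel = AssayPanel(
        variants=[VariantRecord(vid, label) for vid, label in variants],
        measurements=measurements,
    )
    return panel, behaviour


def generate_panel(config: GeneratorConfig) -> AssayPanel:
    """Generate a synthetic panel (see :func:`generate_panel_with_truth`)."""
    return generate_panel_with_truth(config)[0]


# Fold placement for planted discordant variants. A benign variant that
# an assay must miscall pathogenic is planted *above* the pathogenic
# cluster, and a pathogenic variant the assay must miss is planted
# *below* the control cluster: if a planted variant sat inside a
# cluster, a threshold splitting that cluster could achieve a higher
# Youden index and the published confusion sets would not be recovered
# deterministically.
_FP_FOLD_FACTOR = 1.3  # x pathogenic_fold, applied to planted false positives
_FN_FOLD = 0.75  # fold for planted false negatives (below control)


def generate_paper_like_panel(
    seed: int, replicate_cv: float = 0.05, n_replicates: int = 5
) -> AssayPanel:
    """Generate the 46+10-variant benchmark panel with the published
    discordance structure planted.

    Benign variants listed as false positives of an assay receive an
    elevated readout in exactly that assay; pathogenic variants listed
    as its false negatives stay at/below control there. VUS are planted
    to follow their published per-assay impact labels. At low replicate
    CV (default 0.05) the Youden-optimal cutoffs recover the published
    false-positive/false-negative sets exactly, so the integrated
    classifier's published behaviour (2 of 46 misclassified, 35 of 46
    concordant in every assay, 6 pathogenic / 4 benign VUS) is
    reproduced end to end.
    """
    rng = np.random.default_rng(seed)
    params = default_assay_params(replicate_cv=replicate_cv)

    roster = (
        [(vid, PriorLabel.PATHOGENIC) for vid in reference.PATHOGENIC_VARIANTS]
        + [(vid, PriorLabel.BENIGN) for vid in reference.BENIGN_VARIANTS]
        + [(vid, PriorLabel.VUS) for vid in reference.VUS_VARIANTS]
    )

    measurements: dict[tuple[str, Assay], AssayMeasurement] = {}
    for assay in Assay:
        p = params[assay]
        controls = _lognormal(rng, p.control_location, p.sigma, n_replicates)
        for vid, label in roster:
            if label is PriorLabel.PATHOGENIC:
                fold = _FN_FOLD if vid in reference.FALSE_NEGATIVES[assay] else p.pathogenic_fold
            elif label is PriorLabel.BENIGN:
                fold = (
                    p.pathogenic_fold * _FP_FOLD_FACTOR
                    if vid in reference.FALSE_POSITIVES[assay]
                    else p.benign_fold
                )
            else:
                fold = p.pathogenic_fold if reference.VUS_IMPACT[vid][assay] else p.benign_fold
            reps = _lognormal(rng, p.control_location * fold, p.sigma, n_replicates)
            measurements[(vid, assay)] = AssayMeasurement(
                variant_id=vid, assay=assay, replicates=reps, control_replicates=controls
            )

    return AssayPanel(
        variants=[VariantRecord(vid, label) for vid, label in roster],
        measurements=measurements,
    )
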