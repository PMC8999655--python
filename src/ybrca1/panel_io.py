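"""Domain types for a variant/assay panel and tabular readers/writers.

A *panel* couples a roster of BRCA1 missense variants (each carrying a
prior clinical label: pathogenic, benign, or VUS) with replicate-level
readouts from up to four yeast functional assays:

* ``intra_hr`` — intra-chromosomal homologous recombination
  (HIS3 colonies per 10^4 plated cells),
* ``inter_hr`` — inter-chromosomal homologous recombination
  (ADE2 colonies per 10^5 plated cells),
* ``gr``       — gene reversion of ilv1-92
  (ILV1 colonies per 10^6 plated cells),
* ``scp``      — small colony phenotype (cells per colony).

Each measurement carries its own wild-type-BRCA1 control replicates so
that readouts can be normalized as fold of the control median.

Interchange format is a long ("tidy") UTF-8 table with columns
``variant_id, prior_label, assay, replicate_index, value, is_control``
— one row per replicate, variant rows and control rows side by side.
HGVS protein strings (e.g. ``p.R71K``) are treated as opaque
identifiers; the pipeline never parses residue positions.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import (
    ConsistencyError,
    FewReplicatesWarning,
    PanelFormatError,
    PanelValidationError,
)

PANEL_COLUMNS = ("variant_id", "prior_label", "assay", "replicate_index", "value", "is_control")

#: Replicate count below which the pipeline warns (assays are run in at
#: least five independent experiments).
MIN_RECOMMENDED_REPLICATES = 5


class Assay(str, enum.Enum):
    """The four yeast-based functional assays."""

    INTRA_HR = "intra_hr"
    INTER_HR = "inter_hr"
    GR = "gr"
    SCP = "scp"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class PriorLabel(str, enum.Enum):
    """Prior clinical classification of a variant."""

    PATHOGENIC = "pathogenic"
    BENIGN = "benign"
    VUS = "vus"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


_LABEL_TOKENS = {
    "pathogenic": PriorLabel.PATHOGENIC,
    "benign": PriorLabel.BENIGN,
    "vus": PriorLabel.VUS,
}

_ASSAY_TOKENS = {a.value: a for a in Assay}

_BOOL_TOKENS = {
    "0": False, "1": True,
    "false": False, "true": True,
    "f": False, "t": True,
    "no": False, "yes": True,
}


def parse_label(token: str) -> PriorLabel:
    try:
        return _LABEL_TOKENS[str(token).strip().lower()]
    except KeyError:
        raise PanelValidationError(f"unknown prior_label token: {token!r}") from None


def parse_assay(token: str) -> Assay:
    try:
        return _ASSAY_TOKENS[str(token).strip().lower()]
    except KeyError:
        raise PanelValidationError(f"unknown assay token: {token!r}") from None


@dataclass(frozen=True)
class VariantRecord:
    """A variant and its prior classification."""

    id: str
    prior_label: PriorLabel

    def __post_init__(self) -> None:
        if not self.id:
            raise PanelValidationError("variant id must be non-empty")
        if not isinstance(self.prior_label, PriorLabel):
            object.__setattr__(self, "prior_label", parse_label(self.prior_label))


def _check_readouts(values: Sequence[float], what: str, variant_id: str, assay: Assay) -> tuple[float, ...]:
    vals = tuple(float(v) for v in values)
    for v in vals:
        if not math.isfinite(v) or v < 0:
            raise PanelValidationError(
                f"{what} readout for {variant_id}/{assay.value} must be finite and >= 0, got {v!r}"
            )
    return vals


@dataclass(frozen=True)
class AssayMeasurement:
    """Replicate readouts for one variant in one assay, plus matched
    wild-type-control readouts measured under the same conditions.

    Replicate order is preserved as given (file order on read)."""

    variant_id: str
    assay: Assay
    replicates: tuple[float, ...]
    control_replicates: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not isinstance(self.assay, Assay):
            object.__setattr__(self, "assay", parse_assay(self.assay))
        object.__setattr__(
            self, "replicates", _check_readouts(self.replicates, "replicate", self.variant_id, self.assay)
        )
        object.__setattr__(
            self,
            "control_replicates",
            _check_readouts(self.control_replicates, "control", self.variant_id, self.assay),
        )
        if len(self.replicates) < 1:
            raise PanelValidationError(
                f"measurement {self.variant_id}/{self.assay.value} has no replicates"
            )
        if len(self.replicates) < MIN_RECOMMENDED_REPLICATES:
            warnings.warn(
                f"{self.variant_id}/{self.assay.value}: only {len(self.replicates)} replicates "
                f"(recommended minimum is {MIN_RECOMMENDED_REPLICATES})",
                FewReplicatesWarning,
                stacklevel=2,
            )


@dataclass
class AssayPanel:
    """A variant roster plus measurements keyed by (variant_id, assay)."""

    variants: list[VariantRecord]
    measurements: dict[tuple[str, Assay], AssayMeasurement] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [v.id for v in self.variants]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise PanelValidationError(f"duplicate variant ids in panel: {dup}")
        known = set(ids)
        for (vid, assay), m in self.measurements.items():
            if vid not in known:
                raise PanelValidationError(f"measurement references unknown variant {vid!r}")
            if (m.variant_id, m.assay) != (vid, assay):
                raise ConsistencyError(
                    f"measurement keyed ({vid}, {assay.value}) describes "
                    f"({m.variant_id}, {m.assay.value})"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def assays(self) -> list[Assay]:
        """Assays present, in canonical enum order."""
        present = {a for (_, a) in self.measurements}
        return [a for a in Assay if a in present]

    def variant(self, variant_id: str) -> VariantRecord:
        for v in self.variants:
            if v.id == variant_id:
                return v
        raise KeyError(variant_id)

    def labels(self) -> dict[str, PriorLabel]:
        return {v.id: v.prior_label for v in self.variants}

    def measurement(self, variant_id: str, assay: Assay) -> AssayMeasurement:
        return self.measurements[(variant_id, assay)]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AssayPanel):
            return NotImplemented
        return (
            sorted(self.variants, key=lambda v: v.id) == sorted(other.variants, key=lambda v: v.id)
            and self.measurements == other.measurements
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _sep_for(path: Path, format: str | None) -> str:
    if format is None:
        format = "csv" if Path(path).suffix.lower() == ".csv" else "tsv"
    if format not in ("tsv", "csv"):
        raise PanelFormatError(f"unknown format {format!r} (expected 'tsv' or 'csv')")
    return "," if format == "csv" else "\t"


def read_panel(path: str | Path, format: str | None = None) -> AssayPanel:
    """Read a long-format panel table into a validated :class:`AssayPanel`.

    Row order within each (variant, assay, is_control) group defines
    replicate order. Row order across groups is irrelevant: shuffling
    the file yields an equal panel.
    """
    path = Path(path)
    sep = _sep_for(path, format)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in PANEL_COLUMNS:
        if col not in df.columns:
            raise PanelFormatError(f"missing required column: {col!r}")

    variants: dict[str, PriorLabel] = {}
    variant_order: list[str] = []
    groups: dict[tuple[str, Assay, bool], list[float]] = {}
    seen_rows: set[tuple[str, Assay, str, bool]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based incl. header
        vid = str(row.variant_id).strip()
        if not vid:
            raise PanelValidationError(f"row {i}: empty variant_id")
        try:
            label = parse_label(row.prior_label)
            assay = parse_assay(row.assay)
            is_control = _BOOL_TOKENS[str(row.is_control).strip().lower()]
        except KeyError:
            raise PanelValidationError(f"row {i}: bad is_control token {row.is_control!r}") from None
        except PanelValidationError as exc:
            raise PanelValidationError(f"row {i}: {exc}") from None
        try:
            value = float(row.value)
        except ValueError:
            raise PanelValidationError(f"row {i}: non-numeric value {row.value!r}") from None

        if vid in variants:
            if variants[vid] is not label:
                raise PanelValidationError(
                    f"row {i}: variant {vid} carries conflicting prior labels "
                    f"({variants[vid].value} vs {label.value})"
                )
        else:
            variants[vid] = label
            variant_order.append(vid)

        key = (vid, assay, str(row.replicate_index).strip(), is_control)
        if key in seen_rows:
            raise PanelValidationError(
                f"row {i}: duplicate replicate ({vid}, {assay.value}, "
                f"index {row.replicate_index}, is_control={int(is_control)})"
            )
        seen_rows.add(key)
        groups.setdefault((vid, assay, is_control), []).append(value)

    measurements: dict[tuple[str, Assay], AssayMeasurement] = {}
    for vid in variant_order:
        for assay in Assay:
            reps = groups.get((vid, assay, False))
            ctrl = groups.get((vid, assay, True), [])
            if reps is None:
                if ctrl:
                    raise PanelValidationError(
                        f"({vid}, {assay.value}) has control rows but no variant rows"
                    )
                continue
            measurements[(vid, assay)] = AssayMeasurement(
                variant_id=vid, assay=assay, replicates=tuple(reps), control_replicates=tuple(ctrl)
            )

    return AssayPanel(
        variants=[VariantRecord(vid, variants[vid]) for vid in variant_order],
        measurements=measurements,
    )


def write_panel(panel: AssayPanel, path: str | Path, format: str | None = None) -> Path:
    """Write a panel in the long interchange format (inverse of :func:`read_panel`)."""
    path = Path(path)
    sep = _sep_for(path, format)
    rows = []
    for v in panel.variants:
        for assay in Assay:
            m = panel.measurements.get((v.id, assay))
            if m is None:
                continue
            for j, val in enumerate(m.replicates, start=1):
                rows.append((v.id, v.prior_label.value, assay.value, j, val, 0))
            for j, val in enumerate(m.control_replicates, start=1):
                rows.append((v.id, v.prior_label.value, assay.value, j, val, 1))
    pd.DataFrame(rows, columns=PANEL_COLUMNS).to_csv(path, sep=sep, index=False)
    return path


def write_calls(
    calls: Sequence["IntegratedCall"],
    per_assay: Sequence["ImpactCall"],
    path: str | Path,
    assays: Sequence[Assay] | None = None,
    prior_labels: Mapping[str, PriorLabel] | None = None,
    format: str | None = None,
) -> Path:
    """Write the final classification table: one row per variant with
    per-assay (PS, FI) column pairs, then PV, PPS, and the final label.

    When ``prior_labels`` is given, two annotation columns are appended:
    the prior label and, for non-VUS variants, whether the final call
    agrees with it.
    """
    path = Path(path)
    sep = _sep_for(path, format)
    by_variant: dict[str, dict[Assay, "ImpactCall"]] = {}
    for ic in per_assay:
        by_variant.setdefault(ic.variant_id, {})[ic.assay] = ic
    if assays is None:
        present = {ic.assay for ic in per_assay}
        assays = [a for a in Assay if a in present]

    call_ids = {c.variant_id for c in calls}
    if call_ids != set(by_variant) and calls:
        raise ConsistencyError(
            "integrated calls and per-assay calls describe different variant sets: "
            f"{sorted(call_ids ^ set(by_variant))}"
        )

    header = ["variant_id"]
    for a in assays:
        header += [f"{a.value}_ps", f"{a.value}_fi"]
    header += ["pv", "pps", "ybrca1"]
    if prior_labels is not None:
        header += ["prior_label", "correct"]

    rows = []
    for c in calls:
        impacts = by_variant.get(c.variant_id, {})
        missing = [a.value for a in assays if a not in impacts]
        if missing:
            raise ConsistencyError(f"variant {c.variant_id} lacks calls for assays {missing}")
        row: list[object] = [c.variant_id]
        for a in assays:
            ic = impacts[a]
            row += [ic.ps, ic.fi.value]
        row += [c.pv, c.pps, c.label.value]
        if prior_labels is not None:
            prior = prior_labels.get(c.variant_id, PriorLabel.VUS)
            row.append(prior.value)
            row.append("" if prior is PriorLabel.VUS else str(c.label is prior).lower())
        rows.append(row)

    pd.DataFrame(rows, columns=header).to_csv(path, sep=sep, index=False)
    return path
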