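"""Published benchmark structure of the yBRCA1 validation panel.

The yBRCA1 study benchmarked four yeast assays on 23 pathogenic and
23 benign BRCA1 missense variants and then scored 10 VUS. The raw
replicate frequencies were not deposited, but the *call structure* was
published: which benign variants each assay miscalled pathogenic
(false positives), which pathogenic variants it miscalled benign
(false negatives), and the per-assay functional-impact label of every
VUS. Those published lists are encoded here; they drive both the
paper-like synthetic panel and the desk-scale reconstruction of the
reported performance numbers.

Only the discordant variants and the VUS were named in the published
lists; the remaining 19 pathogenic and 16 benign concordant variants
are filled with synthetic placeholder ids (``p.PATsyn##`` /
``p.BENsyn##``). Every downstream statistic depends on the confusion
structure, not on variant identity, so the placeholders are inert.
"""

from __future__ import annotations

from .panel_io import Assay, PriorLabel

N_PATHOGENIC = 23
N_BENIGN = 23
N_VUS = 10

#: Benign variants each assay called pathogenic (false positives).
FALSE_POSITIVES: dict[Assay, tuple[str, ...]] = {
    Assay.INTRA_HR: ("p.Y179C", "p.I1275V", "p.R1347G", "p.S1512I", "p.P1776H"),
    Assay.INTER_HR: ("p.Y179C", "p.I1275V"),
    Assay.GR: ("p.N132K", "p.I1275V", "p.T1675I"),
    Assay.SCP: ("p.I1275V", "p.S1512I"),
}

#: Pathogenic variants each assay called benign (false negatives).
FALSE_NEGATIVES: dict[Assay, tuple[str, ...]] = {
    Assay.INTRA_HR: ("p.R71K",),
    Assay.INTER_HR: ("p.R71K", "p.R1699W", "p.A1708E"),
    Assay.GR: ("p.R71K", "p.R1495M"),
    Assay.SCP: (),
}

#: Per-assay functional-impact labels published for the 10 VUS
#: (True = pathogenic call in that assay).
VUS_IMPACT: dict[str, dict[Assay, bool]] = {
    "p.A1669S": {Assay.INTER_HR: True, Assay.INTRA_HR: False, Assay.GR: False, Assay.SCP: False},
    "p.A1789T": {Assay.INTER_HR: False, Assay.INTRA_HR: False, Assay.GR: False, Assay.SCP: True},
    "p.E1352K": {Assay.INTER_HR: False, Assay.INTRA_HR: True, Assay.GR: True, Assay.SCP: True},
    "p.N1730I": {Assay.INTER_HR: False, Assay.INTRA_HR: True, Assay.GR: True, Assay.SCP: True},
    "p.N1819S": {Assay.INTER_HR: False, Assay.INTRA_HR: False, Assay.GR: True, Assay.SCP: True},
    "p.P1010S": {Assay.INTER_HR: True, Assay.INTRA_HR: False, Assay.GR: True, Assay.SCP: False},
    "p.S1164I": {Assay.INTER_HR: True, Assay.INTRA_HR: True, Assay.GR: True, Assay.SCP: False},
    "p.S592N": {Assay.INTER_HR: False, Assay.INTRA_HR: True, Assay.GR: True, Assay.SCP: True},
    "p.V1791L": {Assay.INTER_HR: True, Assay.INTRA_HR: True, Assay.GR: False, Assay.SCP: True},
    "p.Y1703C": {Assay.INTER_HR: True, Assay.INTRA_HR: True, Assay.GR: True, Assay.SCP: True},
}

_NAMED_PATHOGENIC = ("p.R71K", "p.R1699W", "p.A1708E", "p.R1495M")
_NAMED_BENIGN = (
    "p.Y179C", "p.I1275V", "p.R1347G", "p.S1512I",
    "p.P1776H", "p.N132K", "p.T1675I",
)

#: Panel roster: named discordant variants plus synthetic concordant fillers.
PATHOGENIC_VARIANTS: tuple[str, ...] = _NAMED_PATHOGENIC + tuple(
    f"p.PATsyn{i:02d}" for i in range(1, N_PATHOGENIC - len(_NAMED_PATHOGENIC) + 1)
)
BENIGN_VARIANTS: tuple[str, ...] = _NAMED_BENIGN + tuple(
    f"p.BENsyn{i:02d}" for i in range(1, N_BENIGN - len(_NAMED_BENIGN) + 1)
)
VUS_VARIANTS: tuple[str, ...] = tuple(VUS_IMPACT)


def reference_call_matrix() -> dict[str, dict[Assay, bool]]:
    """Per-variant, per-assay published calls for the 46 classified
    variants (True = called pathogenic by that assay)."""
    matrix: dict[str, dict[Assay, bool]] = {}
    for vid in PATHOGENIC_VARIANTS:
        matrix[vid] = {a: vid not in FALSE_NEGATIVES[a] for a in Assay}
    for vid in BENIGN_VARIANTS:
        matrix[vid] = {a: vid in FALSE_POSITIVES[a] for a in Assay}
    return matrix


def reference_truth() -> dict[str, PriorLabel]:
    """Prior labels of the full 56-variant roster."""
    truth = {vid: PriorLabel.PATHOGENIC for vid in PATHOGENIC_VARIANTS}
    truth.update({vid: PriorLabel.BENIGN for vid in BENIGN_VARIANTS})
    truth.update({vid: PriorLabel.VUS for vid in VUS_VARIANTS})
    return truth
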