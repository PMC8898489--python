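"""ACMG/AMP criterion assignment and combining.

Only the pathogenic-side criteria that the tiered trio workflow can
substantiate are implemented: PVS1, PS1, PS2, PM1, PM2_Supporting, PM3,
PM5, PP1, PP3, PP4, PP5. PM2 is used exclusively at supporting strength
(the ClinGen SVI recommendation). Benign-side criteria are not implemented:
the frequency/in-silico cascade removes their targets before interpretation.

Combining follows the standard ACMG rule matrix with two SVI-era
adjustments: PM2_Supporting counts as a supporting criterion, and PVS1 plus
one supporting criterion reaches likely pathogenic (the SVI recommendation
for PVS1 + PM2_Supporting).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import FrozenSet, Iterable, Optional

from .model import (
    AnnotatedVariant,
    Classification,
    Consequence,
    ContractError,
    FrequencyPanel,
    GeneRecord,
    PredictorPanel,
    TRUNCATING,
)
from .segregation import Model


class Criterion(str, Enum):
    PVS1 = "PVS1"
    PS1 = "PS1"
    PS2 = "PS2"
    PM1 = "PM1"
    PM2_SUPPORTING = "PM2_Supporting"
    PM3 = "PM3"
    PM5 = "PM5"
    PP1 = "PP1"
    PP3 = "PP3"
    PP4 = "PP4"
    PP5 = "PP5"


_VERY_STRONG = {Criterion.PVS1}
_STRONG = {Criterion.PS1, Criterion.PS2}
_MODERATE = {Criterion.PM1, Criterion.PM3, Criterion.PM5}
_SUPPORTING = {Criterion.PM2_SUPPORTING, Criterion.PP1, Criterion.PP3, Criterion.PP4, Criterion.PP5}

_PVS1_CONSEQUENCES = TRUNCATING | {Consequence.SPLICE_CANONICAL}


@dataclass
class PM2Config:
    """Quantitative reading of "absent or extremely low frequency".

    PM2_Supporting holds when the variant is absent from every database, or
    every present global-database MAF is below ``global_cutoff`` and every
    present Japanese-database MAF is below ``japanese_cutoff`` — the
    strictest rarity bar the filtering cascade itself applies.
    """

    global_cutoff: float = 1e-3
    japanese_cutoff: float = 5e-3


@dataclass
class EvidenceContext:
    """Everything the rules engine may consult for one variant.

    Tri-state flags (True / False / None=unknown) never raise: unknown
    evidence simply fails to fire its criterion.
    """

    gene: GeneRecord
    segregation: Optional[Model] = None
    freqs: Optional[FrequencyPanel] = None  # None: no SNV frequency panel (e.g. CNV allele)
    consequence: Consequence = Consequence.OTHER
    predictors: Optional[PredictorPanel] = None
    nmd_escape: Optional[bool] = None
    known_same_variant: Classification = Classification.NONE
    known_same_aa_plp: Optional[bool] = None  # same AA change, different nucleotide reported P/LP
    known_other_aa_same_residue_plp: Optional[bool] = None
    known_hotspot: Optional[bool] = None
    known_pp5: Optional[bool] = None  # reported pathogenic, evidence not accessible
    in_trans_with_plp: Optional[bool] = None
    cosegregation: Optional[bool] = None
    phenotype_match: Optional[bool] = None


def pm2_supporting(freqs: Optional[FrequencyPanel], cfg: Optional[PM2Config] = None) -> bool:
    if freqs is None:
        return False
    cfg = cfg or PM2Config()
    if freqs.absent_everywhere():
        return True
    from .model import JAPANESE_DBS

    for db, maf in freqs.present().items():
        cutoff = cfg.japanese_cutoff if db in JAPANESE_DBS else cfg.global_cutoff
        if maf >= cutoff:
            return False
    return True


def pp3_insilico_support(panel: Optional[PredictorPanel], min_fraction: float = 0.5) -> bool:
    """At least ``min_fraction`` of the *present* predictor calls damaging."""
    if panel is None:
        return False
    present = panel.n_present()
    if present == 0:
        return False
    return panel.n_damaging() / present >= min_fraction


def assign_criteria(
    v: AnnotatedVariant,
    ctx: EvidenceContext,
    pm2cfg: Optional[PM2Config] = None,
    pp3_fraction: float = 0.5,
) -> FrozenSet[Criterion]:
    """Map one variant's evidence context to its criterion set.

    PVS1 fires for truncating/canonical-splice changes in genes with an
    established loss-of-function mechanism; a predicted NMD-escaping
    truncation keeps PVS1 only in genes where truncation escape is itself a
    known disease mechanism, and loses it otherwise.
    """
    out = set()

    if v.consequence in _PVS1_CONSEQUENCES and ctx.gene.lof_mechanism:
        escapes = bool(ctx.nmd_escape) if v.consequence in TRUNCATING else False
        if not escapes or ctx.gene.truncation_escape_pathogenic:
            out.add(Criterion.PVS1)

    if ctx.known_same_aa_plp:
        out.add(Criterion.PS1)
    if ctx.segregation is Model.DE_NOVO:
        out.add(Criterion.PS2)

    if ctx.known_hotspot:
        out.add(Criterion.PM1)
    freqs = ctx.freqs if ctx.freqs is not None else v.freqs
    if pm2_supporting(freqs, pm2cfg):
        out.add(Criterion.PM2_SUPPORTING)
    if ctx.in_trans_with_plp:
        out.add(Criterion.PM3)
    if ctx.known_other_aa_same_residue_plp:
        out.add(Criterion.PM5)

    if ctx.cosegregation:
        out.add(Criterion.PP1)
    if v.consequence is Consequence.MISSENSE and pp3_insilico_support(
        ctx.predictors if ctx.predictors is not None else v.predictors, pp3_fraction
    ):
        out.add(Criterion.PP3)
    if ctx.phenotype_match:
        out.add(Criterion.PP4)
    if ctx.known_pp5:
        out.add(Criterion.PP5)

    return frozenset(out)


def combine(criteria: Iterable[Criterion]) -> Classification:
    """Combine a criterion set into pathogenic / likely pathogenic / VUS."""
    cs = frozenset(Criterion(c) for c in criteria)
    pvs = len(cs & _VERY_STRONG)
    ps = len(cs & _STRONG)
    pm = len(cs & _MODERATE)
    pp = len(cs & _SUPPORTING)

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp >= 1) or pp >= 2))
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    if pathogenic:
        return Classification.PATHOGENIC

    likely = (
        (pvs >= 1 and pm >= 1)
        or (pvs >= 1 and pp >= 1)  # SVI: PVS1 + PM2_Supporting
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    if likely:
        return Classification.LIKELY_PATHOGENIC
    return Classification.VUS


def format_criteria(criteria: Iterable[Criterion]) -> str:
    """Serialize a criterion set as comma-joined tokens in canonical
    strength order, e.g. ``"PVS1, PS2, PM2_Supporting, PP4"``."""
    order = {c: i for i, c in enumerate(Criterion)}
    return ", ".join(c.value for c in sorted(frozenset(criteria), key=order.get))


def parse_criteria(text: str) -> FrozenSet[Criterion]:
    toks = [t.strip() for t in text.split(",") if t.strip()]
    return frozenset(Criterion(t) for t in toks)
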