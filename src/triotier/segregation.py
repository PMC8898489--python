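"""Trio genotype segregation logic.

Phase is inferred only from parental origin: a pair of heterozygous variants
in one gene is called compound heterozygous (in trans) when one is
transmitted exclusively by the father and the other exclusively by the
mother. De novo status requires both parents genotyped and homozygous
reference — a duo family can never yield a de novo call. Mendelian-error
genotypes (e.g. a homozygous-alternate proband with a homozygous-reference
parent) yield no model label plus a logged inconsistency rather than an
exception, since real call sets contain genotyping errors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Set, Tuple

from .model import (
    AnnotatedVariant,
    Family,
    Genotype,
    InheritanceMode,
    TrioGenotypes,
)

logger = logging.getLogger(__name__)


class Model(str, Enum):
    DE_NOVO = "de_novo"
    HOM_BIALLELIC = "hom_biallelic"
    COMPOUND_HET = "compound_het"
    AD_INHERITED = "ad_inherited"
    UNRESOLVED = "unresolved"


class Origin(str, Enum):
    PATERNAL = "paternal"
    MATERNAL = "maternal"
    DE_NOVO = "de_novo"
    AMBIGUOUS = "ambiguous"  # both parents carry the allele
    UNKNOWN = "unknown"  # a parent is ungenotyped


@dataclass
class SegregationCall:
    model: Model
    variants: Tuple[AnnotatedVariant, ...]
    origins: Dict = field(default_factory=dict)  # variant key -> Origin
    both_parents_genotyped: bool = True
    phase_unknown: bool = False


def is_mendelian_error(tg: TrioGenotypes) -> bool:
    """Impossible transmission given the genotyped parents.

    A hom-alt child needs an alt allele from each genotyped parent; a
    hom-ref child cannot have a hom-alt parent; a het child cannot have two
    hom-alt parents. (A het child of two hom-ref parents is a de novo
    event, not an error.)
    """
    p, f, m = tg.proband, tg.father, tg.mother
    if p is Genotype.HOM_ALT:
        if f is Genotype.HOM_REF or m is Genotype.HOM_REF:
            return True
    if p is Genotype.HOM_REF:
        if f is Genotype.HOM_ALT or m is Genotype.HOM_ALT:
            return True
    if p is Genotype.HET:
        if f is Genotype.HOM_ALT and m is Genotype.HOM_ALT:
            return True
    return False


def classify_single(tg: TrioGenotypes, family: Family) -> Set[Model]:
    """All single-variant segregation models consistent with one trio
    genotype vector under the family's structure.

    de_novo: proband het, both parents genotyped hom-ref.
    hom_biallelic: proband hom-alt, every genotyped parent carries >= 1 alt.
    ad_inherited: proband het, exactly the affected parent het (the
    unaffected parent, when genotyped, does not carry the allele).
    An empty set means the variant does not segregate under any model;
    Mendelian errors also return the empty set (logged).
    """
    labels: Set[Model] = set()
    if is_mendelian_error(tg):
        logger.info("Mendelian inconsistency in family %s: %s", family.family_id, tg)
        return labels

    both = tg.father is not Genotype.MISSING and tg.mother is not Genotype.MISSING
    father_in_ped = family.father is not None
    mother_in_ped = family.mother is not None

    if (
        tg.proband is Genotype.HET
        and both
        and father_in_ped
        and mother_in_ped
        and tg.father is Genotype.HOM_REF
        and tg.mother is Genotype.HOM_REF
    ):
        labels.add(Model.DE_NOVO)

    if tg.proband is Genotype.HOM_ALT:
        ok = True
        for gt in (tg.father, tg.mother):
            if gt is not Genotype.MISSING and not gt.carries_alt():
                ok = False
        if ok:
            labels.add(Model.HOM_BIALLELIC)

    if tg.proband is Genotype.HET:
        affected = family.affected_parents()
        if len(affected) == 1:
            parent = affected[0]
            if family.father is not None and parent is family.father:
                carrier_gt, other_gt = tg.father, tg.mother
            else:
                carrier_gt, other_gt = tg.mother, tg.father
            if carrier_gt is Genotype.HET and (
                other_gt is Genotype.MISSING or not other_gt.carries_alt()
            ):
                labels.add(Model.AD_INHERITED)
    return labels


def variant_origin(tg: TrioGenotypes) -> Origin:
    """Parental origin of a heterozygous proband allele."""
    f, m = tg.father, tg.mother
    if f is Genotype.MISSING or m is Genotype.MISSING:
        return Origin.UNKNOWN
    f_carries, m_carries = f.carries_alt(), m.carries_alt()
    if f_carries and not m_carries:
        return Origin.PATERNAL
    if m_carries and not f_carries:
        return Origin.MATERNAL
    if f_carries and m_carries:
        return Origin.AMBIGUOUS
    return Origin.DE_NOVO


def find_compound_het(
    variants_in_gene: Sequence[Tuple[AnnotatedVariant, TrioGenotypes]],
) -> List[SegregationCall]:
    """Enumerate trans pairs among proband-heterozygous variants of one gene.

    A pair is compound heterozygous when one variant is transmitted only by
    the father and the other only by the mother. Cis pairs (both from one
    parent) are rejected. Pairs involving an ungenotyped parent are emitted
    as unresolved with a phase-unknown flag. Output is invariant to input
    ordering and symmetric in pair order.
    """
    hets = [(v, tg) for v, tg in variants_in_gene if tg.proband is Genotype.HET]
    hets.sort(key=lambda item: (item[0].pos, item[0].hgvs_c))
    calls: List[SegregationCall] = []
    for (v1, t1), (v2, t2) in itertools.combinations(hets, 2):
        o1, o2 = variant_origin(t1), variant_origin(t2)
        origins = {v1.key: o1, v2.key: o2}
        if {o1, o2} == {Origin.PATERNAL, Origin.MATERNAL}:
            calls.append(SegregationCall(Model.COMPOUND_HET, (v1, v2), origins))
        elif Origin.UNKNOWN in (o1, o2) and Origin.AMBIGUOUS not in (o1, o2):
            calls.append(
                SegregationCall(
                    Model.UNRESOLVED,
                    (v1, v2),
                    origins,
                    both_parents_genotyped=False,
                    phase_unknown=True,
                )
            )
    return calls


def models_for_family(family: Family) -> List[Model]:
    """Ordered list of segregation models to evaluate for a family mode."""
    mode = family.mode
    if mode is InheritanceMode.SPORADIC:
        return [Model.DE_NOVO, Model.HOM_BIALLELIC, Model.COMPOUND_HET]
    if mode is InheritanceMode.AR:
        return [Model.HOM_BIALLELIC, Model.COMPOUND_HET]
    if mode is InheritanceMode.AD:
        return [Model.AD_INHERITED, Model.DE_NOVO]
    return [Model.DE_NOVO, Model.HOM_BIALLELIC, Model.COMPOUND_HET, Model.AD_INHERITED]


@dataclass
class ReanalysisEvent:
    family_id: str
    parent_id: str
    parent_gene: str
    reason: str = "affected parent carries an independent biallelic cause"


def needs_reanalysis(
    family: Family,
    parent_biallelic_gene: Optional[str],
    proband_carries_biallelic: bool,
) -> bool:
    """Pedigree/genetic-mode discrepancy trigger.

    When an affected parent's phenotype is explained by its own biallelic
    allele (e.g. a homozygous gene deletion) that the proband carries only
    heterozygously, pedigree-based dominant transmission is an illusion: the
    proband is re-queued for analysis under the remaining models with the
    parent's gene set aside.
    """
    if parent_biallelic_gene is None:
        return False
    if not family.affected_parents():
        return False
    return not proband_carries_biallelic
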