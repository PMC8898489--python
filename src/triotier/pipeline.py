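"""End-to-end orchestration: filter -> segregation -> ACMG -> tier
prioritization -> CNV merge -> per-family reports.

Handles the pedigree/genetic-mode discrepancy pattern: when an affected
parent turns out to carry its own biallelic cause (a homozygous gene
deletion) that the proband carries only heterozygously, apparent dominant
transmission is spurious. The parent receives its own causal record and the
proband is re-analyzed under the remaining models with the parent's gene
set aside, so one family can legitimately report two member-level causes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Sequence, Set, Tuple

from .acmg import (
    Criterion,
    EvidenceContext,
    PM2Config,
    assign_criteria,
    combine,
)
from .filtering import FilterConfig, filter_variants, retained
from .io import KnownVariantDB
from .model import (
    AnnotatedVariant,
    Classification,
    Consequence,
    Family,
    GeneRecord,
    GeneRegistry,
    Genotype,
    TRUNCATING,
    TranscriptModel,
    TrioGenotypes,
    nmd_escape,
)
from .prioritize import (
    Candidate,
    FamilyCandidateReport,
    VariantEvidence,
    prioritize_family,
    syndromic_exclusion,
)
from .segregation import (
    Model,
    ReanalysisEvent,
    classify_single,
    find_compound_het,
    models_for_family,
    needs_reanalysis,
)

logger = logging.getLogger(__name__)

PLP = (Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC)


def null_allele_criteria(gene: GeneRecord) -> FrozenSet[Criterion]:
    """A homozygous whole-gene deletion is a null allele: PVS1 when loss of
    function is the gene's established mechanism. No SNV frequency panel
    exists for the allele, so PM2 is not assessable."""
    return frozenset({Criterion.PVS1}) if gene.lof_mechanism else frozenset()


def deletion_allele(gene: str, chrom: str = ".", pos: int = 1) -> AnnotatedVariant:
    return AnnotatedVariant(
        chrom=chrom, pos=pos, ref="N", alt="<DEL>", gene=gene,
        hgvs_c="c.(?_-1)_(*1_?)del", consequence=Consequence.OTHER,
    )


@dataclass
class CohortBundle:
    """Everything one analysis run consumes."""

    families: List[Family]
    records: Dict[str, List[Tuple[AnnotatedVariant, TrioGenotypes]]]
    registry: GeneRegistry
    known_db: KnownVariantDB = field(default_factory=KnownVariantDB)
    transcripts: Dict[str, TranscriptModel] = field(default_factory=dict)
    #: (family_id, gene, hgvs_c) triples with reported cosegregation in
    #: additional affected relatives (PP1 evidence).
    coseg: Set[Tuple[str, str, str]] = field(default_factory=set)
    #: family_id -> member role ("proband"|"father"|"mother") -> gene -> copies
    cnv_copies: Dict[str, Dict[str, Dict[str, int]]] = field(default_factory=dict)

    def __post_init__(self):
        known = {f.family_id for f in self.families}
        stray = set(self.records) - known
        if stray:
            raise ValueError(f"variant records for unknown families: {sorted(stray)}")


@dataclass
class PipelineResult:
    reports: List[FamilyCandidateReport]
    reanalyses: List[ReanalysisEvent]
    audits: Dict[str, list]


def _evidence_context(
    v: AnnotatedVariant,
    model: Model,
    family: Family,
    bundle: CohortBundle,
    partner: Optional[AnnotatedVariant] = None,
) -> EvidenceContext:
    gene = bundle.registry.get(v.gene)
    known = bundle.known_db.lookup(v.gene, v.hgvs_c)
    escape = None
    tm = bundle.transcripts.get(v.transcript)
    if tm is not None and v.consequence in TRUNCATING:
        try:
            escape = nmd_escape(v, tm)
        except Exception:
            escape = None
    in_trans = None
    if partner is not None:
        in_trans = bundle.known_db.classification(partner.gene, partner.hgvs_c) in PLP
    return EvidenceContext(
        gene=gene,
        segregation=model,
        freqs=v.freqs,
        consequence=v.consequence,
        predictors=v.predictors,
        nmd_escape=escape,
        known_same_variant=known["classification"],
        known_same_aa_plp=known["same_aa_plp"],
        known_other_aa_same_residue_plp=known["other_aa_same_residue_plp"],
        known_hotspot=known["hotspot"],
        known_pp5=known["pp5"],
        in_trans_with_plp=in_trans,
        cosegregation=(family.family_id, v.gene, v.hgvs_c) in bundle.coseg,
        phenotype_match=bool(gene.characteristic_features & family.phenotype),
    )


def _evidence(v, model, family, bundle, pm2cfg, partner=None) -> VariantEvidence:
    ctx = _evidence_context(v, model, family, bundle, partner)
    crit = assign_criteria(v, ctx, pm2cfg)
    return VariantEvidence(variant=v, criteria=crit, classification=combine(crit))


def candidates_for_family(
    family: Family,
    records: Sequence[Tuple[AnnotatedVariant, TrioGenotypes]],
    bundle: CohortBundle,
    cfg: FilterConfig,
    pm2cfg: PM2Config,
    exclude_genes: Set[str] = frozenset(),
) -> Tuple[List[Candidate], list]:
    """Filter one family's records and enumerate gene-level candidates
    consistent with the family's segregation models."""
    audits = filter_variants(records, family, cfg)
    surviving = retained(audits)
    models = models_for_family(family)

    by_gene: Dict[str, List[Tuple[AnnotatedVariant, TrioGenotypes]]] = {}
    for v, tg in surviving:
        if v.gene in exclude_genes:
            continue
        by_gene.setdefault(v.gene, []).append((v, tg))

    candidates: List[Candidate] = []
    for gene, items in sorted(by_gene.items()):
        tier = bundle.registry.tier(gene)
        for v, tg in items:
            labels = classify_single(tg, family)
            for model in models:
                if model in labels and model is not Model.COMPOUND_HET:
                    candidates.append(
                        Candidate(gene=gene, tier=tier, model=model,
                                  variants=[_evidence(v, model, family, bundle, pm2cfg)])
                    )
        if Model.COMPOUND_HET in models and len(items) >= 2:
            for call in find_compound_het(items):
                if call.model is not Model.COMPOUND_HET:
                    continue  # phase-unknown pairs are never candidates
                v1, v2 = call.variants
                candidates.append(
                    Candidate(
                        gene=gene, tier=tier, model=Model.COMPOUND_HET,
                        variants=[
                            _evidence(v1, Model.COMPOUND_HET, family, bundle, pm2cfg, partner=v2),
                            _evidence(v2, Model.COMPOUND_HET, family, bundle, pm2cfg, partner=v1),
                        ],
                    )
                )

    # CNV merge: a proband homozygous gene deletion is a biallelic null candidate
    proband_cnv = bundle.cnv_copies.get(family.family_id, {}).get("proband", {})
    for gene, copies in sorted(proband_cnv.items()):
        if gene in exclude_genes or copies != 0:
            continue
        if Model.HOM_BIALLELIC not in models:
            continue
        rec = bundle.registry.get(gene)
        crit = null_allele_criteria(rec)
        candidates.append(
            Candidate(
                gene=gene, tier=rec.tier, model=Model.HOM_BIALLELIC,
                variants=[VariantEvidence(deletion_allele(gene), crit, combine(crit))],
                notes=["homozygous deletion from read-depth/qPCR screen"],
            )
        )

    kept = []
    for c in candidates:
        keep, reason = syndromic_exclusion(c, family, bundle.known_db, bundle.registry)
        if keep:
            kept.append(c)
        else:
            logger.info("family %s: dropped %s (%s)", family.family_id, c.gene, reason)
    # collapse duplicate (gene, model) candidates, keep best-classified
    dedup: Dict[Tuple[str, str], Candidate] = {}
    for c in kept:
        key = (c.gene, c.model.value)
        prev = dedup.get(key)
        if prev is None or _better(c, prev):
            dedup[key] = c
    return list(dedup.values()), audits


def _better(a: Candidate, b: Candidate) -> bool:
    from .prioritize import rank_key

    return rank_key(a) < rank_key(b)


def run_family(
    family: Family,
    bundle: CohortBundle,
    cfg: Optional[FilterConfig] = None,
    pm2cfg: Optional[PM2Config] = None,
) -> Tuple[List[FamilyCandidateReport], List[ReanalysisEvent], list]:
    """Analyze one family; may emit several member-level reports."""
    cfg = cfg or FilterConfig()
    pm2cfg = pm2cfg or PM2Config()
    records = bundle.records.get(family.family_id, [])
    fam_cnv = bundle.cnv_copies.get(family.family_id, {})

    reports: List[FamilyCandidateReport] = []
    events: List[ReanalysisEvent] = []
    exclude: Set[str] = set()

    # Discrepancy check: an affected parent with its own biallelic (deleted)
    # cause that the proband does not carry biallelically.
    for role, parent in (("father", family.father), ("mother", family.mother)):
        if parent is None or not parent.affected:
            continue
        for gene, copies in sorted(fam_cnv.get(role, {}).items()):
            if copies != 0:
                continue
            proband_copies = fam_cnv.get("proband", {}).get(gene)
            if needs_reanalysis(family, gene, proband_carries_biallelic=proband_copies == 0):
                rec = bundle.registry.get(gene)
                crit = null_allele_criteria(rec)
                parent_candidate = Candidate(
                    gene=gene, tier=rec.tier, model=Model.HOM_BIALLELIC,
                    variants=[VariantEvidence(deletion_allele(gene), crit, combine(crit))],
                    notes=[f"cause of affected parent {parent.individual_id}"],
                )
                reports.append(
                    prioritize_family(family, [parent_candidate], member_id=parent.individual_id)
                )
                events.append(
                    ReanalysisEvent(family.family_id, parent.individual_id, gene)
                )
                exclude.add(gene)

    candidates, audits = candidates_for_family(family, records, bundle, cfg, pm2cfg, exclude)
    proband_report = prioritize_family(family, candidates)
    proband_report.reanalyzed = bool(events)
    reports.append(proband_report)
    for rep in reports:
        logger.info("family %s member %s: %s", rep.family_id, rep.member_id, rep.status.value)
    return reports, events, audits


def run_cohort(
    bundle: CohortBundle,
    cfg: Optional[FilterConfig] = None,
    pm2cfg: Optional[PM2Config] = None,
) -> PipelineResult:
    reports: List[FamilyCandidateReport] = []
    reanalyses: List[ReanalysisEvent] = []
    audits: Dict[str, list] = {}
    for family in bundle.families:
        reps, events, aud = run_family(family, bundle, cfg, pm2cfg)
        reports.extend(reps)
        reanalyses.extend(events)
        audits[family.family_id] = aud
    return PipelineResult(reports=reports, reanalyses=reanalyses, audits=audits)
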