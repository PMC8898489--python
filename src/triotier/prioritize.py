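"""Four-tier gene prioritization and per-family candidate reduction.

Genes are ranked Tier 1 (known human deafness genes) < Tier 2 (animal-model
deafness genes) < Tier 3 (cochlea-enriched genes) < Tier 4 (everything
else); within a tier, candidates order by ACMG classification and then by
segregation-model specificity. Syndromic genes are excluded for a
nonsyndromic-presenting proband unless the variant is previously reported
pathogenic/likely pathogenic or the proband exhibits the gene's
characteristic multi-organ features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from .acmg import Criterion, format_criteria
from .io import KnownVariantDB
from .model import (
    AnnotatedVariant,
    Classification,
    Family,
    GeneRegistry,
    InheritanceMode,
)
from .segregation import Model


class FamilyStatus(str, Enum):
    SOLVED_TIER1 = "solved_tier1"
    SINGLE_CANDIDATE = "single_candidate"
    MULTIPLE_CANDIDATES = "multiple_candidates"
    NO_CANDIDATE = "no_candidate"


@dataclass
class VariantEvidence:
    variant: AnnotatedVariant
    criteria: FrozenSet[Criterion]
    classification: Classification


@dataclass
class Candidate:
    gene: str
    tier: int
    model: Model
    variants: List[VariantEvidence]
    notes: List[str] = field(default_factory=list)

    @property
    def classification(self) -> Classification:
        """Gene-level class: the best classification among the supporting
        variants (a recessive pair with one LP and one VUS allele still
        nominates the gene at LP)."""
        order = [Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC,
                 Classification.VUS, Classification.NONE]
        for c in order:
            if any(ve.classification is c for ve in self.variants):
                return c
        return Classification.NONE


@dataclass
class FamilyCandidateReport:
    family_id: str
    member_id: str
    candidates: List[Candidate]  # ranked, best first
    status: FamilyStatus
    reanalyzed: bool = False

    @property
    def top(self) -> Optional[Candidate]:
        return self.candidates[0] if self.candidates else None


def assign_tier(gene: str, reg: GeneRegistry) -> int:
    return reg.tier(gene)


def syndromic_exclusion(
    candidate: Candidate,
    family: Family,
    known_db: KnownVariantDB,
    reg: GeneRegistry,
) -> Tuple[bool, str]:
    """Apply the syndromic-gene exclusion rule to one candidate.

    Returns (keep, reason). A syndromic gene is dropped iff (1) none of the
    candidate's variants is previously reported pathogenic/likely
    pathogenic AND (2) the proband lacks the gene's characteristic
    multi-organ features. Either clause failing keeps the candidate.
    """
    rec = reg.get(candidate.gene)
    if not rec.syndromic:
        return True, "gene not syndromic"
    reported = any(
        known_db.classification(candidate.gene, ve.variant.hgvs_c)
        in (Classification.PATHOGENIC, Classification.LIKELY_PATHOGENIC)
        for ve in candidate.variants
    )
    if reported:
        return True, "variant previously reported pathogenic"
    if rec.characteristic_features & family.phenotype:
        return True, "proband shows characteristic features"
    return False, "unreported variant in syndromic gene; no characteristic features"


_CLASS_RANK = {
    Classification.PATHOGENIC: 0,
    Classification.LIKELY_PATHOGENIC: 1,
    Classification.VUS: 2,
    Classification.NONE: 3,
}

#: Model specificity used only as a deterministic tie-break within a tier
#: and classification; more constrained trio patterns rank first.
_MODEL_RANK = {
    Model.DE_NOVO: 0,
    Model.HOM_BIALLELIC: 1,
    Model.COMPOUND_HET: 2,
    Model.AD_INHERITED: 3,
    Model.UNRESOLVED: 9,
}


def rank_key(c: Candidate):
    return (c.tier, _CLASS_RANK[c.classification], _MODEL_RANK[c.model], c.gene)


def prioritize_family(
    family: Family,
    candidates: Sequence[Candidate],
    member_id: Optional[str] = None,
) -> FamilyCandidateReport:
    """Rank surviving candidates and reduce the family to a status.

    ``solved_tier1`` requires a Tier-1 candidate reaching pathogenic or
    likely pathogenic; otherwise ``single_candidate`` when exactly one gene
    survives across tiers. Ties in the ranking key are listed in gene order,
    never silently broken.
    """
    ranked = sorted(candidates, key=rank_key)
    genes = {c.gene for c in ranked}
    status = FamilyStatus.NO_CANDIDATE
    if ranked:
        top = ranked[0]
        if top.tier == 1 and top.classification in (
            Classification.PATHOGENIC,
            Classification.LIKELY_PATHOGENIC,
        ):
            status = FamilyStatus.SOLVED_TIER1
        elif len(genes) == 1:
            status = FamilyStatus.SINGLE_CANDIDATE
        else:
            status = FamilyStatus.MULTIPLE_CANDIDATES
    return FamilyCandidateReport(
        family_id=family.family_id,
        member_id=member_id or family.proband.individual_id,
        candidates=ranked,
        status=status,
    )


def report_rows(reports: Sequence[FamilyCandidateReport]) -> List[Dict]:
    """Flatten reports into writable rows (one per family x member x gene)."""
    rows = []
    for rep in reports:
        if not rep.candidates:
            rows.append({
                "family_id": rep.family_id, "member_id": rep.member_id,
                "status": rep.status.value, "rank": "", "gene": "", "tier": "",
                "model": "", "variants": "", "criteria": "", "classification": "",
            })
            continue
        for rank, c in enumerate(rep.candidates, start=1):
            rows.append({
                "family_id": rep.family_id,
                "member_id": rep.member_id,
                "status": rep.status.value,
                "rank": str(rank),
                "gene": c.gene,
                "tier": str(c.tier),
                "model": c.model.value,
                "variants": ";".join(ve.variant.hgvs_c or ve.variant.alt for ve in c.variants),
                "criteria": " | ".join(format_criteria(ve.criteria) for ve in c.variants),
                "classification": c.classification.value,
            })
    return rows


@dataclass
class CohortSummary:
    n_families: int
    n_individuals: int
    mode_counts: Dict[str, int]
    syndromic_mode_counts: Dict[str, int]
    nonsyndromic_mode_counts: Dict[str, int]
    n_nonsyndromic: int
    tier1_families: int  # families whose top-ranked candidate is a Tier 1 gene
    tier1_genes: List[str]
    gene_family_counts: Dict[str, int]
    narrowed_to_one: int  # solved_tier1 + single_candidate families

    def as_tables(self) -> Dict[str, "object"]:
        import pandas as pd

        modes = [m.value for m in InheritanceMode]
        tab = pd.DataFrame(
            {
                "nonsyndromic": [self.nonsyndromic_mode_counts.get(m, 0) for m in modes],
                "syndromic": [self.syndromic_mode_counts.get(m, 0) for m in modes],
            },
            index=modes,
        )
        genes = pd.Series(self.gene_family_counts, name="n_families").sort_values(
            ascending=False
        )
        return {"families_by_mode": tab, "gene_family_counts": genes}


def cohort_summary(
    reports: Sequence[FamilyCandidateReport],
    families: Sequence[Family],
    reg: GeneRegistry,
) -> CohortSummary:
    """Cohort-level tables: family counts by mode and syndromic status,
    per-gene family counts, Tier-1 yield, and narrowed-to-one counts."""
    fam_by_id = {f.family_id: f for f in families}
    mode_counts: Dict[str, int] = {}
    syn_counts: Dict[str, int] = {}
    nonsyn_counts: Dict[str, int] = {}
    for f in families:
        mode_counts[f.mode.value] = mode_counts.get(f.mode.value, 0) + 1
        bucket = nonsyn_counts if f.nonsyndromic else syn_counts
        bucket[f.mode.value] = bucket.get(f.mode.value, 0) + 1

    tier1_fams = set()
    tier1_genes = set()
    gene_fams: Dict[str, set] = {}
    narrowed_fams = set()
    for rep in reports:
        top = rep.top
        if top is not None:
            gene_fams.setdefault(top.gene, set()).add(rep.family_id)
            if top.tier == 1:
                tier1_fams.add(rep.family_id)
                tier1_genes.add(top.gene)
        if rep.status in (FamilyStatus.SOLVED_TIER1, FamilyStatus.SINGLE_CANDIDATE):
            narrowed_fams.add(rep.family_id)

    return CohortSummary(
        n_families=len(families),
        n_individuals=sum(f.n_members for f in families),
        mode_counts=mode_counts,
        syndromic_mode_counts=syn_counts,
        nonsyndromic_mode_counts=nonsyn_counts,
        n_nonsyndromic=sum(nonsyn_counts.values()),
        tier1_families=len(tier1_fams),
        tier1_genes=sorted(tier1_genes),
        gene_family_counts={g: len(s) for g, s in sorted(gene_fams.items())},
        narrowed_to_one=len(narrowed_fams),
    )
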