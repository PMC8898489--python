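"""Domain types for trio-exome variant prioritization.

The pipeline operates on annotated single-alt variant records, trio
genotypes, family/pedigree descriptions, and a gene registry that assigns
each symbol to one of four priority tiers (known human deafness genes;
animal-model deafness genes; cochlea-enriched genes; everything else).
Coordinates are 1-based inclusive, matching HGVS g. notation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class Consequence(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE_CANONICAL = "splice_canonical"
    SPLICE_REGION = "splice_region"
    INFRAME_INDEL = "inframe_indel"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


#: Consequences that truncate the reading frame (premature termination).
TRUNCATING = frozenset({Consequence.NONSENSE, Consequence.FRAMESHIFT})

#: Consequence classes the in-silico missense consensus applies to.
MISSENSE_LIKE = frozenset({Consequence.MISSENSE})


class PredictorCall(str, Enum):
    DAMAGING = "damaging"
    BENIGN = "benign"
    MISSING = "missing"


class HSFVerdict(str, Enum):
    AFFECTED = "affected"
    NOT_AFFECTED = "not_affected"
    ABSENT = "absent"


class Genotype(str, Enum):
    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    def carries_alt(self) -> bool:
        return self in (Genotype.HET, Genotype.HOM_ALT)

    def alt_count(self) -> Optional[int]:
        return {"hom_ref": 0, "het": 1, "hom_alt": 2}.get(self.value)


class InheritanceMode(str, Enum):
    SPORADIC = "sporadic"
    AD = "AD"
    AR = "AR"
    UNDETERMINED = "undetermined"


class Classification(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "VUS"
    NONE = "none"


#: Population databases carrying allele frequencies, split into global and
#: Japanese panels because the frequency filter applies different thresholds.
GLOBAL_DBS = ("KG_EAS", "ESP6500", "ExAC", "gnomAD")
JAPANESE_DBS = ("HGVD", "INHOUSE")
ALL_DBS = GLOBAL_DBS + JAPANESE_DBS

#: The eight in-silico missense predictors used by the consensus exclusion.
PREDICTORS = (
    "LRT",
    "LR",
    "MutationAssessor",
    "MutationTaster",
    "PolyPhen2_HDIV",
    "PolyPhen2_HVAR",
    "RadialSVM",
    "SIFT",
)


class ContractError(ValueError):
    """An operation was called outside its stated preconditions."""


class HGVSParseError(ValueError):
    """An HGVS string could not be mapped to a consequence class."""


@dataclass(frozen=True)
class FrequencyPanel:
    """Per-database minor allele frequencies.

    ``None`` means *absent from the database*, which is deliberately distinct
    from an observed frequency of 0.0: absence can never exclude a variant
    and feeds the PM2_Supporting rarity criterion.
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        for db, v in self.values.items():
            if db not in ALL_DBS:
                raise ContractError(f"unknown frequency database: {db!r}")
            if v is not None and not (0.0 <= v <= 1.0):
                raise ContractError(f"MAF out of [0,1] for {db}: {v}")

    def get(self, db: str) -> Optional[float]:
        return self.values.get(db)

    def present(self) -> dict:
        return {db: v for db, v in self.values.items() if v is not None}

    def absent_everywhere(self) -> bool:
        return not self.present()

    @classmethod
    def absent(cls) -> "FrequencyPanel":
        return cls({})


@dataclass(frozen=True)
class PredictorPanel:
    """Calls from the eight missense predictors plus carried-along scores.

    REVEL and CADD are annotations only: the filtering cascade never
    consults them (exactly eight categorical calls drive the consensus).
    """

    calls: dict = field(default_factory=dict)
    revel: Optional[float] = None
    cadd: Optional[float] = None

    def __post_init__(self):
        unknown = set(self.calls) - set(PREDICTORS)
        if unknown:
            raise ContractError(f"unknown predictors: {sorted(unknown)}")
        # normalize: every slot present, missing by default
        full = {p: PredictorCall(self.calls.get(p, PredictorCall.MISSING)) for p in PREDICTORS}
        object.__setattr__(self, "calls", full)
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise ContractError(f"REVEL out of [0,1]: {self.revel}")
        if self.cadd is not None and self.cadd < 0:
            raise ContractError(f"CADD negative: {self.cadd}")

    def n_benign(self) -> int:
        return sum(1 for c in self.calls.values() if c is PredictorCall.BENIGN)

    def n_damaging(self) -> int:
        return sum(1 for c in self.calls.values() if c is PredictorCall.DAMAGING)

    def n_present(self) -> int:
        return sum(1 for c in self.calls.values() if c is not PredictorCall.MISSING)

    @classmethod
    def all_missing(cls) -> "PredictorPanel":
        return cls({})

    @classmethod
    def uniform(cls, call: PredictorCall, **kw) -> "PredictorPanel":
        return cls({p: call for p in PREDICTORS}, **kw)


@dataclass(frozen=True)
class SpliceAnnotation:
    """MaxEntScan ref/alt scores and the Human Splicing Finder verdict."""

    maxent_ref: Optional[float] = None
    maxent_alt: Optional[float] = None
    hsf_verdict: HSFVerdict = HSFVerdict.ABSENT

    def __post_init__(self):
        if not isinstance(self.hsf_verdict, HSFVerdict):
            object.__setattr__(self, "hsf_verdict", HSFVerdict(self.hsf_verdict))


@dataclass(frozen=True)
class AnnotatedVariant:
    """One alternate allele with its annotations (multi-allelics are split
    upstream, so a record always carries exactly one alt)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str = ""
    hgvs_c: str = ""
    hgvs_p: str = ""
    consequence: Consequence = Consequence.OTHER
    exon_index: Optional[int] = None
    freqs: FrequencyPanel = field(default_factory=FrequencyPanel.absent)
    predictors: PredictorPanel = field(default_factory=PredictorPanel.all_missing)
    splice: Optional[SpliceAnnotation] = None
    rs_id: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ContractError(f"position must be >= 1: {self.pos}")
        if self.alt == self.ref:
            raise ContractError(f"alt equals ref at {self.chrom}:{self.pos}")
        if not isinstance(self.consequence, Consequence):
            object.__setattr__(self, "consequence", Consequence(self.consequence))

    @property
    def key(self):
        return (self.gene, self.hgvs_c or f"{self.chrom}:{self.pos}{self.ref}>{self.alt}")


@dataclass(frozen=True)
class TrioGenotypes:
    proband: Genotype
    father: Genotype = Genotype.MISSING
    mother: Genotype = Genotype.MISSING

    def __post_init__(self):
        for name in ("proband", "father", "mother"):
            v = getattr(self, name)
            if not isinstance(v, Genotype):
                object.__setattr__(self, name, Genotype(v))
        if self.proband is Genotype.MISSING:
            raise ContractError("proband genotype may not be missing")


@dataclass
class Member:
    individual_id: str
    affected: Optional[bool] = None  # None = unknown phenotype
    sex: Optional[str] = None


@dataclass
class Family:
    family_id: str
    proband: Member
    father: Optional[Member] = None
    mother: Optional[Member] = None
    mode: InheritanceMode = InheritanceMode.SPORADIC
    phenotype: frozenset = frozenset()
    nonsyndromic: bool = True

    def __post_init__(self):
        if not isinstance(self.mode, InheritanceMode):
            self.mode = InheritanceMode(self.mode)
        self.phenotype = frozenset(self.phenotype)

    @property
    def is_duo(self) -> bool:
        return self.father is None or self.mother is None

    @property
    def n_members(self) -> int:
        return 1 + (self.father is not None) + (self.mother is not None)

    def affected_parents(self):
        out = []
        for parent in (self.father, self.mother):
            if parent is not None and parent.affected:
                out.append(parent)
        return out


@dataclass(frozen=True)
class GeneRecord:
    """Registry entry for one gene symbol.

    ``lof_mechanism`` marks genes for which loss of function is an
    established disease mechanism (gating PVS1); ``truncation_escape_pathogenic``
    marks genes where NMD-escaping last-exon truncations are themselves a
    known (often more severe) disease mechanism, so PVS1 is retained for them.
    """

    symbol: str
    tier: int
    disease: str = ""
    disease_inheritance: str = "AR"  # AD | AR | both
    syndromic: bool = False
    lof_mechanism: bool = True
    truncation_escape_pathogenic: bool = False
    characteristic_features: frozenset = frozenset()

    def __post_init__(self):
        if self.tier not in (1, 2, 3, 4):
            raise ContractError(f"tier must be 1..4: {self.tier}")
        object.__setattr__(self, "characteristic_features", frozenset(self.characteristic_features))


class GeneRegistry:
    """symbol -> GeneRecord lookup; unknown symbols default to Tier 4."""

    def __init__(self, records=()):
        self._records = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: GeneRecord):
        if rec.symbol in self._records:
            raise ContractError(f"duplicate registry symbol {rec.symbol}")
        self._records[rec.symbol] = rec

    def __len__(self):
        return len(self._records)

    def __contains__(self, symbol):
        return symbol in self._records

    def get(self, symbol: str) -> GeneRecord:
        rec = self._records.get(symbol)
        if rec is None:
            return GeneRecord(symbol=symbol, tier=4)
        return rec

    def tier(self, symbol: str) -> int:
        return self.get(symbol).tier

    def symbols(self):
        return list(self._records)


@dataclass(frozen=True)
class TranscriptModel:
    """Coding-exon structure of one transcript.

    ``coding_exon_lengths[i]`` is the number of coding nucleotides in exon
    i+1 (exon indices contiguous from 1). Only junction positions in CDS
    coordinates are needed for the NMD-escape rule.
    """

    transcript: str
    coding_exon_lengths: tuple
    strand: str = "+"

    def __post_init__(self):
        if not self.coding_exon_lengths or any(l <= 0 for l in self.coding_exon_lengths):
            raise ContractError("coding exon lengths must be positive and non-empty")
        object.__setattr__(self, "coding_exon_lengths", tuple(self.coding_exon_lengths))

    @property
    def n_exons(self) -> int:
        return len(self.coding_exon_lengths)

    @property
    def coding_length(self) -> int:
        return sum(self.coding_exon_lengths)

    @property
    def final_junction_cds(self) -> int:
        """CDS coordinate of the last nucleotide before the final exon-exon
        junction (end of the penultimate coding exon)."""
        if self.n_exons == 1:
            return 0
        return self.coding_length - self.coding_exon_lengths[-1]


# --------------------------------------------------------------------------
# HGVS parsing / consequence normalization


_C_INTRONIC = re.compile(r"c\.[\d*+-]*?(\d+)(?:_\d+)?([+-])(\d+)")
_C_BODY = re.compile(r"^c\.(.+)$")
_P_FS = re.compile(r"fs", re.IGNORECASE)
_P_SUB = re.compile(r"^p\.\(?([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|Ter|=)\)?$")


def _intron_offset(hgvs_c: str) -> Optional[int]:
    """Smallest absolute intronic offset named by the c. string, or None for
    purely exonic descriptions."""
    offsets = []
    for m in re.finditer(r"(\d+)([+-])(\d+)", hgvs_c):
        offsets.append(int(m.group(3)))
    return min(offsets) if offsets else None


def normalize_consequence(
    hgvs_c: str = "",
    hgvs_p: str = "",
    splice_distance: Optional[int] = None,
) -> Consequence:
    """Deterministically map HGVS c./p. descriptions to a consequence class.

    Intronic offsets of 1 or 2 nucleotides are canonical splice sites;
    deeper intronic offsets are splice-region. ``fs`` in the protein change
    marks a frameshift; a substitution to ``Ter`` is nonsense. In-frame
    deletions/duplications (length divisible by 3) without a frameshift are
    in-frame indels.
    """
    if not hgvs_c and not hgvs_p:
        raise HGVSParseError("no HGVS string provided")

    c = (hgvs_c or "").strip()
    p = (hgvs_p or "").strip()

    offset = splice_distance
    if offset is None and c:
        offset = _intron_offset(c)
    if offset is not None:
        if abs(offset) <= 2:
            return Consequence.SPLICE_CANONICAL
        return Consequence.SPLICE_REGION

    if p in ("p.(=)", "p.="):
        return Consequence.SYNONYMOUS
    if p and _P_FS.search(p):
        return Consequence.FRAMESHIFT
    m = _P_SUB.match(p) if p else None
    if m:
        ref_aa, _, alt_aa = m.groups()
        if alt_aa == "Ter":
            return Consequence.NONSENSE
        if alt_aa == "=" or alt_aa == ref_aa:
            return Consequence.SYNONYMOUS
        return Consequence.MISSENSE

    if c:
        body = _C_BODY.match(c)
        if body:
            desc = body.group(1)
            indel = re.match(r"^(\d+)(?:_(\d+))?(del|dup|ins)([ACGT]*|\d*)$", desc)
            if indel:
                start = int(indel.group(1))
                end = int(indel.group(2)) if indel.group(2) else start
                kind = indel.group(3)
                seq = indel.group(4)
                if kind == "ins":
                    length = len(seq) if seq and seq.isalpha() else (int(seq) if seq else 1)
                else:
                    length = end - start + 1
                if length % 3 == 0:
                    return Consequence.INFRAME_INDEL
                return Consequence.FRAMESHIFT
            if re.match(r"^\d+[ACGT]>[ACGT]$", desc):
                # substitution with no interpretable protein change
                if p in ("p.?", "p.(?)", ""):
                    return Consequence.OTHER
                return Consequence.OTHER
    raise HGVSParseError(f"cannot classify HGVS description: c={c!r} p={p!r}")


# --------------------------------------------------------------------------
# NMD escape


def premature_stop_cds(hgvs_c: str, hgvs_p: str, consequence: Consequence) -> int:
    """CDS coordinate (first nucleotide of the stop codon) of the premature
    termination described by a nonsense or frameshift variant.

    Nonsense: the stop is the codon containing the substituted nucleotide.
    Frameshift ``p.(Xxx123YyyfsTer45)``: the new stop is codon 123 + 45 - 1.
    """
    if consequence is Consequence.NONSENSE:
        m = re.match(r"^c\.(\d+)", hgvs_c or "")
        if not m:
            raise HGVSParseError(f"cannot locate nonsense position in {hgvs_c!r}")
        pos = int(m.group(1))
        codon = (pos - 1) // 3 + 1
        return 3 * (codon - 1) + 1
    if consequence is Consequence.FRAMESHIFT:
        m = re.match(r"^p\.\(?[A-Z][a-z]{2}(\d+)[A-Z][a-z]{2}fsTer(\d+)\)?$", hgvs_p or "")
        if not m:
            raise HGVSParseError(f"cannot locate frameshift stop in {hgvs_p!r}")
        first_changed, ter_offset = int(m.group(1)), int(m.group(2))
        stop_codon = first_changed + ter_offset - 1
        return 3 * (stop_codon - 1) + 1
    raise ContractError(f"not a truncating consequence: {consequence}")


def nmd_escape(variant: AnnotatedVariant, tm: TranscriptModel, rule_nt: int = 50) -> bool:
    """Whether a truncating variant is predicted to escape nonsense-mediated
    decay under the 50-nucleotide rule.

    A premature stop escapes NMD when it falls in the last exon, or within
    ``rule_nt`` coding nucleotides upstream of the final exon-exon junction.
    Frameshift stops running past the natural stop (into what was 3' UTR)
    are last-exon stops by construction.
    """
    if variant.consequence not in TRUNCATING:
        raise ContractError(
            f"nmd_escape requires a truncating variant, got {variant.consequence}"
        )
    if variant.transcript and tm.transcript and variant.transcript != tm.transcript:
        raise ContractError(
            f"transcript mismatch: {variant.transcript} vs {tm.transcript}"
        )
    stop = premature_stop_cds(variant.hgvs_c, variant.hgvs_p, variant.consequence)
    junction = tm.final_junction_cds
    if junction == 0:  # single-exon transcript: everything escapes
        return True
    return stop >= junction - rule_nt
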