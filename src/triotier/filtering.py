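"""Stage-1 variant filtering: inheritance-mode-specific MAF thresholds,
eight-predictor in-silico consensus exclusion, and splice-effect retention.

The frequency filter is deliberately asymmetric between presumed dominant
and recessive/sporadic families: dominant-acting alleles must be vanishingly
rare everywhere (< 0.001), while recessive alleles tolerate slightly higher
carrier frequencies (< 0.003 in global databases, < 0.005 in the Japanese
panels, whose reference cohorts are small). Absence from a database is
never grounds for exclusion. The in-silico consensus removes a missense
variant only when *all eight* predictors agree it is benign — a missing call
breaks unanimity and retains the variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import yaml

from .model import (
    ALL_DBS,
    GLOBAL_DBS,
    JAPANESE_DBS,
    MISSENSE_LIKE,
    AnnotatedVariant,
    Consequence,
    ContractError,
    Family,
    InheritanceMode,
    PredictorCall,
    PredictorPanel,
    SpliceAnnotation,
    HSFVerdict,
    TrioGenotypes,
)


@dataclass
class FilterConfig:
    """Thresholds of the filtering cascade.

    maf_ad applies to every database under a presumed-AD model; the
    recessive tier splits thresholds between global and Japanese databases.
    ``maxent_drop`` is the fractional MaxEntScan score reduction treated as
    splice-disrupting, with ``maxent_min_ref`` guarding near-zero reference
    scores.
    """

    maf_ad: float = 0.001
    maf_recessive_global: float = 0.003
    maf_recessive_japanese: float = 0.005
    global_dbs: Tuple[str, ...] = GLOBAL_DBS
    japanese_dbs: Tuple[str, ...] = JAPANESE_DBS
    maxent_drop: float = 0.15
    maxent_min_ref: float = 3.0
    drop_non_protein_altering: bool = True

    def __post_init__(self):
        for name in ("maf_ad", "maf_recessive_global", "maf_recessive_japanese"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ContractError(f"{name} must lie in (0,1): {v}")
        if self.maf_ad > self.maf_recessive_global:
            raise ContractError(
                "maf_ad must not exceed maf_recessive_global "
                f"({self.maf_ad} > {self.maf_recessive_global})"
            )
        unknown = (set(self.global_dbs) | set(self.japanese_dbs)) - set(ALL_DBS)
        if unknown:
            raise ContractError(f"unknown database keys: {sorted(unknown)}")
        if set(self.global_dbs) | set(self.japanese_dbs) != set(ALL_DBS):
            raise ContractError("database partition must cover all databases")

    def to_yaml(self) -> str:
        d = {k: getattr(self, k) for k in (
            "maf_ad", "maf_recessive_global", "maf_recessive_japanese",
            "maxent_drop", "maxent_min_ref", "drop_non_protein_altering")}
        d["global_dbs"] = list(self.global_dbs)
        d["japanese_dbs"] = list(self.japanese_dbs)
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "FilterConfig":
        d = yaml.safe_load(text) or {}
        if "global_dbs" in d:
            d["global_dbs"] = tuple(d["global_dbs"])
        if "japanese_dbs" in d:
            d["japanese_dbs"] = tuple(d["japanese_dbs"])
        return cls(**d)


def maf_filter(
    v: AnnotatedVariant,
    mode: InheritanceMode,
    cfg: Optional[FilterConfig] = None,
) -> bool:
    """True iff the variant survives the mode-specific frequency thresholds.

    AD: every present MAF in every database must be < cfg.maf_ad.
    sporadic/AR/undetermined: present global-database MAFs < recessive_global
    and present Japanese-database MAFs < recessive_japanese. One database
    at or above its threshold suffices to exclude; absent values never do.
    """
    cfg = cfg or FilterConfig()
    mode = InheritanceMode(mode)
    present = v.freqs.present()
    if mode is InheritanceMode.AD:
        return all(maf < cfg.maf_ad for maf in present.values())
    for db, maf in present.items():
        limit = cfg.maf_recessive_japanese if db in cfg.japanese_dbs else cfg.maf_recessive_global
        if maf >= limit:
            return False
    return True


def insilico_consensus(p: PredictorPanel, consequence: Consequence) -> bool:
    """True iff the variant is retained by the predictor consensus rule.

    Applies only to missense changes: excluded iff all eight calls are
    benign. Any damaging *or missing* call retains (unanimity cannot be
    asserted with a missing call). Non-missense consequences bypass.
    """
    if Consequence(consequence) not in MISSENSE_LIKE:
        return True
    return p.n_benign() < len(p.calls)


def splice_retained(
    s: Optional[SpliceAnnotation],
    consequence: Consequence,
    cfg: Optional[FilterConfig] = None,
) -> bool:
    """Retention rule for splice-site variants.

    Canonical +/-1,2 sites are always retained. Splice-region variants are
    retained when Human Splicing Finder calls the site affected, or when the
    MaxEntScan score drops by at least ``cfg.maxent_drop`` of the reference
    score (reference score at least ``cfg.maxent_min_ref``). A missing
    annotation retains conservatively.
    """
    cfg = cfg or FilterConfig()
    consequence = Consequence(consequence)
    if consequence not in (Consequence.SPLICE_CANONICAL, Consequence.SPLICE_REGION):
        raise ContractError(f"splice_retained requires a splice consequence: {consequence}")
    if consequence is Consequence.SPLICE_CANONICAL:
        return True
    if s is None or (s.maxent_ref is None and s.hsf_verdict is HSFVerdict.ABSENT):
        return True  # conservative: cannot rule out an effect
    if s.hsf_verdict is HSFVerdict.AFFECTED:
        return True
    if s.maxent_ref is not None and s.maxent_alt is not None:
        if s.maxent_ref >= cfg.maxent_min_ref:
            drop = (s.maxent_ref - s.maxent_alt) / abs(s.maxent_ref)
            if drop >= cfg.maxent_drop:
                return True
    return False


@dataclass
class FilterAudit:
    """Outcome of the cascade for one record: retained or the first failing
    rule name."""

    variant: AnnotatedVariant
    genotypes: TrioGenotypes
    retained: bool
    failed_rule: Optional[str] = None


_SPLICE = (Consequence.SPLICE_CANONICAL, Consequence.SPLICE_REGION)


def filter_variants(
    records: Sequence[Tuple[AnnotatedVariant, TrioGenotypes]],
    family: Family,
    cfg: Optional[FilterConfig] = None,
) -> List[FilterAudit]:
    """Run the full stage-1 cascade for one family's records.

    Order of rules (first failure recorded): protein-altering check,
    mode-specific MAF filter, then the consequence-specific rule (in-silico
    consensus for missense, splice retention for splice variants; all other
    protein-altering classes bypass).
    """
    cfg = cfg or FilterConfig()
    audits: List[FilterAudit] = []
    for v, tg in records:
        rule = None
        if cfg.drop_non_protein_altering and v.consequence in (
            Consequence.SYNONYMOUS,
            Consequence.OTHER,
        ):
            rule = "not_protein_altering"
        elif not maf_filter(v, family.mode, cfg):
            rule = "maf"
        elif v.consequence in MISSENSE_LIKE and not insilico_consensus(v.predictors, v.consequence):
            rule = "insilico_consensus"
        elif v.consequence in _SPLICE and not splice_retained(v.splice, v.consequence, cfg):
            rule = "splice_effect"
        audits.append(FilterAudit(v, tg, retained=rule is None, failed_rule=rule))
    return audits


def retained(audits: Iterable[FilterAudit]) -> List[Tuple[AnnotatedVariant, TrioGenotypes]]:
    return [(a.variant, a.genotypes) for a in audits if a.retained]
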