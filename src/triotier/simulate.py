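"""Seeded synthetic trio-cohort generator.

Generates annotated trio variant tables, locus depth matrices, and qPCR Ct
tables with the statistical structure the pipeline assumes, so every stage
is testable without access to the (non-public) study genotypes. Each family
receives Mendelian-consistent background variants plus, optionally, one
planted causal configuration (de novo, homozygous, compound het, dominant
inherited, homozygous deletion, or the parent/proband discrepancy pattern);
a ground-truth ledger records every planted fact. The same seed always
reproduces the identical cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import yaml

from .cnv import DepthProfile, ExonDepth, QPCRRun
from .filtering import FilterConfig, filter_variants
from .io import KnownVariantDB
from .model import (
    ALL_DBS,
    AnnotatedVariant,
    ContractError,
    Family,
    FrequencyPanel,
    GeneRecord,
    GeneRegistry,
    Genotype,
    InheritanceMode,
    Member,
    PredictorCall,
    PredictorPanel,
    PREDICTORS,
    TrioGenotypes,
)
from .pipeline import CohortBundle
from .reference_cohort import make_registry

SCENARIOS = ("de_novo", "hom", "compound_het", "ad_inherited",
             "hom_deletion", "discrepancy", "control")

#: scenarios compatible with each presumed inheritance mode
_MODE_SCENARIOS = {
    InheritanceMode.SPORADIC: ("de_novo", "hom", "compound_het", "hom_deletion"),
    InheritanceMode.AR: ("hom", "compound_het", "hom_deletion"),
    InheritanceMode.AD: ("ad_inherited", "discrepancy"),
    InheritanceMode.UNDETERMINED: ("de_novo", "hom", "compound_het"),
}


@dataclass
class SimConfig:
    """Study-condition defaults: the 72-family mode mix of the emulated
    cohort (52 sporadic : 9 AD : 10 AR : 1 undetermined), log-uniform
    database frequency spectra spanning every filter threshold, per-predictor
    benign probability 0.9 for background missense variants, log-normal
    exon-depth noise, and 0.1-cycle Gaussian Ct noise."""

    n_families: int = 60
    mode_mix: Dict[str, float] = field(default_factory=lambda: {
        "sporadic": 52 / 72, "AD": 9 / 72, "AR": 10 / 72, "undetermined": 1 / 72,
    })
    background_variants: int = 80
    p_absent: float = 0.6
    freq_range: Tuple[float, float] = (1e-6, 5e-2)
    absent_freq_range: Tuple[float, float] = (1e-6, 1e-4)
    predictor_benign_p: float = 0.9
    p_background_truncating: float = 0.05
    planted_tier: int = 1
    #: explicit per-family scenarios; None = choose per mode. "control"
    #: plants nothing.
    scenarios: Optional[Sequence[str]] = None
    depth_sigma: float = 0.3
    ct_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        total = sum(self.mode_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ContractError(f"mode mix must sum to 1, got {total}")
        if self.seed is None:
            raise ContractError("seed is mandatory")
        if self.scenarios is not None:
            if len(self.scenarios) != self.n_families:
                raise ContractError("scenarios must match n_families")
            for s in self.scenarios:
                if s not in SCENARIOS:
                    raise ContractError(f"unknown scenario {s!r}")

    def to_yaml(self) -> str:
        d = {k: getattr(self, k) for k in (
            "n_families", "mode_mix", "background_variants", "p_absent",
            "predictor_benign_p", "p_background_truncating", "planted_tier",
            "depth_sigma", "ct_noise_sd", "seed")}
        d["freq_range"] = list(self.freq_range)
        d["absent_freq_range"] = list(self.absent_freq_range)
        d["scenarios"] = list(self.scenarios) if self.scenarios else None
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "SimConfig":
        d = yaml.safe_load(text) or {}
        for k in ("freq_range", "absent_freq_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PlantedTruth:
    family_id: str
    scenario: str
    gene: str
    tier: int
    variants: List[AnnotatedVariant] = field(default_factory=list)
    origins: List[str] = field(default_factory=list)
    extra: Dict = field(default_factory=dict)


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_parent(rng, f: float) -> Genotype:
    n = int(rng.random() < f) + int(rng.random() < f)
    return [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT][n]


def _transmit(rng, gt: Genotype) -> int:
    if gt is Genotype.HOM_ALT:
        return 1
    if gt is Genotype.HET:
        return int(rng.random() < 0.5)
    return 0


class CohortGenerator:
    """Stateful generator for one cohort draw."""

    def __init__(self, cfg: SimConfig, registry: Optional[GeneRegistry] = None):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.registry = registry or make_registry()
        # background gene universe: every registry symbol plus a Tier-4 pool
        self.background_genes = self.registry.symbols() + [
            f"T4SYN{i:03d}" for i in range(2000)
        ]
        # plantable genes per tier: synthetic non-syndromic LoF-mechanism fillers
        self.plantable = {
            t: [s for s in self.registry.symbols()
                if self.registry.get(s).tier == t and s.startswith(f"T{t}SYN")]
            for t in (1, 2, 3)
        }
        self.plantable[4] = [f"T4SYN{i:03d}" for i in range(2000)]
        self._pos = 1

    # -- variants ----------------------------------------------------------

    def _next_pos(self) -> int:
        self._pos += 211
        return self._pos

    def _background_variant(self) -> Tuple[AnnotatedVariant, float]:
        rng, cfg = self.rng, self.cfg
        gene = self.background_genes[int(rng.integers(len(self.background_genes)))]
        u = rng.random()
        if u < cfg.p_background_truncating:
            consequence, hgvs_p, hgvs_c = "nonsense", "p.(Arg10Ter)", "c.28C>T"
            panel = PredictorPanel({})
        elif u < cfg.p_background_truncating + 0.75:
            consequence, hgvs_p, hgvs_c = "missense", "p.(Ala20Val)", "c.59C>T"
            calls = {
                p: (PredictorCall.BENIGN if rng.random() < cfg.predictor_benign_p
                    else PredictorCall.DAMAGING)
                for p in PREDICTORS
            }
            panel = PredictorPanel(calls)
        else:
            consequence, hgvs_p, hgvs_c = "synonymous", "p.(=)", "c.60G>A"
            panel = PredictorPanel({})

        if rng.random() < cfg.p_absent:
            true_f = _loguniform(rng, *cfg.absent_freq_range)
            freqs = FrequencyPanel({})
        else:
            true_f = _loguniform(rng, *cfg.freq_range)
            vals = {}
            for db in ALL_DBS:
                if rng.random() < 0.85:  # not every database observed it
                    vals[db] = min(1.0, true_f * float(rng.uniform(0.7, 1.3)))
            freqs = FrequencyPanel(vals)

        pos = self._next_pos()
        v = AnnotatedVariant(
            chrom="1", pos=pos, ref="C", alt="T", gene=gene,
            transcript="NM_BG.1", hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            consequence=consequence, freqs=freqs, predictors=panel,
        )
        return v, true_f

    def _planted_variant(self, gene: str, kind: str, suffix: int = 0) -> AnnotatedVariant:
        pos = self._next_pos()
        if kind == "truncating":
            hgvs_c, hgvs_p, consequence = f"c.{100 + suffix * 3}del", \
                f"p.(Lys{34 + suffix}SerfsTer10)", "frameshift"
            panel = PredictorPanel({})
        else:
            hgvs_c, hgvs_p, consequence = f"c.{200 + suffix * 3}G>A", \
                f"p.(Gly{67 + suffix}Ser)", "missense"
            panel = PredictorPanel.uniform(PredictorCall.DAMAGING)
        return AnnotatedVariant(
            chrom="1", pos=pos, ref="G", alt="A", gene=gene,
            transcript="NM_PL.1", hgvs_c=hgvs_c, hgvs_p=hgvs_p,
            consequence=consequence, freqs=FrequencyPanel({}), predictors=panel,
        )

    # -- families ----------------------------------------------------------

    def _make_family(self, idx: int, mode: InheritanceMode, scenario: str) -> Family:
        fid = f"F{idx:04d}"
        father_affected = mother_affected = False
        if mode is InheritanceMode.AD:
            if scenario == "discrepancy":
                mother_affected = True
            else:
                father_affected = self.rng.random() < 0.5
                mother_affected = not father_affected
        elif mode is InheritanceMode.UNDETERMINED:
            father_affected = mother_affected = True
        return Family(
            family_id=fid,
            proband=Member(f"{fid}-P", affected=True),
            father=Member(f"{fid}-F", affected=father_affected, sex="M"),
            mother=Member(f"{fid}-M", affected=mother_affected, sex="F"),
            mode=mode,
        )

    def _background_records(self, family: Family):
        rng = self.rng
        records = []
        for _ in range(self.cfg.background_variants):
            v, true_f = self._background_variant()
            f_gt = _draw_parent(rng, true_f)
            m_gt = _draw_parent(rng, true_f)
            child = _transmit(rng, f_gt) + _transmit(rng, m_gt)
            p_gt = [Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT][child]
            if p_gt is Genotype.HOM_REF and f_gt is Genotype.HOM_REF and m_gt is Genotype.HOM_REF:
                continue  # nobody carries the allele: not in the call set
            records.append((v, TrioGenotypes(p_gt, f_gt, m_gt)))
        return records

    def _plant(self, family: Family, scenario: str) -> Tuple[list, Optional[PlantedTruth]]:
        if scenario == "control":
            return [], None
        cfg, rng = self.cfg, self.rng
        tier = cfg.planted_tier
        pool = self.plantable[tier]
        gene = pool[int(rng.integers(len(pool)))]
        truth = PlantedTruth(family.family_id, scenario, gene, tier)

        if scenario == "de_novo":
            v = self._planted_variant(gene, "truncating")
            truth.variants = [v]
            truth.origins = ["de_novo"]
            return [(v, TrioGenotypes(Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF))], truth
        if scenario == "hom":
            v = self._planted_variant(gene, "truncating")
            truth.variants = [v]
            truth.origins = ["biparental"]
            return [(v, TrioGenotypes(Genotype.HOM_ALT, Genotype.HET, Genotype.HET))], truth
        if scenario == "compound_het":
            v1 = self._planted_variant(gene, "truncating", 0)
            v2 = self._planted_variant(gene, "truncating", 1)
            truth.variants = [v1, v2]
            truth.origins = ["paternal", "maternal"]
            return [
                (v1, TrioGenotypes(Genotype.HET, Genotype.HET, Genotype.HOM_REF)),
                (v2, TrioGenotypes(Genotype.HET, Genotype.HOM_REF, Genotype.HET)),
            ], truth
        if scenario == "ad_inherited":
            v = self._planted_variant(gene, "missense")
            truth.variants = [v]
            affected_father = bool(family.father and family.father.affected)
            truth.origins = ["paternal" if affected_father else "maternal"]
            gts = (
                TrioGenotypes(Genotype.HET, Genotype.HET, Genotype.HOM_REF)
                if affected_father
                else TrioGenotypes(Genotype.HET, Genotype.HOM_REF, Genotype.HET)
            )
            return [(v, gts)], truth
        if scenario == "hom_deletion":
            truth.extra = {"copies": {"proband": 0, "father": 1, "mother": 1}}
            return [], truth
        if scenario == "discrepancy":
            # affected mother homozygously deleted; proband het-deleted plus
            # a de novo point variant in a second gene of the same tier
            gene2 = pool[int(rng.integers(len(pool)))]
            while gene2 == gene:
                gene2 = pool[int(rng.integers(len(pool)))]
            v = self._planted_variant(gene2, "missense")
            truth.variants = [v]
            truth.origins = ["de_novo"]
            truth.extra = {
                "deleted_gene": gene,
                "point_gene": gene2,
                "copies": {"proband": 1, "father": 2, "mother": 0},
            }
            return [(v, TrioGenotypes(Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF))], truth
        raise ContractError(f"unknown scenario {scenario!r}")

    def generate(self) -> Tuple[CohortBundle, List[PlantedTruth]]:
        cfg, rng = self.cfg, self.rng
        modes = [InheritanceMode(m) for m in cfg.mode_mix]
        probs = np.array([cfg.mode_mix[m.value] for m in modes])
        drawn = rng.choice(len(modes), size=cfg.n_families, p=probs)

        families: List[Family] = []
        records: Dict[str, list] = {}
        cnv_copies: Dict[str, Dict[str, Dict[str, int]]] = {}
        truths: List[PlantedTruth] = []

        for i, mi in enumerate(drawn):
            mode = modes[int(mi)]
            if cfg.scenarios is not None:
                scenario = cfg.scenarios[i]
                if scenario != "control" and scenario not in _MODE_SCENARIOS[mode]:
                    raise ContractError(
                        f"scenario {scenario!r} incompatible with mode {mode.value}"
                    )
            else:
                options = _MODE_SCENARIOS[mode]
                scenario = options[int(rng.integers(len(options)))]
            family = self._make_family(i, mode, scenario)
            planted, truth = self._plant(family, scenario)
            recs = self._background_records(family) + planted
            if truth is not None:
                truths.append(truth)
                copies = truth.extra.get("copies")
                if copies:
                    deleted_gene = truth.extra.get("deleted_gene", truth.gene)
                    cnv_copies[family.family_id] = {
                        role: {deleted_gene: cn} for role, cn in copies.items()
                    }
            families.append(family)
            records[family.family_id] = recs

        bundle = CohortBundle(
            families=families,
            records=records,
            registry=self.registry,
            known_db=KnownVariantDB(),
            cnv_copies=cnv_copies,
        )
        self._self_check(bundle, truths)
        return bundle, truths

    def _self_check(self, bundle: CohortBundle, truths: List[PlantedTruth]) -> None:
        """Every planted causal variant must survive the filtering cascade
        under its family's mode."""
        fams = {f.family_id: f for f in bundle.families}
        cfg = FilterConfig()
        for t in truths:
            if not t.variants:
                continue
            fam = fams[t.family_id]
            planted_keys = {v.key for v in t.variants}
            audits = filter_variants(
                [(v, tg) for v, tg in bundle.records[t.family_id] if v.key in planted_keys],
                fam, cfg,
            )
            bad = [a for a in audits if not a.retained]
            if bad:
                raise AssertionError(
                    f"planted variant failed filtering in {t.family_id}: "
                    f"{bad[0].failed_rule}"
                )


def generate_cohort(cfg: SimConfig, registry: Optional[GeneRegistry] = None):
    """Generate one seeded cohort; returns (bundle, ground-truth ledger)."""
    return CohortGenerator(cfg, registry).generate()


# --------------------------------------------------------------------------
# Depth matrices


@dataclass
class LocusModel:
    gene: str
    chrom: str
    start: int
    n_exons: int
    multimap: Set[int]
    exon_span: int = 200
    exon_gap: int = 200


def generate_depth_profile(
    rng: np.random.Generator,
    locus: LocusModel,
    sample_id: str,
    deleted_exons: Set[int] = frozenset(),
    copies: int = 0,
    median: float = 144.0,
    sigma: float = 0.3,
) -> DepthProfile:
    """One sample's per-exon depth: log-normal noise around the sample
    median; deleted informative exons drop to the copy-number fraction of
    the median (near zero for a homozygous deletion) while multimap exons
    keep pseudogene-masked, normal-looking depth."""
    exons = []
    step = locus.exon_span + locus.exon_gap
    for i in range(1, locus.n_exons + 1):
        s = locus.start + (i - 1) * step
        mm = i in locus.multimap
        noise = float(np.exp(rng.normal(0.0, sigma)))
        if not mm and i in deleted_exons:
            frac = {0: 0.0, 1: 0.5, 2: 1.0}[copies]
            depth = median * frac * noise + (float(rng.uniform(0.0, 2.0)) if copies == 0 else 0.0)
        else:
            depth = median * noise
        exons.append(ExonDepth(locus.gene, locus.gene, i, locus.chrom, s,
                               s + locus.exon_span - 1, depth, mm))
    return DepthProfile(sample_id, exons, median)


def generate_depth_matrix(
    cfg: SimConfig,
    locus: LocusModel,
    samples: Dict[str, Tuple[Set[int], int]],
    median: float = 144.0,
) -> Dict[str, DepthProfile]:
    """Depth profiles for several samples of one locus; ``samples`` maps
    sample id -> (deleted exon set, copy number)."""
    rng = np.random.default_rng(cfg.seed + 101)
    return {
        sid: generate_depth_profile(rng, locus, sid, deleted, copies,
                                    median=median, sigma=cfg.depth_sigma)
        for sid, (deleted, copies) in samples.items()
    }


# --------------------------------------------------------------------------
# qPCR


def generate_qpcr(
    cfg: SimConfig,
    true_cn: int,
    rng: Optional[np.random.Generator] = None,
    base_ct: float = 24.0,
    replicates: int = 2,
) -> QPCRRun:
    """Ct values for one sample at a known copy number: the target shifts
    by -log2(cn/2) cycles versus the two-copy calibrator (no amplification
    at zero copies) plus Gaussian noise of sd ``cfg.ct_noise_sd``."""
    if true_cn not in (0, 1, 2):
        raise ContractError(f"true_cn must be 0, 1 or 2: {true_cn}")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 202)
    sd = cfg.ct_noise_sd

    def wells(mu):
        return tuple(float(mu + rng.normal(0.0, sd)) for _ in range(replicates))

    if true_cn == 0:
        target = tuple(None for _ in range(replicates))
    else:
        target = wells(base_ct - math.log2(true_cn / 2.0))
    return QPCRRun(
        sample_target=target,
        sample_ref=wells(base_ct),
        calibrator_target=wells(base_ct),
        calibrator_ref=wells(base_ct),
    )
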