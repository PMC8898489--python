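"""Readers and writers for the pipeline's external artifacts.

Canonical interchange is a documented TSV dialect (one row per alt allele,
one column per annotation); VCF v4.2 is accepted with annotations mapped
from INFO keys through a configurable key table. Pedigrees are 6-column PED
(an optional 7th column names the presumed inheritance mode); gene tier
lists are one-symbol-per-line text with ``#`` comments.

Every reader rejects schema violations with a located error; every writer's
output re-reads losslessly.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    ALL_DBS,
    PREDICTORS,
    AnnotatedVariant,
    Classification,
    Consequence,
    Family,
    FrequencyPanel,
    GeneRecord,
    GeneRegistry,
    Genotype,
    HSFVerdict,
    InheritanceMode,
    Member,
    PredictorPanel,
    SpliceAnnotation,
    TrioGenotypes,
    normalize_consequence,
)


class SchemaError(ValueError):
    """A file violates its declared schema (missing column, bad value)."""


class PedigreeError(ValueError):
    """Referential or structural problem in a PED file."""


# --------------------------------------------------------------------------
# Variant tables

#: Mandatory TSV columns; everything else is optional annotation.
REQUIRED_COLUMNS = ("family_id", "gene", "chrom", "pos", "ref", "alt", "gt_proband")

_MAF_COLUMNS = {db: f"maf_{db}" for db in ALL_DBS}

_GT_ALIASES = {
    "0/0": Genotype.HOM_REF, "0|0": Genotype.HOM_REF, "hom_ref": Genotype.HOM_REF,
    "0/1": Genotype.HET, "1/0": Genotype.HET, "0|1": Genotype.HET,
    "1|0": Genotype.HET, "het": Genotype.HET,
    "1/1": Genotype.HOM_ALT, "1|1": Genotype.HOM_ALT, "hom_alt": Genotype.HOM_ALT,
    "./.": Genotype.MISSING, ".": Genotype.MISSING, "": Genotype.MISSING,
    "missing": Genotype.MISSING,
}


def _parse_genotype(text: str, line_no: int) -> Genotype:
    gt = _GT_ALIASES.get(text.strip())
    if gt is None:
        raise SchemaError(f"line {line_no}: malformed genotype {text!r}")
    return gt


def _opt_float(row: Dict[str, str], col: str) -> Optional[float]:
    raw = (row.get(col) or "").strip()
    if raw in ("", ".", "NA", "-"):
        return None
    try:
        return float(raw)
    except ValueError as e:
        raise SchemaError(f"column {col}: not a number: {raw!r}") from e


def _row_to_variant(row: Dict[str, str], line_no: int, alt: str) -> AnnotatedVariant:
    freqs = FrequencyPanel(
        {db: v for db, col in _MAF_COLUMNS.items() if (v := _opt_float(row, col)) is not None}
    )
    calls = {}
    for p in PREDICTORS:
        raw = (row.get(p) or "").strip().lower()
        if raw in ("damaging", "d"):
            calls[p] = "damaging"
        elif raw in ("benign", "b", "tolerated", "neutral"):
            calls[p] = "benign"
        elif raw in ("", ".", "missing"):
            pass
        else:
            raise SchemaError(f"line {line_no}: bad predictor call {raw!r} for {p}")
    panel = PredictorPanel(calls, revel=_opt_float(row, "revel"), cadd=_opt_float(row, "cadd"))

    splice = None
    hsf_raw = (row.get("hsf") or "").strip().lower()
    maxent_ref = _opt_float(row, "maxent_ref")
    maxent_alt = _opt_float(row, "maxent_alt")
    if hsf_raw or maxent_ref is not None:
        verdict = {
            "affected": HSFVerdict.AFFECTED,
            "not_affected": HSFVerdict.NOT_AFFECTED,
            "": HSFVerdict.ABSENT,
        }.get(hsf_raw)
        if verdict is None:
            raise SchemaError(f"line {line_no}: bad HSF verdict {hsf_raw!r}")
        splice = SpliceAnnotation(maxent_ref, maxent_alt, verdict)

    cons_raw = (row.get("consequence") or "").strip()
    if cons_raw:
        consequence = Consequence(cons_raw)
    else:
        consequence = normalize_consequence(row.get("hgvs_c", ""), row.get("hgvs_p", ""))

    exon_raw = (row.get("exon") or "").strip()
    return AnnotatedVariant(
        chrom=row["chrom"].strip(),
        pos=int(row["pos"]),
        ref=row["ref"].strip(),
        alt=alt,
        gene=row["gene"].strip(),
        transcript=(row.get("transcript") or "").strip(),
        hgvs_c=(row.get("hgvs_c") or "").strip(),
        hgvs_p=(row.get("hgvs_p") or "").strip(),
        consequence=consequence,
        exon_index=int(exon_raw) if exon_raw else None,
        freqs=freqs,
        predictors=panel,
        splice=splice,
        rs_id=(row.get("rs_id") or "").strip() or None,
    )


def read_variant_table(
    path, dialect: str = "tsv", vcf_info_map: Optional[Dict[str, str]] = None
) -> List[Tuple[str, AnnotatedVariant, TrioGenotypes]]:
    """Read an annotated trio variant table.

    Returns a list of ``(family_id, variant, trio_genotypes)``. Multi-allelic
    rows (comma-separated alts) are split into one record per alt allele
    before anything downstream sees them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "tsv":
        return _read_variant_tsv(path)
    if dialect == "vcf":
        return _read_variant_vcf(path, vcf_info_map)
    raise SchemaError(f"unsupported dialect: {dialect!r}")


def _read_variant_tsv(path: Path):
    out = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing mandatory column(s): {', '.join(missing)}")
        for line_no, row in enumerate(reader, start=2):
            tg = TrioGenotypes(
                proband=_parse_genotype(row.get("gt_proband", ""), line_no),
                father=_parse_genotype(row.get("gt_father", "missing"), line_no),
                mother=_parse_genotype(row.get("gt_mother", "missing"), line_no),
            )
            for alt in row["alt"].split(","):
                v = _row_to_variant(row, line_no, alt.strip())
                out.append((row["family_id"].strip(), v, tg))
    return out


#: Default mapping of annotation field -> VCF INFO key.
DEFAULT_VCF_INFO_MAP = {
    "gene": "GENE",
    "transcript": "TRANSCRIPT",
    "hgvs_c": "HGVSC",
    "hgvs_p": "HGVSP",
    "consequence": "CSQ_CLASS",
    "exon": "EXON",
    "rs_id": "RS",
    **{f"maf_{db}": f"MAF_{db}" for db in ALL_DBS},
    **{p: f"PRED_{p}" for p in PREDICTORS},
    "revel": "REVEL",
    "cadd": "CADD",
    "maxent_ref": "MAXENT_REF",
    "maxent_alt": "MAXENT_ALT",
    "hsf": "HSF",
}


def _read_variant_vcf(path: Path, info_map: Optional[Dict[str, str]]):
    from cyvcf2 import VCF

    info_map = info_map or DEFAULT_VCF_INFO_MAP
    vcf = VCF(str(path))
    samples = vcf.samples
    if not 1 <= len(samples) <= 3:
        raise SchemaError(f"{path}: expected 1-3 samples (proband, father, mother)")
    out = []
    family_id = path.stem
    for rec in vcf:
        fam = rec.INFO.get("FAMILY") or family_id
        gts = []
        for i in range(len(samples)):
            a = rec.genotypes[i][:-1]
            if any(x < 0 for x in a):
                gts.append(Genotype.MISSING)
            else:
                gts.append([Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT][sum(1 for x in a if x > 0)])
        while len(gts) < 3:
            gts.append(Genotype.MISSING)
        tg = TrioGenotypes(proband=gts[0], father=gts[1], mother=gts[2])
        for alt in rec.ALT:
            row = {"chrom": rec.CHROM, "pos": str(rec.POS), "ref": rec.REF, "alt": alt,
                   "family_id": str(fam), "gt_proband": tg.proband.value}
            for field, key in info_map.items():
                val = rec.INFO.get(key)
                if val is not None:
                    row[field] = str(val)
            v = _row_to_variant(row, rec.POS, alt)
            out.append((str(fam), v, tg))
    return out


#: Column order of the TSV dialect (writers emit exactly these).
TSV_COLUMNS = (
    ["family_id", "gene", "transcript", "chrom", "pos", "ref", "alt", "hgvs_c",
     "hgvs_p", "consequence", "exon", "rs_id"]
    + [f"maf_{db}" for db in ALL_DBS]
    + list(PREDICTORS)
    + ["revel", "cadd", "maxent_ref", "maxent_alt", "hsf",
       "gt_proband", "gt_father", "gt_mother"]
)


def write_variant_table(records, path) -> None:
    """Write ``(family_id, variant, genotypes)`` records to the TSV dialect."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSV_COLUMNS)
        for family_id, v, tg in records:
            row = {
                "family_id": family_id, "gene": v.gene, "transcript": v.transcript,
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "hgvs_c": v.hgvs_c, "hgvs_p": v.hgvs_p,
                "consequence": v.consequence.value,
                "exon": v.exon_index if v.exon_index is not None else "",
                "rs_id": v.rs_id or "",
                "revel": v.predictors.revel if v.predictors.revel is not None else "",
                "cadd": v.predictors.cadd if v.predictors.cadd is not None else "",
                "gt_proband": tg.proband.value, "gt_father": tg.father.value,
                "gt_mother": tg.mother.value,
            }
            for db in ALL_DBS:
                maf = v.freqs.get(db)
                row[f"maf_{db}"] = repr(maf) if maf is not None else ""
            for p in PREDICTORS:
                call = v.predictors.calls[p]
                row[p] = "" if call.value == "missing" else call.value
            if v.splice is not None:
                row["maxent_ref"] = v.splice.maxent_ref if v.splice.maxent_ref is not None else ""
                row["maxent_alt"] = v.splice.maxent_alt if v.splice.maxent_alt is not None else ""
                row["hsf"] = "" if v.splice.hsf_verdict is HSFVerdict.ABSENT else v.splice.hsf_verdict.value
            else:
                row["maxent_ref"] = row["maxent_alt"] = row["hsf"] = ""
            w.writerow([row.get(c, "") for c in TSV_COLUMNS])


# --------------------------------------------------------------------------
# Pedigrees

_AFFECTED_CODES = {"2": True, "1": False, "0": None, "-9": None}


def read_ped(path) -> List[Family]:
    """Read a 6-column PED file into Family objects.

    Affected coding: 2 = affected, 1 = unaffected, 0 / -9 = unknown.
    An optional 7th column on the proband row names the presumed
    inheritance mode (sporadic / AD / AR / undetermined); without it the
    mode defaults from parental phenotypes (one affected parent -> AD, both
    affected -> undetermined, otherwise sporadic). Duo families (one parent
    listed as 0) are permitted and flagged.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeError(f"{path}:{line_no}: expected >= 6 columns, got {len(parts)}")
            rows.append((line_no, parts))

    by_id: Dict[Tuple[str, str], dict] = {}
    for line_no, p in rows:
        fam, iid, father, mother, sex, pheno = p[:6]
        if pheno not in _AFFECTED_CODES:
            raise PedigreeError(f"{path}:{line_no}: bad phenotype code {pheno!r}")
        by_id[(fam, iid)] = {
            "line": line_no, "father": father, "mother": mother,
            "sex": {"1": "M", "2": "F"}.get(sex),
            "affected": _AFFECTED_CODES[pheno],
            "mode": p[6] if len(p) > 6 else None,
        }

    families: Dict[str, Family] = {}
    for (fam, iid), info in by_id.items():
        if info["father"] == "0" and info["mother"] == "0":
            continue  # founder row
        for parent_key in ("father", "mother"):
            pid = info[parent_key]
            if pid != "0" and (fam, pid) not in by_id:
                raise PedigreeError(
                    f"{path}:{info['line']}: individual {iid} references absent "
                    f"{parent_key} {pid!r} in family {fam}"
                )
        if fam in families:
            raise PedigreeError(f"{path}: multiple probands in family {fam}")

        def member(pid):
            if pid == "0":
                return None
            pinfo = by_id[(fam, pid)]
            return Member(pid, affected=pinfo["affected"], sex=pinfo["sex"])

        father = member(info["father"])
        mother = member(info["mother"])
        if info["mode"]:
            mode = InheritanceMode(info["mode"])
        else:
            n_aff = sum(1 for m in (father, mother) if m is not None and m.affected)
            mode = (
                InheritanceMode.UNDETERMINED if n_aff == 2
                else InheritanceMode.AD if n_aff == 1
                else InheritanceMode.SPORADIC
            )
        families[fam] = Family(
            family_id=fam,
            proband=Member(iid, affected=info["affected"], sex=info["sex"]),
            father=father,
            mother=mother,
            mode=mode,
        )
    return sorted(families.values(), key=lambda f: f.family_id)


def write_ped(families: Sequence[Family], path) -> None:
    code = {True: "2", False: "1", None: "0"}
    sex = {"M": "1", "F": "2", None: "0"}
    with open(path, "w") as fh:
        for fam in families:
            for parent in (fam.father, fam.mother):
                if parent is not None:
                    fh.write(
                        f"{fam.family_id}\t{parent.individual_id}\t0\t0\t"
                        f"{sex[parent.sex]}\t{code[parent.affected]}\n"
                    )
            fh.write(
                f"{fam.family_id}\t{fam.proband.individual_id}\t"
                f"{fam.father.individual_id if fam.father else 0}\t"
                f"{fam.mother.individual_id if fam.mother else 0}\t"
                f"{sex[fam.proband.sex]}\t{code[fam.proband.affected]}\t{fam.mode.value}\n"
            )


# --------------------------------------------------------------------------
# Gene tier lists

import warnings


def read_gene_list(path) -> List[str]:
    symbols = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                symbols.append(line)
    if not symbols:
        warnings.warn(f"empty gene list: {path}", stacklevel=2)
    return symbols


def read_tier_registry(
    tier1_path, tier2_path, tier3_path,
    annotations: Optional[Dict[str, GeneRecord]] = None,
) -> GeneRegistry:
    """Build a registry from three tier lists.

    Duplicate symbols across lists resolve by precedence Tier 1 > 2 > 3
    (lower tiers are defined as "not already in a higher tier"). Registry
    size equals the union of symbols; unknown symbols resolve to Tier 4 at
    lookup time. ``annotations`` supplies full GeneRecord metadata (disease,
    inheritance, syndromic/LoF flags) for symbols that have it.
    """
    annotations = annotations or {}
    reg = GeneRegistry()
    seen = set()
    for tier, path in ((1, tier1_path), (2, tier2_path), (3, tier3_path)):
        for symbol in read_gene_list(path):
            if symbol in seen:
                continue
            seen.add(symbol)
            ann = annotations.get(symbol)
            if ann is not None and ann.tier == tier:
                reg.add(ann)
            else:
                reg.add(GeneRecord(symbol=symbol, tier=tier))
    return reg


# --------------------------------------------------------------------------
# Known-variant lookup (OMIM/HGMD/ClinVar stand-in)


class KnownVariantDB:
    """Lookup of previously reported variants keyed by (gene, hgvs_c)."""

    COLUMNS = ("gene", "hgvs_c", "classification", "same_aa_plp",
               "other_aa_same_residue_plp", "hotspot", "pp5", "phenotype")

    def __init__(self, entries: Optional[Dict] = None):
        self.entries = entries or {}

    def lookup(self, gene: str, hgvs_c: str) -> dict:
        return self.entries.get(
            (gene, hgvs_c),
            {"classification": Classification.NONE, "same_aa_plp": False,
             "other_aa_same_residue_plp": False, "hotspot": False,
             "pp5": False, "phenotype": frozenset()},
        )

    def classification(self, gene: str, hgvs_c: str) -> Classification:
        return self.lookup(gene, hgvs_c)["classification"]

    @classmethod
    def read_tsv(cls, path) -> "KnownVariantDB":
        entries = {}
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = [c for c in cls.COLUMNS[:3] if c not in (reader.fieldnames or [])]
            if missing:
                raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
            for row in reader:
                entries[(row["gene"], row["hgvs_c"])] = {
                    "classification": Classification(row["classification"]),
                    "same_aa_plp": row.get("same_aa_plp", "0") == "1",
                    "other_aa_same_residue_plp": row.get("other_aa_same_residue_plp", "0") == "1",
                    "hotspot": row.get("hotspot", "0") == "1",
                    "pp5": row.get("pp5", "0") == "1",
                    "phenotype": frozenset(
                        t for t in (row.get("phenotype") or "").split(";") if t
                    ),
                }
        return cls(entries)

    def write_tsv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(self.COLUMNS)
            for (gene, hgvs_c), e in sorted(self.entries.items()):
                w.writerow([
                    gene, hgvs_c, e["classification"].value,
                    int(e["same_aa_plp"]), int(e["other_aa_same_residue_plp"]),
                    int(e["hotspot"]), int(e["pp5"]), ";".join(sorted(e["phenotype"])),
                ])


# --------------------------------------------------------------------------
# Candidate reports

REPORT_COLUMNS = (
    "family_id", "member_id", "status", "rank", "gene", "tier", "model",
    "variants", "criteria", "classification",
)


def write_candidate_report(rows: Sequence[Dict], path, format: str = "tsv") -> None:
    """Write flat report rows (one per family x member x gene) with a
    deterministic column order. Round-trips losslessly through
    :func:`read_candidate_report`."""
    rows = list(rows)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(REPORT_COLUMNS)
            for r in rows:
                w.writerow([r.get(c, "") for c in REPORT_COLUMNS])
    elif format == "json":
        with open(path, "w") as fh:
            json.dump([{c: r.get(c, "") for c in REPORT_COLUMNS} for r in rows],
                      fh, indent=1, sort_keys=False)
            fh.write("\n")
    else:
        raise SchemaError(f"unsupported report format: {format!r}")


def read_candidate_report(path, format: str = "tsv") -> List[Dict]:
    if format == "tsv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            missing = [c for c in REPORT_COLUMNS if c not in (reader.fieldnames or [])]
            if missing:
                raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
            return [dict(row) for row in reader]
    if format == "json":
        with open(path) as fh:
            return [{c: str(r.get(c, "")) for c in REPORT_COLUMNS} for r in json.load(fh)]
    raise SchemaError(f"unsupported report format: {format!r}")
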