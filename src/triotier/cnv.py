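"""Pseudogene-aware copy-number screening at a single locus.

The STRC/CATSPER2 region on 15q15.3 harbors near-identical pseudogenes
(STRCP1, CATSPER2P1), so short reads from many exons align ambiguously and
per-exon depth there is uninformative: those exons look normal even on a
homozygously deleted allele. The screen therefore treats multimap exons as
transparent — they neither contribute deletion evidence nor interrupt a run
of informative deleted exons. Deletion calls from read depth are bounded by
MLPA probe coordinates (inner/outer breakpoint interval) and validated per
family member by duplicate-well qPCR relative quantification (2 x 2^-ddCt
against a two-copy calibrator and a reference amplicon).
"""

from __future__ import annotations

import csv
import math
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple


class LocusError(ValueError):
    pass


class UninformativeLocus(LocusError):
    """All exons multimapped: a negative call cannot be made."""


class UnboundedDeletion(LocusError):
    """Deleted MLPA probes touch the probe-set edge; a flank is unbounded."""


# --------------------------------------------------------------------------
# Read-depth screen


@dataclass(frozen=True)
class ExonDepth:
    locus: str
    gene: str
    exon_index: int
    chrom: str
    start: int  # 1-based inclusive
    end: int
    depth: float
    multimap: bool = False

    def __post_init__(self):
        if self.depth < 0:
            raise LocusError(f"negative depth at {self.gene} exon {self.exon_index}")


@dataclass
class DepthProfile:
    sample_id: str
    exons: List[ExonDepth]
    sample_median_depth: float

    def __post_init__(self):
        if self.sample_median_depth <= 0:
            raise LocusError("sample-wide median depth must be positive")
        order = [(e.chrom, e.start) for e in self.exons]
        if order != sorted(order):
            raise LocusError("exon records must be in genomic order")


@dataclass(frozen=True)
class DeletionCall:
    sample_id: str
    gene: str
    first_exon: int
    last_exon: int
    exons: Tuple[int, ...]  # informative exons supporting the call
    mean_depth_fraction: float

    def hgvs_allele(self) -> str:
        """Whole-gene deletion allele in HGVS-style uncertain-breakpoint
        notation, as used for reporting STRC deletions."""
        return "c.(?_-1)_(*1_?)del"


def call_homozygous_deletion(
    dp: DepthProfile,
    min_run: int = 2,
    depth_fraction: float = 0.10,
) -> List[DeletionCall]:
    """Emit homozygous-deletion calls from per-exon depth.

    A run of >= ``min_run`` consecutive *informative* (non-multimap) exons,
    each with depth < ``depth_fraction`` x sample median, is one call.
    Multimap exons are transparent: they do not break runs and contribute no
    evidence. Calls are scale-invariant in absolute depth because the
    threshold is a fraction of the sample median.
    """
    informative = [e for e in dp.exons if not e.multimap]
    if not informative:
        raise UninformativeLocus(
            f"{dp.sample_id}: every exon is multimapped; locus uninformative"
        )
    cutoff = depth_fraction * dp.sample_median_depth
    calls: List[DeletionCall] = []
    by_gene: Dict[str, List[ExonDepth]] = {}
    for e in informative:
        by_gene.setdefault(e.gene, []).append(e)
    for gene, exons in by_gene.items():
        run: List[ExonDepth] = []
        for e in exons + [None]:
            if e is not None and e.depth < cutoff:
                run.append(e)
                continue
            if len(run) >= min_run:
                calls.append(
                    DeletionCall(
                        sample_id=dp.sample_id,
                        gene=gene,
                        first_exon=run[0].exon_index,
                        last_exon=run[-1].exon_index,
                        exons=tuple(x.exon_index for x in run),
                        mean_depth_fraction=(
                            sum(x.depth for x in run) / len(run) / dp.sample_median_depth
                        ),
                    )
                )
            run = []
    calls.sort(key=lambda c: (c.gene, c.first_exon))
    return calls


def read_depth_table(path) -> Dict[str, DepthProfile]:
    """Read a BED-like TSV of per-exon depths.

    Columns: sample, locus, chrom, start, end, gene, exon, depth, multimap
    (0/1), median (sample-wide median depth, repeated per row).
    """
    profiles: Dict[str, List[ExonDepth]] = {}
    medians: Dict[str, float] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample", "chrom", "start", "end", "gene", "exon", "depth", "multimap", "median"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise LocusError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
        for row in reader:
            e = ExonDepth(
                locus=row.get("locus", ""),
                gene=row["gene"],
                exon_index=int(row["exon"]),
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                depth=float(row["depth"]),
                multimap=row["multimap"] == "1",
            )
            profiles.setdefault(row["sample"], []).append(e)
            medians[row["sample"]] = float(row["median"])
    return {
        s: DepthProfile(sample_id=s, exons=exons, sample_median_depth=medians[s])
        for s, exons in profiles.items()
    }


def write_depth_table(profiles: Sequence[DepthProfile], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample", "locus", "chrom", "start", "end", "gene", "exon",
                    "depth", "multimap", "median"])
        for dp in profiles:
            for e in dp.exons:
                w.writerow([dp.sample_id, e.locus, e.chrom, e.start, e.end, e.gene,
                            e.exon_index, repr(e.depth), int(e.multimap),
                            repr(dp.sample_median_depth)])


# --------------------------------------------------------------------------
# MLPA


@dataclass(frozen=True)
class Probe:
    label: str
    coordinate: int  # GRCh37/38 g. position of the probe
    ratio: float  # normalized against control samples; 1.0 = two copies


@dataclass
class MLPAProbeSet:
    probes: List[Probe]

    def __post_init__(self):
        coords = [p.coordinate for p in self.probes]
        if any(b <= a for a, b in zip(coords, coords[1:])):
            raise LocusError("probe coordinates must be strictly increasing")

    def labels(self) -> List[str]:
        return [p.label for p in self.probes]


def breakpoint_interval(
    probes: MLPAProbeSet, deleted: Sequence[str]
) -> Tuple[float, float]:
    """Inner and outer bounds (kb, one decimal) of a deleted block.

    The deleted probes must form one contiguous block strictly inside the
    probe set. The inner bound is the span of the deleted probes themselves;
    the outer bound is the span between the nearest retained probes flanking
    the block — the true breakpoints lie between the two.
    """
    deleted_set = set(deleted)
    unknown = deleted_set - set(probes.labels())
    if unknown:
        raise LocusError(f"unknown probe label(s): {sorted(unknown)}")
    flags = [p.label in deleted_set for p in probes.probes]
    idx = [i for i, f in enumerate(flags) if f]
    if not idx:
        raise LocusError("no deleted probes given")
    if idx != list(range(idx[0], idx[-1] + 1)):
        raise LocusError("deleted probes must form one contiguous block")
    if idx[0] == 0 or idx[-1] == len(flags) - 1:
        raise UnboundedDeletion("deleted block touches the probe-set edge")
    inner = probes.probes[idx[-1]].coordinate - probes.probes[idx[0]].coordinate
    outer = probes.probes[idx[-1] + 1].coordinate - probes.probes[idx[0] - 1].coordinate
    return round(inner / 1000.0, 1), round(outer / 1000.0, 1)


#: MLPA ratio class boundaries (config-exposed, not vendor-mandated).
MLPA_CLASSES = (
    (0.0, 0.2, 0),
    (0.4, 0.65, 1),
    (0.8, 1.2, 2),
)


def mlpa_interpret(probes: MLPAProbeSet, classes=MLPA_CLASSES) -> Dict[str, object]:
    """Per-probe copy-number classes from normalized ratios; ratios falling
    between bands are flagged rather than forced into a class."""
    out: Dict[str, object] = {}
    for p in probes.probes:
        cls = "flagged"
        for lo, hi, copies in classes:
            if lo <= p.ratio <= hi:
                cls = copies
                break
        out[p.label] = cls
    return out


def read_mlpa_table(path) -> MLPAProbeSet:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = {"label", "coordinate", "ratio"} - set(reader.fieldnames or [])
        if missing:
            raise LocusError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
        probes = [Probe(r["label"], int(r["coordinate"]), float(r["ratio"])) for r in reader]
    return MLPAProbeSet(probes)


# --------------------------------------------------------------------------
# qPCR relative copy number (ddCt)


@dataclass
class QPCRRun:
    """Duplicate-well Ct values for one sample/amplicon quantification.

    ``None`` Ct values model absent amplification (target not present).
    The calibrator is a two-copy control individual.
    """

    sample_target: Tuple[Optional[float], ...]
    sample_ref: Tuple[float, ...]
    calibrator_target: Tuple[float, ...]
    calibrator_ref: Tuple[float, ...]
    target_label: str = "STRC_ex19"
    ref_label: str = "MYO7A_ex10"

    def __post_init__(self):
        for name in ("sample_target", "sample_ref", "calibrator_target", "calibrator_ref"):
            vals = tuple(getattr(self, name))
            setattr(self, name, vals)
            if len(vals) < 2:
                raise LocusError(f"{name}: duplicated qPCR requires >= 2 replicates")
            for v in vals:
                if v is not None and v <= 0:
                    raise LocusError(f"{name}: Ct must be positive, got {v}")
        if any(v is None for v in self.sample_ref + self.calibrator_target + self.calibrator_ref):
            raise LocusError("reference and calibrator amplicons must amplify")


@dataclass(frozen=True)
class CopyNumberCall:
    estimate: Optional[float]
    call: object  # 0 | 1 | 2 | "amplified" | "ambiguous"
    reason: str = ""


def qpcr_copy_number(
    run: QPCRRun,
    ct_tolerance: float = 0.5,
    bands: Tuple[Tuple[float, float, int], ...] = ((0.5, 1.5, 1), (1.5, 2.5, 2)),
    zero_cutoff: float = 0.3,
) -> CopyNumberCall:
    """Relative copy number by the ddCt method.

    ddCt = (mean Ct_target - mean Ct_ref)_sample
         - (mean Ct_target - mean Ct_ref)_calibrator;
    estimate = 2 x 2^(-ddCt), so the estimate halves exactly per +1 cycle.
    Absent target amplification (any replicate None) calls 0 copies.
    Replicate spread beyond ``ct_tolerance`` yields an ambiguous call with a
    reason — the situation of a sample whose copy number could not be
    measured reliably.
    """
    if any(v is None for v in run.sample_target):
        return CopyNumberCall(estimate=0.0, call=0, reason="no target amplification")

    for name in ("sample_target", "sample_ref", "calibrator_target", "calibrator_ref"):
        vals = getattr(run, name)
        if max(vals) - min(vals) > ct_tolerance:
            return CopyNumberCall(
                estimate=None, call="ambiguous",
                reason=f"replicate spread {max(vals) - min(vals):.2f} > {ct_tolerance} in {name}",
            )

    d_sample = statistics.fmean(run.sample_target) - statistics.fmean(run.sample_ref)
    d_cal = statistics.fmean(run.calibrator_target) - statistics.fmean(run.calibrator_ref)
    ddct = d_sample - d_cal
    estimate = 2.0 * 2.0 ** (-ddct)

    if estimate < zero_cutoff:
        return CopyNumberCall(estimate=estimate, call=0)
    for lo, hi, copies in bands:
        if lo <= estimate < hi:
            return CopyNumberCall(estimate=estimate, call=copies)
    if estimate >= bands[-1][1]:
        return CopyNumberCall(estimate=estimate, call="amplified")
    return CopyNumberCall(estimate=estimate, call="ambiguous", reason="estimate between bands")


def read_qpcr_table(path) -> Dict[str, QPCRRun]:
    """Read a qPCR Ct table: columns sample, role (target|ref), well, ct,
    calibrator (0/1). Returns one QPCRRun per non-calibrator sample."""
    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = {"sample", "role", "ct", "calibrator"} - set(reader.fieldnames or [])
        if missing:
            raise LocusError(f"{path}: missing column(s): {', '.join(sorted(missing))}")
        rows = list(reader)

    def cts(sample, role, calibrator):
        out = []
        for r in rows:
            if r["sample"] == sample and r["role"] == role and (r["calibrator"] == "1") == calibrator:
                out.append(None if r["ct"] in ("", ".", "NA") else float(r["ct"]))
        return tuple(out)

    cal_samples = {r["sample"] for r in rows if r["calibrator"] == "1"}
    if not cal_samples:
        raise LocusError(f"{path}: no calibrator sample")
    cal = sorted(cal_samples)[0]
    runs = {}
    for sample in sorted({r["sample"] for r in rows} - cal_samples):
        runs[sample] = QPCRRun(
            sample_target=cts(sample, "target", False),
            sample_ref=cts(sample, "ref", False),
            calibrator_target=cts(cal, "target", True),
            calibrator_ref=cts(cal, "ref", True),
        )
    return runs
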