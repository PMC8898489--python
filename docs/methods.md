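# Methods

This note records the models, parameter choices, numerical conventions,
and known limitations of the `triotier` pipeline, in the order the data
flows through it.

## Inputs and conventions

Variant records are single-alt: multi-allelic rows are split before any
stage sees them. Coordinates are 1-based inclusive (HGVS g. convention);
the only half-open intervals are internal to pandas operations and never
serialized. Genotypes arrive unphased; phase is inferred exclusively from
parental origin. An absent database frequency is stored as missing, not
zero — "not observed" and "observed at 0" behave identically in the
frequency filter (neither excludes) but are distinct states of evidence.
PED files use 2 = affected, 1 = unaffected, 0/−9 = unknown; an optional
seventh column on the proband row names the presumed inheritance mode,
otherwise the mode defaults from parental phenotypes (one affected parent
→ AD, both → undetermined, none → sporadic). Duo families are permitted
and flagged; they can never yield a de novo call.

## Frequency filter

Thresholds (config-exposed in `FilterConfig`, serialized as YAML):

| parameter | default | applies to |
|---|---|---|
| `maf_ad` | 0.001 | every database, presumed-AD families |
| `maf_recessive_global` | 0.003 | 1000G-EAS, ESP6500, ExAC, gnomAD; sporadic/AR/undetermined |
| `maf_recessive_japanese` | 0.005 | HGVD, in-house; sporadic/AR/undetermined |

Sporadic families use the recessive thresholds for *all* their models,
including de novo — the strict 0.001 bar is reserved for pedigrees with
dominant transmission. Exclusion is any-database: one database at or above
its threshold removes the variant. dbSNP membership alone (an rs ID with
no frequency) never excludes. Comparisons are strict (`<` retains), so a
database frequency printed exactly at a threshold excludes; bundled
fixtures encode frequencies at full precision rather than printed
rounding where the two disagree.

## In-silico consensus and splice retention

The consensus applies to missense only: excluded iff all eight categorical
predictor calls are benign. A missing call counts as non-benign, because
unanimity cannot be asserted from seven opinions. In-frame indels bypass
the consensus (the predictors are missense tools); this is the
conservative reading of an unstated case and is noted here deliberately.
REVEL/CADD are carried but never filter — two bundled reference variants
(PDZD7 p.Arg168Pro, REVEL 0.123; PCNX2 p.Arg1169Trp, REVEL 0.139) would be
lost by a REVEL cutoff and illustrate why the unanimity rule is the
stringency backstop instead.

Canonical ±1/2 splice variants always survive. Splice-region variants
survive on a Human Splicing Finder "affected" verdict or a MaxEntScan
relative score drop ≥ 15% with a reference score ≥ 3 (both config-exposed;
the 15%/3 convention is the tool's documented default, adopted here
because no numeric threshold is published for the workflow itself). A
splice-region variant with no annotation at all is retained with a
warning: the cascade must not silently discard what it cannot assess.

## Segregation

Single-variant models, given trio genotypes and the family structure:

- **de novo** — proband het, both parents present in the pedigree,
  genotyped, and hom-ref. Requires confirmed biparental genotypes (PS2
  presumes parentage), hence never fires in duos.
- **hom_biallelic** — proband hom-alt and every *genotyped* parent carries
  at least one alternate allele.
- **ad_inherited** — proband het, exactly the affected parent het, the
  other genotyped parent non-carrier.

Mendelian-impossible vectors (hom-alt child of a hom-ref parent, etc.)
yield the empty label set plus a logged inconsistency — real call sets
contain genotyping errors and must not crash the run. Compound
heterozygotes are pairs of proband-het variants in one gene with opposite
exclusive parental origins; cis pairs are rejected, pairs with an
ungenotyped parent are emitted as unresolved/phase-unknown and never
become candidates. A sporadic proband with a single het allele in a
recessive gene and no second hit is likewise reported unresolved, never as
a candidate. The per-mode model schedule is: sporadic → de novo,
hom, compound het; AR → hom, compound het; AD → ad-inherited, de novo;
undetermined → all four. X-linked and mitochondrial models are out of
scope (the emulated workflow prescreens the mitochondrial variants).

**Discrepancy resolution.** If an affected parent carries its own
biallelic cause (operationally: a homozygous gene deletion from the CNV
screen) that the proband carries only heterozygously, the apparent
dominant transmission is spurious: the parent receives a member-level
causal record, the gene is set aside, and the proband is re-analyzed under
the remaining models. One family can therefore report two causes.

## ACMG engine

Implemented criteria: PVS1, PS1, PS2, PM1, PM2_Supporting, PM3, PM5, PP1,
PP3, PP4, PP5. Benign-side criteria are not implemented; the cascade
removes their targets before interpretation. Operationalizations where the
guideline leaves room:

- **PM2_Supporting** — absent from every database, or every present global
  MAF < 1e−3 and every present Japanese MAF < 5e−3 (`PM2Config`). This is
  the strictest rarity bar the cascade itself applies; a tighter literal
  cutoff (e.g. 1e−4) would contradict reported assignments for variants
  with HGVD frequencies of 0.002–0.003 that nonetheless carry
  PM2_Supporting. A whole-gene deletion allele has no SNV frequency
  panel, so PM2 is not assessable for it and is omitted.
- **PVS1** — truncating or canonical-splice consequence in a gene with an
  established LoF mechanism. An NMD-escaping truncation (50-nt rule: stop
  in the last exon or ≤ 50 coding nt upstream of the final junction, with
  the boundary counted as escaping) loses PVS1 unless the registry marks
  truncation escape as itself pathogenic for that gene (*SOX10*, where
  escaping alleles cause the severe PCWH presentation).
- **PP3** — at least half of the *present* predictor calls damaging
  (config-exposed fraction); the guideline never quantifies PP3.
- **PS1/PM5/PM1/PP5** — driven by the known-variant lookup table
  (the OMIM/HGMD/ClinVar stand-in): same-residue matches, hotspot
  annotations and report-only pathogenicity are curated evidence, not
  inferences.
- **PM3** — fires for an allele in trans with a partner reported
  pathogenic/likely pathogenic in the lookup table (not with a partner the
  engine itself just classified — no bootstrapped circularity).

Combining follows the standard rule matrix with PM2_Supporting counted at
supporting strength and PVS1 + ≥ 1 supporting → likely pathogenic (SVI).
The function is pure and monotone on the pathogenic partial order
(property-tested).

A homozygous whole-gene deletion feeds prioritization as a PVS1-bearing
null allele. PVS1 alone combines to VUS under the strict matrix; cohort
summaries therefore count "resolved Tier-1 families" by top-ranked Tier-1
candidate rather than by P/LP classification, which matches how such
cohorts report *STRC* deletions and VUS-level compound hets among their
solved families. The stricter `solved_tier1` status still requires P/LP.

## Tier prioritization

Registry lookup with Tier 1 > 2 > 3 precedence on duplicate symbols;
unknown symbols are Tier 4 with *no* presumed LoF mechanism (PVS1 needs an
established mechanism, which an unstudied gene cannot have). Syndromic
genes are excluded for a proband iff the variant is unreported (not P/LP
in the lookup) *and* the proband lacks the gene's characteristic
multi-organ features — both clauses must hold to drop. Candidates rank by
(tier ascending, classification descending, model specificity, gene name);
the final key makes the order a deterministic total preorder, and ties are
listed, never silently broken. Whether a Tier-2 survivor should ever
outrank a Tier-3 one of better classification is genuinely open; tier
ascending is this package's choice and is visible in the ranked output.

## CNV locus screen

Depth calls: runs of ≥ `min_run` = 2 consecutive informative exons below
`depth_fraction` = 0.10 × sample median. Both knobs are this package's
quantification of what the original workflow did by visual IGV
inspection, and both are config-exposed. Multimapped exons are transparent
in both directions: they contribute no evidence and do not interrupt runs.
An all-multimapped locus raises an "uninformative" signal rather than
returning a negative call. The screen is locus-generic — the same code
runs on an *OTOA* fixture and returns nothing. Whether *STRC* exons 17–18
are informative is not reported; the fixture marks them multimapped, which
is the conservative choice (they cannot rescue or break a call either
way). MLPA ratio class bands (< 0.2 → 0 copies; 0.4–0.65 → 1; 0.8–1.2 →
2; otherwise flagged) are this package's, chosen at the conventional MLPA
analysis bands. qPCR copy number is 2 × 2^(−ΔΔCt) with duplicate wells; a
replicate spread above 0.5 cycles yields an ambiguous call with a reason
(the unmeasurable-sample case), and absent target amplification is copy
number 0.

## Synthetic cohort generator

The generator emulates the study conditions: 60-family cohorts at the
published mode mix (52:9:10:1 over sporadic/AD/AR/undetermined), 80
background variants per trio, database frequencies 60% absent (true
population frequency log-uniform on [1e−6, 1e−4] — absent from gnomAD
implies rare) and otherwise log-uniform on [1e−6, 5e−2], spanning both
sides of every threshold; per-predictor benign probability 0.9 for
background missense; 5% of background variants truncating; log-normal
depth noise (σ = 0.3); Gaussian Ct noise (sd 0.1). Background trio
genotypes are drawn parent-first and transmitted, so they are Mendelian-
consistent by construction and can never fake a de novo event — the zero
false-solved guarantee on control cohorts is therefore partly structural
(background de novo artifacts are impossible; background truncating
alleles in Tier-1 genes are possible but vanishingly rare under the
frequency model), and passing it says nothing about pipelines fed
genotyping errors. Planted scenarios construct their variants to survive
filtering (the generator self-checks this invariant on every draw) and
cover all six configurations including the full parent/proband discrepancy
structure. The generator does not model linkage disequilibrium, population
structure, region-level artifacts, or read-level noise; recovery rates on
it are upper bounds for real data.

Problem sizes used by the test suite — 60 families × seeds 1–10 for
recovery/specificity, 100 seeds for depth-screen specificity, 200 seeds
for qPCR call accuracy — are the smallest sizes at which the binomial
bounds asserted by the tests are meaningful.

## Reference cohort fixture

`reference_cohort.py` encodes the published tables of the emulated study:
72 families (215 individuals, one duo), the 23 point variants with their
printed frequencies, the STRC/CATSPER2 depth/MLPA/qPCR fixture, tier lists
padded with synthetic symbols to the published 293/328/305 sizes, and a
curated known-variant lookup. Everything the study did not print —
per-predictor calls, cosegregation flags, hotspot annotations, transcript
exon structures (collapsed so only the final-junction CDS coordinate is
meaningful), background-family variants, and two family identifiers — is
synthetic and marked as such in the module. One printed frequency (EYA1
c.1082G>A, 1000G "0.0010") is encoded at 1/1008 EAS alleles (0.000992),
since the printed rounding would contradict the strict < 0.001 dominant
threshold the variant demonstrably survived.

## Limitations

Read mapping, variant calling and annotation are upstream and out of
scope, as are repeat-region/strand-bias prefilters, X-linked and
mitochondrial inheritance, statistical phasing, genome-wide CNV calling,
and base-pair breakpoint resolution. HGVS strings are pattern-parsed for
consequence class, not validated against reference sequence.
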