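"""ACMG criterion assignment and combining rules."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triotier.acmg import (
    Criterion,
    EvidenceContext,
    PM2Config,
    assign_criteria,
    combine,
    format_criteria,
    parse_criteria,
    pm2_supporting,
    pp3_insilico_support,
)
from triotier.model import (
    AnnotatedVariant,
    Classification,
    Consequence,
    FrequencyPanel,
    GeneRecord,
    PredictorCall,
    PredictorPanel,
)
from triotier.segregation import Model

C = Criterion


# --------------------------------------------------------------------------
# combining


#: Hand-encoded rule-matrix expectations (independent of the implementation).
COMBINE_CASES = [
    ({C.PVS1, C.PS2, C.PM2_SUPPORTING, C.PP4}, Classification.PATHOGENIC),
    ({C.PVS1, C.PS1}, Classification.PATHOGENIC),
    ({C.PVS1, C.PM3, C.PM5}, Classification.PATHOGENIC),
    ({C.PVS1, C.PM2_SUPPORTING, C.PP1}, Classification.PATHOGENIC),  # PVS1 + >=2 supporting
    ({C.PS1, C.PS2}, Classification.PATHOGENIC),
    ({C.PS1, C.PM1, C.PM3, C.PM5}, Classification.PATHOGENIC),
    ({C.PVS1, C.PM2_SUPPORTING}, Classification.LIKELY_PATHOGENIC),  # SVI adjustment
    ({C.PVS1, C.PM3}, Classification.LIKELY_PATHOGENIC),
    ({C.PS1, C.PM2_SUPPORTING, C.PM5}, Classification.LIKELY_PATHOGENIC),
    ({C.PS1, C.PP1, C.PP3}, Classification.LIKELY_PATHOGENIC),
    ({C.PM1, C.PM3, C.PM5}, Classification.LIKELY_PATHOGENIC),
    ({C.PM2_SUPPORTING}, Classification.VUS),
    ({C.PM2_SUPPORTING, C.PM3}, Classification.VUS),
    ({C.PM1, C.PM2_SUPPORTING, C.PP1}, Classification.VUS),
    ({C.PM2_SUPPORTING, C.PP1, C.PP3}, Classification.VUS),
    (set(), Classification.VUS),
]


@pytest.mark.parametrize("criteria,expected", COMBINE_CASES,
                         ids=lambda x: format_criteria(x) if isinstance(x, set) else x.value)
def test_combine_rule_matrix(criteria, expected):
    assert combine(criteria) is expected


def test_combine_is_pure():
    cs = {C.PVS1, C.PM2_SUPPORTING}
    assert combine(cs) is combine(frozenset(cs))


_RANK = {Classification.VUS: 0, Classification.LIKELY_PATHOGENIC: 1,
         Classification.PATHOGENIC: 2}


@given(
    base=st.sets(st.sampled_from(list(Criterion))),
    extra=st.sampled_from(list(Criterion)),
)
@settings(max_examples=300, deadline=None)
def test_combine_monotone_on_pathogenic_evidence(base, extra):
    """Adding a pathogenic-side criterion never lowers the classification."""
    assert _RANK[combine(base | {extra})] >= _RANK[combine(base)]


def test_criteria_serialization_roundtrip():
    cs = frozenset({C.PVS1, C.PS2, C.PM2_SUPPORTING, C.PP4})
    text = format_criteria(cs)
    assert text == "PVS1, PS2, PM2_Supporting, PP4"
    assert parse_criteria(text) == cs


# --------------------------------------------------------------------------
# PM2_Supporting / PP3 operationalizations


def test_pm2_absent_everywhere():
    assert pm2_supporting(FrequencyPanel({}))


def test_pm2_cutoffs_split_global_and_japanese():
    assert pm2_supporting(FrequencyPanel({"gnomAD": 5e-4, "HGVD": 0.003}))
    assert not pm2_supporting(FrequencyPanel({"gnomAD": 2e-3}))
    assert not pm2_supporting(FrequencyPanel({"HGVD": 6e-3}))
    tight = PM2Config(global_cutoff=1e-4, japanese_cutoff=1e-4)
    assert not pm2_supporting(FrequencyPanel({"gnomAD": 5e-4}), tight)


def test_pm2_not_assessable_without_frequency_panel():
    """A structural deletion allele carries no SNV panel: PM2 is unknown."""
    assert not pm2_supporting(None)


def test_pp3_half_of_present_calls():
    half = PredictorPanel({p: "damaging" for p in ("LRT", "LR", "SIFT", "RadialSVM")})
    assert pp3_insilico_support(half)  # 4 damaging of 4 present
    mixed = PredictorPanel({"LRT": "damaging", "LR": "benign", "SIFT": "benign"})
    assert not pp3_insilico_support(mixed)  # 1 of 3
    assert not pp3_insilico_support(PredictorPanel({}))


# --------------------------------------------------------------------------
# criterion assignment


def _variant(consequence, gene="MYO15A"):
    return AnnotatedVariant(
        chrom="17", pos=100, ref="C", alt="T", gene=gene,
        hgvs_c="c.100C>T", hgvs_p="p.(Gln34Ter)", consequence=consequence,
    )


LOF_GENE = GeneRecord("MYO15A", 1, lof_mechanism=True)
ESCAPE_GENE = GeneRecord("SOX10", 1, lof_mechanism=True, truncation_escape_pathogenic=True)
NON_LOF = GeneRecord("PTPN11", 1, lof_mechanism=False)


def test_pvs1_requires_lof_mechanism():
    v = _variant(Consequence.NONSENSE)
    assert C.PVS1 in assign_criteria(v, EvidenceContext(gene=LOF_GENE))
    assert C.PVS1 not in assign_criteria(v, EvidenceContext(gene=NON_LOF))
    assert C.PVS1 not in assign_criteria(
        _variant(Consequence.MISSENSE), EvidenceContext(gene=LOF_GENE))


def test_pvs1_nmd_escape_gating():
    v = _variant(Consequence.FRAMESHIFT)
    escaped = EvidenceContext(gene=LOF_GENE, nmd_escape=True)
    assert C.PVS1 not in assign_criteria(v, escaped)
    # genes where escape itself is pathogenic keep PVS1
    kept = EvidenceContext(gene=ESCAPE_GENE, nmd_escape=True)
    assert C.PVS1 in assign_criteria(v, kept)
    # canonical splice variants are not gated on NMD
    splice = _variant(Consequence.SPLICE_CANONICAL)
    assert C.PVS1 in assign_criteria(splice, EvidenceContext(gene=LOF_GENE, nmd_escape=True))


def test_ps2_requires_de_novo_call():
    v = _variant(Consequence.MISSENSE)
    assert C.PS2 in assign_criteria(v, EvidenceContext(gene=LOF_GENE, segregation=Model.DE_NOVO))
    assert C.PS2 not in assign_criteria(
        v, EvidenceContext(gene=LOF_GENE, segregation=Model.COMPOUND_HET))


def test_all_unknown_context_yields_pm2_only_and_never_errors():
    v = _variant(Consequence.MISSENSE)
    v2 = AnnotatedVariant(chrom="17", pos=100, ref="C", alt="T", gene="MYO15A",
                          hgvs_c="c.100C>T", hgvs_p="p.(Gln34Arg)",
                          consequence=Consequence.MISSENSE,
                          freqs=FrequencyPanel({}))
    got = assign_criteria(v2, EvidenceContext(gene=LOF_GENE))
    assert got == {C.PM2_SUPPORTING}
    common = AnnotatedVariant(chrom="17", pos=100, ref="C", alt="T", gene="MYO15A",
                              hgvs_c="c.100C>T", hgvs_p="p.(Gln34Arg)",
                              consequence=Consequence.MISSENSE,
                              freqs=FrequencyPanel({"gnomAD": 0.01}))
    assert assign_criteria(common, EvidenceContext(gene=NON_LOF)) == frozenset()


def test_known_database_driven_criteria():
    v = _variant(Consequence.MISSENSE)
    ctx = EvidenceContext(
        gene=NON_LOF, segregation=Model.DE_NOVO,
        known_same_aa_plp=True, known_other_aa_same_residue_plp=True,
        known_hotspot=True, known_pp5=True, in_trans_with_plp=True,
        cosegregation=True, phenotype_match=True,
        predictors=PredictorPanel.uniform(PredictorCall.DAMAGING),
    )
    got = assign_criteria(v, ctx)
    assert got >= {C.PS1, C.PS2, C.PM1, C.PM3, C.PM5, C.PP1, C.PP3, C.PP4, C.PP5}


def test_null_allele_criteria():
    from triotier.pipeline import null_allele_criteria

    assert null_allele_criteria(LOF_GENE) == {C.PVS1}
    assert null_allele_criteria(NON_LOF) == frozenset()
    assert combine(null_allele_criteria(LOF_GENE)) is Classification.VUS
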