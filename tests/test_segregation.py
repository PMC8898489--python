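"""Trio segregation logic against exhaustive independent oracles."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triotier.model import (
    AnnotatedVariant,
    Consequence,
    Family,
    Genotype,
    InheritanceMode,
    Member,
    TrioGenotypes,
)
from triotier.segregation import (
    Model,
    Origin,
    classify_single,
    find_compound_het,
    is_mendelian_error,
    models_for_family,
    needs_reanalysis,
    variant_origin,
)

GT3 = (Genotype.HOM_REF, Genotype.HET, Genotype.HOM_ALT)


def _family(mode, father_affected=False, mother_affected=False, duo=False):
    return Family(
        family_id="T",
        proband=Member("P", affected=True),
        father=None if duo else Member("F", affected=father_affected, sex="M"),
        mother=Member("M", affected=mother_affected, sex="F"),
        mode=mode,
    )


def _oracle_labels(p, f, m, family):
    """Independent restatement of the single-variant segregation rules."""
    labels = set()
    # Mendelian errors first
    if p is Genotype.HOM_ALT and Genotype.HOM_REF in (f, m):
        return labels
    if p is Genotype.HOM_REF and Genotype.HOM_ALT in (f, m):
        return labels
    if p is Genotype.HET and f is Genotype.HOM_ALT and m is Genotype.HOM_ALT:
        return labels
    if (p is Genotype.HET and f is Genotype.HOM_REF and m is Genotype.HOM_REF
            and family.father is not None and family.mother is not None):
        labels.add(Model.DE_NOVO)
    if p is Genotype.HOM_ALT and all(
        gt in (Genotype.HET, Genotype.HOM_ALT, Genotype.MISSING) for gt in (f, m)
    ):
        labels.add(Model.HOM_BIALLELIC)
    affected = [x for x in (family.father, family.mother) if x is not None and x.affected]
    if p is Genotype.HET and len(affected) == 1:
        aff_is_father = family.father is not None and affected[0] is family.father
        carrier, other = (f, m) if aff_is_father else (m, f)
        if carrier is Genotype.HET and other in (Genotype.HOM_REF, Genotype.MISSING):
            labels.add(Model.AD_INHERITED)
    return labels


FAMILIES = [
    _family(InheritanceMode.SPORADIC),
    _family(InheritanceMode.AD, father_affected=True),
    _family(InheritanceMode.AD, mother_affected=True),
    _family(InheritanceMode.AR),
    _family(InheritanceMode.UNDETERMINED, father_affected=True, mother_affected=True),
]


@pytest.mark.parametrize("family", FAMILIES, ids=lambda f: f"{f.mode.value}")
def test_classify_single_matches_27_case_oracle(family):
    """All 27 fully-genotyped trio combinations for every family structure."""
    for p, f, m in itertools.product(GT3, repeat=3):
        got = classify_single(TrioGenotypes(p, f, m), family)
        assert got == _oracle_labels(p, f, m, family), (p, f, m, family.mode)


def test_classify_single_with_missing_parents():
    fam = _family(InheritanceMode.SPORADIC)
    # a missing parent blocks de novo but not hom_biallelic
    assert classify_single(
        TrioGenotypes(Genotype.HET, Genotype.MISSING, Genotype.HOM_REF), fam) == set()
    assert classify_single(
        TrioGenotypes(Genotype.HOM_ALT, Genotype.MISSING, Genotype.HET), fam
    ) == {Model.HOM_BIALLELIC}


def test_duo_family_never_yields_de_novo():
    duo = _family(InheritanceMode.SPORADIC, duo=True)
    got = classify_single(
        TrioGenotypes(Genotype.HET, Genotype.MISSING, Genotype.HOM_REF), duo)
    assert Model.DE_NOVO not in got


def test_de_novo_and_ad_inherited_mutually_exclusive():
    """de novo needs both parents hom-ref; dominant inheritance needs the
    affected parent het — no genotype vector satisfies both."""
    for family in FAMILIES:
        for p, f, m in itertools.product(GT3, repeat=3):
            got = classify_single(TrioGenotypes(p, f, m), family)
            assert not {Model.DE_NOVO, Model.AD_INHERITED} <= got


def test_mendelian_error_yields_empty_set_not_exception():
    fam = _family(InheritanceMode.AR)
    tg = TrioGenotypes(Genotype.HOM_ALT, Genotype.HOM_REF, Genotype.HET)
    assert is_mendelian_error(tg)
    assert classify_single(tg, fam) == set()


# --------------------------------------------------------------------------
# compound heterozygotes


def _var(i, gene="OTOG"):
    return AnnotatedVariant(
        chrom="11", pos=1000 + i * 10, ref="C", alt="T", gene=gene,
        hgvs_c=f"c.{100 + i}C>T", hgvs_p="p.(Gln34Ter)",
        consequence=Consequence.NONSENSE,
    )


def _pair(origins):
    gts = {
        "P": TrioGenotypes(Genotype.HET, Genotype.HET, Genotype.HOM_REF),
        "M": TrioGenotypes(Genotype.HET, Genotype.HOM_REF, Genotype.HET),
        "D": TrioGenotypes(Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF),
        "U": TrioGenotypes(Genotype.HET, Genotype.MISSING, Genotype.HET),
        "A": TrioGenotypes(Genotype.HET, Genotype.HET, Genotype.HET),
    }
    return [(_var(i), gts[o]) for i, o in enumerate(origins)]


def test_trans_pair_called():
    """One paternal and one maternal het allele make a compound het."""
    calls = find_compound_het(_pair("MP"))
    assert len(calls) == 1
    assert calls[0].model is Model.COMPOUND_HET
    assert sorted(o.value for o in calls[0].origins.values()) == ["maternal", "paternal"]


def test_cis_pair_rejected():
    assert find_compound_het(_pair("PP")) == []
    assert find_compound_het(_pair("MM")) == []


def test_three_variants_fmm_yield_two_trans_pairs():
    calls = [c for c in find_compound_het(_pair("PMM")) if c.model is Model.COMPOUND_HET]
    assert len(calls) == 2


def test_missing_parent_pair_is_phase_unknown():
    calls = find_compound_het(_pair("UM"))
    assert len(calls) == 1
    assert calls[0].model is Model.UNRESOLVED
    assert calls[0].phase_unknown and not calls[0].both_parents_genotyped


def test_ambiguous_origin_never_called():
    assert find_compound_het(_pair("AP")) == []


def _oracle_pairs(origins):
    """Brute-force pair enumeration over origin strings."""
    n = 0
    for a, b in itertools.combinations(origins, 2):
        if {a, b} == {"P", "M"}:
            n += 1
    return n


@given(st.lists(st.sampled_from("PMDA"), min_size=2, max_size=4),
       st.randoms(use_true_random=False))
@settings(max_examples=200, deadline=None)
def test_compound_het_matches_pair_oracle_and_is_order_invariant(origins, rnd):
    items = _pair("".join(origins))
    shuffled = list(items)
    rnd.shuffle(shuffled)
    calls = [c for c in find_compound_het(items) if c.model is Model.COMPOUND_HET]
    calls_shuffled = [c for c in find_compound_het(shuffled) if c.model is Model.COMPOUND_HET]
    assert len(calls) == _oracle_pairs(origins)
    key = lambda c: tuple(sorted(v.hgvs_c for v in c.variants))
    assert sorted(map(key, calls)) == sorted(map(key, calls_shuffled))


def test_variant_origin_classes():
    assert variant_origin(TrioGenotypes(Genotype.HET, Genotype.HET, Genotype.HOM_REF)) is Origin.PATERNAL
    assert variant_origin(TrioGenotypes(Genotype.HET, Genotype.HOM_REF, Genotype.HET)) is Origin.MATERNAL
    assert variant_origin(TrioGenotypes(Genotype.HET, Genotype.HET, Genotype.HET)) is Origin.AMBIGUOUS
    assert variant_origin(TrioGenotypes(Genotype.HET, Genotype.HOM_REF, Genotype.HOM_REF)) is Origin.DE_NOVO
    assert variant_origin(TrioGenotypes(Genotype.HET, Genotype.MISSING, Genotype.HET)) is Origin.UNKNOWN


# --------------------------------------------------------------------------
# model schedules and discrepancy trigger


def test_models_for_family_schedule():
    assert models_for_family(_family(InheritanceMode.SPORADIC)) == [
        Model.DE_NOVO, Model.HOM_BIALLELIC, Model.COMPOUND_HET]
    assert models_for_family(_family(InheritanceMode.AR)) == [
        Model.HOM_BIALLELIC, Model.COMPOUND_HET]
    assert models_for_family(_family(InheritanceMode.AD, father_affected=True)) == [
        Model.AD_INHERITED, Model.DE_NOVO]
    assert len(models_for_family(
        _family(InheritanceMode.UNDETERMINED, father_affected=True,
                mother_affected=True))) == 4


def test_needs_reanalysis_trigger():
    fam = _family(InheritanceMode.AD, mother_affected=True)
    assert needs_reanalysis(fam, "STRC", proband_carries_biallelic=False)
    assert not needs_reanalysis(fam, "STRC", proband_carries_biallelic=True)
    assert not needs_reanalysis(fam, None, proband_carries_biallelic=False)
    sporadic = _family(InheritanceMode.SPORADIC)
    assert not needs_reanalysis(sporadic, "STRC", proband_carries_biallelic=False)
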