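"""Filtering cascade: MAF thresholds by inheritance mode, the eight-predictor
consensus against a full truth-table oracle, and splice retention."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triotier.filtering import (
    FilterConfig,
    FilterAudit,
    filter_variants,
    insilico_consensus,
    maf_filter,
    retained,
    splice_retained,
)
from triotier.model import (
    ALL_DBS,
    GLOBAL_DBS,
    JAPANESE_DBS,
    AnnotatedVariant,
    Consequence,
    ContractError,
    FrequencyPanel,
    HSFVerdict,
    InheritanceMode,
    PredictorCall,
    PredictorPanel,
    PREDICTORS,
    SpliceAnnotation,
    TrioGenotypes,
)
from triotier.reference_cohort import build_bundle


def _missense(freqs=None, panel=None):
    return AnnotatedVariant(
        chrom="1", pos=100, ref="A", alt="G", gene="TMC1",
        hgvs_c="c.100A>G", hgvs_p="p.(Lys34Glu)", consequence=Consequence.MISSENSE,
        freqs=freqs or FrequencyPanel({}), predictors=panel or PredictorPanel({}),
    )


# --------------------------------------------------------------------------
# MAF filter


def _oracle_maf(present, mode):
    """Independent restatement of the frequency rule."""
    if mode is InheritanceMode.AD:
        return all(f < 0.001 for f in present.values())
    for db, f in present.items():
        if db in JAPANESE_DBS and f >= 0.005:
            return False
        if db in GLOBAL_DBS and f >= 0.003:
            return False
    return True


GRID = [None, 0.0, 5e-4, 2e-3, 4e-3, 6e-3]


@pytest.mark.parametrize("mode", list(InheritanceMode))
def test_maf_filter_matches_grid_oracle(mode):
    """Exhaustive one-database grid plus mixed two-database combinations."""
    for db in ALL_DBS:
        for val in GRID:
            freqs = FrequencyPanel({} if val is None else {db: val})
            assert maf_filter(_missense(freqs), mode) == _oracle_maf(freqs.present(), mode)
    for db1, db2 in itertools.combinations(ALL_DBS, 2):
        for v1, v2 in itertools.product(GRID, repeat=2):
            vals = {k: v for k, v in ((db1, v1), (db2, v2)) if v is not None}
            freqs = FrequencyPanel(vals)
            assert maf_filter(_missense(freqs), mode) == _oracle_maf(vals, mode)


def test_maf_filter_reported_otof_variant_retained_sporadic():
    freqs = FrequencyPanel({"ExAC": 2.54e-5, "gnomAD": 3.38e-5, "HGVD": 0.002})
    assert maf_filter(_missense(freqs), InheritanceMode.SPORADIC)


def test_maf_absent_everywhere_retained_in_any_mode():
    for mode in InheritanceMode:
        assert maf_filter(_missense(FrequencyPanel({})), mode)


def test_maf_mode_asymmetry():
    freqs = FrequencyPanel({"gnomAD": 0.002})
    assert not maf_filter(_missense(freqs), InheritanceMode.AD)
    assert maf_filter(_missense(freqs), InheritanceMode.AR)


def test_ad_retained_subset_of_ar_retained():
    """0.001 < 0.003 <= 0.005: anything surviving the AD filter survives AR."""
    for db in ALL_DBS:
        for val in GRID:
            freqs = FrequencyPanel({} if val is None else {db: val})
            v = _missense(freqs)
            if maf_filter(v, InheritanceMode.AD):
                assert maf_filter(v, InheritanceMode.AR)


@given(
    vals=st.dictionaries(st.sampled_from(ALL_DBS),
                         st.floats(0, 0.05, allow_nan=False), max_size=6),
    scale=st.floats(0.1, 1.0),
)
@settings(max_examples=200, deadline=None)
def test_maf_monotone_in_thresholds(vals, scale):
    """Tightening every threshold never grows the retained set."""
    v = _missense(FrequencyPanel(vals))
    loose = FilterConfig()
    tight = FilterConfig(
        maf_ad=loose.maf_ad * scale,
        maf_recessive_global=loose.maf_recessive_global * scale,
        maf_recessive_japanese=loose.maf_recessive_japanese * scale,
    )
    for mode in InheritanceMode:
        if maf_filter(v, mode, tight):
            assert maf_filter(v, mode, loose)


def test_config_validation():
    with pytest.raises(ContractError):
        FilterConfig(maf_ad=0.01, maf_recessive_global=0.003)
    with pytest.raises(ContractError):
        FilterConfig(maf_ad=0.0)
    cfg = FilterConfig()
    assert FilterConfig.from_yaml(cfg.to_yaml()) == cfg


# --------------------------------------------------------------------------
# in-silico consensus


def test_consensus_equals_truth_table_oracle_over_all_panels():
    """All 3^8 = 6561 call vectors against the rule 'excluded iff every
    call is benign'."""
    calls = (PredictorCall.DAMAGING, PredictorCall.BENIGN, PredictorCall.MISSING)
    for combo in itertools.product(calls, repeat=8):
        panel = PredictorPanel(dict(zip(PREDICTORS, combo)))
        expected = not all(c is PredictorCall.BENIGN for c in combo)
        assert insilico_consensus(panel, Consequence.MISSENSE) == expected


def test_consensus_missing_call_breaks_unanimity():
    calls = {p: PredictorCall.BENIGN for p in PREDICTORS[:-1]}
    assert insilico_consensus(PredictorPanel(calls), Consequence.MISSENSE)


def test_consensus_bypasses_non_missense():
    all_benign = PredictorPanel.uniform(PredictorCall.BENIGN)
    assert not insilico_consensus(all_benign, Consequence.MISSENSE)
    assert insilico_consensus(all_benign, Consequence.FRAMESHIFT)
    assert insilico_consensus(all_benign, Consequence.INFRAME_INDEL)


# --------------------------------------------------------------------------
# splice retention


def test_splice_canonical_always_retained():
    assert splice_retained(None, Consequence.SPLICE_CANONICAL)


@pytest.mark.parametrize(
    "ref,alt,verdict,expected",
    [
        (8.59, 0.41, HSFVerdict.AFFECTED, True),     # large drop + HSF affected
        (10.90, -9.39, HSFVerdict.AFFECTED, True),   # score collapses below zero
        (9.0, 8.9, HSFVerdict.NOT_AFFECTED, False),  # negligible drop
        (9.0, 5.0, HSFVerdict.NOT_AFFECTED, True),   # >= 15% drop alone suffices
        (1.0, 0.1, HSFVerdict.NOT_AFFECTED, False),  # reference score too low
    ],
)
def test_splice_region_rules(ref, alt, verdict, expected):
    s = SpliceAnnotation(ref, alt, verdict)
    assert splice_retained(s, Consequence.SPLICE_REGION) == expected


def test_splice_region_missing_annotation_is_conservative():
    assert splice_retained(None, Consequence.SPLICE_REGION)


def test_splice_requires_splice_consequence():
    with pytest.raises(ContractError):
        splice_retained(None, Consequence.MISSENSE)


# --------------------------------------------------------------------------
# full cascade


def test_all_reported_variants_survive_their_family_filters(bundle):
    """Every curated variant survived the study's own cascade by
    construction; the reimplementation must agree."""
    fams = {f.family_id: f for f in bundle.families}
    for fid, recs in bundle.records.items():
        if fid.startswith("B"):
            continue
        audits = filter_variants(recs, fams[fid])
        assert all(a.retained for a in audits), (fid, [a.failed_rule for a in audits])


def test_background_families_are_fully_filtered(bundle):
    fams = {f.family_id: f for f in bundle.families}
    for fid, recs in bundle.records.items():
        if not fid.startswith("B"):
            continue
        audits = filter_variants(recs, fams[fid])
        assert not any(a.retained for a in audits)
        assert {a.failed_rule for a in audits} == {
            "maf", "insilico_consensus", "not_protein_altering"}


def test_empty_record_list_yields_empty_output(bundle):
    fam = bundle.families[0]
    assert filter_variants([], fam) == []


def test_cascade_deterministic_on_synthetic_cohort():
    from triotier.simulate import SimConfig, generate_cohort

    fractions = []
    for _ in range(2):
        b, _truths = generate_cohort(
            SimConfig(seed=1, scenarios=["control"] * 60))
        fams = {f.family_id: f for f in b.families}
        kept = total = 0
        for fid, recs in b.records.items():
            audits = filter_variants(recs, fams[fid])
            kept += sum(a.retained for a in audits)
            total += len(audits)
        fractions.append(kept / total)
    assert fractions[0] == fractions[1]
    assert fractions[0] < 0.5  # background is mostly filtered away
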