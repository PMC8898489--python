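"""Pseudogene-aware depth screen, MLPA breakpoint bounding, ddCt qPCR."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from triotier.cnv import (
    CopyNumberCall,
    DeletionCall,
    DepthProfile,
    ExonDepth,
    LocusError,
    MLPAProbeSet,
    Probe,
    QPCRRun,
    UnboundedDeletion,
    UninformativeLocus,
    breakpoint_interval,
    call_homozygous_deletion,
    mlpa_interpret,
    qpcr_copy_number,
    read_depth_table,
    read_mlpa_table,
    read_qpcr_table,
    write_depth_table,
)
from triotier.reference_cohort import (
    MLPA_DELETED_PROBES,
    STRC_DELETED_UNIQUE,
    STRC_MULTIMAP,
    make_mlpa_probeset,
    make_otoa_profiles,
    make_qpcr_runs,
    make_strc_profiles,
)


def _profile(depths, multimap=(), median=100.0, gene="STRC"):
    exons = [
        ExonDepth(gene, gene, i + 1, "15", 1000 + i * 400, 1000 + i * 400 + 199,
                  d, (i + 1) in multimap)
        for i, d in enumerate(depths)
    ]
    return DepthProfile("S", exons, median)


# --------------------------------------------------------------------------
# depth screen


def test_strc_fixture_called_as_single_run_spanning_exons_16_to_26():
    """Unique exons 16 and 19-26 are near zero; multimap exons 17-18 are
    transparent and do not break the run."""
    profiles = make_strc_profiles()
    calls = call_homozygous_deletion(profiles["1410-P"])
    assert len(calls) == 1
    call = calls[0]
    assert (call.first_exon, call.last_exon) == (16, 26)
    assert set(call.exons) == STRC_DELETED_UNIQUE
    assert call.mean_depth_fraction < 0.05


def test_control_and_heterozygous_profiles_yield_no_calls():
    profiles = make_strc_profiles()
    assert call_homozygous_deletion(profiles["1470-P"]) == []
    # family 1633 proband: one deleted allele, ~half depth, not homozygous
    assert call_homozygous_deletion(profiles["1633/II-1"]) == []


def test_uniform_depth_profile_yields_no_calls():
    assert call_homozygous_deletion(_profile([100.0] * 10)) == []


def test_otoa_locus_generic_screen_is_negative():
    for dp in make_otoa_profiles().values():
        assert call_homozygous_deletion(dp) == []


def test_min_run_suppresses_single_exon_dropouts():
    depths = [100.0] * 10
    depths[4] = 1.0
    assert call_homozygous_deletion(_profile(depths), min_run=2) == []
    assert len(call_homozygous_deletion(_profile(depths), min_run=1)) == 1


@given(scale=st.floats(0.1, 30.0, allow_nan=False))
@settings(max_examples=50, deadline=None)
def test_scale_invariance(scale):
    base = make_strc_profiles()["1410-P"]
    scaled = DepthProfile(
        base.sample_id,
        [ExonDepth(e.locus, e.gene, e.exon_index, e.chrom, e.start, e.end,
                   e.depth * scale, e.multimap) for e in base.exons],
        base.sample_median_depth * scale,
    )
    a = call_homozygous_deletion(base)
    b = call_homozygous_deletion(scaled)
    assert [(c.gene, c.exons) for c in a] == [(c.gene, c.exons) for c in b]


@given(positions=st.sets(st.integers(0, 9), max_size=5))
@settings(max_examples=50, deadline=None)
def test_multimap_insertion_invariance(positions):
    """Marking any additional normal-depth exons multimapped (inserting
    uninformative exons anywhere) never changes the informative call."""
    depths = [100.0] * 4 + [1.0, 1.0, 1.0] + [100.0] * 3
    base = call_homozygous_deletion(_profile(depths))
    noisy = call_homozygous_deletion(
        _profile(depths, multimap={p + 1 for p in positions if not 4 <= p <= 6}))
    assert [c.exons for c in base] == [c.exons for c in noisy]


def test_all_multimap_is_uninformative_not_negative():
    with pytest.raises(UninformativeLocus):
        call_homozygous_deletion(_profile([100.0] * 5, multimap={1, 2, 3, 4, 5}))


def test_depth_table_roundtrip(tmp_path):
    profiles = make_strc_profiles()
    path = tmp_path / "depth.tsv"
    write_depth_table(list(profiles.values()), path)
    back = read_depth_table(path)
    assert set(back) == set(profiles)
    for sid in profiles:
        assert [e.depth for e in back[sid].exons] == [e.depth for e in profiles[sid].exons]
        assert [e.multimap for e in back[sid].exons] == [e.multimap for e in profiles[sid].exons]


# --------------------------------------------------------------------------
# MLPA breakpoints


def test_breakpoint_interval_reported_probe_coordinates():
    inner, outer = breakpoint_interval(make_mlpa_probeset(), MLPA_DELETED_PROBES)
    assert (inner, outer) == (50.5, 187.6)


def test_single_deleted_probe_has_zero_inner_span():
    probes = MLPAProbeSet([Probe("a", 1000, 1.0), Probe("b", 5000, 0.0),
                           Probe("c", 9000, 1.0)])
    inner, outer = breakpoint_interval(probes, ["b"])
    assert inner == 0.0
    assert outer == 8.0


def test_deleted_block_touching_edge_is_unbounded():
    probes = MLPAProbeSet([Probe("a", 1000, 0.0), Probe("b", 5000, 0.0),
                           Probe("c", 9000, 1.0)])
    with pytest.raises(UnboundedDeletion):
        breakpoint_interval(probes, ["a", "b"])


def test_non_contiguous_deleted_block_rejected():
    probes = MLPAProbeSet([Probe(l, 1000 * (i + 1), 1.0) for i, l in enumerate("abcde")])
    with pytest.raises(LocusError):
        breakpoint_interval(probes, ["b", "d"])


@given(
    coords=st.lists(st.integers(1, 10_000_000), min_size=4, max_size=12,
                    unique=True),
    data=st.data(),
)
@settings(max_examples=100, deadline=None)
def test_breakpoint_interval_matches_minmax_oracle(coords, data):
    coords = sorted(coords)
    probes = MLPAProbeSet([Probe(f"p{i}", c, 1.0) for i, c in enumerate(coords)])
    start = data.draw(st.integers(1, len(coords) - 2))
    end = data.draw(st.integers(start, len(coords) - 2))
    deleted = [f"p{i}" for i in range(start, end + 1)]
    inner, outer = breakpoint_interval(probes, deleted)
    del_coords = coords[start:end + 1]
    assert inner == round((max(del_coords) - min(del_coords)) / 1000, 1)
    assert outer == round((coords[end + 1] - coords[start - 1]) / 1000, 1)
    assert inner <= outer


def test_mlpa_ratio_classes():
    probes = MLPAProbeSet([Probe("a", 1, 0.0), Probe("b", 2, 1.0),
                           Probe("c", 3, 0.5), Probe("d", 4, 0.3)])
    got = mlpa_interpret(probes)
    assert got == {"a": 0, "b": 2, "c": 1, "d": "flagged"}


def test_mlpa_probe_coordinates_must_increase():
    with pytest.raises(LocusError):
        MLPAProbeSet([Probe("a", 10, 1.0), Probe("b", 5, 1.0)])


def test_mlpa_table_reader(tmp_path):
    path = tmp_path / "mlpa.tsv"
    path.write_text(
        "label\tcoordinate\tratio\n"
        "PPIP5K1_ex27\t43851168\t1.0\nCKMT1B_ex8\t43890333\t0.0\n"
        "CATSPER2_ex1\t43940784\t0.0\nPDIA3_ex1\t44038794\t1.0\n"
    )
    probes = read_mlpa_table(path)
    assert breakpoint_interval(probes, ["CKMT1B_ex8", "CATSPER2_ex1"]) == (50.5, 187.6)


# --------------------------------------------------------------------------
# qPCR ddCt


def _run(ddct=0.0, spread=0.0, absent=False):
    base = 24.0
    target = (None, None) if absent else (base + ddct - spread / 2, base + ddct + spread / 2)
    return QPCRRun(target, (base, base), (base, base), (base, base))


def test_ddct_identity_gives_two_copies():
    call = qpcr_copy_number(_run(0.0))
    assert call.estimate == pytest.approx(2.0)
    assert call.call == 2


def test_one_cycle_shift_gives_one_copy():
    call = qpcr_copy_number(_run(1.0))
    assert call.estimate == pytest.approx(1.0)  # 2 x 2^-1, closed form
    assert call.call == 1


def test_absent_amplification_calls_zero():
    call = qpcr_copy_number(_run(absent=True))
    assert call.call == 0 and "no target amplification" in call.reason


@given(ddct=st.floats(-3, 6, allow_nan=False))
@settings(max_examples=100, deadline=None)
def test_estimate_halves_exactly_per_added_cycle(ddct):
    a = qpcr_copy_number(_run(ddct)).estimate
    b = qpcr_copy_number(_run(ddct + 1.0)).estimate
    assert b == pytest.approx(a / 2.0, rel=1e-12)


def test_replicate_spread_beyond_tolerance_is_ambiguous():
    call = qpcr_copy_number(_run(1.0, spread=1.6))
    assert call.call == "ambiguous" and "replicate spread" in call.reason


def test_amplified_and_between_band_calls():
    assert qpcr_copy_number(_run(-1.0)).call == "amplified"  # estimate 4.0
    between = qpcr_copy_number(_run(2.2))  # estimate ~0.435: between 0 and 1 bands
    assert between.call == "ambiguous"


def test_reference_qpcr_fixture_reproduces_member_genotypes():
    runs = make_qpcr_runs()
    assert qpcr_copy_number(runs["1410-P"]).call == 0
    assert qpcr_copy_number(runs["1410-F"]).call == 1
    assert qpcr_copy_number(runs["1633/I-1"]).call == 2
    # the unmeasurable mother of family 1564
    assert qpcr_copy_number(runs["1564-M"]).call == "ambiguous"


def test_qpcr_requires_duplicates():
    with pytest.raises(LocusError):
        QPCRRun((24.0,), (24.0, 24.0), (24.0, 24.0), (24.0, 24.0))


def test_qpcr_table_reader(tmp_path):
    path = tmp_path / "qpcr.tsv"
    lines = ["sample\trole\twell\tct\tcalibrator"]
    for w, ct in enumerate(("", "")):
        lines.append(f"S1\ttarget\t{w}\t{ct}\t0")
    for w in range(2):
        lines.append(f"S1\tref\t{w}\t24.0\t0")
    for w in range(2):
        lines.append(f"CAL\ttarget\t{w}\t24.0\t1")
        lines.append(f"CAL\tref\t{w}\t24.0\t1")
    path.write_text("\n".join(lines) + "\n")
    runs = read_qpcr_table(path)
    assert qpcr_copy_number(runs["S1"]).call == 0
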