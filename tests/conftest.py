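import pytest

from triotier.pipeline import run_cohort
from triotier.reference_cohort import build_bundle


@pytest.fixture(scope="session")
def bundle():
    return build_bundle()


@pytest.fixture(scope="session")
def result(bundle):
    return run_cohort(bundle)


@pytest.fixture(scope="session")
def criteria_by_row(result):
    """(family, gene, hgvs_c) -> formatted criterion string, across all
    member-level reports."""
    from triotier.acmg import format_criteria

    out = {}
    for rep in result.reports:
        for cand in rep.candidates:
            for ve in cand.variants:
                out[(rep.family_id, cand.gene, ve.variant.hgvs_c)] = format_criteria(ve.criteria)
    return out
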