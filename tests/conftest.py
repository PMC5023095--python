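import pytest

from paleokin import mito, strprofiles, ylineage
from paleokin.kinship import AlleleFrequencyTable


@pytest.fixture(scope="session")
def reference():
    return mito.synthetic_reference()


@pytest.fixture(scope="session")
def hvr1_segment(reference):
    return mito.region_segment(reference, mito.HVR1)


@pytest.fixture(scope="session")
def hvr2_segment(reference):
    return mito.region_segment(reference, mito.HVR2)


@pytest.fixture(scope="session")
def haplotype_rows():
    """Bundled study haplotype table rows, keyed (sample, lab)."""
    return {(r.haplotype.sample_id, r.lab): r
            for r in mito.load_fixture_haplotypes()}


@pytest.fixture(scope="session")
def body_haplotypes(haplotype_rows):
    return {sample: row.haplotype
            for (sample, lab), row in haplotype_rows.items()
            if row.group == "body" and lab == "1"}


@pytest.fixture(scope="session")
def researcher_haplotypes(haplotype_rows):
    return [row.haplotype for row in haplotype_rows.values()
            if row.group == "researcher"]


@pytest.fixture(scope="session")
def astr_tables():
    return strprofiles.load_fixture_astr_replicates()


@pytest.fixture(scope="session")
def astr_consensus(astr_tables):
    loci = (strprofiles.AMELOGENIN, *strprofiles.ASTR_LOCI)
    return {sample: strprofiles.call_consensus(table, loci=loci)
            for sample, table in astr_tables.items()}


@pytest.fixture(scope="session")
def ystr_consensus():
    tables = strprofiles.load_fixture_ystr_replicates()
    return {sample: strprofiles.consensus_to_y_profile(
        strprofiles.call_consensus(table))
        for sample, table in tables.items()}


@pytest.fixture(scope="session")
def marker_calls():
    return ylineage.load_fixture_marker_calls()


@pytest.fixture(scope="session")
def freqs():
    return AlleleFrequencyTable.synthetic_default()
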