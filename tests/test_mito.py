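"""mtDNA variant notation, calling, classification and distance."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from paleokin import mito
from paleokin.mito import (HVR1, HVR2, AmbiguousBaseWarning, MtHaplotype,
                           MtVariant, VariantParseError, VariantRangeError,
                           apply_variants, call_variants,
                           classify_mt_haplogroup, haplotype_distance,
                           parse_variant)


@pytest.mark.parametrize("text,expected", [
    ("16093C", MtVariant(16093, "sub", "C")),
    ("249del", MtVariant(249, "del")),
    ("310+3C", MtVariant(310, "ins", "C", 3)),
    ("309+C", MtVariant(309, "ins", "C", 1)),
])
def test_parse_variant_canonical_forms(text, expected):
    v = parse_variant(text)
    assert v == expected
    assert v.serialize() == text


def test_parse_variant_dot_dialect_maps_to_plus_notation():
    assert parse_variant("309.1C") == MtVariant(309, "ins", "C", 1)
    assert parse_variant("310.3C").serialize() == "310+3C"


@pytest.mark.parametrize("bad", ["", "16093", "delC", "309++C", "16093X", "C16093"])
def test_parse_variant_rejects_malformed_strings(bad):
    with pytest.raises(VariantParseError):
        parse_variant(bad)


def test_parse_variant_rejects_out_of_range_position():
    with pytest.raises(VariantRangeError):
        parse_variant("16570A")


@settings(derandomize=True, max_examples=200)
@given(position=st.integers(1, mito.RCRS_LENGTH),
       kind=st.sampled_from(["sub", "del", "ins"]),
       base=st.sampled_from("ACGT"),
       count=st.integers(1, 5))
def test_serialize_parse_identity(position, kind, base, count):
    v = MtVariant(position, kind, None if kind == "del" else base,
                  count if kind == "ins" else 1)
    assert parse_variant(v.serialize()) == v


def test_apply_no_variants_is_identity(hvr1_segment):
    assert apply_variants(hvr1_segment, HVR1, []) == hvr1_segment


def test_apply_single_substitution_changes_one_position(hvr1_segment):
    v = parse_variant("16223T")
    edited = apply_variants(hvr1_segment, HVR1, [v])
    diffs = [i for i, (a, b) in enumerate(zip(hvr1_segment, edited)) if a != b]
    assert diffs == [16223 - HVR1.start]
    assert edited[16223 - HVR1.start] == "T"


def test_apply_insertion_lengthens_by_direct_string_edit(hvr2_segment):
    # oracle: direct string surgery at the anchor offset
    edited = apply_variants(hvr2_segment, HVR2, [parse_variant("309+C")])
    i = 309 - HVR2.start + 1
    assert edited == hvr2_segment[:i] + "C" + hvr2_segment[i:]
    assert len(edited) == len(hvr2_segment) + 1


def test_apply_rejects_substitution_equal_to_reference(hvr1_segment):
    ref_base = hvr1_segment[16223 - HVR1.start]
    with pytest.raises(mito.InvalidVariantError):
        apply_variants(hvr1_segment, HVR1, [MtVariant(16223, "sub", ref_base)])


def test_call_variants_reference_vs_itself_is_empty(hvr1_segment):
    assert call_variants(hvr1_segment, HVR1, hvr1_segment) == ()


def test_call_variants_single_edit(hvr1_segment):
    i = 16223 - HVR1.start
    sample = hvr1_segment[:i] + "T" + hvr1_segment[i + 1:]
    assert call_variants(sample, HVR1, hvr1_segment) == (parse_variant("16223T"),)


def test_call_variants_places_insertion_at_three_prime_end_of_run(hvr2_segment):
    # the reference C-run ends at 309; one extra C anywhere in the run must
    # be reported as 309+C (oracle: all in-run placements are equivalent)
    for offset in range(303, 310):
        i = offset - HVR2.start
        sample = hvr2_segment[:i] + "C" + hvr2_segment[i:]
        assert call_variants(sample, HVR2, hvr2_segment) == (
            parse_variant("309+C"),), f"insertion before {offset}"


def test_call_variants_empty_sequence_errors(hvr1_segment):
    with pytest.raises(ValueError):
        call_variants("", HVR1, hvr1_segment)


def test_call_variants_excludes_ambiguous_bases_with_warning(hvr1_segment):
    i = 16223 - HVR1.start
    sample = hvr1_segment[:i] + "N" + hvr1_segment[i + 1:]
    with pytest.warns(AmbiguousBaseWarning):
        assert call_variants(sample, HVR1, hvr1_segment) == ()


def _random_variant_set(rng, region, segment, n_edits):
    """Non-overlapping, canonically placed edits for round-trip checks."""
    variants = []
    positions = []

    def far_enough(p):
        return all(abs(p - q) > 4 for q in positions)

    def ref(p):
        return segment[p - region.start]

    attempts = 0
    while len(variants) < n_edits and attempts < 500:
        attempts += 1
        p = rng.randrange(region.start + 3, region.end - 3)
        if not far_enough(p):
            continue
        kind = rng.choice(["sub", "del", "ins"])
        if kind == "sub":
            base = rng.choice([b for b in "ACGT" if b != ref(p)])
            variants.append(MtVariant(p, "sub", base))
        elif kind == "del":
            if ref(p + 1) == ref(p):  # not the 3' end of its run
                continue
            variants.append(MtVariant(p, "del"))
        else:
            base = rng.choice([b for b in "ACGT" if b != ref(p + 1)])
            variants.append(MtVariant(p, "ins", base, rng.randint(1, 3)))
        positions.append(p)
    return variants


@pytest.mark.parametrize("seed", range(8))
def test_round_trip_call_of_applied_variants(seed, hvr1_segment):
    rng = random.Random(seed)
    variants = _random_variant_set(rng, HVR1, hvr1_segment, rng.randint(1, 6))
    sample = apply_variants(hvr1_segment, HVR1, variants)
    called = call_variants(sample, HVR1, hvr1_segment)
    assert set(called) == set(variants)


# ---------------------------------------------------------------------------
# haplogroup classification
# ---------------------------------------------------------------------------


def test_table_rows_classify_to_printed_haplogroups(haplotype_rows):
    for (sample, lab), row in haplotype_rows.items():
        if row.group != "body":
            continue
        result = classify_mt_haplogroup(row.haplotype)
        assert result.label == row.reported_haplogroup, (sample, lab)


def test_researcher_rows_lack_coding_calls_and_stay_undetermined(haplotype_rows):
    # researcher haplogroups are metadata (their defining SNPs are not given)
    for (sample, lab), row in haplotype_rows.items():
        if row.group == "researcher":
            assert classify_mt_haplogroup(row.haplotype).label == "reference"


def test_classification_ignores_variant_input_order(body_haplotypes):
    h = body_haplotypes["MN0104"]
    shuffled = MtHaplotype(h.sample_id, tuple(reversed(h.variants)),
                           dict(reversed(list(h.coding_calls.items()))))
    assert (classify_mt_haplogroup(shuffled).label
            == classify_mt_haplogroup(h).label == "D4")


def test_empty_haplotype_classifies_as_reference():
    assert classify_mt_haplogroup(MtHaplotype("blank")).label == "reference"


def test_conflicting_coding_calls_rejected():
    with pytest.raises(ValueError):
        MtHaplotype.from_strings("x", "", "", "10398G,10398C")


# ---------------------------------------------------------------------------
# haplotype distance
# ---------------------------------------------------------------------------


def test_distance_zero_for_identical_table_rows(body_haplotypes):
    assert haplotype_distance(body_haplotypes["MN0104"],
                              body_haplotypes["MN0125"]) == 0


def test_distance_identity_and_symmetry(body_haplotypes, researcher_haplotypes):
    haps = list(body_haplotypes.values()) + researcher_haplotypes
    for h1 in haps:
        assert haplotype_distance(h1, h1) == 0
        for h2 in haps:
            assert haplotype_distance(h1, h2) == haplotype_distance(h2, h1)


def test_distance_body_vs_lab_worker_counts_differing_entries(
        body_haplotypes, researcher_haplotypes):
    # hand count from the printed rows: MN0104 has 16171G, 16311C, 309+C and
    # 310+C that Lab Worker 1 lacks; Lab Worker 1 has 195C, 198T and 315+C
    lw1 = next(h for h in researcher_haplotypes if h.sample_id == "LabWorker1")
    assert haplotype_distance(body_haplotypes["MN0104"], lw1) == 7
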