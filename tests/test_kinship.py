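"""Likelihood-ratio kinship: IBS counts, locus LRs, posteriors, exclusions."""

from fractions import Fraction
from itertools import combinations_with_replacement, product

import pytest

from paleokin.kinship import (DEFAULT_HYPOTHESES, FULL_SIBLING,
                              PARENT_OFFSPRING, UNRELATED,
                              AlleleFrequencyTable, MissingFrequencyError,
                              classify_pair, combined_lr, genotype_probability,
                              locus_lr, posterior, shared_allele_count,
                              trio_mendelian_check)
from paleokin.strprofiles import ASTR_LOCI

THREE_ALLELES = {"L": {"10": Fraction(1, 2), "11": Fraction(3, 10),
                       "12": Fraction(1, 5)}}


@pytest.fixture(scope="module")
def small_freqs():
    return AlleleFrequencyTable(THREE_ALLELES)


@pytest.mark.parametrize("g1,g2,expected", [
    (("29", "29"), ("30", "33.2"), 0),   # the published zero-IBS D21S11 pair
    (("21", "27"), ("19", "22"), 0),     # the published zero-IBS FGA pair
    (("9", "9"), ("9", "9"), 2),
    (("13", "17"), ("13", "13"), 1),     # largest one-to-one matching
    (("9", "11"), ("8", "9"), 1),
])
def test_shared_allele_count(g1, g2, expected):
    assert shared_allele_count(g1, g2) == expected
    assert shared_allele_count(g2, g1) == expected


def test_unrelated_lr_is_always_one(small_freqs):
    genotypes = list(combinations_with_replacement(["10", "11", "12"], 2))
    for g1, g2 in product(genotypes, repeat=2):
        assert locus_lr(g1, g2, UNRELATED, "L", small_freqs) == 1


def test_parent_offspring_exclusion_zeroes_lr(small_freqs):
    assert locus_lr(("10", "11"), ("12", "12"), PARENT_OFFSPRING,
                    "L", small_freqs) == 0


def test_parent_offspring_lr_closed_form():
    # g1=a/b, g2=a/c with p_a = 0.1: LR = 1/(4 p_a) = 2.5
    freqs = AlleleFrequencyTable({"L": {
        "10": Fraction(1, 10), "11": Fraction(4, 10), "12": Fraction(5, 10)}})
    lr = locus_lr(("10", "11"), ("10", "12"), PARENT_OFFSPRING, "L", freqs)
    assert lr == Fraction(5, 2)


def test_conditional_distribution_over_g2_sums_to_one(small_freqs):
    """For fixed g1 and each hypothesis, P(g2|g1,H) = LR * P_HWE(g2) must be
    a probability distribution over the genotype space (enumeration check)."""
    genotypes = list(combinations_with_replacement(["10", "11", "12"], 2))
    for hyp in DEFAULT_HYPOTHESES:
        for g1 in genotypes:
            total = sum(
                locus_lr(g1, g2, hyp, "L", small_freqs)
                * genotype_probability(g2, "L", small_freqs)
                for g2 in genotypes)
            assert total == 1, (hyp.label, g1)


def test_combined_lr_is_product_and_order_invariant(small_freqs):
    freqs = AlleleFrequencyTable({"A": THREE_ALLELES["L"],
                                  "B": THREE_ALLELES["L"]})
    g1 = {"A": ("10", "11"), "B": ("10", "10")}
    g2 = {"A": ("10", "12"), "B": ("10", "11")}
    lr_a = locus_lr(g1["A"], g2["A"], FULL_SIBLING, "A", freqs)
    lr_b = locus_lr(g1["B"], g2["B"], FULL_SIBLING, "B", freqs)
    combined, skipped = combined_lr(g1, g2, FULL_SIBLING, freqs)
    assert combined == lr_a * lr_b
    assert skipped == ()
    reversed_combined, _ = combined_lr(g1, g2, FULL_SIBLING, freqs,
                                       loci=["B", "A"])
    assert reversed_combined == combined


def test_missing_loci_are_skipped_and_reported(small_freqs):
    combined, skipped = combined_lr(
        {"L": ("10", "11")}, {"L": ("10", "11"), "M": ("9", "9")},
        FULL_SIBLING, small_freqs)
    assert skipped == ("M",)
    assert combined == locus_lr(("10", "11"), ("10", "11"), FULL_SIBLING,
                                "L", small_freqs)


def test_missing_frequency_requires_floor():
    table = AlleleFrequencyTable(THREE_ALLELES)
    with pytest.raises(MissingFrequencyError):
        table.frequency("L", "99")
    floored = AlleleFrequencyTable(THREE_ALLELES, floor=Fraction(1, 1000))
    assert floored.frequency("L", "99") == Fraction(1, 1000)
    assert ("L", "99") in floored.floored


class TestPosterior:

    def test_zero_lr_gives_zero_posterior(self):
        post = posterior({"parent_offspring": Fraction(0),
                          "unrelated": Fraction(1)})
        assert post["parent_offspring"] == 0
        assert post["unrelated"] == 1

    def test_equal_lrs_return_priors(self):
        priors = {"a": Fraction(1, 4), "b": Fraction(3, 4)}
        assert posterior({"a": Fraction(7), "b": Fraction(7)}, priors) == priors

    def test_uniform_prior_arithmetic(self):
        post = posterior({"po": Fraction(4), "sib": Fraction(1),
                          "un": Fraction(1)})
        assert post["po"] == Fraction(2, 3)
        assert sum(post.values()) == 1


class TestFixturePairs:

    def test_exclusion_pair_has_zero_po_posterior_in_every_scenario(
            self, astr_consensus, freqs):
        results = classify_pair(astr_consensus["MN0104"],
                                astr_consensus["MN0126"], freqs,
                                loci=ASTR_LOCI)
        assert len(results) == 2  # both D21S11 candidates evaluated
        for res in results:
            assert set(res.exclusion_loci) == {"D21S11", "FGA"}
            assert res.combined["parent_offspring"] == 0
            assert res.posteriors["parent_offspring"] == 0
            assert sum(res.posteriors.values()) == 1

    def test_mother_pairs_have_positive_po_and_sib_posteriors(
            self, astr_consensus, freqs):
        # the qualitative ordering holds under any strictly positive table
        for child in ("MN0104", "MN0126"):
            for res in classify_pair(astr_consensus["MN0125"],
                                     astr_consensus[child], freqs,
                                     loci=ASTR_LOCI):
                if res.exclusion_loci:
                    continue  # the 30/30 candidate scenario for MN0126
                assert res.posteriors["parent_offspring"] > 0
                assert res.posteriors["full_sibling"] > 0

    def test_identical_profiles_sibling_lr_dominates_unrelated(
            self, astr_consensus, freqs):
        res = classify_pair(astr_consensus["MN0104"], astr_consensus["MN0104"],
                            freqs, loci=ASTR_LOCI)[0]
        for locus, lr in res.locus_lrs["full_sibling"].items():
            assert lr >= res.locus_lrs["unrelated"][locus]

    def test_trio_check_mother_compatible_at_all_loci(self, astr_consensus):
        trio = trio_mendelian_check(
            astr_consensus["MN0125"],
            [astr_consensus["MN0104"], astr_consensus["MN0126"]],
            loci=ASTR_LOCI)
        assert trio.compatible_counts() == {"MN0104": (8, 8), "MN0126": (8, 8)}

    def test_trio_check_flags_incompatible_locus(self, astr_consensus):
        trio = trio_mendelian_check(
            astr_consensus["MN0104"], [astr_consensus["MN0376"]],
            loci=ASTR_LOCI)
        report = trio.per_child["MN0376"]
        assert report["D21S11"] is False  # 29/29 vs 31/32.2 shares nothing
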