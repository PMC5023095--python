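"""Synthetic pedigree, replicate-noise and deamination generators."""

import numpy as np
import pytest

from paleokin.kinship import shared_allele_count
from paleokin.simulate import (NoiseModel, PedigreeMember, PedigreeSpec,
                               ZERO_NOISE, run_recovery_experiment,
                               simulate_deamination, simulate_pedigree,
                               simulate_replicates)

MOTHER_SONS = (
    PedigreeMember("mother", "female"),
    PedigreeMember("father", "male"),
    PedigreeMember("son1", "male", father="father", mother="mother"),
    PedigreeMember("son2", "male", father="father", mother="mother"),
    PedigreeMember("son3", "male", father="father", mother="mother"),
)


@pytest.fixture()
def family_spec(freqs):
    return PedigreeSpec(MOTHER_SONS, freqs, seed=7)


def test_same_seed_reproduces_bitwise(family_spec):
    assert simulate_pedigree(family_spec) == simulate_pedigree(family_spec)


def test_different_seeds_differ(family_spec, freqs):
    other = PedigreeSpec(MOTHER_SONS, freqs, seed=8)
    assert simulate_pedigree(family_spec) != simulate_pedigree(other)


def test_inheritance_invariants_hold_for_every_member(family_spec):
    people = simulate_pedigree(family_spec)
    father, mother = people["father"], people["mother"]
    for son_id in ("son1", "son2", "son3"):
        son = people[son_id]
        assert son.y_str == father.y_str            # patrilineal identity
        assert son.mt_variants == mother.mt_variants  # matrilineal identity
        for locus, genotype in son.autosomal.items():
            assert shared_allele_count(genotype, mother.autosomal[locus]) >= 1
            assert shared_allele_count(genotype, father.autosomal[locus]) >= 1


def test_founders_only_pedigree(freqs):
    spec = PedigreeSpec((PedigreeMember("a", "female"),
                         PedigreeMember("b", "male")), freqs, seed=1)
    people = simulate_pedigree(spec)
    assert set(people) == {"a", "b"}
    assert people["a"].mt_variants != people["b"].mt_variants


def test_cyclic_pedigree_rejected(freqs):
    with pytest.raises(ValueError):
        PedigreeSpec((PedigreeMember("a", "female", mother="b"),
                      PedigreeMember("b", "female", mother="a")), freqs)


def test_unrelated_zero_sharing_fraction_matches_enumeration(freqs):
    """One locus with two equifrequent alleles: the chance two unrelated
    genotypes share no allele is enumerable exactly; the simulated fraction
    must fall within 3 binomial SE."""
    from fractions import Fraction
    from paleokin.kinship import AlleleFrequencyTable, genotype_probability

    table = AlleleFrequencyTable({"L": {"10": Fraction(1, 2),
                                        "12": Fraction(1, 2)}})
    genotypes = [("10", "10"), ("10", "12"), ("12", "12")]
    exact = float(sum(
        genotype_probability(g1, "L", table) * genotype_probability(g2, "L", table)
        for g1 in genotypes for g2 in genotypes
        if shared_allele_count(g1, g2) == 0))

    rng = np.random.default_rng(3)
    n = 10_000
    hits = 0
    for _ in range(n):
        spec = PedigreeSpec((PedigreeMember("a", "female"),
                             PedigreeMember("b", "male")),
                            table, autosomal_loci=("L",))
        people = simulate_pedigree(spec, rng)
        hits += shared_allele_count(people["a"].autosomal["L"],
                                    people["b"].autosomal["L"]) == 0
    se = (exact * (1 - exact) / n) ** 0.5
    assert abs(hits / n - exact) <= 3 * se


class TestReplicateNoise:

    TRUTH = {"A": ("10", "12"), "B": ("9", "9")}

    def test_zero_noise_replicates_equal_truth(self):
        table = simulate_replicates(self.TRUTH, ZERO_NOISE, 4, rng=0)
        for rep in table.replicates:
            assert dict(rep.calls) == self.TRUTH

    def test_certain_locus_dropout_blanks_the_locus(self):
        noise = NoiseModel(locus_dropout=1.0)
        table = simulate_replicates(self.TRUTH, noise, 3, rng=0)
        for rep in table.replicates:
            assert rep.calls["A"] is None and rep.calls["B"] is None

    def test_allelic_dropout_rate_matches_binomial(self):
        d = 0.25
        noise = NoiseModel(allelic_dropout=d)
        table = simulate_replicates({"A": ("10", "12")}, noise, 10_000, rng=5)
        apparent_hom = sum(
            1 for rep in table.replicates
            if len(set(rep.calls["A"])) == 1)
        n = len(table.replicates)
        se = (d * (1 - d) / n) ** 0.5
        assert abs(apparent_hom / n - d) <= 3 * se

    def test_misread_shifts_by_one_repeat_preserving_microvariant(self):
        noise = NoiseModel(misread=1.0)
        table = simulate_replicates({"A": ("33.2", "33.2")}, noise, 1, rng=2)
        (genotype,) = {table.replicates[0].calls["A"]}
        assert set(genotype) <= {"32.2", "34.2"}


class TestDeamination:

    def test_zero_rate_means_inactive_equals_active(self, body_haplotypes):
        sim = simulate_deamination(body_haplotypes["MN0104"].variants,
                                   damage_rate=0.0, n_inactive=5, n_active=5,
                                   rng=0)
        assert (sim.inactive.consensus_variants()
                == sim.active.consensus_variants())

    def test_full_rate_damages_every_clone_at_single_site(self, body_haplotypes):
        sim = simulate_deamination(body_haplotypes["MN0376"].variants,
                                   damage_rate=1.0, n_inactive=5, n_active=4,
                                   rng=0, positions=[16250])
        fractions = sim.inactive.variant_fractions()
        assert fractions["16250T"] == 1.0

    def test_damaged_fraction_matches_binomial(self, body_haplotypes):
        rate, depth = 0.3, 20
        sim = simulate_deamination(body_haplotypes["MN0376"].variants,
                                   damage_rate=rate, n_inactive=depth,
                                   n_active=4, rng=42, positions=[16250])
        observed = sim.inactive.variant_fractions().get("16250T", 0.0)
        se = (rate * (1 - rate) / depth) ** 0.5
        assert abs(observed - rate) <= 3 * se


class TestRecoveryExperiment:

    def test_zero_pairs_gives_empty_matrix(self, freqs):
        result = run_recovery_experiment(freqs, n_pairs=0, seed=0)
        assert all(not row for row in result.confusion.values())

    def test_noise_free_po_pairs_never_excluded_and_mostly_recovered(self, freqs):
        result = run_recovery_experiment(
            freqs, relationships=("parent_offspring",), n_pairs=60, seed=1)
        assert result.exclusion_rate["parent_offspring"] == 0.0
        row = result.confusion["parent_offspring"]
        # PO vs full siblings is intrinsically hard at 8 loci: require only
        # that unrelated is (almost) never the winner
        assert row.get("unrelated", 0) <= 2

    def test_deterministic_given_seed(self, freqs):
        r1 = run_recovery_experiment(freqs, n_pairs=20, seed=9)
        r2 = run_recovery_experiment(freqs, n_pairs=20, seed=9)
        assert r1.confusion == r2.confusion
        assert r1.exclusion_rate == r2.exclusion_rate
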