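"""Synthetic families and noisy laboratory observations.

The generator embodies the inheritance model the analysis assumes: diploid
autosomal STR genotypes segregate by Mendel's law from founders drawn under
Hardy-Weinberg proportions; Y-STR haplotypes copy father to son; mtDNA
haplotypes copy mother to child (no mutation anywhere — matching the
no-mutation kinship model).  Replicate observation noise emulates the
missingness patterns of low-template typing: whole-replicate failure,
whole-locus dropout, allelic dropout of one heterozygote allele (producing
an apparent homozygote) and +/-1-repeat misreads.  Deamination damage is
simulated per clone as C→T / G→A conversions that active-UDG treatment
repairs.

Everything is deterministic given a seed, and the output is produced in the
same containers the analysis modules consume, so every downstream stage can
be exercised end to end without fixture files.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .authenticity import CloneSet
from .kinship import (AlleleFrequencyTable, DEFAULT_HYPOTHESES,
                      RelationshipHypothesis, classify_pair)
from .mito import HVR1, MtVariant, RegionSpec, region_segment, \
    synthetic_reference
from .strprofiles import (ASTR_LOCI, ConsensusProfile, Genotype, Replicate,
                          ReplicateTable, call_consensus, normalize_genotype)

Rng = np.random.Generator


def _rng(seed_or_rng: int | Rng) -> Rng:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PedigreeMember:
    individual_id: str
    sex: str  # "male" | "female"
    father: str | None = None
    mother: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.individual_id}: sex must be male/female")


@dataclass(frozen=True)
class PedigreeSpec:
    """A pedigree plus the panels and frequencies that drive simulation."""

    members: tuple[PedigreeMember, ...]
    frequencies: AlleleFrequencyTable
    autosomal_loci: tuple[str, ...] = ASTR_LOCI
    y_loci: tuple[str, ...] = ("DYS19", "DYS390", "DYS391", "DYS393")
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate individual ids")
        known = set(ids)
        for m in self.members:
            for parent in (m.father, m.mother):
                if parent is not None and parent not in known:
                    raise ValueError(f"{m.individual_id}: unknown parent {parent}")
        self._topological_order()  # rejects cycles

    def _topological_order(self) -> list[PedigreeMember]:
        by_id = {m.individual_id: m for m in self.members}
        order: list[PedigreeMember] = []
        state: dict[str, int] = {}

        def visit(mid: str) -> None:
            if state.get(mid) == 2:
                return
            if state.get(mid) == 1:
                raise ValueError("pedigree contains a cycle")
            state[mid] = 1
            m = by_id[mid]
            for parent in (m.father, m.mother):
                if parent is not None:
                    visit(parent)
            state[mid] = 2
            order.append(m)

        for m in self.members:
            visit(m.individual_id)
        return order


@dataclass(frozen=True)
class SimulatedIndividual:
    individual_id: str
    sex: str
    autosomal: Mapping[str, Genotype]
    y_str: Mapping[str, tuple[str, ...]] | None  # None for females
    mt_variants: frozenset[MtVariant]


def _draw_allele(rng: Rng, alleles: list[str], probs: np.ndarray) -> str:
    return alleles[int(rng.choice(len(alleles), p=probs))]


def _founder_mt_haplotype(index: int, reference: str) -> frozenset[MtVariant]:
    """A distinct single-substitution matriline for founder number ``index``."""
    position = 16101 + index
    if not HVR1.contains(position):
        raise ValueError("too many founder matrilines for the default scheme")
    ref_base = reference[position - 1]
    base = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref_base]
    return frozenset({MtVariant(position, "sub", base)})


def simulate_pedigree(spec: PedigreeSpec,
                      rng: int | Rng | None = None
                      ) -> dict[str, SimulatedIndividual]:
    """Draw true genetic profiles for every pedigree member.

    Founders: autosomal genotypes under Hardy-Weinberg from the frequency
    table; each founder male a distinct Y haplotype; each founder a distinct
    matriline.  Children: one uniformly chosen allele from each parent per
    autosomal locus; the father's Y (sons only); the mother's mtDNA.
    """
    rng = _rng(spec.seed if rng is None else rng)
    reference = synthetic_reference()
    freq_tables = {
        locus: (list(spec.frequencies.freqs[locus]),
                np.array([float(f) for f in spec.frequencies.freqs[locus].values()]))
        for locus in spec.autosomal_loci}
    out: dict[str, SimulatedIndividual] = {}
    founder_count = 0
    for member in spec._topological_order():
        father = out.get(member.father) if member.father else None
        mother = out.get(member.mother) if member.mother else None
        autosomal: dict[str, Genotype] = {}
        for locus in spec.autosomal_loci:
            alleles, probs = freq_tables[locus]
            paternal = (str(rng.choice(father.autosomal[locus]))
                        if father else _draw_allele(rng, alleles, probs))
            maternal = (str(rng.choice(mother.autosomal[locus]))
                        if mother else _draw_allele(rng, alleles, probs))
            autosomal[locus] = normalize_genotype([paternal, maternal])
        if member.sex == "male":
            if father is not None:
                y_str = dict(father.y_str or {})
            else:
                y_str = {locus: (str(int(rng.integers(8, 21))),)
                         for locus in spec.y_loci}
        else:
            y_str = None
        if mother is not None:
            mt = mother.mt_variants
        else:
            mt = _founder_mt_haplotype(founder_count, reference)
        if father is None and mother is None:
            founder_count += 1
        out[member.individual_id] = SimulatedIndividual(
            member.individual_id, member.sex, autosomal, y_str, mt)
    return out


# ---------------------------------------------------------------------------
# Replicate noise
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Per-replicate corruption probabilities for STR typing."""

    locus_dropout: float = 0.0      # whole-locus failure
    allelic_dropout: float = 0.0    # heterozygote -> apparent homozygote
    misread: float = 0.0            # an allele shifts by one full repeat
    replicate_failure: float = 0.0  # the whole replicate fails

    def __post_init__(self) -> None:
        for name, p in vars(self).items():
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be within [0, 1]")


ZERO_NOISE = NoiseModel()


def _shift_repeat(allele: str, step: int) -> str:
    """Shift an allele by whole repeats, preserving any microvariant suffix."""
    if "." in allele:
        whole, frac = allele.split(".")
        return f"{max(1, int(whole) + step)}.{frac}"
    return str(max(1, int(allele) + step))


def simulate_replicates(true_profile: Mapping[str, Genotype], noise: NoiseModel,
                        n: int, rng: int | Rng, sample_id: str = "SIM",
                        lab_id: str = "sim") -> ReplicateTable:
    """Independent noisy replicates of one true profile."""
    rng = _rng(rng)
    replicates = []
    for i in range(n):
        calls: dict[str, Genotype | None] = {}
        failed = rng.random() < noise.replicate_failure
        for locus, genotype in true_profile.items():
            if failed or rng.random() < noise.locus_dropout:
                calls[locus] = None
                continue
            alleles = list(genotype)
            if (len(set(alleles)) > 1 and rng.random() < noise.allelic_dropout):
                kept = str(rng.choice(alleles))
                alleles = [kept, kept]
            alleles = [
                _shift_repeat(a, int(rng.choice([-1, 1])))
                if rng.random() < noise.misread else a
                for a in alleles]
            calls[locus] = normalize_genotype(alleles)
        replicates.append(Replicate(str(i + 1), lab_id, calls))
    return ReplicateTable(sample_id, tuple(replicates))


# ---------------------------------------------------------------------------
# Deamination damage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DeaminationSim:
    inactive: CloneSet
    active: CloneSet
    planted: tuple[int, ...]  # positions eligible for damage


def simulate_deamination(variants: Iterable[MtVariant], damage_rate: float,
                         n_inactive: int, n_active: int, rng: int | Rng,
                         sample_id: str = "SIM", region: RegionSpec = HVR1,
                         reference: str | None = None,
                         positions: Sequence[int] | None = None) -> DeaminationSim:
    """Simulate clone sets with and without UDG repair.

    Each inactive-UDG clone independently converts each eligible C to T (and
    G to A) with probability ``damage_rate``; active-UDG clones carry no
    conversions.  ``positions`` restricts the eligible sites (default: every
    C/G of the sample sequence in the region).
    """
    rng = _rng(rng)
    if not 0 <= damage_rate <= 1:
        raise ValueError("damage_rate must be within [0, 1]")
    reference = reference or synthetic_reference()
    base_variants = frozenset(v for v in variants if region.contains(v.position))
    segment = region_segment(reference, region)
    # sample base per position (indels shift downstream coordinates, so for
    # eligibility we use substitution-adjusted reference coordinates)
    sample_base = {
        pos: next((v.base for v in base_variants
                   if v.kind == "sub" and v.position == pos),
                  reference[pos - 1])
        for pos in range(region.start, region.end + 1)}
    if positions is None:
        eligible = [p for p, b in sorted(sample_base.items()) if b in "CG"]
    else:
        eligible = [p for p in positions if sample_base[p] in "CG"]
        if len(eligible) != len(positions):
            raise ValueError("a requested damage position is not a C or G")

    def damage_clone() -> frozenset[MtVariant]:
        clone = dict.fromkeys(base_variants)
        for pos in eligible:
            if rng.random() >= damage_rate:
                continue
            new_base = "T" if sample_base[pos] == "C" else "A"
            old = next((v for v in clone if v.kind == "sub" and v.position == pos),
                       None)
            if old is not None:
                del clone[old]
            if new_base != reference[pos - 1]:
                clone[MtVariant(pos, "sub", new_base)] = None
        return frozenset(clone)

    inactive = CloneSet.from_variant_sets(
        sample_id, "inactive_udg", (damage_clone() for _ in range(n_inactive)),
        region)
    active = CloneSet.from_variant_sets(
        sample_id, "active_udg", (base_variants for _ in range(n_active)), region)
    return DeaminationSim(inactive, active, tuple(eligible))


# ---------------------------------------------------------------------------
# Kinship recovery experiment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryResult:
    """Confusion of maximum-posterior labels against planted relationships."""

    confusion: Mapping[str, Mapping[str, int]]  # truth -> predicted -> count
    exclusion_rate: Mapping[str, float]         # truth -> P(>=1 exclusion locus)

    def accuracy(self) -> dict[str, float]:
        return {truth: row.get(truth, 0) / max(1, sum(row.values()))
                for truth, row in self.confusion.items()}


def _simulate_pair(relationship: str, freqs: AlleleFrequencyTable,
                   loci: Sequence[str], rng: Rng
                   ) -> tuple[dict[str, Genotype], dict[str, Genotype]]:
    members = {
        "unrelated": (PedigreeMember("A", "female"), PedigreeMember("B", "male")),
        "parent_offspring": (PedigreeMember("A", "female"),
                             PedigreeMember("F", "male"),
                             PedigreeMember("B", "male", father="F", mother="A")),
        "full_sibling": (PedigreeMember("M", "female"), PedigreeMember("F", "male"),
                         PedigreeMember("A", "female", father="F", mother="M"),
                         PedigreeMember("B", "male", father="F", mother="M")),
    }[relationship]
    spec = PedigreeSpec(members, freqs, autosomal_loci=tuple(loci))
    profiles = simulate_pedigree(spec, rng)
    return dict(profiles["A"].autosomal), dict(profiles["B"].autosomal)


def _profile_from_genotypes(sample_id: str, genotypes: Mapping[str, Genotype],
                            noise: NoiseModel | None, replicates: int,
                            rng: Rng) -> ConsensusProfile:
    if noise is None:
        table = simulate_replicates(genotypes, ZERO_NOISE, 1, rng, sample_id)
        return call_consensus(table, min_count=1)
    table = simulate_replicates(genotypes, noise, replicates, rng, sample_id)
    return call_consensus(table)


def run_recovery_experiment(freqs: AlleleFrequencyTable,
                            loci: Sequence[str] = ASTR_LOCI,
                            relationships: Sequence[str] = (
                                "unrelated", "parent_offspring", "full_sibling"),
                            n_pairs: int = 500,
                            noise: NoiseModel | None = None,
                            replicates: int = 3,
                            hypotheses: Sequence[RelationshipHypothesis] =
                            DEFAULT_HYPOTHESES,
                            seed: int | Rng = 0) -> RecoveryResult:
    """Simulate pairs of known relationship and score classify_pair on them.

    For every pair the maximum-posterior hypothesis label is tallied against
    the planted truth; exclusion rates (share-nothing loci) are reported per
    relationship.  Deterministic given the seed.  Discrimination between
    parent-offspring and full siblings at 8 loci is intrinsically imperfect;
    the confusion matrix reports it rather than thresholding it away.
    """
    rng = _rng(seed)
    confusion: dict[str, Counter] = {}
    exclusion: dict[str, float] = {}
    for relationship in relationships:
        tally: Counter = Counter()
        n_excluded = 0
        for _ in range(n_pairs):
            g1, g2 = _simulate_pair(relationship, freqs, loci, rng)
            p1 = _profile_from_genotypes("A", g1, noise, replicates, rng)
            p2 = _profile_from_genotypes("B", g2, noise, replicates, rng)
            result = classify_pair(p1, p2, freqs, hypotheses, loci=loci)[0]
            if result.exclusion_loci:
                n_excluded += 1
            best = max(sorted(result.posteriors), key=lambda h: result.posteriors[h])
            tally[best] += 1
        confusion[relationship] = tally
        exclusion[relationship] = n_excluded / n_pairs if n_pairs else 0.0
    return RecoveryResult(
        confusion={k: dict(v) for k, v in confusion.items()},
        exclusion_rate=exclusion)
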