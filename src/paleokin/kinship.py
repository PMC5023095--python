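"""Forensic kinship inference from autosomal STR profiles.

Pairwise relatedness is evaluated with identity-by-descent likelihood
ratios.  A relationship hypothesis is summarised by its Cotterman
coefficients (k0, k1, k2) — the probabilities that the pair shares 0, 1 or
2 alleles identical by descent:

    unrelated         (1,   0,   0)
    parent-offspring  (0,   1,   0)
    full siblings     (1/4, 1/2, 1/4)

The per-locus likelihood ratio against unrelatedness is

    LR = k0 + k1 * T1 + k2 * T2

where T1 compares the probability of the second genotype given one IBD
allele transmitted from the first (the transmitted allele is a uniform
draw from the first genotype, the other allele comes from the population)
with its Hardy-Weinberg probability, and T2 = 1/P(g2) when the genotypes
are identical (else 0).  Loci are treated as independent (product rule)
and a no-mutation model is used: a parent-offspring pair sharing no allele
at any locus (a Mendelian exclusion) has combined LR exactly 0.

All arithmetic is exact (``fractions.Fraction``) so zero-versus-nonzero
decisions are robust; floats appear only in reports.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .strprofiles import ConsensusProfile, Genotype, normalize_genotype

_DATA_DIR = Path(__file__).parent / "data"


class MissingFrequencyError(KeyError):
    """An allele has no population frequency and no floor is configured."""


@dataclass(frozen=True)
class RelationshipHypothesis:
    """A named pair relationship with Cotterman IBD-sharing coefficients."""

    label: str
    cotterman: tuple[Fraction, Fraction, Fraction]

    def __post_init__(self) -> None:
        if sum(self.cotterman) != 1:
            raise ValueError(f"{self.label}: k0+k1+k2 must equal 1")
        if any(k < 0 for k in self.cotterman):
            raise ValueError(f"{self.label}: coefficients must be nonnegative")


UNRELATED = RelationshipHypothesis(
    "unrelated", (Fraction(1), Fraction(0), Fraction(0)))
PARENT_OFFSPRING = RelationshipHypothesis(
    "parent_offspring", (Fraction(0), Fraction(1), Fraction(0)))
FULL_SIBLING = RelationshipHypothesis(
    "full_sibling", (Fraction(1, 4), Fraction(1, 2), Fraction(1, 4)))

DEFAULT_HYPOTHESES = (UNRELATED, PARENT_OFFSPRING, FULL_SIBLING)


class AlleleFrequencyTable:
    """Population allele frequencies: locus -> allele label -> Fraction.

    Frequencies must be positive and sum to 1 (within 1e-6) per locus.  An
    allele absent from the table is substituted with ``floor`` when one is
    configured (and recorded in :attr:`floored`), else it is an error.
    """

    def __init__(self, freqs: Mapping[str, Mapping[str, Fraction]],
                 floor: Fraction | None = None):
        self.freqs = {locus: dict(table) for locus, table in freqs.items()}
        self.floor = floor
        self.floored: list[tuple[str, str]] = []
        for locus, table in self.freqs.items():
            if any(f <= 0 for f in table.values()):
                raise ValueError(f"{locus}: frequencies must be positive")
            total = sum(table.values())
            if abs(total - 1) > Fraction(1, 10**6):
                raise ValueError(f"{locus}: frequencies sum to {float(total):.6f}")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 floor: Fraction | None = None) -> "AlleleFrequencyTable":
        freqs: dict[str, dict[str, Fraction]] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                freqs.setdefault(row["locus"], {})[row["allele"]] = (
                    Fraction(row["frequency"]))
        return cls(freqs, floor=floor)

    @classmethod
    def synthetic_default(cls, floor: Fraction | None = None) -> "AlleleFrequencyTable":
        """The bundled synthetic table for the 8-locus autosomal panel."""
        return cls.from_tsv(_DATA_DIR / "synthetic_allele_frequencies.tsv",
                            floor=floor)

    def frequency(self, locus: str, allele: str) -> Fraction:
        table = self.freqs.get(locus, {})
        if allele in table:
            return table[allele]
        if self.floor is not None:
            self.floored.append((locus, allele))
            return self.floor
        raise MissingFrequencyError(f"no frequency for {locus} allele {allele}")

    def loci(self) -> tuple[str, ...]:
        return tuple(self.freqs)


# ---------------------------------------------------------------------------
# Per-locus quantities
# ---------------------------------------------------------------------------


def shared_allele_count(g1: Genotype, g2: Genotype) -> int:
    """Identity-by-state count: size of the largest one-to-one allele matching."""
    remaining = list(g2)
    shared = 0
    for allele in g1:
        if allele in remaining:
            remaining.remove(allele)
            shared += 1
    return shared


def genotype_probability(genotype: Genotype, locus: str,
                         freqs: AlleleFrequencyTable) -> Fraction:
    """Hardy-Weinberg genotype probability."""
    a, b = genotype
    pa, pb = freqs.frequency(locus, a), freqs.frequency(locus, b)
    return pa * pb if a == b else 2 * pa * pb


def _transmission_probability(g1: Genotype, g2: Genotype, locus: str,
                              freqs: AlleleFrequencyTable) -> Fraction:
    """P(g2 | one allele of g2 is a uniform IBD draw from g1, other random)."""
    c, d = g2
    prob = Fraction(0)
    for transmitted in g1:
        if c == d:
            contrib = freqs.frequency(locus, c) if transmitted == c else Fraction(0)
        else:
            contrib = Fraction(0)
            if transmitted == c:
                contrib += freqs.frequency(locus, d)
            if transmitted == d:
                contrib += freqs.frequency(locus, c)
        prob += Fraction(1, len(g1)) * contrib
    return prob


def locus_lr(g1: Genotype, g2: Genotype, hypothesis: RelationshipHypothesis,
             locus: str, freqs: AlleleFrequencyTable) -> Fraction:
    """Single-locus likelihood ratio of ``hypothesis`` versus unrelatedness."""
    g1, g2 = normalize_genotype(g1), normalize_genotype(g2)
    k0, k1, k2 = hypothesis.cotterman
    lr = Fraction(k0)
    p2 = genotype_probability(g2, locus, freqs)
    if k1:
        lr += k1 * _transmission_probability(g1, g2, locus, freqs) / p2
    if k2 and g1 == g2:
        lr += k2 / p2
    return lr


# ---------------------------------------------------------------------------
# Profile-level inference
# ---------------------------------------------------------------------------


def combined_lr(genos1: Mapping[str, Genotype], genos2: Mapping[str, Genotype],
                hypothesis: RelationshipHypothesis,
                freqs: AlleleFrequencyTable,
                loci: Sequence[str] | None = None
                ) -> tuple[Fraction, tuple[str, ...]]:
    """Product of locus LRs over loci definable in both profiles.

    Returns (combined LR, loci skipped because either side is missing).
    Invariant to locus order.
    """
    panel = tuple(loci) if loci is not None else tuple(
        dict.fromkeys([*genos1, *genos2]))
    usable = [l for l in panel if l in genos1 and l in genos2]
    skipped = tuple(l for l in panel if l not in usable)
    if not usable:
        raise ValueError("no locus definable in both profiles")
    lr = Fraction(1)
    for locus in usable:
        lr *= locus_lr(genos1[locus], genos2[locus], hypothesis, locus, freqs)
    return lr, skipped


def posterior(lrs: Mapping[str, Fraction],
              priors: Mapping[str, Fraction] | None = None
              ) -> dict[str, Fraction]:
    """Posterior over hypotheses: prior-weighted LRs, normalised to sum to 1."""
    if priors is None:
        priors = {label: Fraction(1, len(lrs)) for label in lrs}
    if sum(priors.values()) != 1:
        raise ValueError("priors must sum to 1")
    weighted = {label: priors[label] * lr for label, lr in lrs.items()}
    total = sum(weighted.values())
    if total == 0:
        raise ValueError("all hypothesis likelihoods are zero")
    return {label: w / total for label, w in weighted.items()}


@dataclass(frozen=True)
class KinshipResult:
    """One scenario's pairwise kinship evaluation."""

    pair: tuple[str, str]
    scenario: str                                  # e.g. "D21S11=30/33.2"
    locus_lrs: Mapping[str, Mapping[str, Fraction]]  # hypothesis -> locus -> LR
    combined: Mapping[str, Fraction]               # hypothesis -> product LR
    posteriors: Mapping[str, Fraction]
    exclusion_loci: tuple[str, ...]                # zero shared alleles
    skipped_loci: tuple[str, ...] = ()


def _scenarios(profile: ConsensusProfile,
               loci: Sequence[str]) -> list[tuple[str, dict[str, Genotype]]]:
    """Expand ambiguous consensus loci into concrete genotype assignments."""
    fixed: dict[str, Genotype] = {}
    ambiguous: list[tuple[str, tuple[Genotype, ...]]] = []
    for locus in loci:
        candidates = profile.candidate_genotypes(locus)
        if len(candidates) == 1:
            fixed[locus] = candidates[0]
        elif len(candidates) > 1:
            ambiguous.append((locus, candidates))
    if not ambiguous:
        return [("", dict(fixed))]
    out = []
    for combo in product(*(cands for _, cands in ambiguous)):
        genos = dict(fixed)
        labels = []
        for (locus, _), genotype in zip(ambiguous, combo):
            genos[locus] = genotype
            labels.append(f"{locus}={'/'.join(genotype)}")
        out.append((",".join(labels), genos))
    return out


def classify_pair(p1: ConsensusProfile, p2: ConsensusProfile,
                  freqs: AlleleFrequencyTable,
                  hypotheses: Sequence[RelationshipHypothesis] = DEFAULT_HYPOTHESES,
                  priors: Mapping[str, Fraction] | None = None,
                  loci: Sequence[str] | None = None) -> list[KinshipResult]:
    """Evaluate every relationship hypothesis for a pair of profiles.

    Ambiguous consensus loci are expanded combinatorially into scenarios,
    each evaluated and reported separately (never averaged).  The default
    prior is uniform over the evaluated hypothesis set.
    """
    panel = tuple(loci) if loci is not None else tuple(
        dict.fromkeys([*p1.calls, *p2.calls]))
    results = []
    for label1, genos1 in _scenarios(p1, panel):
        for label2, genos2 in _scenarios(p2, panel):
            scenario = ";".join(
                part for part in (
                    f"{p1.sample_id}:{label1}" if label1 else "",
                    f"{p2.sample_id}:{label2}" if label2 else "") if part)
            usable = [l for l in panel if l in genos1 and l in genos2]
            exclusions = tuple(
                l for l in usable
                if shared_allele_count(genos1[l], genos2[l]) == 0)
            locus_lrs: dict[str, dict[str, Fraction]] = {}
            combined: dict[str, Fraction] = {}
            skipped: tuple[str, ...] = ()
            for hyp in hypotheses:
                per_locus = {
                    l: locus_lr(genos1[l], genos2[l], hyp, l, freqs)
                    for l in usable}
                locus_lrs[hyp.label] = per_locus
                lr, skipped = combined_lr(genos1, genos2, hyp, freqs, panel)
                combined[hyp.label] = lr
            results.append(KinshipResult(
                pair=(p1.sample_id, p2.sample_id),
                scenario=scenario,
                locus_lrs=locus_lrs,
                combined=combined,
                posteriors=posterior(combined, priors),
                exclusion_loci=exclusions,
                skipped_loci=skipped))
    return results


@dataclass(frozen=True)
class TrioReport:
    """Mother-versus-children Mendelian compatibility summary."""

    mother: str
    per_child: Mapping[str, Mapping[str, bool]]  # child -> locus -> compatible

    def compatible_counts(self) -> dict[str, tuple[int, int]]:
        return {child: (sum(loci.values()), len(loci))
                for child, loci in self.per_child.items()}


def trio_mendelian_check(mother: ConsensusProfile,
                         children: Iterable[ConsensusProfile],
                         loci: Sequence[str] | None = None) -> TrioReport:
    """Per-child, per-locus Mendelian compatibility with a putative mother.

    A locus is compatible when mother and child share at least one allele
    under some combination of their candidate genotypes (ambiguous loci are
    resolved optimistically, and the report is per-locus so the resolution
    is visible).
    """
    children = list(children)
    panel = tuple(loci) if loci is not None else tuple(
        dict.fromkeys([l for p in (mother, *children) for l in p.calls]))
    per_child: dict[str, dict[str, bool]] = {}
    for child in children:
        report: dict[str, bool] = {}
        for locus in panel:
            m_cands = mother.candidate_genotypes(locus)
            c_cands = child.candidate_genotypes(locus)
            if not m_cands or not c_cands:
                continue  # locus not definable in both; not scored
            report[locus] = any(
                shared_allele_count(gm, gc) >= 1
                for gm in m_cands for gc in c_cands)
        per_child[child.sample_id] = report
    return TrioReport(mother.sample_id, per_child)
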