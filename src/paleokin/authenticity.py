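"""Ancient-DNA authenticity checks.

Two computational screens accompany replicate-consensus typing:

* a contamination screen comparing each ancient haplotype against the
  mitochondrial haplotypes of everyone who handled the material — a match
  means the sample cannot be distinguished from modern contamination;

* damage detection comparing directly amplified sequence with clone sets
  built from uracil-DNA-glycosylase (UDG) treated and untreated aliquots.
  Post-mortem cytosine deamination shows up as C→T (or G→A on the other
  strand) transitions in the untreated (inactive-UDG) clones that revert
  to the direct sequence after active UDG treatment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .mito import (HVR1, MtHaplotype, MtVariant, RegionSpec,
                   haplotype_distance, synthetic_reference)

DEAMINATION_CHANGES = frozenset({("C", "T"), ("G", "A")})


@dataclass(frozen=True)
class CloneSet:
    """Clone haplotypes from one treatment of one sample.

    ``clones`` maps each observed clone variant set to its clone count;
    variant sets are relative to the same region/reference as the direct
    haplotype they will be compared with.
    """

    sample_id: str
    treatment: str  # direct | active_udg | inactive_udg
    clones: tuple[tuple[frozenset[MtVariant], int], ...]
    region: RegionSpec = HVR1

    def __post_init__(self) -> None:
        if self.treatment not in ("direct", "active_udg", "inactive_udg"):
            raise ValueError(f"unknown treatment {self.treatment!r}")
        if not self.clones or sum(n for _, n in self.clones) < 1:
            raise ValueError(f"{self.sample_id}: at least one clone required")

    @classmethod
    def from_variant_sets(cls, sample_id: str, treatment: str,
                          variant_sets: Iterable[Iterable[MtVariant]],
                          region: RegionSpec = HVR1) -> "CloneSet":
        counts = Counter(frozenset(vs) for vs in variant_sets)
        return cls(sample_id, treatment, tuple(sorted(
            counts.items(), key=lambda kv: sorted(v.sort_key() for v in kv[0]))),
            region)

    def depth(self) -> int:
        return sum(n for _, n in self.clones)

    def consensus_variants(self, min_fraction: float = 0.5) -> frozenset[MtVariant]:
        """Variants present in more than ``min_fraction`` of clones."""
        depth = self.depth()
        tally: Counter[MtVariant] = Counter()
        for variants, n in self.clones:
            for v in variants:
                tally[v] += n
        return frozenset(v for v, n in tally.items() if n > min_fraction * depth)

    def variant_fractions(self) -> dict[str, float]:
        """Per-variant clone support, for transparency reporting."""
        depth = self.depth()
        tally: Counter[MtVariant] = Counter()
        for variants, n in self.clones:
            for v in variants:
                tally[v] += n
        return {v.serialize(): n / depth
                for v, n in sorted(tally.items(), key=lambda kv: kv[0].sort_key())}


@dataclass(frozen=True)
class DamageCall:
    position: int
    change: tuple[str, str]  # ("C","T") or ("G","A")
    reverted_by_udg: bool

    def __post_init__(self) -> None:
        if self.change not in DEAMINATION_CHANGES:
            raise ValueError(f"{self.change}: not a deamination-consistent change")


@dataclass(frozen=True)
class DamageReport:
    calls: tuple[DamageCall, ...]
    anomalies: tuple[tuple[int, str, str], ...]  # non-deamination discrepancies
    clone_fractions: Mapping[str, Mapping[str, float]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Contamination screen
# ---------------------------------------------------------------------------


def screen_contamination(sample: MtHaplotype,
                         references: Iterable[MtHaplotype],
                         max_distance: int = 0) -> list[tuple[str, int]]:
    """References whose haplotype distance to the sample is <= max_distance.

    An empty list is a pass; any entry means the ancient haplotype cannot be
    told apart from a person who handled the sample.
    """
    references = list(references)
    if not references:
        raise ValueError("reference haplotype set is empty")
    hits = []
    for ref in references:
        d = haplotype_distance(sample, ref)
        if d <= max_distance:
            hits.append((ref.sample_id, d))
    return hits


# ---------------------------------------------------------------------------
# UDG damage detection
# ---------------------------------------------------------------------------


def _base_at(position: int, variants: frozenset[MtVariant] | tuple[MtVariant, ...],
             reference: str) -> str:
    """Observed base at a position: the substitution base if present, else rCRS."""
    for v in variants:
        if v.kind == "sub" and v.position == position:
            return v.base  # type: ignore[return-value]
    return reference[position - 1]


def detect_damage(direct: MtHaplotype, active: CloneSet, inactive: CloneSet,
                  min_clone_fraction: float = 0.5,
                  reference: str | None = None) -> DamageReport:
    """Compare clone consensuses against the direct sequence.

    A :class:`DamageCall` is emitted at every position where the
    inactive-UDG clone consensus differs from the direct haplotype by a
    C→T or G→A transition; it is flagged ``reverted_by_udg`` when the
    active-UDG consensus agrees with the direct sequence there.  Any other
    consensus discrepancy is reported as an anomaly, not damage.
    """
    if active.region != inactive.region:
        raise ValueError("clone sets cover different regions")
    reference = reference or synthetic_reference()
    region = inactive.region
    direct_vars = frozenset(v for v in direct.variants if region.contains(v.position))
    inactive_cons = inactive.consensus_variants(min_clone_fraction)
    active_cons = active.consensus_variants(min_clone_fraction)

    calls: list[DamageCall] = []
    anomalies: list[tuple[int, str, str]] = []
    diff_positions = sorted({v.position for v in direct_vars ^ inactive_cons})
    for pos in diff_positions:
        base_direct = _base_at(pos, direct_vars, reference)
        base_inactive = _base_at(pos, inactive_cons, reference)
        if base_direct == base_inactive:
            # indel-only discrepancy: deamination cannot create indels
            anomalies.append((pos, base_direct, base_inactive))
            continue
        if (base_direct, base_inactive) in DEAMINATION_CHANGES:
            reverted = _base_at(pos, active_cons, reference) == base_direct
            calls.append(DamageCall(pos, (base_direct, base_inactive), reverted))
        else:
            anomalies.append((pos, base_direct, base_inactive))
    return DamageReport(
        calls=tuple(calls),
        anomalies=tuple(anomalies),
        clone_fractions={
            "inactive_udg": inactive.variant_fractions(),
            "active_udg": active.variant_fractions()})
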