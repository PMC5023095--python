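"""Mitochondrial control-region haplotypes in forensic rCRS notation.

Human mtDNA haplotypes are conventionally reported as a list of differences
from the revised Cambridge Reference Sequence (rCRS): ``16223T`` is a
substitution, ``249del`` a deletion and ``309+C`` / ``310+3C`` insertions of
one and three bases after the anchor position.  This module parses and
serialises that notation, applies variant sets to a reference segment,
calls variants from a sampled sequence by exact global alignment, assigns
haplogroups from a loadable SNP rule tree and computes pairwise haplotype
distances for contamination screening.

Coordinates are 1-based rCRS positions throughout.  Indels inside
homopolymer runs are normalised to the 3' end of the run, the standard
forensic convention, so variant calling is deterministic.
"""

from __future__ import annotations

import csv
import functools
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import Align, SeqIO

RCRS_LENGTH = 16569

#: IUPAC codes that denote an ambiguous base (everything but A, C, G, T).
AMBIGUOUS_BASES = set("RYSWKMBDHVN")

_DATA_DIR = Path(__file__).parent / "data"


class VariantParseError(ValueError):
    """Raised for a malformed variant string."""


class VariantRangeError(ValueError):
    """Raised when a variant position falls outside 1..16569."""


class InvalidVariantError(ValueError):
    """Raised when a variant cannot be realised on the reference."""


class AmbiguousBaseWarning(UserWarning):
    """Emitted when an ambiguous IUPAC base is excluded from variant calling."""


# ---------------------------------------------------------------------------
# Regions and the synthetic reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionSpec:
    """A named 1-based, inclusive interval of the mitochondrial genome."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= RCRS_LENGTH):
            raise ValueError(f"invalid region {self.name}: {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


HVR1 = RegionSpec("HVR1", 15977, 16399)
HVR2 = RegionSpec("HVR2", 29, 381)

# Reference bases forced at positions that bundled fixtures and demos touch,
# so the synthetic reference behaves like the real one where it matters:
# the HVR2 C-tract (303-309 C, 310 T, 311-315 C) and a C at 16,250.
_REFERENCE_PATCHES: dict[int, str] = {
    **{p: "C" for p in range(303, 310)},
    310: "T",
    **{p: "C" for p in range(311, 316)},
    316: "G",
    16250: "C",
}
# Fixture substitution sites: reference base must differ from the variant
# base; where the fixture base is A or could be, use G instead.
_FIXTURE_SUB_SITES = {
    73: "A", 146: "A", 150: "A", 152: "A", 195: "A", 198: "A", 217: "A",
    249: "A", 263: "A", 290: "A", 291: "A",
    16092: "A", 16093: "A", 16129: "G", 16171: "A", 16172: "A", 16189: "A",
    16217: "A", 16223: "A", 16234: "A", 16257: "G", 16261: "A", 16262: "A",
    16266: "A", 16269: "A", 16271: "A", 16288: "A", 16298: "A", 16299: "A",
    16304: "A", 16311: "A", 16362: "A",
}
_REFERENCE_PATCHES.update(_FIXTURE_SUB_SITES)


@functools.lru_cache(maxsize=1)
def synthetic_reference() -> str:
    """Full-length synthetic mitochondrial reference (NOT the real rCRS).

    A deterministic 16,569-base stand-in that reproduces the structural
    features of the rCRS at every position the bundled fixtures exercise
    (HVR2 homopolymer tract, a C at 16,250, non-variant bases at fixture
    substitution sites).  It exists so that sequence-level operations are
    testable without shipping the real reference; analyses of real data
    should load the rCRS with :func:`read_fasta_region`.
    """
    # simple deterministic LCG so the sequence is stable across platforms
    bases = "ACGT"
    state = 2_463_534_242
    seq = []
    for _ in range(RCRS_LENGTH):
        state = (6_364_136_223_846_793_005 * state + 1_442_695_040_888_963_407) % 2**64
        seq.append(bases[(state >> 33) % 4])
    for pos, base in _REFERENCE_PATCHES.items():
        seq[pos - 1] = base
    # break accidental homopolymer runs adjacent to patched indel anchors
    seq[301] = "A"  # position 302
    seq[316] = "T"  # position 317
    return "".join(seq)


def region_segment(reference: str, region: RegionSpec) -> str:
    """Extract a region's sequence from a full-length reference."""
    if len(reference) != RCRS_LENGTH:
        raise ValueError("reference must be full length (16,569 bases)")
    return reference[region.start - 1 : region.end]


def read_fasta_region(path: str | Path) -> str:
    """Read a single-record FASTA (e.g. the real rCRS) and return its sequence."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


# ---------------------------------------------------------------------------
# Variant notation
# ---------------------------------------------------------------------------

_SUB_RE = re.compile(r"^(\d+)([ACGT])$")
_DEL_RE = re.compile(r"^(\d+)del$")
_INS_RE = re.compile(r"^(\d+)\+(\d*)([ACGT])$")
_DOT_RE = re.compile(r"^(\d+)\.(\d+)([ACGT])$")  # "309.1C" dialect


@dataclass(frozen=True)
class MtVariant:
    """A single difference from the reference.

    ``kind`` is one of ``"sub"``, ``"del"`` or ``"ins"``; ``base`` is the
    substituted/inserted base (None for deletions) and ``repeat_count`` the
    number of inserted copies (insertions only).
    """

    position: int
    kind: str
    base: str | None = None
    repeat_count: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.position <= RCRS_LENGTH):
            raise VariantRangeError(f"position {self.position} outside 1..{RCRS_LENGTH}")
        if self.kind not in ("sub", "del", "ins"):
            raise VariantParseError(f"unknown variant kind {self.kind!r}")
        if self.kind in ("sub", "ins") and self.base not in ("A", "C", "G", "T"):
            raise VariantParseError(f"invalid base {self.base!r}")
        if self.kind == "del" and self.base is not None:
            raise VariantParseError("deletions carry no base")
        if self.repeat_count < 1:
            raise VariantParseError("repeat_count must be positive")

    def sort_key(self) -> tuple[int, str, str, int]:
        return (self.position, self.kind, self.base or "", self.repeat_count)

    def serialize(self) -> str:
        if self.kind == "sub":
            return f"{self.position}{self.base}"
        if self.kind == "del":
            return f"{self.position}del"
        count = str(self.repeat_count) if self.repeat_count > 1 else ""
        return f"{self.position}+{count}{self.base}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.serialize()


def parse_variant(text: str) -> MtVariant:
    """Parse one canonical variant string (``16171G``, ``249del``, ``310+3C``).

    The alternative forensic dot dialect (``309.1C``) is also accepted; the
    trailing index is interpreted as the copy count of the inserted base, so
    ``310.3C`` round-trips to ``310+3C``.
    """
    text = text.strip()
    if m := _SUB_RE.match(text):
        return MtVariant(int(m.group(1)), "sub", m.group(2))
    if m := _DEL_RE.match(text):
        return MtVariant(int(m.group(1)), "del")
    if m := _INS_RE.match(text):
        count = int(m.group(2)) if m.group(2) else 1
        return MtVariant(int(m.group(1)), "ins", m.group(3), count)
    if m := _DOT_RE.match(text):
        return MtVariant(int(m.group(1)), "ins", m.group(3), int(m.group(2)))
    raise VariantParseError(f"malformed variant string: {text!r}")


def parse_variant_list(text: str) -> tuple[MtVariant, ...]:
    """Parse a whitespace- or comma-separated list of variant strings."""
    tokens = [t for t in re.split(r"[,\s]+", text.strip()) if t and t != "-"]
    return tuple(sorted((parse_variant(t) for t in tokens), key=MtVariant.sort_key))


# ---------------------------------------------------------------------------
# Haplotypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MtHaplotype:
    """A sample's control-region variants plus typed coding-region SNP calls."""

    sample_id: str
    variants: tuple[MtVariant, ...] = ()
    coding_calls: Mapping[int, str] = field(default_factory=dict)
    regions: tuple[RegionSpec, ...] = (HVR1, HVR2)

    def __post_init__(self) -> None:
        ordered = tuple(sorted(self.variants, key=MtVariant.sort_key))
        object.__setattr__(self, "variants", ordered)
        subs = [v.position for v in ordered if v.kind == "sub"]
        if len(subs) != len(set(subs)):
            raise ValueError(f"{self.sample_id}: multiple substitutions at one position")
        for v in ordered:
            if not any(r.contains(v.position) for r in self.regions):
                raise ValueError(
                    f"{self.sample_id}: variant {v} outside declared regions")
        for pos in self.coding_calls:
            if any(r.contains(pos) for r in self.regions):
                raise ValueError(
                    f"{self.sample_id}: coding call {pos} inside a control region")

    @classmethod
    def from_strings(cls, sample_id: str, hvr1: str, hvr2: str,
                     coding: str = "") -> "MtHaplotype":
        """Build a haplotype from table-style strings.

        ``coding`` is a comma-separated list of observed coding bases such
        as ``"3010A,5178A"``; ``"-"`` or empty means no coding calls.
        """
        variants = parse_variant_list(hvr1) + parse_variant_list(hvr2)
        calls: dict[int, str] = {}
        if coding.strip() not in ("", "-"):
            for token in re.split(r"[,\s]+", coding.strip()):
                if not token:
                    continue
                m = _SUB_RE.match(token)
                if not m:
                    raise VariantParseError(f"malformed coding call {token!r}")
                pos, base = int(m.group(1)), m.group(2)
                if pos in calls and calls[pos] != base:
                    raise ValueError(f"{sample_id}: conflicting coding calls at {pos}")
                calls[pos] = base
        return cls(sample_id, tuple(sorted(variants, key=MtVariant.sort_key)), calls)

    def variant_strings(self) -> tuple[str, ...]:
        return tuple(v.serialize() for v in self.variants)


def haplotype_distance(h1: MtHaplotype, h2: MtHaplotype) -> int:
    """Symmetric difference of the two variant sets over shared regions.

    Zero iff the haplotypes are identical over the regions both declare;
    used as the match criterion by the contamination screen.
    """
    shared = [r1 for r1 in h1.regions for r2 in h2.regions
              if r1.name == r2.name]
    if not shared:
        raise ValueError("haplotypes share no region")
    v1 = {v for v in h1.variants if any(r.contains(v.position) for r in shared)}
    v2 = {v for v in h2.variants if any(r.contains(v.position) for r in shared)}
    return len(v1 ^ v2)


# ---------------------------------------------------------------------------
# Applying and calling variants
# ---------------------------------------------------------------------------


def apply_variants(reference_segment: str, region: RegionSpec,
                   variants: Iterable[MtVariant]) -> str:
    """Realise a variant set on a reference region sequence.

    The inverse of :func:`call_variants`: substitutions replace the base at
    their position, deletions remove it and insertions add ``repeat_count``
    copies of ``base`` immediately after the anchor position.
    """
    if len(reference_segment) != len(region):
        raise ValueError("segment length does not match region span")
    edits = sorted(variants, key=lambda v: (v.position, v.kind))
    seen: set[tuple[int, str]] = set()
    for v in edits:
        if not region.contains(v.position):
            raise InvalidVariantError(f"{v} outside region {region.name}")
        key = (v.position, v.kind)
        if key in seen:
            raise InvalidVariantError(f"overlapping edits at {v.position}")
        seen.add(key)
    out = list(reference_segment)
    # right-to-left so earlier edits do not shift later coordinates
    for v in reversed(edits):
        i = v.position - region.start
        if v.kind == "sub":
            if out[i] == v.base:
                raise InvalidVariantError(
                    f"{v}: stated base equals the reference base")
            out[i] = v.base
        elif v.kind == "del":
            del out[i]
        else:
            out[i + 1 : i + 1] = [v.base] * v.repeat_count
    return "".join(out)


_ALIGNER = Align.PairwiseAligner()
_ALIGNER.mode = "global"
_ALIGNER.match_score = 0
_ALIGNER.mismatch_score = -1
_ALIGNER.open_gap_score = -1
_ALIGNER.extend_gap_score = -1


def _aligned_columns(reference: str, sample: str) -> list[tuple[str, str]]:
    """Column pairs (ref_char, sample_char) of one optimal global alignment."""
    alignment = _ALIGNER.align(reference, sample)[0]
    ref_aln, sample_aln = str(alignment[0]), str(alignment[1])
    return list(zip(ref_aln, sample_aln))


def call_variants(sample_sequence: str, region: RegionSpec,
                  reference_segment: str) -> tuple[MtVariant, ...]:
    """Call variants of a sampled region sequence against the reference.

    Exact global alignment with unit mismatch/gap costs (the regions are a
    few hundred bases, so dynamic programming is exact and fast), followed
    by 3'-normalisation of indels within homopolymer runs.  Ambiguous
    IUPAC bases are excluded from the variant set and reported through an
    :class:`AmbiguousBaseWarning`.
    """
    sample_sequence = sample_sequence.upper().replace("-", "")
    if not sample_sequence:
        raise ValueError("empty sample sequence")
    if len(reference_segment) != len(region):
        raise ValueError("segment length does not match region span")

    columns = _aligned_columns(reference_segment, sample_sequence)
    raw_subs: list[tuple[int, str]] = []
    raw_dels: list[int] = []
    raw_ins: list[tuple[int, str]] = []  # (anchor position, base)
    ambiguous: list[int] = []
    pos = region.start - 1  # last consumed reference position
    for ref_c, smp_c in columns:
        if ref_c != "-":
            pos += 1
        if ref_c == "-":
            raw_ins.append((pos, smp_c))
        elif smp_c == "-":
            raw_dels.append(pos)
        elif smp_c != ref_c:
            if smp_c in AMBIGUOUS_BASES:
                ambiguous.append(pos)
            else:
                raw_subs.append((pos, smp_c))

    ref = reference_segment

    def ref_base(p: int) -> str:
        return ref[p - region.start]

    variants: list[MtVariant] = [MtVariant(p, "sub", b) for p, b in raw_subs]

    for p in raw_dels:
        while p + 1 <= region.end and ref_base(p + 1) == ref_base(p):
            p += 1
        variants.append(MtVariant(p, "del"))

    # merge consecutive same-base insertions, then 3'-shift the anchor
    i = 0
    while i < len(raw_ins):
        anchor, base = raw_ins[i]
        count = 1
        while (i + count < len(raw_ins) and raw_ins[i + count] == (anchor, base)):
            count += 1
        while anchor + 1 <= region.end and ref_base(anchor + 1) == base:
            anchor += 1
        variants.append(MtVariant(max(anchor, region.start), "ins", base, count))
        i += count

    for p in ambiguous:
        warnings.warn(f"ambiguous base at position {p} excluded from variants",
                      AmbiguousBaseWarning, stacklevel=2)
    return tuple(sorted(variants, key=MtVariant.sort_key))


# ---------------------------------------------------------------------------
# Haplogroup classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HaplogroupRule:
    """One node of the haplogroup tree: a label and its defining SNPs."""

    label: str
    parent: str | None
    defining_snps: frozenset[tuple[int, str]]


class HaplogroupTree:
    """A rooted tree of :class:`HaplogroupRule` nodes.

    The bundled default encodes only the diagnostic coding SNPs the study
    fixtures carry (10398G for M; 4715G for CZ; 3394C for M9; 5178A for D;
    3010A for D4; 10398C+12705C for R); it is a plain TSV so a fuller motif
    table can be substituted.
    """

    def __init__(self, rules: Sequence[HaplogroupRule], root: str = "reference"):
        self.root = root
        self.nodes: dict[str, HaplogroupRule] = {}
        for rule in rules:
            if rule.label in self.nodes:
                raise ValueError(f"duplicate haplogroup label {rule.label}")
            self.nodes[rule.label] = rule
        if root not in self.nodes:
            raise ValueError(f"root node {root!r} missing")
        for rule in rules:
            if rule.label != root and rule.parent not in self.nodes:
                raise ValueError(f"{rule.label}: unknown parent {rule.parent}")
        # reject cycles
        for label in self.nodes:
            self.path(label)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HaplogroupTree":
        rules = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                snps = frozenset(
                    (int(m.group(1)), m.group(2))
                    for token in row["snps"].split(",")
                    if token.strip() not in ("", "-")
                    for m in [_SUB_RE.match(token.strip())]
                    if m)
                parent = None if row["parent"] == "-" else row["parent"]
                rules.append(HaplogroupRule(row["label"], parent, snps))
        return cls(rules)

    @classmethod
    def default(cls) -> "HaplogroupTree":
        return cls.from_tsv(_DATA_DIR / "mt_haplogroup_rules.tsv")

    def path(self, label: str) -> list[HaplogroupRule]:
        """Nodes from root (exclusive) down to ``label`` (inclusive)."""
        chain: list[HaplogroupRule] = []
        node = self.nodes[label]
        seen = set()
        while node.label != self.root:
            if node.label in seen:
                raise ValueError("haplogroup rules contain a cycle")
            seen.add(node.label)
            chain.append(node)
            node = self.nodes[node.parent]  # type: ignore[index]
        return list(reversed(chain))

    def depth(self, label: str) -> int:
        return len(self.path(label))


@dataclass(frozen=True)
class MtClassification:
    label: str
    matched_snps: frozenset[tuple[int, str]]
    unmatched_expected: frozenset[tuple[int, str]]


def classify_mt_haplogroup(haplotype: MtHaplotype,
                           tree: HaplogroupTree | None = None) -> MtClassification:
    """Assign the deepest haplogroup whose full root-path motif is observed.

    Observations are the typed coding-region calls plus control-region
    substitutions; a coding call takes priority over a control-region
    variant at the same position.  Pure function of its inputs: permuting
    variant order never changes the result.  With no matching rule the
    root ("reference"/undetermined) label is returned.
    """
    tree = tree or HaplogroupTree.default()
    observed: dict[int, str] = {}
    for v in haplotype.variants:
        if v.kind == "sub":
            observed[v.position] = v.base  # type: ignore[assignment]
    for pos, base in sorted(haplotype.coding_calls.items()):
        observed[pos] = base  # coding calls take priority

    def snps_observed(snps: Iterable[tuple[int, str]]) -> bool:
        return all(observed.get(p) == b for p, b in snps)

    best = tree.root
    best_depth = 0
    for label in sorted(tree.nodes):
        if label == tree.root:
            continue
        chain = tree.path(label)
        if all(snps_observed(node.defining_snps) for node in chain):
            depth = len(chain)
            if depth > best_depth:
                best, best_depth = label, depth
    matched = frozenset(
        snp for node in ([] if best == tree.root else tree.path(best))
        for snp in node.defining_snps)
    unmatched = frozenset(
        snp
        for label, node in tree.nodes.items()
        if label != tree.root and best in [n.label for n in tree.path(label)[:-1]]
        for snp in node.defining_snps
        if observed.get(snp[0]) != snp[1])
    return MtClassification(best, matched, unmatched)


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MtTableRow:
    """One row of a haplotype table (sample metadata plus haplotype)."""

    haplotype: MtHaplotype
    group: str
    lab: str
    sex_anth: str
    amel: str
    reported_haplogroup: str


def read_haplotype_table(path: str | Path) -> list[MtTableRow]:
    """Read a TSV haplotype table (sample, HVR1, HVR2, coding, haplogroup)."""
    rows = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            hap = MtHaplotype.from_strings(
                row["sample"], row["hvr1"], row["hvr2"], row.get("coding", ""))
            rows.append(MtTableRow(
                haplotype=hap,
                group=row.get("group", "body"),
                lab=row.get("lab", "-"),
                sex_anth=row.get("sex_anth", "-"),
                amel=row.get("amel", "-"),
                reported_haplogroup=row.get("haplogroup", "-")))
    return rows


def write_haplotype_table(path: str | Path, rows: Iterable[MtTableRow]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample", "group", "lab", "sex_anth", "amel",
                         "hvr1", "hvr2", "coding", "haplogroup"])
        for r in rows:
            h = r.haplotype
            hvr1 = " ".join(v.serialize() for v in h.variants
                            if HVR1.contains(v.position)) or "-"
            hvr2 = " ".join(v.serialize() for v in h.variants
                            if HVR2.contains(v.position)) or "-"
            coding = ",".join(f"{p}{b}" for p, b in sorted(h.coding_calls.items())) or "-"
            writer.writerow([h.sample_id, r.group, r.lab, r.sex_anth, r.amel,
                             hvr1, hvr2, coding, r.reported_haplogroup])


def load_fixture_haplotypes() -> list[MtTableRow]:
    """The bundled study haplotype table (both laboratories plus researchers)."""
    return read_haplotype_table(_DATA_DIR / "mt_haplotypes.tsv")
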