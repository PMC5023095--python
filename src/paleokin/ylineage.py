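"""Y-chromosome lineage analysis: biallelic-marker haplogroups and Y-STR matching.

Patrilineal origin is typed on a small hierarchical panel of biallelic
markers (M175, RPS4Y, M231, M174, M304, M242, M207, M173, M17, M343); the
derived state of each marker defines a haplogroup nested under its parent
(e.g. M343 defines R1b under R1-M173 under R-M207).  Y-STR haplotypes on
the 16-locus panel are compared locus-wise, with the duplicated DYS385
locus handled as an unordered multiset.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

_DATA_DIR = Path(__file__).parent / "data"

Y_STR_LOCI = (
    "DYS19", "DYS385", "DYS389I", "DYS389II", "DYS390", "DYS391", "DYS392",
    "DYS393", "DYS437", "DYS438", "DYS439", "DYS448", "DYS456", "DYS458",
    "DYS635", "YGATAH4",
)

#: Loci that may legitimately carry more than one allele in a haploid profile.
MULTI_COPY_LOCI = frozenset({"DYS385", "YGATAH4"})

MISSING_TOKENS = frozenset({"-", "ND", ""})


class InconsistentLineageError(ValueError):
    """Derived states observed on incompatible branches of the marker tree."""


# ---------------------------------------------------------------------------
# Marker panel and calls
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class YMarker:
    name: str
    haplogroup: str
    parent: str           # parent haplogroup ("root" at the top level)
    mutation: str         # "sub" or "del"
    ancestral: str        # observed value in the ancestral state
    derived: str          # observed value in the derived state


class YMarkerPanel:
    """A tree-structured panel of biallelic markers, keyed by marker name."""

    def __init__(self, markers: Iterable[YMarker]):
        self.markers: dict[str, YMarker] = {}
        self.by_haplogroup: dict[str, YMarker] = {}
        for m in markers:
            if m.name in self.markers or m.haplogroup in self.by_haplogroup:
                raise ValueError(f"duplicate marker/haplogroup {m.name}")
            self.markers[m.name] = m
            self.by_haplogroup[m.haplogroup] = m
        for m in self.markers.values():
            if m.parent != "root" and m.parent not in self.by_haplogroup:
                raise ValueError(f"{m.name}: unknown parent haplogroup {m.parent}")
            self.path(m.haplogroup)  # rejects cycles

    @classmethod
    def from_tsv(cls, path: str | Path) -> "YMarkerPanel":
        with open(path, newline="") as fh:
            return cls(YMarker(row["marker"], row["haplogroup"], row["parent"],
                               row["mutation"], row["ancestral"], row["derived"])
                       for row in csv.DictReader(fh, delimiter="\t"))

    @classmethod
    def default(cls) -> "YMarkerPanel":
        return cls.from_tsv(_DATA_DIR / "y_marker_panel.tsv")

    def path(self, haplogroup: str) -> list[YMarker]:
        """Markers from the top level down to ``haplogroup``, inclusive."""
        chain: list[YMarker] = []
        node = self.by_haplogroup[haplogroup]
        seen: set[str] = set()
        while True:
            if node.haplogroup in seen:
                raise ValueError("marker panel contains a cycle")
            seen.add(node.haplogroup)
            chain.append(node)
            if node.parent == "root":
                return list(reversed(chain))
            node = self.by_haplogroup[node.parent]

    def call_state(self, marker: str, raw_value: str) -> str:
        """Map a printed table value to ``ancestral``/``derived``/``missing``."""
        m = self.markers[marker]
        value = raw_value.strip()
        if value in MISSING_TOKENS:
            return "missing"
        if value == m.ancestral:
            return "ancestral"
        if value == m.derived or (m.mutation == "del" and "del" in value):
            return "derived"
        raise ValueError(f"{marker}: cannot interpret observed value {value!r}")


@dataclass(frozen=True)
class YMarkerCall:
    marker: str
    state: str  # ancestral | derived | missing

    def __post_init__(self) -> None:
        if self.state not in ("ancestral", "derived", "missing"):
            raise ValueError(f"invalid marker state {self.state!r}")


@dataclass(frozen=True)
class YClassification:
    label: str
    support: tuple[str, ...]   # derived markers observed on the accepted path
    inferred: bool             # some marker on the path was missing


def classify_y_haplogroup(calls: Iterable[YMarkerCall],
                          panel: YMarkerPanel | None = None) -> YClassification:
    """Deepest haplogroup whose defining marker is observed derived.

    A node is acceptable only if no defining marker on its root path is
    observed ancestral.  Missing intermediate markers do not block descent —
    the call is then flagged ``inferred`` (the study assigns R1b from a
    partial panel this way).  All-ancestral panels return the root label.
    Derived states on branches that are not nested within one another are an
    inconsistency and raise :class:`InconsistentLineageError`.
    """
    panel = panel or YMarkerPanel.default()
    states: dict[str, str] = {}
    for c in calls:
        if c.marker not in panel.markers:
            raise ValueError(f"unknown marker {c.marker}")
        if states.get(c.marker, c.state) != c.state:
            raise ValueError(f"conflicting calls for marker {c.marker}")
        states[c.marker] = c.state
    if all(s == "missing" for s in states.values()) or not states:
        raise ValueError("at least one non-missing call is required")

    derived = [panel.markers[name] for name, s in states.items() if s == "derived"]
    if not derived:
        return YClassification("root", (), False)

    # all derived markers must lie on a single root-to-leaf chain
    by_depth = sorted(derived, key=lambda m: len(panel.path(m.haplogroup)),
                      reverse=True)
    deepest = by_depth[0]
    chain_names = {m.name for m in panel.path(deepest.haplogroup)}
    clashes = sorted(m.name for m in derived if m.name not in chain_names)
    if clashes:
        raise InconsistentLineageError(
            f"derived states on incompatible branches: {deepest.name} vs "
            f"{', '.join(clashes)}")

    # accept the deepest derived node whose path carries no observed-ancestral
    # defining marker; shallower derived nodes are the fallback
    for node in by_depth:
        path = panel.path(node.haplogroup)
        if any(states.get(m.name) == "ancestral" for m in path):
            continue
        support = tuple(m.name for m in path if states.get(m.name) == "derived")
        inferred = any(states.get(m.name, "missing") == "missing" for m in path)
        return YClassification(node.haplogroup, support, inferred)
    raise InconsistentLineageError(
        "every derived marker is contradicted by an ancestral call on its path")


def read_marker_table(path: str | Path,
                      panel: YMarkerPanel | None = None
                      ) -> dict[str, tuple[YMarkerCall, ...]]:
    """Read a sample x marker TSV of printed values into marker calls."""
    panel = panel or YMarkerPanel.default()
    table: dict[str, tuple[YMarkerCall, ...]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            sample = row.pop("sample")
            table[sample] = tuple(
                YMarkerCall(marker, panel.call_state(marker, value))
                for marker, value in row.items())
    return table


def load_fixture_marker_calls() -> dict[str, tuple[YMarkerCall, ...]]:
    """Marker states of the three typable male bodies, as printed."""
    return read_marker_table(_DATA_DIR / "y_marker_calls.tsv")


# ---------------------------------------------------------------------------
# Y-STR profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class YStrProfile:
    """A haploid STR haplotype: locus -> multiset of allele labels.

    Allele labels are canonical strings ("13", "33.2"); DYS385 (and any
    multi-copy locus) carries up to two.  Missing loci are simply absent
    from the mapping.
    """

    sample_id: str
    loci: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for locus, alleles in self.loci.items():
            if not alleles:
                raise ValueError(f"{locus}: empty allele set; omit missing loci")
            if any(float(a) <= 0 for a in alleles):
                raise ValueError(f"{locus}: allele values must be positive")

    def definable(self) -> frozenset[str]:
        return frozenset(self.loci)


@dataclass(frozen=True)
class YMatchSummary:
    """Locus-wise comparison of two haploid profiles.

    ``identical + partial + mismatch == definable_both``; "partial" means a
    non-empty allele intersection that is not full multiset identity at a
    multi-copy locus.
    """

    definable_both: int
    identical: int
    partial: int
    mismatch: int
    mismatch_loci: tuple[str, ...] = ()
    partial_loci: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.identical + self.partial + self.mismatch != self.definable_both:
            raise ValueError("match categories must partition definable loci")


def _compare_locus(a: tuple[str, ...], b: tuple[str, ...]) -> str:
    """Compare allele multisets at one locus: identical/partial/mismatch.

    A single reported value at a multi-copy locus is one observed allele
    with the partner possibly dropped out, not a homozygote: it scores
    identical when the partner has no other distinct allele, partial when
    the partner carries a second distinct allele, mismatch when absent.
    """
    ma, mb = sorted(a), sorted(b)
    if ma == mb:
        return "identical"
    if len(ma) > len(mb):
        ma, mb = mb, ma
    if len(ma) == 1:
        if ma[0] in mb:
            return "identical" if len(set(mb)) == 1 else "partial"
        return "mismatch"
    return "partial" if set(ma) & set(mb) else "mismatch"


def compare_y_str(p1: YStrProfile, p2: YStrProfile) -> YMatchSummary:
    """Locus-wise match summary over loci definable in both profiles."""
    shared = sorted(p1.definable() & p2.definable())
    counts = {"identical": 0, "partial": 0, "mismatch": 0}
    by_category: dict[str, list[str]] = {"partial": [], "mismatch": []}
    for locus in shared:
        category = _compare_locus(tuple(p1.loci[locus]), tuple(p2.loci[locus]))
        counts[category] += 1
        if category in by_category:
            by_category[category].append(locus)
    return YMatchSummary(
        definable_both=len(shared),
        identical=counts["identical"],
        partial=counts["partial"],
        mismatch=counts["mismatch"],
        mismatch_loci=tuple(by_category["mismatch"]),
        partial_loci=tuple(by_category["partial"]))
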