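"""Replicate STR genotype tables, consensus calling and sex determination.

Low-template ancient DNA is typed in several independent PCR replicates
(here: repeated extractions in two laboratories); the per-locus consensus
is the genotype supported by a strict majority of the successful replicate
calls.  Non-unanimity marks a locus discordant; a tie between distinct
genotypes yields an explicit candidate set that downstream kinship analysis
expands into scenarios rather than averaging away.

Genotypes are multisets of allele labels: canonical strings such as "12" or
the microvariant "33.2".  At an autosomal (diploid) locus a single printed
value denotes an apparent homozygote and is stored as a pair; haploid Y
profiles keep single values as single alleles.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .ylineage import YStrProfile, Y_STR_LOCI

_DATA_DIR = Path(__file__).parent / "data"

ASTR_LOCI = ("D13S317", "D7S820", "D2S1338", "D21S11", "D16S359", "D18S51",
             "CSF1PO", "FGA")
AMELOGENIN = "Amel"

Genotype = tuple[str, ...]


def _allele_key(allele: str) -> tuple[float, str]:
    return (float(allele), allele)


def normalize_genotype(alleles: Iterable[str]) -> Genotype:
    """Canonical (sorted) allele tuple."""
    return tuple(sorted((a.strip() for a in alleles), key=_allele_key))


def parse_genotype(text: str, diploid: bool = True) -> Genotype | None:
    """Parse a table cell like ``"11/12"``, ``"13"`` or ``"-"`` (missing).

    With ``diploid=True`` a single value is recorded as an apparent
    homozygote (``"29"`` -> ``("29", "29")``), following how the replicate
    tables print them.
    """
    text = text.strip()
    if text in ("", "-", "ND"):
        return None
    alleles = [a for a in text.split("/") if a]
    for a in alleles:
        float(a)  # validates numeric allele labels
    if diploid and len(alleles) == 1:
        alleles = alleles * 2
    if len(alleles) > 2:
        raise ValueError(f"more than two alleles in {text!r}")
    return normalize_genotype(alleles)


def format_genotype(genotype: Genotype | None) -> str:
    return "/".join(genotype) if genotype else "-"


# ---------------------------------------------------------------------------
# Replicate tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Replicate:
    replicate_id: str
    lab_id: str
    calls: Mapping[str, Genotype | None]  # locus -> genotype, None = failed

    def is_failed(self) -> bool:
        return all(g is None for g in self.calls.values())


@dataclass(frozen=True)
class ReplicateTable:
    sample_id: str
    replicates: tuple[Replicate, ...]

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(f"{self.sample_id}: at least one replicate required")

    def loci(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rep in self.replicates:
            for locus in rep.calls:
                seen.setdefault(locus)
        return tuple(seen)


@dataclass(frozen=True)
class ConsensusCall:
    """Per-locus consensus: either one genotype or an ambiguous candidate set."""

    genotype: Genotype | None
    candidates: tuple[Genotype, ...]
    support: int           # replicates voting for the consensus (or top tie)
    n_typed: int           # successful replicate calls at the locus
    discordant: bool

    @property
    def ambiguous(self) -> bool:
        return self.genotype is None and len(self.candidates) > 1

    @property
    def missing(self) -> bool:
        return self.genotype is None and not self.candidates


@dataclass(frozen=True)
class ConsensusProfile:
    sample_id: str
    calls: Mapping[str, ConsensusCall] = field(default_factory=dict)

    def genotype(self, locus: str) -> Genotype | None:
        call = self.calls.get(locus)
        return call.genotype if call else None

    def candidate_genotypes(self, locus: str) -> tuple[Genotype, ...]:
        """The consensus genotype, or every candidate when ambiguous."""
        call = self.calls.get(locus)
        if call is None or call.missing:
            return ()
        return (call.genotype,) if call.genotype else call.candidates

    def discordant_loci(self) -> tuple[str, ...]:
        return tuple(l for l, c in self.calls.items() if c.discordant)


def call_consensus(table: ReplicateTable, min_fraction: float = 0.5,
                   min_count: int = 2,
                   loci: Sequence[str] | None = None) -> ConsensusProfile:
    """Majority consensus over successful replicate calls, per locus.

    A replicate votes for its whole genotype at the locus (genotype-level,
    not allele-level, voting).  The consensus is the genotype held by more
    than ``min_fraction`` of the successful calls and by at least
    ``min_count`` replicates; a tie among distinct genotypes produces an
    ambiguous candidate set.  Any non-unanimity sets ``discordant``.
    Wholly failed replicates contribute neither support nor discordance.
    """
    if not 0 < min_fraction:
        raise ValueError("min_fraction must be positive")
    loci = tuple(loci) if loci is not None else table.loci()
    calls: dict[str, ConsensusCall] = {}
    for locus in loci:
        votes = [rep.calls.get(locus) for rep in table.replicates]
        typed = [g for g in votes if g is not None]
        if not typed:
            calls[locus] = ConsensusCall(None, (), 0, 0, False)
            continue
        counts = Counter(typed)
        top_count = max(counts.values())
        leaders = sorted(g for g, c in counts.items() if c == top_count)
        discordant = len(counts) > 1
        if (len(leaders) == 1 and top_count > min_fraction * len(typed)
                and top_count >= min_count):
            calls[locus] = ConsensusCall(leaders[0], tuple(leaders), top_count,
                                         len(typed), discordant)
        else:
            calls[locus] = ConsensusCall(None, tuple(leaders), top_count,
                                         len(typed), discordant)
    return ConsensusProfile(table.sample_id, calls)


def count_discordances(tables: Iterable[ReplicateTable],
                       loci: Sequence[str] = ASTR_LOCI) -> tuple[int, int]:
    """(discordant_cells, total_cells) over a panel of loci.

    A cell (sample x locus) is discordant when its successful replicate
    calls are not unanimous; total is samples x loci.
    """
    tables = list(tables)
    discordant = 0
    for table in tables:
        profile = call_consensus(table, loci=loci)
        discordant += sum(1 for locus in loci if profile.calls[locus].discordant)
    return discordant, len(tables) * len(loci)


def sex_from_amelogenin(table: ReplicateTable) -> str:
    """XX / XY / ND by strict majority over successful amelogenin calls."""
    votes = Counter()
    for rep in table.replicates:
        g = rep.calls.get(AMELOGENIN)
        if g is not None:
            votes["".join(g)] += 1
    if not votes:
        return "ND"
    total = sum(votes.values())
    label, count = votes.most_common(1)[0]
    return label if count * 2 > total else "ND"


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------


def read_replicate_table(path: str | Path, diploid: bool = True,
                         amelogenin: bool = True) -> dict[str, ReplicateTable]:
    """Read a replicate TSV (sample, replicate[, lab], locus columns).

    "-" cells are missing calls.  Amelogenin cells (XX/XY) are kept verbatim
    as a two-allele genotype.  Haploid tables (``diploid=False``) keep single
    values as single alleles.
    """
    grouped: dict[str, list[Replicate]] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        meta = {"sample", "replicate", "lab"}
        for row in reader:
            calls: dict[str, Genotype | None] = {}
            for column, value in row.items():
                if column in meta:
                    continue
                if amelogenin and column == AMELOGENIN:
                    value = value.strip()
                    calls[AMELOGENIN] = tuple(value) if value not in ("-", "", "ND") else None
                else:
                    calls[column] = parse_genotype(value, diploid=diploid)
            grouped.setdefault(row["sample"], []).append(
                Replicate(row["replicate"], row.get("lab", "-"), calls))
    return {sample: ReplicateTable(sample, tuple(reps))
            for sample, reps in grouped.items()}


def write_consensus_table(path: str | Path,
                          profiles: Iterable[ConsensusProfile],
                          loci: Sequence[str]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["sample", *loci])
        for p in profiles:
            row = [p.sample_id]
            for locus in loci:
                call = p.calls.get(locus)
                if call is None or call.missing:
                    row.append("-")
                elif call.ambiguous:
                    row.append(" or ".join(format_genotype(g) for g in call.candidates))
                else:
                    row.append(format_genotype(call.genotype))
            writer.writerow(row)


def consensus_to_y_profile(profile: ConsensusProfile) -> YStrProfile:
    """Project a haploid consensus onto a Y-STR profile (missing loci dropped)."""
    loci = {}
    for locus in Y_STR_LOCI:
        g = profile.genotype(locus)
        if g is not None:
            loci[locus] = g
    return YStrProfile(profile.sample_id, loci)


def load_fixture_astr_replicates() -> dict[str, ReplicateTable]:
    """The bundled autosomal replicate table (6 bodies x 3 replicates)."""
    return read_replicate_table(_DATA_DIR / "astr_replicates.tsv", diploid=True)


def load_fixture_ystr_replicates() -> dict[str, ReplicateTable]:
    """The bundled Y-STR replicate table (3 males x 3 replicates)."""
    return read_replicate_table(_DATA_DIR / "y_str_replicates.tsv",
                                diploid=False, amelogenin=False)
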