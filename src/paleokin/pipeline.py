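"""End-to-end study orchestration.

``run_study`` executes the full molecular-genealogy analysis on a set of
input tables — replicate consensus, mtDNA haplogroup classification,
Y-haplogroup assignment, Y-STR matching, pairwise kinship with scenario
expansion, the trio Mendelian check and the authenticity screens — and
returns a deterministic, machine-readable report.  With no explicit inputs
the bundled study tables are used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import combinations
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import authenticity, kinship, mito, simulate, strprofiles, ylineage

logger = logging.getLogger("paleokin")

SCHEMA_VERSION = "1.0"

_DATA_DIR = Path(__file__).parent / "data"


@dataclass(frozen=True)
class StudyConfig:
    """Inputs and thresholds of one study run; round-trips through YAML."""

    haplotype_table: str = str(_DATA_DIR / "mt_haplotypes.tsv")
    y_marker_table: str = str(_DATA_DIR / "y_marker_calls.tsv")
    y_str_table: str = str(_DATA_DIR / "y_str_replicates.tsv")
    astr_table: str = str(_DATA_DIR / "astr_replicates.tsv")
    frequency_table: str = str(_DATA_DIR / "synthetic_allele_frequencies.tsv")
    min_fraction: float = 0.5
    min_count: int = 2
    frequency_floor: str | None = None  # e.g. "0.001"; exact decimal string
    max_contamination_distance: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        for path in (self.haplotype_table, self.y_marker_table,
                     self.y_str_table, self.astr_table, self.frequency_table):
            if not Path(path).exists():
                raise FileNotFoundError(path)

    def to_dict(self) -> dict[str, Any]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "StudyConfig":
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "StudyConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class StudyReport:
    """The full study output; every number is recomputable from the inputs."""

    payload: Mapping[str, Any] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.payload, sort_keys=True, indent=2)

    def __getitem__(self, key: str) -> Any:
        return self.payload[key]


def _fr(x: Fraction) -> dict[str, Any]:
    """Exact and float renderings of a Fraction for the report."""
    return {"exact": f"{x.numerator}/{x.denominator}", "value": float(x)}


def _stage(name: str):
    def decorator(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"study stage {name!r} failed: {exc}") from exc
        return wrapper
    return decorator


@_stage("consensus")
def _consensus_stage(config: StudyConfig) -> dict[str, Any]:
    tables = strprofiles.read_replicate_table(config.astr_table)
    loci = strprofiles.ASTR_LOCI
    profiles = {
        sample: strprofiles.call_consensus(
            table, config.min_fraction, config.min_count,
            loci=(strprofiles.AMELOGENIN, *loci))
        for sample, table in sorted(tables.items())}
    for sample, profile in profiles.items():
        for locus, call in profile.calls.items():
            if call.ambiguous:
                logger.info("ambiguous consensus at %s %s: candidates %s",
                            sample, locus,
                            " or ".join("/".join(g) for g in call.candidates))
    discordant, total = strprofiles.count_discordances(tables.values(), loci)
    section = {
        "profiles": {
            sample: {
                locus: {
                    "genotype": strprofiles.format_genotype(call.genotype),
                    "candidates": ["/".join(g) for g in call.candidates],
                    "support": call.support,
                    "n_typed": call.n_typed,
                    "discordant": call.discordant,
                } for locus, call in profile.calls.items()}
            for sample, profile in profiles.items()},
        "sex": {sample: strprofiles.sex_from_amelogenin(table)
                for sample, table in sorted(tables.items())},
        "discordant_cells": discordant,
        "total_cells": total,
    }
    return {"profiles": profiles, "tables": tables, "section": section}


@_stage("mt_classification")
def _mt_stage(config: StudyConfig) -> dict[str, Any]:
    rows = mito.read_haplotype_table(config.haplotype_table)
    tree = mito.HaplogroupTree.default()
    bodies: dict[str, list[mito.MtTableRow]] = {}
    researchers: list[mito.MtTableRow] = []
    for row in rows:
        if row.group == "researcher":
            researchers.append(row)
        else:
            bodies.setdefault(row.haplotype.sample_id, []).append(row)
    section: dict[str, Any] = {"samples": {}, "lab_concordant": {}}
    classified: dict[str, str] = {}
    for sample, sample_rows in sorted(bodies.items()):
        first = sample_rows[0].haplotype
        concordant = all(
            mito.haplotype_distance(first, r.haplotype) == 0
            and r.haplotype.coding_calls == first.coding_calls
            for r in sample_rows[1:])
        result = mito.classify_mt_haplogroup(first, tree)
        classified[sample] = result.label
        section["samples"][sample] = {
            "haplogroup": result.label,
            "matched_snps": sorted(f"{p}{b}" for p, b in result.matched_snps),
            "hvr_variants": list(first.variant_strings()),
        }
        section["lab_concordant"][sample] = concordant
    return {"bodies": bodies, "researchers": researchers,
            "classified": classified, "section": section}


@_stage("y_lineage")
def _y_stage(config: StudyConfig) -> dict[str, Any]:
    panel = ylineage.YMarkerPanel.default()
    marker_calls = ylineage.read_marker_table(config.y_marker_table, panel)
    y_tables = strprofiles.read_replicate_table(
        config.y_str_table, diploid=False, amelogenin=False)
    y_profiles = {
        sample: strprofiles.consensus_to_y_profile(
            strprofiles.call_consensus(table, config.min_fraction,
                                       config.min_count))
        for sample, table in sorted(y_tables.items())}
    section: dict[str, Any] = {"haplogroups": {}, "matches": {}}
    for sample, calls in sorted(marker_calls.items()):
        result = ylineage.classify_y_haplogroup(calls, panel)
        section["haplogroups"][sample] = {
            "label": result.label,
            "support": list(result.support),
            "inferred": result.inferred,
        }
    for s1, s2 in combinations(sorted(y_profiles), 2):
        summary = ylineage.compare_y_str(y_profiles[s1], y_profiles[s2])
        section["matches"][f"{s1}-{s2}"] = {
            "definable_both": summary.definable_both,
            "identical": summary.identical,
            "partial": summary.partial,
            "mismatch": summary.mismatch,
            "mismatch_loci": list(summary.mismatch_loci),
            "partial_loci": list(summary.partial_loci),
        }
    return {"section": section, "y_profiles": y_profiles}


@_stage("kinship")
def _kinship_stage(config: StudyConfig,
                   profiles: Mapping[str, strprofiles.ConsensusProfile]
                   ) -> dict[str, Any]:
    floor = Fraction(config.frequency_floor) if config.frequency_floor else None
    freqs = kinship.AlleleFrequencyTable.from_tsv(config.frequency_table,
                                                  floor=floor)
    loci = strprofiles.ASTR_LOCI
    section: dict[str, Any] = {"pairs": {}, "trio": {}}
    for s1, s2 in combinations(sorted(profiles), 2):
        results = kinship.classify_pair(profiles[s1], profiles[s2], freqs,
                                        loci=loci)
        scenarios = []
        for res in results:
            if res.scenario:
                logger.info("kinship %s-%s evaluated under scenario %s",
                            s1, s2, res.scenario)
            scenarios.append({
                "scenario": res.scenario,
                "exclusion_loci": list(res.exclusion_loci),
                "skipped_loci": list(res.skipped_loci),
                "combined_lr": {h: _fr(lr) for h, lr in res.combined.items()},
                "posterior": {h: _fr(p) for h, p in res.posteriors.items()},
            })
        section["pairs"][f"{s1}-{s2}"] = scenarios
    if {"MN0125", "MN0104", "MN0126"} <= set(profiles):
        trio = kinship.trio_mendelian_check(
            profiles["MN0125"], [profiles["MN0104"], profiles["MN0126"]],
            loci=loci)
        section["trio"] = {
            "mother": trio.mother,
            "per_child": {c: dict(r) for c, r in trio.per_child.items()},
            "compatible_counts": {
                c: list(n) for c, n in trio.compatible_counts().items()},
        }
    return {"section": section, "freqs": freqs}


@_stage("authenticity")
def _authenticity_stage(config: StudyConfig,
                        bodies: Mapping[str, list[mito.MtTableRow]],
                        researchers: list[mito.MtTableRow]) -> dict[str, Any]:
    reference_haps = [r.haplotype for r in researchers]
    section: dict[str, Any] = {"contamination": {}, "damage": {}}
    for sample, rows in sorted(bodies.items()):
        hits = (authenticity.screen_contamination(
            rows[0].haplotype, reference_haps, config.max_contamination_distance)
            if reference_haps else [])
        section["contamination"][sample] = {
            "passed": not hits,
            "matches": [{"reference": r, "distance": d} for r, d in hits],
        }
    # deterministic synthetic reconstruction of the damaged-clone comparison:
    # the direct haplotype of the damage-carrying sample, untreated clones all
    # carrying the deamination at 16,250 and UDG-repaired clones without it
    if "MN0376" in bodies:
        direct = bodies["MN0376"][0].haplotype
        sim = simulate.simulate_deamination(
            direct.variants, damage_rate=1.0, n_inactive=5, n_active=4,
            rng=config.seed, sample_id="MN0376", positions=[16250])
        report = authenticity.detect_damage(direct, sim.active, sim.inactive,
                                            config.min_fraction)
        section["damage"]["MN0376"] = {
            "calls": [{"position": c.position,
                       "change": f"{c.change[0]}->{c.change[1]}",
                       "reverted_by_udg": c.reverted_by_udg}
                      for c in report.calls],
            "anomalies": [list(a) for a in report.anomalies],
            "synthetic_reconstruction": True,
        }
    return {"section": section}


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Run every stage in order and assemble the versioned report.

    Deterministic on fixed inputs: running twice with the same config yields
    byte-identical JSON (stable ordering, no timestamps).  Any stage failure
    aborts with the stage name and the offending sample or locus in the
    message.
    """
    config = config or StudyConfig()
    cons = _consensus_stage(config)
    mt = _mt_stage(config)
    y = _y_stage(config)
    kin = _kinship_stage(config, cons["profiles"])
    auth = _authenticity_stage(config, mt["bodies"], mt["researchers"])

    mt_counts: dict[str, int] = {}
    for label in mt["classified"].values():
        mt_counts[label] = mt_counts.get(label, 0) + 1

    pair_0104_0126 = kin["section"]["pairs"].get("MN0104-MN0126", [])
    po_posteriors = [s["posterior"]["parent_offspring"]["value"]
                     for s in pair_0104_0126]
    summary = {
        "mt_haplogroup_counts": dict(sorted(mt_counts.items())),
        "astr_discordant_cells": cons["section"]["discordant_cells"],
        "astr_total_cells": cons["section"]["total_cells"],
        "parent_offspring_posterior_percent_MN0104_MN0126": (
            max(po_posteriors) * 100 if po_posteriors else None),
        "exclusion_loci_MN0104_MN0126": sorted({
            l for s in pair_0104_0126 for l in s["exclusion_loci"]}),
    }
    payload = {
        "schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "consensus": cons["section"],
        "mtdna": mt["section"],
        "y_lineage": y["section"],
        "kinship": kin["section"],
        "authenticity": auth["section"],
        "summary": summary,
    }
    return StudyReport(payload)
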