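# Methods

## Scope and data flow

The pipeline (`paleokin.pipeline.run_study`) executes, in order: replicate
consensus calling → mtDNA haplogroup classification → Y-haplogroup
assignment and Y-STR matching → pairwise kinship with scenario expansion and
the trio Mendelian check → authenticity screens. All inputs are plain TSV
tables; the bundled defaults are the printed genotype tables of a
seven-skeleton medieval aDNA study (six A-STR-typed bodies, three
Y-typed males, two laboratories' mtDNA haplotypes, five researcher
reference haplotypes). Every number in the report is recomputed from these
inputs on each run; the report is canonical JSON with stable key order and
no timestamps, so repeated runs are byte-identical.

## Replicate consensus

A replicate votes for its whole genotype at a locus (genotype-level, not
allele-level, voting — this is what makes 11/12 vs 12/12 a majority
decision rather than an allele tally). The consensus requires a strict
majority (`min_fraction = 0.5`) of the successful calls and at least
`min_count = 2` supporting replicates. Wholly failed replicates contribute
neither support nor discordance. Non-unanimity flags the cell discordant; a
tie between distinct genotypes is kept as an explicit candidate set.
The study text states its identity rule for sequence data over six
replicates ("identical in at least 5–6 experiments") while the printed STR
tables carry three replicates per sample; the thresholds are therefore
configurable, with strict majority as the default that reproduces every
printed consensus row, including the single ambiguous cell
(D21S11 = 30/30 or 30/33.2).

## mtDNA haplotypes

Variants are named in the forensic rCRS convention: `16223T` substitution,
`249del` deletion, `309+C` / `310+3C` insertions after the anchor position
with an optional copy count. The alternative dot dialect (`309.1C`) is read
but the plus dialect is canonical on output. Indels inside homopolymer runs
are normalised to the 3′ end of the run, so variant calling is
deterministic. Calling uses exact global alignment (unit mismatch and gap
costs); the regions are ≤ ~450 bp so dynamic programming is exact and fast.
Ambiguous IUPAC bases are excluded from the variant set with a warning —
heteroplasmy is not modelled.

The real rCRS is not shipped. Sequence-level operations in the tests and the
clone-reconstruction demo run against a deterministic **synthetic**
full-length reference (`mito.synthetic_reference`) that reproduces the
structural features the fixtures exercise: the HVR2 C-tract (303–309 C,
310 T, 311–315 C), a C at 16,250 and non-variant bases at every fixture
substitution site. Analyses of real data should load the actual rCRS FASTA
via `mito.read_fasta_region`.

Haplogroups are assigned from a loadable rule tree; the deepest node whose
entire root-path SNP motif is observed wins (ties broken by label, coding
calls taking priority over control-region variants at the same position).
The bundled tree encodes only the diagnostic coding SNPs the fixture tables
carry — 10398G → M; 4715G → CZ (within M); 3394C → M9 (within M);
5178A → D; 3010A → D4 (within D); 10398C + 12705C → R. D hangs off the
root rather than under M because the D4 samples were typed only at 3010 and
5178; a fuller motif table (e.g. a PhyloTree extract) can be substituted as
a TSV. Classification within CZ stops at CZ: the typed SNPs do not separate
C from Z. Researcher haplogroup labels in the fixture ("D4/G", "R9b") are
metadata — their defining coding SNPs were never typed — so the classifier
reports them as undetermined, by design.

## Y lineage

The ten-marker biallelic panel forms a tree (O, C, N, D, J, Q, R at the top
level; R1 under R; R1a1a and R1b under R1). The classifier returns the
deepest haplogroup whose defining marker is observed derived and whose path
carries no observed-ancestral defining marker; missing intermediate markers
do not block descent but flag the call `inferred` (this is how a partial
panel still yields R1b). Derived states on branches not nested within one
another raise an inconsistency error listing the clash.

Y-STR comparison counts, over loci definable in both profiles, identical /
partial / mismatch categories that always partition the definable set. A
single reported allele at a multi-copy locus (DYS385, and the occasionally
duplicated YGATAH4) is treated as one observed allele with the partner
possibly dropped out — *not* as a homozygote: it scores identical when
contained in a partner with no second distinct allele, partial when the
partner carries one, mismatch when absent. This convention reproduces the
7-identical + 1-shared count of the study pair. DYS389II is compared as
printed (no DYS389I subtraction).

## Kinship

Per-locus likelihood ratios use the Cotterman decomposition
LR = k₀ + k₁·T₁ + k₂·T₂ described in the README, with exact rational
arithmetic throughout; floats appear only at reporting. Design choices:

* **No-mutation model.** Any parent–offspring exclusion (zero shared
  alleles) zeroes that hypothesis exactly. A mutation-tolerant variant is
  out of scope.
* **Scenario expansion.** Ambiguous consensus loci are expanded
  combinatorially (at most two candidates per locus here) and each scenario
  is evaluated and reported separately — never averaged.
* **Priors.** Posteriors use a uniform prior over the evaluated hypothesis
  set, stated in every report.
* **Independence.** Loci multiply; no θ/co-ancestry correction, no
  inbreeding adjustment.
* **Frequencies.** The bundled allele-frequency table is explicitly
  synthetic (`synthetic_allele_frequencies.tsv`): the population reference
  table used by the original study is unpublished. Consequently the study's
  sibling-probability figures are not reproducible and are replaced by
  property-based checks: the exact LRs are validated against an independent
  Monte-Carlo pedigree oracle (10⁶ draws per genotype configuration on a
  3-allele locus, 3-SE agreement), and parameter recovery is demonstrated on
  simulated pairs (500 per relationship at the 8-locus panel: true
  parent–offspring pairs never show an exclusion; unrelated pairs show one
  at the exactly enumerated rate within 3 SE). Only the frequency-independent
  conclusions — exclusions, the 0% parent–offspring posterior — are asserted
  as numbers.
* An allele missing from the frequency table is an error unless a floor
  frequency is configured, in which case the substitution is recorded.

The trio check scores a locus compatible when mother and child share at
least one allele under some combination of their candidate genotypes;
ambiguity resolution is therefore optimistic but visible per locus.

## Authenticity

The contamination screen flags any reference haplotype within
`max_distance` (default 0) of a sample, where distance is the symmetric
difference of control-region variant sets over shared regions. Damage is
called at clone-consensus level (the study reports consensus comparisons),
with per-variant clone fractions emitted for transparency; both C→T and
G→A are accepted as deamination-consistent because strand is not tracked.
Consensus discrepancies that are not deamination-consistent transitions
(including indel-only differences) are reported as anomalies, never as
damage. The published 16,250 C→T / UDG-reversion example is exercised on a
synthetic reconstruction (direct haplotype plus clones carrying the planted
transition), since the original clone sequences are not printed.

## Synthetic data generator

`paleokin.simulate` draws founders under Hardy–Weinberg from a frequency
table, transmits autosomal alleles by Mendel's law, copies Y haplotypes
father→son and mtDNA mother→child, with no mutation anywhere — exactly the
assumptions of the inference modules, which is the point: it provides
planted truth for oracle tests, not a portrait of real populations. The
noise model covers whole-replicate failure, whole-locus dropout, allelic
dropout (heterozygote → apparent homozygote) and ±1-repeat misreads;
microvariant creation, stutter, peak heights and mixtures are not simulated.
Deamination is simulated per clone at rate `damage_rate` over eligible C/G
sites (optionally restricted to chosen positions), with active-UDG clones
carrying no damage. Everything is deterministic given a seed.

Passing tests on this generator therefore show internal consistency of the
inference chain under its own model — they do not certify performance on
real electropherograms, population substructure, or mutation.

## Problem sizes and numerical conventions

The bundled study is desk-scale (6 samples × 8 autosomal loci, 16 Y loci,
two control regions) and runs in well under a second. The statistical
checks use 10⁶ Monte-Carlo draws per genotype configuration for the LR
oracle, 500 simulated pairs per relationship for recovery, and 10⁴
randomized fixtures for the nomenclature/consensus invariants; all
tolerances are 3 standard errors of the corresponding estimator. Exact
rational arithmetic is used wherever a zero-versus-nonzero decision matters
(LRs, posteriors, frequency sums); alignment tie-breaks are resolved by the
3′ homopolymer convention; classification ties by depth are broken
lexicographically by label.

## Known limitations

* No probabilistic damage model (position-dependent deamination rates,
  read-level evidence) — damage detection is consensus-level.
* No haplogroup calling beyond the bundled/loadable SNP motifs; no
  phylogenetic placement against reference databases.
* Kinship is pairwise plus a trio Mendelian screen; joint likelihoods over
  larger pedigrees are not computed.
* The synthetic frequency table makes non-degenerate posteriors
  illustrative only; swap in a population table (TSV: locus, allele,
  frequency) for real casework-style numbers.
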