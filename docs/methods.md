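# Methods

This note documents the models and procedures `bmcscan` implements, the
parameters that matter, the synthetic data the pipeline is validated on,
and the design decisions taken where the design was genuinely open.

## Problem setting

Input is a cohort of annotated prokaryotic genomes: per genome a protein
FASTA and a gene-coordinate table (1-based inclusive coordinates, GFF3
convention; draft genomes with multiple contigs are supported and context
rules never span contigs). Curated knowledge travels in a *reference
bundle*: functional roles with labeled reference proteins, pathway rosters
with signature roles, shell-domain seed alignments, and a labeled glycyl
radical enzyme (GRE) reference set. The output is a set of typed BMC loci
per genome, standalone-enzyme calls, form tables, and phyletic summaries.

## Pairwise search and filter regimes

Alignment is optimal local Smith–Waterman–Gotoh, BLOSUM62, affine gaps
costing `11 + L` for a gap of length L (the standard protein-search
setting the thresholds below presuppose). The dynamic programming is
delegated to `Bio.Align.PairwiseAligner`; the test suite checks raw-score
equality against an independent exhaustive DP oracle on hundreds of random
pairs. Traceback is the library's deterministic one; on exactly tied
optimal tracebacks the per-column statistics could differ from another
aligner's choice, but scores never do.

Scores are normalized with Karlin–Altschul statistics,
`bits = (λ·raw − ln K)/ln 2` and `E = m·n·2^(−bits)`, with the gapped
BLOSUM62 constants λ = 0.267, K = 0.041; `n` is the summed length of the
searched proteome. Identity and positives use the full alignment length
including gap columns; query coverage is aligned query residues over query
length, single best alignment per pair (no HSP summation).

Three filter regimes, all comparisons inclusive:

| regime    | bits | E-value | identity | positives | coverage |
|-----------|------|---------|----------|-----------|----------|
| bbh       | ≥150 | ≤1e-50  | ≥30%     | ≥50%      | ≥70%     |
| shell     | ≥20  | ≤1e-5   | ≥30%     | ≥50%      | ≥40%     |
| evolution | ≥100 | ≤1e-30  | ≥30%     | —         | —        |

## Genomic context

Intergenic distance is the number of bases strictly between two adjacent
genes (`b.start − a.stop − 1`), floored at 0 for overlaps. Operons are
maximal co-oriented runs with every adjacent distance ≤ 100 bp; any
opposite-strand gene or contig end breaks the run; singletons are
one-gene operons. An operon's start is the translation start of its first
gene — leftmost coordinate on the + strand, rightmost on the − strand. A
divergon is an adjacent (−,+) operon pair whose start-to-start distance is
≤ 400 bp.

## Orthology with context support

Annotation propagates reference → genome (not all-vs-all): each reference
protein's best passing hit under the bbh regime nominates a candidate
gene, which is called when its own best hit back into the pooled reference
set belongs to the same role. Context support operationalizes "similar
genomic context": a call is *co-clustered* when its gene shares an operon
or divergon with another gene called for a different role of the same
pathway's role group (the pathway roster plus the shared shell roles), and
it is *supported* when that configuration exists for its role in more than
one species of the cohort (the witness set includes the call's own
species). Raw BBH calls and the context flag are both recorded, so either
policy can be reported downstream; locus assembly uses the raw calls and
reports the flag.

## Shell-protein classification

Shell detection is a two-stage filter: a gene must (1) pass the relaxed
shell regime against a shell reference protein and (2) carry a shell
domain confirmed by an ungapped PSSM scan. Profiles are built per family
(Pfam00936 for BMC-H/BMC-T, Pfam03319 for BMC-P) from seed alignments:
column log-odds `log2((f + w·b)/(1+w)/b)` with pseudocount weight
w = 0.1 against the Robinson–Robinson background; the gathering threshold
is the minimum seed self-score minus 2 bits (both config-exposed). Windows
at or above threshold are pruned greedily to a non-overlapping set by
descending score. One Pfam00936 hit → BMC-H, two or more → BMC-T (three or
more is collapsed to the tandem class and logged), Pfam03319 without
Pfam00936 → BMC-P; when both families hit, the higher-scoring family wins.
The PSSM replaces a live domain-database search so the pipeline runs
self-contained; results are therefore relative to the bundled seed
alignments.

## Locus assembly and typing

Candidate loci are maximal runs of member genes (shell proteins or
role-called genes) in which consecutive members are separated by at most 3
non-member genes and at most 5,000 bp (both invented, config-exposed: the
source procedure worked from manually curated clusters and never states a
boundary rule). Runs without a shell gene are not loci. Typing follows the
signature enzymes present: ethanolamine ammonia-lyase → Eut, propanediol
dehydratase (B12-dependent, or a GRE member tree-labeled PduC) → Pdu, a
GRE member tree-labeled CutC → Cut, the fucose/rhamnose aldolase → Pvm,
1-amino-2-propanol dehydrogenase → Aut, the ring-opening hydrolase of the
xanthine cluster → Xau. A B12-dependent dehydratase inside a cluster that
also carries Pvm-specific roles types the locus Pvm (a deterministic
tie-break encoding the observed co-localization in a fucose/rhamnose
cluster). Shell-only loci, or loci with conflicting signatures, are typed
`unknown` (with a warning for conflicts). Signature calls outside every
locus become standalone-enzyme calls; "associated with the BMC" means
*same locus* by default, with *same genome* available as a config switch.
Alternative forms of the phosphotransacylase (Pfam01515 / Pfam06130 /
HAD), the ethanolamine transporters (EutH / Eat / EatA), the choline
transporters (LicB / BetT / TRAP-like) and the two dehydratase types are
tabulated per genome.

## GRE tree pipeline

GRE queries are placed on a reference tree built by a deliberately
lightweight, deterministic stand-in for a full ML pipeline: progressive
alignment (3-mer cosine guide tree, profile–profile Needleman–Wunsch with
BLOSUM62 expected column scores, linear gap cost 8 per column; queries are
added to the cached reference alignment); removal of alignment columns
whose quality — mean BLOSUM62 score against the score-maximizing consensus
residue, gaps scoring −4 — is ≤ 0; Poisson-corrected distances
`−ln(1−p)` with pairwise gap deletion (capped at 10); neighbor joining
(scikit-bio; negative branch lengths clamped to zero; exact on additive
matrices); midpoint rooting. A query takes the label of the smallest
clade containing it whose labeled leaves are unanimous; if the first
labeled clade is mixed, the nearest labeled leaf by path length decides,
and an exact tie yields `unclassified`. Bootstrap support is not
computed; confidence comes from the held-out simulation benchmark
instead. The column-quality score is this module's own explicit
definition, chosen because the profile-space score of interactive
alignment viewers is version-dependent and unpublished.

## Synthetic data

The generators define the validation conditions. Reference proteins are
independent random sequences per role (Robinson–Robinson composition,
lengths 150–450; the lower bound keeps a perfect self-hit safely inside
the bbh e-value cutoff). Shell references embed actual seed-family
members between random flanks (20 residues; tandem linker 10), so they
score at or above the gathering threshold by construction. GRE families
are six independent 350-residue ancestors with three references each,
mutated at 5%, plus a single outgroup. Mutations substitute residues with
probability proportional to `p_b·2^(S(a,b)/2)` (no indels), so moderate
rates keep positives realistically high.

Cohorts place background genes (length ~ Normal(300, 60) floored at 50)
with uniform 150–600 bp gaps — never operonic by accident — and implants
as mutated reference copies with 20 bp operonic spacing on the + strand,
2 kb clear of their surroundings. Ground truth records every implanted
gene, role and pathway. The standard benchmark cohort is 20 genomes ×
25 background genes with all six pathways implanted in two distinct
species each; the mutation-rate curve uses a reduced three-pathway,
six-genome cohort, and the negative control uses 100 background-only
two-genome cohorts. These sizes keep the full validation in the
minutes range on a single CPU while exercising every stage.

What the generator does *not* emulate: indels and rearrangements, gene
family evolution (paralogs arise only as implanted copies), compositional
bias, shared ancestry between different roles, pseudogenes, and real
operon structure beyond the implanted clusters. Passing tests therefore
demonstrate the correctness of the decision rules and their wiring, not
recall on real proteomes, where homology is remote, domains circularly
permute, and role boundaries blur.

## Numerical and degenerate-input choices

- All randomness flows through seeded `numpy` generators; reference and
  cohort streams are domain-separated so a shared seed never replays
  reference sequences as background genes.
- A local alignment with no positive-scoring pair is a no-hit (`None`),
  not a zero-score hit.
- Percentages are exact decimal arithmetic, round half up at one decimal,
  trailing `.0` trimmed (13/646 → "2%", 21/646 → "3.3%"); round-half-even
  would print 3.2% there. One surveyed pair (70 of 646 printed as 10.7%)
  is inconsistent with any standard rounding of 10.835; the reporting
  module follows its own arithmetic (10.8%) and the discrepancy is noted
  here rather than reproduced.
- Two-leaf trees are midpoint-rooted explicitly (the general rerooting
  path degenerates there).
- `filter_columns` on an alignment losing every column, empty cohorts,
  empty proteomes, cross-contig distance queries, unknown regimes and
  ragged seed alignments are hard errors.
- Genomes with identical canonical content compare equal regardless of
  input row order; all writers round-trip losslessly.

## Known limitations

- Exhaustive alignment is quadratic per pair; the pipeline is meant for
  desk-scale cohorts (hundreds of genes per genome), not metagenome-scale
  search.
- The PSSM has no insert/delete states; a full profile HMM would be more
  sensitive to gapped shell domains.
- Operon prediction uses the two distance rules only — no promoter or
  terminator signals.
- Pathway chemistry (reaction orders, the two possible Aut scenarios) is
  carried as fixed reference metadata, not inferred.
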