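# bmcscan

Detection and classification of **bacterial microcompartment (BMC) loci**
in annotated prokaryotic genomes.

BMCs are organelle-like bodies enclosed by a semi-permeable protein shell.
Catabolic BMCs (metabolosomes) concentrate a pathway's signature enzyme
together with aldehyde/alcohol dehydrogenases and a phosphotransacylase,
sequestering a toxic aldehyde intermediate and recycling NAD⁺/NADH and CoA
internally. They are widespread in gut bacteria — ethanolamine and
1,2-propanediol utilization in particular are linked to enteric pathogens —
but annotating them is subtle: shell proteins come in three domain
architectures, and the signature enzymes include glycyl radical enzymes
(GREs) whose function cannot be told apart by similarity alone.

`bmcscan` implements the comparative-genomics procedure for this problem as
a reusable, tested pipeline for cohorts of annotated genomes:

- **Orthology**: best bidirectional hits (BBH) between curated reference
  proteins and each proteome, filtered at score ≥ 150 bits, E ≤ 1e-50,
  identity ≥ 30%, positives ≥ 50%, query coverage ≥ 70% (exact local
  alignment, BLOSUM62, affine gaps 11/1, Karlin–Altschul statistics with
  λ = 0.267, K = 0.041), accepted with *genomic context support*: the role
  must co-occur with other roles of its pathway in one operon or divergon
  in more than one species.
- **Genomic context**: genes form an operon when co-oriented with
  intergenic gaps ≤ 100 bp; two adjacent, divergently transcribed operons
  whose translation starts lie within 400 bp form a divergon.
- **Shell proteins**: homologs of shell references (score ≥ 20 bits,
  E ≤ 1e-5, identity ≥ 30%, positives ≥ 50%, coverage ≥ 40%) are kept only
  when a PSSM scan confirms a shell domain: one Pfam00936 domain → BMC-H,
  a tandem Pfam00936 repeat → BMC-T, a Pfam03319 domain → BMC-P.
- **Locus typing**: runs of shell + role genes become candidate loci and
  are assigned one of six pathway types — Pdu (1,2-propanediol), Eut
  (ethanolamine), Cut (choline), Pvm (fucose/rhamnose), Aut
  (1-amino-2-propanol/-one), Xau (xanthine) — from the signature enzymes
  present. GRE members (CutC vs PduC vs non-BMC functions DhaB, HpdB,
  HypD, PhdB) are first disambiguated on a labeled reference tree
  (progressive alignment → zero-quality column removal → Poisson-corrected
  neighbor joining → midpoint rooting → clade membership).
- **Reporting**: signature enzymes found outside any locus are reported as
  standalone calls; alternative transporter/phosphotransacylase forms are
  tabulated per genome; presence/absence matrices feed count/percentage
  summaries and per-phylum breakdowns.
- **Synthetic cohorts**: seeded generators build reference bundles and
  multi-species cohorts with implanted BMC clusters against random
  background genes, so every stage is testable end to end without
  downloads.

## Worked example

```bash
python examples/01_detect_loci.py
```

builds a six-genome cohort with an Eut cluster implanted in two species
and a Cut cluster in two others, then runs detection:

```
32 ortholog calls across 6 genomes

G001  contig_1:36323-43124  pathway=Eut  shell=3 genes  evidence=EutB
G002  contig_1:35145-41946  pathway=Eut  shell=3 genes  evidence=EutB
G003  contig_1:35635-40824  pathway=Cut  shell=2 genes  evidence=CutC
G004  contig_1:34880-40069  pathway=Cut  shell=2 genes  evidence=CutC
```

Each line is one assembled locus: its genomic span, the number of shell
genes, and the signature-enzyme evidence behind the pathway call — EutB
(ethanolamine ammonia-lyase) for Eut, and a GRE gene whose tree placement
labels it CutC (choline trimethylamine-lyase) for Cut. The two genomes
without implants produce no locus. The other scripts in `examples/` walk
through operon/divergon prediction, shell classification, GRE tree
placement and the presence/absence summaries.

The same pipeline is available from a shell:

```bash
bmcscan simulate --seed 5 --genomes 4 --implant Eut:0,1 --implant Cut:2,3 --out-dir demo/
bmcscan detect demo/ --out-dir out/
bmcscan report demo/ --seed 5 --out out/report.json
```

## Layout

- `src/bmcscan/` — the library (`model`, `io`, `align`, `context`,
  `orthology`, `shell`, `loci`, `phylo`, `simulate`, `pipeline`,
  `report`, `benchmarks`, `cli`)
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, parameters, design decisions, limitations
- `tests/` — unit, property and acceptance tests
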