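"""End-to-end orchestration: detect shell proteins and role orthologs,
assemble and type loci, call standalone enzymes and accessory forms."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

import math

from .align import local_align, passes, raw_align_score
from .config import DEFAULT_CONFIG, PipelineConfig
from .loci import (
    assemble_loci,
    call_accessory_forms,
    call_standalone_enzymes,
    classify_locus,
)
from .model import BMCLocus, Genome, OrthologCall, ReferenceBundle, ShellClass, StandaloneCall
from .orthology import annotate_roles
from .phylo import classify_gre
from .shell import build_shell_profiles, classify_shell

log = logging.getLogger(__name__)


@dataclass
class DetectionResult:
    """Everything the detection stage produces for a cohort."""

    calls: list[OrthologCall]
    shell_classes: dict[str, dict[str, ShellClass]]  # genome_id -> gene_id -> class
    loci: list[BMCLocus]
    standalone: list[StandaloneCall]
    forms: pd.DataFrame
    gre_labels: dict[str, dict[str, str]] = field(default_factory=dict)


def _shell_candidates(
    genome: Genome, bundle: ReferenceBundle, config: PipelineConfig
) -> list:
    """Genes passing the relaxed shell-homolog regime against shell references.

    Unlike the BBH search this keeps every passing gene, not just the best
    hit — one genome can carry many shell genes.  A raw-score prefilter
    derived from the regime's bit and e-value cutoffs avoids tracebacks for
    the overwhelmingly non-homologous background.
    """
    shell_refs = [
        (f"{r.role_id}::{src}", seq)
        for r in bundle.roles
        if r.domain_family in ("Pfam00936", "Pfam03319")
        for src, seq in r.reference_proteins
    ]
    db_len = genome.proteome_length
    regime = config.regimes["shell"]
    candidates = []
    for gene in genome.genes:
        for rid, ref_seq in shell_refs:
            min_bits = regime.min_bits or 0.0
            if regime.max_evalue:
                # E = m*n*2^-bits <= max_E  =>  bits >= log2(m*n/max_E)
                min_bits = max(
                    min_bits,
                    math.log2(len(ref_seq) * db_len / regime.max_evalue),
                )
            min_raw = (min_bits * math.log(2) + math.log(config.ka_k)) / config.ka_lambda
            if raw_align_score(ref_seq, gene.protein, config) < min_raw:
                continue
            hit = local_align(
                ref_seq,
                gene.protein,
                query_id=rid,
                target_id=gene.gene_id,
                config=config,
                db_length=db_len,
            )
            if hit is not None and passes(hit, regime, config):
                candidates.append(gene)
                break
    return candidates


def detect(
    genomes: list[Genome],
    bundle: ReferenceBundle,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> DetectionResult:
    """Run the full detection pipeline over a cohort.

    Stages: (1) role annotation by context-checked BBH; (2) shell-protein
    detection — homologs of shell references under the relaxed regime,
    kept only when a Pfam00936/Pfam03319 domain scan confirms the shell
    class; (3) GRE disambiguation on the reference tree; (4) locus
    assembly and pathway typing; (5) standalone-enzyme and form calls.
    """
    profiles = build_shell_profiles(bundle.seed_alignments, config)
    calls = annotate_roles(genomes, bundle, config)
    log.info("role annotation: %d ortholog calls", len(calls))

    shell_classes: dict[str, dict[str, ShellClass]] = {}
    for genome in genomes:
        per_gene: dict[str, ShellClass] = {}
        for gene in _shell_candidates(genome, bundle, config):
            sc = classify_shell(gene.protein, profiles)
            if sc.value != "none":
                per_gene[gene.gene_id] = sc
        shell_classes[genome.genome_id] = per_gene
    n_shell = sum(len(v) for v in shell_classes.values())
    log.info("shell detection: %d shell proteins", n_shell)

    # GRE disambiguation for genes called with a GRE-family role
    gre_labels: dict[str, dict[str, str]] = {}
    gre_queries: dict[str, list[tuple[str, str]]] = {}
    gene_lookup = {g.genome_id: g for g in genomes}
    for c in calls:
        if c.role_id in ("PduC-GRE", "CutC"):
            gene = gene_lookup[c.genome_id].gene(c.gene_id)
            gre_queries.setdefault(c.genome_id, []).append((c.gene_id, gene.protein))
    for genome_id, queries in gre_queries.items():
        # deduplicate genes hit by both GRE roles
        unique = list(dict(queries).items())
        gre_labels[genome_id] = classify_gre(bundle, unique)

    loci: list[BMCLocus] = []
    standalone: list[StandaloneCall] = []
    form_tables: list[pd.DataFrame] = []
    for genome in genomes:
        genome_loci = assemble_loci(
            genome, shell_classes[genome.genome_id], calls, config
        )
        labels = gre_labels.get(genome.genome_id, {})
        for locus in genome_loci:
            classify_locus(locus, bundle, labels)
        loci.extend(genome_loci)
        standalone.extend(
            call_standalone_enzymes(genome, calls, genome_loci, bundle, labels, config)
        )
        form_tables.append(call_accessory_forms(genome, calls))
    forms = (
        pd.concat(form_tables, ignore_index=True)
        if form_tables
        else pd.DataFrame(columns=["genome_id", "function", "form", "gene_id"])
    )
    log.info(
        "assembled %d loci, %d standalone calls", len(loci), len(standalone)
    )
    return DetectionResult(
        calls=calls,
        shell_classes=shell_classes,
        loci=loci,
        standalone=standalone,
        forms=forms,
        gre_labels=gre_labels,
    )


def evaluate_detection(
    loci: list[BMCLocus], truth: pd.DataFrame
) -> dict[str, float]:
    """Sensitivity and precision of locus detection + typing vs ground truth.

    An implanted cluster (ground-truth rows sharing genome and implant
    index, generated with shell genes) counts as recovered when a detected
    locus in that genome overlaps its genes and carries its pathway type; a
    detected locus is correct when it matches some implanted cluster the
    same way.
    """
    implants = []
    if not truth.empty:
        for (genome_id, idx), grp in truth[truth["with_shell"]].groupby(
            ["genome_id", "implant_index"]
        ):
            implants.append(
                {
                    "genome_id": genome_id,
                    "genes": set(grp["gene_id"]),
                    "pathway": grp["pathway"].iloc[0],
                }
            )

    def matches(locus: BMCLocus, implant: dict) -> bool:
        return (
            locus.genome_id == implant["genome_id"]
            and bool(set(locus.member_genes) & implant["genes"])
            and locus.pathway == implant["pathway"]
        )

    recovered = sum(
        any(matches(l, imp) for l in loci) for imp in implants
    )
    correct = sum(any(matches(l, imp) for imp in implants) for l in loci)
    sensitivity = recovered / len(implants) if implants else float("nan")
    precision = correct / len(loci) if loci else (1.0 if not implants else float("nan"))
    return {
        "n_implanted": len(implants),
        "n_detected": len(loci),
        "sensitivity": sensitivity,
        "precision": precision,
    }
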