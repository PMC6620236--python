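"""Locus assembly, six-pathway typing, standalone enzymes and form calls.

A candidate BMC locus is a maximal run of shell-protein genes and
BMC-role orthologs in which consecutive members are separated by at most a
few intervening genes and a bounded genomic gap; only runs containing at
least one shell gene become loci.  The pathway type (Pdu, Eut, Cut, Pvm,
Aut, Xau) follows from the signature enzymes present, with GRE-family
members first disambiguated on the reference tree, and the fucose/rhamnose
(Pvm) type taking precedence when a B12-dependent dehydratase sits inside
a cluster that also carries Pvm-specific roles.
"""

from __future__ import annotations

import logging

import pandas as pd

from .config import DEFAULT_CONFIG, PipelineConfig
from .context import intergenic_distance
from .model import (
    FORM_GROUPS,
    BMCLocus,
    Genome,
    OrthologCall,
    ReferenceBundle,
    ShellClass,
    StandaloneCall,
)

log = logging.getLogger(__name__)

#: GRE tree label -> the signature role it corresponds to (other GRE
#: functions are not BMC signatures)
GRE_LABEL_TO_ROLE = {"PduC": "PduC-GRE", "CutC": "CutC"}


def assemble_loci(
    genome: Genome,
    shell_classes: dict[str, ShellClass],
    calls: list[OrthologCall],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[BMCLocus]:
    """Cluster shell and BMC-role genes of one genome into candidate loci."""
    role_calls_by_gene: dict[str, set[str]] = {}
    for c in calls:
        if c.genome_id == genome.genome_id:
            role_calls_by_gene.setdefault(c.gene_id, set()).add(c.role_id)
    shell_genes = {
        gid for gid, sc in shell_classes.items() if sc.value != "none"
    }
    members = shell_genes | set(role_calls_by_gene)

    loci: list[BMCLocus] = []
    run: list = []
    intervening = 0

    def flush() -> None:
        nonlocal run
        if run:
            run_shell = [g.gene_id for g in run if g.gene_id in shell_genes]
            if run_shell:
                loci.append(
                    BMCLocus(
                        genome_id=genome.genome_id,
                        contig=run[0].contig,
                        member_genes=[g.gene_id for g in run],
                        shell_genes=run_shell,
                        role_calls={
                            (g.gene_id, r)
                            for g in run
                            for r in role_calls_by_gene.get(g.gene_id, ())
                        },
                        span=(run[0].start, max(g.stop for g in run)),
                    )
                )
        run = []

    prev_contig = None
    for gene in genome.genes:
        if gene.contig != prev_contig:
            flush()
            prev_contig = gene.contig
            intervening = 0
        if gene.gene_id not in members:
            intervening += 1
            if run and intervening > config.locus_max_intervening_genes:
                flush()
            continue
        if run and (
            intervening > config.locus_max_intervening_genes
            or intergenic_distance(run[-1], gene) > config.locus_max_gap_bp
        ):
            flush()
        run.append(gene)
        intervening = 0
    flush()
    return loci


def classify_locus(
    locus: BMCLocus,
    bundle: ReferenceBundle,
    gre_labels: dict[str, str] | None = None,
) -> str:
    """Assign a pathway type from the signature roles present in the locus.

    ``gre_labels`` maps gene ids of GRE-family members to their tree-derived
    function; a GRE member only counts as a signature when its label maps
    back to a BMC signature role.  Sets ``locus.pathway`` and
    ``locus.evidence`` and returns the pathway.
    """
    gre_labels = gre_labels or {}
    gre_roles = {r for r in ("PduC-GRE", "CutC") if _has_role(bundle, r)}
    signature_of: dict[str, str] = {}
    for pw, pd_ in bundle.pathways.items():
        for rid in pd_.signature_roles:
            signature_of[rid] = pw

    evidence: list[str] = []
    pathways: set[str] = set()
    for gene_id, role_id in sorted(locus.role_calls):
        effective = role_id
        if role_id in gre_roles:
            label = gre_labels.get(gene_id)
            if label is not None:
                effective = GRE_LABEL_TO_ROLE.get(label)
                if effective is None:
                    continue  # a non-BMC GRE function: no signature evidence
        if effective in signature_of:
            evidence.append(effective)
            pathways.add(signature_of[effective])

    pvm_specific = {
        r for r in bundle.pathways.get("Pvm", None).roles if _pathway_of_role(bundle, r) == "Pvm"
    } if "Pvm" in bundle.pathways else set()
    locus_roles = {r for _, r in locus.role_calls}

    if not pathways:
        pathway = "unknown"
    elif pathways == {"Pdu", "Pvm"} and locus_roles & pvm_specific:
        # B12-dependent dehydratase co-localized with the fucose/rhamnose BMC
        pathway = "Pvm"
    elif len(pathways) == 1:
        pathway = pathways.pop()
    else:
        log.warning(
            "locus %s:%s carries signatures of multiple pathways %s; typed unknown",
            locus.genome_id,
            locus.contig,
            sorted(pathways),
        )
        pathway = "unknown"
    locus.pathway = pathway
    locus.evidence = sorted(set(evidence))
    return pathway


def _has_role(bundle: ReferenceBundle, role_id: str) -> bool:
    return any(r.role_id == role_id for r in bundle.roles)


def _pathway_of_role(bundle: ReferenceBundle, role_id: str) -> str:
    return bundle.role(role_id).pathway


def call_standalone_enzymes(
    genome: Genome,
    calls: list[OrthologCall],
    loci: list[BMCLocus],
    bundle: ReferenceBundle,
    gre_labels: dict[str, str] | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[StandaloneCall]:
    """Signature-enzyme orthologs not associated with any BMC locus.

    With ``standalone_scope == "locus"`` (default) a signature gene outside
    every locus is standalone; with ``"genome"`` it is standalone only when
    the genome carries no locus of that pathway at all.
    """
    gre_labels = gre_labels or {}
    signature_of: dict[str, str] = {}
    for pw, pd_ in bundle.pathways.items():
        for rid in pd_.signature_roles:
            signature_of[rid] = pw
    gre_roles = {r for r in ("PduC-GRE", "CutC") if _has_role(bundle, r)}
    locus_genes = {
        g for l in loci if l.genome_id == genome.genome_id for g in l.member_genes
    }
    locus_pathways = {l.pathway for l in loci if l.genome_id == genome.genome_id}

    out: list[StandaloneCall] = []
    for c in calls:
        if c.genome_id != genome.genome_id:
            continue
        effective = c.role_id
        if c.role_id in gre_roles:
            label = gre_labels.get(c.gene_id)
            if label is not None:
                effective = GRE_LABEL_TO_ROLE.get(label)
                if effective is None:
                    continue
        if effective not in signature_of:
            continue
        pathway = signature_of[effective]
        if config.standalone_scope == "genome":
            associated = pathway in locus_pathways
        else:
            associated = c.gene_id in locus_genes
        if not associated:
            out.append(
                StandaloneCall(
                    genome_id=genome.genome_id,
                    gene_id=c.gene_id,
                    role_id=effective,
                    pathway=pathway,
                )
            )
    return out


def call_accessory_forms(
    genome: Genome, calls: list[OrthologCall]
) -> pd.DataFrame:
    """Which form of each multi-form function a genome carries.

    Covers the three phosphotransacylase forms (Pfam01515 / Pfam06130 /
    HAD), the three ethanolamine transporters (EutH / Eat / EatA), the
    three choline transporters (LicB / BetT / TRAP-like) and the two
    propanediol dehydratase types (B12-dependent / GRE).
    """
    rows = []
    for group, form_roles in FORM_GROUPS.items():
        for c in calls:
            if c.genome_id == genome.genome_id and c.role_id in form_roles:
                rows.append(
                    {
                        "genome_id": genome.genome_id,
                        "function": group,
                        "form": c.role_id,
                        "gene_id": c.gene_id,
                    }
                )
    return pd.DataFrame(rows, columns=["genome_id", "function", "form", "gene_id"])


__all__ = [
    "assemble_loci",
    "classify_locus",
    "call_standalone_enzymes",
    "call_accessory_forms",
    "GRE_LABEL_TO_ROLE",
]
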