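"""Best-bidirectional-hit orthology with genomic-context support.

Annotation propagates from curated reference proteins to genome proteomes:
a gene is called for a role when the reference's best hit in the proteome
and the gene's best hit back into the reference set pick each other's role,
both passing the strict ortholog filter regime.  A call gains genomic
context support when the role co-occurs with other roles of the same
pathway in one operon or divergon, and that configuration exists in more
than one microbial species of the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .align import local_align, passes, raw_align_score
from .config import DEFAULT_CONFIG, PipelineConfig
from .context import predict_divergons, predict_operons
from .model import (
    AlignmentHit,
    BmcscanError,
    Genome,
    OrthologCall,
    ReferenceBundle,
)


def _min_raw_for_bits(min_bits: float, config: PipelineConfig) -> float:
    """Smallest raw score whose bit score can reach ``min_bits`` (prefilter)."""
    return (min_bits * math.log(2) + math.log(config.ka_k)) / config.ka_lambda


def best_hit(
    query: str,
    proteome: list[tuple[str, str]],
    regime: str = "bbh",
    *,
    query_id: str = "query",
    config: PipelineConfig = DEFAULT_CONFIG,
    db_length: Optional[int] = None,
) -> Optional[AlignmentHit]:
    """Best passing hit of ``query`` against a proteome, or ``None``.

    "Best" is maximal bit score among hits passing the regime, ties broken
    by lower e-value and then lexicographic target id.  Raw scores are
    computed for every target (exhaustive search); the full alignment with
    its percentage statistics is only evaluated for candidates whose raw
    score could clear the regime's bit threshold.
    """
    if not proteome:
        raise BmcscanError("best_hit: empty proteome")
    if db_length is None:
        db_length = sum(len(seq) for _, seq in proteome)
    t = config.regimes[regime] if isinstance(regime, str) else regime
    min_raw = _min_raw_for_bits(t.min_bits, config) if t.min_bits else 0.0

    scored = sorted(
        ((raw_align_score(query, seq, config), tid, seq) for tid, seq in proteome),
        key=lambda x: (-x[0], x[1]),
    )
    for raw, tid, seq in scored:
        if raw <= 0 or raw < min_raw:
            break  # sorted descending: nothing below can pass
        hit = local_align(
            query,
            seq,
            query_id=query_id,
            target_id=tid,
            config=config,
            db_length=db_length,
        )
        if hit is not None and passes(hit, t, config):
            return hit
    return None


def bidirectional_best_hits(
    genome_a: Genome,
    genome_b: Genome,
    regime: str = "bbh",
    config: PipelineConfig = DEFAULT_CONFIG,
) -> list[tuple[str, str]]:
    """Reciprocal best-hit gene pairs between two genomes (symmetric)."""
    prot_a = [(g.gene_id, g.protein) for g in genome_a.genes]
    prot_b = [(g.gene_id, g.protein) for g in genome_b.genes]
    best_ab = {
        g.gene_id: h.target_id
        for g in genome_a.genes
        if (h := best_hit(g.protein, prot_b, regime, query_id=g.gene_id, config=config))
    }
    best_ba = {
        g.gene_id: h.target_id
        for g in genome_b.genes
        if (h := best_hit(g.protein, prot_a, regime, query_id=g.gene_id, config=config))
    }
    return sorted(
        (a, b) for a, b in best_ab.items() if best_ba.get(b) == a
    )


@dataclass
class CohortContext:
    """Precomputed operon/divergon membership for a cohort."""

    #: (genome_id, gene_id) -> list of unit keys the gene belongs to
    units_of_gene: dict[tuple[str, str], list[tuple]]
    #: unit key -> set of (genome_id, gene_id)
    genes_of_unit: dict[tuple, set[tuple[str, str]]]
    species_of_genome: dict[str, str]


def build_cohort_context(
    genomes: list[Genome], config: PipelineConfig = DEFAULT_CONFIG
) -> CohortContext:
    units_of_gene: dict[tuple[str, str], list[tuple]] = {}
    genes_of_unit: dict[tuple, set[tuple[str, str]]] = {}
    species = {}
    for genome in genomes:
        if not genome.species:
            raise BmcscanError(f"genome {genome.genome_id}: missing species label")
        species[genome.genome_id] = genome.species
        operons = predict_operons(genome, config)
        for i, op in enumerate(operons):
            key = ("op", genome.genome_id, i)
            members = {(genome.genome_id, gid) for gid in op.gene_ids}
            genes_of_unit[key] = members
            for m in members:
                units_of_gene.setdefault(m, []).append(key)
        for i, div in enumerate(predict_divergons(operons, config)):
            key = ("div", genome.genome_id, i)
            members = {(genome.genome_id, gid) for gid in div.gene_ids}
            genes_of_unit[key] = members
            for m in members:
                units_of_gene.setdefault(m, []).append(key)
    return CohortContext(units_of_gene, genes_of_unit, species)


def context_support(
    calls: list[OrthologCall],
    ctx: CohortContext,
    role_groups: dict[str, set[str]],
) -> list[OrthologCall]:
    """Evaluate genomic-context support for each call (fills flags in place).

    A call is *co-clustered* when its gene shares an operon or divergon with
    another gene called for a different role of the same pathway role group.
    The witnesses of a co-clustered call are the species in which such a
    configuration exists for its role anywhere in the cohort; support
    requires witnesses from more than one species.
    """
    calls_by_gene: dict[tuple[str, str], set[str]] = {}
    for c in calls:
        calls_by_gene.setdefault((c.genome_id, c.gene_id), set()).add(c.role_id)

    def co_clustered(call: OrthologCall) -> bool:
        group = role_groups.get(call.role_id, set())
        me = (call.genome_id, call.gene_id)
        for unit in ctx.units_of_gene.get(me, []):
            for other in ctx.genes_of_unit[unit]:
                if other == me:
                    continue
                if calls_by_gene.get(other, set()) & group:
                    return True
        return False

    witnesses_by_role: dict[str, set[str]] = {}
    flags = [co_clustered(c) for c in calls]
    for c, ok in zip(calls, flags):
        if ok:
            witnesses_by_role.setdefault(c.role_id, set()).add(
                ctx.species_of_genome[c.genome_id]
            )
    for c, ok in zip(calls, flags):
        c.context_witnesses = set(witnesses_by_role.get(c.role_id, set())) if ok else set()
        c.context_supported = len(c.context_witnesses) >= 2
    return calls


def annotate_roles(
    genomes: list[Genome],
    bundle: ReferenceBundle,
    config: PipelineConfig = DEFAULT_CONFIG,
    regime: str = "bbh",
) -> list[OrthologCall]:
    """Propagate every reference role to every genome by context-checked BBH.

    For each role and genome, each reference protein's best passing hit
    nominates a candidate gene; the candidate is called when its own best
    hit back into the pooled reference set belongs to the same role.
    Context support is then evaluated cohort-wide.
    """
    ref_proteome = [
        (f"{role.role_id}::{src}", seq)
        for role in bundle.roles
        for src, seq in role.reference_proteins
    ]
    ref_role_of = {key: key.split("::", 1)[0] for key, _ in ref_proteome}
    ref_db_len = sum(len(s) for _, s in ref_proteome)

    calls: list[OrthologCall] = []
    for genome in genomes:
        proteome = [(g.gene_id, g.protein) for g in genome.genes]
        if not proteome:
            continue
        db_len = genome.proteome_length
        seen: set[tuple[str, str]] = set()
        for role in bundle.roles:
            for src, ref_seq in role.reference_proteins:
                fwd = best_hit(
                    ref_seq,
                    proteome,
                    regime,
                    query_id=f"{role.role_id}::{src}",
                    config=config,
                    db_length=db_len,
                )
                if fwd is None or (role.role_id, fwd.target_id) in seen:
                    continue
                gene = genome.gene(fwd.target_id)
                rev = best_hit(
                    gene.protein,
                    ref_proteome,
                    regime,
                    query_id=gene.gene_id,
                    config=config,
                    db_length=ref_db_len,
                )
                if rev is None or ref_role_of[rev.target_id] != role.role_id:
                    continue
                seen.add((role.role_id, fwd.target_id))
                calls.append(
                    OrthologCall(
                        role_id=role.role_id,
                        genome_id=genome.genome_id,
                        gene_id=gene.gene_id,
                        forward_hit=fwd,
                        reverse_hit=rev,
                    )
                )

    ctx = build_cohort_context(genomes, config)
    role_groups = {
        role.role_id: bundle.role_group(role.pathway) for role in bundle.roles
    }
    return context_support(calls, ctx, role_groups)


__all__ = [
    "best_hit",
    "bidirectional_best_hits",
    "build_cohort_context",
    "context_support",
    "annotate_roles",
    "CohortContext",
]
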