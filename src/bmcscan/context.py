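"""Operon and divergon prediction from gene coordinates.

Two distance rules drive everything here: co-oriented adjacent genes whose
intergenic gap does not exceed 100 bp form an operon, and a pair of adjacent,
divergently transcribed operons whose translation starts lie within 400 bp
form a divergon.  The start of an operon is the translation start of its
first gene — the leftmost coordinate on the + strand, the rightmost on the
− strand.  Contig ends always break operons; no circular wrap-around.
"""

from __future__ import annotations

from .config import DEFAULT_CONFIG, PipelineConfig
from .model import BmcscanError, Divergon, Gene, Genome, Operon


def intergenic_distance(a: Gene, b: Gene) -> int:
    """Bases strictly between two genes, ``a`` leftmost; overlaps clamp to 0."""
    if a.contig != b.contig:
        raise BmcscanError(
            f"genes {a.gene_id!r} and {b.gene_id!r} lie on different contigs"
        )
    return max(0, b.start - a.stop - 1)


def predict_operons(
    genome: Genome, config: PipelineConfig = DEFAULT_CONFIG
) -> list[Operon]:
    """Partition all genes into maximal co-oriented runs.

    Any strand switch, contig boundary or gap above the operon rule breaks a
    run; singletons are one-gene operons.  Genes of a − strand operon are
    returned in transcription order (right to left).
    """
    operons: list[Operon] = []
    run: list[Gene] = []

    def flush() -> None:
        if not run:
            return
        genes = run[::-1] if run[0].strand == "-" else list(run)
        operons.append(Operon(genes=genes, strand=run[0].strand, contig=run[0].contig))
        run.clear()

    for gene in genome.genes:  # canonical order: contig, then leftmost coordinate
        if run and (
            gene.contig != run[-1].contig
            or gene.strand != run[-1].strand
            or intergenic_distance(run[-1], gene) > config.operon_gap_bp
        ):
            flush()
        run.append(gene)
    flush()
    return operons


def predict_divergons(
    operons: list[Operon], config: PipelineConfig = DEFAULT_CONFIG
) -> list[Divergon]:
    """All adjacent (−,+) operon pairs with translation-start gap within rule.

    Operons must come from one genome; adjacency means no other operon (hence
    no other gene) lies between the two first genes.
    """
    # restore genomic order: operons sorted by contig and leftmost coordinate
    ordered = sorted(operons, key=lambda op: (op.contig, min(g.start for g in op.genes)))
    divergons: list[Divergon] = []
    for left, right in zip(ordered, ordered[1:]):
        if left.contig != right.contig:
            continue
        if left.strand == "-" and right.strand == "+":
            gap = right.start - left.start
            if 0 <= gap <= config.divergon_start_gap_bp:
                divergons.append(Divergon(left_operon=left, right_operon=right))
    return divergons


__all__ = ["intergenic_distance", "predict_operons", "predict_divergons"]
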