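"""Readers and writers for genomes, reference bundles and result tables.

Genomes arrive as a protein FASTA plus a gene-coordinate table, either a
TSV with columns ``genome_id, species, phylum, contig, gene_id, start,
stop, strand`` (1-based inclusive coordinates) or a GFF3 file of CDS
features carrying ``ID=`` attributes.  Reference bundles are JSON.  All
writers emit plain text (TSV/JSON) and round-trip losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

from .model import (
    BMCLocus,
    BmcscanError,
    Gene,
    Genome,
    GreReference,
    OrthologCall,
    PathwayDefinition,
    ReferenceBundle,
    ReferenceRole,
    StandaloneCall,
)

GENE_TABLE_COLUMNS = [
    "genome_id",
    "species",
    "phylum",
    "contig",
    "gene_id",
    "start",
    "stop",
    "strand",
]


def _read_fasta(fasta_path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}


def read_gene_table(
    path: str | Path,
    fasta_path: str | Path,
    *,
    genome_id: Optional[str] = None,
    species: Optional[str] = None,
    phylum: Optional[str] = None,
) -> Genome:
    """Read one genome from a gene table (TSV or GFF3) plus a protein FASTA.

    For GFF3 input the genome-level labels come from ``#!genome-id``,
    ``#!species`` and ``#!phylum`` directives, overridable by the keyword
    arguments (which are required if the directives are absent).
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows, meta = _parse_gff3(path)
        genome_id = genome_id or meta.get("genome-id")
        species = species or meta.get("species")
        phylum = phylum or meta.get("phylum", "")
        if not genome_id or not species:
            raise BmcscanError(
                f"{path}: GFF3 input needs genome-id and species "
                "(directives or keyword arguments)"
            )
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise BmcscanError(f"{path}: missing columns {sorted(missing)}")
        if df.empty:
            raise BmcscanError(f"{path}: empty gene table")
        ids = df["genome_id"].unique()
        if len(ids) > 1:
            raise BmcscanError(f"{path}: multiple genome_ids in one table: {ids}")
        genome_id = genome_id or ids[0]
        species = species or df["species"].iloc[0]
        phylum = phylum or df["phylum"].iloc[0]
        rows = [
            (r.contig, r.gene_id, int(r.start), int(r.stop), r.strand)
            for r in df.itertuples()
        ]

    proteins = _read_fasta(fasta_path)
    genes = []
    for contig, gene_id, start, stop, strand in rows:
        if gene_id not in proteins:
            raise BmcscanError(
                f"gene {gene_id!r}: no protein record in {fasta_path}"
            )
        genes.append(
            Gene(
                gene_id=gene_id,
                contig=contig,
                start=start,
                stop=stop,
                strand=strand,
                protein=proteins[gene_id],
            )
        )
    return Genome(genome_id=genome_id, species=species, phylum=phylum or "", genes=genes)


def _parse_gff3(path: Path) -> tuple[list[tuple], dict[str, str]]:
    """CDS features with ID attributes (via gffutils); ``#!key value`` pragmas."""
    import gffutils

    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#!"):
                key, _, value = line[2:].rstrip("\n").partition(" ")
                meta[key] = value
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    rows: list[tuple] = []
    for feature in db.features_of_type("CDS"):
        if "ID" not in feature.attributes:
            raise BmcscanError(f"{path}: CDS without ID attribute at {feature.start}")
        rows.append(
            (
                feature.seqid,
                feature.attributes["ID"][0],
                int(feature.start),
                int(feature.end),
                feature.strand,
            )
        )
    return rows, meta


def write_gene_table(genome: Genome, table_path: str | Path, fasta_path: str | Path) -> None:
    """Write a genome back to TSV + FASTA (inverse of :func:`read_gene_table`)."""
    df = pd.DataFrame(
        [
            {
                "genome_id": genome.genome_id,
                "species": genome.species,
                "phylum": genome.phylum,
                "contig": g.contig,
                "gene_id": g.gene_id,
                "start": g.start,
                "stop": g.stop,
                "strand": g.strand,
            }
            for g in genome.genes
        ],
        columns=GENE_TABLE_COLUMNS,
    )
    df.to_csv(table_path, sep="\t", index=False)
    with open(fasta_path, "w") as fh:
        for g in genome.genes:
            fh.write(f">{g.gene_id}\n{g.protein}\n")


def write_gff3(genome: Genome, path: str | Path) -> None:
    """Write gene coordinates as GFF3 CDS features with metadata directives."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"#!genome-id {genome.genome_id}\n")
        fh.write(f"#!species {genome.species}\n")
        fh.write(f"#!phylum {genome.phylum}\n")
        for g in genome.genes:
            fh.write(
                f"{g.contig}\tbmcscan\tCDS\t{g.start}\t{g.stop}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# reference bundle (JSON)
# ---------------------------------------------------------------------------


def read_reference_bundle(path: str | Path) -> ReferenceBundle:
    """Load a JSON reference bundle and validate its invariants."""
    with open(path) as fh:
        raw = json.load(fh)
    roles = [
        ReferenceRole(
            role_id=r["role_id"],
            description=r.get("description", ""),
            pathway=r["pathway"],
            signature=bool(r["signature"]),
            domain_family=r.get("domain_family"),
            reference_proteins=[tuple(p) for p in r["reference_proteins"]],
        )
        for r in raw["roles"]
    ]
    pathways = {
        name: PathwayDefinition(
            pathway=name,
            roles=list(pd_raw["roles"]),
            signature_roles=list(pd_raw["signature_roles"]),
        )
        for name, pd_raw in raw["pathways"].items()
    }
    seeds = {
        fam: [tuple(row) for row in rows]
        for fam, rows in raw.get("seed_alignments", {}).items()
    }
    gre = [
        GreReference(seq_id=g["seq_id"], family=g["family"], sequence=g["sequence"])
        for g in raw.get("gre_references", [])
    ]
    return ReferenceBundle(
        roles=roles, pathways=pathways, seed_alignments=seeds, gre_references=gre
    )


def write_reference_bundle(bundle: ReferenceBundle, path: str | Path) -> None:
    raw = {
        "roles": [
            {
                "role_id": r.role_id,
                "description": r.description,
                "pathway": r.pathway,
                "signature": r.signature,
                "domain_family": r.domain_family,
                "reference_proteins": [list(p) for p in r.reference_proteins],
            }
            for r in bundle.roles
        ],
        "pathways": {
            name: {"roles": pd_.roles, "signature_roles": pd_.signature_roles}
            for name, pd_ in bundle.pathways.items()
        },
        "seed_alignments": {
            fam: [list(row) for row in rows]
            for fam, rows in bundle.seed_alignments.items()
        },
        "gre_references": [
            {"seq_id": g.seq_id, "family": g.family, "sequence": g.sequence}
            for g in bundle.gre_references
        ],
    }
    with open(path, "w") as fh:
        json.dump(raw, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------


def ortholog_table(calls: list[OrthologCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "role_id": c.role_id,
                "genome_id": c.genome_id,
                "gene_id": c.gene_id,
                "bit_score": round(c.forward_hit.bit_score, 1),
                "evalue": c.forward_hit.evalue,
                "identity_pct": round(c.forward_hit.identity_pct, 1),
                "coverage_pct": round(c.forward_hit.query_coverage_pct, 1),
                "context_supported": c.context_supported,
                "witnesses": ";".join(sorted(c.context_witnesses)),
            }
            for c in calls
        ],
        columns=[
            "role_id",
            "genome_id",
            "gene_id",
            "bit_score",
            "evalue",
            "identity_pct",
            "coverage_pct",
            "context_supported",
            "witnesses",
        ],
    )


def locus_table(loci: list[BMCLocus]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": l.genome_id,
                "contig": l.contig,
                "span_start": l.span[0],
                "span_stop": l.span[1],
                "members": ";".join(l.member_genes),
                "shell_genes": ";".join(l.shell_genes),
                "pathway": l.pathway,
                "evidence": ";".join(l.evidence),
            }
            for l in loci
        ],
        columns=[
            "genome_id",
            "contig",
            "span_start",
            "span_stop",
            "members",
            "shell_genes",
            "pathway",
            "evidence",
        ],
    )


def standalone_table(calls: list[StandaloneCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "gene_id": c.gene_id,
                "role_id": c.role_id,
                "pathway": c.pathway,
            }
            for c in calls
        ],
        columns=["genome_id", "gene_id", "role_id", "pathway"],
    )


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def write_json_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
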