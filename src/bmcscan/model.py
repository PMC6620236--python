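"""Core domain objects for BMC locus detection.

The pipeline reasons about annotated prokaryotic genomes: protein-coding
genes with 1-based inclusive coordinates on contigs, grouped into genomes
carrying species and phylum labels.  Reference knowledge (functional roles,
pathway rosters, shell-domain seed alignments, glycyl-radical-enzyme
reference families) travels as a :class:`ReferenceBundle`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted in input proteins (X = unknown)
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")

#: the six BMC pathway types
PATHWAYS = ("Pdu", "Eut", "Cut", "Pvm", "Aut", "Xau")

#: legal pathway values for a reference role
ROLE_PATHWAYS = PATHWAYS + ("shared", "none")

DOMAIN_FAMILIES = (
    "Pfam00936",  # BMC-H / BMC-T shell domain
    "Pfam03319",  # BMC-P shell domain
    "Pfam01515",  # phosphate acetyl/butyryl transferase (EutD form)
    "Pfam06130",  # phosphate propanoyltransferase (PduL-like form)
    "Pfam12710",  # HAD family (Fusobacterial phosphotransacylase form)
    "Pfam01636",  # APH phosphotransferase (AutD)
    "Pfam02417",  # ChrA family (EatA transporter)
    "other",
)

#: GRE reference family labels used for phylogenetic disambiguation
GRE_FAMILIES = ("CutC", "DhaB", "HpdB", "HypD", "PduC", "PhdB")
GRE_OUTGROUP = "PflB-outgroup"


class BmcscanError(ValueError):
    """Base class for validation and input errors."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene: 1-based inclusive coordinates, leftmost start."""

    gene_id: str
    contig: str
    start: int
    stop: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise BmcscanError(
                f"gene {self.gene_id!r}: start {self.start} > stop {self.stop}"
            )
        if self.strand not in ("+", "-"):
            raise BmcscanError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")
        if not self.protein:
            raise BmcscanError(f"gene {self.gene_id!r}: empty protein")
        bad = set(self.protein) - PROTEIN_ALPHABET
        if bad:
            raise BmcscanError(
                f"gene {self.gene_id!r}: non-amino-acid characters {sorted(bad)}"
            )

    @property
    def translation_start(self) -> int:
        """Coordinate of the start of translation.

        For a + strand gene this is the leftmost (start) coordinate; for a
        − strand gene translation begins at the rightmost (stop) coordinate.
        """
        return self.start if self.strand == "+" else self.stop


@dataclass
class Genome:
    """An annotated genome with canonically ordered genes.

    Genes are ordered by (contig, start, stop, gene_id); the ordering is
    re-established on construction so it is independent of input row order.
    """

    genome_id: str
    species: str
    phylum: str
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            raise BmcscanError(f"genome {self.genome_id!r}: species label required")
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise BmcscanError(
                    f"genome {self.genome_id!r}: duplicate gene_id {g.gene_id!r}"
                )
            seen.add(g.gene_id)
        self.genes = sorted(
            self.genes, key=lambda g: (g.contig, g.start, g.stop, g.gene_id)
        )

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def proteome_length(self) -> int:
        return sum(len(g.protein) for g in self.genes)


@dataclass
class ReferenceRole:
    """A curated functional role with labeled reference proteins."""

    role_id: str
    description: str
    pathway: str
    signature: bool
    reference_proteins: list[tuple[str, str]]
    domain_family: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pathway not in ROLE_PATHWAYS:
            raise BmcscanError(
                f"role {self.role_id!r}: unknown pathway {self.pathway!r}"
            )
        if self.domain_family is not None and self.domain_family not in DOMAIN_FAMILIES:
            raise BmcscanError(
                f"role {self.role_id!r}: unknown domain family {self.domain_family!r}"
            )
        if not self.reference_proteins:
            raise BmcscanError(f"role {self.role_id!r}: no reference proteins")


@dataclass
class PathwayDefinition:
    """Role roster for one pathway; signature roles define the pathway call."""

    pathway: str
    roles: list[str]
    signature_roles: list[str]


@dataclass
class GreReference:
    """A labeled reference sequence for the glycyl radical enzyme tree."""

    seq_id: str
    family: str  # one of GRE_FAMILIES or GRE_OUTGROUP
    sequence: str


@dataclass
class ReferenceBundle:
    """Everything the pipeline knows a priori.

    ``seed_alignments`` maps shell domain family -> list of (id, aligned row);
    rows are equal length, '-' for gaps.
    """

    roles: list[ReferenceRole]
    pathways: dict[str, PathwayDefinition]
    seed_alignments: dict[str, list[tuple[str, str]]]
    gre_references: list[GreReference] = field(default_factory=list)

    def __post_init__(self) -> None:
        role_ids = {r.role_id for r in self.roles}
        for pd in self.pathways.values():
            unknown = set(pd.roles) - role_ids
            if unknown:
                raise BmcscanError(
                    f"pathway {pd.pathway}: undeclared roles {sorted(unknown)}"
                )
            if not pd.signature_roles:
                raise BmcscanError(f"pathway {pd.pathway}: no signature role")
            for rid in pd.signature_roles:
                if rid not in pd.roles:
                    raise BmcscanError(
                        f"pathway {pd.pathway}: signature role {rid!r} not in roster"
                    )

    def role(self, role_id: str) -> ReferenceRole:
        for r in self.roles:
            if r.role_id == role_id:
                return r
        raise KeyError(role_id)

    def role_group(self, pathway: str) -> set[str]:
        """Roles expected to co-cluster for a pathway: its roster plus the
        shared shell roles.  For 'shared' roles the group is every BMC role."""
        shared = {r.role_id for r in self.roles if r.pathway == "shared"}
        if pathway == "shared":
            return {r.role_id for r in self.roles if r.pathway != "none"}
        if pathway == "none":
            return set()
        return set(self.pathways[pathway].roles) | shared

    @property
    def gre_role_ids(self) -> set[str]:
        """Roles whose members belong to the GRE superfamily and need
        phylogenetic disambiguation before a locus is typed."""
        return {
            r.role_id
            for r in self.roles
            if r.domain_family == "other" and r.role_id in ("PduC-GRE", "CutC")
        }


@dataclass
class Operon:
    """Maximal run of co-oriented genes with intergenic gaps <= the operon rule."""

    genes: list[Gene]  # transcription order
    strand: str
    contig: str

    @property
    def start(self) -> int:
        """Translation start of the first gene (transcription order)."""
        return self.genes[0].translation_start

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class Divergon:
    """A pair of adjacent, divergently transcribed operons with nearby starts."""

    left_operon: Operon  # − strand, genomically left
    right_operon: Operon  # + strand, genomically right

    @property
    def start_gap(self) -> int:
        return self.right_operon.start - self.left_operon.start

    @property
    def gene_ids(self) -> list[str]:
        return self.left_operon.gene_ids + self.right_operon.gene_ids


@dataclass(frozen=True)
class AlignmentHit:
    """A scored local alignment between a query and a target protein."""

    query_id: str
    target_id: str
    raw_score: int
    bit_score: float
    evalue: float
    identity_pct: float
    positives_pct: float
    query_coverage_pct: float
    query_span: tuple[int, int]  # 1-based inclusive on the query
    target_span: tuple[int, int]


@dataclass
class OrthologCall:
    """A best-bidirectional-hit role assignment, with genomic-context evidence."""

    role_id: str
    genome_id: str
    gene_id: str
    forward_hit: AlignmentHit
    reverse_hit: AlignmentHit
    context_supported: bool = False
    context_witnesses: set[str] = field(default_factory=set)


@dataclass
class ShellClass:
    """Shell classification of one protein from its domain hits."""

    value: str  # BMC-H | BMC-T | BMC-P | none
    domain_hits: list[tuple[str, tuple[int, int], float]] = field(default_factory=list)


@dataclass
class BMCLocus:
    """A clustered set of shell + enzyme genes with an assigned pathway type."""

    genome_id: str
    contig: str
    member_genes: list[str]  # ordered by coordinate
    shell_genes: list[str]
    role_calls: set[tuple[str, str]]  # (gene_id, role_id)
    pathway: str = "unknown"
    evidence: list[str] = field(default_factory=list)  # signature roles found
    span: tuple[int, int] = (0, 0)  # leftmost/rightmost coordinate of members


@dataclass
class StandaloneCall:
    """A signature-enzyme ortholog found outside every BMC locus."""

    genome_id: str
    gene_id: str
    role_id: str
    pathway: str


#: functional groups whose alternative forms the paper tracks per genome
FORM_GROUPS: dict[str, list[str]] = {
    "phosphotransacylase": ["EutD", "EutD-PduL", "EutD-HAD"],
    "ethanolamine_transporter": ["EutH", "Eat", "EatA"],
    "choline_transporter": ["LicB", "BetT", "TrapT"],
    "propanediol_dehydratase": ["PduC-B12", "PduC-GRE"],
}
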