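"""Seeded generators for reference bundles and synthetic genome cohorts.

The generators emulate the structure the detector assumes: multi-species
cohorts of gene-dense prokaryotic genomes in which BMC gene clusters
(shell proteins plus pathway enzymes, operonic spacing) are implanted
against a background of random genes whose spacing can never satisfy the
operon rule by accident.  Reference proteins are synthetic random
sequences per functional role — role distinguishability under the strict
BBH regime is a property of the construction (independent sequences do
not align) — so the whole pipeline is testable without any downloads.

Everything is deterministic in the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd

from .align import _matrix
from .model import (
    AMINO_ACIDS,
    GRE_FAMILIES,
    GRE_OUTGROUP,
    BmcscanError,
    Gene,
    Genome,
    GreReference,
    PathwayDefinition,
    ReferenceBundle,
    ReferenceRole,
)
from .shell import ROBINSON_FREQS

_AA = np.array(list(AMINO_ACIDS))
_BG = np.array([ROBINSON_FREQS[aa] for aa in AMINO_ACIDS])
_BG = _BG / _BG.sum()


@lru_cache(maxsize=1)
def _substitution_probs() -> np.ndarray:
    """P(b | a) for mutating residue a, BLOSUM62-conditional.

    Substitution targets are drawn with probability proportional to
    ``p_b * 2^(S(a,b)/2)`` over b != a, so moderate mutation rates keep the
    positives fraction of an alignment realistically high.
    """
    m = _matrix("BLOSUM62")
    probs = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            if i != j:
                probs[i, j] = _BG[j] * 2.0 ** (m[a, b] / 2.0)
        probs[i] /= probs[i].sum()
    return probs


def random_protein(rng: np.random.Generator, length: int) -> str:
    """Random protein with Robinson–Robinson residue frequencies."""
    return "".join(rng.choice(_AA, size=length, p=_BG))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each residue with probability ``rate`` (no indels)."""
    if not 0 <= rate < 0.5:
        raise BmcscanError(f"mutation rate {rate} outside [0, 0.5)")
    if rate == 0:
        return seq
    probs = _substitution_probs()
    idx = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    out = []
    hits = rng.random(len(seq)) < rate
    for aa, hit in zip(seq, hits):
        if hit and aa in idx:
            out.append(str(rng.choice(_AA, p=probs[idx[aa]])))
        else:
            out.append(aa)
    return "".join(out)


# ---------------------------------------------------------------------------
# reference bundle
# ---------------------------------------------------------------------------

#: (role_id, description, pathway, signature, domain_family)
ROLE_SPECS: list[tuple[str, str, str, bool, Optional[str]]] = [
    # shell proteins (shared across all BMC types)
    ("BmcH", "BMC-H hexameric shell protein", "shared", False, "Pfam00936"),
    ("BmcT", "BMC-T tandem-domain shell protein", "shared", False, "Pfam00936"),
    ("BmcP", "BMC-P pentameric vertex protein", "shared", False, "Pfam03319"),
    # ethanolamine utilization
    ("EutB", "ethanolamine ammonia-lyase, large subunit", "Eut", True, None),
    ("EutC", "ethanolamine ammonia-lyase, small subunit", "Eut", False, None),
    ("EutE", "acetaldehyde dehydrogenase", "Eut", False, None),
    ("EutG", "alcohol dehydrogenase", "Eut", False, None),
    ("EutD", "phosphotransacylase, acetyl/butyryl transferase form", "Eut", False, "Pfam01515"),
    ("EutD-PduL", "phosphotransacylase, PduL-like form", "Eut", False, "Pfam06130"),
    ("EutD-HAD", "phosphotransacylase, HAD-family form", "Eut", False, "Pfam12710"),
    ("EutH", "ethanolamine transporter EutH", "Eut", False, None),
    ("Eat", "ethanolamine transporter Eat", "Eut", False, None),
    ("EatA", "ChrA-family ethanolamine transporter", "Eut", False, "Pfam02417"),
    # 1,2-propanediol utilization
    ("PduC-B12", "B12-dependent propanediol dehydratase, large subunit", "Pdu", True, None),
    ("PduC-GRE", "GRE-family B12-independent propanediol dehydratase", "Pdu", True, "other"),
    ("PduD", "B12-dependent dehydratase, medium subunit", "Pdu", False, None),
    ("PduE", "B12-dependent dehydratase, small subunit", "Pdu", False, None),
    ("PduP", "CoA-acylating propionaldehyde dehydrogenase", "Pdu", False, None),
    ("PduQ", "1-propanol dehydrogenase", "Pdu", False, None),
    ("PduL", "phosphate propanoyltransferase", "Pdu", False, "Pfam06130"),
    # choline utilization
    ("CutC", "choline trimethylamine-lyase", "Cut", True, "other"),
    ("CutD", "choline trimethylamine-lyase activase", "Cut", False, None),
    ("CutF", "aldehyde dehydrogenase", "Cut", False, None),
    ("CutO", "alcohol dehydrogenase", "Cut", False, None),
    ("LicB", "choline transporter LicB", "Cut", False, None),
    ("BetT", "choline transporter BetT", "Cut", False, None),
    ("TrapT", "TRAP-like choline transporter", "Cut", False, None),
    # fucose/rhamnose utilization
    ("PvmA", "fuculose/rhamnulose aldolase", "Pvm", True, None),
    ("PvmB", "lactaldehyde dehydrogenase", "Pvm", False, None),
    ("PvmC", "aldehyde dehydrogenase", "Pvm", False, None),
    # 1-amino-2-propanol / 1-amino-2-propanone utilization
    ("AutP", "GabP-family permease", "Aut", False, None),
    ("AutA", "1-amino-2-propanol aminotransferase", "Aut", False, None),
    ("AutB", "1-amino-2-propanol dehydrogenase", "Aut", True, None),
    ("AutC", "aldehyde/alcohol dehydrogenase", "Aut", False, None),
    ("AutD", "APH-family phosphotransferase", "Aut", False, "Pfam01636"),
    # xanthine utilization
    ("XanD", "xanthine dehydrogenase", "Xau", False, None),
    ("XauA", "six-membered-ring-opening hydrolase", "Xau", True, None),
    ("XauB", "permease", "Xau", False, None),
    ("XauC", "carbamoyl-removing amidohydrolase", "Xau", False, None),
    ("XauD", "decarboxylase", "Xau", False, None),
    ("XauE", "amidohydrolase", "Xau", False, None),
    ("XauF", "five-membered-ring-opening hydrolase", "Xau", False, None),
    ("XauG", "formimidoyltransferase", "Xau", False, None),
]

_DOMAIN_LENGTHS = {"Pfam00936": 90, "Pfam03319": 80}
_SEEDS_PER_FAMILY = 4
_SEED_MUTATION = 0.05
_GRE_LENGTH = 350
_GRE_REFS_PER_FAMILY = 3
_SHELL_FLANK = 20
_TANDEM_LINKER = 10
#: reference length range; the lower bound keeps a perfect self-hit safely
#: inside the strict BBH e-value cutoff
_ROLE_LENGTH_RANGE = (150, 450)


def generate_reference_set(seed: int) -> ReferenceBundle:
    """Synthetic stand-in for a curated reference-role bundle.

    Covers all six pathways (with signature roles), the alternative
    transporter and phosphotransacylase forms, B12-dependent and GRE
    dehydratase variants, shell-domain seed alignments for Pfam00936 and
    Pfam03319, and a labeled GRE reference family set with an outgroup.
    """
    # domain-separated stream: a cohort generated from the same seed must
    # not replay the reference sequences
    rng = np.random.default_rng([0, seed])

    # shell domain consensus sequences and seed alignments
    consensus = {
        fam: random_protein(rng, length) for fam, length in _DOMAIN_LENGTHS.items()
    }
    seed_alignments = {
        fam: [
            (f"{fam}_seed{i+1}", mutate(consensus[fam], _SEED_MUTATION, rng))
            for i in range(_SEEDS_PER_FAMILY)
        ]
        for fam in _DOMAIN_LENGTHS
    }

    # GRE reference families (each an independent ancestral sequence)
    gre_refs: list[GreReference] = []
    family_refs: dict[str, list[tuple[str, str]]] = {}
    for fam in GRE_FAMILIES + (GRE_OUTGROUP,):
        ancestor = random_protein(rng, _GRE_LENGTH)
        n = _GRE_REFS_PER_FAMILY if fam != GRE_OUTGROUP else 1
        refs = [
            (f"{fam}_ref{i+1}", mutate(ancestor, _SEED_MUTATION, rng))
            for i in range(n)
        ]
        family_refs[fam] = refs
        gre_refs.extend(
            GreReference(seq_id=sid, family=fam, sequence=s) for sid, s in refs
        )

    def shell_protein(fam: str, tandem: bool, which: int) -> str:
        # the domain IS a seed family member, so it scores at or above the
        # gathering threshold by construction
        domain = seed_alignments[fam][which][1].replace("-", "")
        flank_l = random_protein(rng, _SHELL_FLANK)
        flank_r = random_protein(rng, _SHELL_FLANK)
        if tandem:
            domain2 = seed_alignments[fam][which + 1][1].replace("-", "")
            linker = random_protein(rng, _TANDEM_LINKER)
            return flank_l + domain + linker + domain2 + flank_r
        return flank_l + domain + flank_r

    roles: list[ReferenceRole] = []
    for role_id, desc, pathway, signature, domfam in ROLE_SPECS:
        if role_id == "BmcH":
            refs = [("BmcH_ref1", shell_protein("Pfam00936", tandem=False, which=0))]
        elif role_id == "BmcT":
            refs = [("BmcT_ref1", shell_protein("Pfam00936", tandem=True, which=1))]
        elif role_id == "BmcP":
            refs = [("BmcP_ref1", shell_protein("Pfam03319", tandem=False, which=0))]
        elif role_id == "PduC-GRE":
            refs = list(family_refs["PduC"])
        elif role_id == "CutC":
            refs = list(family_refs["CutC"])
        else:
            length = int(rng.integers(*_ROLE_LENGTH_RANGE))
            refs = [(f"{role_id}_ref1", random_protein(rng, length))]
        roles.append(
            ReferenceRole(
                role_id=role_id,
                description=desc,
                pathway=pathway,
                signature=signature,
                domain_family=domfam,
                reference_proteins=refs,
            )
        )

    pathways = {}
    for pw in ("Pdu", "Eut", "Cut", "Pvm", "Aut", "Xau"):
        pw_roles = [r.role_id for r in roles if r.pathway == pw]
        sig = [r.role_id for r in roles if r.pathway == pw and r.signature]
        pathways[pw] = PathwayDefinition(pathway=pw, roles=pw_roles, signature_roles=sig)

    return ReferenceBundle(
        roles=roles,
        pathways=pathways,
        seed_alignments=seed_alignments,
        gre_references=gre_refs,
    )


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass
class ImplantSpec:
    """One BMC gene cluster implanted into selected genomes."""

    pathway: str
    genomes: list[int]  # genome indices within the cohort
    include_shell: bool = True
    include_signature: bool = True
    operonic_gap: int = 20  # bp between adjacent implant genes
    mutation_rate: float = 0.0  # per-residue substitution probability
    variant: Optional[str] = None  # pathway-specific variant selector

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate < 0.5:
            raise BmcscanError("mutation_rate outside [0, 0.5)")


@dataclass
class CohortSpec:
    """A synthetic cohort: genome count, labels, background, implants."""

    n_genomes: int
    seed: int
    species: Optional[list[str]] = None  # per-genome; default all distinct
    phyla: Optional[list[str]] = None
    n_background_genes: int = 25
    background_length_mean: float = 300.0
    background_length_sd: float = 60.0
    background_min_length: int = 50
    intergenic_range: tuple[int, int] = (150, 600)  # never operonic by accident
    implants: list[ImplantSpec] = field(default_factory=list)


_DEFAULT_PHYLA = (
    "Firmicutes",
    "Proteobacteria",
    "Actinobacteria",
    "Bacteroidetes",
    "Fusobacteria",
)

#: enzyme rosters per pathway (shell genes are added separately)
_PATHWAY_ROSTERS: dict[str, list[str]] = {
    "Eut": ["EutB", "EutC", "EutE", "EutG", "EutD-PduL", "EutH"],
    "Pdu": ["PduC-B12", "PduD", "PduE", "PduP", "PduQ", "PduL"],
    "Cut": ["CutC", "CutD", "CutF", "CutO", "LicB"],
    "Pvm": ["PvmA", "PvmB", "PvmC"],
    "Aut": ["AutP", "AutA", "AutB", "AutC", "AutD"],
    "Xau": ["XanD", "XauA", "XauB", "XauC", "XauD", "XauE", "XauF", "XauG"],
}

_SHELL_ROSTERS: dict[str, list[str]] = {
    "Eut": ["BmcH", "BmcT", "BmcP"],
    "Pdu": ["BmcH", "BmcT", "BmcP"],
    "Cut": ["BmcH", "BmcP"],
    "Pvm": ["BmcH", "BmcT", "BmcP"],
    "Aut": ["BmcH", "BmcP"],
    "Xau": ["BmcH", "BmcT", "BmcP"],
}

_SIGNATURES: dict[str, set[str]] = {
    "Eut": {"EutB"},
    "Pdu": {"PduC-B12", "PduC-GRE"},
    "Cut": {"CutC"},
    "Pvm": {"PvmA"},
    "Aut": {"AutB"},
    "Xau": {"XauA"},
}


def implant_roster(spec: ImplantSpec) -> list[str]:
    """Ordered role list for one implant, honoring variants and flags."""
    if spec.pathway not in _PATHWAY_ROSTERS:
        raise BmcscanError(f"unknown pathway {spec.pathway!r}")
    roles = list(_PATHWAY_ROSTERS[spec.pathway])
    v = spec.variant
    if spec.pathway == "Pdu" and v == "GRE":
        roles = ["PduC-GRE", "PduP", "PduQ", "PduL"]
    elif spec.pathway == "Eut" and v in ("EutD", "HAD"):
        roles[roles.index("EutD-PduL")] = "EutD" if v == "EutD" else "EutD-HAD"
    elif spec.pathway == "Cut" and v in ("BetT", "TrapT"):
        roles[roles.index("LicB")] = v
    elif spec.pathway == "Pvm" and v == "withB12":
        roles = roles + ["PduC-B12"]
    elif v is not None and not (spec.pathway == "Pdu" and v == "B12"):
        raise BmcscanError(f"unknown variant {v!r} for pathway {spec.pathway}")
    if not spec.include_signature:
        roles = [r for r in roles if r not in _SIGNATURES[spec.pathway]]
    if spec.include_shell:
        roles = _SHELL_ROSTERS[spec.pathway] + roles
    return roles


def generate_cohort(
    spec: CohortSpec, bundle: Optional[ReferenceBundle] = None
) -> tuple[list[Genome], pd.DataFrame]:
    """Generate genomes plus a ground-truth table of implanted genes.

    Background genes are random proteins (length ~ Normal(300, 60), floored)
    separated by uniform 150–600 bp gaps, so they never satisfy the 100 bp
    operon rule; implants are mutated copies of the bundle's reference
    proteins laid out with operonic spacing on the + strand at the end of
    the contig.
    """
    rng = np.random.default_rng([1, spec.seed])
    if bundle is None:
        bundle = generate_reference_set(spec.seed)
    for imp in spec.implants:
        for gi in imp.genomes:
            if not 0 <= gi < spec.n_genomes:
                raise BmcscanError(
                    f"implant {imp.pathway}: genome index {gi} outside cohort"
                )

    species = spec.species or [f"Species sp{i+1}" for i in range(spec.n_genomes)]
    phyla = spec.phyla or [
        _DEFAULT_PHYLA[i % len(_DEFAULT_PHYLA)] for i in range(spec.n_genomes)
    ]
    if len(species) != spec.n_genomes or len(phyla) != spec.n_genomes:
        raise BmcscanError("species/phyla lists must match n_genomes")

    ref_seq = {r.role_id: r.reference_proteins[0][1] for r in bundle.roles}

    genomes: list[Genome] = []
    truth_rows: list[dict] = []
    for gi in range(spec.n_genomes):
        genome_id = f"G{gi+1:03d}"
        genes: list[Gene] = []
        pos = 1001
        counter = 0

        def add_gene(protein: str, strand: str, gap_after: int) -> Gene:
            nonlocal pos, counter
            counter += 1
            nt = 3 * len(protein)
            gene = Gene(
                gene_id=f"{genome_id}_g{counter:04d}",
                contig="contig_1",
                start=pos,
                stop=pos + nt - 1,
                strand=strand,
                protein=protein,
            )
            genes.append(gene)
            pos += nt + gap_after
            return gene

        for _ in range(spec.n_background_genes):
            length = max(
                spec.background_min_length,
                int(round(rng.normal(spec.background_length_mean, spec.background_length_sd))),
            )
            strand = "+" if rng.random() < 0.5 else "-"
            gap = int(rng.integers(spec.intergenic_range[0], spec.intergenic_range[1] + 1))
            add_gene(random_protein(rng, length), strand, gap)

        for ii, imp in enumerate(spec.implants):
            if gi not in imp.genomes:
                continue
            pos += 2000  # clear separation from whatever precedes the cluster
            roster = implant_roster(imp)
            for role_id in roster:
                protein = mutate(ref_seq[role_id], imp.mutation_rate, rng)
                gene = add_gene(protein, "+", imp.operonic_gap)
                truth_rows.append(
                    {
                        "genome_id": genome_id,
                        "gene_id": gene.gene_id,
                        "role_id": role_id,
                        "pathway": imp.pathway,
                        "implant_index": ii,
                        "with_shell": imp.include_shell,
                        "mutation_rate": imp.mutation_rate,
                    }
                )

        genomes.append(
            Genome(genome_id=genome_id, species=species[gi], phylum=phyla[gi], genes=genes)
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "genome_id",
            "gene_id",
            "role_id",
            "pathway",
            "implant_index",
            "with_shell",
            "mutation_rate",
        ],
    )
    return genomes, truth


__all__ = [
    "ImplantSpec",
    "CohortSpec",
    "generate_reference_set",
    "generate_cohort",
    "implant_roster",
    "random_protein",
    "mutate",
    "ROLE_SPECS",
]
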