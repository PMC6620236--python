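"""Locus assembly, pathway typing, standalone enzymes and form calls."""

import numpy as np
import pytest

from bmcscan.loci import (
    assemble_loci,
    call_accessory_forms,
    call_standalone_enzymes,
    classify_locus,
)
from bmcscan.model import (
    AlignmentHit,
    BMCLocus,
    Gene,
    Genome,
    OrthologCall,
    ShellClass,
)
from bmcscan.pipeline import detect
from bmcscan.simulate import CohortSpec, ImplantSpec, generate_cohort, random_protein


def _hit(q="q", t="t"):
    return AlignmentHit(q, t, 900, 350.0, 1e-90, 95.0, 98.0, 100.0, (1, 200), (1, 200))


def _call(genome_id, gene_id, role_id):
    return OrthologCall(role_id, genome_id, gene_id, _hit(), _hit())


def _genome(n_genes, gap=200, length_aa=100):
    rng = np.random.default_rng(1)
    genes, pos = [], 1000
    for i in range(n_genes):
        nt = 3 * length_aa
        genes.append(
            Gene(f"g{i}", "c1", pos, pos + nt - 1, "+", random_protein(rng, length_aa))
        )
        pos += nt + gap
    return Genome("G1", "Sp test", "Firmicutes", genes)


SHELL = {"g0": ShellClass("BMC-H")}


class TestAssembleLoci:
    def test_contiguous_cluster_is_one_locus(self):
        genome = _genome(6)
        calls = [_call("G1", f"g{i}", "EutB") for i in range(1, 4)]
        loci = assemble_loci(genome, SHELL, calls)
        assert len(loci) == 1
        assert loci[0].member_genes == ["g0", "g1", "g2", "g3"]
        assert loci[0].shell_genes == ["g0"]

    def test_four_intervening_genes_split_the_run(self):
        genome = _genome(8)
        calls = [_call("G1", "g5", "EutB"), _call("G1", "g6", "EutC")]
        # g0 is shell; g1-g4 are 4 intervening non-members -> two runs,
        # only the shell-containing one becomes a locus
        loci = assemble_loci(genome, SHELL, calls)
        assert len(loci) == 1
        assert loci[0].member_genes == ["g0"]

    def test_large_gap_splits_the_run(self):
        genome = _genome(3, gap=6000)
        calls = [_call("G1", "g1", "EutB")]
        loci = assemble_loci(genome, SHELL, calls)
        assert len(loci) == 1 and loci[0].member_genes == ["g0"]

    def test_no_shell_gene_means_no_locus(self):
        genome = _genome(4)
        calls = [_call("G1", "g1", "EutB"), _call("G1", "g2", "EutC")]
        assert assemble_loci(genome, {}, calls) == []

    def test_genes_belong_to_at_most_one_locus(self):
        genome = _genome(10)
        shell = {"g0": ShellClass("BMC-H"), "g9": ShellClass("BMC-P")}
        calls = [_call("G1", f"g{i}", "EutB") for i in (1, 2, 8)]
        loci = assemble_loci(genome, shell, calls)
        seen = [g for l in loci for g in l.member_genes]
        assert len(seen) == len(set(seen))


def _locus(role_calls):
    return BMCLocus(
        genome_id="G1",
        contig="c1",
        member_genes=sorted({g for g, _ in role_calls}),
        shell_genes=["s1"],
        role_calls=set(role_calls),
    )


class TestClassifyLocus:
    def test_eut_signature(self, bundle):
        locus = _locus([("g1", "EutB"), ("g2", "EutC")])
        assert classify_locus(locus, bundle) == "Eut"
        assert locus.evidence == ["EutB"]

    def test_gre_member_typed_by_tree_label(self, bundle):
        locus = _locus([("g1", "CutC")])
        assert classify_locus(locus, bundle, {"g1": "CutC"}) == "Cut"
        locus2 = _locus([("g1", "PduC-GRE")])
        assert classify_locus(locus2, bundle, {"g1": "PduC"}) == "Pdu"

    def test_gre_member_with_non_bmc_function_gives_no_signature(self, bundle):
        locus = _locus([("g1", "CutC")])
        # the tree says this GRE is a glycerol dehydratase, not a BMC enzyme
        assert classify_locus(locus, bundle, {"g1": "DhaB"}) == "unknown"

    def test_b12_dehydratase_inside_pvm_cluster_is_pvm(self, bundle):
        locus = _locus([("g1", "PduC-B12"), ("g2", "PvmA"), ("g3", "PvmB")])
        assert classify_locus(locus, bundle) == "Pvm"
        assert "PduC-B12" in locus.evidence and "PvmA" in locus.evidence

    def test_conflicting_signatures_are_unknown(self, bundle):
        locus = _locus([("g1", "EutB"), ("g2", "CutC")])
        assert classify_locus(locus, bundle, {"g2": "CutC"}) == "unknown"

    def test_no_signature_is_unknown(self, bundle):
        locus = _locus([("g1", "EutC"), ("g2", "PduP")])
        assert classify_locus(locus, bundle) == "unknown"

    def test_classification_is_rerun_stable(self, bundle):
        locus = _locus([("g1", "XauA"), ("g2", "XauD")])
        assert classify_locus(locus, bundle) == classify_locus(locus, bundle) == "Xau"


class TestStandaloneAndForms:
    def test_signature_without_shell_is_standalone(self, bundle):
        spec = CohortSpec(
            n_genomes=3,
            seed=21,
            n_background_genes=6,
            implants=[
                ImplantSpec(pathway="Eut", genomes=[0, 1]),
                ImplantSpec(pathway="Eut", genomes=[2], include_shell=False),
            ],
        )
        genomes, _ = generate_cohort(spec, bundle)
        res = detect(genomes, bundle)
        assert sorted({l.genome_id for l in res.loci}) == ["G001", "G002"]
        standalone = [(s.genome_id, s.pathway) for s in res.standalone]
        assert standalone == [("G003", "Eut")]

    def test_full_locus_produces_no_standalone_call(self, bundle):
        spec = CohortSpec(
            n_genomes=2,
            seed=22,
            n_background_genes=6,
            implants=[ImplantSpec(pathway="Xau", genomes=[0, 1])],
        )
        genomes, _ = generate_cohort(spec, bundle)
        res = detect(genomes, bundle)
        assert len(res.loci) == 2
        assert res.standalone == []

    def test_form_bookkeeping(self, bundle):
        genome = _genome(4)
        calls = [
            _call("G1", "g1", "EutD-HAD"),
            _call("G1", "g2", "LicB"),
            _call("G1", "g3", "BetT"),
        ]
        forms = call_accessory_forms(genome, calls)
        assert set(forms["form"]) == {"EutD-HAD", "LicB", "BetT"}
        pta = forms[forms["function"] == "phosphotransacylase"]
        assert list(pta["form"]) == ["EutD-HAD"]
        choline = forms[forms["function"] == "choline_transporter"]
        assert len(choline) == 2  # both transporter forms reported
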