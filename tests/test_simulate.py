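"""Synthetic reference bundles and genome cohorts: determinism + structure."""

import json

import numpy as np
import pytest

from bmcscan.align import local_align, passes
from bmcscan.io import write_reference_bundle
from bmcscan.model import BmcscanError, PATHWAYS
from bmcscan.simulate import (
    CohortSpec,
    ImplantSpec,
    generate_cohort,
    generate_reference_set,
    implant_roster,
    mutate,
    random_protein,
)


class TestReferenceSet:
    def test_same_seed_gives_byte_identical_bundles(self, tmp_path):
        p1, p2 = tmp_path / "b1.json", tmp_path / "b2.json"
        write_reference_bundle(generate_reference_set(4), p1)
        write_reference_bundle(generate_reference_set(4), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_every_pathway_has_a_signature_role(self, bundle):
        for pw in PATHWAYS:
            assert bundle.pathways[pw].signature_roles

    def test_cross_role_references_are_distinguishable(self, bundle):
        # sample of roles: each reference passes the strict regime against
        # itself and fails it against other roles' references
        sample = ["EutB", "PduC-B12", "CutD", "PvmA", "AutB", "XauA"]
        seqs = {r: bundle.role(r).reference_proteins[0][1] for r in sample}
        for r, seq in seqs.items():
            self_hit = local_align(seq, seq)
            assert passes(self_hit, "bbh"), r
            for other, other_seq in seqs.items():
                if other == r:
                    continue
                cross = local_align(seq, other_seq)
                assert cross is None or not passes(cross, "bbh"), (r, other)

    def test_gre_reference_families_complete(self, bundle):
        from bmcscan.model import GRE_FAMILIES, GRE_OUTGROUP

        families = {g.family for g in bundle.gre_references}
        assert families == set(GRE_FAMILIES) | {GRE_OUTGROUP}


class TestMutate:
    def test_rate_zero_is_identity(self):
        rng = np.random.default_rng(0)
        seq = random_protein(rng, 100)
        assert mutate(seq, 0.0, rng) == seq

    def test_rate_bounds_enforced(self):
        rng = np.random.default_rng(0)
        with pytest.raises(BmcscanError):
            mutate("MKVLA", 0.5, rng)

    def test_observed_substitution_fraction_tracks_rate(self):
        rng = np.random.default_rng(6)
        seq = random_protein(rng, 2000)
        for rate in (0.1, 0.3):
            mut = mutate(seq, rate, rng)
            frac = sum(a != b for a, b in zip(seq, mut)) / len(seq)
            assert frac == pytest.approx(rate, abs=0.03)


class TestCohorts:
    def test_same_seed_gives_identical_cohorts(self, bundle):
        spec = CohortSpec(
            n_genomes=3, seed=9, implants=[ImplantSpec(pathway="Aut", genomes=[0])]
        )
        g1, t1 = generate_cohort(spec, bundle)
        g2, t2 = generate_cohort(spec, bundle)
        assert g1 == g2
        assert t1.equals(t2)

    def test_background_spacing_never_operonic(self, bundle):
        from bmcscan.context import predict_operons

        genomes, _ = generate_cohort(CohortSpec(n_genomes=2, seed=13), bundle)
        for g in genomes:
            ops = predict_operons(g)
            assert all(len(op.genes) == 1 for op in ops)

    def test_implant_forms_a_single_operon(self, bundle):
        from bmcscan.context import predict_operons

        spec = CohortSpec(
            n_genomes=1, seed=14, implants=[ImplantSpec(pathway="Xau", genomes=[0])]
        )
        genomes, truth = generate_cohort(spec, bundle)
        implant_genes = set(truth["gene_id"])
        ops = predict_operons(genomes[0])
        containing = [op for op in ops if set(op.gene_ids) & implant_genes]
        assert len(containing) == 1
        assert set(containing[0].gene_ids) == implant_genes

    def test_truth_matches_roster(self, bundle):
        imp = ImplantSpec(pathway="Pdu", genomes=[0], variant="GRE")
        spec = CohortSpec(n_genomes=1, seed=15, implants=[imp])
        _, truth = generate_cohort(spec, bundle)
        assert list(truth["role_id"]) == implant_roster(imp)
        assert "PduC-GRE" in set(truth["role_id"])
        assert "PduC-B12" not in set(truth["role_id"])

    def test_bad_genome_index_is_an_error(self, bundle):
        spec = CohortSpec(
            n_genomes=2, seed=16, implants=[ImplantSpec(pathway="Eut", genomes=[5])]
        )
        with pytest.raises(BmcscanError, match="index"):
            generate_cohort(spec, bundle)

    def test_unknown_variant_is_an_error(self):
        with pytest.raises(BmcscanError, match="variant"):
            implant_roster(ImplantSpec(pathway="Eut", genomes=[0], variant="bogus"))
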