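"""BBH orthology and genomic-context support."""

import numpy as np
import pytest

from bmcscan.model import BmcscanError, Gene, Genome
from bmcscan.orthology import (
    annotate_roles,
    best_hit,
    bidirectional_best_hits,
    build_cohort_context,
    context_support,
)
from bmcscan.simulate import (
    CohortSpec,
    ImplantSpec,
    generate_cohort,
    mutate,
    random_protein,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(77)


class TestBestHit:
    def test_identical_copy_wins(self, rng):
        q = random_protein(rng, 200)
        proteome = [("p1", random_protein(rng, 200)), ("p2", q), ("p3", random_protein(rng, 180))]
        hit = best_hit(q, proteome)
        assert hit is not None and hit.target_id == "p2"

    def test_unrelated_proteome_is_no_hit(self, rng):
        q = random_protein(rng, 200)
        proteome = [(f"p{i}", random_protein(rng, 200)) for i in range(5)]
        assert best_hit(q, proteome) is None

    def test_least_mutated_target_wins(self, rng):
        # graded similarity: scores verified independently via the raw aligner
        from bmcscan.align import raw_align_score

        q = random_protein(rng, 250)
        targets = {
            "far": mutate(q, 0.25, rng),
            "mid": mutate(q, 0.15, rng),
            "near": mutate(q, 0.05, rng),
        }
        scores = {k: raw_align_score(q, v) for k, v in targets.items()}
        expected = max(scores, key=scores.get)
        assert expected == "near"
        hit = best_hit(q, sorted(targets.items()))
        assert hit.target_id == expected

    def test_empty_proteome_is_an_error(self):
        with pytest.raises(BmcscanError):
            best_hit("MKVLA", [])


def _genome(gid, species, proteins):
    genes, pos = [], 1000
    for name, seq in proteins:
        genes.append(
            Gene(f"{gid}_{name}", "c1", pos, pos + 3 * len(seq) - 1, "+", seq)
        )
        pos += 3 * len(seq) + 500
    return Genome(gid, species, "Firmicutes", genes)


class TestBBH:
    def test_shared_family_pairs_and_symmetry(self, rng):
        fam1, fam2 = random_protein(rng, 200), random_protein(rng, 220)
        a = _genome("A", "Sp a", [("x", mutate(fam1, 0.05, rng)), ("y", mutate(fam2, 0.05, rng))])
        b = _genome("B", "Sp b", [("x", mutate(fam1, 0.05, rng)), ("y", mutate(fam2, 0.05, rng))])
        ab = bidirectional_best_hits(a, b)
        assert ab == [("A_x", "B_x"), ("A_y", "B_y")]
        ba = bidirectional_best_hits(b, a)
        assert sorted((p, q) for q, p in ba) == ab

    def test_only_closer_paralog_pairs(self, rng):
        fam = random_protein(rng, 220)
        a = _genome("A", "Sp a", [("a1", mutate(fam, 0.20, rng)), ("a2", mutate(fam, 0.04, rng))])
        b = _genome("B", "Sp b", [("b", mutate(fam, 0.04, rng))])
        pairs = bidirectional_best_hits(a, b)
        assert pairs == [("A_a2", "B_b")]

    def test_unrelated_genomes_have_no_pairs(self, rng):
        a = _genome("A", "Sp a", [("x", random_protein(rng, 200))])
        b = _genome("B", "Sp b", [("x", random_protein(rng, 200))])
        assert bidirectional_best_hits(a, b) == []


class TestContextSupport:
    def _run(self, species_labels, bundle):
        spec = CohortSpec(
            n_genomes=3,
            seed=5,
            species=species_labels,
            n_background_genes=6,
            implants=[ImplantSpec(pathway="Eut", genomes=[0, 1])],
        )
        genomes, _ = generate_cohort(spec, bundle)
        return annotate_roles(genomes, bundle)

    def test_two_species_supported(self, bundle):
        calls = self._run(["Sp one", "Sp two", "Sp three"], bundle)
        eutb = [c for c in calls if c.role_id == "EutB"]
        assert eutb and all(c.context_supported for c in eutb)
        assert all(c.context_witnesses == {"Sp one", "Sp two"} for c in eutb)

    def test_same_species_unsupported(self, bundle):
        calls = self._run(["Sp one", "Sp one", "Sp three"], bundle)
        eutb = [c for c in calls if c.role_id == "EutB"]
        assert eutb and not any(c.context_supported for c in eutb)

    def test_scattered_copies_unsupported(self, bundle):
        # the role is present in several species but never co-clustered
        role = bundle.role("EutB")
        seq = role.reference_proteins[0][1]
        genomes = [
            _genome(f"G{i}", f"Sp {i}", [("bg", random_protein(np.random.default_rng(i), 200)), ("eutb", seq)])
            for i in range(3)
        ]
        calls = annotate_roles(genomes, bundle)
        eutb = [c for c in calls if c.role_id == "EutB"]
        assert len(eutb) == 3
        assert not any(c.context_supported for c in eutb)

    def test_raising_thresholds_never_increases_calls(self, bundle):
        from bmcscan.config import PipelineConfig, ThresholdSet

        spec = CohortSpec(
            n_genomes=2,
            seed=8,
            n_background_genes=5,
            implants=[ImplantSpec(pathway="Cut", genomes=[0, 1], mutation_rate=0.1)],
        )
        genomes, _ = generate_cohort(spec, bundle)
        base = len(annotate_roles(genomes, bundle))
        strict = PipelineConfig()
        strict.regimes = dict(strict.regimes)
        strict.regimes["bbh"] = ThresholdSet(
            min_bits=400.0, max_evalue=1e-80, min_identity_pct=60.0,
            min_positives_pct=80.0, min_coverage_pct=90.0,
        )
        assert len(annotate_roles(genomes, bundle, strict)) <= base
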