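"""PSSM construction, domain scanning and BMC-H/T/P classification."""

import numpy as np
import pytest

from bmcscan.model import BmcscanError
from bmcscan.shell import (
    ROBINSON_FREQS,
    build_profile,
    classify_shell,
    scan,
)
from bmcscan.simulate import random_protein


def _aligned(rows):
    return [(f"s{i}", r) for i, r in enumerate(rows)]


class TestBuildProfile:
    def test_conserved_column_scores_maximal_positive(self):
        prof = build_profile("fam", _aligned(["GAC", "GAC", "GAC"]), threshold_margin=1.0)
        g_col = prof.pssm[0]
        g_idx = "ACDEFGHIKLMNPQRSTVWY".index("G")
        assert g_col[g_idx] > 0
        assert g_col[g_idx] == max(g_col)

    def test_background_column_scores_near_zero(self):
        # a column populated proportionally to background is uninformative
        aas = "ACDEFGHIKLMNPQRSTVWY"
        rows = [aa * 3 for aa in aas]
        counts = np.array([ROBINSON_FREQS[a] for a in aas])
        # build a synthetic column by repeating residues by background weight
        col = "".join(a * max(1, round(100 * f)) for a, f in zip(aas, counts))
        prof = build_profile(
            "fam", _aligned([c + "WW" for c in col]), threshold_margin=0.1
        )
        assert abs(prof.pssm[0]).max() < 0.5

    def test_ragged_alignment_is_an_error(self):
        with pytest.raises(BmcscanError, match="ragged"):
            build_profile("fam", _aligned(["GAC", "GA", "GAC"]))

    def test_seed_members_score_at_or_above_threshold(self, bundle, shell_profiles):
        for fam, seeds in bundle.seed_alignments.items():
            prof = shell_profiles[fam]
            for _, row in seeds:
                # recompute by direct summation over columns
                direct = sum(
                    prof.pssm[i, "ACDEFGHIKLMNPQRSTVWY".index(aa)]
                    for i, aa in enumerate(row)
                    if aa != "-"
                )
                assert direct >= prof.threshold


class TestScan:
    def test_seed_sequence_yields_one_covering_hit(self, bundle, shell_profiles):
        fam = "Pfam00936"
        seq = bundle.seed_alignments[fam][0][1].replace("-", "")
        hits = scan(seq, shell_profiles[fam])
        assert len(hits) == 1
        assert hits[0][0] == (1, shell_profiles[fam].length)

    def test_random_sequences_rarely_hit(self, shell_profiles):
        rng = np.random.default_rng(23)
        prof = shell_profiles["Pfam00936"]
        false_hits = sum(
            bool(scan(random_protein(rng, prof.length), prof)) for _ in range(100)
        )
        assert false_hits <= 1

    def test_tandem_concatenation_yields_two_hits(self, bundle, shell_profiles):
        fam = "Pfam00936"
        seq = bundle.seed_alignments[fam][0][1].replace("-", "")
        hits = scan(seq + seq, shell_profiles[fam])
        assert len(hits) == 2
        (s1, e1), (s2, e2) = hits[0][0], hits[1][0]
        assert e1 < s2  # non-overlapping

    def test_short_protein_is_empty(self, shell_profiles):
        assert scan("MKVLA", shell_profiles["Pfam00936"]) == []


class TestClassifyShell:
    def test_single_domain_is_bmc_h(self, bundle, shell_profiles):
        seq = bundle.seed_alignments["Pfam00936"][0][1]
        assert classify_shell(seq, shell_profiles).value == "BMC-H"

    def test_tandem_repeat_is_bmc_t(self, bundle, shell_profiles):
        rng = np.random.default_rng(9)
        seq = bundle.seed_alignments["Pfam00936"][0][1]
        linker = random_protein(rng, 10)
        assert classify_shell(seq + linker + seq, shell_profiles).value == "BMC-T"

    def test_pentamer_domain_is_bmc_p(self, bundle, shell_profiles):
        seq = bundle.seed_alignments["Pfam03319"][0][1]
        assert classify_shell(seq, shell_profiles).value == "BMC-P"

    def test_unrelated_protein_is_none(self, shell_profiles):
        rng = np.random.default_rng(31)
        assert classify_shell(random_protein(rng, 200), shell_profiles).value == "none"

    def test_every_seed_recovers_its_own_family(self, bundle, shell_profiles):
        expect = {"Pfam00936": "BMC-H", "Pfam03319": "BMC-P"}
        for fam, seeds in bundle.seed_alignments.items():
            for _, row in seeds:
                assert classify_shell(row.replace("-", ""), shell_profiles).value == expect[fam]

    def test_bundled_reference_shell_proteins_classify(self, bundle, shell_profiles):
        for role_id, expect in (("BmcH", "BMC-H"), ("BmcT", "BMC-T"), ("BmcP", "BMC-P")):
            seq = bundle.role(role_id).reference_proteins[0][1]
            assert classify_shell(seq, shell_profiles).value == expect
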