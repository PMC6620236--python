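"""Shell-protein domain detection and BMC-H / BMC-T / BMC-P classification.

BMC shells are built from proteins carrying one Pfam00936 domain (BMC-H),
two tandem Pfam00936 domains (BMC-T) or a Pfam03319 domain (BMC-P).  The
detector is an ungapped position-specific scoring matrix (PSSM) built from
a seed alignment per family: per-column log-odds against the
Robinson–Robinson background, a gathering threshold anchored to the lowest
self-score among the seeds, and a greedy non-overlapping window scan.
"""

from __future__ import annotations

import numpy as np

from .config import DEFAULT_CONFIG, PipelineConfig
from .model import AMINO_ACIDS, BmcscanError, ShellClass

#: Robinson & Robinson amino-acid background frequencies
ROBINSON_FREQS: dict[str, float] = {
    "A": 0.07805, "C": 0.01925, "D": 0.05364, "E": 0.06295, "F": 0.03856,
    "G": 0.07377, "H": 0.02199, "I": 0.05142, "K": 0.05744, "L": 0.09019,
    "M": 0.02243, "N": 0.04487, "P": 0.05203, "Q": 0.04264, "R": 0.05129,
    "S": 0.07120, "T": 0.05841, "V": 0.06441, "W": 0.01330, "Y": 0.03216,
}

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_BACKGROUND = np.array([ROBINSON_FREQS[aa] for aa in AMINO_ACIDS])


class DomainProfile:
    """Ungapped PSSM for one shell domain family.

    ``pssm`` has shape (length, 20) in bits; ``threshold`` is the gathering
    cutoff below which windows are not reported.
    """

    def __init__(self, family: str, pssm: np.ndarray, threshold: float):
        if threshold <= 0:
            raise BmcscanError(f"profile {family}: threshold must be positive")
        self.family = family
        self.pssm = pssm
        self.threshold = threshold

    @property
    def length(self) -> int:
        return self.pssm.shape[0]

    def score_sequence(self, seq: str) -> float:
        """Score a sequence of exactly profile length (X and gaps score 0)."""
        if len(seq) != self.length:
            raise BmcscanError("sequence length != profile length")
        total = 0.0
        for i, aa in enumerate(seq):
            if aa in _AA_INDEX:
                total += self.pssm[i, _AA_INDEX[aa]]
        return float(total)


def build_profile(
    family: str,
    seed_alignment: list[tuple[str, str]],
    pseudocount: float | None = None,
    threshold_margin: float | None = None,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> DomainProfile:
    """Build a log-odds PSSM from an aligned seed set.

    Column scores are ``log2((f_ic + w*b_i) / (1 + w) / b_i)`` with
    pseudocount weight ``w`` and background ``b``; gap characters are
    excluded from the column frequencies.  The gathering threshold is the
    minimum self-score among the seed members minus a safety margin.
    """
    if len(seed_alignment) < 3:
        raise BmcscanError(f"profile {family}: need >= 3 seed sequences")
    w = config.profile_pseudocount if pseudocount is None else pseudocount
    margin = (
        config.profile_threshold_margin_bits
        if threshold_margin is None
        else threshold_margin
    )
    rows = [row for _, row in seed_alignment]
    length = len(rows[0])
    if any(len(r) != length for r in rows):
        raise BmcscanError(f"profile {family}: ragged seed alignment")

    counts = np.zeros((length, 20))
    for row in rows:
        for i, aa in enumerate(row):
            if aa in _AA_INDEX:
                counts[i, _AA_INDEX[aa]] += 1
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1  # all-gap column: frequencies 0, pseudocount only
    freqs = counts / totals
    pssm = np.log2((freqs + w * _BACKGROUND) / (1.0 + w) / _BACKGROUND)

    profile = DomainProfile(family, pssm, threshold=1.0)  # placeholder threshold
    # gap characters are not indexed, so they contribute 0 to a self-score
    self_scores = [profile.score_sequence(row) for row in rows]
    threshold = min(self_scores) - margin
    if threshold <= 0:
        raise BmcscanError(
            f"profile {family}: seed self-scores too low for a positive threshold"
        )
    return DomainProfile(family, pssm, threshold)


def scan(protein: str, profile: DomainProfile) -> list[tuple[tuple[int, int], float]]:
    """All non-overlapping windows scoring at or above the gathering threshold.

    Windows are 1-based inclusive spans; overlap resolution is greedy by
    descending score (ties by leftmost start).  Proteins shorter than the
    profile yield an empty list.
    """
    L = profile.length
    n = len(protein)
    if n < L:
        return []
    # residues -> one-hot indices; X/unknown contribute 0 via a zero column
    idx = np.array([_AA_INDEX.get(aa, 20) for aa in protein])
    pssm = np.hstack([profile.pssm, np.zeros((L, 1))])
    per_pos = pssm[np.arange(L)[None, :], idx[np.arange(n - L + 1)[:, None] + np.arange(L)[None, :]]]
    window_scores = per_pos.sum(axis=1)

    candidates = [
        (float(s), start)
        for start, s in enumerate(window_scores)
        if s >= profile.threshold
    ]
    candidates.sort(key=lambda t: (-t[0], t[1]))
    taken: list[tuple[tuple[int, int], float]] = []
    occupied: list[tuple[int, int]] = []
    for score, start in candidates:
        span = (start + 1, start + L)  # 1-based inclusive
        if all(span[1] < s or span[0] > e for s, e in occupied):
            taken.append((span, score))
            occupied.append(span)
    taken.sort(key=lambda t: t[0][0])
    return taken


def classify_shell(
    protein: str, profiles: dict[str, DomainProfile]
) -> ShellClass:
    """Classify a protein as BMC-H, BMC-T, BMC-P or none from its domain hits.

    One Pfam00936 hit -> BMC-H; two or more (tandem repeat) -> BMC-T; at
    least one Pfam03319 hit and no Pfam00936 -> BMC-P.  If both families
    hit, the family with the higher best hit score wins.
    """
    hits_h = scan(protein, profiles["Pfam00936"]) if "Pfam00936" in profiles else []
    hits_p = scan(protein, profiles["Pfam03319"]) if "Pfam03319" in profiles else []
    domain_hits = [("Pfam00936", span, score) for span, score in hits_h] + [
        ("Pfam03319", span, score) for span, score in hits_p
    ]
    if hits_h and hits_p:
        best_h = max(s for _, s in hits_h)
        best_p = max(s for _, s in hits_p)
        if best_p > best_h:
            hits_h = []
        else:
            hits_p = []
    if hits_h:
        value = "BMC-H" if len(hits_h) == 1 else "BMC-T"
    elif hits_p:
        value = "BMC-P"
    else:
        value = "none"
    return ShellClass(value=value, domain_hits=domain_hits)


def build_shell_profiles(
    seed_alignments: dict[str, list[tuple[str, str]]],
    config: PipelineConfig = DEFAULT_CONFIG,
) -> dict[str, DomainProfile]:
    return {
        family: build_profile(family, seeds, config=config)
        for family, seeds in seed_alignments.items()
    }


__all__ = [
    "DomainProfile",
    "build_profile",
    "build_shell_profiles",
    "scan",
    "classify_shell",
    "ROBINSON_FREQS",
]
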