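"""Deterministic local protein alignment and the three hit-filter regimes.

Alignment is optimal Smith–Waterman–Gotoh under affine gap costs (a gap of
length L costs ``gap_open + L * gap_extend``), scored with BLOSUM62 by
default.  Bit scores and e-values follow Karlin–Altschul statistics::

    bits = (lambda * raw - ln K) / ln 2
    E    = m * n * 2 ** (-bits)

where ``m`` is the query length and ``n`` the summed length of the searched
proteome.  The dynamic programming itself is delegated to
:class:`Bio.Align.PairwiseAligner`; this module owns scoring statistics,
per-hit percentages and the filter regimes.
"""

from __future__ import annotations

import math
from functools import lru_cache
from typing import Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .config import DEFAULT_CONFIG, REGIMES, PipelineConfig, ThresholdSet
from .model import PROTEIN_ALPHABET, AlignmentHit, BmcscanError


@lru_cache(maxsize=8)
def _matrix(name: str):
    return substitution_matrices.load(name)


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = _matrix(matrix)
    # biopython charges open_gap_score for the first gap position, so the
    # BLAST-style "11/1" scheme maps to open=-(11+1), extend=-1.
    aln.open_gap_score = -(gap_open + gap_extend)
    aln.extend_gap_score = -gap_extend
    return aln


def _check_protein(seq: str, what: str) -> None:
    if not seq:
        raise BmcscanError(f"{what}: empty sequence")
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise BmcscanError(f"{what}: non-amino-acid characters {sorted(bad)}")


def bit_score(raw_score: float, lambda_: float, K: float) -> float:
    """Normalized score in bits."""
    if lambda_ <= 0 or K <= 0:
        raise BmcscanError("Karlin–Altschul parameters must be positive")
    return (lambda_ * raw_score - math.log(K)) / math.log(2)


def evalue(bits: float, m: int, n: int) -> float:
    """Expected number of chance hits of at least this score."""
    if m < 1 or n < 1:
        raise BmcscanError("search space dimensions must be >= 1")
    return m * n * 2.0 ** (-bits)


def raw_align_score(
    query: str, target: str, config: PipelineConfig = DEFAULT_CONFIG
) -> float:
    """Optimal local alignment raw score only (fast path, no traceback)."""
    aligner = _aligner(config.matrix, config.gap_open, config.gap_extend)
    return aligner.score(query, target)


def local_align(
    query: str,
    target: str,
    *,
    query_id: str = "query",
    target_id: str = "target",
    config: PipelineConfig = DEFAULT_CONFIG,
    db_length: Optional[int] = None,
) -> Optional[AlignmentHit]:
    """Optimal local alignment of two proteins.

    Returns ``None`` when no alignment with positive score exists (a no-hit).
    ``db_length`` is the summed length of the searched proteome for e-value
    purposes; it defaults to the target length (single-sequence search space).

    Identity and positives percentages use the full alignment length
    (including gap columns, which count as neither identical nor positive);
    query coverage is the fraction of query residues inside the aligned
    region.
    """
    _check_protein(query, "query")
    _check_protein(target, "target")
    if config.gap_open < config.gap_extend or config.gap_extend <= 0:
        raise BmcscanError("require gap_open >= gap_extend > 0")
    aligner = _aligner(config.matrix, config.gap_open, config.gap_extend)
    score = aligner.score(query, target)
    if score <= 0:
        return None
    alignment = aligner.align(query, target)[0]
    matrix = _matrix(config.matrix)

    qblocks, tblocks = alignment.aligned
    columns = identities = positives = aligned_query = 0
    for i, ((qs, qe), (ts, te)) in enumerate(zip(qblocks, tblocks)):
        if i:
            # internal gap columns between consecutive aligned blocks
            columns += (qs - qblocks[i - 1][1]) + (ts - tblocks[i - 1][1])
        columns += qe - qs
        aligned_query += qe - qs
        for qa, ta in zip(query[qs:qe], target[ts:te]):
            if qa == ta:
                identities += 1
            if matrix[qa, ta] > 0:
                positives += 1

    bits = bit_score(score, config.ka_lambda, config.ka_k)
    n = db_length if db_length is not None else len(target)
    return AlignmentHit(
        query_id=query_id,
        target_id=target_id,
        raw_score=int(round(score)),
        bit_score=bits,
        evalue=evalue(bits, len(query), n),
        identity_pct=100.0 * identities / columns,
        positives_pct=100.0 * positives / columns,
        query_coverage_pct=100.0 * aligned_query / len(query),
        query_span=(int(qblocks[0][0]) + 1, int(qblocks[-1][1])),
        target_span=(int(tblocks[0][0]) + 1, int(tblocks[-1][1])),
    )


def passes(
    hit: AlignmentHit,
    regime: str | ThresholdSet,
    config: PipelineConfig = DEFAULT_CONFIG,
) -> bool:
    """Apply one of the named filter regimes (all comparisons inclusive)."""
    if isinstance(regime, ThresholdSet):
        t = regime
    else:
        try:
            t = config.regimes[regime]
        except KeyError:
            raise BmcscanError(f"unknown threshold regime {regime!r}") from None
    if t.min_bits is not None and hit.bit_score < t.min_bits:
        return False
    if t.max_evalue is not None and hit.evalue > t.max_evalue:
        return False
    if t.min_identity_pct is not None and hit.identity_pct < t.min_identity_pct:
        return False
    if t.min_positives_pct is not None and hit.positives_pct < t.min_positives_pct:
        return False
    if t.min_coverage_pct is not None and hit.query_coverage_pct < t.min_coverage_pct:
        return False
    return True


__all__ = [
    "bit_score",
    "evalue",
    "local_align",
    "raw_align_score",
    "passes",
    "REGIMES",
]
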