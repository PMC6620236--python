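"""Independent brute-force oracles used only by the tests.

The local-alignment oracle is a direct three-matrix Gotoh recurrence with
no shared code with the package's alignment path; it is deliberately
simple and only meant for short sequences.
"""

from __future__ import annotations

from fractions import Fraction

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
NEG = float("-inf")


def sw_gotoh_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Optimal Smith–Waterman score, affine gaps costing open + L*extend."""
    la, lb = len(a), len(b)
    # H: best ending in a match; E: gap in a (vertical); F: gap in b
    H = [[0.0] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    best = 0.0
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            E[i][j] = max(
                H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend
            )
            F[i][j] = max(
                H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend
            )
            s = _B62[a[i - 1], b[j - 1]]
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return int(best)


def round_half_up_pct(k: int, n: int) -> Fraction:
    """Exact rational round-half-up of 100*k/n to one decimal place."""
    x = Fraction(1000 * k, n)  # tenths of a percent, exact
    floor = x.numerator // x.denominator
    rem = x - floor
    tenths = floor + (1 if rem >= Fraction(1, 2) else 0)
    return Fraction(tenths, 10)
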