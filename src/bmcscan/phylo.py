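"""Desk-scale tree pipeline for glycyl radical enzyme (GRE) classification.

The GRE superfamily mixes functionally distinct members (choline
trimethylamine-lyase CutC, B12-independent propanediol dehydratase PduC,
glycerol dehydratase DhaB, 4-hydroxyphenylacetate decarboxylase HpdB,
4-hydroxyproline dehydratase HypD, phenylacetate decarboxylase PhdB), so a
BBH alone cannot type a locus that carries one; function is read off a
phylogenetic tree with labeled reference clades and a pyruvate
formate-lyase outgroup.

The pipeline here is deliberately deterministic and lightweight: k-mer
guide tree + profile–profile progressive alignment, removal of
zero-quality columns, Poisson-corrected distances, neighbor joining
(via scikit-bio) and midpoint rooting.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

from .align import _matrix  # shared BLOSUM62 load
from .model import AMINO_ACIDS, BmcscanError, ReferenceBundle

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"
_GAP_VS_RESIDUE = -4.0  # score of a gap column entry against any residue
_GAP_PENALTY = 8.0  # linear per-column gap cost in profile alignment


@lru_cache(maxsize=1)
def _score21() -> np.ndarray:
    """BLOSUM62 extended with a 21st gap state."""
    m = _matrix("BLOSUM62")
    s = np.zeros((21, 21))
    for a, ai in _AA_INDEX.items():
        for b, bi in _AA_INDEX.items():
            s[ai, bi] = m[a, b]
        s[ai, 20] = s[20, ai] = _GAP_VS_RESIDUE
    return s


@dataclass
class MSA:
    """A multiple sequence alignment; '-' for gaps."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise BmcscanError("MSA: ids/rows length mismatch")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise BmcscanError("MSA: ragged rows")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)].replace(GAP, "")


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency matrix over 20 residues + gap (shape L x 21)."""
    L = len(rows[0])
    counts = np.zeros((L, 21))
    for row in rows:
        for i, aa in enumerate(row):
            counts[i, _AA_INDEX.get(aa, 20)] += 1
    return counts / counts.sum(axis=1, keepdims=True)


def _align_profiles(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    """Global profile–profile alignment; returns gapped row sets.

    Needleman–Wunsch with a linear per-column gap cost; expected
    column-vs-column score under the two frequency profiles.  Tie-break in
    the traceback prefers diagonal, then a gap in B, then a gap in A.
    """
    pa, pb = _profile(rows_a), _profile(rows_b)
    M = pa @ _score21() @ pb.T
    la, lb = M.shape
    H = np.zeros((la + 1, lb + 1))
    ptr = np.zeros((la + 1, lb + 1), dtype=np.uint8)  # 0 diag, 1 up, 2 left
    H[1:, 0] = -_GAP_PENALTY * np.arange(1, la + 1)
    H[0, 1:] = -_GAP_PENALTY * np.arange(1, lb + 1)
    ptr[1:, 0] = 1
    ptr[0, 1:] = 2
    for i in range(1, la + 1):
        diag = H[i - 1, :-1] + M[i - 1]
        up = H[i - 1, 1:] - _GAP_PENALTY
        row = H[i]
        p = ptr[i]
        for j in range(1, lb + 1):
            left = row[j - 1] - _GAP_PENALTY
            d, u = diag[j - 1], up[j - 1]
            if d >= u and d >= left:
                row[j], p[j] = d, 0
            elif u >= left:
                row[j], p[j] = u, 1
            else:
                row[j], p[j] = left, 2
    # traceback
    i, j = la, lb
    take: list[int] = []  # 0 both, 1 column from A only, 2 from B only
    while i > 0 or j > 0:
        move = ptr[i, j]
        take.append(move)
        if move == 0:
            i, j = i - 1, j - 1
        elif move == 1:
            i -= 1
        else:
            j -= 1
    take.reverse()
    out_a = ["".join(_emit(row, take, which=0)) for row in rows_a]
    out_b = ["".join(_emit(row, take, which=1)) for row in rows_b]
    return out_a, out_b


def _emit(row: str, take: list[int], which: int):
    it = iter(row)
    own = (0, 1) if which == 0 else (0, 2)
    for move in take:
        yield next(it) if move in own else GAP


def _kmer_vector(seq: str, k: int = 3) -> dict[str, int]:
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def _cosine_distance(a: dict[str, int], b: dict[str, int]) -> float:
    shared = set(a) & set(b)
    dot = sum(a[k] * b[k] for k in shared)
    na = np.sqrt(sum(v * v for v in a.values()))
    nb = np.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 1.0
    return 1.0 - dot / (na * nb)


def progressive_align(sequences: list[tuple[str, str]]) -> MSA:
    """Deterministic progressive alignment (3-mer guide tree, BLOSUM62).

    The guide tree is average-linkage clustering of pairwise 3-mer cosine
    distances; clusters are merged by profile–profile alignment.
    """
    if len(sequences) < 2:
        raise BmcscanError("progressive_align: need >= 2 sequences")
    ids = [sid for sid, _ in sequences]
    if len(set(ids)) != len(ids):
        raise BmcscanError("progressive_align: duplicate sequence ids")
    vectors = [_kmer_vector(seq) for _, seq in sequences]
    n = len(sequences)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _cosine_distance(vectors[i], vectors[j])
    Z = linkage(squareform(dm, checks=False), method="average")

    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([ids[i]], [seq]) for i, (_, seq) in enumerate(sequences)
    }
    for step, (a, b, _, _) in enumerate(Z):
        ids_a, rows_a = clusters.pop(int(a))
        ids_b, rows_b = clusters.pop(int(b))
        rows_a, rows_b = _align_profiles(rows_a, rows_b)
        clusters[n + step] = (ids_a + ids_b, rows_a + rows_b)
    (final_ids, final_rows), = clusters.values()
    # restore input order
    order = sorted(range(len(final_ids)), key=lambda i: ids.index(final_ids[i]))
    return MSA(ids=[final_ids[i] for i in order], rows=[final_rows[i] for i in order])


def align_to_msa(msa: MSA, seq_id: str, sequence: str) -> MSA:
    """Add one sequence to an existing alignment (profile vs single row)."""
    if seq_id in msa.ids:
        raise BmcscanError(f"align_to_msa: duplicate id {seq_id!r}")
    rows_a, rows_b = _align_profiles(msa.rows, [sequence])
    return MSA(ids=msa.ids + [seq_id], rows=rows_a + rows_b)


def filter_columns(msa: MSA) -> MSA:
    """Drop alignment columns whose quality score is zero or below.

    Column quality is the mean BLOSUM62 score of the column's entries
    against its score-maximizing consensus residue, with gaps scoring −4;
    an alignment losing every column is unusable.
    """
    s21 = _score21()
    profile = _profile(msa.rows)  # L x 21
    # mean score against each candidate consensus residue; take the best
    quality = (profile @ s21[:, :20]).max(axis=1)
    keep = np.where(quality > 0)[0]
    if keep.size == 0:
        raise BmcscanError("filter_columns: no columns left (alignment unusable)")
    rows = ["".join(row[i] for i in keep) for row in msa.rows]
    return MSA(ids=list(msa.ids), rows=rows)


def poisson_distance_matrix(msa: MSA, max_distance: float = 10.0) -> DistanceMatrix:
    """Poisson-corrected p-distances, −ln(1−p), with pairwise gap deletion."""
    n = len(msa.ids)
    arr = np.array([[_AA_INDEX.get(c, 20) for c in row] for row in msa.rows])
    gaps = arr == 20
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gaps[i] | gaps[j])
            total = int(valid.sum())
            if total == 0:
                d = max_distance
            else:
                p = float((arr[i][valid] != arr[j][valid]).sum()) / total
                d = max_distance if p >= 1.0 else min(-np.log(1.0 - p), max_distance)
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=msa.ids)


def nj_tree(dm: DistanceMatrix | np.ndarray, ids: list[str] | None = None) -> TreeNode:
    """Neighbor-joining tree; negative branch lengths are clamped to zero."""
    if not isinstance(dm, DistanceMatrix):
        arr = np.asarray(dm, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise BmcscanError("nj_tree: matrix must be square")
        if not np.allclose(arr, arr.T):
            raise BmcscanError("nj_tree: matrix must be symmetric")
        if not np.allclose(np.diag(arr), 0):
            raise BmcscanError("nj_tree: diagonal must be zero")
        dm = DistanceMatrix(arr, ids=ids)
    return nj(dm)


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root at the midpoint of the longest leaf-to-leaf path."""
    tips = list(tree.tips())
    if len(tips) == 2:
        # two-leaf tree: place the root explicitly halfway along the path
        half = (sum(t.length or 0.0 for t in tips) + (0.0 if tree.length is None else tree.length)) / 2.0
        a = TreeNode(name=tips[0].name, length=half)
        b = TreeNode(name=tips[1].name, length=half)
        return TreeNode(children=[a, b])
    return tree.root_at_midpoint()


def assign_function(
    tree: TreeNode, labels: dict[str, str], query_leaf: str, atol: float = 1e-9
) -> str:
    """Function label for a query leaf from labeled reference clades.

    The smallest clade containing the query whose labeled leaves are
    unanimous provides the label.  If the first labeled clade on the way to
    the root is mixed, the query takes the label of the nearest labeled
    leaf by path length; an exact tie between different labels yields
    ``"unclassified"``.
    """
    if not labels:
        raise BmcscanError("assign_function: no labeled leaves")
    query = tree.find(query_leaf)
    node = query.parent
    while node is not None:
        found = {
            labels[tip.name]
            for tip in node.tips()
            if tip.name in labels and tip.name != query_leaf
        }
        if found:
            if len(found) == 1:
                return found.pop()
            break  # mixed clade: unanimity is impossible higher up
        node = node.parent
    # nearest labeled leaf by path length
    best: list[tuple[float, str]] = []
    for tip in tree.tips():
        if tip.name in labels and tip.name != query_leaf:
            best.append((query.distance(tip), labels[tip.name]))
    best.sort(key=lambda t: t[0])
    nearest_d, nearest_label = best[0]
    tied = {lab for d, lab in best if abs(d - nearest_d) <= atol}
    return nearest_label if len(tied) == 1 else "unclassified"


# ---------------------------------------------------------------------------
# GRE classification over a reference bundle
# ---------------------------------------------------------------------------

_REF_MSA_CACHE: dict[int, MSA] = {}


def gre_reference_msa(bundle: ReferenceBundle) -> MSA:
    """Aligned GRE reference set (cached per bundle object)."""
    key = id(bundle)
    if key not in _REF_MSA_CACHE:
        seqs = [(g.seq_id, g.sequence) for g in bundle.gre_references]
        if len(seqs) < 2:
            raise BmcscanError("bundle has no usable GRE reference set")
        _REF_MSA_CACHE[key] = progressive_align(seqs)
    return _REF_MSA_CACHE[key]


def classify_gre(
    bundle: ReferenceBundle, queries: list[tuple[str, str]]
) -> dict[str, str]:
    """Assign a GRE family label to each query protein.

    Each query is added to the aligned reference set; zero-quality columns
    are removed, a Poisson-corrected NJ tree is built and midpoint-rooted,
    and the query takes the function of the reference clade it falls in.
    """
    labels = {g.seq_id: g.family for g in bundle.gre_references}
    ref_msa = gre_reference_msa(bundle)
    out: dict[str, str] = {}
    for qid, seq in queries:
        msa = align_to_msa(ref_msa, qid, seq)
        tree = midpoint_root(nj_tree(poisson_distance_matrix(filter_columns(msa))))
        out[qid] = assign_function(tree, labels, qid)
    return out


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def read_newick(path: str | Path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("leaf\tfunction\n")
        for leaf, fn in sorted(labels.items()):
            fh.write(f"{leaf}\t{fn}\n")


def read_labels(path: str | Path) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            leaf, fn = line.rstrip("\n").split("\t")
            labels[leaf] = fn
    return labels
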