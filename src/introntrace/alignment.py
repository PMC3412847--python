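"""Deterministic progressive multiple alignment.

Pairwise distances from k-mer counts feed a neighbor-joining guide tree
(scikit-bio); profiles are then merged up the tree with affine-gap
profile–profile dynamic programming (Gotoh recurrences, vectorized per
row).  The same engine aligns proteins (BLOSUM62 by default) and DNA
(match/mismatch scoring), so intron sets and ortholog families go through
one code path.

Ties in the DP are broken in a fixed order (diagonal, then up, then left),
making every alignment a pure function of sequences and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix
from skbio.tree import nj

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

NEG = -1e30


@dataclass(frozen=True)
class AlignParams:
    """Affine-gap alignment parameters (penalties are positive numbers)."""

    gap_open: float = 10.0
    gap_extend: float = 0.5
    matrix: str = "BLOSUM62"   # proteins
    match: float = 2.0         # DNA
    mismatch: float = -1.0     # DNA
    kmer: int = 3


def _protein_score_matrix(name: str) -> np.ndarray:
    sub = substitution_matrices.load(name)
    k = len(PROTEIN_ALPHABET)
    S = np.zeros((k, k))
    for i, a in enumerate(PROTEIN_ALPHABET):
        for j, b in enumerate(PROTEIN_ALPHABET):
            S[i, j] = sub[a, b]
    return S


def _dna_score_matrix(match: float, mismatch: float) -> np.ndarray:
    k = len(DNA_ALPHABET)
    S = np.full((k, k), mismatch)
    np.fill_diagonal(S, match)
    return S


def _to_profile(gapped: list[str], alphabet: str, allow_ambiguous: bool) -> np.ndarray:
    """Column frequency profile (L, |alphabet|); gaps and ambiguous symbols
    contribute zero weight."""
    idx = {c: i for i, c in enumerate(alphabet)}
    L = len(gapped[0])
    prof = np.zeros((L, len(alphabet)))
    for row in gapped:
        for j, c in enumerate(row.upper()):
            if c == "-":
                continue
            i = idx.get(c)
            if i is None:
                if allow_ambiguous and c in "NX*":
                    continue
                raise ValueError(f"symbol {c!r} not in alphabet {alphabet!r}")
            prof[j, i] += 1
    return prof / len(gapped)


def _profile_align(
    prof_a: np.ndarray,
    prof_b: np.ndarray,
    S: np.ndarray,
    gap_open: float,
    gap_extend: float,
) -> list[str]:
    """Affine-gap DP between two profiles; returns the op string over
    {'D','U','L'} (both advance / A only / B only)."""
    La, Lb = len(prof_a), len(prof_b)
    col = prof_a @ S @ prof_b.T  # (La, Lb) expected column score

    M = np.full((La + 1, Lb + 1), NEG)
    X = np.full((La + 1, Lb + 1), NEG)  # gap in B: A row consumed
    Y = np.full((La + 1, Lb + 1), NEG)  # gap in A: B column consumed
    M[0, 0] = 0.0
    if La >= 1:
        X[1:, 0] = -gap_open - gap_extend * np.arange(La)
    if Lb >= 1:
        Y[0, 1:] = -gap_open - gap_extend * np.arange(Lb)

    for i in range(1, La + 1):
        prev = np.maximum(np.maximum(M[i - 1, :-1], X[i - 1, :-1]), Y[i - 1, :-1])
        M[i, 1:] = col[i - 1] + prev
        X[i] = np.maximum(M[i - 1] - gap_open, X[i - 1] - gap_extend)
        # Y[i, j] = max(M[i, j-1] - open, Y[i, j-1] - ext), unrolled to a
        # running max of M[i, k] - open + k*ext over k <= j-1
        a = M[i, :-1] - gap_open + gap_extend * np.arange(Lb)
        run = np.maximum.accumulate(a)
        Y[i, 1:] = run - gap_extend * np.arange(Lb)

    # traceback
    i, j = La, Lb
    state = int(np.argmax([M[i, j], X[i, j], Y[i, j]]))  # 0=M 1=X 2=Y
    ops: list[str] = []
    while i > 0 or j > 0:
        if state == 0:
            ops.append("D")
            trio = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            state = int(np.argmax(trio))
            i -= 1
            j -= 1
        elif state == 1:
            ops.append("U")
            state = 0 if M[i - 1, j] - gap_open >= X[i - 1, j] - gap_extend else 1
            i -= 1
        else:
            ops.append("L")
            state = 0 if M[i, j - 1] - gap_open >= Y[i, j - 1] - gap_extend else 2
            j -= 1
    ops.reverse()
    return ops


def _apply_ops(rows_a: dict[str, str], rows_b: dict[str, str], ops: list[str]) -> dict[str, str]:
    out: dict[str, list[str]] = {k: [] for k in list(rows_a) + list(rows_b)}
    ia = ib = 0
    for op in ops:
        if op == "D":
            for k, r in rows_a.items():
                out[k].append(r[ia])
            for k, r in rows_b.items():
                out[k].append(r[ib])
            ia += 1
            ib += 1
        elif op == "U":
            for k, r in rows_a.items():
                out[k].append(r[ia])
            for k in rows_b:
                out[k].append("-")
            ia += 1
        else:
            for k in rows_a:
                out[k].append("-")
            for k, r in rows_b.items():
                out[k].append(r[ib])
            ib += 1
    return {k: "".join(v) for k, v in out.items()}


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    c: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        w = seq[i:i + k]
        c[w] = c.get(w, 0) + 1
    return c


def kmer_distance(a: str, b: str, k: int) -> float:
    """1 - (shared k-mers / smaller k-mer total); 0 for identical sequences."""
    ca, cb = _kmer_counts(a, k), _kmer_counts(b, k)
    shared = sum(min(n, cb.get(w, 0)) for w, n in ca.items())
    denom = min(sum(ca.values()), sum(cb.values()))
    if denom == 0:
        return 1.0
    return 1.0 - shared / denom


def guide_tree(seqs: dict[str, str], k: int):
    """Neighbor-joining tree from pairwise k-mer distances (scikit-bio)."""
    ids = sorted(seqs)
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = kmer_distance(seqs[ids[i]], seqs[ids[j]], k)
            dm[i, j] = dm[j, i] = d
    return nj(DistanceMatrix(dm, ids))


def progressive_align(
    seqs: dict[str, str],
    kind: str = "protein",
    params: AlignParams | None = None,
) -> dict[str, str]:
    """Progressive multiple alignment of named sequences.

    ``kind`` is ``"protein"`` or ``"dna"``.  Deterministic for fixed inputs
    and parameters.  A single sequence aligns to itself; two sequences skip
    the guide tree.
    """
    if params is None:
        params = AlignParams()
    if not seqs:
        raise ValueError("no sequences to align")
    for name, s in seqs.items():
        if not s:
            raise ValueError(f"empty sequence for {name!r}")
    if kind == "protein":
        S = _protein_score_matrix(params.matrix)
        alphabet, allow_amb = PROTEIN_ALPHABET, True
        for name, s in seqs.items():
            bad = set(s.upper()) - set(PROTEIN_ALPHABET) - {"X"}
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains non-amino-acid symbols {sorted(bad)}"
                )
    elif kind == "dna":
        S = _dna_score_matrix(params.match, params.mismatch)
        alphabet, allow_amb = DNA_ALPHABET, True
        for name, s in seqs.items():
            bad = set(s.upper()) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"sequence {name!r} contains non-nucleotide symbols {sorted(bad)}"
                )
    else:
        raise ValueError(f"unknown kind {kind!r}")

    names = sorted(seqs)
    if len(names) == 1:
        return {names[0]: seqs[names[0]]}

    def merge(group_a: dict[str, str], group_b: dict[str, str]) -> dict[str, str]:
        pa = _to_profile(list(group_a.values()), alphabet, allow_amb)
        pb = _to_profile(list(group_b.values()), alphabet, allow_amb)
        ops = _profile_align(pa, pb, S, params.gap_open, params.gap_extend)
        return _apply_ops(group_a, group_b, ops)

    if len(names) == 2:
        return merge({names[0]: seqs[names[0]]}, {names[1]: seqs[names[1]]})

    tree = guide_tree(seqs, params.kmer)

    def build(node) -> dict[str, str]:
        if node.is_tip():
            return {node.name: seqs[node.name]}
        children = [build(c) for c in node.children]
        acc = children[0]
        for nxt in children[1:]:
            acc = merge(acc, nxt)
        return acc

    return build(tree.root())


def pairwise_align(
    a: str, b: str, kind: str = "dna", params: AlignParams | None = None
) -> tuple[str, str]:
    """Global pairwise alignment via the same engine."""
    res = progressive_align({"a": a, "b": b}, kind=kind, params=params)
    return res["a"], res["b"]


def percent_identity(row_a: str, row_b: str) -> float:
    """Identity over aligned columns, gap-gap columns excluded, gap-base
    columns counted as differences; percentage in [0, 100]."""
    same = total = 0
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            continue
        total += 1
        if x == y:
            same += 1
    if total == 0:
        raise ValueError("no aligned columns")
    return 100.0 * same / total
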