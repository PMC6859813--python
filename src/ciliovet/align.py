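"""Minimal deterministic progressive aligner.

Guide tree: neighbor joining on k-mer distances, midpoint-rooted. Merges:
profile-profile global alignment with affine gaps, profile columns scored by
the expected BLOSUM62 substitution score between column residue
distributions. This is plumbing for realignment after clade extraction —
adequate for the moderately diverged, mostly indel-free protein families the
vetting stage handles, and deterministic given the input.
"""
from __future__ import annotations

import numpy as np
from numba import njit
from Bio.Align import substitution_matrices

from .model import AA_ALPHABET, N_STATES
from .treebuild import kmer_distance_matrix, neighbor_joining


def _blosum20() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    letters = m.alphabet
    out = np.zeros((N_STATES, N_STATES))
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            out[i, j] = m[letters.index(a), letters.index(b)]
    return out


_S20 = _blosum20()
GAP_FIRST = 12.0  # opening a gap (first gap column)
GAP_EXT = 1.0


@njit(cache=False)
def _gotoh(C, gfA, geA, gfB, geB):  # pragma: no cover - numba kernel
    # global affine DP on a profile-profile score matrix; gap penalties are
    # per-position (occupancy-scaled): gfA/geA penalise gapping B against
    # A's row i, gfB/geB penalise gapping A against B's column j
    n, m = C.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in B (consume A row)
    Y = np.full((n + 1, m + 1), NEG)  # gap in A (consume B col)
    tb = np.zeros((n + 1, m + 1, 3), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -gfA[0] if i == 1 else X[i - 1, 0] - geA[i - 1]
        tb[i, 0, 1] = 1
    for j in range(1, m + 1):
        Y[0, j] = -gfB[0] if j == 1 else Y[0, j - 1] - geB[j - 1]
        tb[0, j, 2] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M: diagonal
            best = M[i - 1, j - 1]
            src = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                src = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                src = 2
            M[i, j] = best + C[i - 1, j - 1]
            tb[i, j, 0] = src
            # X: gap in B
            a = M[i - 1, j] - gfA[i - 1]
            b = X[i - 1, j] - geA[i - 1]
            if a >= b:
                X[i, j] = a
                tb[i, j, 1] = 0
            else:
                X[i, j] = b
                tb[i, j, 1] = 1
            # Y: gap in A
            a = M[i, j - 1] - gfB[j - 1]
            b = Y[i, j - 1] - geB[j - 1]
            if a >= b:
                Y[i, j] = a
                tb[i, j, 2] = 0
            else:
                Y[i, j] = b
                tb[i, j, 2] = 2
    state = 0
    best = M[n, m]
    if X[n, m] > best:
        best = X[n, m]
        state = 1
    if Y[n, m] > best:
        best = Y[n, m]
        state = 2
    # traceback: 0 = match, 1 = consume A, 2 = consume B
    path = np.empty(n + m, dtype=np.int8)
    k = n + m
    i, j = n, m
    while i > 0 or j > 0:
        k -= 1
        if state == 0:
            prev = tb[i, j, 0]
            path[k] = 0
            i -= 1
            j -= 1
            state = prev
        elif state == 1:
            prev = tb[i, j, 1]
            path[k] = 1
            i -= 1
            state = 0 if prev == 0 else 1
        else:
            prev = tb[i, j, 2]
            path[k] = 2
            j -= 1
            state = 0 if prev == 0 else 2
    return best, path[k:]


_LUT = np.full(256, -1, dtype=np.int8)
for _i, _ch in enumerate(AA_ALPHABET):
    _LUT[ord(_ch)] = _i


def _encode_rows(rows: list[str]) -> np.ndarray:
    arr = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return _LUT[arr].reshape(len(rows), len(rows[0]))


def _profile(rows: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(residue-frequency matrix, per-column occupancy)."""
    codes = _encode_rows(rows)
    L = codes.shape[1]
    F = np.zeros((L, N_STATES))
    rr, cc = np.nonzero(codes >= 0)
    np.add.at(F, (cc, codes[rr, cc]), 1.0)
    occ = F.sum(axis=1)
    tot = np.where(occ == 0, 1.0, occ)
    return F / tot[:, None], occ / len(rows)


def _merge(rows_a: list[str], rows_b: list[str]) -> tuple[list[str], list[str]]:
    Fa, occ_a = _profile(rows_a)
    Fb, occ_b = _profile(rows_b)
    C = (occ_a[:, None] * occ_b[None, :]) * (Fa @ _S20 @ Fb.T)
    # gapping against a mostly-gap column is cheap (occupancy scaling)
    _, path = _gotoh(
        C,
        GAP_FIRST * occ_a, GAP_EXT * occ_a,
        GAP_FIRST * occ_b, GAP_EXT * occ_b,
    )
    path = np.asarray(path)

    def expand(rows, consume_mask):
        M = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
        M = M.reshape(len(rows), -1)
        out = np.full((len(rows), len(path)), ord("-"), dtype=np.uint8)
        out[:, consume_mask] = M
        return [bytes(r).decode("ascii") for r in out]

    return expand(rows_a, path != 2), expand(rows_b, path != 1)


@njit(cache=False)
def _sp_score(codes, S, gap_first, gap_ext):  # pragma: no cover - numba kernel
    """Affine sum-of-pairs score of an alignment (rows as int codes,
    gap = -1); every pairwise projection skips double-gap columns."""
    k, L = codes.shape
    total = 0.0
    for a in range(k):
        for b in range(a + 1, k):
            in_gap = 0
            for j in range(L):
                ca = codes[a, j]
                cb = codes[b, j]
                if ca < 0 and cb < 0:
                    continue
                if ca < 0 or cb < 0:
                    if in_gap == 0:
                        total -= gap_first
                    else:
                        total -= gap_ext
                    in_gap = 1
                else:
                    total += S[ca, cb]
                    in_gap = 0
    return total


def sp_score(rows: list[str]) -> float:
    """Affine sum-of-pairs score under the aligner's scoring scheme."""
    return float(_sp_score(_encode_rows(rows), _S20, GAP_FIRST, GAP_EXT))


def _strip_allgap_columns(rows: list[str]) -> list[str]:
    M = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    M = M.reshape(len(rows), -1)
    keep = (M != ord("-")).any(axis=0)
    return [bytes(r).decode("ascii") for r in M[:, keep]]


def _refine(labels: list[str], rows: list[str], rounds: int) -> list[str]:
    """Leave-one-out refinement: realign each sequence to the profile of
    the rest, keeping the move only if the sum-of-pairs score improves."""
    best = sp_score(rows)
    for _ in range(rounds):
        improved = False
        for i in range(len(rows)):
            rest = _strip_allgap_columns(rows[:i] + rows[i + 1 :])
            rest_out, one_out = _merge(rest, [rows[i].replace("-", "")])
            cand = rest_out[:i] + one_out + rest_out[i:]
            s = sp_score(cand)
            if s > best + 1e-9:
                rows, best, improved = cand, s, True
        if not improved:
            break
    return rows


def progressive_align(seqs, refine: int = 1) -> dict:
    """Align SeqRecordX-like records (``.id``/``.seq``); returns id -> row.

    Requires >= 2 sequences; gap characters in the inputs are stripped
    before alignment.
    """
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("progressive alignment needs >= 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    clean = {s.id: s.seq.replace("-", "") for s in seqs}
    if len(seqs) == 2:
        (a,), (b,) = _merge([clean[ids[0]]], [clean[ids[1]]])
        return {ids[0]: a, ids[1]: b}
    D = kmer_distance_matrix([clean[i] for i in ids], k=3)
    guide = neighbor_joining(ids, D)
    guide.t.reroot_at_midpoint(update_bipartitions=False)

    def walk(node) -> tuple[list[str], list[str]]:
        if node.is_leaf():
            lbl = node.taxon.label
            return [lbl], [clean[lbl]]
        parts = [walk(ch) for ch in node.child_nodes()]
        labels, rows = parts[0]
        for lab2, rows2 in parts[1:]:
            rows, rows2 = _merge(rows, rows2)
            labels = labels + lab2
            rows = rows + rows2
        return labels, rows

    labels, rows = walk(guide.t.seed_node)
    if refine:
        rows = _refine(labels, rows, refine)
    return dict(zip(labels, rows))
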