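"""Distance-based tree building: ML pairwise distances, neighbor joining,
and nonparametric bootstrap support.

NJ is implemented directly (saitou-nei Q-criterion, negative branch lengths
clamped to zero with the deficit moved to the sibling) so that its
additivity guarantees can be asserted exactly; trees are emitted through the
package's PhyloTree wrapper.
"""
from __future__ import annotations

from typing import Callable, Iterable, Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .model import N_STATES, SubstModel, encode_alignment
from .trees import PhyloTree

_MAX_DIST = 10.0


def ml_pairwise_distance(
    codes_a: np.ndarray, codes_b: np.ndarray, model: SubstModel
) -> tuple[float, bool]:
    """Two-sequence ML distance under the model; (distance, fallback_used).

    Falls back to a capped corrected p-distance when the likelihood surface
    is degenerate (e.g. saturation).
    """
    shared = (codes_a >= 0) & (codes_b >= 0)
    if not shared.any():
        raise ValueError("zero pairwise overlap")
    a, b = codes_a[shared], codes_b[shared]
    rates = model.category_rates()
    weights = model.category_weights()
    freqs = model.freqs
    pinv = model.p_invariant
    n = float(a.shape[0])
    same = float((a == b).sum())
    p = 1.0 - same / n

    if model._uniform_poisson:
        # two-sequence MLE has a scalar sufficient statistic: match the
        # expected identity q(t) = 1/20 + 19/20 * E_c[exp(-beta*t*r_c)]
        from scipy.optimize import brentq

        beta = N_STATES / (N_STATES - 1.0)
        if p <= 0:
            return 0.0, False
        target = (same / n - 1.0 / N_STATES) / (1.0 - 1.0 / N_STATES)

        def g(t):
            return float(weights @ np.exp(-beta * t * rates)) - target

        lo, hi = 1e-9, _MAX_DIST
        glo, ghi = g(lo), g(hi)
        if glo <= 0:
            return 0.0, False
        if ghi >= 0:
            return _MAX_DIST, True
        return float(brentq(g, lo, hi, xtol=1e-8)), False

    Nxy = np.zeros((N_STATES, N_STATES))
    np.add.at(Nxy, (a, b), 1.0)

    def negll(t):
        M = np.zeros((N_STATES, N_STATES))
        for w, r in zip(weights, rates):
            M += w * model.transition_matrix(r * t)
        if pinv > 0:
            M += pinv * np.eye(N_STATES)
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(freqs[:, None] * M, 1e-300))
        return -float((Nxy * lp).sum())

    if p <= 0:
        return 0.0, False
    res = minimize_scalar(negll, bounds=(1e-9, _MAX_DIST), method="bounded")
    if res.success and res.x < _MAX_DIST * 0.999:
        return float(res.x), False
    # corrected p-distance fallback (F81-style correction, capped)
    b_ = 1.0 - float(freqs @ freqs)
    if p >= b_:
        return _MAX_DIST, True
    return float(-b_ * np.log(1.0 - p / b_)), True


def pairwise_distance(
    alignment: dict, model: SubstModel
) -> tuple[list[str], np.ndarray]:
    """ML distance matrix over all rows of an aligned dict label->row."""
    labels = sorted(alignment)
    if len(labels) < 2:
        raise ValueError("need >= 2 sequences")
    codes = encode_alignment([alignment[l] for l in labels])
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d, _ = ml_pairwise_distance(codes[i], codes[j], model)
            except ValueError as e:
                raise ValueError(f"pair ({labels[i]}, {labels[j]}): {e}") from e
            D[i, j] = D[j, i] = d
    return labels, D


def neighbor_joining(labels: list[str], D: np.ndarray) -> PhyloTree:
    """Standard NJ; returns an unrooted tree (trifurcating seed node)."""
    D = np.asarray(D, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    if D.shape != (n, n) or not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be square and symmetric")

    def fmt(sub, bl):
        return f"{sub}:{float(bl)!r}"

    nodes = [lbl for lbl in labels]  # newick fragments
    act = list(range(n))
    Dw = D.copy()
    while len(act) > 3:
        m = len(act)
        sub = Dw[np.ix_(act, act)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        ai, aj = act[i_], act[j_]
        dij = sub[i_, j_]
        li = 0.5 * dij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        new = f"({fmt(nodes[ai], li)},{fmt(nodes[aj], lj)})"
        # distances to the new node
        dnew = 0.5 * (Dw[ai, act] + Dw[aj, act] - dij)
        Dw = np.pad(Dw, ((0, 1), (0, 1)))
        k = Dw.shape[0] - 1
        Dw[k, act] = dnew
        Dw[act, k] = dnew
        nodes.append(new)
        act = [a for a in act if a not in (ai, aj)] + [k]
    a, b, c = act
    la = 0.5 * (Dw[a, b] + Dw[a, c] - Dw[b, c])
    lb = 0.5 * (Dw[a, b] + Dw[b, c] - Dw[a, c])
    lc = 0.5 * (Dw[a, c] + Dw[b, c] - Dw[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = f"({fmt(nodes[a], la)},{fmt(nodes[b], lb)},{fmt(nodes[c], lc)});"
    return PhyloTree.from_newick(newick)


def nj_tree(alignment: dict, model: Optional[SubstModel] = None) -> PhyloTree:
    """NJ tree from ML model distances on an alignment dict."""
    model = model or SubstModel()
    labels, D = pairwise_distance(alignment, model)
    return neighbor_joining(labels, D)


# -- k-mer distances (guide trees, no model) -------------------------------

def kmer_distance_matrix(seqs: list[str], k: int = 3) -> np.ndarray:
    sets = [
        {s[i : i + k] for i in range(max(len(s) - k + 1, 0))} or {s} for s in seqs
    ]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(sets[i] & sets[j])
            denom = min(len(sets[i]), len(sets[j])) or 1
            D[i, j] = D[j, i] = 1.0 - inter / denom
    return D


# -- bootstrap -------------------------------------------------------------

def bootstrap_support(
    alignment: dict,
    tree_builder: Callable[[dict], PhyloTree],
    n: int = 1000,
    seed: int = 0,
    tree: Optional[PhyloTree] = None,
) -> tuple[PhyloTree, dict]:
    """Column-resampling bootstrap; support = % replicates containing each split.

    Returns (tree whose internal nodes carry ``support`` attributes, and a
    dict split(frozenset) -> support percentage).
    """
    rng = np.random.default_rng(seed)
    labels = sorted(alignment)
    L = len(alignment[labels[0]])
    base = tree if tree is not None else tree_builder(alignment)
    counts: dict = {}
    for _ in range(n):
        idx = rng.integers(0, L, size=L)
        rep = {l: "".join(alignment[l][i] for i in idx) for l in labels}
        try:
            rt = tree_builder(rep)
        except ValueError:
            continue
        for bp in rt.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1
    support = {bp: 100.0 * c / n for bp, c in counts.items()}
    ref = min(labels)
    full = set(labels)
    for nd in base.t.preorder_internal_node_iter():
        if nd.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in nd.leaf_iter())
        if ref in side:
            side = frozenset(full - side)
        nd.support = support.get(side, 0.0)
    return base, support
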