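"""Felsenstein pruning, branch-length optimisation and site-rate estimation.

Likelihoods are computed over the discrete-gamma categories (plus an
optional invariant class); gaps and unknown residues are missing data
(partial likelihood 1 in every state). Per-node scaling keeps partials in
range on deeper trees; all per-site quantities are combined in log space.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .model import N_STATES, SubstModel, encode_alignment
from .trees import PhyloTree

_MIN_BL = 1e-9
_MAX_BL = 20.0


@dataclass
class _FlatTree:
    """Array view of a rooted-for-computation tree."""

    parent: np.ndarray       # parent index per node, -1 for root
    children: list           # list of child-index lists
    lengths: np.ndarray      # branch length above each node
    postorder: np.ndarray
    leaf_index: dict         # leaf label -> node index
    nodes: list              # dendropy node per index


def flatten(tree: PhyloTree) -> _FlatTree:
    nodes = list(tree.t.preorder_node_iter())
    idx = {id(n): i for i, n in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    children: list = [[] for _ in nodes]
    lengths = np.zeros(len(nodes))
    leaf_index = {}
    for i, n in enumerate(nodes):
        if n.parent_node is not None:
            p = idx[id(n.parent_node)]
            parent[i] = p
            children[p].append(i)
            lengths[i] = max(n.edge.length or 0.0, 0.0)
        if n.is_leaf():
            leaf_index[n.taxon.label] = i
    post = np.array(
        sorted(range(len(nodes)), key=lambda i: -i), dtype=int
    )  # preorder reversed = valid postorder
    return _FlatTree(parent, children, lengths, post, leaf_index, nodes)


def _leaf_partials(codes: np.ndarray) -> np.ndarray:
    """(L, 20) indicator partials for one sequence; missing -> ones."""
    L = codes.shape[0]
    out = np.zeros((L, N_STATES))
    miss = codes < 0
    out[np.arange(L)[~miss], codes[~miss]] = 1.0
    out[miss] = 1.0
    return out


class TreeLikelihood:
    """Pruning engine bound to one tree + alignment + model.

    ``alignment`` maps leaf label -> aligned amino-acid row (equal lengths).
    """

    def __init__(self, tree: PhyloTree, alignment: dict, model: SubstModel):
        self.tree = tree
        self.model = model
        self.ft = flatten(tree)
        labels = sorted(alignment)
        if set(labels) != set(self.ft.leaf_index):
            raise ValueError(
                "alignment rows and tree leaves disagree: "
                f"{sorted(set(labels) ^ set(self.ft.leaf_index))}"
            )
        codes = encode_alignment([alignment[l] for l in labels])
        self.L = codes.shape[1]
        self.leaf_part = {}
        for r, lab in enumerate(labels):
            self.leaf_part[self.ft.leaf_index[lab]] = _leaf_partials(codes[r])
        self.codes = {self.ft.leaf_index[l]: codes[r] for r, l in enumerate(labels)}
        self.rates = model.category_rates()
        self.weights = model.category_weights()

    # -- core pruning ------------------------------------------------------
    def _up_pass(self, lengths: Optional[np.ndarray] = None):
        """Partials (ncat, L, 20) and log-scalers (ncat, L) per node."""
        ft = self.ft
        if lengths is None:
            lengths = ft.lengths
        ncat = len(self.rates)
        up = [None] * len(ft.nodes)
        scale = [None] * len(ft.nodes)
        for i in ft.postorder:
            if not ft.children[i]:
                p = self.leaf_part[i]
                up[i] = np.broadcast_to(p, (ncat,) + p.shape)
                scale[i] = np.zeros((ncat, self.L))
                continue
            acc = np.ones((ncat, self.L, N_STATES))
            sc = np.zeros((ncat, self.L))
            for ch in ft.children[i]:
                msgs = np.empty((ncat, self.L, N_STATES))
                for c, r in enumerate(self.rates):
                    P = self.model.transition_matrix(r * lengths[ch])
                    msgs[c] = up[ch][c] @ P.T
                acc *= msgs
                sc += scale[ch]
            m = acc.max(axis=2)
            m[m == 0.0] = 1.0
            acc /= m[:, :, None]
            sc += np.log(m)
            up[i] = acc
            scale[i] = sc
        return up, scale

    def _invariant_loglik_part(self) -> np.ndarray:
        """log(p_inv * pi_x) for constant-or-missing sites, -inf otherwise."""
        pinv = self.model.p_invariant
        out = np.full(self.L, -np.inf)
        if pinv <= 0:
            return out
        freqs = self.model.freqs
        # a site can be invariant iff some state is compatible with every row
        compat = np.ones((self.L, N_STATES), bool)
        for i, codes in self.codes.items():
            obs = codes >= 0
            rowc = np.ones((self.L, N_STATES), bool)
            rowc[obs] = False
            rowc[np.arange(self.L)[obs], codes[obs]] = True
            compat &= rowc
        with np.errstate(divide="ignore"):
            vals = np.where(compat, freqs[None, :], 0.0).sum(axis=1)
            out = np.where(vals > 0, np.log(pinv * np.maximum(vals, 1e-300)), -np.inf)
        return out

    def site_loglik(self, lengths: Optional[np.ndarray] = None) -> np.ndarray:
        """Per-site log-likelihood vector (length = alignment columns)."""
        up, scale = self._up_pass(lengths)
        root = 0
        freqs = self.model.freqs
        ncat = len(self.rates)
        per_cat = np.empty((ncat, self.L))
        vals = up[root] @ freqs  # (ncat, L)
        with np.errstate(divide="ignore"):
            per_cat = np.log(np.maximum(vals, 1e-300)) + scale[root]
        logw = np.log(self.weights)
        var_part = logsumexp(per_cat + logw[:, None], axis=0)
        if self.model.p_invariant > 0:
            inv = self._invariant_loglik_part()
            return np.logaddexp(var_part, inv)
        return var_part

    def loglik(self, lengths: Optional[np.ndarray] = None) -> float:
        return float(self.site_loglik(lengths).sum())

    # -- posterior site rates ---------------------------------------------
    def site_rates(self) -> np.ndarray:
        """Empirical-Bayes posterior mean rate per site."""
        up, scale = self._up_pass()
        freqs = self.model.freqs
        vals = up[0] @ freqs
        with np.errstate(divide="ignore"):
            logc = np.log(np.maximum(vals, 1e-300)) + scale[0] + np.log(self.weights)[:, None]
        rates = list(self.rates)
        if self.model.p_invariant > 0:
            inv = self._invariant_loglik_part()
            logc = np.vstack([logc, inv[None, :]])
            rates = rates + [0.0]
        logZ = logsumexp(logc, axis=0)
        post = np.exp(logc - logZ[None, :])
        return post.T @ np.array(rates)

    # -- branch-length optimisation ----------------------------------------
    def _down_pass(self, up, scale, lengths):
        """G messages: joint prob of data outside subtree(v) and the state
        at v's parent (per cat, site, state), with log-scalers."""
        ft = self.ft
        ncat = len(self.rates)
        G = [None] * len(ft.nodes)
        Gs = [None] * len(ft.nodes)
        order = [i for i in range(len(ft.nodes))]  # preorder
        freqs = self.model.freqs
        # messages from child subtrees through their edges, cached
        def edge_msg(ch):
            msgs = np.empty((ncat, self.L, N_STATES))
            for c, r in enumerate(self.rates):
                P = self.model.transition_matrix(r * lengths[ch])
                msgs[c] = up[ch][c] @ P.T
            return msgs

        msg_cache = {}
        for i in order:
            for ch in ft.children[i]:
                msg_cache[ch] = edge_msg(ch)
        for v in order:
            u = ft.parent[v]
            if u == -1:
                continue
            acc = np.ones((ncat, self.L, N_STATES))
            sc = np.zeros((ncat, self.L))
            for sib in ft.children[u]:
                if sib == v:
                    continue
                acc *= msg_cache[sib]
                sc += scale[sib]
            if u == 0:  # parent is root: include stationary freqs
                acc *= freqs[None, None, :]
            else:
                # pass parent's own G through the edge above u
                down = np.empty((ncat, self.L, N_STATES))
                for c, r in enumerate(self.rates):
                    P = self.model.transition_matrix(r * lengths[u])
                    down[c] = G[u][c] @ P
                acc *= down
                sc += Gs[u]
            m = acc.max(axis=2)
            m[m == 0.0] = 1.0
            acc /= m[:, :, None]
            sc += np.log(m)
            G[v] = acc
            Gs[v] = sc
        return G, Gs

    def _edge_loglik_fn(self, G, Gs, up, scale, v):
        """Return f(t) = total logL as a function of edge-above-v length,
        via the model's eigenbasis (cheap per evaluation)."""
        Vb = self.model._V
        Wb = self.model._W
        evals = self.model._evals
        ncat = len(self.rates)
        AB = np.empty((ncat, self.L, N_STATES))
        for c in range(ncat):
            AB[c] = (G[v][c] @ Vb) * (up[v][c] @ Wb.T)
        sc = Gs[v] + scale[v] + np.log(self.weights)[:, None]
        inv = self._invariant_loglik_part() if self.model.p_invariant > 0 else None
        rates = self.rates

        def f(t):
            per_cat = np.empty((ncat, self.L))
            for c in range(ncat):
                vals = AB[c] @ np.exp(evals * (rates[c] * t))
                per_cat[c] = np.log(np.maximum(vals, 1e-300))
            tot = logsumexp(per_cat + sc, axis=0)
            if inv is not None:
                tot = np.logaddexp(tot, inv)
            return float(tot.sum())

        return f

    def optimize_branch_lengths(
        self, max_sweeps: int = 20, tol: float = 1e-4, bl_tol: float = 1e-6
    ) -> tuple[PhyloTree, float]:
        """Coordinate-wise branch-length optimisation (Brent per branch).

        Messages are refreshed once per sweep; a sweep's update is accepted
        only if the total log-likelihood improved, so the total is
        non-decreasing across sweeps. Returns (tree with new lengths, logL).
        """
        ft = self.ft
        lengths = ft.lengths.copy()
        best = self.loglik(lengths)
        for _ in range(max_sweeps):
            up, scale = self._up_pass(lengths)
            G, Gs = self._down_pass(up, scale, lengths)
            new = lengths.copy()
            for v in range(len(ft.nodes)):
                if ft.parent[v] == -1:
                    continue
                f = self._edge_loglik_fn(G, Gs, up, scale, v)
                res = minimize_scalar(
                    lambda t: -f(t),
                    bounds=(_MIN_BL, _MAX_BL),
                    method="bounded",
                    options={"xatol": bl_tol},
                )
                new[v] = float(res.x)
            cand = self.loglik(new)
            if cand < best:
                # stale-message overshoot: damp towards previous lengths
                mid = 0.5 * (lengths + new)
                cand_mid = self.loglik(mid)
                if cand_mid > best:
                    new, cand = mid, cand_mid
                else:
                    break
            improved = cand - best
            lengths, best = new, cand
            if improved < tol:
                break
        out = self.tree.copy()
        oft = flatten(out)
        for i, nd in enumerate(oft.nodes):
            if oft.parent[i] != -1:
                nd.edge.length = float(lengths[i])
        self.ft.lengths = lengths
        return out, best


# -- module-level convenience wrappers -------------------------------------

def site_loglik(tree: PhyloTree, alignment: dict, model: SubstModel) -> np.ndarray:
    return TreeLikelihood(tree, alignment, model).site_loglik()


def optimize_branch_lengths(
    tree: PhyloTree, alignment: dict, model: SubstModel, **kw
) -> tuple[PhyloTree, float]:
    return TreeLikelihood(tree, alignment, model).optimize_branch_lengths(**kw)


def estimate_site_rates(tree: PhyloTree, alignment: dict, model: SubstModel) -> np.ndarray:
    return TreeLikelihood(tree, alignment, model).site_rates()


def fit_gamma_shape(
    tree: PhyloTree,
    alignment: dict,
    n_categories: int = 4,
    shapes=(0.2, 0.35, 0.5, 0.8, 1.2, 2.0, 5.0, 20.0, 100.0),
    **model_kw,
) -> tuple[float, float]:
    """Profile the gamma shape over a grid, re-optimising branch lengths at
    each value; returns (best shape, its maximized logL). A very large
    shape approximates rate homogeneity, so richer rate models fitted this
    way nest the single-rate model."""
    best = (None, -np.inf)
    for a in shapes:
        model = SubstModel(gamma_shape=a, n_categories=n_categories, **model_kw)
        tl = TreeLikelihood(tree, alignment, model)
        _, ll = tl.optimize_branch_lengths()
        if ll > best[1]:
            best = (a, ll)
    return best
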