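"""Topology tests among fixed candidate trees by RELL resampling.

All four statistics operate on per-site log-likelihood vectors computed
once per hypothesis tree (branch lengths optimised on the fixed topology,
no re-optimisation within resamples): the RELL bootstrap proportion, the
one-sided Kishino–Hasegawa test, the Shimodaira–Hasegawa test with the
centred max statistic, and the approximately unbiased test by multiscale
bootstrap with probit-scale weighted least squares extrapolation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .likelihood import TreeLikelihood
from .model import SubstModel
from .trees import PhyloTree


def rell_matrix(site_logL: np.ndarray, n: int = 10000, seed: int = 0) -> np.ndarray:
    """Resampled totals, shape (n, n_trees).

    ``site_logL``: (n_trees, L). Each resample draws L sites with
    replacement once and applies the same index set to every tree.
    """
    site_logL = np.atleast_2d(np.asarray(site_logL, dtype=float))
    ntrees, L = site_logL.shape
    if L == 0:
        raise ValueError("no sites")
    rng = np.random.default_rng(seed)
    out = np.empty((n, ntrees))
    for b in range(n):
        idx = rng.integers(0, L, size=L)
        out[b] = site_logL[:, idx].sum(axis=1)
    return out


def bp_rell(resampled_totals: np.ndarray) -> np.ndarray:
    """Per-tree fraction of resamples won (argmax); exact ties split equally."""
    T = np.asarray(resampled_totals, dtype=float)
    n, k = T.shape
    best = T.max(axis=1, keepdims=True)
    winners = T >= best - 1e-12
    weights = winners / winners.sum(axis=1, keepdims=True)
    return weights.sum(axis=0) / n


def kh_test(
    siteL_a: np.ndarray, siteL_b: np.ndarray, n: int = 10000, seed: int = 0
) -> float:
    """One-sided KH p-value for tree b against reference tree a.

    Per-site differences d = logL_a - logL_b are centred to mean zero (the
    null of equal expected log-likelihood), resampled, and the p-value is
    the fraction of resampled centred sums at or above the observed sum.
    The test is one-sided and pre-specified (signed observed difference,
    not its absolute value), which keeps it calibrated under the null; a
    clearly better tree b yields p near 1, a clearly worse one p near 0.
    """
    d = np.asarray(siteL_a, dtype=float) - np.asarray(siteL_b, dtype=float)
    L = d.shape[0]
    obs = d.sum()
    centered = d - d.mean()
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n):
        idx = rng.integers(0, L, size=L)
        if centered[idx].sum() >= obs:
            count += 1
    return count / n


def sh_test(siteL_all: np.ndarray, n: int = 10000, seed: int = 0) -> np.ndarray:
    """SH p-value per tree (centred max-statistic null over the tree set)."""
    S = np.atleast_2d(np.asarray(siteL_all, dtype=float))
    k, L = S.shape
    totals = S.sum(axis=1)
    obs_diff = totals.max() - totals  # observed best-minus-k
    centered = S - S.mean(axis=1, keepdims=True)
    rng = np.random.default_rng(seed)
    count = np.zeros(k)
    for _ in range(n):
        idx = rng.integers(0, L, size=L)
        t = centered[:, idx].sum(axis=1)
        stat = t.max() - t  # null max-statistic per tree
        count += stat >= obs_diff
    return count / n


def _au_fit(bp: np.ndarray, scales: np.ndarray, n_per_scale: int):
    """Weighted least squares of probit(1-BP_r) = d*sqrt(r) + c/sqrt(r).

    Scales whose win proportion is degenerate (0 or 1 — outside the
    binomial resolution) carry no curvature information and would bias the
    fit through clipping, so they are excluded; at least two informative
    scales are required.
    """
    usable = (bp > 0.0) & (bp < 1.0)
    if usable.sum() < 2:
        return None
    bpu = bp[usable]
    sc = scales[usable]
    eps = 0.5 / n_per_scale
    bpc = np.clip(bpu, eps, 1 - eps)
    z = norm.ppf(1.0 - bpc)
    # binomial delta-method weights on the probit scale
    w = n_per_scale * (norm.pdf(z) ** 2) / (bpc * (1 - bpc))
    X = np.column_stack([np.sqrt(sc), 1.0 / np.sqrt(sc)])
    W = np.diag(w)
    A = X.T @ W @ X
    if np.linalg.cond(A) > 1e12:
        return None
    beta = np.linalg.solve(A, X.T @ W @ z)
    d, c = beta
    return float(d), float(c)


def au_test(
    siteL_all: np.ndarray,
    scales: Sequence[float] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10)),
    n_per_scale: int = 2000,
    seed: int = 0,
) -> tuple[np.ndarray, list]:
    """AU p-value per tree via multiscale RELL bootstrap.

    At each scale r, ceil(r*L) sites are resampled and the per-tree win
    proportion recorded; probit-transformed proportions are fitted by WLS
    to d*sqrt(r) + c/sqrt(r) and p_AU = 1 - Phi(d - c). Degenerate scales
    (win proportion exactly 0 or 1) are excluded from the fit; trees with
    fewer than two informative scales get p clamped to 0 (or 1) with a
    flag, and singular fits yield NaN with a flag, never silently.
    """
    S = np.atleast_2d(np.asarray(siteL_all, dtype=float))
    k, L = S.shape
    scales = np.asarray(list(scales), dtype=float)
    rng = np.random.default_rng(seed)
    bp = np.zeros((len(scales), k))
    for si, r in enumerate(scales):
        m = int(np.ceil(r * L))
        wins = np.zeros(k)
        for _ in range(n_per_scale):
            idx = rng.integers(0, L, size=m)
            t = S[:, idx].sum(axis=1)
            best = t.max()
            winners = t >= best - 1e-12
            wins += winners / winners.sum()
        bp[si] = wins / n_per_scale
    p = np.empty(k)
    flags: list = []
    for j in range(k):
        usable = int(((bp[:, j] > 0) & (bp[:, j] < 1)).sum())
        if usable < 2:
            # (almost) never or always winning: no multiscale information
            mean_bp = float(bp[:, j].mean())
            p[j] = 0.0 if mean_bp < 0.5 else 1.0
            flags.append(
                (j, "bp_zero_all_scales" if mean_bp < 0.5 else "bp_one_all_scales")
            )
            continue
        fit = _au_fit(bp[:, j], scales, n_per_scale)
        if fit is None:
            p[j] = np.nan
            flags.append((j, "fit_singular"))
            continue
        d, c = fit
        p[j] = float(1.0 - norm.cdf(d - c))
    return p, flags


@dataclass
class TopologyTestResult:
    tree_ids: list
    logL: np.ndarray
    bp: np.ndarray
    kh: np.ndarray
    sh: np.ndarray
    au: np.ndarray
    n_resamples: int
    seed: int

    def as_table(self) -> "object":
        import pandas as pd

        return pd.DataFrame(
            {
                "tree_id": self.tree_ids,
                "logL": self.logL,
                "bp_rell": self.bp,
                "kh": self.kh,
                "sh": self.sh,
                "au": self.au,
            }
        )


def run_hypotheses(
    alignment: dict,
    model: SubstModel,
    hypothesis_trees: dict,
    n_resamples: int = 10000,
    seed: int = 0,
    au_scales: Sequence[float] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10)),
    au_n_per_scale: int = 2000,
) -> TopologyTestResult:
    """Fixed-topology tests: optimise branch lengths per hypothesis,
    compute site log-likelihoods, run all four tests.

    ``hypothesis_trees``: tree_id -> PhyloTree spanning the alignment rows.
    Results are independent of input order (ids are processed sorted).
    """
    ids = sorted(hypothesis_trees)
    site = []
    totals = []
    for tid in ids:
        tl = TreeLikelihood(hypothesis_trees[tid], alignment, model)
        tl.optimize_branch_lengths()
        v = tl.site_loglik()
        site.append(v)
        totals.append(v.sum())
    S = np.vstack(site)
    k = len(ids)
    if k == 1:
        return TopologyTestResult(ids, np.array(totals), np.ones(1), np.ones(1),
                                  np.ones(1), np.ones(1), n_resamples, seed)
    T = rell_matrix(S, n=n_resamples, seed=seed)
    bp = bp_rell(T)
    best = int(np.argmax(totals))
    kh = np.empty(k)
    for j in range(k):
        ref = best if j != best else int(np.argsort(totals)[-2])
        kh[j] = kh_test(S[ref], S[j], n=n_resamples, seed=seed + 1)
    sh = sh_test(S, n=n_resamples, seed=seed + 2)
    au, _ = au_test(S, scales=au_scales, n_per_scale=au_n_per_scale, seed=seed + 3)
    return TopologyTestResult(ids, np.array(totals), bp, kh, sh, au, n_resamples, seed)
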