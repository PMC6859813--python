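"""Supermatrix assembly: occupancy trimming, concatenation with partition
bookkeeping, missing-data accounting, parsimony-informative counting,
coverage-based gene reduction and rate-threshold site removal."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

logger = logging.getLogger("ciliovet")

MISSING = "-"


def trim_by_occupancy(rows: dict, min_frac: float = 0.60) -> dict:
    """Keep columns present (non-gap) in >= min_frac of the sequences."""
    labels = sorted(rows)
    M = np.array([list(rows[l]) for l in labels])
    if M.size == 0:
        return dict(rows)
    occ = (M != MISSING).sum(axis=0) / M.shape[0]
    keep = occ >= min_frac
    return {l: "".join(M[i, keep]) for i, l in enumerate(labels)}


@dataclass
class Supermatrix:
    taxa: list
    matrix: np.ndarray            # (n_taxa, L) of single characters
    partitions: list              # (gene, start, end) 0-based half-open
    site_rates: Optional[np.ndarray] = None

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def rows(self) -> list[str]:
        return ["".join(r) for r in self.matrix]

    def as_dict(self) -> dict:
        return dict(zip(self.taxa, self.rows()))

    @property
    def per_taxon_missing(self) -> np.ndarray:
        return (self.matrix == MISSING).sum(axis=1) / self.n_sites


def concatenate(vetted_alignments: dict, taxon_universe: list) -> Supermatrix:
    """Concatenate per-gene alignments into one matrix.

    ``vetted_alignments``: gene -> list of (taxon_id, aligned_row). A taxon
    appearing twice within one gene (a paralog leak) is an error; taxa
    absent from a gene get a missing block.
    """
    genes = sorted(vetted_alignments)
    if not genes:
        raise ValueError("no alignments to concatenate")
    idx = {t: i for i, t in enumerate(taxon_universe)}
    blocks = []
    partitions = []
    start = 0
    for gene in genes:
        pairs = vetted_alignments[gene]
        seen = set()
        for taxon, _ in pairs:
            if taxon in seen:
                raise ValueError(f"gene {gene}: duplicate taxon {taxon}")
            seen.add(taxon)
        L = len(pairs[0][1])
        if any(len(r) != L for _, r in pairs):
            raise ValueError(f"gene {gene}: ragged alignment")
        block = np.full((len(taxon_universe), L), MISSING, dtype="<U1")
        for taxon, row in pairs:
            if taxon not in idx:
                raise ValueError(f"gene {gene}: taxon {taxon} not in universe")
            block[idx[taxon]] = list(row)
        blocks.append(block)
        partitions.append((gene, start, start + L))
        start += L
    sm = Supermatrix(list(taxon_universe), np.hstack(blocks), partitions)
    logger.info(
        "supermatrix: %d taxa x %d sites from %d genes; mean missing %.3f",
        len(sm.taxa), sm.n_sites, len(genes), sm.per_taxon_missing.mean(),
    )
    return sm


def count_parsimony_informative(matrix: np.ndarray) -> int:
    """Sites with >= 2 distinct non-missing states each in >= 2 taxa."""
    n = 0
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        col = col[(col != MISSING) & (col != "X") & (col != "?")]
        if col.size < 4:
            continue
        _, counts = np.unique(col, return_counts=True)
        if (counts >= 2).sum() >= 2:
            n += 1
    return n


def reduce_by_gene_coverage(
    vetted_alignments: dict,
    ciliate_taxa: Iterable[str],
    min_taxon_frac: float = 0.80,
) -> dict:
    """Keep genes covering strictly more than min_taxon_frac of the ciliate
    taxon set (by distinct taxa present in the gene)."""
    cil = set(ciliate_taxa)
    if not cil:
        raise ValueError("empty ciliate taxon set")
    out = {}
    for gene, pairs in vetted_alignments.items():
        present = {t for t, _ in pairs} & cil
        if len(present) / len(cil) > min_taxon_frac:
            out[gene] = pairs
    logger.info("gene coverage reduction: %d/%d genes kept", len(out), len(vetted_alignments))
    return out


def remove_fast_sites(
    sm: Supermatrix, rates: np.ndarray, threshold: float
) -> Supermatrix:
    """Drop columns with posterior-mean rate >= threshold; partitions are
    re-spanned and the rate vector subset accordingly."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape[0] != sm.n_sites:
        raise ValueError("rates length does not match matrix")
    keep = rates < threshold
    if not keep.any():
        raise ValueError("all sites at or above threshold; empty matrix")
    new_parts = []
    start = 0
    for gene, s, e in sm.partitions:
        L = int(keep[s:e].sum())
        if L:
            new_parts.append((gene, start, start + L))
        start += L
    return Supermatrix(
        list(sm.taxa), sm.matrix[:, keep], new_parts, site_rates=rates[keep]
    )


def missing_report(sm: Supermatrix, groups: dict) -> dict:
    """Mean missing-data fraction per named taxon group."""
    m = sm.per_taxon_missing
    idx = {t: i for i, t in enumerate(sm.taxa)}
    out = {}
    for name, taxa in groups.items():
        members = [idx[t] for t in taxa if t in idx]
        out[name] = float(np.mean(m[members])) if members else float("nan")
    return out
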