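"""Prey-reference subtraction screen (the cd-hit-2d-style strategy).

A protein from the mixed host library is removed when the pure-prey
reference can explain it: some prey protein matches at >= 80% identity
(identities over the shorter sequence, the cd-hit convention) AND the host
protein is at most 150 aa longer than that prey protein. Host proteins that
exceed the length slack are retained even at perfect identity — that
relaxation is deliberate and is the screen's known false-negative source,
together with prey transcripts absent from the pure reference (kleptokaryon
expression): those leak through by construction, which is why tree-based
vetting follows.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .similarity import search

logger = logging.getLogger("ciliovet")


@dataclass(frozen=True)
class SubtractionDecision:
    host_seq_id: str
    verdict: str  # removed_prey_like | retained_unique
    best_prey_match: Optional[tuple] = None  # (prey_id, identity_fraction, length_excess_aa)


def subtract(
    host_lib: Iterable,
    prey_lib: Iterable,
    identity: float = 0.80,
    slack_aa: int = 150,
    evalue_loose: float = 1e-4,
    max_hits: int = 10,
) -> tuple[list, list[SubtractionDecision]]:
    """Remove prey-explainable host proteins; returns (retained, decisions).

    Removal requires ANY prey match with identity_fraction >= ``identity``
    and (len(host) - len(prey)) <= ``slack_aa`` (lengths of the full
    sequences; the slack is asymmetric — a prey sequence longer than the
    host never blocks removal). Candidate pairs come from a permissive
    similarity search (E <= ``evalue_loose``).
    """
    host_lib = list(host_lib)
    prey_lib = list(prey_lib)
    if not host_lib or not prey_lib:
        raise ValueError("both libraries must be nonempty")
    prey_len = {r.id: len(r.seq) for r in prey_lib}
    hits = search(
        host_lib, prey_lib, evalue_cutoff=evalue_loose, max_hits=max_hits
    )
    by_query: dict = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    retained, decisions = [], []
    for rec in host_lib:
        removed = False
        best = None
        for h in by_query.get(rec.id, []):
            excess = len(rec.seq) - prey_len[h.subject_id]
            cand = (h.subject_id, h.identity_fraction, excess)
            if best is None or h.identity_fraction > best[1]:
                best = cand
            if h.identity_fraction >= identity and excess <= slack_aa:
                removed = True
                best = cand
                break
        if removed:
            decisions.append(SubtractionDecision(rec.id, "removed_prey_like", best))
        else:
            decisions.append(SubtractionDecision(rec.id, "retained_unique", best))
            retained.append(rec)
    logger.info(
        "subtract: %d/%d removed as prey-like, %d retained",
        len(host_lib) - len(retained),
        len(host_lib),
        len(retained),
    )
    return retained, decisions


def leakage_report(decisions: Iterable[SubtractionDecision], truth_origin: dict) -> dict:
    """Score decisions against ground truth (synthetic mode).

    truth_origin: seq_id -> origin in {host, prey_shared, prey_klepto_unique}.
    Reports removal recall on shared prey, retained-set purity, and the
    leakage rate (prey-origin sequences that survived the screen).
    """
    n = {"host": 0, "prey_shared": 0, "prey_klepto_unique": 0}
    removed = dict(n)
    for d in decisions:
        o = truth_origin[d.host_seq_id]
        n[o] += 1
        if d.verdict == "removed_prey_like":
            removed[o] += 1
    retained_prey = (n["prey_shared"] - removed["prey_shared"]) + (
        n["prey_klepto_unique"] - removed["prey_klepto_unique"]
    )
    retained_total = sum(n.values()) - sum(removed.values())
    return {
        "recall_prey_shared": (
            removed["prey_shared"] / n["prey_shared"] if n["prey_shared"] else float("nan")
        ),
        "host_retention": (
            (n["host"] - removed["host"]) / n["host"] if n["host"] else float("nan")
        ),
        "retained_prey_count": retained_prey,
        "retained_host_purity": (
            (retained_total - retained_prey) / retained_total if retained_total else float("nan")
        ),
        "leakage_rate": retained_prey / retained_total if retained_total else float("nan"),
    }
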