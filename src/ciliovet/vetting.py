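"""Iterative monophyly-based vetting of candidate gene families.

The decontamination core: for each family, build a gene tree, root it with
the outgroup, extract the maximal all-ciliate clade that contains a genome
anchor (an axenic-genome sequence whose origin is beyond doubt), resolve
in-paralog sets, pick the nearest outgroup sequences, and repeat the whole
procedure on the extracted set. Sequences that fail to join the anchored
ciliate clade — typically prey transcripts that survived the similarity
screens — are dropped; families whose host sequences all fall among the
prey/outgroup are rejected outright, and families whose membership is
unstable between rounds are rejected as too uncertain.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import median
from typing import Callable, Iterable, Optional

from .align import progressive_align
from .families import GeneFamily
from .model import SubstModel
from .records import HOST_GROUP, OUTGROUP, Provenance, is_ciliate
from .treebuild import nj_tree
from .trees import PhyloTree

logger = logging.getLogger("ciliovet")

KEPT = "kept"
REJECTED_NO_ANCHOR = "rejected_no_anchor_clade"
REJECTED_HOST_WITH_PREY = "rejected_host_with_prey"
REJECTED_UNSTABLE = "rejected_unstable"


@dataclass
class VettingResult:
    family_key: str
    round: int
    verdict: str
    kept: list = field(default_factory=list)
    outgroup_picks: list = field(default_factory=list)
    dropped_contaminants: list = field(default_factory=list)
    flags: list = field(default_factory=list)
    alignment: dict = field(default_factory=dict)  # final rows for kept + outgroups


def select_vetted_clade(
    clades: list[list[str]],
    meta: dict,
    anchors_required: int = 1,
) -> Optional[list[str]]:
    """Choose among candidate all-ciliate clades.

    ``meta``: seq_id -> member record (taxon_id, provenance). Only clades
    holding >= ``anchors_required`` genome-anchor sequences qualify; among
    those, the greatest number of distinct taxa wins, then the most
    sequences, then the smallest leaf id (stable).
    """
    qualified = []
    for clade in clades:
        anchors = sum(
            1 for sid in clade if meta[sid].provenance == Provenance.genome_anchor
        )
        if anchors >= anchors_required:
            taxa = {meta[sid].taxon_id for sid in clade}
            qualified.append((-len(taxa), -len(clade), min(clade), clade))
    if not qualified:
        return None
    qualified.sort(key=lambda q: q[:3])
    return qualified[0][3]


def pick_outgroups(
    tree: PhyloTree,
    clade: list[str],
    outgroup_ids: Iterable[str],
    k_min: int = 1,
    k_max: int = 4,
) -> tuple[list[str], list[str]]:
    """Outgroup leaves nearest the clade root (edge count, then branch
    length); up to k_max, flagged if fewer than k_min exist."""
    flags = []
    og = sorted(set(outgroup_ids) & set(tree.leaf_labels()))
    if not og:
        return [], ["no_outgroup_leaves"]
    node = tree.mrca(clade) if len(clade) > 1 else tree._leaf(clade[0])
    paths = tree.node_to_leaf_paths(node)
    ranked = sorted(og, key=lambda l: (paths[l][0], paths[l][1], l))
    picks = ranked[:k_max]
    if len(picks) < k_min:
        flags.append("fewer_outgroups_than_k_min")
    return picks, flags


def _induced_taxon_splits(tree: PhyloTree, clade: list[str], taxon_of: dict, taxa: set):
    """Nested taxon groupings inside a clade, restricted to a taxon subset
    (rooted clade-set comparison). None if taxa repeat within the clade."""
    ids = [sid for sid in clade if taxon_of[sid] in taxa]
    if len({taxon_of[s] for s in ids}) != len(ids):
        return None
    idset = set(ids)
    node = tree.mrca(ids) if len(ids) > 1 else None
    if node is None:
        return frozenset()
    out = set()
    n = len(ids)
    for nd in node.preorder_iter():
        if nd is node or nd.is_leaf():
            continue
        sub = frozenset(
            taxon_of[l.taxon.label]
            for l in nd.leaf_iter()
            if l.taxon.label in idset
        )
        if 1 < len(sub) < n:
            out.add(sub)
    return frozenset(out)


def split_paralog_sets(
    tree: PhyloTree,
    clades: list[list[str]],
    meta: dict,
    anchors_required: int = 1,
    keep_one: bool = True,
) -> tuple[list[list[str]], list[str]]:
    """Resolve multiple anchored ciliate clades (paralog sets).

    Consistent duplicated sets (same relationships on their shared taxa)
    are either all emitted as separate family instances or reduced to the
    single best one (``keep_one``, the default). Sets that conflict with
    the best set are dropped and logged.
    """
    flags = []
    taxon_of = {sid: m.taxon_id for sid, m in meta.items()}
    anchored = [
        c
        for c in clades
        if sum(1 for sid in c if meta[sid].provenance == Provenance.genome_anchor)
        >= anchors_required
    ]
    if len(anchored) <= 1:
        return (anchored if anchored else []), flags
    best = select_vetted_clade(anchored, meta, anchors_required)
    emitted = [best]
    for c in anchored:
        if c is best:
            continue
        shared = {taxon_of[s] for s in best} & {taxon_of[s] for s in c}
        if len(shared) >= 3:
            sp_a = _induced_taxon_splits(tree, best, taxon_of, shared)
            sp_b = _induced_taxon_splits(tree, c, taxon_of, shared)
            consistent = sp_a is not None and sp_b is not None and sp_a == sp_b
        else:
            consistent = True  # too small to conflict
        if not consistent:
            flags.append(f"paralog_conflict_dropped:{min(c)}")
        elif not keep_one:
            emitted.append(c)
        else:
            flags.append(f"inparalog_set_merged_away:{min(c)}")
    return emitted, flags


def collapse_inparalogs(
    tree: PhyloTree, clade: list[str], meta: dict
) -> tuple[list[str], list[str]]:
    """Within a clade, keep the single longest sequence per taxon whose
    copies form a taxon-pure subclade; impure (out-paralog) copies are all
    kept and flagged."""
    flags = []
    by_taxon: dict = {}
    for sid in clade:
        by_taxon.setdefault(meta[sid].taxon_id, []).append(sid)
    kept = []
    clade_set = set(clade)
    for taxon, ids in sorted(by_taxon.items()):
        if len(ids) == 1:
            kept.extend(ids)
            continue
        node = tree.mrca(ids)
        under = [l for l in tree.clade_leaves(node) if l in clade_set]
        pure = all(meta[l].taxon_id == taxon for l in under)
        if pure:
            longest = max(ids, key=lambda s: (len(meta[s].seq.replace("-", "")), s))
            kept.append(longest)
        else:
            kept.extend(ids)
            flags.append(f"outparalogs_kept:{taxon}")
    return sorted(kept), flags


def _vet_round(
    members: list,
    anchors_required: int,
    k_min: int,
    k_max: int,
    min_coverage_frac: float,
    keep_one: bool,
    model: SubstModel,
    alignment: Optional[dict],
    aligner: Callable,
):
    """One round: align, tree, root, extract. Returns per-round state."""
    meta = {m.id: m for m in members}
    # coverage screen (reproducible proxy for removing short/spurious rows)
    lens = [len(m.seq.replace("-", "")) for m in members]
    med = median(lens)
    ok = [m for m, l in zip(members, lens) if l >= min_coverage_frac * med]
    short_dropped = [m.id for m in members if m not in ok]
    members = ok
    if len(members) < 4:
        return None
    if alignment is not None and all(m.id in alignment for m in members):
        rows = {m.id: alignment[m.id] for m in members}
        keep_cols = [
            i
            for i in range(len(next(iter(rows.values()))))
            if any(r[i] != "-" for r in rows.values())
        ]
        rows = {k: "".join(v[i] for i in keep_cols) for k, v in rows.items()}
    else:
        rows = aligner(members)
    tree = nj_tree(rows, model)
    og_ids = [m.id for m in members if m.class_label == OUTGROUP]
    if not og_ids:
        return None
    rooted = tree.root_with_outgroup(og_ids)
    clades = rooted.maximal_label_clades(
        lambda sid: is_ciliate(meta[sid].class_label)
    )
    emitted, pflags = split_paralog_sets(
        rooted, clades, meta, anchors_required, keep_one
    )
    best = select_vetted_clade(emitted, meta, anchors_required) if emitted else None
    state = {
        "meta": meta,
        "rows": rows,
        "tree": rooted,
        "short_dropped": short_dropped,
        "flags": pflags,
        "clade": None,
        "outgroups": [],
    }
    if best is None:
        return state
    kept, cflags = collapse_inparalogs(rooted, best, meta)
    picks, oflags = pick_outgroups(rooted, kept, og_ids, k_min, k_max)
    state["clade"] = kept
    state["outgroups"] = picks
    state["flags"] += cflags + oflags
    return state


def iterative_vet(
    family: GeneFamily,
    rounds: int = 2,
    anchors_required: int = 1,
    k_min: int = 1,
    k_max: int = 4,
    min_coverage_frac: float = 0.50,
    stability_tol: float = 0.25,
    keep_one_inparalog_set: bool = True,
    model: Optional[SubstModel] = None,
    alignment: Optional[dict] = None,
    aligner: Callable = progressive_align,
) -> VettingResult:
    """Two-round (by default) monophyly vetting of one family.

    Round 1 runs on all members; round 2 realigns only the extracted clade
    plus its outgroup picks and re-extracts. The verdict is
    ``rejected_host_with_prey`` when host sequences were present but none
    survived inside the vetted clade, and ``rejected_unstable`` when the
    ciliate membership changes by more than ``stability_tol`` between
    rounds.
    """
    members = list(family.members)
    if len(members) < 4:
        raise ValueError(f"family {family.key}: need >= 4 members, got {len(members)}")
    model = model or SubstModel()
    all_ids = {m.id for m in members}
    host_ids = {m.id for m in members if m.class_label == HOST_GROUP}

    kw = dict(
        anchors_required=anchors_required,
        k_min=k_min,
        k_max=k_max,
        min_coverage_frac=min_coverage_frac,
        keep_one=keep_one_inparalog_set,
        model=model,
        aligner=aligner,
    )
    state = _vet_round(members, alignment=alignment, **kw)
    if state is None or state["clade"] is None:
        verdict = REJECTED_NO_ANCHOR
        dropped = sorted(all_ids)
        return VettingResult(family.key, 1, verdict, [], [], dropped,
                             state["flags"] if state else ["degenerate_round1"])
    prev_clade = set(state["clade"])
    final = state
    n_rounds_done = 1
    for r in range(2, rounds + 1):
        subset_ids = set(state["clade"]) | set(state["outgroups"])
        subset = [m for m in members if m.id in subset_ids]
        if len(subset) < 4:
            break
        nxt = _vet_round(subset, alignment=alignment, **kw)
        if nxt is None or nxt["clade"] is None:
            # extraction broke down on the reduced set: reject as unstable
            return VettingResult(
                family.key, r, REJECTED_UNSTABLE, [], [], sorted(all_ids),
                (nxt["flags"] if nxt else []) + ["round_collapse"])
        final = nxt
        n_rounds_done = r
        cur = set(nxt["clade"])
        change = len(prev_clade ^ cur) / max(len(prev_clade), 1)
        if change > stability_tol:
            return VettingResult(
                family.key, r, REJECTED_UNSTABLE, [], [], sorted(all_ids),
                nxt["flags"] + [f"membership_change={change:.2f}"])
        prev_clade = cur
        state = nxt

    kept = sorted(final["clade"])
    picks = final["outgroups"]
    dropped = sorted(all_ids - set(kept) - set(picks))
    flags = final["flags"]
    if host_ids and not (host_ids & set(kept)):
        return VettingResult(
            family.key, n_rounds_done, REJECTED_HOST_WITH_PREY, [], picks,
            sorted(all_ids - set(picks)), flags)
    rows = {k: v for k, v in final["rows"].items() if k in set(kept) | set(picks)}
    return VettingResult(
        family.key, n_rounds_done, KEPT, kept, picks, dropped, flags, rows
    )


def vet_families(families: list[GeneFamily], **kw) -> list[VettingResult]:
    out = []
    for fam in families:
        try:
            out.append(iterative_vet(fam, **kw))
        except ValueError as e:
            logger.info("vetting skipped %s: %s", fam.key, e)
    n_kept = sum(1 for r in out if r.verdict == KEPT)
    logger.info("vetting: %d/%d families kept", n_kept, len(out))
    return out
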