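"""Candidate gene families: annotation-keyed grouping and composition rules.

Families are the unit of vetting. The primary constructor groups proteins
by a KO-style annotation key (the annotation itself is produced upstream
and consumed as a TSV; in synthetic mode the true gene id plays that role).
An alternative constructor seeds families from a reference protein set and
collects top-k similarity hits per database, which is the other route the
decontamination workflow supports.

Two composition filters narrow the candidate set before tree building:
stage 1 requires minimal three-way representation (host group, curated
ciliate collection, outgroup); stage 2 enforces the operating counts
(>= 24 core host+curated sequences, >= 1 SRA-derived sequence, >= 4
outgroup sequences at published defaults). Family counts in and out of each
stage are logged so a run leaves a funnel ledger.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .records import HOST_GROUP, OUTGROUP, Provenance, SeqRecordX, is_ciliate
from .similarity import search

logger = logging.getLogger("ciliovet")


@dataclass
class GeneFamily:
    key: str
    members: list = field(default_factory=list)  # SeqRecordX, deduplicated by id

    def add(self, rec: SeqRecordX) -> None:
        if all(m.id != rec.id for m in self.members):
            self.members.append(rec)

    def __len__(self) -> int:
        return len(self.members)

    def taxa(self) -> set:
        return {m.taxon_id for m in self.members}

    def count(self, predicate) -> int:
        return sum(1 for m in self.members if predicate(m))


def load_annotations(path) -> dict:
    """TSV (seq_id, key, score) -> best-scoring key per sequence."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "key": str})
    except Exception as e:
        raise ValueError(f"malformed annotation table: {e}") from e
    for col in ("seq_id", "key", "score"):
        if col not in df.columns:
            raise ValueError(f"annotation table missing column {col!r}")
    bad = df[df["score"].isna() | df["seq_id"].isna() | df["key"].isna()]
    if len(bad):
        raise ValueError(f"malformed annotation rows at lines {list(bad.index + 2)}")
    best = df.sort_values(["seq_id", "score"], ascending=[True, False]).drop_duplicates(
        "seq_id", keep="first"
    )
    return dict(zip(best["seq_id"], best["key"]))


def build_families(
    seqs: Iterable[SeqRecordX],
    annotations: dict,
    max_members: int = 200,
) -> tuple[list[GeneFamily], dict]:
    """Group annotated sequences into families; one family per key.

    Unannotated sequences are excluded and counted. Families exceeding
    ``max_members`` are dropped (the reproducible stand-in for excluding
    families too large to inspect).
    """
    fams: dict = {}
    skipped = 0
    for rec in seqs:
        key = annotations.get(rec.id)
        if key is None:
            skipped += 1
            continue
        fams.setdefault(key, GeneFamily(key)).add(rec)
    oversize = [k for k, f in fams.items() if len(f) > max_members]
    for k in oversize:
        del fams[k]
    counts = {
        "annotated": sum(len(f) for f in fams.values()),
        "skipped_unannotated": skipped,
        "families": len(fams),
        "dropped_oversize": len(oversize),
    }
    logger.info("families: %s", counts)
    return [fams[k] for k in sorted(fams)], counts


def build_families_from_seeds(
    seeds: Iterable[SeqRecordX],
    databases: dict,
    evalue_cutoff: float = 1e-30,
    max_hits: int = 6,
) -> list[GeneFamily]:
    """Seed-based constructor: one family per seed protein, members = the
    top-k hits of that seed in each target database (plus the seed)."""
    out = []
    for seed in seeds:
        fam = GeneFamily(seed.id)
        fam.add(seed)
        for _, db in sorted(databases.items()):
            for h in search([seed], db, evalue_cutoff=evalue_cutoff, max_hits=max_hits):
                match = next(r for r in db if r.id == h.subject_id)
                fam.add(match)
        out.append(fam)
    return out


def stage1_composition(family: GeneFamily) -> bool:
    """>= 1 host-group member, >= 1 curated-collection ciliate (non-host),
    and >= 1 outgroup member."""
    if not family.members:
        raise ValueError("empty family")
    has_host = family.count(lambda m: m.class_label == HOST_GROUP)
    has_curated_ciliate = family.count(
        lambda m: is_ciliate(m.class_label)
        and m.class_label != HOST_GROUP
        and m.provenance == Provenance.curated
    )
    has_outgroup = family.count(lambda m: m.class_label == OUTGROUP)
    return bool(has_host and has_curated_ciliate and has_outgroup)


def stage2_composition(
    family: GeneFamily,
    min_core: int = 24,
    min_sra: int = 1,
    min_outgroup: int = 4,
) -> bool:
    """Operating-count filter: core = host-group members plus curated
    ciliate sequences; plus minimum SRA-derived and outgroup counts."""
    core = family.count(
        lambda m: m.class_label == HOST_GROUP
        or (is_ciliate(m.class_label) and m.provenance == Provenance.curated)
    )
    sra = family.count(
        lambda m: is_ciliate(m.class_label) and m.provenance == Provenance.sra
    )
    outgroup = family.count(lambda m: m.class_label == OUTGROUP)
    return core >= min_core and sra >= min_sra and outgroup >= min_outgroup


def composition_funnel(
    families: list[GeneFamily],
    min_core: int = 24,
    min_sra: int = 1,
    min_outgroup: int = 4,
) -> tuple[list[GeneFamily], dict]:
    """Apply stage 1 then stage 2; returns survivors and the funnel counts."""
    s1 = [f for f in families if stage1_composition(f)]
    s2 = [f for f in s1 if stage2_composition(f, min_core, min_sra, min_outgroup)]
    funnel = {"input": len(families), "stage1": len(s1), "stage2": len(s2)}
    logger.info("composition funnel: %s", funnel)
    return s2, funnel


def write_families_tsv(families: list[GeneFamily], path) -> None:
    rows = [
        {
            "key": f.key,
            "seq_id": m.id,
            "taxon": m.taxon_id,
            "class": m.class_label,
            "provenance": m.provenance.value if m.provenance else "",
        }
        for f in families
        for m in f.members
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
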