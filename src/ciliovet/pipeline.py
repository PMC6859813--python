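"""End-to-end orchestration on synthetic datasets.

Chains the stages the way a real run would: ORF recall under the host's
genetic code, prey-reference subtraction, annotation-keyed family building
with composition filters, iterative monophyly vetting, per-gene occupancy
trimming, supermatrix concatenation and distance/NJ placement of the host
clade. A ``naive`` variant skips subtraction and vetting (keeping the
longest sequence per taxon per family) to expose the artefact the vetting
exists to prevent: prey transcripts riding along under the host's name and
dragging it out of its class.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from .families import build_families, composition_funnel
from .genetic_codes import build_code, find_orfs
from .model import SubstModel
from .records import OUTGROUP, SeqRecordX
from .simulate import MIXED_TAXON, SISTER_CLASS, SyntheticDataset
from .subtraction import leakage_report, subtract
from .supermatrix import Supermatrix, concatenate, trim_by_occupancy
from .treebuild import nj_tree
from .trees import PhyloTree
from .vetting import KEPT, VettingResult, vet_families

logger = logging.getLogger("ciliovet")


def recall_proteins(records, code_name: str = "mesodinium", min_nt: int = 150):
    """Longest-ORF protein per nucleotide record (same id); records whose
    best ORF is shorter than min_nt are dropped."""
    code = build_code(code_name)
    out = []
    for rec in records:
        orfs = find_orfs(rec.seq, code, min_len=min_nt, contig_id=rec.id)
        if not orfs:
            continue
        best = max(orfs, key=lambda o: (len(o.aa_seq), o.frame, -o.start))
        out.append(
            SeqRecordX(
                id=rec.id,
                seq=best.aa_seq,
                taxon_id=rec.taxon_id,
                class_label=rec.class_label,
                provenance=rec.provenance,
            )
        )
    return out


@dataclass
class PipelineResult:
    retained: list = field(default_factory=list)
    subtraction_report: dict = field(default_factory=dict)
    funnel: dict = field(default_factory=dict)
    vetting: list = field(default_factory=list)
    supermatrix: Optional[Supermatrix] = None
    placement_tree: Optional[PhyloTree] = None
    kept_prey_fraction: float = float("nan")
    host_gene_recall: float = float("nan")
    placed_correctly: Optional[bool] = None


def _per_taxon_rows(result: VettingResult, taxon_of: dict) -> list:
    """(taxon, row) pairs from a vetting result, longest row per taxon."""
    ids = list(result.kept) + list(result.outgroup_picks)
    by_taxon: dict = {}
    for sid in ids:
        row = result.alignment[sid]
        t = taxon_of[sid]
        cur = by_taxon.get(t)
        if cur is None or len(row.replace("-", "")) > len(cur.replace("-", "")):
            by_taxon[t] = row
    return sorted(by_taxon.items())


def evaluate_placement(tree: PhyloTree, ds: SyntheticDataset) -> bool:
    """True iff the host clade is recovered and sits sister to its true
    class (both splits present in the unrooted placement tree)."""
    hosts = [t for t in ds.host_taxa() if t in tree.leaf_labels()]
    sisters = [t for t in ds.sister_class_taxa() if t in tree.leaf_labels()]
    if len(hosts) < len(ds.host_taxa()) or not sisters:
        return False
    if len(hosts) >= 2 and not tree.has_clade(hosts):
        return False
    return tree.has_clade(hosts + sisters)


def run_pipeline(
    ds: SyntheticDataset,
    subtract_identity: float = 0.80,
    subtract_slack_aa: int = 150,
    orf_min_nt: int = 150,
    min_core: Optional[int] = None,
    min_sra: int = 1,
    min_outgroup: int = 4,
    occupancy_min_frac: float = 0.60,
    naive: bool = False,
    model: Optional[SubstModel] = None,
) -> PipelineResult:
    """Run the full decontamination + placement pipeline on one dataset.

    ``min_core`` defaults to (host clade size + number of curated ciliate
    taxa - 1): the published count assumes the published taxon sampling, so
    synthetic runs scale it to their own taxon table.
    """
    model = model or SubstModel(gamma_shape=ds.config.gamma_shape)
    res = PipelineResult()
    taxa = ds.taxa
    host_meta = taxa[MIXED_TAXON]

    mixed_nt = [
        SeqRecordX(r.id, r.seq, taxon_id=MIXED_TAXON,
                   class_label=host_meta.class_label,
                   provenance=host_meta.provenance)
        for r in ds.mixed_library
    ]
    # the vetted pipeline recalls ORFs under the host's code; the naive run
    # models a default workflow: standard code (host proteins truncate at
    # the first in-frame TAA/TAG), no subtraction, no vetting
    mixed_aa = recall_proteins(
        mixed_nt, "standard" if naive else "mesodinium", orf_min_nt
    )
    prey_aa = recall_proteins(
        [SeqRecordX(r.id, r.seq) for r in ds.pure_prey], "standard", orf_min_nt
    )
    if naive:
        retained = mixed_aa
    else:
        retained, decisions = subtract(
            mixed_aa, prey_aa, identity=subtract_identity, slack_aa=subtract_slack_aa
        )
        origin = {r.id: ds.truth[r.id][0] for r in mixed_aa}
        res.subtraction_report = leakage_report(decisions, origin)
    res.retained = retained

    pool = list(retained)
    for recs in ds.reference_proteins.values():
        pool.extend(recs)
    families, _ = build_families(pool, ds.annotations, max_members=200)
    if min_core is None:
        n_curated_ciliates = sum(
            1
            for m in taxa
            if m.class_label.startswith("ciliate_class:")
            and m.provenance.value == "curated"
        )
        min_core = len(ds.host_taxa()) + n_curated_ciliates - 1
    families, res.funnel = composition_funnel(
        families, min_core=min_core, min_sra=min_sra, min_outgroup=min_outgroup
    )

    taxon_of = {}
    for fam in families:
        for m in fam.members:
            taxon_of[m.id] = m.taxon_id

    vetted_alignments: dict = {}
    if naive:
        from .align import progressive_align

        for fam in families:
            by_taxon: dict = {}
            for m in fam.members:
                cur = by_taxon.get(m.taxon_id)
                if cur is None or len(m.seq) > len(cur.seq):
                    by_taxon[m.taxon_id] = m
            picks = list(by_taxon.values())
            if len(picks) < 4:
                continue
            rows = progressive_align(picks)
            rows = trim_by_occupancy(rows, occupancy_min_frac)
            vetted_alignments[fam.key] = [
                (taxon_of[sid], row) for sid, row in sorted(rows.items())
            ]
    else:
        res.vetting = vet_families(families, model=model)
        kept_results = [v for v in res.vetting if v.verdict == KEPT]
        # truth-scored vetting quality (synthetic mode only)
        kept_ids = [sid for v in kept_results for sid in v.kept]
        prey_kept = sum(
            1
            for sid in kept_ids
            if sid in ds.truth and ds.truth[sid][0] != "host"
        )
        res.kept_prey_fraction = prey_kept / len(kept_ids) if kept_ids else float("nan")
        host_genes_present = {
            ds.truth[r.id][1] for r in mixed_aa if ds.truth[r.id][0] == "host"
        }
        host_genes_kept = {
            v.family_key
            for v in kept_results
            if any(sid in ds.truth and ds.truth[sid][0] == "host" for sid in v.kept)
        }
        res.host_gene_recall = (
            len(host_genes_kept & host_genes_present) / len(host_genes_present)
            if host_genes_present
            else float("nan")
        )
        for v in kept_results:
            rows = trim_by_occupancy(v.alignment, occupancy_min_frac)
            vetted_alignments[v.family_key] = _per_taxon_rows(
                VettingResult(
                    v.family_key, v.round, v.verdict, v.kept, v.outgroup_picks,
                    v.dropped_contaminants, v.flags, rows,
                ),
                taxon_of,
            )

    if not vetted_alignments:
        return res
    universe = [m.taxon_id for m in taxa]
    sm = concatenate(vetted_alignments, universe)
    # taxa with no data cannot be placed
    present = sm.per_taxon_missing < 1.0
    sm = Supermatrix(
        [t for t, p in zip(sm.taxa, present) if p], sm.matrix[present], sm.partitions
    )
    res.supermatrix = sm
    if len(sm.taxa) >= 4:
        tree = nj_tree(sm.as_dict(), model)
        res.placement_tree = tree
        res.placed_correctly = evaluate_placement(tree, ds)
    return res
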