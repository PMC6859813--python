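"""Synthetic mixed-culture transcriptome generator with full ground truth.

The generator emulates the data situation of a mixotrophic ciliate culture
fed on an algal prey: a species tree with a fast-evolving host clade sister
to one ingroup class, the prey inside the outgroup radiation, and a mixed
sequencing library in which most transcripts are prey-derived. Host genes
use the Mesodinium genetic code (TAA/TAG are tyrosine), so translating them
with the standard code truncates at the first in-frame TAA/TAG. A fraction
of prey transcripts come from genes absent from the pure-culture prey
reference (kleptokaryon-only expression) and therefore cannot be removed by
subtraction — the screen's built-in failure mode. In-paralogs arise by
post-speciation duplication with at least one substitution.

Amino-acid evolution is simulated site-wise under the Poisson model with
gamma-distributed site rates and back-translated with uniform synonymous
codon choice; gene trees are the species tree with log-normal branch-length
jitter. Indels are off: the true per-gene alignment is the ungapped
sequence set, so vetting can be validated independent of aligner quality.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .genetic_codes import GeneticCode, build_code
from .model import AA_ALPHABET
from .records import (
    CILIATE_CLASS_PREFIX,
    HOST_GROUP,
    OUTGROUP,
    Provenance,
    SeqRecordX,
    TaxonMeta,
    TaxonTable,
)
from .trees import PhyloTree

_BETA = 20.0 / 19.0  # Poisson/uniform-frequency rate normalisation


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_ingroup_classes: int = 4
    taxa_per_class: int = 3
    n_outgroup: int = 5
    host_clade_size: int = 2
    prey_taxon_position: int = 2      # index into the outgroup radiation
    n_genes: int = 60
    codons_per_gene: int = 120
    gamma_shape: float = 0.8
    host_rate_multiplier: float = 2.0
    contamination_fraction: float = 0.85
    kleptokaryon_unique_fraction: float = 0.10
    inparalog_prob: float = 0.05
    branch_jitter_sigma: float = 0.15
    isoform_mut_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        for name in (
            "contamination_fraction",
            "kleptokaryon_unique_fraction",
            "inparalog_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.contamination_fraction >= 1.0:
            raise ValueError("contamination_fraction must be < 1")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.host_clade_size < 1:
            raise ValueError("host_clade_size must be >= 1")
        if self.host_rate_multiplier < 1.0:
            raise ValueError("host_rate_multiplier must be >= 1")
        if not (0 <= self.prey_taxon_position < self.n_outgroup):
            raise ValueError("prey_taxon_position must index the outgroup radiation")
        if self.n_ingroup_classes < 1 or self.taxa_per_class < 1:
            raise ValueError("need at least one ingroup class with one taxon")


# -- taxa and species tree -------------------------------------------------

MIXED_TAXON = "host_1"  # the mixed-culture library belongs to this taxon
PREY_TAXON = "prey"
SISTER_CLASS = "cls0"


def taxon_table(config: SimulationConfig) -> TaxonTable:
    """Taxa with class labels and provenance; one genome anchor and one
    SRA-derived library per ingroup class, the rest curated."""
    metas = []
    for i in range(1, config.host_clade_size + 1):
        metas.append(TaxonMeta(f"host_{i}", HOST_GROUP, Provenance.transcriptome))
    for c in range(config.n_ingroup_classes):
        label = f"{CILIATE_CLASS_PREFIX}cls{c}"
        for j in range(1, config.taxa_per_class + 1):
            if j == 1:
                prov = Provenance.genome_anchor
            elif j == 2 and config.taxa_per_class >= 3:
                prov = Provenance.sra
            else:
                prov = Provenance.curated
            metas.append(TaxonMeta(f"cls{c}_t{j}", label, prov))
    for k in range(config.n_outgroup):
        name = PREY_TAXON if k == config.prey_taxon_position else f"og_{k + 1}"
        metas.append(TaxonMeta(name, OUTGROUP, Provenance.curated))
    return TaxonTable.from_list(metas)


def simulate_species_tree(config: SimulationConfig) -> PhyloTree:
    """Species tree: (outgroup radiation, (((host, cls0), cls1), ...)).

    Branch lengths are uniform draws per edge; every edge inside (and
    subtending) the host clade is multiplied by host_rate_multiplier.
    Deterministic given config.seed.
    """
    rng = np.random.default_rng(config.seed)

    def draw(lo, hi):
        return float(rng.uniform(lo, hi))

    # nodes: ("L", name) | ("I", [children]); edge lengths assigned on wrap
    def leaf(name, lo, hi, scale=1.0):
        return (("L", name), draw(lo, hi) * scale)

    def join(parts, stem):
        return (("I", list(parts)), stem)

    def ladder(leaves, pend_rng, int_rng, stem, scale=1.0):
        node = leaf(leaves[0], *pend_rng, scale)
        for name in leaves[1:-1] if len(leaves) > 1 else []:
            node = join([node, leaf(name, *pend_rng, scale)],
                        draw(*int_rng) * scale)
        if len(leaves) > 1:
            node = join([node, leaf(leaves[-1], *pend_rng, scale)], stem)
        else:
            node = (node[0], stem)
        return node

    def render(entry):
        (kind, payload), length = entry
        if kind == "L":
            return f"{payload}:{length!r}"
        inner = ",".join(render(ch) for ch in payload)
        return f"({inner}):{length!r}"

    mult = config.host_rate_multiplier
    host_leaves = [f"host_{i}" for i in range(1, config.host_clade_size + 1)]
    host = ladder(host_leaves, (0.05, 0.12), (0.03, 0.08),
                  stem=0.10 * mult, scale=mult)
    classes = [
        ladder(
            [f"cls{c}_t{j}" for j in range(1, config.taxa_per_class + 1)],
            (0.05, 0.12), (0.03, 0.08), stem=draw(0.12, 0.20),
        )
        for c in range(config.n_ingroup_classes)
    ]
    ingroup = join([host, classes[0]], draw(0.06, 0.12))
    for cl in classes[1:]:
        ingroup = join([ingroup, cl], draw(0.06, 0.12))
    ingroup = (ingroup[0], 0.30)  # edge from root to the ingroup
    og_leaves = [
        PREY_TAXON if k == config.prey_taxon_position else f"og_{k + 1}"
        for k in range(config.n_outgroup)
    ]
    outgroup = ladder(og_leaves, (0.10, 0.20), (0.08, 0.15), stem=0.25)
    newick = f"({render(outgroup)},{render(ingroup)});"
    return PhyloTree.from_newick(newick)


# -- sequence evolution ----------------------------------------------------

def _jittered(tree: PhyloTree, sigma: float, rng) -> PhyloTree:
    """Gene tree: species tree with log-normal branch-length jitter (mean 1)."""
    gt = tree.copy()
    if sigma > 0:
        for nd in gt.t.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length:
                nd.edge.length = float(
                    nd.edge.length * rng.lognormal(-0.5 * sigma**2, sigma)
                )
    return gt


def evolve_codons(
    tree: PhyloTree,
    codons: int,
    gamma_shape: float,
    codes: dict,
    rng,
) -> tuple[dict, dict, np.ndarray]:
    """Simulate one gene along a tree.

    ``codes``: taxon -> GeneticCode for back-translation (host taxa get the
    Mesodinium code, so tyrosines may be encoded TAA/TAG). Returns
    (nt per taxon, aa per taxon — the true, gap-free alignment, site rates).
    """
    rates = rng.gamma(gamma_shape, 1.0 / gamma_shape, size=codons)
    root_states = rng.integers(0, 20, size=codons)
    states = {id(tree.t.seed_node): root_states}
    for nd in tree.t.preorder_node_iter():
        if nd.parent_node is None:
            continue
        parent = states[id(nd.parent_node)]
        t = max(nd.edge.length or 0.0, 0.0)
        stay = np.exp(-_BETA * t * rates)
        redraw = rng.random(codons) >= stay
        child = parent.copy()
        child[redraw] = rng.integers(0, 20, size=int(redraw.sum()))
        states[id(nd)] = child
    aa, nt = {}, {}
    for leaf in tree.t.leaf_node_iter():
        taxon = leaf.taxon.label
        seq = "".join(AA_ALPHABET[s] for s in states[id(leaf)])
        aa[taxon] = seq
        code = codes[taxon]
        nt[taxon] = "".join(
            code.codons_for(ch)[rng.integers(0, len(code.codons_for(ch)))]
            for ch in seq
        )
    return nt, aa, rates


def _mutate_aa(seq: str, n_subs: int, rng) -> str:
    chars = list(seq)
    pos = rng.choice(len(chars), size=min(n_subs, len(chars)), replace=False)
    for p in pos:
        cur = chars[p]
        alt = AA_ALPHABET[rng.integers(0, 20)]
        while alt == cur:
            alt = AA_ALPHABET[rng.integers(0, 20)]
        chars[p] = alt
    return "".join(chars)


# -- dataset assembly ------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimulationConfig
    taxa: TaxonTable
    species_tree: PhyloTree
    gene_aa: dict                  # gene -> taxon -> aa (true alignment)
    gene_nt: dict                  # gene -> taxon -> nt
    site_rates: dict               # gene -> np.ndarray
    mixed_library: list            # nt SeqRecordX, taxon MIXED_TAXON
    pure_prey: list                # nt SeqRecordX
    reference_proteins: dict       # taxon -> list of aa SeqRecordX
    truth: dict                    # transcript/protein id -> (origin, gene)
    annotations: dict = field(default_factory=dict)  # seq_id -> gene key

    def host_taxa(self) -> list[str]:
        return self.taxa.host_taxa()

    def sister_class_taxa(self) -> list[str]:
        return [
            m.taxon_id
            for m in self.taxa
            if m.class_label == f"{CILIATE_CLASS_PREFIX}{SISTER_CLASS}"
        ]


def build_mixed_library(
    host_nt: dict, prey_nt: dict, config: SimulationConfig, rng
) -> tuple[list, list, dict]:
    """Assemble the mixed host library and the pure-prey reference.

    ``host_nt``/``prey_nt``: gene -> nt sequence for the mixed-culture host
    taxon / the prey taxon. The mixed library holds every host transcript
    plus prey transcripts (isoform-jittered copies) in the ratio set by
    contamination_fraction; a kleptokaryon_unique_fraction of prey
    transcripts come from genes withheld from the pure reference entirely.
    Returns (mixed, pure_reference, truth).
    """
    genes = sorted(host_nt)
    if not genes or not prey_nt:
        raise ValueError("empty gene sets")
    std = build_code("standard")
    n_host = len(genes)
    cf = config.contamination_fraction
    n_prey = int(round(cf / (1.0 - cf) * n_host)) if cf > 0 else 0
    prey_genes = sorted(prey_nt)
    copies = rng.multinomial(n_prey, np.full(len(prey_genes), 1.0 / len(prey_genes)))
    # withhold genes from the pure reference until ~the requested fraction
    # of prey transcripts is kleptokaryon-only
    order = list(rng.permutation(len(prey_genes)))
    target = config.kleptokaryon_unique_fraction * n_prey
    klepto: set = set()
    acc = 0
    for gi in order:
        if copies[gi] > 0 and abs(acc + copies[gi] - target) < abs(acc - target):
            klepto.add(prey_genes[gi])
            acc += copies[gi]
    mixed: list[SeqRecordX] = []
    truth: dict = {}
    for g in genes:
        tid = f"mix_{g}_host"
        mixed.append(SeqRecordX(id=tid, seq=host_nt[g], taxon_id=MIXED_TAXON))
        truth[tid] = ("host", g)
    prey_aa_cache = {}
    for gi, g in enumerate(prey_genes):
        for k in range(copies[gi]):
            if g not in prey_aa_cache:
                from .genetic_codes import translate

                prey_aa_cache[g] = translate(prey_nt[g], std)
            aa = prey_aa_cache[g]
            n_subs = rng.binomial(len(aa), config.isoform_mut_rate)
            iso = _mutate_aa(aa, n_subs, rng) if n_subs else aa
            ntseq = "".join(
                std.codons_for(ch)[rng.integers(0, len(std.codons_for(ch)))]
                for ch in iso
            )
            tid = f"mix_{g}_prey{k + 1}"
            origin = "prey_klepto_unique" if g in klepto else "prey_shared"
            mixed.append(SeqRecordX(id=tid, seq=ntseq, taxon_id=MIXED_TAXON))
            truth[tid] = (origin, g)
    pure = [
        SeqRecordX(id=f"preyref_{g}", seq=prey_nt[g], taxon_id=PREY_TAXON)
        for g in prey_genes
        if g not in klepto
    ]
    if not pure:
        raise ValueError("every prey gene became kleptokaryon-only; lower the fraction")
    return mixed, pure, truth


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full synthetic dataset: tree, per-gene sequences, mixed library,
    pure-prey reference, per-taxon reference protein libraries, truth."""
    rng = np.random.default_rng(config.seed + 1)
    taxa = taxon_table(config)
    tree = simulate_species_tree(config)
    mes = build_code("mesodinium")
    std = build_code("standard")
    codes = {
        m.taxon_id: (mes if m.class_label == HOST_GROUP else std) for m in taxa
    }
    gene_aa, gene_nt, site_rates = {}, {}, {}
    for g in range(config.n_genes):
        gene = f"g{g:03d}"
        gt = _jittered(tree, config.branch_jitter_sigma, rng)
        nt, aa, rates = evolve_codons(
            gt, config.codons_per_gene, config.gamma_shape, codes, rng
        )
        gene_aa[gene], gene_nt[gene], site_rates[gene] = aa, nt, rates
    host_nt = {g: gene_nt[g][MIXED_TAXON] for g in gene_nt}
    prey_nt = {g: gene_nt[g][PREY_TAXON] for g in gene_nt}
    mixed, pure, truth = build_mixed_library(host_nt, prey_nt, config, rng)
    # host in-paralogs land in the mixed library
    extra = []
    for rec in list(mixed):
        origin, g = truth[rec.id]
        if origin == "host" and rng.random() < config.inparalog_prob:
            aa = gene_aa[g][MIXED_TAXON]
            dup = _mutate_aa(aa, 1 + rng.poisson(1.0), rng)
            ntseq = "".join(
                codes[MIXED_TAXON].codons_for(ch)[
                    rng.integers(0, len(codes[MIXED_TAXON].codons_for(ch)))
                ]
                for ch in dup
            )
            tid = f"{rec.id}_p2"
            extra.append(SeqRecordX(id=tid, seq=ntseq, taxon_id=MIXED_TAXON))
            truth[tid] = ("host", g)
    mixed.extend(extra)
    # reference protein libraries for every taxon except the mixed library's
    reference: dict = {}
    for m in taxa:
        if m.taxon_id == MIXED_TAXON:
            continue
        recs = []
        for g in sorted(gene_aa):
            sid = f"{m.taxon_id}_{g}"
            recs.append(
                SeqRecordX(
                    id=sid,
                    seq=gene_aa[g][m.taxon_id],
                    taxon_id=m.taxon_id,
                    class_label=m.class_label,
                    provenance=m.provenance,
                )
            )
            if rng.random() < config.inparalog_prob:
                dup = _mutate_aa(gene_aa[g][m.taxon_id], 1 + rng.poisson(1.0), rng)
                recs.append(
                    SeqRecordX(
                        id=f"{sid}_p2",
                        seq=dup,
                        taxon_id=m.taxon_id,
                        class_label=m.class_label,
                        provenance=m.provenance,
                    )
                )
        reference[m.taxon_id] = recs
    annotations = {tid: g for tid, (_, g) in truth.items()}
    # reference ids end in the gene key (possibly followed by _p2)
    for recs in reference.values():
        for r in recs:
            gene = r.id.split("_")[-2] if r.id.endswith("_p2") else r.id.split("_")[-1]
            annotations[r.id] = gene
    return SyntheticDataset(
        config=config,
        taxa=taxa,
        species_tree=tree,
        gene_aa=gene_aa,
        gene_nt=gene_nt,
        site_rates=site_rates,
        mixed_library=mixed,
        pure_prey=pure,
        reference_proteins=reference,
        truth=truth,
        annotations=annotations,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write the on-disk form: FASTA libraries, truth table, tree, taxa."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_fasta(ds.mixed_library, outdir / "mixed_library.fna")
    io.write_fasta(ds.pure_prey, outdir / "pure_prey.fna")
    io.write_taxon_table(ds.taxa, outdir / "taxa.tsv")
    io.write_newick(ds.species_tree, outdir / "species_tree.nwk")
    rows = [
        {"transcript_id": tid, "origin": o, "gene": g, "taxon": MIXED_TAXON}
        for tid, (o, g) in sorted(ds.truth.items())
    ]
    pd.DataFrame(rows).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    adir = outdir / "true_alignments"
    adir.mkdir(exist_ok=True)
    for gene, aln in ds.gene_aa.items():
        io.write_fasta(
            [SeqRecordX(id=t, seq=s) for t, s in sorted(aln.items())],
            adir / f"{gene}.faa",
        )
    refdir = outdir / "reference_proteins"
    refdir.mkdir(exist_ok=True)
    for taxon, recs in ds.reference_proteins.items():
        io.write_fasta(recs, refdir / f"{taxon}.faa")
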