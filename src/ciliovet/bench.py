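"""Validation experiments on synthetic data with known ground truth.

These are the package's own adequacy checks, shared by the test suite and
the results-reproduction script: decontamination recovery, end-to-end host
placement (vetted vs naive), topology-test calibration, and parameter
recovery for the likelihood machinery. Every experiment is deterministic
given its seed.
"""
from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .likelihood import TreeLikelihood
from .model import AA_ALPHABET, SubstModel
from .pipeline import run_pipeline
from .simulate import SimulationConfig, generate_dataset, simulate_species_tree
from .topotests import au_test, kh_test, run_hypotheses, sh_test
from .treebuild import nj_tree
from .trees import PhyloTree, regraft


# -- criterion experiments -------------------------------------------------

def decontamination_trial(seed: int, n_genes: int = 60) -> dict:
    """One seed of the decontamination-recovery experiment (study
    conditions: 85% contamination, 10% kleptokaryon-unique prey)."""
    ds = generate_dataset(SimulationConfig(n_genes=n_genes, seed=seed))
    res = run_pipeline(ds)
    rep = res.subtraction_report
    return {
        "recall_prey_shared": rep["recall_prey_shared"],
        "leakage_count": rep["retained_prey_count"],
        "kept_prey_fraction": res.kept_prey_fraction,
        "host_gene_recall": res.host_gene_recall,
    }


def placement_trial(seed: int, n_genes: int = 100) -> dict:
    """One seed of the end-to-end placement experiment: vetted pipeline vs
    the naive run (standard code, no subtraction, no vetting)."""
    ds = generate_dataset(
        SimulationConfig(n_genes=n_genes, host_rate_multiplier=2.0, seed=seed)
    )
    vetted = run_pipeline(ds)
    naive = run_pipeline(ds, naive=True)
    return {
        "vetted_placed": bool(vetted.placed_correctly),
        "naive_misplaced": not bool(naive.placed_correctly),
    }


def _symmetric_null_site_logls(seed: int, L: int = 300) -> np.ndarray:
    """Site log-likelihoods for two equally true topologies.

    Each site evolves on one of two symmetric four-taxon resolutions
    (chosen with probability 1/2), and both fixed trees are evaluated on
    the mixed alignment — so the expected per-site log-likelihood
    difference is exactly zero while its distribution has genuine spread:
    a non-degenerate equal-fit null for the resampling tests.
    """
    rng = np.random.default_rng(seed)
    beta = 20.0 / 19.0
    t1 = PhyloTree.from_newick("((A:0.3,B:0.3):0.15,(C:0.3,D:0.3):0.15);")
    t2 = PhyloTree.from_newick("((A:0.3,C:0.3):0.15,(B:0.3,D:0.3):0.15);")

    def simulate(tree, n):
        from .likelihood import flatten

        ft = flatten(tree)
        states = {0: rng.integers(0, 20, n)}
        for i in range(1, len(ft.nodes)):
            parent = states[ft.parent[i]]
            stay = rng.random(n) < np.exp(-beta * ft.lengths[i])
            states[i] = np.where(stay, parent, rng.integers(0, 20, n))
        return {lbl: states[idx] for lbl, idx in ft.leaf_index.items()}

    n1 = int(rng.binomial(L, 0.5))
    part1 = simulate(t1, n1)
    part2 = simulate(t2, L - n1)
    aln = {
        lbl: "".join(AA_ALPHABET[i] for i in np.concatenate([part1[lbl], part2[lbl]]))
        for lbl in part1
    }
    model = SubstModel(n_categories=1)
    return np.vstack(
        [TreeLikelihood(t, aln, model).site_loglik() for t in (t1, t2)]
    )


def kh_sh_null_trial(seed: int, L: int = 300, n_resamples: int = 1000) -> dict:
    """KH and SH p-values for a pre-specified tree on one null replicate."""
    S = _symmetric_null_site_logls(seed, L=L)
    kh = kh_test(S[0], S[1], n=n_resamples, seed=seed + 10_000)
    sh = sh_test(S, n=n_resamples, seed=seed + 20_000)
    return {"kh_p": kh, "sh_p": float(sh[1])}


def au_null_trial(seed: int, L: int = 300, n_per_scale: int = 1000) -> dict:
    """AU p-value for a pre-specified tree on the symmetric two-tree null."""
    S = _symmetric_null_site_logls(seed, L=L)
    p, _ = au_test(S, n_per_scale=n_per_scale, seed=seed + 30_000)
    return {"au_p": float(p[0])}


def hypothesis_trees(ds) -> dict:
    """The three candidate placements of the host clade: sister to its true
    class, sister to the whole ingroup, sister to a wrong class."""
    tree = ds.species_tree
    hosts = ds.host_taxa()
    ingroup = [l for l in tree.leaf_labels() if l.startswith("cls")]
    wrong_class = [l for l in ingroup if l.startswith("cls1_")]
    return {
        "h1_sister_to_class": tree.copy(),
        "h2_sister_to_ingroup": regraft(tree, hosts, ingroup),
        "h3_sister_to_wrong_class": regraft(tree, hosts, wrong_class),
    }


def topology_test_trial(
    seed: int,
    n_genes: int = 25,
    n_resamples: int = 2000,
    au_n_per_scale: int = 500,
) -> dict:
    """Data generated under hypothesis 1; all three placements tested."""
    cfg = SimulationConfig(
        n_ingroup_classes=3,
        taxa_per_class=2,
        n_outgroup=3,
        host_clade_size=2,
        n_genes=n_genes,
        codons_per_gene=120,
        contamination_fraction=0.0,
        kleptokaryon_unique_fraction=0.0,
        inparalog_prob=0.0,
        seed=seed,
    )
    ds = generate_dataset(cfg)
    aln = {}
    for taxon in ds.taxa.rows:
        aln[taxon] = "".join(ds.gene_aa[g][taxon] for g in sorted(ds.gene_aa))
    model = SubstModel(gamma_shape=cfg.gamma_shape)
    result = run_hypotheses(
        aln,
        model,
        hypothesis_trees(ds),
        n_resamples=n_resamples,
        seed=seed + 40_000,
        au_n_per_scale=au_n_per_scale,
    )
    i_true = result.tree_ids.index("h1_sister_to_class")
    rivals = [j for j in range(len(result.tree_ids)) if j != i_true]
    return {
        "bp_true": float(result.bp[i_true]),
        "au_true": float(result.au[i_true]),
        "max_rival_au": float(max(result.au[j] for j in rivals)),
        "logL_true_is_best": bool(np.argmax(result.logL) == i_true),
    }


def rate_recovery_trial(seed: int, n_sites: int = 5000, shape: float = 0.5) -> dict:
    """Spearman correlation of true vs posterior-mean site rates."""
    cfg = SimulationConfig(
        n_ingroup_classes=2,
        taxa_per_class=2,
        n_outgroup=2,
        prey_taxon_position=1,
        host_clade_size=1,
        host_rate_multiplier=1.0,
        n_genes=1,
        codons_per_gene=n_sites,
        gamma_shape=shape,
        contamination_fraction=0.0,
        inparalog_prob=0.0,
        seed=seed,
    )
    tree = simulate_species_tree(cfg)
    ds = generate_dataset(cfg)
    gene = sorted(ds.gene_aa)[0]
    aln = ds.gene_aa[gene]
    model = SubstModel(gamma_shape=shape)
    tl = TreeLikelihood(tree, aln, model)
    est = tl.site_rates()
    rho = spearmanr(ds.site_rates[gene], est).statistic
    return {"spearman": float(rho)}


def nj_topology_recovery_trial(seed: int, n_sites: int = 5000) -> dict:
    """NJ + model distances on clean 12-taxon data (no rate acceleration):
    does the tree match the true species-tree topology?"""
    cfg = SimulationConfig(
        n_ingroup_classes=3,
        taxa_per_class=3,
        n_outgroup=2,
        prey_taxon_position=1,
        host_clade_size=1,
        host_rate_multiplier=1.0,
        n_genes=1,
        codons_per_gene=n_sites,
        contamination_fraction=0.0,
        inparalog_prob=0.0,
        seed=seed,
    )
    tree = simulate_species_tree(cfg)
    ds = generate_dataset(cfg)
    gene = sorted(ds.gene_aa)[0]
    est = nj_tree(ds.gene_aa[gene], SubstModel(gamma_shape=cfg.gamma_shape))
    return {"recovered": est.same_topology(tree)}
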