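"""Occupancy trimming, concatenation, PI counting, site removal."""
import numpy as np
import pytest

from ciliovet.model import SubstModel
from ciliovet.likelihood import site_loglik
from ciliovet.supermatrix import (
    Supermatrix,
    concatenate,
    count_parsimony_informative,
    missing_report,
    reduce_by_gene_coverage,
    remove_fast_sites,
    trim_by_occupancy,
)
from ciliovet.trees import PhyloTree


class TestOccupancyTrim:
    def test_gap_free_unchanged(self):
        rows = {"A": "MKVL", "B": "MKVW"}
        assert trim_by_occupancy(rows, 0.60) == rows

    def test_threshold_boundary_inclusive(self):
        # column present in 5/10 rows removed at 0.60; 6/10 kept
        rows = {f"t{i}": ("A" if i < 5 else "-") + ("C" if i < 6 else "-")
                for i in range(10)}
        out = trim_by_occupancy(rows, 0.60)
        assert all(len(v) == 1 for v in out.values())
        assert out["t0"] == "C"

    def test_matches_bruteforce_column_filter(self, rng):
        for _ in range(5):
            n, L = int(rng.integers(3, 9)), int(rng.integers(5, 30))
            rows = {
                f"t{i}": "".join(
                    "-" if rng.random() < 0.4 else "ACDEFG"[rng.integers(0, 6)]
                    for _ in range(L)
                )
                for i in range(n)
            }
            frac = float(rng.choice([0.3, 0.5, 0.6, 0.8]))
            out = trim_by_occupancy(rows, frac)
            keep = [
                j for j in range(L)
                if sum(rows[k][j] != "-" for k in rows) / n >= frac
            ]
            expect = {k: "".join(rows[k][j] for j in keep) for k in rows}
            assert out == expect


class TestConcatenate:
    def test_disjoint_taxa_missing_blocks(self):
        sm = concatenate(
            {"g1": [("A", "MK"), ("B", "MV")], "g2": [("B", "WYV"), ("C", "WYL")]},
            ["A", "B", "C"],
        )
        assert sm.n_sites == 5
        d = sm.as_dict()
        assert d["A"] == "MK---" and d["C"] == "--WYL"

    def test_single_gene_identity(self):
        sm = concatenate({"g": [("A", "MK"), ("B", "MV")]}, ["A", "B"])
        assert sm.as_dict() == {"A": "MK", "B": "MV"}

    def test_per_taxon_missing_recount(self):
        sm = concatenate(
            {
                "g1": [("A", "MK"), ("B", "MV")],
                "g2": [("B", "WYV")],
                "g3": [("A", "LLLLL"), ("B", "LLLLL")],
            },
            ["A", "B"],
        )
        # A misses g2 (3 of 10 cols)
        assert sm.per_taxon_missing[sm.taxa.index("A")] == pytest.approx(0.3)
        assert sm.per_taxon_missing[sm.taxa.index("B")] == 0.0

    def test_duplicate_taxon_within_gene_errors(self):
        with pytest.raises(ValueError, match="g1"):
            concatenate({"g1": [("A", "MK"), ("A", "MV")]}, ["A"])

    def test_partition_loglik_additivity(self, small_dataset):
        """Total supermatrix logL equals the sum of per-partition logLs on
        the same tree (gaps as missing)."""
        ds = small_dataset
        genes = sorted(ds.gene_aa)[:3]
        taxa = sorted(ds.gene_aa[genes[0]])
        sm = concatenate(
            {g: [(t, ds.gene_aa[g][t]) for t in taxa] for g in genes}, taxa
        )
        model = SubstModel(gamma_shape=0.8)
        tree = ds.species_tree
        total = site_loglik(tree, sm.as_dict(), model).sum()
        parts = 0.0
        for g, s, e in sm.partitions:
            sub = {t: sm.as_dict()[t][s:e] for t in taxa}
            parts += site_loglik(tree, sub, model).sum()
        assert total == pytest.approx(parts, abs=1e-6)


class TestParsimonyInformative:
    @pytest.mark.parametrize(
        "col,informative",
        [("AAAA", False), ("AABB", True), ("AABC", False), ("AA-B", False),
         ("AABB--", True)],
    )
    def test_definition(self, col, informative):
        M = np.array([[c] for c in col])
        assert count_parsimony_informative(M) == int(informative)

    def test_matches_bruteforce(self, rng):
        for _ in range(5):
            n, L = int(rng.integers(4, 11)), 50
            M = rng.choice(list("ACDE-"), size=(n, L))
            got = count_parsimony_informative(M)
            expect = 0
            for j in range(L):
                col = [M[i, j] for i in range(n) if M[i, j] != "-"]
                counts = {c: col.count(c) for c in set(col)}
                if sum(1 for v in counts.values() if v >= 2) >= 2:
                    expect += 1
            assert got == expect


class TestGeneCoverage:
    def test_strict_greater_boundary(self):
        taxa = [f"c{i}" for i in range(36)]
        genes = {
            "g29": [(t, "M") for t in taxa[:29]],
            "g30": [(t, "M") for t in taxa[:30]],
            "gall": [(t, "M") for t in taxa],
        }
        out = reduce_by_gene_coverage(genes, taxa, 0.80)
        # 29/36 = 0.8055... > 0.80 passes the strict rule; 30/36 clearly does
        assert set(out) == {"g29", "g30", "gall"}
        out2 = reduce_by_gene_coverage(
            {"g28": [(t, "M") for t in taxa[:28]], **genes}, taxa, 0.80
        )
        assert "g28" not in out2  # 28/36 = 0.777 fails

    def test_random_recount(self, rng):
        taxa = [f"c{i}" for i in range(10)]
        for _ in range(5):
            genes = {}
            for g in range(6):
                k = int(rng.integers(1, 11))
                genes[f"g{g}"] = [(t, "M") for t in rng.choice(taxa, k, replace=False)]
            out = reduce_by_gene_coverage(genes, taxa, 0.5)
            for g, pairs in genes.items():
                present = len({t for t, _ in pairs})
                assert (g in out) == (present / 10 > 0.5)


class TestRemoveFastSites:
    def _sm(self):
        M = np.array([list("AAAACCCCGG"), list("AAAACCCCGG"), list("AATACCTCGG")])
        return Supermatrix(["A", "B", "C"], M, [("g1", 0, 4), ("g2", 4, 10)])

    def test_infinite_threshold_identity(self):
        sm = self._sm()
        rates = np.linspace(0.1, 3.0, 10)
        out = remove_fast_sites(sm, rates, np.inf)
        assert out.n_sites == 10 and out.partitions == sm.partitions

    def test_successive_equals_single_threshold(self):
        sm = self._sm()
        rates = np.linspace(0.1, 3.0, 10)
        once = remove_fast_sites(sm, rates, 1.0)
        two = remove_fast_sites(sm, rates, 2.0)
        step = remove_fast_sites(two, two.site_rates, 1.0)
        assert once.rows() == step.rows()
        assert once.partitions == step.partitions

    def test_monotone_subset(self):
        sm = self._sm()
        rates = np.linspace(0.1, 3.0, 10)
        loose = remove_fast_sites(sm, rates, 2.0)
        tight = remove_fast_sites(sm, rates, 1.0)
        assert tight.n_sites <= loose.n_sites

    def test_all_sites_fast_errors(self):
        sm = self._sm()
        with pytest.raises(ValueError):
            remove_fast_sites(sm, np.full(10, 5.0), 1.0)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            remove_fast_sites(self._sm(), np.ones(7), 1.0)


class TestMissingReport:
    def test_complete_matrix_zero(self):
        sm = concatenate({"g": [("A", "MK"), ("B", "MV")]}, ["A", "B"])
        rep = missing_report(sm, {"all": ["A", "B"]})
        assert rep["all"] == 0.0

    def test_half_missing(self):
        sm = concatenate(
            {"g1": [("A", "MK"), ("B", "MV")], "g2": [("B", "WY")]}, ["A", "B"]
        )
        rep = missing_report(sm, {"a": ["A"], "b": ["B"]})
        assert rep["a"] == pytest.approx(0.5) and rep["b"] == 0.0

    def test_groupwise_recount_on_synthetic_run(self, small_dataset):
        ds = small_dataset
        genes = sorted(ds.gene_aa)[:4]
        taxa = sorted(ds.gene_aa[genes[0]])
        blocks = {}
        for i, g in enumerate(genes):
            present = taxa if i % 2 == 0 else taxa[:10]
            blocks[g] = [(t, ds.gene_aa[g][t]) for t in present]
        sm = concatenate(blocks, taxa)
        groups = {"first10": taxa[:10], "rest": taxa[10:]}
        rep = missing_report(sm, groups)
        m = sm.per_taxon_missing
        for name, members in groups.items():
            expect = np.mean([m[sm.taxa.index(t)] for t in members])
            assert rep[name] == pytest.approx(expect)
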