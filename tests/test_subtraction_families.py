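"""Prey-reference subtraction and family composition rules."""
import itertools

import pytest

from ciliovet.families import (
    GeneFamily,
    build_families,
    build_families_from_seeds,
    composition_funnel,
    load_annotations,
    stage1_composition,
    stage2_composition,
)
from ciliovet.records import Provenance, SeqRecordX
from ciliovet.similarity import align_pair_local
from ciliovet.subtraction import leakage_report, subtract

from conftest import random_aa


class TestSubtract:
    def test_identical_sequence_removed(self, rng):
        s = random_aa(rng, 120)
        host = [SeqRecordX("h1", s)]
        prey = [SeqRecordX("p1", s)]
        retained, decisions = subtract(host, prey)
        assert retained == [] and decisions[0].verdict == "removed_prey_like"

    def test_length_slack_boundary_retains_long_host(self, rng):
        core = random_aa(rng, 120)
        host = [SeqRecordX("h1", core + random_aa(rng, 200))]
        prey = [SeqRecordX("p1", core)]
        retained, decisions = subtract(host, prey, identity=0.80, slack_aa=150)
        # identity over the shorter sequence is 1.0 but the host protein is
        # 200 aa longer than the prey match: retained by the slack rule
        assert [r.id for r in retained] == ["h1"]
        d = decisions[0]
        assert d.verdict == "retained_unique"
        assert d.best_prey_match[1] >= 0.99 and d.best_prey_match[2] == 200

    def test_slack_is_asymmetric(self, rng):
        core = random_aa(rng, 300)
        host = [SeqRecordX("h1", core[:100])]
        prey = [SeqRecordX("p1", core)]
        retained, _ = subtract(host, prey)
        assert retained == []  # prey longer than host never blocks removal

    def test_monotonicity_in_thresholds(self, rng):
        host, prey = [], []
        base = random_aa(rng, 150)
        for i in range(12):
            s = list(base)
            for p in rng.integers(0, 150, size=rng.integers(0, 60)):
                s[p] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
            ext = random_aa(rng, int(rng.integers(0, 250)))
            host.append(SeqRecordX(f"h{i}", "".join(s) + ext))
        prey.append(SeqRecordX("p0", base))
        removed = {}
        for ident in (0.7, 0.8, 0.9):
            for slack in (50, 150, 300):
                ret, _ = subtract(host, prey, identity=ident, slack_aa=slack)
                removed[(ident, slack)] = {h.id for h in host} - {r.id for r in ret}
        assert removed[(0.8, 150)] <= removed[(0.7, 150)]
        assert removed[(0.9, 150)] <= removed[(0.8, 150)]
        assert removed[(0.8, 50)] <= removed[(0.8, 150)]
        assert removed[(0.8, 150)] <= removed[(0.8, 300)]

    def test_matches_literal_allpairs_oracle(self, small_dataset):
        from ciliovet.pipeline import recall_proteins

        ds = small_dataset
        host_aa = recall_proteins(
            [SeqRecordX(r.id, r.seq) for r in ds.mixed_library], "mesodinium", 150
        )
        prey_aa = recall_proteins(
            [SeqRecordX(r.id, r.seq) for r in ds.pure_prey], "standard", 150
        )
        _, decisions = subtract(host_aa, prey_aa)
        verdicts = {d.host_seq_id: d.verdict for d in decisions}
        for h in host_aa:
            removable = False
            for p in prey_aa:
                hit = align_pair_local(h.seq, p.seq)
                if hit is None or hit.evalue > 1e-4:
                    continue
                if hit.identity_fraction >= 0.80 and len(h.seq) - len(p.seq) <= 150:
                    removable = True
                    break
            expect = "removed_prey_like" if removable else "retained_unique"
            assert verdicts[h.id] == expect

    def test_klepto_unique_prey_necessarily_leaks(self, small_dataset):
        """Prey transcripts from genes absent in the pure reference cannot
        be subtracted: the screen's documented failure mode."""
        from ciliovet.pipeline import recall_proteins

        ds = small_dataset
        host_aa = recall_proteins(
            [SeqRecordX(r.id, r.seq) for r in ds.mixed_library], "mesodinium", 150
        )
        prey_aa = recall_proteins(
            [SeqRecordX(r.id, r.seq) for r in ds.pure_prey], "standard", 150
        )
        _, decisions = subtract(host_aa, prey_aa)
        rep = leakage_report(decisions, {r.id: ds.truth[r.id][0] for r in host_aa})
        assert rep["retained_prey_count"] > 0
        assert rep["recall_prey_shared"] >= 0.95

    def test_empty_library_errors(self):
        with pytest.raises(ValueError):
            subtract([], [SeqRecordX("p", "MK")])


class TestAnnotations:
    def test_three_rows(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("seq_id\tkey\tscore\na\tK1\t10\nb\tK2\t5\nc\tK1\t3\n")
        assert load_annotations(p) == {"a": "K1", "b": "K2", "c": "K1"}

    def test_best_score_wins(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("seq_id\tkey\tscore\na\tK1\t40\na\tK2\t50\n")
        assert load_annotations(p) == {"a": "K2"}

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("seq_id\tkey\tscore\na\tK1\t40\nb\tK2\t\n")
        with pytest.raises(ValueError, match="3"):
            load_annotations(p)

    def test_truth_as_annotation_recovers_gene_partition(self, small_dataset):
        ds = small_dataset
        pool = [r for recs in ds.reference_proteins.values() for r in recs]
        fams, counts = build_families(pool, ds.annotations)
        for fam in fams:
            assert {ds.annotations[m.id] for m in fam.members} == {fam.key}
        assert sum(len(f) for f in fams) == len(pool)


class TestBuildFamilies:
    def test_partition_and_counts(self):
        seqs = [SeqRecordX(f"s{i}", "MKV") for i in range(10)]
        ann = {f"s{i}": ("K1" if i < 6 else "K2") for i in range(9)}  # s9 skipped
        fams, counts = build_families(seqs, ann)
        assert {f.key: len(f) for f in fams} == {"K1": 6, "K2": 3}
        assert counts["skipped_unannotated"] == 1

    def test_no_annotations(self):
        fams, counts = build_families([SeqRecordX("a", "M")], {})
        assert fams == [] and counts["skipped_unannotated"] == 1

    def test_oversize_family_dropped(self):
        seqs = [SeqRecordX(f"s{i}", "MKV") for i in range(30)]
        ann = {s.id: "K1" for s in seqs}
        fams, counts = build_families(seqs, ann, max_members=20)
        assert fams == [] and counts["dropped_oversize"] == 1

    def test_seed_based_constructor(self, rng):
        base = random_aa(rng, 100)
        seed = SeqRecordX("seed1", base)
        db = []
        for i in range(10):
            s = list(base)
            for p in rng.integers(0, 100, size=2 + 2 * i):
                s[p] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(0, 20)]
            db.append(SeqRecordX(f"d{i}", "".join(s)))
        fams = build_families_from_seeds([seed], {"db": db}, evalue_cutoff=1e-10,
                                         max_hits=4)
        assert len(fams) == 1 and fams[0].key == "seed1"
        assert 2 <= len(fams[0]) <= 5  # seed + at most 4 hits


def _member(cls, prov):
    _member.n = getattr(_member, "n", 0) + 1
    return SeqRecordX(
        f"m{_member.n}", "M", taxon_id=f"t{_member.n}", class_label=cls,
        provenance=prov,
    )


class TestComposition:
    def test_stage1_truth_table(self):
        """All 8 presence/absence combinations match the boolean rule."""
        for has_host, has_cur, has_out in itertools.product([0, 1], repeat=3):
            fam = GeneFamily("k")
            fam.add(_member("ciliate_class:x", Provenance.sra))  # never counts
            if has_host:
                fam.add(_member("host_group", Provenance.transcriptome))
            if has_cur:
                fam.add(_member("ciliate_class:x", Provenance.curated))
            if has_out:
                fam.add(_member("outgroup", Provenance.curated))
            assert stage1_composition(fam) == bool(has_host and has_cur and has_out)

    def test_stage2_boundaries(self):
        def fam_with(core, sra, out):
            fam = GeneFamily("k")
            for _ in range(core):
                fam.add(_member("ciliate_class:x", Provenance.curated))
            for _ in range(sra):
                fam.add(_member("ciliate_class:x", Provenance.sra))
            for _ in range(out):
                fam.add(_member("outgroup", Provenance.curated))
            return fam

        assert stage2_composition(fam_with(24, 1, 4))
        assert not stage2_composition(fam_with(23, 1, 4))
        assert not stage2_composition(fam_with(24, 0, 4))
        assert not stage2_composition(fam_with(24, 1, 3))

    def test_stage2_counts_host_members_as_core(self):
        fam = GeneFamily("k")
        for _ in range(20):
            fam.add(_member("host_group", Provenance.transcriptome))
        for _ in range(4):
            fam.add(_member("ciliate_class:x", Provenance.curated))
        fam.add(_member("ciliate_class:x", Provenance.sra))
        for _ in range(4):
            fam.add(_member("outgroup", Provenance.curated))
        assert stage2_composition(fam)

    def test_stage2_verdicts_equal_recount_on_random_families(self, rng):
        classes = ["host_group", "ciliate_class:x", "outgroup"]
        provs = list(Provenance)
        for _ in range(20):
            fam = GeneFamily("k")
            for _ in range(int(rng.integers(5, 40))):
                fam.add(_member(str(rng.choice(classes)), provs[rng.integers(0, 4)]))
            core = sum(
                1 for m in fam.members
                if m.class_label == "host_group"
                or (m.class_label.startswith("ciliate") and m.provenance == Provenance.curated)
            )
            sra = sum(
                1 for m in fam.members
                if m.class_label in ("host_group",) or m.class_label.startswith("ciliate")
                if m.provenance == Provenance.sra
            )
            out = sum(1 for m in fam.members if m.class_label == "outgroup")
            expect = core >= 10 and sra >= 1 and out >= 2
            assert stage2_composition(fam, 10, 1, 2) == expect

    def test_stage2_implies_stage1_with_host(self, rng):
        """At defaults, any family passing stage 2 that has a host member
        also passes stage 1 (the funnel narrows monotonically)."""
        classes = ["host_group", "ciliate_class:x", "outgroup"]
        provs = list(Provenance)
        checked = 0
        for _ in range(200):
            fam = GeneFamily("k")
            fam.add(_member("host_group", Provenance.transcriptome))
            for _ in range(int(rng.integers(25, 45))):
                fam.add(_member(str(rng.choice(classes)), provs[rng.integers(0, 4)]))
            if stage2_composition(fam):
                checked += 1
                assert stage1_composition(fam)
        assert checked > 0

    def test_funnel_counts(self):
        fams = []
        f1 = GeneFamily("k1")
        f1.add(_member("host_group", Provenance.transcriptome))
        f1.add(_member("ciliate_class:x", Provenance.curated))
        f1.add(_member("outgroup", Provenance.curated))
        fams.append(f1)
        f2 = GeneFamily("k2")
        f2.add(_member("host_group", Provenance.transcriptome))
        fams.append(f2)
        kept, funnel = composition_funnel(fams, min_core=2, min_sra=0, min_outgroup=1)
        assert funnel == {"input": 2, "stage1": 1, "stage2": 1}
        assert [f.key for f in kept] == ["k1"]
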