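"""Tree I/O, duplicated-topology construction, screening, concatenation."""

import numpy as np
import pytest

from wgdchronos import treeio as T
from wgdchronos.synthetic import _prune_tree_to_labels, default_design


class TestParseWrite:
    def test_basic_structure(self):
        t = T.parse_newick("((A,B),C);")
        assert t.n_leaves == 3
        assert t.n_nodes == 5
        root_clades = {t.clade_leafset(c) for c in t.children[t.root]}
        assert root_clades == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_ultrametric_path_lengths(self):
        t = T.parse_newick("((A:1,B:1):1,C:2);")
        t.set_ages_from_edge_lengths()
        assert t.ages[t.root] == pytest.approx(2.0)
        assert all(t.ages[i] == 0 for i in t.leaf_ids)

    def test_polytomy_rejected_by_default(self):
        with pytest.raises(T.ParseError, match="non-binary"):
            T.parse_newick("((A,B,C),D);")

    def test_polytomy_resolved_deterministically(self):
        t = T.parse_newick("((A,B,C),D);", resolve_polytomies=True)
        assert t.is_binary()
        t2 = T.parse_newick("((A,B,C),D);", resolve_polytomies=True)
        assert T.write_newick(t) == T.write_newick(t2)

    def test_duplicate_leaf_label_rejected(self):
        # the error must name the offending label
        with pytest.raises(T.ParseError, match="uplicate.*A"):
            T.parse_newick("((A,A),C);")

    def test_malformed_rejected(self):
        with pytest.raises(T.ParseError):
            T.parse_newick("((A,B),C;")

    @pytest.mark.parametrize(
        "nwk",
        [
            "((A:1,B:1):1,C:2);",
            "(((A:0.1,B:0.2):0.3,C:0.4):0.5,(D:0.6,E:0.7):0.8);",
            "(A:1.5,B:1.5);",
        ],
    )
    def test_round_trip(self, nwk):
        t1 = T.parse_newick(nwk)
        t2 = T.parse_newick(T.write_newick(t1))
        assert sorted(t1.leaf_labels) == sorted(t2.leaf_labels)
        # same clade sets and branch lengths
        def clades(t):
            return {
                t.clade_leafset(v): round(float(t.edge_lengths[v]), 9)
                for v in range(t.n_nodes)
                if v != t.root
            }
        assert clades(t1) == clades(t2)

    def test_write_from_ages(self):
        t = T.parse_newick("((A,B)AB,C);")
        ages = np.zeros(t.n_nodes)
        ages[t.root] = 2.0
        ages[t.mrca(["A", "B"])] = 1.0
        t.set_ages(ages)
        lengths = sorted(
            float(x) for x in t.branch_durations() if not np.isnan(x)
        )
        assert lengths == [1.0, 1.0, 1.0, 2.0]
        back = T.parse_newick(T.write_newick(t))
        back.set_ages_from_edge_lengths()
        assert back.ages[back.root] == pytest.approx(2.0)

    def test_two_leaf_form(self):
        t = T.parse_newick("(A:3,B:3);")
        assert T.write_newick(t) == "(A:3,B:3);"

    def test_child_older_than_parent_rejected(self):
        t = T.parse_newick("((A,B),C);")
        ages = np.zeros(t.n_nodes)
        ages[t.root] = 1.0
        ages[t.mrca(["A", "B"])] = 2.0
        with pytest.raises(T.TreeError, match="older than"):
            t.set_ages(ages)


class TestDuplicatedTopology:
    def test_leaf_count_and_mirrors(self, design):
        dup = T.build_duplicated_topology(
            design.species_tree(), design.duplicated_taxa, ("_1", "_2")
        )
        assert dup.n_leaves == 6 + 2 * 6 == 18
        wgd = dup.find_node("WGD")
        kids = dup.children[wgd]
        strip = lambda s: s.rsplit("_", 1)[0]
        c0 = {strip(l) for l in dup.clade_leafset(kids[0])}
        c1 = {strip(l) for l in dup.clade_leafset(kids[1])}
        assert c0 == c1 == set(design.duplicated_taxa)
        # mirrored crown-teleost node exists exactly twice
        assert dup.labels.count("Teleostei_1") == 1
        assert dup.labels.count("Teleostei_2") == 1

    @pytest.mark.parametrize("clade", [("A", "B"), ("A", "B", "C")])
    def test_leaf_count_formula(self, clade):
        sp = T.parse_newick("(((A,B),C),(D,E));")
        dup = T.build_duplicated_topology(sp, clade)
        assert dup.n_leaves == 5 - len(clade) + 2 * len(clade)

    def test_non_monophyletic_rejected(self):
        sp = T.parse_newick("(((A,B),C),(D,E));")
        with pytest.raises(T.TreeError, match="monophyletic"):
            T.build_duplicated_topology(sp, {"A", "D"})

    def test_suffix_collision_rejected(self):
        sp = T.parse_newick("((A,A_1),C);")
        with pytest.raises(T.TreeError, match="collision"):
            T.build_duplicated_topology(sp, {"A"}, ("_1", "_2"))


class TestScreen:
    @pytest.fixture(scope="class")
    def expected(self):
        return default_design().duplicated_tree()

    def test_identical_passes(self, expected):
        gt = T.parse_newick(T.write_newick(expected))
        assert T.screen_orthogroup(gt, expected).passed

    def test_missing_taxa_pass(self, expected):
        keep = set(expected.leaf_labels) - {"Polyodon", "Danio_2"}
        gt = _prune_tree_to_labels(expected, keep)
        assert T.screen_orthogroup(gt, expected).passed

    def test_lineage_specific_duplication_fails(self, expected):
        # the two Danio copies as sisters is a post-speciation duplication,
        # not 3R paralogy: must fail under every copy assignment
        base = _prune_tree_to_labels(
            expected, set(expected.leaf_labels) - {"Danio_2"}
        )
        nwk = T.write_newick(base).replace("Danio_1", "(Danio_1,Danio_2)")
        verdict = T.screen_orthogroup(T.parse_newick(nwk), expected)
        assert not verdict.passed
        assert "clade" in verdict.reason

    def test_leaf_order_permutation_invariant(self, expected):
        gt = T.parse_newick(T.write_newick(expected))
        # rotate children everywhere: same unrooted topology
        for ch in gt.children:
            ch.reverse()
        assert T.screen_orthogroup(T.parse_newick(T.write_newick(gt)), expected).passed

    def test_global_suffix_swap_invariant(self, expected):
        swapped = (
            T.write_newick(expected)
            .replace("_1", "_x")
            .replace("_2", "_1")
            .replace("_x", "_2")
        )
        assert T.screen_orthogroup(T.parse_newick(swapped), expected).passed

    def test_unrootable_without_outgroup(self, expected):
        ingroup = {l for l in expected.leaf_labels if l.endswith(("_1", "_2"))}
        gt = _prune_tree_to_labels(expected, ingroup)
        with pytest.raises(T.ScreenError, match="unrootable"):
            T.screen_orthogroup(gt, expected)

    def test_uninformative_too_few_copies(self, expected):
        keep = set(default_design().outgroup_taxa) | {"Danio_1", "Danio_2"}
        gt = _prune_tree_to_labels(expected, keep)
        verdict = T.screen_orthogroup(gt, expected)
        assert not verdict.passed
        assert "uninformative" in verdict.reason


def _fake_locus(lid, labels, length):
    return T.LocusAlignment(lid, {lab: "A" * length for lab in labels})


class TestFilterConcatenate:
    @pytest.fixture(scope="class")
    def roster(self):
        d = default_design()
        return d.roster()

    def test_short_locus_discarded(self, roster):
        loci = [
            _fake_locus("keep", roster.expected_labels, 120),
            _fake_locus("drop", roster.expected_labels, 90),
        ]
        ohno, summary = T.filter_and_concatenate(loci, roster, min_len=100)
        assert [l.locus_id for l in ohno.loci] == ["keep"]
        assert summary.n_loci == 1

    def test_reference_design_counts(self, roster):
        # 30 loci x 18 sequences, 3 genes deleted across 3 loci
        labels = roster.expected_labels
        loci = []
        for i in range(30):
            labs = labels[1:] if i < 3 else labels
            loci.append(_fake_locus(f"l{i}", labs, 100 + i))
        ohno, summary = T.filter_and_concatenate(loci, roster)
        assert summary.n_sequences_total == 30 * 18 - 3 == 537
        assert summary.n_complete_loci == 27
        # brute-force recount
        assert summary.n_columns_total == sum(l.length for l in loci)
        assert sum(len(l.sequences) for l in ohno.loci) == 537

    def test_empty_inputs_error(self, roster):
        with pytest.raises(ValueError, match="no input loci"):
            T.filter_and_concatenate([], roster)
        with pytest.raises(ValueError, match="no loci pass"):
            T.filter_and_concatenate(
                [_fake_locus("short", roster.expected_labels, 50)], roster
            )

    def test_concatenated_supermatrix(self, roster):
        loci = [
            _fake_locus("a", roster.expected_labels, 100),
            _fake_locus("b", roster.expected_labels[2:], 150),
        ]
        ohno, _ = T.filter_and_concatenate(loci, roster)
        cat = ohno.concatenated()
        assert cat.length == 250
        absent = roster.expected_labels[0]
        assert cat.sequences[absent][100:] == "?" * 150


class TestFasta:
    def test_round_trip(self, tmp_path):
        aln = T.LocusAlignment("x", {"A": "ACD-EF", "B": "ACD?EF"})
        path = tmp_path / "x.fasta"
        T.write_fasta_alignment(aln, path)
        back = T.read_fasta_alignment(path)
        assert back.sequences == aln.sequences
        assert back.length == 6

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            T.LocusAlignment("x", {"A": "ACDEF", "B": "ACD"})
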