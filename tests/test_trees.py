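"""NJ estimation, bootstrap consensus support, clade recovery, summaries."""

import dendropy
import numpy as np
import pytest

import radphylo as rp
from radphylo.supermatrix import SNPMatrix
from radphylo.trees import (
    RunResult,
    bootstrap_support,
    clade_recovery,
    estimate_tree,
    snp_distance_matrix,
    support_vs_snps,
    tally_support,
)


def _matrix(rows: dict[str, str]) -> SNPMatrix:
    ids = list(rows)
    sites = np.array([list(rows[s]) for s in ids], dtype="<U1")
    return SNPMatrix(ids, sites)


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


def _sim_matrix(seed=3, n_taxa=8, n_loci=150):
    """Error-free matrix simulated on a known tree, plus that tree."""
    cfg = rp.SimulationConfig(
        n_taxa=n_taxa, n_loci=n_loci, per_site_mutation_rate=8e-3,
        coverage_law=(2.0, 2.0), seq_error_rate=0.0, seed=seed,
    )
    tree = rp.simulate_species_tree(cfg)
    truth = rp.simulate_loci(tree, cfg)
    calls = {
        lid: truth.true_alignment(j)
        for j, lid in enumerate(truth.locus_ids)
    }
    wl = rp.make_whitelist(truth.locus_presence, 0.9)
    matrix = rp.build_snp_matrix(calls, wl, truth.sample_ids)
    return matrix, tree


class TestDistances:
    def test_pairwise_deletion(self):
        m = _matrix({"A": "ACGTN", "B": "ACGAN", "C": "NNGTA"})
        d = snp_distance_matrix(m)
        assert d[0, 1] == pytest.approx(1 / 4)  # 4 shared sites, 1 mismatch
        assert d[0, 2] == pytest.approx(0.0)  # shared: GT vs GT
        assert d[1, 2] == pytest.approx(1 / 2)  # shared: GA vs GT -> 1 of 2

    def test_zero_overlap_pair_gets_max_observed(self):
        m = _matrix({"A": "ACNN", "B": "ACNN", "C": "NNGT", "D": "NNGA"})
        with pytest.warns(UserWarning, match="no called sites"):
            d = snp_distance_matrix(m)
        finite_max = 0.5  # C vs D mismatch proportion
        assert d[0, 2] == pytest.approx(finite_max)
        assert d[2, 3] == pytest.approx(0.5)


class TestEstimateTree:
    def test_three_taxa_single_internal_node(self):
        m = _matrix({"A": "AAAA", "B": "AACC", "C": "CCCC"})
        tree = estimate_tree(m, outgroup="C")
        internal = [n for n in tree if not n.is_leaf() and n.parent_node]
        assert len(tree.leaf_nodes()) == 3
        assert len(internal) == 1

    def test_recovers_known_topology(self):
        # balanced 8-taxon tree with long internal branches: NJ on an
        # error-free, no-missing-data matrix must recover it exactly
        newick = (
            "(((S01:1,S02:1):1,(S03:1,S04:1):1):1,"
            "((S05:1,S06:1):1,(S07:1,S08:1):1):1);"
        )
        cfg = rp.SimulationConfig(
            n_taxa=8, n_loci=200, per_site_mutation_rate=8e-3,
            coverage_law=(2.0, 2.0), seq_error_rate=0.0, seed=3,
        )
        true_tree = dendropy.Tree.get(data=newick, schema="newick")
        truth = rp.simulate_loci(true_tree, cfg)
        calls = {lid: truth.true_alignment(j) for j, lid in enumerate(truth.locus_ids)}
        wl = rp.make_whitelist(truth.locus_presence, 0.9)
        matrix = rp.build_snp_matrix(calls, wl, truth.sample_ids)
        est = estimate_tree(matrix, outgroup="S01")
        assert clade_recovery(est, true_tree) == 1.0

    def test_row_order_invariance(self):
        matrix, _ = _sim_matrix(seed=9)
        perm = np.random.default_rng(0).permutation(len(matrix.sample_ids))
        shuffled = SNPMatrix(
            [matrix.sample_ids[i] for i in perm], matrix.sites[perm]
        )
        a = estimate_tree(matrix, outgroup=matrix.sample_ids[0])
        b = estimate_tree(shuffled, outgroup=matrix.sample_ids[0])
        assert clade_recovery(a, b) == 1.0

    def test_unknown_outgroup_rejected(self):
        with pytest.raises(ValueError, match="outgroup"):
            estimate_tree(_matrix({"A": "AC", "B": "AG", "C": "AT"}), "Z")

    def test_degenerate_matrices_rejected(self):
        with pytest.raises(ValueError, match="3 samples"):
            estimate_tree(_matrix({"A": "AC", "B": "AG"}), "A")


class TestBootstrapSupport:
    def test_clean_repeated_signal_gives_full_support(self):
        # one clade signal repeated in every column: AB | CD
        m = _matrix({"A": "A" * 30, "B": "A" * 30, "C": "C" * 30, "D": "C" * 30})
        st = bootstrap_support(m, outgroup="D", B=50, seed=1)
        assert st.clade_support
        assert all(v == 100.0 for v in st.clade_support.values())

    def test_single_replicate_reproduces_point_tree(self):
        matrix, _ = _sim_matrix(seed=5)
        out = matrix.sample_ids[0]
        st = bootstrap_support(matrix, outgroup=out, B=1, seed=2)
        rng = np.random.default_rng(2)
        cols = rng.integers(0, matrix.n_sites, size=matrix.n_sites)
        rep = SNPMatrix(matrix.sample_ids, matrix.sites[:, cols])
        point = estimate_tree(rep, out)
        assert clade_recovery(st.tree, point) == 1.0
        assert all(v == 100.0 for v in st.clade_support.values())

    def test_supports_within_consensus_bounds(self):
        matrix, _ = _sim_matrix(seed=7)
        st = bootstrap_support(matrix, outgroup=matrix.sample_ids[0], B=40, seed=0)
        for v in st.clade_support.values():
            assert 50.0 <= v <= 100.0

    def test_label_permutation_symmetry(self):
        """Support values follow a relabelling of the taxa exactly."""
        matrix, _ = _sim_matrix(seed=13, n_taxa=6)
        out = matrix.sample_ids[0]
        st = bootstrap_support(matrix, outgroup=out, B=30, seed=4)
        mapping = {sid: f"X{i}" for i, sid in enumerate(matrix.sample_ids)}
        renamed = SNPMatrix([mapping[s] for s in matrix.sample_ids], matrix.sites)
        st2 = bootstrap_support(renamed, outgroup=mapping[out], B=30, seed=4)
        relabelled = {
            frozenset(mapping[x] for x in clade): v
            for clade, v in st.clade_support.items()
        }
        assert relabelled == st2.clade_support


class TestTallySupport:
    def test_forty_two_of_forty_five(self):
        # the headline support tally: 42 of 45 internal nodes >= 70%
        supports = [95.0] * 42 + [60.0, 55.0, 50.0]
        clades = {frozenset({f"a{i}", f"b{i}"}): s for i, s in enumerate(supports)}
        st = rp.SupportedTree(tree=_tree("(a,b);"), clade_support=clades, outgroup="o")
        n_int, n_sup, prop = tally_support(st, cutoff=70)
        assert (n_int, n_sup) == (45, 42)
        assert prop == pytest.approx(42 / 45)
        assert round(prop, 3) == 0.933

    def test_all_hundred_gives_one(self):
        clades = {frozenset({f"a{i}", f"b{i}"}): 100.0 for i in range(7)}
        st = rp.SupportedTree(_tree("(a,b);"), clades, "o")
        assert tally_support(st)[2] == 1.0

    def test_cutoff_zero_gives_one(self):
        clades = {frozenset({f"a{i}", f"b{i}"}): 50.0 + i for i in range(5)}
        st = rp.SupportedTree(_tree("(a,b);"), clades, "o")
        assert tally_support(st, cutoff=0)[2] == 1.0


class TestCladeRecovery:
    def test_identical_trees(self):
        t = _tree("((A,B),(C,(D,E)));")
        assert clade_recovery(t, _tree("((A,B),(C,(D,E)));")) == 1.0

    def test_star_tree_recovers_nothing(self):
        star = _tree("(A,B,C,D,E);")
        truth = _tree("((A,B),(C,(D,E)));")
        assert clade_recovery(star, truth) == 0.0

    def test_one_nni_away_on_six_taxa(self):
        truth = _tree("(((A,B),(C,D)),(E,F));")
        nni = _tree("(((A,C),(B,D)),(E,F));")
        # brute-force oracle: enumerate non-trivial bipartitions of both
        def splits(newick):
            t = _tree(newick)
            labels = sorted(l.taxon.label for l in t.leaf_node_iter())
            out = set()
            for node in t.preorder_node_iter():
                if node.is_leaf() or node.parent_node is None:
                    continue
                side = frozenset(l.taxon.label for l in node.leaf_iter())
                if 2 <= len(side) <= len(labels) - 2:
                    comp = frozenset(labels) - side
                    out.add(min(side, comp, key=lambda s: tuple(sorted(s))))
            return out

        true_s = splits("(((A,B),(C,D)),(E,F));")
        est_s = splits("(((A,C),(B,D)),(E,F));")
        expected = len(true_s & est_s) / len(true_s)
        assert clade_recovery(nni, truth) == pytest.approx(expected)
        assert 0.0 < expected < 1.0

    def test_leaf_mismatch_rejected(self):
        with pytest.raises(ValueError, match="leaf sets"):
            clade_recovery(_tree("((A,B),C);"), _tree("((A,B),D);"))


class TestSupportVsSnps:
    def _results(self, snps):
        return [
            RunResult(f"R{i}", 0.5, s, 10, min(10, s // 10), min(1.0, s / 100))
            for i, s in enumerate(snps)
        ]

    def test_single_row_identity(self):
        table = support_vs_snps(self._results([42]))
        assert len(table) == 1 and table.loc[0, "n_snps"] == 42

    def test_sorted_by_snps_with_stable_ties(self):
        table = support_vs_snps(self._results([30, 10, 30, 5]))
        assert list(table["n_snps"]) == [5, 10, 30, 30]
        assert list(table[table["n_snps"] == 30]["run_id"]) == ["R0", "R2"]

    def test_plot_written(self, tmp_path):
        path = tmp_path / "curve.png"
        support_vs_snps(self._results([5, 50, 500]), plot_path=path)
        assert path.stat().st_size > 0
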