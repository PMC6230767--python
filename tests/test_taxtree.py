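"""UPGMA construction, bootstrap, collapse, assignment and leaf ordering."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from tests.oracles import naive_upgma
from virclade.cgj import DistanceMatrix
from virclade.genome_io import AnnotatedGenome, DatasetManifest, Taxonomy
from virclade.signatures import SignatureTable
from virclade.taxtree import (
    assign_unclassified,
    bootstrap_supports,
    collapse,
    leaf_order_for_heatmap,
    upgma,
)


def _dm(ids, cond):
    n = len(ids)
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = cond
    m = m + m.T
    return DistanceMatrix(list(ids), m)


class TestUPGMA:
    def test_three_taxa_hand_example(self):
        """d(A,B)=0.2, d(A,C)=0.6, d(B,C)=0.8: A,B merge at 0.2 and C joins
        at the unweighted mean (0.6+0.8)/2 = 0.7."""
        D = _dm(["A", "B", "C"], [0.2, 0.6, 0.8])
        tree = upgma(D)
        assert tree.root.height == pytest.approx(0.7)
        heights = sorted(n.height for n in tree.internal_nodes())
        assert heights == pytest.approx([0.2, 0.7])
        assert frozenset(["A", "B"]) in tree.clades()

    def test_two_taxa_root_at_their_distance(self):
        tree = upgma(_dm(["A", "B"], [0.42]))
        assert tree.root.height == pytest.approx(0.42)
        assert sorted(tree.root.leaves()) == ["A", "B"]

    def test_equal_distances_all_heights_equal(self):
        D = _dm(list("ABCD"), [0.5] * 6)
        tree = upgma(D)
        assert all(n.height == pytest.approx(0.5) for n in tree.internal_nodes())

    def test_matches_naive_oracle_and_is_order_invariant(self):
        """Over every leaf ordering of a random 5-taxon matrix, the package
        tree has identical newick text and reproduces the independently
        coded UPGMA's cophenetic matrix and merge heights."""
        rng = np.random.default_rng(31)
        ids = ["t1", "t2", "t3", "t4", "t5"]
        cond = rng.random(10)
        base = _dm(ids, cond)
        coph_oracle, heights_oracle, clades_oracle = naive_upgma(
            ids, base.values
        )
        ref_newick = None
        for perm in itertools.permutations(range(5)):
            pids = [ids[i] for i in perm]
            pvals = base.values[np.ix_(perm, perm)]
            tree = upgma(DistanceMatrix(pids, pvals))
            nwk = tree.to_newick()
            if ref_newick is None:
                ref_newick = nwk
            assert nwk == ref_newick
            np.testing.assert_allclose(
                tree.cophenetic().values, coph_oracle, atol=1e-12
            )
            assert sorted(n.height for n in tree.internal_nodes()) == pytest.approx(
                sorted(heights_oracle)
            )
            assert set(tree.clades()) >= {c for c in clades_oracle if len(c) < 5}

    def test_cophenetic_fixed_point_on_ultrametric_input(self):
        """UPGMA applied to an ultrametric matrix reproduces it exactly."""
        rng = np.random.default_rng(4)
        first = upgma(_dm([f"g{i}" for i in range(6)], rng.random(15)))
        C = first.cophenetic()
        again = upgma(C)
        np.testing.assert_allclose(again.cophenetic().values, C.values, atol=1e-12)

    def test_nan_rejected(self):
        # bypass the DistanceMatrix validator to exercise upgma's own check
        D = DistanceMatrix.__new__(DistanceMatrix)
        D.genome_ids = ["a", "b"]
        D.values = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            upgma(D)

    def test_single_taxon_rejected(self):
        D = DistanceMatrix(["a"], np.zeros((1, 1)))
        with pytest.raises(ValueError, match="at least two"):
            upgma(D)


def _three_group_table() -> SignatureTable:
    """Two identical-signature genomes plus a distant outgroup."""
    pphmm = np.array(
        [
            [9.0, 8.0, 0.0, 0.0],
            [9.0, 8.0, 0.0, 0.0],
            [0.0, 0.0, 7.0, 6.0],
        ]
    )
    return SignatureTable(
        genome_ids=["in1", "in2", "out"],
        pphmm_ids=["p1", "p2", "p3", "p4"],
        family_ids=[],
        pphmm_block=pphmm,
        gom_block=np.zeros((3, 0)),
        location_profiles=np.sign(pphmm) * 0.5,
    )


class TestBootstrap:
    def test_identical_rows_pair_has_full_support(self):
        tree = bootstrap_supports(_three_group_table(), n_reps=50, seed=1)
        pair = next(
            n for n in tree.internal_nodes() if set(n.leaves()) == {"in1", "in2"}
        )
        assert pair.support == 100.0

    def test_same_seed_reproduces_supports(self):
        t1 = bootstrap_supports(_three_group_table(), n_reps=50, seed=9)
        t2 = bootstrap_supports(_three_group_table(), n_reps=50, seed=9)
        s1 = {frozenset(n.leaves()): n.support for n in t1.internal_nodes()}
        s2 = {frozenset(n.leaves()): n.support for n in t2.internal_nodes()}
        assert s1 == s2

    def test_supports_within_percentage_range(self):
        tree = bootstrap_supports(_three_group_table(), n_reps=50, seed=2)
        assert all(0.0 <= n.support <= 100.0 for n in tree.internal_nodes())

    def test_invalid_rep_count_rejected(self):
        with pytest.raises(ValueError, match="n_reps"):
            bootstrap_supports(_three_group_table(), n_reps=0, seed=0)


class TestCollapse:
    def _tree(self):
        # two tight pairs joined high: ((a1,a2):0.1, (b1,b2):0.2):0.95
        D = _dm(
            ["a1", "a2", "b1", "b2"],
            # order: (a1,a2), (a1,b1), (a1,b2), (a2,b1), (a2,b2), (b1,b2)
            [0.1, 0.95, 0.95, 0.95, 0.95, 0.2],
        )
        return upgma(D)

    def test_threshold_between_levels_splits_pairs(self):
        part = collapse(self._tree(), 0.8)
        assert sorted(map(tuple, part.clusters)) == [("a1", "a2"), ("b1", "b2")]

    def test_threshold_above_root_single_cluster(self):
        part = collapse(self._tree(), 1.0)
        assert part.n_clusters == 1

    def test_threshold_zero_makes_singletons(self):
        part = collapse(self._tree(), 0.0)
        assert part.n_clusters == 4

    def test_out_of_range_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            collapse(self._tree(), 1.5)

    def test_partition_matches_cophenetic_rule(self):
        """i, j share a cluster exactly when their cophenetic distance is
        strictly below the threshold."""
        rng = np.random.default_rng(12)
        ids = [f"g{i}" for i in range(7)]
        tree = upgma(_dm(ids, rng.random(21)))
        coph = tree.cophenetic()
        for t in (0.2, 0.5, 0.8):
            part = collapse(tree, t)
            assign = {g: part.cluster_of(g) for g in ids}
            for a, b in itertools.combinations(ids, 2):
                same = assign[a] == assign[b]
                assert same == (coph.get(a, b) < t)


def _manifest_for_assignment():
    genomes = []
    spec = {
        "m1": ("Myoviridae", True),
        "m2": ("Myoviridae", True),
        "m3": ("Myoviridae", True),
        "u1": ("", False),
        "n1": ("", False),
        "n2": ("", False),
        "z1": ("", False),
    }
    for gid, (fam, _) in spec.items():
        genomes.append(
            AnnotatedGenome(
                genome_id=gid,
                accession=gid,
                segment_lengths=[100],
                features=[],
                taxonomy=Taxonomy(family=fam, genbank_accession=gid),
            )
        )
    return DatasetManifest(
        genomes=genomes, classified={g: spec[g][1] for g in spec}
    )


class TestAssignment:
    def _partition(self):
        # u1 clusters with the three classified Myoviridae; n1+n2 alone; z1 alone
        D = _dm(
            ["m1", "m2", "m3", "u1", "n1", "n2", "z1"],
            # condensed upper triangle, order pairs (m1,m2),(m1,m3),(m1,u1),(m1,n1),(m1,n2),(m1,z1),
            # (m2,m3),(m2,u1),(m2,n1),(m2,n2),(m2,z1),(m3,u1),(m3,n1),(m3,n2),(m3,z1),
            # (u1,n1),(u1,n2),(u1,z1),(n1,n2),(n1,z1),(n2,z1)
            [0.1, 0.1, 0.3, 1, 1, 1,
             0.1, 0.3, 1, 1, 1, 0.3, 1, 1, 1,
             1, 1, 1, 0.2, 1, 1],
        )
        return collapse(upgma(D), 0.8, _manifest_for_assignment())

    def test_unclassified_in_classified_cluster_reports_family(self):
        report = assign_unclassified(self._partition(), _manifest_for_assignment())
        row = report.set_index("genome_id").loc["u1"]
        assert row["cluster_families"] == "Myoviridae:3"
        assert not row["is_utu"]

    def test_pure_unclassified_cluster_flagged_utu(self):
        report = assign_unclassified(self._partition(), _manifest_for_assignment())
        rows = report.set_index("genome_id")
        assert rows.loc["n1", "is_utu"] and rows.loc["n2", "is_utu"]
        assert rows.loc["n1", "cluster_id"] == rows.loc["n2", "cluster_id"]

    def test_all_zero_signature_reported_as_no_similarity(self):
        manifest = _manifest_for_assignment()
        ids = manifest.genome_ids
        pphmm = np.ones((7, 2))
        pphmm[ids.index("z1")] = 0.0
        table = SignatureTable(
            genome_ids=ids,
            pphmm_ids=["p1", "p2"],
            family_ids=[],
            pphmm_block=pphmm,
            gom_block=np.zeros((7, 0)),
            location_profiles=np.zeros((7, 2)),
        )
        report = assign_unclassified(self._partition(), manifest, table)
        row = report.set_index("genome_id").loc["z1"]
        assert row["no_similarity"] and not row["is_utu"]

    def test_composition_counts(self):
        part = self._partition()
        comp = part.composition
        utu_cluster = part.cluster_of("n1")
        assert comp.loc[utu_cluster, "n_classified"] == 0
        assert comp.loc[utu_cluster, "n_unclassified"] == 2
        myo_cluster = part.cluster_of("m1")
        assert comp.loc[myo_cluster, "n_classified"] == 3


class TestLeafOrderAndNewick:
    def test_leaf_order_is_permutation_and_stable(self):
        rng = np.random.default_rng(77)
        ids = [f"g{i}" for i in range(6)]
        tree = upgma(_dm(ids, rng.random(15)))
        order1 = leaf_order_for_heatmap(tree)
        order2 = leaf_order_for_heatmap(upgma(_dm(ids, tree.cophenetic().condensed())))
        assert sorted(order1) == sorted(ids)
        assert order1 == order2

    def test_newick_parses_with_supports_and_ultrametric_depths(self):
        import dendropy

        table = _three_group_table()
        tree = bootstrap_supports(table, n_reps=20, seed=5)
        nwk = tree.to_newick()
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == {
            "in1",
            "in2",
            "out",
        }
        # root-to-leaf path lengths all equal the root height (ultrametric)
        depths = []
        for leaf in parsed.leaf_node_iter():
            d, node = 0.0, leaf
            while node.parent_node is not None:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths.append(d)
        assert max(depths) - min(depths) < 1e-9
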