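"""Protein similarity, clustering, alignment, PPHMM build and scanning."""

from __future__ import annotations

import itertools
import random

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from tests.oracles import enumerate_forward_bits, sw_score_dp
from virclade.genome_io import AnnotatedGenome, DatasetManifest, GeneFeature, Taxonomy
from virclade.homology import (
    AMINO_ACIDS,
    BACKGROUND,
    PPHMMDatabase,
    ProteinCluster,
    ScoringScheme,
    SimilarityEdge,
    _make_aligner,
    align_cluster,
    build_pphmm,
    cluster_proteins,
    filter_singletons,
    forward_bits,
    pairwise_similarity,
    scan_genome,
)


def _protein(fid: str, seq: str, genome: str = "G1", start: int = 1) -> GeneFeature:
    return GeneFeature(
        feature_id=fid,
        genome_id=genome,
        start=start,
        end=start + 3 * len(seq) + 2,
        strand="+",
        translation=seq,
    )


def _random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS) for _ in range(n))


class TestPairwiseSimilarity:
    def test_classic_sw_worked_example_scores_28(self):
        """HEAGAWGHEE vs PAWHEAE under BLOSUM50 with a flat gap cost of 8
        per residue has an optimal local alignment score of 28."""
        scoring = ScoringScheme(matrix="BLOSUM50", gap_open=8, gap_extend=8)
        aligner = _make_aligner(scoring, "local")
        raw = aligner.score("HEAGAWGHEE", "PAWHEAE")
        assert raw == 28
        sub = substitution_matrices.load("BLOSUM50")
        assert sw_score_dp("HEAGAWGHEE", "PAWHEAE", sub, 8, 8) == 28

    def test_matches_brute_force_dp_on_random_pairs(self):
        rng = random.Random(11)
        scoring = ScoringScheme()
        aligner = _make_aligner(scoring, "local")
        sub = substitution_matrices.load("BLOSUM62")
        for _ in range(15):
            a = _random_seq(rng, rng.randint(5, 25))
            b = _random_seq(rng, rng.randint(5, 25))
            assert aligner.score(a, b) == pytest.approx(
                sw_score_dp(a, b, sub, scoring.gap_open, scoring.gap_extend)
            )

    def test_self_similarity_is_maximal(self):
        rng = random.Random(5)
        seq = _random_seq(rng, 50)
        proteins = [_protein("a", seq), _protein("b", seq)] + [
            _protein(f"r{i}", _random_seq(rng, 50)) for i in range(4)
        ]
        edges = pairwise_similarity(proteins, min_score=0.0)
        scores = {frozenset((e.protein_a, e.protein_b)): e.bit_score for e in edges}
        self_score = scores[frozenset(("a", "b"))]
        others = [
            s for k, s in scores.items() if ("a" in k or "b" in k) and k != frozenset(("a", "b"))
        ]
        assert all(self_score > s for s in others)

    def test_symmetry(self):
        rng = random.Random(3)
        scoring = ScoringScheme()
        aligner = _make_aligner(scoring, "local")
        for _ in range(10):
            a = _random_seq(rng, 30)
            b = _random_seq(rng, 20)
            assert aligner.score(a, b) == aligner.score(b, a)

    def test_dissimilar_sequences_make_no_edge(self):
        proteins = [_protein("a", "AAAAAAAAAA"), _protein("b", "WWWWWWWWWW")]
        assert pairwise_similarity(proteins, min_score=20.0) == []

    def test_empty_sequence_rejected(self):
        good = _protein("a", "MAAA")
        with pytest.raises(Exception):
            pairwise_similarity([good, _protein("b", "")])


class TestClusterProteins:
    def _proteins(self, ids):
        return [_protein(i, "MAAA", genome=f"g_{i}") for i in ids]

    def test_threshold_splits_components(self):
        edges = [SimilarityEdge("A", "B", 40.0), SimilarityEdge("B", "C", 5.0)]
        clusters = cluster_proteins(edges, self._proteins("ABC"), threshold=20.0)
        members = sorted(tuple(c.feature_ids) for c in clusters)
        assert members == [("A", "B"), ("C",)]

    def test_no_edges_all_singletons(self):
        clusters = cluster_proteins([], self._proteins("ABCD"), threshold=20.0)
        assert all(len(c.members) == 1 for c in clusters)
        assert len(clusters) == 4

    def test_complete_graph_single_cluster(self):
        ids = "ABCD"
        edges = [
            SimilarityEdge(a, b, 50.0) for a, b in itertools.combinations(ids, 2)
        ]
        clusters = cluster_proteins(edges, self._proteins(ids), threshold=20.0)
        assert len(clusters) == 1
        assert clusters[0].n_member_viruses == 4

    def test_invariant_under_edge_permutation(self):
        rng = random.Random(0)
        ids = "ABCDEFG"
        edges = [
            SimilarityEdge(a, b, rng.uniform(0, 60))
            for a, b in itertools.combinations(ids, 2)
        ]
        ref = cluster_proteins(edges, self._proteins(ids), threshold=30.0)
        for _ in range(5):
            rng.shuffle(edges)
            out = cluster_proteins(edges, self._proteins(ids), threshold=30.0)
            assert [c.members for c in out] == [c.members for c in ref]

    def test_mcl_like_recovers_clean_blocks(self):
        ids = "ABCDEF"
        within = [("A", "B"), ("B", "C"), ("A", "C"), ("D", "E"), ("E", "F"), ("D", "F")]
        edges = [SimilarityEdge(a, b, 50.0) for a, b in within]
        clusters = cluster_proteins(
            edges, self._proteins(ids), method="mcl_like", threshold=20.0
        )
        members = sorted(tuple(c.feature_ids) for c in clusters)
        assert members == [("A", "B", "C"), ("D", "E", "F")]


class TestAlignCluster:
    def test_singleton_cluster_single_ungapped_row(self):
        p = _protein("a", "MKLV")
        cl = ProteinCluster("c1", [("G1", "a")])
        assert align_cluster(cl, [p]) == ["MKLV"]

    def test_identical_sequences_identical_rows(self):
        ps = [_protein("a", "MKLVA"), _protein("b", "MKLVA")]
        cl = ProteinCluster("c1", [("G1", "a"), ("G1", "b")])
        assert align_cluster(cl, ps) == ["MKLVA", "MKLVA"]

    def test_single_deletion_placed_optimally(self):
        ps = [_protein("a", "ACDE"), _protein("b", "ACE")]
        cl = ProteinCluster("c1", [("G1", "a"), ("G1", "b")])
        assert align_cluster(cl, ps) == ["ACDE", "AC-E"]

    def test_ungapping_recovers_originals(self):
        rng = random.Random(9)
        base = _random_seq(rng, 30)
        seqs = {}
        for i in range(4):
            s = list(base)
            del s[rng.randrange(len(s))]
            seqs[f"m{i}"] = "".join(s)
        ps = [_protein(f, s) for f, s in seqs.items()]
        cl = ProteinCluster("c1", [("G1", f) for f in seqs])
        msa = align_cluster(cl, ps)
        assert len({len(r) for r in msa}) == 1
        for row, fid in zip(msa, sorted(seqs)):
            assert row.replace("-", "") == seqs[fid]


class TestBuildPPHMM:
    def _cluster(self, n=1):
        return ProteinCluster("c1", [("G1", f"f{i}") for i in range(n)])

    def test_single_row_msa_all_match_states(self):
        p = build_pphmm(["AAA"], self._cluster())
        assert p.n_match_states == 3
        a_idx = AMINO_ACIDS.index("A")
        assert all(np.argmax(row) == a_idx for row in p.match_emissions)

    def test_majority_gap_column_is_not_match(self):
        msa = ["A-AA", "A-AA", "A-AA", "AAAA"]  # column 2: 75% gaps
        p = build_pphmm(msa, self._cluster(4))
        assert p.n_match_states == 3

    def test_half_gap_column_is_match(self):
        msa = ["AA", "A-"]  # 50% gaps: at the threshold, still a match column
        p = build_pphmm(msa, self._cluster(2))
        assert p.n_match_states == 2

    def test_pseudocount_formula(self):
        """Two observed A's with background-weighted Laplace strength 1:
        P(A) = (2 + q_A) / (2 + 1)."""
        p = build_pphmm(["A", "A"], self._cluster(2), alpha=1.0)
        a_idx = AMINO_ACIDS.index("A")
        expected = (2 + BACKGROUND[a_idx]) / 3.0
        assert p.match_emissions[0, a_idx] == pytest.approx(expected, abs=1e-12)

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            build_pphmm(["AA", "AAA"], self._cluster(2))

    def test_probability_rows_normalised(self):
        msa = ["ACD-", "AC-E", "ACDE"]
        p = build_pphmm(msa, self._cluster(3))
        p.validate(atol=1e-9)


class TestForwardScore:
    def _toy_pphmm(self, msa, n=2):
        return build_pphmm(msa, ProteinCluster("c1", [("G1", f"f{i}") for i in range(n)]))

    @pytest.mark.parametrize(
        "msa, seqs",
        [
            (["ACD", "ACD"], ["ACD", "AD", "AACD", "W", "ACDE"]),
            (["AC-", "ACD"], ["AC", "ACD", "CA"]),
            (["WY", "WY", "W-"], ["WY", "W", "YW", "WWY"]),
        ],
    )
    def test_forward_matches_exhaustive_path_enumeration(self, msa, seqs):
        p = self._toy_pphmm(msa, n=len(msa))
        for seq in seqs:
            expect = enumerate_forward_bits(seq, p)
            got = forward_bits(seq, p)
            assert got == pytest.approx(expect, abs=1e-6)

    def test_member_sequence_outscores_random_decoys(self):
        rng = random.Random(21)
        member = _random_seq(rng, 30)
        p = self._toy_pphmm([member], n=1)
        member_score = forward_bits(member, p)
        assert member_score > 0
        for _ in range(20):
            decoy = _random_seq(rng, 30)
            assert member_score >= forward_bits(decoy, p)

    def test_empty_sequence_rejected(self):
        p = self._toy_pphmm(["AA"], n=1)
        with pytest.raises(ValueError, match="empty"):
            forward_bits("", p)


def _manifest_with_families(family_sizes: dict[str, int]) -> DatasetManifest:
    genomes = []
    for fam, size in family_sizes.items():
        for i in range(size):
            gid = f"{fam}_g{i}"
            genomes.append(
                AnnotatedGenome(
                    genome_id=gid,
                    accession=gid,
                    segment_lengths=[1000],
                    features=[],
                    taxonomy=Taxonomy(family=fam, genbank_accession=gid),
                )
            )
    return DatasetManifest(
        genomes=genomes, classified={g.genome_id: True for g in genomes}
    )


def _pphmm_with_members(pid: str, member_ids: list[str]):
    cl = ProteinCluster(pid, [(m, f"{m}|x") for m in member_ids])
    return build_pphmm(["AAAA"] * max(len(member_ids), 1), cl)


class TestFilterSingletons:
    def test_singleton_from_large_family_removed(self):
        manifest = _manifest_with_families({"Big": 5, "Small": 2})
        db = PPHMMDatabase([_pphmm_with_members("p1", ["Big_g0"])])
        assert len(filter_singletons(db, manifest)) == 0

    def test_singleton_from_two_virus_family_retained(self):
        manifest = _manifest_with_families({"Big": 5, "Small": 2})
        db = PPHMMDatabase([_pphmm_with_members("p1", ["Small_g0"])])
        assert len(filter_singletons(db, manifest)) == 1

    def test_multi_virus_pphmm_always_retained(self):
        manifest = _manifest_with_families({"Big": 5})
        db = PPHMMDatabase([_pphmm_with_members("p1", ["Big_g0", "Big_g1"])])
        assert len(filter_singletons(db, manifest)) == 1

    def test_unclassified_singleton_retained(self):
        manifest = _manifest_with_families({"Big": 5})
        manifest.genomes[0].taxonomy = Taxonomy()  # strip the family label
        db = PPHMMDatabase([_pphmm_with_members("p1", ["Big_g0"])])
        assert len(filter_singletons(db, manifest)) == 1

    def test_idempotent(self):
        manifest = _manifest_with_families({"Big": 5, "Small": 2})
        db = PPHMMDatabase(
            [
                _pphmm_with_members("p1", ["Big_g0"]),
                _pphmm_with_members("p2", ["Small_g0"]),
                _pphmm_with_members("p3", ["Big_g0", "Big_g1"]),
            ]
        )
        once = filter_singletons(db, manifest)
        twice = filter_singletons(once, manifest)
        assert once.pphmm_ids == twice.pphmm_ids == ["p2", "p3"]


class TestScanGenome:
    def _genome(self, seqs: list[str], gid="G1") -> AnnotatedGenome:
        features = []
        pos = 1
        for i, s in enumerate(seqs):
            nt_len = 3 * len(s) + 3
            features.append(
                GeneFeature(
                    feature_id=f"{gid}|p{i}",
                    genome_id=gid,
                    start=pos,
                    end=pos + nt_len - 1,
                    strand="+",
                    translation=s,
                )
            )
            pos += nt_len + 10
        return AnnotatedGenome(
            genome_id=gid, accession=gid, segment_lengths=[pos + 100], features=features
        )

    def test_no_proteins_no_hits(self):
        genome = AnnotatedGenome(
            genome_id="G0", accession="G0", segment_lengths=[500], features=[]
        )
        db = PPHMMDatabase([_pphmm_with_members("p1", ["x"])])
        assert scan_genome(genome, db) == []

    def test_best_hit_rule_keeps_single_strongest(self):
        rng = random.Random(2)
        member = _random_seq(rng, 40)
        mutated = list(member)
        for i in rng.sample(range(40), 20):
            mutated[i] = rng.choice(AMINO_ACIDS.replace(mutated[i], ""))
        genome = self._genome([member, "".join(mutated)])
        cl = ProteinCluster("c1", [("G9", "G9|x")])
        db = PPHMMDatabase([build_pphmm([member], cl)])
        hits = scan_genome(genome, db)
        assert len(hits) == 1
        assert hits[0].feature_id == "G1|p0"

    def test_midpoint_and_strand_recorded(self):
        genome = self._genome(["MKLVAAEE"])
        f = genome.features[0]
        cl = ProteinCluster("c1", [("G9", "G9|x")])
        db = PPHMMDatabase([build_pphmm(["MKLVAAEE"], cl)])
        (hit,) = scan_genome(genome, db)
        assert hit.midpoint == pytest.approx(
            ((f.start + f.end) / 2) / genome.total_length
        )
        assert hit.strand == "+"
        assert 0 < hit.midpoint <= 1

    def test_empty_database_rejected(self):
        genome = self._genome(["MKLV"])
        with pytest.raises(ValueError, match="empty"):
            scan_genome(genome, PPHMMDatabase([]))
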