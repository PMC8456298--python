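"""Tests for read-similarity clustering: identity metric, graph, components,
superfamily classification."""

import numpy as np
import pytest

from ssapipe.clustering import (
    LibraryIndex, build_similarity_graph, classify_cluster, cluster_reads,
    filter_reads, pairwise_identity, reverse_complement,
)
from ssapipe.simulate import (RepeatLibrary, TEFamily, mutate_sequence,
                              random_seq, seq_to_str)


def _rand(n, rng):
    return seq_to_str(random_seq(n, rng))


def _family_reads(consensus, n, L, rng, divergence=0.05, prefix="Sp"):
    """Reads sampled from mutated copies of a consensus, species-prefixed."""
    reads = []
    for i in range(n):
        copy = mutate_sequence(consensus, divergence, rng)
        start = int(rng.integers(0, len(copy) - L + 1))
        seq = copy[start:start + L]
        if rng.random() < 0.5:
            seq = reverse_complement(seq)
        reads.append((f"{prefix}_{i:04d}", seq))
    return reads


def partition_of(table):
    """read_id -> frozenset cluster key, for comparing partitions."""
    groups = {}
    for _, row in table.assignments.iterrows():
        groups.setdefault(row.cluster_id, set()).add(row.read_id)
    return {frozenset(v) for v in groups.values()}


class TestFilterReads:
    def test_boundary_inclusive(self, rng):
        reads = [("a_1", _rand(20, rng)), ("a_2", _rand(45, rng)),
                 ("a_3", _rand(150, rng))]
        kept = filter_reads(reads, 45)
        assert [r[0] for r in kept] == ["a_2", "a_3"]

    def test_all_retained_and_empty(self, rng):
        reads = [("a_1", _rand(150, rng))]
        assert filter_reads(reads, 45) == reads
        assert filter_reads([], 45) == []


class TestPairwiseIdentity:
    def test_self_alignment(self, rng):
        r = _rand(120, rng)
        ident, cols = pairwise_identity(r, r)
        assert ident == 1.0
        assert cols == 120

    def test_reverse_complement_symmetry(self, rng):
        r = _rand(100, rng)
        ident, _ = pairwise_identity(r, reverse_complement(r))
        assert ident == 1.0

    def test_fifteen_substitutions_give_point_nine(self, rng):
        r = list(_rand(150, rng))
        # 15 interior substitutions, spaced so local trimming cannot improve
        positions = list(range(10, 140, 9))[:15]
        other = "ACGT"
        mutated = r[:]
        for p in positions:
            mutated[p] = other[(other.index(r[p]) + 1) % 4]
        ident, cols = pairwise_identity("".join(r), "".join(mutated))
        assert cols == 150
        assert ident == pytest.approx(135 / 150)

    def test_no_hit_below_min_overlap(self, rng):
        # unrelated sequences rarely align over >=55% of the shorter read
        assert pairwise_identity(_rand(100, rng), _rand(100, rng)) is None

    def test_empty_read_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_identity("", _rand(50, rng))


class TestSimilarityGraph:
    def test_identical_reads_form_complete_graph(self, rng):
        r = _rand(100, rng)
        reads = [(f"a_{i}", r) for i in range(10)]
        g = build_similarity_graph(reads)
        assert g.graph.number_of_edges() == 45

    def test_diverged_families_stay_separate(self, rng):
        # families at the library's inter-ancestral divergence must not link
        base = seq_to_str(random_seq(400, rng))
        fam2 = mutate_sequence(base, 0.45, rng)
        reads = (_family_reads(base, 25, 100, rng, prefix="a")
                 + [(f"b_{i:04d}", s) for i, (_, s) in
                    enumerate(_family_reads(fam2, 25, 100, rng))])
        g = build_similarity_graph(reads, brute_force=True)
        for u, v in g.graph.edges():
            assert u.split("_")[0] == v.split("_")[0]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_prefilter_matches_brute_force_at_low_divergence(self, seed):
        # the k-mer prefilter is exact in its design regime: well-covered
        # families at modest divergence (boundary-overlap pairs at ~10%
        # divergence can share no intact 15-mer and need the oracle mode)
        rng = np.random.default_rng(seed)
        reads = []
        for fi in range(3):
            cons = seq_to_str(random_seq(300, rng))
            reads += _family_reads(cons, 22, 100, rng, divergence=0.02,
                                   prefix=f"f{fi}")
        reads += [(f"bg_{i:04d}", _rand(100, rng)) for i in range(20)]
        reads = [(f"{rid}x{i}", s) for i, (rid, s) in enumerate(reads)]
        fast = cluster_reads(build_similarity_graph(reads), min_cluster_size=1)
        brute = cluster_reads(build_similarity_graph(reads, brute_force=True),
                              min_cluster_size=1)
        assert partition_of(fast) == partition_of(brute)

    def test_strand_invariance(self, rng):
        cons = seq_to_str(random_seq(300, rng))
        reads = _family_reads(cons, 30, 90, rng)
        flipped = [(rid, reverse_complement(s) if i % 3 == 0 else s)
                   for i, (rid, s) in enumerate(reads)]
        p1 = partition_of(cluster_reads(build_similarity_graph(reads),
                                        min_cluster_size=1))
        p2 = partition_of(cluster_reads(build_similarity_graph(flipped),
                                        min_cluster_size=1))
        assert p1 == p2

    def test_threshold_monotonicity(self, rng):
        reads = []
        for fi in range(2):
            cons = seq_to_str(random_seq(300, rng))
            reads += _family_reads(cons, 15, 90, rng, divergence=0.06,
                                   prefix=f"f{fi}")
        reads = [(f"{rid}m{i}", s) for i, (rid, s) in enumerate(reads)]
        loose = cluster_reads(build_similarity_graph(reads, identity_threshold=0.80,
                                                     brute_force=True), 1)
        tight = cluster_reads(build_similarity_graph(reads, identity_threshold=0.90,
                                                     brute_force=True), 1)
        loose_map = {r: cid for r, cid in
                     zip(loose.assignments.read_id, loose.assignments.cluster_id)}
        # raising the threshold only refines: every tight cluster sits inside
        # one loose cluster
        for tight_cluster in partition_of(tight):
            assert len({loose_map[r] for r in tight_cluster}) == 1

    def test_bad_threshold_rejected(self, rng):
        with pytest.raises(ValueError):
            build_similarity_graph([("a_1", _rand(50, rng))], identity_threshold=0.0)


class TestClusterReads:
    def test_complete_graph_single_cluster(self, rng):
        r = _rand(100, rng)
        g = build_similarity_graph([(f"a_{i}", r) for i in range(10)])
        table = cluster_reads(g, min_cluster_size=2)
        assert table.n_clusters == 1
        assert len(table.assignments) == 10

    def test_edgeless_graph_all_unclustered(self, rng):
        reads = [(f"a_{i}", _rand(100, rng)) for i in range(6)]
        table = cluster_reads(build_similarity_graph(reads, brute_force=True),
                              min_cluster_size=2)
        assert table.n_clusters == 0
        assert len(table.unclustered) == 6

    def test_cluster_ids_ordered_by_size(self, rng):
        r1, r2 = _rand(100, rng), _rand(100, rng)
        reads = [(f"a_{i}", r1) for i in range(6)] + [(f"b_{i}", r2) for i in range(4)]
        table = cluster_reads(build_similarity_graph(reads), min_cluster_size=2)
        sizes = table.cluster_sizes()
        assert sizes[1] == 6 and sizes[2] == 4

    def test_small_components_reported_unclustered(self, rng):
        r1, r2 = _rand(100, rng), _rand(100, rng)
        reads = [(f"a_{i}", r1) for i in range(6)] + [(f"b_{i}", r2) for i in range(3)]
        table = cluster_reads(build_similarity_graph(reads), min_cluster_size=5)
        assert table.n_clusters == 1
        assert len(table.unclustered) == 3

    def test_per_species_counts_sum_to_cluster_size(self, rng):
        r = _rand(100, rng)
        reads = [(f"sp{i % 3}_{i}", r) for i in range(9)]
        table = cluster_reads(build_similarity_graph(reads), min_cluster_size=2)
        summary = table.summary()
        row = summary.iloc[0]
        assert row["size"] == row[["sp0", "sp1", "sp2"]].sum() == 9


class TestClassification:
    @pytest.fixture()
    def library(self, rng):
        return RepeatLibrary([
            TEFamily("H_00", "Gypsy", random_seq(900, rng), "H"),
            TEFamily("H_01", "Copia", random_seq(700, rng), "H"),
            TEFamily("C_00", "DNA", random_seq(500, rng), "C"),
        ])

    def test_reads_from_one_family_get_its_superfamily(self, library, rng):
        cons = seq_to_str(library["H_00"].consensus)
        reads = [s for _, s in _family_reads(cons, 30, 100, rng)]
        assert classify_cluster(reads, LibraryIndex(library)) == "Gypsy"

    def test_random_reads_are_unknown(self, library, rng):
        reads = [_rand(100, rng) for _ in range(30)]
        assert classify_cluster(reads, LibraryIndex(library)) == "unknown"

    def test_plurality_vote(self, library, rng):
        g = [s for _, s in _family_reads(seq_to_str(library["H_00"].consensus),
                                         12, 100, rng)]
        c = [s for _, s in _family_reads(seq_to_str(library["H_01"].consensus),
                                         8, 100, rng)]
        assert classify_cluster(g + c, LibraryIndex(library)) == "Gypsy"

    def test_empty_library_rejected(self, rng):
        idx = LibraryIndex(RepeatLibrary([]))
        with pytest.raises(ValueError):
            classify_cluster([_rand(100, rng)], idx)
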