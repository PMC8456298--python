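"""Unit and property tests for the genome/read simulator."""

import numpy as np
import pytest
from scipy import stats

from ssapipe.simulate import (
    Event, GenomeState, LineageNode, ReadSamplingSpec, RepeatLibrary, Scenario,
    SubgenomeBlock, TEFamily, default_scenario, fractionate, hybridize,
    mutate_sequence, null_scenario, random_seq, sample_reads, seq_to_str,
    simulate, str_to_seq, te_burst, revcomp,
)


def _genome(label, n_blocks=4, block_len=5000, rng=None, plastome_len=500):
    rng = rng or np.random.default_rng(1)
    return GenomeState(
        label=label,
        blocks=[SubgenomeBlock(label, random_seq(block_len, rng)) for _ in range(n_blocks)],
        plastome=random_seq(plastome_len, rng),
        plastome_lineage=label,
        ploidy_contrib={label: 2},
    )


def _library():
    rng = np.random.default_rng(7)
    return RepeatLibrary([
        TEFamily("H_00", "Gypsy", random_seq(800, rng), "H"),
        TEFamily("H_01", "Copia", random_seq(500, rng), "H"),
        TEFamily("C_00", "DNA", random_seq(400, rng), "C"),
    ])


class TestMutateSequence:
    def test_zero_rate_is_identity(self):
        assert mutate_sequence("ACGT", 0.0, 123) == "ACGT"

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            mutate_sequence("ACGT", -0.1, 0)

    def test_observed_divergence_matches_rate(self):
        seq = seq_to_str(random_seq(1000, np.random.default_rng(5)))
        out = mutate_sequence(seq, 0.10, 1)
        frac = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert 0.07 <= frac <= 0.13  # binomial 1000 trials, p=0.1

    def test_deterministic_given_seed(self):
        seq = seq_to_str(random_seq(300, np.random.default_rng(2)))
        assert mutate_sequence(seq, 0.2, 99) == mutate_sequence(seq, 0.2, 99)

    def test_rate_capped_at_three_quarters(self):
        seq = seq_to_str(random_seq(4000, np.random.default_rng(3)))
        out = mutate_sequence(seq, 5.0, 1)
        frac = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert frac < 0.80


class TestHybridize:
    def test_merges_blocks_ploidy_and_maternal_plastome(self):
        a = _genome("H")
        b = _genome("C", n_blocks=5)
        child = hybridize(a, b, maternal="H")
        assert child.ploidy == 4
        assert len(child.blocks) == len(a.blocks) + len(b.blocks)
        assert child.total_length == a.total_length + b.total_length
        assert np.array_equal(child.plastome, a.plastome)
        assert child.plastome_lineage == "H"

    def test_self_cross_doubles(self):
        a = _genome("X")
        child = hybridize(a, a, maternal="X")
        assert child.ploidy == 4
        assert len(child.blocks) == 2 * len(a.blocks)

    def test_unknown_maternal_rejected(self):
        with pytest.raises(ValueError):
            hybridize(_genome("H"), _genome("C"), maternal="Z")


class TestFractionate:
    def test_f_zero_is_noop(self):
        g = hybridize(_genome("H"), _genome("C"), maternal="H")
        out = fractionate(g, "H", 0.0, 0)
        assert len(out.blocks) == len(g.blocks)
        assert out.ploidy == 4

    def test_f_one_removes_parent_and_diploidizes(self):
        g = hybridize(_genome("H"), _genome("C"), maternal="H")
        out = fractionate(g, "H", 1.0, 0)
        assert all(b.parent_label == "C" for b in out.blocks)
        assert out.ploidy == 2

    def test_unknown_label_and_bad_f_rejected(self):
        g = _genome("H")
        with pytest.raises(ValueError):
            fractionate(g, "Z", 0.5, 0)
        with pytest.raises(ValueError):
            fractionate(g, "H", 1.5, 0)

    def test_retention_within_binomial_interval(self):
        rng = np.random.default_rng(11)
        h = GenomeState("H", [SubgenomeBlock("H", random_seq(200, rng))
                              for _ in range(100)],
                        random_seq(100, rng), "H", {"H": 2})
        out = fractionate(h, "H", 0.9, 42)
        lo, hi = stats.binom.ppf([0.005, 0.995], 100, 0.1)
        assert lo <= len(out.blocks) <= hi

    def test_post_hybrid_copies_in_retained_blocks_survive(self):
        lib = _library()
        g = hybridize(_genome("H"), _genome("C"), maternal="H")
        g = te_burst(g, lib, "H_00", 20, post_hybrid=True, seed=3)
        out = fractionate(g, "H", 1.0, 0)
        surviving = out.family_copy_counts().get("H_00", 0)
        in_c_before = sum(1 for b in g.blocks if b.parent_label == "C"
                          for fid, *_ in b.copies if fid == "H_00")
        assert surviving == in_c_before > 0


class TestTeBurst:
    def test_zero_copies_is_identity(self):
        g = _genome("H")
        out = te_burst(g, _library(), "H_00", 0, False, 0)
        assert out.total_length == g.total_length

    def test_length_grows_by_inserted_copies(self):
        g = _genome("H")
        out = te_burst(g, _library(), "H_01", 50, False, 0)
        n = out.family_copy_counts()["H_01"]
        assert n == 50
        assert out.total_length == g.total_length + n * 500
        out.validate()

    def test_deterministic_given_seed(self):
        g = _genome("H")
        a = te_burst(g, _library(), "H_00", 10, False, 7)
        b = te_burst(g, _library(), "H_00", 10, False, 7)
        assert [x.copies for x in a.blocks] == [y.copies for y in b.blocks]

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            te_burst(_genome("H"), _library(), "Q_99", 1, False, 0)


class TestReadSampling:
    def test_read_count_closed_form(self):
        spec = ReadSamplingSpec.from_coverage(L=150, C=0.5, G=300_000_000,
                                              paired=False)
        assert spec.N == 1_000_000
        assert spec.C == pytest.approx(0.5)

    def test_recomputed_coverage_at_least_requested(self):
        for c in (0.123, 0.5, 1.26, 5.1):
            spec = ReadSamplingSpec.from_coverage(L=100, C=c, G=1_000_003)
            assert spec.C >= c
            assert spec.C == pytest.approx(spec.L * spec.N / spec.G)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            ReadSamplingSpec.from_coverage(L=0, C=1, G=100)
        with pytest.raises(ValueError):
            ReadSamplingSpec(L=100, N=10, G=1000, C=0.9)  # C != LN/G

    def test_truth_fraction_tracks_genomic_fraction(self):
        # one family occupying ~10% of the genome: the truth-labeled read
        # fraction converges on the length fraction
        rng = np.random.default_rng(8)
        lib = RepeatLibrary([TEFamily("H_00", "Gypsy", random_seq(1000, rng), "H")])
        g = GenomeState("H", [SubgenomeBlock("H", random_seq(45_000, rng))
                              for _ in range(4)],
                        random_seq(500, rng), "H", {"H": 2})
        g = te_burst(g, lib, "H_00", 20, False, 1)
        frac_true = 20_000 / g.total_length
        spec = ReadSamplingSpec(L=100, N=20_000, G=g.total_length,
                                C=100 * 20_000 / g.total_length, paired=False, seed=5)
        rs = sample_reads(g, spec, "Sp")
        frac = sum(f == "H_00" for f in rs.family_ids) / len(rs)
        assert abs(frac - frac_true) <= 0.01

    def test_read_ids_carry_species_prefix_and_truth_covers_all(self):
        g = _genome("H")
        spec = ReadSamplingSpec.from_coverage(L=100, C=0.2, G=g.total_length, seed=1)
        rs = sample_reads(g, spec, "SpA")
        assert len(rs) == spec.N
        assert all(r.startswith("SpA_") for r in rs.read_ids)
        assert len(rs.truth()) == len(rs)

    def test_read_longer_than_genome_rejected(self):
        g = _genome("H", n_blocks=1, block_len=50)
        spec = ReadSamplingSpec(L=100, N=2, G=100, C=2.0, paired=False)
        with pytest.raises(ValueError):
            sample_reads(g, spec, "Sp")


class TestScenario:
    def test_default_scenario_validates(self):
        sc = default_scenario()
        sc.validate()
        assert len(sc.tips()) == 17
        assert set(sc.clades) == {"Olyreae", "Arundinarieae", "NWB", "PWB"}

    def test_default_plastome_lineages(self):
        sc = default_scenario()
        lin = {t.name: sc.expected_plastome_lineage(t.name) for t in sc.tips()}
        for sp, clade in sc.clade_map.items():
            if clade in ("Olyreae", "NWB", "PWB"):
                assert lin[sp] == "H"
            elif clade == "Arundinarieae":
                assert lin[sp] != "H"

    def test_yaml_round_trip(self, tmp_path):
        sc = null_scenario(species_per_clade=2, size_scale=0.05)
        path = tmp_path / "scenario.yaml"
        sc.to_yaml(path)
        sc2 = Scenario.from_yaml(path)
        assert [n.name for n in sc2.nodes] == [n.name for n in sc.nodes]
        assert sc2.clade_map == sc.clade_map

    def test_hybridization_must_reference_defined_lineage(self):
        sc = null_scenario(species_per_clade=2, size_scale=0.05)
        sc.nodes[2].events.append(
            Event("hybridization", {"partner": "GHOST", "maternal": "GHOST"}))
        with pytest.raises(ValueError):
            sc.validate()


@pytest.fixture(scope="module")
def small_sim():
    sc = default_scenario(species_per_clade=2, size_scale=0.08)
    return sc, simulate(sc, 42)


class TestSimulate:
    def test_simulated_lineages_match_maternal_traversal(self, small_sim):
        sc, sim = small_sim
        for sp, g in sim.genomes.items():
            assert g.plastome_lineage == sc.expected_plastome_lineage(sp)

    def test_ploidy_bookkeeping(self, small_sim):
        sc, sim = small_sim
        for sp, g in sim.genomes.items():
            clade = sc.clade_map[sp]
            if clade == "Olyreae":
                assert g.ploidy == 2
            elif clade in ("Arundinarieae", "PWB"):
                assert g.ploidy == 4
            elif clade == "NWB":
                assert g.ploidy >= 2
            g.validate()

    def test_plastomes_equal_length(self, small_sim):
        _, sim = small_sim
        lengths = {len(p) for p in sim.plastomes.values()}
        assert len(lengths) == 1

    def test_byte_identical_fastq_for_same_seed(self, tmp_path):
        sc = default_scenario(species_per_clade=2, size_scale=0.05)
        outs = []
        for d in ("a", "b"):
            sim = simulate(sc, 7)
            p = tmp_path / d
            p.mkdir()
            sim.write_outputs(p, write_reads=True)
            outs.append((p / "reads.fastq").read_bytes())
        assert outs[0] == outs[1]

    def test_zero_branches_no_events_tips_equal_root(self):
        rng = np.random.default_rng(3)
        lib = RepeatLibrary([TEFamily("A_00", "Gypsy", random_seq(300, rng), "A")])
        nodes = [
            LineageNode("ROOT", None, 0.0,
                        [Event("establish", {"label": "A", "ancestral_copies": {}})]),
            LineageNode("T1", "ROOT", 0.0, tip=True),
            LineageNode("T2", "ROOT", 0.0, tip=True),
        ]
        sc = Scenario(nodes=nodes, library=lib,
                      clade_map={"T1": "Olyreae", "T2": "Olyreae"},
                      species_params={t: {"coverage": 0.1} for t in ("T1", "T2")},
                      background_length=40_000, block_size=10_000,
                      plastome_length=1000)
        sim = simulate(sc, 1)
        s1 = b"".join(seq_to_str(b.seq).encode() for b in sim.genomes["T1"].blocks)
        s2 = b"".join(seq_to_str(b.seq).encode() for b in sim.genomes["T2"].blocks)
        assert s1 == s2
        assert np.array_equal(sim.plastomes["T1"], sim.plastomes["T2"])

    def test_full_fractionation_without_bursts_erases_donor_mobilome(self):
        lib = _library()
        rng = np.random.default_rng(9)
        h = _genome("H", rng=rng)
        h = te_burst(h, lib, "H_00", 30, False, 2)
        c = _genome("C", rng=rng)
        g = fractionate(hybridize(h, c, maternal="H"), "H", 1.0, 0)
        spec = ReadSamplingSpec.from_coverage(L=100, C=1.0, G=g.total_length, seed=3)
        rs = sample_reads(g, spec, "Sp")
        assert not any(f.startswith("H_") for f in rs.family_ids)


class TestSequencePrimitives:
    def test_round_trip_and_revcomp(self):
        s = "ACGTTGCA"
        arr = str_to_seq(s)
        assert seq_to_str(arr) == s
        assert seq_to_str(revcomp(arr)) == "TGCAACGT"

    def test_bad_characters_rejected(self):
        with pytest.raises(ValueError):
            str_to_seq("ACGN")
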