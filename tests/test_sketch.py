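"""Unit and property tests for k-mer shingling and M3Hash sketching."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bishash.sketch import (
    UNDEFINED,
    MetricMode,
    Sketch,
    SketchConfig,
    base_hash,
    collapse_kmer,
    compare_sketches,
    m3hash_sketch,
    multi_metric_jaccard,
    partition_index,
    shingle,
    sketch_sequence,
)
from conftest import overlapping_kmer_pair, random_kmers

ALL_3MERS = ["".join(p) for p in itertools.product("ACGT", repeat=3)]

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


class TestShingle:
    @pytest.mark.parametrize(
        "seq,k,expected",
        [
            ("ACGTA", 3, {"ACG", "CGT", "GTA"}),
            ("AAAA", 3, {"AAA"}),
            ("ACNGA", 3, set()),  # every window touches the N
            ("AC", 3, set()),  # shorter than k
            ("acgta", 3, {"ACG", "CGT", "GTA"}),  # case-insensitive
        ],
    )
    def test_examples(self, seq, k, expected):
        assert shingle(seq, k) == expected

    @settings(derandomize=True, max_examples=50)
    @given(seq=dna, k=st.integers(1, 6))
    def test_members_are_substrings_of_length_k(self, seq, k):
        kmers = shingle(seq, k)
        for km in kmers:
            assert len(km) == k
            assert km in seq

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            shingle("ACGT", 0)


class TestCollapse:
    @pytest.mark.parametrize(
        "kmer,mode,expected",
        [
            ("ACT", MetricMode.COLLAPSE_CT, "ATT"),
            ("ACG", MetricMode.COLLAPSE_GA, "ACA"),
            ("TTT", MetricMode.COLLAPSE_CT, "TTT"),
            ("ACGT", MetricMode.IDENTITY, "ACGT"),
        ],
    )
    def test_examples(self, kmer, mode, expected):
        assert collapse_kmer(kmer, mode) == expected

    @pytest.mark.parametrize("mode", list(MetricMode))
    def test_idempotent_on_all_3mers(self, mode):
        for km in ALL_3MERS:
            once = collapse_kmer(km, mode)
            assert collapse_kmer(once, mode) == once

    def test_identity_refines_collapses(self):
        # equal raw k-mers trivially have equal collapsed images; the
        # meaningful direction: collapse merges exactly C/T (resp. G/A)
        assert collapse_kmer("C", MetricMode.COLLAPSE_CT) == collapse_kmer(
            "T", MetricMode.COLLAPSE_CT
        )
        assert collapse_kmer("G", MetricMode.COLLAPSE_GA) == collapse_kmer(
            "A", MetricMode.COLLAPSE_GA
        )

    def test_malformed_kmer_rejected(self):
        with pytest.raises(ValueError):
            collapse_kmer("ACN", MetricMode.COLLAPSE_CT)


class TestPartition:
    def test_zero_cell(self):
        assert partition_index("AAGT", 2, MetricMode.COLLAPSE_CT) == 0

    def test_base3_encoding(self):
        # C -> merged digit 2, G -> 1: 2*3 + 1 = 7
        assert partition_index("CGAA", 2, MetricMode.COLLAPSE_CT) == 7

    def test_cell_count_is_3_pow_kappa(self):
        cells = {partition_index("".join(p) + "A", 2, MetricMode.COLLAPSE_CT)
                 for p in itertools.product("ACGT", repeat=2)}
        assert cells == set(range(9))  # kappa=2 -> exactly z=9 reachable cells
        assert SketchConfig(k=16, kappa=2).z == 9

    def test_conversion_cannot_move_cells(self):
        # C->T in the prefix leaves the CT-mode cell unchanged
        for km in ALL_3MERS:
            converted = km.replace("C", "T")
            assert partition_index(km, 2, MetricMode.COLLAPSE_CT) == partition_index(
                converted, 2, MetricMode.COLLAPSE_CT
            )

    def test_kappa_too_large(self):
        with pytest.raises(ValueError):
            partition_index("ACG", 4, MetricMode.COLLAPSE_CT)


class TestBaseHash:
    def test_metric_class_constancy_exhaustive_3mers(self):
        for mode in (MetricMode.COLLAPSE_CT, MetricMode.COLLAPSE_GA):
            for km in ALL_3MERS:
                image = collapse_kmer(km, mode)
                for seed in (0, 1, 987654321):
                    assert base_hash(km, mode, seed) == base_hash(image, mode, seed)

    def test_identity_distinguishes_collapsed_pair(self):
        assert base_hash("ACT", MetricMode.IDENTITY, 42) != base_hash(
            "ATT", MetricMode.IDENTITY, 42
        )

    def test_seed_sensitivity(self):
        diffs = sum(
            base_hash(km, MetricMode.IDENTITY, 1) != base_hash(km, MetricMode.IDENTITY, 2)
            for km in ALL_3MERS
        )
        assert diffs > 0


class TestSketch:
    config = SketchConfig(k=4, kappa=1, metrics=(MetricMode.IDENTITY, MetricMode.COLLAPSE_CT),
                          R=3, master_seed=5)

    def test_empty_set_all_undefined(self):
        sk = m3hash_sketch(set(), self.config, MetricMode.COLLAPSE_CT)
        assert (sk.values == UNDEFINED).all()

    def test_deterministic(self):
        kmers = random_kmers(np.random.default_rng(0), 50, 4)
        a = m3hash_sketch(kmers, self.config, MetricMode.COLLAPSE_CT)
        b = m3hash_sketch(kmers, self.config, MetricMode.COLLAPSE_CT)
        assert np.array_equal(a.values, b.values)

    def test_undefined_pattern_uniform_across_metrics_and_reps(self):
        kmers = random_kmers(np.random.default_rng(1), 10, 4)
        sk = m3hash_sketch(kmers, self.config, MetricMode.COLLAPSE_CT)
        undef = sk.values == UNDEFINED
        per_cell = undef[:, 0, 0]
        assert (undef == per_cell[:, None, None]).all()

    def test_ct_image_shares_ct_metric_entries(self):
        cfg = SketchConfig(k=3, kappa=1,
                           metrics=(MetricMode.IDENTITY, MetricMode.COLLAPSE_CT),
                           R=2, master_seed=9)
        a = sketch_sequence("ACGACGAC", cfg, MetricMode.COLLAPSE_CT)
        b = sketch_sequence("ATGATGAT", cfg, MetricMode.COLLAPSE_CT)
        defined = (a.values[:, 1, :] != UNDEFINED) & (b.values[:, 1, :] != UNDEFINED)
        assert defined.any()
        assert np.array_equal(a.values[:, 1, :][defined], b.values[:, 1, :][defined])

    def test_sequence_and_set_paths_agree(self):
        seq = "ACGTACGGTTACG"
        via_set = m3hash_sketch(shingle(seq, 4), self.config, MetricMode.COLLAPSE_CT)
        via_seq = sketch_sequence(seq, self.config, MetricMode.COLLAPSE_CT)
        assert np.array_equal(via_set.values, via_seq.values)

    def test_serialization_round_trip(self):
        kmers = random_kmers(np.random.default_rng(3), 30, 4)
        sk = m3hash_sketch(kmers, self.config, MetricMode.COLLAPSE_CT)
        back = Sketch.from_bytes(sk.to_bytes())
        assert np.array_equal(back.values, sk.values)
        assert back.config_fingerprint == sk.config_fingerprint


class TestCompare:
    config = SketchConfig(k=6, kappa=2, metrics=(MetricMode.IDENTITY, MetricMode.COLLAPSE_CT),
                          R=4, master_seed=11)

    def test_self_comparison_is_one(self):
        sk = sketch_sequence("ACGTACGTTGCAACGGT", self.config, MetricMode.COLLAPSE_CT)
        stat = compare_sketches(sk, sk)
        assert stat.xi_s == 1.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a, b = overlapping_kmer_pair(rng, k=6, pool=60, draw=30)
            sa = m3hash_sketch(a, self.config, MetricMode.COLLAPSE_CT)
            sb = m3hash_sketch(b, self.config, MetricMode.COLLAPSE_CT)
            ab = compare_sketches(sa, sb)
            ba = compare_sketches(sb, sa)
            assert ab.xi_s == ba.xi_s
            assert ab.vote_count == ba.vote_count
            assert 0.0 <= ab.xi_s <= 1.0
            assert ab.vote_count <= self.config.z * self.config.delta * self.config.R

    def test_fully_dissimilar_sets(self):
        # sets disagreeing in their final base (G vs A, which CT collapse
        # leaves alone) share no k-mer under either metric, while random
        # prefixes populate every partition cell in both sketches
        rng = np.random.default_rng(5)
        prefixes = {"".join("ACGT"[c] for c in rng.integers(0, 4, 5))
                    for _ in range(300)}
        a_set = {p + "G" for p in prefixes}
        b_set = {p + "A" for p in prefixes}
        sa = m3hash_sketch(a_set, self.config, MetricMode.COLLAPSE_CT)
        sb = m3hash_sketch(b_set, self.config, MetricMode.COLLAPSE_CT)
        assert sa.defined_cells.all() and sb.defined_cells.all()
        assert compare_sketches(sa, sb).xi_s == 0.0

    def test_both_empty_cells_count_as_match(self):
        cfg = SketchConfig(k=4, kappa=2, metrics=(MetricMode.IDENTITY,), R=2,
                           master_seed=3)
        sa = m3hash_sketch({"GGGG"}, cfg, MetricMode.COLLAPSE_CT)
        sb = m3hash_sketch({"GGGG"}, cfg, MetricMode.COLLAPSE_CT)
        stat = compare_sketches(sa, sb)
        assert stat.xi_s == 1.0  # one matching cell, the rest empty-empty

    def test_one_empty_cell_is_a_non_match(self):
        cfg = SketchConfig(k=4, kappa=2, metrics=(MetricMode.IDENTITY,), R=2,
                           master_seed=3)
        sa = m3hash_sketch({"GGGG"}, cfg, MetricMode.COLLAPSE_CT)
        sb = m3hash_sketch({"GGGG", "AAAA"}, cfg, MetricMode.COLLAPSE_CT)
        stat = compare_sketches(sa, sb)
        assert stat.xi_per_cell[0] == 0.0  # AAAA's cell: defined in b only

    def test_config_mismatch_rejected(self):
        other = SketchConfig(k=6, kappa=2, metrics=(MetricMode.IDENTITY,), R=4,
                             master_seed=11)
        sa = sketch_sequence("ACGTACGTAC", self.config, MetricMode.COLLAPSE_CT)
        sb = sketch_sequence("ACGTACGTAC", other, MetricMode.COLLAPSE_CT)
        with pytest.raises(ValueError):
            compare_sketches(sa, sb)

    def test_adding_a_metric_never_lowers_xi_pointwise(self):
        # repetition seeds depend only on (j, r), so the identity-metric
        # coordinates coincide between the two configs and the indicator
        # with the extra metric dominates rep by rep
        rng = np.random.default_rng(6)
        single = SketchConfig(k=6, kappa=1, metrics=(MetricMode.IDENTITY,), R=50,
                              master_seed=13)
        double = SketchConfig(k=6, kappa=1,
                              metrics=(MetricMode.IDENTITY, MetricMode.COLLAPSE_CT),
                              R=50, master_seed=13)
        for _ in range(20):
            a, b = overlapping_kmer_pair(rng, k=6, pool=80, draw=40)
            x1 = compare_sketches(
                m3hash_sketch(a, single, MetricMode.COLLAPSE_CT),
                m3hash_sketch(b, single, MetricMode.COLLAPSE_CT),
            ).xi_s
            x2 = compare_sketches(
                m3hash_sketch(a, double, MetricMode.COLLAPSE_CT),
                m3hash_sketch(b, double, MetricMode.COLLAPSE_CT),
            ).xi_s
            assert x2 >= x1


class TestMultiMetricJaccard:
    def test_identical_sets(self):
        cfg = SketchConfig(k=5, kappa=1)
        a = random_kmers(np.random.default_rng(7), 40, 5)
        rep = multi_metric_jaccard(a, a, cfg, MetricMode.COLLAPSE_CT)
        assert rep.classic == 1.0
        assert rep.multi_metric == 1.0

    def test_disjoint_under_all_metrics(self):
        cfg = SketchConfig(k=4, kappa=1)
        rep = multi_metric_jaccard({"GGAA"}, {"CCTT"}, cfg, MetricMode.COLLAPSE_CT)
        assert rep.multi_metric == 0.0

    def test_reduces_to_classic_jaccard(self):
        cfg = SketchConfig(k=5, kappa=0, metrics=(MetricMode.IDENTITY,))
        rng = np.random.default_rng(8)
        for _ in range(100):
            a, b = overlapping_kmer_pair(rng, k=5, pool=50, draw=25)
            rep = multi_metric_jaccard(a, b, cfg, MetricMode.COLLAPSE_CT)
            expected = len(a & b) / len(a | b)
            assert rep.multi_metric == pytest.approx(expected, abs=0)
            assert rep.classic == pytest.approx(expected, abs=0)

    def test_empty_sets_convention(self):
        cfg = SketchConfig(k=4, kappa=1)
        rep = multi_metric_jaccard(set(), set(), cfg, MetricMode.COLLAPSE_CT)
        assert rep.classic == 0.0 and rep.multi_metric == 0.0
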