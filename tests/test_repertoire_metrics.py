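import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clonotrace.repertoire_metrics import (
    clonality,
    common_depth,
    diversity,
    downsample,
    overlap,
    repertoire_fraction,
    shannon_entropy,
)

from _oracles import hypergeom_mean, hypergeom_sd, shannon_entropy_oracle
from conftest import make_repertoire

counts_strategy = st.dictionaries(
    st.sampled_from([f"CASS{a}" for a in "ACDEFGHIKLMNPQRSTVWY"]),
    st.integers(min_value=1, max_value=200),
    min_size=1,
    max_size=15,
)


class TestDownsample:
    def test_identity_at_full_depth(self, tiny_rep):
        out = downsample(tiny_rep, tiny_rep.depth, seed=0)
        assert {k: c.count for k, c in out.clones.items()} == {"CASSA": 3, "CASSN": 1}

    def test_exact_depth_and_never_inflates(self):
        rep = make_repertoire({"CASSA": 100, "CASSN": 37, "CASSC": 5})
        for seed in range(20):
            out = downsample(rep, 50, seed=seed)
            assert out.depth == 50
            assert all(out.count(k) <= rep.count(k) for k in rep.clones)

    def test_two_singleton_draw_is_fair(self):
        # one read from {A:1, B:1}: each outcome has probability 1/2
        rep = make_repertoire({"CASSA": 1, "CASSN": 1})
        n = 10_000
        hits = sum(downsample(rep, 1, seed=s).count("CASSA") for s in range(n))
        sd = math.sqrt(n * 0.25)
        assert abs(hits - n / 2) < 3 * sd

    def test_mean_matches_hypergeometric_expectation(self):
        rep = make_repertoire({"CASSA": 9000, "CASSN": 1000})
        n_rep, draw = 1000, 1000
        counts = np.array(
            [downsample(rep, draw, seed=s).count("CASSA") for s in range(n_rep)]
        )
        mean = hypergeom_mean(10_000, 9000, draw)  # 900
        sem = hypergeom_sd(10_000, 9000, draw) / math.sqrt(n_rep)
        assert abs(counts.mean() - mean) < 3 * sem

    def test_deterministic_given_seed(self):
        rep = make_repertoire({"CASSA": 50, "CASSN": 50, "CASSC": 20})
        a = downsample(rep, 30, seed=42)
        b = downsample(rep, 30, seed=42)
        assert {k: c.count for k, c in a.clones.items()} == {
            k: c.count for k, c in b.clones.items()
        }

    def test_invalid_targets_rejected(self, tiny_rep):
        with pytest.raises(ValueError):
            downsample(tiny_rep, 0, seed=0)
        with pytest.raises(ValueError):
            downsample(tiny_rep, tiny_rep.depth + 1, seed=0)


class TestCommonDepth:
    def test_minimum_of_set(self):
        reps = [make_repertoire({"CASSA": d}) for d in (5000, 12_000, 7000)]
        assert common_depth(reps) == 5000

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            common_depth([])


class TestClonalityAndDiversity:
    def test_even_repertoire_has_zero_clonality(self, even_rep):
        assert clonality(even_rep) == pytest.approx(0.0, abs=1e-12)

    def test_monoclonal_repertoire_has_clonality_one(self):
        rep = make_repertoire({"CASSA": 50})
        assert clonality(rep) == 1.0
        report = diversity(rep)
        assert report.richness == 1
        assert report.shannon_entropy == pytest.approx(0.0, abs=1e-12)

    def test_three_to_one_mixture_frozen_value(self, tiny_rep):
        # H = -(0.75 ln 0.75 + 0.25 ln 0.25) = 0.562335 nats
        h = shannon_entropy(tiny_rep)
        assert h == pytest.approx(0.5623351446188083, abs=1e-12)
        assert h == pytest.approx(shannon_entropy_oracle([3, 1]), abs=1e-12)
        assert clonality(tiny_rep) == pytest.approx(1 - h / math.log(2), abs=1e-12)

    def test_diversity_reports_depth_used(self, tiny_rep):
        assert diversity(tiny_rep).depth_used == 4

    def test_empty_repertoire_rejected(self):
        rep = make_repertoire({})
        for fn in (clonality, diversity, shannon_entropy):
            with pytest.raises(ValueError):
                fn(rep)

    @given(counts_strategy, st.integers(min_value=2, max_value=9))
    def test_clonality_invariant_to_relabeling_and_scaling(self, counts, scale):
        rep = make_repertoire(counts)
        relabeled = make_repertoire(
            {f"CASR{k[4:]}": v for k, v in counts.items()}
        )
        scaled = make_repertoire({k: v * scale for k, v in counts.items()})
        c = clonality(rep)
        assert 0.0 <= c <= 1.0
        assert clonality(relabeled) == pytest.approx(c, abs=1e-12)
        assert clonality(scaled) == pytest.approx(c, abs=1e-12)

    @given(counts_strategy)
    def test_entropy_bounded_by_log_richness(self, counts):
        rep = make_repertoire(counts)
        assert shannon_entropy(rep) <= math.log(len(counts)) + 1e-12


class TestOverlapAndFraction:
    def test_set_partition(self):
        a = make_repertoire({"CASSA": 1, "CASSN": 2, "CASSC": 3})
        b = make_repertoire({"CASSN": 1, "CASSC": 1, "CASSD": 1})
        res = overlap(a, b)
        assert res.shared == {"CASSN", "CASSC"}
        assert res.unique_a == {"CASSA"}
        assert res.unique_b == {"CASSD"}

    def test_identical_and_disjoint(self):
        a = make_repertoire({"CASSA": 1, "CASSN": 2})
        assert overlap(a, a).n_shared == 2
        assert overlap(a, a).n_unique_a == 0
        d = make_repertoire({"CASSC": 1})
        assert overlap(a, d).n_shared == 0

    def test_fraction_direct_formula(self):
        rep = make_repertoire({"CASSA": 250, "CASSN": 750})
        assert repertoire_fraction({"CASSA"}, rep) == 0.25
        assert repertoire_fraction(set(rep.clones), rep) == 1.0
        assert repertoire_fraction({"CASSQ"}, rep) == 0.0

    @given(counts_strategy, st.randoms(use_true_random=False))
    def test_fraction_over_partition_sums_to_one(self, counts, rnd):
        rep = make_repertoire(counts)
        keys = list(counts)
        rnd.shuffle(keys)
        cut = rnd.randint(0, len(keys))
        part_a, part_b = set(keys[:cut]), set(keys[cut:])
        total = repertoire_fraction(part_a, rep) + repertoire_fraction(part_b, rep)
        assert total == pytest.approx(1.0, abs=1e-12)
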