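import math

import numpy as np
import pytest

from clonotrace.enrichment import EnrichmentResult, Tier
from clonotrace.repertoire_io import Compartment
from clonotrace.tracking import (
    persisting_abundance,
    post_unique_in_blood,
    timepoint_sort_key,
    track_clones,
)

from _oracles import signed_rank_exact_oracle
from conftest import make_repertoire


def pbmc(counts, timepoint):
    return make_repertoire(counts, timepoint=timepoint)


def tumor(counts, timepoint):
    return make_repertoire(counts, timepoint=timepoint, compartment=Compartment.TUMOR)


class TestTrackClones:
    def test_absent_clone_traces_zeros(self):
        samples = [pbmc({"CASSA": 10}, "baseline"), tumor({"CASSA": 10}, "baseline")]
        (tc,) = track_clones({"CASSQ"}, samples, seed=0)
        assert all(e.count == 0 and e.fraction == 0.0 for e in tc.trace)
        assert tc.detected_in_tumor is False

    def test_fraction_of_depth(self):
        samples = [pbmc({"CASSA": 120, "CASSN": 880}, "week7")]
        (tc,) = track_clones({"CASSA"}, samples, seed=0)
        assert tc.trace[0].fraction == pytest.approx(0.12)

    def test_detected_in_tumor_from_single_read(self):
        samples = [
            pbmc({"CASSN": 100}, "week7"),
            tumor({"CASSA": 1, "CASSN": 99}, "week15"),
        ]
        (tc,) = track_clones({"CASSA"}, samples, seed=0)
        assert tc.detected_in_tumor is True

    def test_order_invariant_to_input_order(self):
        samples = [
            pbmc({"CASSA": 50, "CASSN": 50}, "week18"),
            pbmc({"CASSA": 30, "CASSN": 70}, "baseline"),
            pbmc({"CASSA": 10, "CASSN": 90}, "week7"),
        ]
        fwd = track_clones({"CASSA"}, samples, seed=3)
        rev = track_clones({"CASSA"}, samples[::-1], seed=3)
        assert [e.meta.timepoint for e in fwd[0].trace] == ["baseline", "week7", "week18"]
        assert [(e.count, e.fraction) for e in fwd[0].trace] == [
            (e.count, e.fraction) for e in rev[0].trace
        ]

    def test_ranked_by_nominating_log_fc(self):
        samples = [pbmc({"CASSA": 5, "CASSN": 5, "CASSC": 90}, "week7")]
        enr = [
            EnrichmentResult("CASSA", 0, 40, 6.0, 1e-4, 1e-3, Tier.NOMINAL),
            EnrichmentResult("CASSN", 0, 90, 7.5, 1e-5, 1e-4, Tier.NOMINAL),
        ]
        tracked = track_clones({"CASSA", "CASSN"}, samples, seed=0, enrichment=enr)
        assert [(t.cdr3_aa, t.rank) for t in tracked] == [("CASSN", 1), ("CASSA", 2)]

    def test_multiple_patients_rejected(self):
        samples = [
            make_repertoire({"CASSA": 1}, patient="N01"),
            make_repertoire({"CASSA": 1}, patient="N02"),
        ]
        with pytest.raises(ValueError, match="multiple patients"):
            track_clones({"CASSA"}, samples, seed=0)

    def test_detection_matches_binomial_probability(self):
        # clone at frequency f sampled multinomially at depth N is detected
        # with probability 1 - (1 - f)^N
        f, depth, n_rep = 1e-4, 30_000, 300
        rng = np.random.default_rng(11)
        detected = 0
        for _ in range(n_rep):
            spike, rest = rng.multinomial(depth, [f, 1 - f])
            counts = {"CASSN": int(rest)}
            if spike > 0:
                counts["CASSA"] = int(spike)
            (tc,) = track_clones({"CASSA"}, [tumor(counts, "week15")], seed=0)
            detected += tc.detected_in_tumor
        p = 1 - (1 - f) ** depth
        sd = math.sqrt(n_rep * p * (1 - p))
        assert abs(detected - n_rep * p) < 3 * sd


class TestTimepointOrdering:
    def test_baseline_first_then_weeks_numerically(self):
        labels = ["week18", "baseline", "week7", "week2"]
        assert sorted(labels, key=timepoint_sort_key) == [
            "baseline", "week2", "week7", "week18",
        ]


class TestPersistingAbundance:
    def test_exact_signed_rank_against_permutation_oracle(self):
        base = tumor({"CASSA": 10, "CASSN": 5, "CASSC": 8, "CASSD": 77}, "baseline")
        post = tumor({"CASSA": 20, "CASSN": 10, "CASSC": 16, "CASSE": 54}, "week15")
        res = persisting_abundance(base, post, seed=0)
        assert res.tested
        assert sorted(res.table["cdr3_aa"]) == ["CASSA", "CASSC", "CASSN"]
        oracle_p = signed_rank_exact_oracle([10, 5, 8])
        assert res.p_value == pytest.approx(oracle_p, abs=1e-12)

    def test_identical_biopsies_degenerate(self):
        rep = {"CASSA": 10, "CASSN": 20}
        res = persisting_abundance(tumor(rep, "baseline"), tumor(rep, "week15"), seed=0)
        assert not res.tested
        assert res.p_value == 1.0

    def test_disjoint_biopsies_skipped(self):
        res = persisting_abundance(
            tumor({"CASSA": 10}, "baseline"), tumor({"CASSN": 10}, "week15"), seed=0
        )
        assert not res.tested
        assert len(res.table) == 0
        assert res.p_value is None


class TestPostUniqueInBlood:
    def test_direct_formula(self):
        base = tumor({"CASSQ": 10}, "baseline")
        post = tumor({"CASSA": 5, "CASSN": 5}, "week15")
        blood = [pbmc({"CASSA": 10, "CASSC": 90}, "week7")]
        df = post_unique_in_blood(base, post, blood, seed=0)
        assert df.loc[0, "n_detected"] == 1
        assert df.loc[0, "repertoire_fraction"] == pytest.approx(0.10)

    def test_subset_post_tumor_gives_zeros(self):
        base = tumor({"CASSA": 10, "CASSN": 10}, "baseline")
        post = tumor({"CASSA": 20}, "week15")
        blood = [pbmc({"CASSA": 100}, "week7")]
        df = post_unique_in_blood(base, post, blood, seed=0)
        assert df["n_detected"].eq(0).all()
        assert df["repertoire_fraction"].eq(0.0).all()

    def test_summed_fraction_never_exceeds_one(self):
        base = tumor({"CASSQ": 1}, "baseline")
        post = tumor({"CASSA": 1, "CASSN": 1, "CASSC": 1}, "week15")
        blood = [
            pbmc({"CASSA": 30, "CASSN": 30, "CASSC": 40}, "week7"),
            pbmc({"CASSA": 100}, "week18"),
        ]
        df = post_unique_in_blood(base, post, blood, seed=0)
        assert (df["repertoire_fraction"] <= 1.0 + 1e-12).all()

    def test_empty_post_tumor_rejected(self):
        with pytest.raises(ValueError):
            post_unique_in_blood(
                tumor({"CASSA": 1}, "baseline"), tumor({}, "week15"), [], seed=0
            )
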