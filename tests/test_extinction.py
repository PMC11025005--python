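import math

import numpy as np
import pytest
from scipy import stats

from paleoselect.data_model import DataError, StageSequence
from paleoselect.extinction import (
    IntervalCounts,
    binomial_ci,
    gap_filler_extinction,
    mean_clade_extinction,
    per_capita_extinction,
    proportional_extinction,
    sampling_completeness,
    stratified_comparison,
    tabulate_interval_counts,
    three_timer_extinction,
)
from conftest import make_annotated, presence_to_summaries
from oracles import brute_force_interval_counts


def counts(**kw):
    base = dict(interval="x", two_timer_prev=0, three_timer=0, part_timer=0,
                gap_filler=0, n_bt=0, n_bL=0, sampled_in_bin=0)
    base.update(kw)
    return IntervalCounts(**base)


class TestBinomialCI:
    def test_zero_successes_closed_form(self):
        low, high = binomial_ci(0, 10)
        assert low == 0.0
        assert high == pytest.approx(1 - 0.025 ** (1 / 10), abs=1e-12)

    def test_all_successes_reaches_one(self):
        low, high = binomial_ci(10, 10)
        assert high == 1.0 and low == pytest.approx(0.025 ** (1 / 10), abs=1e-12)

    def test_matches_direct_beta_quantiles(self):
        # Clopper-Pearson bounds are Beta quantiles evaluated independently
        k, n = 7, 20
        low, high = binomial_ci(k, n)
        assert low == pytest.approx(stats.beta.ppf(0.025, k, n - k + 1), abs=1e-12)
        assert high == pytest.approx(stats.beta.ppf(0.975, k + 1, n - k), abs=1e-12)

    def test_wilson_brackets_the_point_estimate(self):
        low, high = binomial_ci(7, 20, method="wilson")
        assert 0 <= low <= 7 / 20 <= high <= 1

    def test_invalid_inputs(self):
        with pytest.raises(DataError):
            binomial_ci(0, 0)
        with pytest.raises(DataError):
            binomial_ci(5, 4)
        with pytest.raises(DataError):
            binomial_ci(1, 4, level=1.5)
        with pytest.raises(DataError):
            binomial_ci(1, 4, method="bogus")


class TestIntervalCounts:
    def test_three_timer_taxon(self, five_stages):
        presence = np.zeros((1, 5), dtype=bool)
        presence[0, 1:4] = True  # present in i-1, i, i+1 for i=2
        c = tabulate_interval_counts(presence_to_summaries(presence, five_stages),
                                     five_stages, 2)
        assert (c.two_timer_prev, c.three_timer, c.part_timer) == (1, 1, 0)

    def test_part_timer_taxon(self, five_stages):
        presence = np.zeros((1, 5), dtype=bool)
        presence[0, [1, 3]] = True  # i-1 and i+1, not i
        c = tabulate_interval_counts(presence_to_summaries(presence, five_stages),
                                     five_stages, 2)
        assert (c.part_timer, c.three_timer, c.two_timer_prev) == (1, 0, 0)
        # its range crosses both boundaries of i
        assert (c.n_bt, c.n_bL) == (1, 0)

    def test_gap_filler_taxon(self, five_stages):
        presence = np.zeros((1, 5), dtype=bool)
        presence[0, [1, 4]] = True  # i-1 and i+2, not i+1
        c = tabulate_interval_counts(presence_to_summaries(presence, five_stages),
                                     five_stages, 2)
        assert c.gap_filler == 1

    def test_window_errors_name_missing_interval(self, five_stages):
        presence = np.ones((2, 5), dtype=bool)
        summ = presence_to_summaries(presence, five_stages)
        with pytest.raises(DataError, match="s1"):
            tabulate_interval_counts(summ, five_stages, 0)
        with pytest.raises(DataError, match="s5"):
            tabulate_interval_counts(summ, five_stages, 4)
        # last interior interval: gap-filler needs i+2, reported as None
        assert tabulate_interval_counts(summ, five_stages, 3).gap_filler is None

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_seeded_matrix_matches_brute_force(self, five_stages, seed):
        rng = np.random.default_rng(seed)
        presence = rng.random((20, 5)) < 0.5
        summ = presence_to_summaries(presence, five_stages)
        for i in (1, 2, 3):
            got = tabulate_interval_counts(summ, five_stages, i)
            want = brute_force_interval_counts(presence, i)
            assert got.two_timer_prev == want["two_timer"]
            assert got.three_timer == want["three_timer"]
            assert got.part_timer == want["part_timer"]
            if got.gap_filler is not None:
                assert got.gap_filler == want["gap_filler"]
            assert got.n_bt == want["n_bt"]
            assert got.n_bL == want["n_bL"]
            assert got.sampled_in_bin == want["sampled"]

    def test_invariant_under_relabeling(self, five_stages):
        rng = np.random.default_rng(5)
        presence = rng.random((15, 5)) < 0.6
        summ = presence_to_summaries(presence, five_stages)
        shuffled = presence[rng.permutation(15)]
        summ2 = presence_to_summaries(shuffled, five_stages)
        assert tabulate_interval_counts(summ, five_stages, 2) == (
            tabulate_interval_counts(summ2, five_stages, 2)
        )


class TestRateEstimators:
    def test_per_capita_no_extinction(self):
        assert per_capita_extinction(counts(n_bt=10, n_bL=0)) == 0.0

    def test_per_capita_half_extinct_is_ln2(self):
        assert per_capita_extinction(counts(n_bt=7, n_bL=7)) == pytest.approx(math.log(2))

    def test_per_capita_undefined(self):
        assert per_capita_extinction(counts(n_bt=0, n_bL=5)) is None

    def test_sampling_completeness_cases(self):
        assert sampling_completeness(
            [counts(two_timer_prev=5, three_timer=5, part_timer=0)]
        ) == 1.0
        assert sampling_completeness(
            [counts(two_timer_prev=3, three_timer=3, part_timer=1),
             counts(two_timer_prev=2, three_timer=2, part_timer=4)]
        ) == 0.5
        with pytest.raises(DataError):
            sampling_completeness([counts(part_timer=3)])

    def test_three_timer_cases(self):
        v, fl = three_timer_extinction(counts(two_timer_prev=6, three_timer=6), 1.0)
        assert v == 0.0 and not fl
        v, _ = three_timer_extinction(counts(two_timer_prev=12, three_timer=6), 1.0)
        assert v == pytest.approx(math.log(2))
        # completeness below 1 can push the raw value negative -> floored + flag
        v, fl = three_timer_extinction(counts(two_timer_prev=6, three_timer=6), 0.5)
        assert v == 0.0 and fl

    def test_gap_filler_cases(self):
        c = counts(two_timer_prev=12, three_timer=6, part_timer=0, gap_filler=0)
        v, _ = gap_filler_extinction(c)
        assert v == pytest.approx(math.log(2))  # reduces to ln(2t/3t)
        v, fl = gap_filler_extinction(
            counts(two_timer_prev=6, three_timer=6, part_timer=0, gap_filler=0)
        )
        assert v == 0.0 and not fl
        with pytest.raises(DataError, match="i\\+2"):
            gap_filler_extinction(counts(two_timer_prev=3, three_timer=2, gap_filler=None))


class TestProportionalExtinction:
    def test_all_extinct(self):
        summ = make_annotated({"coral": [True] * 10})
        (est,) = proportional_extinction(summ)
        assert est.value == 1.0 and est.n_total == 10 and est.ci_high == 1.0

    def test_none_extinct(self):
        summ = make_annotated({"fish": [False] * 4})
        (est,) = proportional_extinction(summ)
        assert est.value == 0.0 and est.ci_low == 0.0

    def test_undefined_excluded_and_empty_group_omitted(self):
        summ = make_annotated({"coral": [True, None], "fish": [None]})
        ests = proportional_extinction(summ)
        assert [e.group for e in ests] == ["coral"]
        assert ests[0].n_total == 1

    def test_group_by_protein(self):
        summ = make_annotated({
            "coral": [True, True], "sponge": [True, False],  # diffusion: 3/4
            "fish": [False, False],  # hemoglobin: 0/2
        })
        by_group = {e.group: e for e in proportional_extinction(summ, "protein_group")}
        assert by_group["diffusion"].value == pytest.approx(0.75)
        assert by_group["hemoglobin"].value == 0.0

    def test_adding_extinct_genus_never_decreases(self):
        summ = make_annotated({"coral": [True, False, False]})
        (before,) = proportional_extinction(summ)
        summ2 = summ + make_annotated({"coral": [True]})
        (after,) = proportional_extinction(summ2)
        assert after.value >= before.value

    def test_simulation_estimate_within_own_ci(self):
        rng = np.random.default_rng(11)
        flags = (rng.random(200) < 0.9).tolist()
        summ = make_annotated({"brachiopod": flags})
        (est,) = proportional_extinction(summ)
        assert est.ci_low <= 0.9 <= est.ci_high

    def test_unweighted_clade_mean(self):
        summ = make_annotated({
            "foraminifera": [True] * 9 + [False],  # 0.9
            "brachiopod": [True, False],  # 0.5
        })
        got = mean_clade_extinction(summ, ["foraminifera", "brachiopod"])
        assert got == pytest.approx((0.9 + 0.5) / 2)


class TestStratifiedComparison:
    def fixture_summaries(self):
        # 12 genera; hand-tallied pooled proportions per bin
        return make_annotated({
            "ostracod": [True, False],  # Hc open: ostracod+gastropod+protobranch
            "gastropod": [True, True, False],
            "bivalve_protobranch": [True],  # -> Hc open pooled 4/6
            "cephalopod": [True, False],  # Hc closed 1/2
            "brachiopod": [True, True, False],  # open Hr 2/3
            "fish": [False],  # closed, not in the open design
        })

    def test_hemocyanin_open_vs_closed(self):
        ests = {e.group: e for e in stratified_comparison(
            self.fixture_summaries(), "hemocyanin_by_circulatory"
        )}
        assert ests["open"].n_extinct == 4 and ests["open"].n_total == 6
        assert ests["closed"].value == pytest.approx(0.5)

    def test_open_circulatory_by_protein(self):
        ests = {e.group: e for e in stratified_comparison(
            self.fixture_summaries(), "open_circulatory_by_protein"
        )}
        assert ests["hemerythrin"].value == pytest.approx(2 / 3)
        assert ests["hemocyanin"].n_total == 6
        assert "hemoglobin" not in ests  # no open-circulatory Hb genera here

    def test_empty_stratum_omitted(self):
        summ = make_annotated({"coral": [True, False]})  # no hemocyanin at all
        assert stratified_comparison(summ, "hemocyanin_by_circulatory") == []

    def test_unknown_design_rejected(self):
        with pytest.raises(DataError):
            stratified_comparison(self.fixture_summaries(), "bogus")
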