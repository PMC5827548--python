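import numpy as np
import pandas as pd
import pytest

from conftest import make_trials
from pulsedetect.binning import (
    BinnedRates,
    bin_index,
    detection_rates,
    frame_to_rates,
    rates_to_frame,
    standardize,
    timecourse_bins,
)


class TestBinIndex:
    @pytest.mark.parametrize(
        "soa,expected", [(0.0, 0), (9.999, 0), (10.0, 1), (50.0, 5), (99.9, 9)]
    )
    def test_half_open_edges(self, soa, expected):
        assert bin_index(soa) == expected

    def test_ten_bins_for_default_cycle(self):
        idx = bin_index(np.arange(0, 100, 0.5))
        assert set(idx) == set(range(10))

    def test_width_must_divide_period(self):
        with pytest.raises(ValueError, match="divide"):
            bin_index(5.0, width=15.0, period=100.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bin_index(100.0)
        with pytest.raises(ValueError):
            bin_index(-0.1)


class TestDetectionRates:
    def test_hand_counted_toy_table(self):
        """3 catch + 1 no-response excluded; 8 scored trials hand-counted."""
        trials = make_trials(
            bins=[2, 2, 5, 5, 5, 7, 7, 7],
            hits=[1, 0, 1, 1, 0, 1, 1, 1],
            extra_catch=3, n_no_response=1,
        )
        (br,) = detection_rates(trials)
        assert br.rates[2] == pytest.approx(0.5)
        assert br.rates[5] == pytest.approx(2 / 3)
        assert br.rates[7] == pytest.approx(1.0)
        empty = [b for b in range(10) if b not in (2, 5, 7)]
        assert np.isnan(br.rates[empty]).all()
        assert br.counts.sum() == 8

    def test_all_hits_give_unit_rates(self):
        trials = make_trials(bins=[0, 3, 9], hits=[1, 1, 1])
        (br,) = detection_rates(trials)
        assert np.nansum(br.rates) == 3.0

    def test_exclusion_contract(self):
        """Converting catch to target-present trials grows denominators."""
        base = make_trials(bins=[2, 2], hits=[1, 0], extra_catch=2)
        (br,) = detection_rates(base)
        flipped = base.copy()
        flipped["catch"] = False
        flipped.loc[flipped["response"] == "correct_rejection", "response"] = "miss"
        (br2,) = detection_rates(flipped)
        assert br2.counts.sum() == br.counts.sum() + 2

    def test_counts_conserve_included_trials(self, small_cohort):
        binned = detection_rates(small_cohort)
        included = small_cohort[
            ~small_cohort["catch"]
            & small_cohort["response"].isin(["hit", "miss"])
        ]
        assert sum(br.counts.sum() for br in binned) == len(included)

    def test_unknown_condition_rejected(self):
        trials = make_trials(bins=[1], hits=[1], condition="drug")
        with pytest.raises(ValueError, match="condition"):
            detection_rates(trials)


class TestStandardize:
    def _mk(self, rates):
        rates = np.asarray(rates, float)
        return BinnedRates("p", "sham", rates,
                           np.where(np.isnan(rates), 0, 10).astype(int))

    def test_hand_computed_zscores(self):
        out = standardize(self._mk([0.2, 0.4, 0.6]))
        np.testing.assert_allclose(out.standardized, [-1.0, 0.0, 1.0], atol=1e-12)

    def test_mean_zero_unit_sd(self):
        out = standardize(self._mk([0.4, 0.6, 0.5, 0.45, 0.62]))
        assert out.standardized.mean() == pytest.approx(0, abs=1e-12)
        assert out.standardized.std(ddof=1) == pytest.approx(1)

    def test_location_invariance(self):
        a = standardize(self._mk([0.2, 0.4, 0.6]))
        b = standardize(self._mk([0.3, 0.5, 0.7]))
        np.testing.assert_allclose(a.standardized, b.standardized, atol=1e-12)

    def test_idempotent_on_standardized_vector(self):
        once = standardize(self._mk([0.2, 0.5, 0.6, 0.35]))
        again = standardize(
            BinnedRates("p", "sham",
                        (once.standardized - once.standardized.min())
                        / np.ptp(once.standardized),  # rescale into [0,1]
                        once.counts)
        )
        # z-scoring is invariant to any affine rescaling
        np.testing.assert_allclose(again.standardized, once.standardized,
                                   atol=1e-12)

    def test_missing_bins_stay_missing(self):
        out = standardize(self._mk([0.2, np.nan, 0.6]))
        assert np.isnan(out.standardized[1])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero variance|constant"):
            standardize(self._mk([0.5, 0.5, 0.5]))

    def test_center_mode(self):
        out = standardize(self._mk([0.2, 0.4, 0.6]), mode="center")
        np.testing.assert_allclose(out.standardized, [-0.2, 0.0, 0.2], atol=1e-12)


class TestTimecourse:
    def test_twelve_bins_for_default_session(self, small_cohort):
        tc = timecourse_bins(small_cohort, bin_size=32)
        assert set(tc["tbin"]) == set(range(12))
        # 384 trials / 32 = 12 bins for every participant x condition
        assert (tc.groupby(["participant_id", "condition"]).size() == 12).all()

    def test_block_boundaries_fall_at_bins_4_and_8(self, default_plan):
        """128 = 4 x 32: block ends align with time bins 4 and 8 (1-based)."""
        assert default_plan.trials_per_block % 32 == 0
        last_of_block0 = default_plan.trials_per_block - 1
        assert last_of_block0 // 32 == 3          # 0-based bin 3 = 4th bin
        first_of_block1 = default_plan.trials_per_block
        assert first_of_block1 // 32 == 4

    def test_all_hits(self):
        trials = make_trials(bins=[1] * 8, hits=[1] * 8)
        tc = timecourse_bins(trials, bin_size=4)
        assert (tc["rate"] == 1.0).all()

    def test_exclusions_keep_positions(self):
        """Catch trials consume positions but not denominators."""
        trials = make_trials(bins=[1, 1, 1], hits=[1, 0, 1], extra_catch=1)
        tc = timecourse_bins(trials, bin_size=4)
        assert len(tc) == 1
        assert tc["count"].iloc[0] == 3
        assert tc["rate"].iloc[0] == pytest.approx(2 / 3)

    def test_indivisible_count_rejected(self):
        trials = make_trials(bins=[1, 1, 1], hits=[1, 0, 1])
        with pytest.raises(ValueError, match="divisible"):
            timecourse_bins(trials, bin_size=2)


def test_rates_frame_roundtrip(small_cohort):
    binned = [standardize(b) for b in detection_rates(small_cohort)]
    frame = rates_to_frame(binned)
    back = frame_to_rates(frame)
    assert len(back) == len(binned)
    for a, b in zip(binned, back):
        np.testing.assert_allclose(a.rates, b.rates)
        np.testing.assert_allclose(a.standardized, b.standardized, atol=1e-12)
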