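import numpy as np
import pingouin as pg
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from pulsedetect.inference import (
    dp_signed_rank,
    exact_signed_rank_p,
    holm,
    jzs_bf_paired,
    paired_t,
    wilcoxon_signed_rank,
)


def trapezoid_jzs(t, n, r=0.707, n_grid=200_000):
    """Independent high-resolution oracle on a substituted finite grid."""
    nu = n - 1
    u = np.linspace(1e-9, 1 - 1e-9, n_grid)
    g = u / (1 - u)
    jac = 1 / (1 - u) ** 2
    prior = (r**2 / 2) ** 0.5 / np.sqrt(np.pi) * g ** (-1.5) * np.exp(
        -r**2 / (2 * g)
    )
    lik = (1 + n * g) ** (-0.5) * (
        1 + t * t / ((1 + n * g) * nu)
    ) ** (-(nu + 1) / 2)
    num = np.trapezoid(prior * lik * jac, u)
    return num / (1 + t * t / nu) ** (-(nu + 1) / 2)


class TestPairedT:
    def test_identical_vectors(self):
        t, df, p = paired_t([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_hand_computed(self):
        # d = [1, 2, 3]: mean 2, sd 1 -> t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        t, df, p = paired_t([2, 4, 6], [1, 2, 3])
        assert t == pytest.approx(2 * np.sqrt(3))
        assert df == 2

    def test_df_is_n_minus_one(self):
        rng = np.random.default_rng(0)
        t, df, p = paired_t(rng.normal(size=36), rng.normal(size=36))
        assert df == 35

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            paired_t([2, 3, 4], [1, 2, 3])


class TestJzsBayesFactor:
    def test_printed_value_reproduced(self):
        """t = 0.65 with 36 pairs and scale 0.707 gives BF10 = 0.22."""
        bf = jzs_bf_paired(0.65, 36, 0.707)
        assert round(bf.bf10, 2) == 0.22

    def test_monotone_in_abs_t(self):
        bfs = [jzs_bf_paired(t, 20).bf10 for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("n", [2, 5, 36, 200])
    def test_zero_t_favors_null(self, n):
        assert jzs_bf_paired(0.0, n).bf10 < 1.0

    def test_matches_trapezoid_oracle(self):
        for t in (-1.5, 0.0, 0.65, 2.3):
            for n in (8, 36, 90):
                mine = jzs_bf_paired(t, n).bf10
                ref = trapezoid_jzs(t, n)
                assert mine == pytest.approx(ref, abs=1e-5, rel=1e-5)

    def test_matches_pingouin(self):
        for t, n in [(0.65, 36), (2.0, 15), (-1.2, 40)]:
            assert jzs_bf_paired(t, n).bf10 == pytest.approx(
                float(pg.bayesfactor_ttest(t, n, paired=True, r=0.707)),
                rel=1e-9,
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            jzs_bf_paired(1.0, 1)
        with pytest.raises(ValueError):
            jzs_bf_paired(1.0, 10, prior_scale=0.0)


class TestWilcoxon:
    def test_symmetric_differences_give_zero_z(self):
        z, p, exact = wilcoxon_signed_rank([-2, -1, 1, 2, -3, 3])
        assert z == 0.0 and p == 1.0

    def test_matches_scipy_z(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.3, 1, 25)
        d[3] = d[7]  # force a tie
        z, p, _ = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, correction=False, method="approx")
        # scipy reports Z from the smaller rank sum (always <= 0);
        # this implementation signs Z by W+ relative to its mean
        assert abs(z) == pytest.approx(abs(ref.zstatistic))
        assert p == pytest.approx(ref.pvalue)

    def test_exact_enumeration_matches_scipy_exact(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.5, 1, 9)
        assert exact_signed_rank_p(d) == pytest.approx(
            stats.wilcoxon(d, method="exact").pvalue
        )

    def test_normal_approx_close_to_exact_at_n8(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.4, 1, 8)
        z, p, exact = wilcoxon_signed_rank(d)
        assert exact is not None
        assert abs(p - exact) < 0.05

    def test_approximation_improves_with_n(self):
        """Sup-norm gap between exact and normal p shrinks as n grows."""
        rng = np.random.default_rng(4)
        gaps = []
        for n in (6, 9, 12):
            worst = 0.0
            for _ in range(20):
                d = rng.normal(0.3, 1, n)
                z, p, exact = wilcoxon_signed_rank(d)
                worst = max(worst, abs(p - exact))
            gaps.append(worst)
        assert gaps[2] < gaps[0]

    def test_shift_increases_rank_sum(self):
        d = np.array([-1.4, 0.6, -0.2, 1.1, 2.0, -0.8])
        z0, *_ = wilcoxon_signed_rank(d)
        z1, *_ = wilcoxon_signed_rank(d + 0.5)
        assert z1 > z0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0] * 10)
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, -1.0, 2.0, 0, 0, 0])  # < 5 nonzero


class TestHolm:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(
            holm([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        assert holm([0.2])[0] == 0.2

    def test_all_equal(self):
        np.testing.assert_allclose(holm([0.02, 0.02, 0.02]), [0.06] * 3)

    def test_clipped_at_one(self):
        assert holm([0.9, 0.8])[0] == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm([0.1, 1.2])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            p = rng.uniform(0, 1, rng.integers(2, 12))
            np.testing.assert_allclose(
                holm(p), multipletests(p, method="holm")[1]
            )


class TestDpSignedRank:
    def test_all_positive_overwhelms_null(self):
        rng = np.random.default_rng(6)
        res = dp_signed_rank(np.abs(rng.normal(1, 0.2, 30)), seed=0)
        assert res.posterior_p_h0 < 0.01
        assert res.bf10 > 1

    def test_symmetric_null_data_supports_h0(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0, 1, 150)
        d = np.concatenate([d, -d])  # exactly symmetric
        res = dp_signed_rank(d, seed=1)
        assert res.posterior_p_h0 > 0.5

    def test_mc_error_scales_inverse_sqrt(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.1, 1, 40)
        sd_small = np.std([
            dp_signed_rank(d, n_mc=1000, seed=s).posterior_p_h0
            for s in range(12)
        ])
        sd_big = np.std([
            dp_signed_rank(d, n_mc=16000, seed=s).posterior_p_h0
            for s in range(12)
        ])
        # 16x the draws -> ~4x smaller spread (allow generous slack)
        assert sd_big < sd_small / 2
        res = dp_signed_rank(d, n_mc=4000, seed=0)
        assert res.mc_error == pytest.approx(
            np.sqrt(res.posterior_p_h0 * (1 - res.posterior_p_h0) / 4000),
            rel=1e-6,
        )

    def test_prior_strength_pulls_toward_null(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.4, 1, 20)
        weak = dp_signed_rank(d, prior_strength=0.0, seed=2)
        strong = dp_signed_rank(d, prior_strength=20.0, seed=2)
        assert strong.posterior_p_h0 > weak.posterior_p_h0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            dp_signed_rank([0.0] * 10)
        with pytest.raises(ValueError):
            dp_signed_rank([1.0, 2.0], n_mc=2000)
        with pytest.raises(ValueError):
            dp_signed_rank(np.ones(10), n_mc=10)
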