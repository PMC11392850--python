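import numpy as np
import pytest

from rempropensity.classify import Chain, SEQUENTIAL, SINGLE
from rempropensity.cycles import RemCycle
from rempropensity.gmm import GmmParams
from rempropensity.propensity import evaluate_curve, mixture_propensity
from rempropensity.stats import (
    StatsError,
    logistic_seq_presence,
    pearson_r_p,
    propensity_at_onset,
    rem_fraction_compare,
)

PARAMS = GmmParams(0.75, 6.8, 0.55, 4.7, 0.45)


def _cycle(n_s=200.0, rempre=30.0, rempost=30.0, rec="r", order=0):
    return RemCycle(
        rempre_s=rempre, n_s=n_s, wake_s=0.0, max_wake_bout_s=0.0,
        rempost_s=rempost, phase=0, bin_index=1, onset_epoch=0,
        recording_id=rec, order=order,
    )


class TestPearson:
    def test_perfect_positive(self):
        res = pearson_r_p([1, 2, 3], [2, 4, 6])
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        res = pearson_r_p([1, 2, 3], [6, 4, 2])
        assert res.r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(41)
        x, y = rng.normal(size=(2, 200))
        res = pearson_r_p(x, y)
        r_direct = float(
            np.cov(x, y, bias=True)[0, 1] / (np.std(x) * np.std(y))
        )
        assert res.r == pytest.approx(r_direct, abs=1e-12)
        # two-tailed t-test p from the t transform
        from scipy.stats import t as tdist

        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * tdist.sf(abs(t), res.n - 2), rel=1e-9)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(42)
        x, y = rng.normal(size=(2, 10_000))
        res = pearson_r_p(x, y)
        assert abs(res.r) < 0.03

    def test_null_p_uniformity(self):
        rng = np.random.default_rng(43)
        ps = []
        for _ in range(200):
            x, y = rng.normal(size=(2, 50))
            ps.append(pearson_r_p(x, y).p)
        # rejection rate close to alpha under the null
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.01 <= rate <= 0.10

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            pearson_r_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(StatsError):
            pearson_r_p([1.0, 2.0], [1.0, 2.0])


class TestOnsetPropensity:
    def test_nearest_grid_second(self):
        curve = evaluate_curve(PARAMS)
        assert propensity_at_onset(_cycle(37.2), curve) == curve.values[36]

    def test_beyond_grid(self):
        curve = evaluate_curve(PARAMS)
        got = propensity_at_onset(_cycle(6000.0), curve)
        assert got == pytest.approx(float(mixture_propensity(PARAMS, 6000.0)))

    def test_equal_n_equal_propensity(self):
        curve = evaluate_curve(PARAMS)
        a = propensity_at_onset(_cycle(412.0), curve)
        b = propensity_at_onset(_cycle(412.0, rempre=55.0), curve)
        assert a == b


class TestLogistic:
    def test_coupled_data_positive_slope(self):
        rng = np.random.default_rng(44)
        x = rng.uniform(0, 1, 600)
        y = (rng.random(600) < 1 / (1 + np.exp(-(4 * x - 2)))).astype(int)
        res = logistic_seq_presence(x, y)
        assert res.slope > 0 and res.p < 0.05 and not res.separated

    def test_null_slope_small(self):
        rng = np.random.default_rng(45)
        x = rng.uniform(0, 1, 2000)
        y = (rng.random(2000) < 0.4).astype(int)
        res = logistic_seq_presence(x, y)
        assert abs(res.slope) < 1.0 and res.p > 0.01

    def test_one_class_rejected(self):
        with pytest.raises(StatsError):
            logistic_seq_presence([0.1, 0.2, 0.3], [1, 1, 1])

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = np.concatenate([np.zeros(20), np.ones(20)]).astype(int)
        res = logistic_seq_presence(x, y)
        assert res.separated or res.p < 1e-4  # flagged, never a crash


class TestRemFractions:
    def test_single_cycle_fraction(self):
        cycles = [_cycle(n_s=270.0, rempre=30.0, order=0),
                  _cycle(n_s=60.0, rempre=30.0, order=1),
                  _cycle(n_s=50.0, rempre=25.0, order=2)]
        labels = [SINGLE, SEQUENTIAL, SEQUENTIAL]
        chains = [Chain(anchor=0, length_S=2, member_indices=(1, 2))]
        res = rem_fraction_compare(cycles, labels, chains)
        assert res.frac_single == pytest.approx(0.1)
        assert res.frac_sequential == pytest.approx((30 / 90 + 25 / 75) / 2)
        # chain fraction pools member epochs
        assert res.frac_chain == pytest.approx((30 + 25) / (90 + 75))

    def test_strong_difference_detected(self):
        rng = np.random.default_rng(46)
        cycles, labels = [], []
        for i in range(200):  # sequential cycles ~3x richer in REM
            cycles.append(_cycle(n_s=float(rng.uniform(500, 900)),
                                 rempre=float(rng.uniform(50, 90)), order=2 * i))
            labels.append(SINGLE)
            cycles.append(_cycle(n_s=float(rng.uniform(100, 200)),
                                 rempre=float(rng.uniform(50, 90)),
                                 order=2 * i + 1))
            labels.append(SEQUENTIAL)
        chains = [
            Chain(anchor=2 * i, length_S=1, member_indices=(2 * i + 1,))
            for i in range(200)
        ]
        res = rem_fraction_compare(cycles, labels, chains)
        assert res.frac_sequential > 2 * res.frac_single
        assert res.p_single_vs_seq < 0.01
        assert res.p_single_vs_chain < 0.01

    def test_missing_group_rejected(self):
        cycles = [_cycle(order=0)]
        with pytest.raises(StatsError):
            rem_fraction_compare(cycles, [SINGLE], [])
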