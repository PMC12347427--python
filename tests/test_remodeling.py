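import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from femrem.errors import (
    EmptyZoneError,
    InsufficientDataError,
    InvalidParameterError,
)
from femrem.meshing import Region
from femrem.remodeling import (
    RemodelingClass,
    ThresholdPair,
    calibrate_upper_threshold,
    classification_accuracy,
    classify_stimulus,
    cortical_overload,
    lower_threshold_from_iqr,
    mechanical_stimulus,
    predict_zone_remodeling,
    weighted_median,
    zone_median_stimulus,
)

RES = RemodelingClass.RESORPTION
NONE = RemodelingClass.NO_ACTIVITY
APP = RemodelingClass.APPOSITION


class TestStimulus:
    def test_zero(self):
        assert mechanical_stimulus(0.0, 600.0) == 0.0

    def test_unit_conversion(self):
        # 0.006 MPa = 6000 J/m^3; / 600 kg/m^3 = 10 J/kg
        assert mechanical_stimulus(0.006, 600.0) == pytest.approx(10.0)

    def test_lower_threshold_scale(self):
        assert mechanical_stimulus(0.0012, 600.0) == pytest.approx(2.0)

    def test_bad_density(self):
        with pytest.raises(InvalidParameterError):
            mechanical_stimulus(1.0, 0.0)

    def test_vectorised(self):
        out = mechanical_stimulus(np.array([0.0, 0.006]), 600.0)
        assert np.allclose(out, [0.0, 10.0])


class TestClassify:
    def test_threshold_rule(self):
        t = ThresholdPair(2.0, 12.0)
        assert classify_stimulus(13.0, t) is APP
        assert classify_stimulus(1.0, t) is RES
        assert classify_stimulus(5.0, t) is NONE

    def test_boundaries_belong_to_lazy_zone(self):
        t = ThresholdPair(2.0, 12.0)
        assert classify_stimulus(12.0, t) is NONE
        assert classify_stimulus(2.0, t) is NONE

    def test_invalid_threshold_pair(self):
        with pytest.raises(InvalidParameterError):
            ThresholdPair(12.0, 2.0)

    @given(st.floats(min_value=0.0, max_value=1e3, allow_nan=False))
    def test_total_partition(self, s):
        t = ThresholdPair(2.0, 12.0)
        assert classify_stimulus(s, t) in (RES, NONE, APP)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=2, max_size=20),
    )
    def test_monotone_in_stimulus(self, values):
        order = {RES: 0, NONE: 1, APP: 2}
        t = ThresholdPair(2.0, 12.0)
        ranked = sorted(values)
        classes = [order[classify_stimulus(v, t)] for v in ranked]
        assert classes == sorted(classes)


class TestWeightedMedian:
    def test_constant(self):
        assert weighted_median([7.0, 7.0, 7.0], [1, 2, 3]) == 7.0

    def test_outlier_robust(self):
        assert weighted_median([1.0, 3.0, 100.0], [1, 1, 1]) == 3.0

    def test_cumulative_area_rule(self):
        # areas {1,1,2}, values {1,2,3}: half-total reached only at 3
        assert weighted_median([1.0, 2.0, 3.0], [1.0, 1.0, 2.0]) == 3.0

    def test_matches_plain_median_odd_n(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.uniform(0, 50, size=9)
            assert weighted_median(x, np.ones(9)) == np.median(x)


class TestZoneMedians:
    def test_all_equal(self):
        stimuli = np.full(14, 4.2)
        areas = np.ones(14)
        zones = np.repeat(np.arange(1, 8), 2)
        med = zone_median_stimulus(stimuli, areas, zones)
        assert all(v == 4.2 for v in med.values())

    def test_empty_zone_error(self):
        with pytest.raises(EmptyZoneError):
            zone_median_stimulus(np.array([1.0]), np.array([1.0]), np.array([1]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        stimuli = rng.uniform(0, 30, 70)
        areas = rng.uniform(0.5, 2.0, 70)
        zones = np.repeat(np.arange(1, 8), 10)
        med1 = zone_median_stimulus(stimuli, areas, zones)
        perm = rng.permutation(70)
        med2 = zone_median_stimulus(stimuli[perm], areas[perm], zones[perm])
        assert med1 == med2


class TestPredict:
    def test_all_lazy(self):
        med = {z: 5.0 for z in range(1, 8)}
        out = predict_zone_remodeling(med, ThresholdPair())
        assert all(z.predicted is NONE for z in out)

    def test_mixed(self):
        med = {1: 1.0, 2: 5.0, 3: 13.0, 4: 0.5, 5: 20.0, 6: 2.0, 7: 12.0}
        out = {z.zone_id: z.predicted for z in predict_zone_remodeling(med, ThresholdPair())}
        assert out == {1: RES, 2: NONE, 3: APP, 4: RES, 5: APP, 6: NONE, 7: NONE}

    def test_elementwise(self):
        med = {z: float(z) for z in range(1, 8)}
        out1 = predict_zone_remodeling(med, ThresholdPair())
        out2 = predict_zone_remodeling(dict(reversed(med.items())), ThresholdPair())
        assert out1 == out2


class TestLowerThreshold:
    def test_worked_example(self):
        assert lower_threshold_from_iqr([1, 2, 2, 3, 5, 7, 8]) == pytest.approx(2.0)

    def test_constant(self):
        assert lower_threshold_from_iqr([4.0] * 6) == 4.0

    def test_insufficient(self):
        with pytest.raises(InsufficientDataError):
            lower_threshold_from_iqr([1.0, 2.0, 3.0])

    def test_matches_numpy_linear(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.uniform(0, 20, size=rng.integers(4, 30))
            assert lower_threshold_from_iqr(x) == pytest.approx(
                float(np.percentile(x, 25, method="linear"))
            )


class TestAccuracy:
    def test_identical(self):
        assert classification_accuracy([APP, RES], [APP, RES]) == 1.0

    def test_discordant(self):
        assert classification_accuracy([APP, RES], [RES, APP]) == 0.0

    def test_five_of_seven(self):
        pred = [APP] * 5 + [RES] * 2
        obs = [APP] * 5 + [NONE] * 2
        assert classification_accuracy(pred, obs) == pytest.approx(5 / 7)

    def test_length_mismatch(self):
        with pytest.raises(InvalidParameterError):
            classification_accuracy([APP], [APP, RES])

    @given(st.permutations(list(range(7))))
    @settings(max_examples=20)
    def test_reorder_invariance(self, perm):
        pred = [APP, RES, NONE, APP, RES, NONE, APP]
        obs = [APP, NONE, NONE, RES, RES, NONE, APP]
        a = classification_accuracy(pred, obs)
        b = classification_accuracy([pred[i] for i in perm], [obs[i] for i in perm])
        assert a == b


def brute_force_oracle(medians, observed, t_low, grid):
    """Independent reimplementation: enumerate the grid, score, find runs."""
    lo, hi, step = grid
    ts = []
    t = lo
    while t <= hi + 1e-9:
        ts.append(round(t, 10))
        t += step
    accs = []
    for t in ts:
        ok = 0
        for m, o in zip(medians, observed):
            if m > t:
                c = APP
            elif m < t_low:
                c = RES
            else:
                c = NONE
            ok += c is o
        accs.append(ok / len(medians))
    best = max(accs)
    runs = []
    cur = None
    for i, a in enumerate(accs):
        if abs(a - best) < 1e-12:
            if cur is None:
                cur = [i, i]
            else:
                cur[1] = i
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
    if cur is not None:
        runs.append(cur)
    run = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    return 0.5 * (ts[run[0]] + ts[run[1]]), best, (ts[run[0]], ts[run[1]])


class TestCalibration:
    def test_hand_enumerated_example(self):
        # 31 grid points in [5, 20] step 0.5; accuracy 1 for t in [5, 12.5]
        cal = calibrate_upper_threshold(
            [1.0, 5.0, 13.0], [RES, NONE, APP], t_low=2.0, grid=(5.0, 20.0, 0.5)
        )
        assert cal.accuracy == 1.0
        assert cal.plateau == (5.0, 12.5)
        assert cal.t_high_star == pytest.approx(8.75)

    def test_all_apposition(self):
        cal = calibrate_upper_threshold(
            [100.0] * 5, [APP] * 5, t_low=2.0, grid=(3.0, 25.0, 0.25)
        )
        assert cal.accuracy == 1.0
        assert cal.plateau[1] == 25.0

    def test_oracle_equivalence_random(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(5, 40))
            medians = rng.uniform(0, 30, n)
            observed = [
                [RES, NONE, APP][i] for i in rng.integers(0, 3, n)
            ]
            grid = (3.0, 25.0, 0.25)
            cal = calibrate_upper_threshold(medians, observed, 2.0, grid)
            star, best, plateau = brute_force_oracle(medians, observed, 2.0, grid)
            assert cal.t_high_star == pytest.approx(star)
            assert cal.accuracy == pytest.approx(best)
            assert cal.plateau == pytest.approx(plateau)

    def test_recovery_of_generating_threshold(self):
        rng = np.random.default_rng(11)
        true = ThresholdPair(2.0, 12.0)
        medians = rng.uniform(0, 25, 200)
        observed = [classify_stimulus(m, true) for m in medians]
        cal = calibrate_upper_threshold(medians, observed, t_low=2.0)
        assert cal.accuracy == 1.0
        assert cal.plateau[0] <= 12.0 <= cal.plateau[1] + cal.grid_step

    def test_empty_grid(self):
        with pytest.raises(InvalidParameterError):
            calibrate_upper_threshold([1.0], [RES], 2.0, grid=(5.0, 4.0, 0.5))

    def test_grid_must_exceed_t_low(self):
        with pytest.raises(InvalidParameterError):
            calibrate_upper_threshold([1.0], [RES], 5.0, grid=(4.0, 10.0, 0.5))


class TestCorticalOverload:
    def _fields(self, stim):
        n = len(stim)
        areas = np.ones(n)
        region = np.array([Region.CORTICAL] * n, dtype=object)
        band = np.ones(n, dtype=bool)
        return np.asarray(stim, float), areas, region, band

    def test_all_below(self):
        s, a, r, b = self._fields([1.0, 2.0, 3.0])
        frac, smax = cortical_overload(s, a, r, b, t_high=12.0)
        assert frac == 0.0
        assert smax == 3.0

    def test_all_above(self):
        s, a, r, b = self._fields([24.0] * 4)
        frac, smax = cortical_overload(s, a, r, b, t_high=12.0)
        assert frac == 1.0
        assert smax == 24.0

    def test_area_weighting(self):
        s = np.array([20.0, 1.0])
        a = np.array([1.0, 3.0])
        r = np.array([Region.CORTICAL, Region.CORTICAL], dtype=object)
        b = np.ones(2, dtype=bool)
        frac, _ = cortical_overload(s, a, r, b, 12.0)
        assert frac == pytest.approx(0.25)

    def test_no_cortical_in_band(self):
        s = np.array([20.0])
        a = np.array([1.0])
        r = np.array([Region.CANCELLOUS], dtype=object)
        b = np.ones(1, dtype=bool)
        assert cortical_overload(s, a, r, b, 12.0) == (0.0, 0.0)
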