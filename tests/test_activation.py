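import numpy as np
import pytest
from scipy.special import expit

from dynsort.activation import (
    ActivationCurve,
    build_activation_curve,
    compare_thresholds,
    fit_sigmoid,
    kfold_split,
)
from dynsort.core import Recording
from dynsort.detect import SpikeCall
from dynsort.errors import InvalidArgumentError, LookupError_
from dynsort.synthetic import gen_amplitude_grid


def _calls(amplitudes, detections, neuron_id=0):
    calls = []
    trial = 0
    for q, dets in zip(amplitudes, detections):
        for d in dets:
            calls.append(SpikeCall(neuron_id=neuron_id, trial=trial, amplitude=q,
                                   detected=bool(d), latency=0 if d else None,
                                   score=float(d)))
            trial += 1
    return calls


class TestBuildCurve:
    def test_probabilities_are_count_ratios(self):
        amps = [0.5, 1.0, 2.0]
        calls = _calls(amps, [[0] * 25, [1] * 10 + [0] * 15, [1] * 25])
        curve = build_activation_curve(calls, 0, stim_electrode=7)
        np.testing.assert_allclose(curve.probabilities, [0.0, 0.4, 1.0])
        np.testing.assert_array_equal(curve.trial_counts, [25, 25, 25])

    def test_no_matching_calls_raises(self):
        with pytest.raises(LookupError_):
            build_activation_curve([], 0, 0)

    def test_threshold_undefined_without_activation(self):
        calls = _calls([0.5, 1.0], [[0] * 5, [0] * 5])
        curve = build_activation_curve(calls, 0, 0)
        q50, slope, converged = fit_sigmoid(curve)
        assert not converged and np.isnan(curve.threshold)


class TestFitSigmoid:
    def test_step_data_threshold_between_brackets(self):
        amps = gen_amplitude_grid(10, 0.5, 2.0)
        k = (amps > 1.0).astype(int) * 20
        curve = ActivationCurve(0, 0, amps, k, np.full(10, 20))
        q50, slope, converged = fit_sigmoid(curve)
        assert converged
        below = amps[amps <= 1.0].max()
        above = amps[amps > 1.0].min()
        assert below <= q50 <= above

    def test_symmetric_data_recovers_center(self):
        amps = np.array([0.5, 1.0, 2.0])
        curve = ActivationCurve(0, 0, amps, np.array([0, 10, 20]),
                                np.array([20, 20, 20]))
        q50, slope, converged = fit_sigmoid(curve)
        assert converged
        assert q50 == pytest.approx(1.0, rel=0.05)

    def test_monte_carlo_recovery_within_ten_percent(self):
        rng = np.random.default_rng(11)
        amps = gen_amplitude_grid(39, 0.1, 4.1)
        q50_true, slope_true = 1.0, 0.1
        p = expit((np.log(amps) - np.log(q50_true)) / slope_true)
        k = rng.binomial(25, p)
        curve = ActivationCurve(0, 0, amps, k, np.full(39, 25))
        q50, slope, converged = fit_sigmoid(curve)
        assert converged
        assert abs(q50 - q50_true) / q50_true < 0.10

    def test_invariant_to_amplitude_ordering(self):
        amps = np.array([0.5, 1.0, 2.0])
        k = np.array([0, 10, 20])
        n = np.array([20, 20, 20])
        a = ActivationCurve(0, 0, amps, k, n)
        perm = [2, 0, 1]
        b = ActivationCurve(0, 0, amps[perm], k[perm], n[perm])
        assert fit_sigmoid(a)[0] == pytest.approx(fit_sigmoid(b)[0], rel=1e-4)


class TestKfold:
    def _rec(self, amps, repeats):
        n = len(amps) * repeats
        return Recording(data=np.zeros((n, 4, 3)),
                         amplitudes=np.repeat(amps, repeats), stim_electrode=0)

    def test_balanced_stratified_split(self):
        rec = self._rec(np.array([1.0, 2.0]), repeats=25)
        folds = kfold_split(rec, 5, seed=0)
        for fold in folds:
            for q in (1.0, 2.0):
                assert np.isin(fold, rec.trials_at(q)).sum() == 5

    def test_folds_disjoint_and_covering(self):
        rec = self._rec(np.array([1.0, 2.0, 3.0]), repeats=10)
        folds = kfold_split(rec, 5, seed=3)
        allidx = np.concatenate(folds)
        assert len(allidx) == rec.n_trials
        assert len(np.unique(allidx)) == rec.n_trials

    def test_leave_one_out_per_amplitude(self):
        rec = self._rec(np.array([1.0]), repeats=4)
        folds = kfold_split(rec, 4, seed=0)
        assert all(f.size == 1 for f in folds)

    def test_k_exceeding_trials_raises(self):
        rec = self._rec(np.array([1.0]), repeats=3)
        with pytest.raises(InvalidArgumentError):
            kfold_split(rec, 5)


class TestCompareThresholds:
    def test_identical_sets(self):
        a = np.array([1.0, 2.0, 3.0])
        r2, n = compare_thresholds(a, a)
        assert r2 == pytest.approx(1.0)
        assert n == 3

    def test_offset_invariance(self):
        a = np.array([1.0, 2.0, 3.0])
        r2, _ = compare_thresholds(a, a + 0.7)
        assert r2 == pytest.approx(1.0)

    def test_toy_pearson_by_hand(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([1.0, 2.0, 4.0])
        # hand Pearson: cov = 1.5, sd_a = sqrt(1), sd_b = sqrt(7/3)
        expected = (1.5 / (1.0 * np.sqrt(7 / 3))) ** 2
        r2, _ = compare_thresholds(a, b)
        assert r2 == pytest.approx(expected)

    def test_nan_pairs_dropped(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, np.nan, 3.0, 4.0])
        _, n = compare_thresholds(a, b)
        assert n == 3

    def test_identity_line_method(self):
        a = np.array([1.0, 2.0, 3.0])
        r2, _ = compare_thresholds(a, a, method="identity")
        assert r2 == pytest.approx(1.0)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(InvalidArgumentError):
            compare_thresholds(np.array([1.0]), np.array([1.0]))
        with pytest.raises(InvalidArgumentError):
            compare_thresholds(np.array([1.0, 1.0]), np.array([1.0, 2.0]))
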