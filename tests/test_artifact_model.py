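import numpy as np
import pytest

from dynsort.artifact import (
    anrmse,
    average_trials,
    averaged_by_amplitude,
    fit_artifact_model,
    fit_artifact_template,
    lower_half_amplitudes,
    predict_artifact,
    select_artifact_electrodes,
)
from dynsort.core import (
    InputTemplate,
    Recording,
    StateSpaceModel,
    build_grid_geometry,
    simulate_lds,
)
from dynsort.errors import EmptySelectionError, InsufficientDataError, LookupError_
from dynsort.synthetic import GroundTruth, NoiseModel, gen_artifact_truth, gen_stim_dataset
from dynsort.core import StimulationProtocol


def _recording(values, amplitudes):
    """trials x T x E recording from a list of per-trial scalars."""
    data = np.array(values, dtype=float)[:, None, None] * np.ones((1, 4, 3))
    return Recording(data=data, amplitudes=np.array(amplitudes, dtype=float),
                     stim_electrode=0)


class TestAverageTrials:
    def test_identical_trials_pass_through(self):
        rec = _recording([5.0, 5.0, 5.0], [1.0, 1.0, 1.0])
        np.testing.assert_allclose(average_trials(rec, 1.0, trim=0.1), 5.0)

    def test_trim_zero_plain_mean(self):
        rec = _recording([0.0, 10.0], [1.0, 1.0])
        np.testing.assert_allclose(average_trials(rec, 1.0, trim=0.0), 5.0)

    def test_trim_discards_tails(self):
        rec = _recording([0.0, 0.0, 0.0, 100.0], [1.0] * 4)
        np.testing.assert_allclose(average_trials(rec, 1.0, trim=0.25), 0.0)

    def test_missing_amplitude_raises(self):
        rec = _recording([1.0], [1.0])
        with pytest.raises(LookupError_):
            average_trials(rec, 9.0)

    def test_noiseless_dataset_average_is_scaled_artifact(self):
        array = build_grid_geometry(4, 4, 60.0)
        art = gen_artifact_truth(array, 5, T=30)
        protocol = StimulationProtocol(amplitudes=np.array([0.5, 2.0]), repeats=4)
        rec, _ = gen_stim_dataset(array, [], art, protocol, GroundTruth(),
                                  NoiseModel(std=0.0), seed=0, stim_electrode=5)
        np.testing.assert_allclose(average_trials(rec, 2.0, trim=0.1), 2.0 * art,
                                   atol=1e-12)


class TestSelectArtifactElectrodes:
    def test_stim_electrode_always_excluded(self):
        array = build_grid_geometry(6, 6, 60.0)
        sel = select_artifact_electrodes(array, 14, radius=1e9)
        assert 14 not in sel
        assert sel.size == 35

    def test_radius_pitch_gives_axial_neighbors(self):
        array = build_grid_geometry(6, 6, 60.0)
        sel = select_artifact_electrodes(array, 14, radius=60.0)
        np.testing.assert_array_equal(sel, [8, 13, 15, 20])

    def test_empty_selection_raises(self):
        array = build_grid_geometry(6, 6, 60.0)
        with pytest.raises(EmptySelectionError):
            select_artifact_electrodes(array, 14, radius=10.0)


class TestArtifactTemplate:
    def test_three_disjoint_unit_pulses_at_onset(self):
        mats = {0.5: np.zeros((6, 20)), 1.0: np.zeros((6, 20))}
        tmpl = fit_artifact_template(mats, np.arange(4))
        assert tmpl.pulses.shape[0] == 3
        np.testing.assert_array_equal(tmpl.pulse_times, [0, 1, 2])
        # disjoint single-sample supports
        for ch, t in enumerate(tmpl.pulse_times):
            assert np.flatnonzero(tmpl.pulses[ch]).tolist() == [t]

    def test_amplitude_independent(self):
        a = fit_artifact_template({0.5: np.zeros((4, 10)), 1.0: np.zeros((4, 10))},
                                  np.arange(3))
        b = fit_artifact_template({1.0: np.zeros((4, 10)), 3.0: np.zeros((4, 10))},
                                  np.arange(3))
        np.testing.assert_array_equal(a.pulses, b.pulses)

    def test_single_amplitude_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_artifact_template({1.0: np.zeros((4, 10))}, np.arange(3))


def _known_artifact(seed=0, T=40):
    rng = np.random.default_rng(seed)
    array = build_grid_geometry(6, 6, 60.0)
    sub = select_artifact_electrodes(array, 14, radius=100.0)
    m = sub.size
    A = rng.standard_normal((m, m))
    A *= 0.7 / np.max(np.abs(np.linalg.eigvals(A)))
    B = rng.standard_normal((m, 3))
    pulses = np.zeros((3, T))
    for ch in range(3):
        pulses[ch, ch] = 1.0
    tmpl = InputTemplate(pulses=pulses, pulse_times=np.array([0, 1, 2]), role="artifact")
    model = StateSpaceModel(A=A, B=B, electrode_subset=sub, template=tmpl,
                            role="artifact", stim_electrode=14)
    return array, model, sub, tmpl


class TestFitArtifactModel:
    def test_exact_refit_linear_in_q(self):
        array, true_model, sub, tmpl = _known_artifact()
        amps = [0.2, 0.7, 1.9, 4.0]
        averaged = {
            q: simulate_lds(true_model, q * tmpl.pulses, n_electrodes=36) for q in amps
        }
        refit = fit_artifact_model(averaged, amps, sub, tmpl, ridge=0.0,
                                   stim_electrode=14)
        for q in amps:
            pred = predict_artifact(refit, q, 36, tmpl.n_samples)
            assert anrmse(averaged[q], pred, sub) < 1e-8

    def test_output_doubles_with_amplitude(self):
        array, true_model, sub, tmpl = _known_artifact()
        averaged = {q: simulate_lds(true_model, q * tmpl.pulses, n_electrodes=36)
                    for q in [0.5, 1.0]}
        refit = fit_artifact_model(averaged, [0.5, 1.0], sub, tmpl, ridge=0.0,
                                   stim_electrode=14)
        p1 = predict_artifact(refit, 1.3, 36, 40)
        p2 = predict_artifact(refit, 2.6, 36, 40)
        np.testing.assert_allclose(p2, 2 * p1, atol=1e-9)

    def test_stim_electrode_never_predicted(self):
        array, true_model, sub, tmpl = _known_artifact()
        averaged = {q: simulate_lds(true_model, q * tmpl.pulses, n_electrodes=36)
                    for q in [0.5, 1.0]}
        refit = fit_artifact_model(averaged, [0.5, 1.0], sub, tmpl, ridge=1e-6,
                                   stim_electrode=14)
        assert 14 not in refit.electrode_subset
        assert np.all(predict_artifact(refit, 2.0, 36, 40)[14] == 0)


class TestAnrmse:
    def test_hand_examples(self):
        sub = np.array([0])
        assert anrmse(np.array([[1.0, 1.0]]), np.array([[1.0, 1.0]]), sub) == 0.0
        assert anrmse(np.array([[1.0, 1.0]]), np.array([[0.0, 0.0]]), sub) == 1.0
        assert anrmse(np.array([[1.0, 1.0]]), np.array([[0.0, 2.0]]), sub) == pytest.approx(1.0)

    def test_zero_reference_raises(self):
        with pytest.raises(ZeroDivisionError):
            anrmse(np.zeros((2, 3)), np.ones((2, 3)), np.array([0]))


class TestFittingAmplitudeSelection:
    def test_lower_half(self):
        amps = np.array([0.1, 0.2, 0.4, 0.8, 1.6, 3.2])
        np.testing.assert_allclose(lower_half_amplitudes(amps), [0.1, 0.2, 0.4])

    def test_averaged_by_amplitude_keys(self):
        rec = _recording([1.0, 2.0], [0.5, 1.5])
        avg = averaged_by_amplitude(rec, trim=0.0)
        assert sorted(avg.keys()) == [0.5, 1.5]
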