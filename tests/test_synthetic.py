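import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynsort.core import StimulationProtocol, build_grid_geometry
from dynsort.errors import InvalidArgumentError, LookupError_
from dynsort.synthetic import (
    GroundTruth,
    NoiseModel,
    SyntheticNeuronSpec,
    activation_probability,
    gen_amplitude_grid,
    gen_artifact_truth,
    gen_stim_dataset,
    gen_stim_waveform,
    gen_synthetic_ei,
)


@pytest.fixture(scope="module")
def array():
    return build_grid_geometry(6, 6, 60.0)


@pytest.fixture(scope="module")
def spec():
    return SyntheticNeuronSpec(
        soma_position=(120.0, 120.0),
        axon_path=np.array([[180.0, 120.0], [300.0, 120.0]]),
        peak_amplitude=30.0,
    )


class TestSyntheticEI:
    def test_peak_amplitude_exact(self, array, spec):
        ei = gen_synthetic_ei(array, spec, T=40, seed=0)
        assert ei.peak_amplitude == pytest.approx(30.0)

    def test_trough_latency_increases_along_axon(self, array, spec):
        ei = gen_synthetic_ei(array, spec, T=40, seed=0)
        # electrodes on the axon row, increasing x: 2 + row offset
        on_path = [2 * 6 + c for c in range(2, 6)]  # y=120 row, x=120..300
        troughs = [int(np.argmin(ei.voltages[e])) for e in on_path]
        assert troughs == sorted(troughs)
        assert troughs[-1] > troughs[0]

    def test_same_seed_identical(self, array, spec):
        a = gen_synthetic_ei(array, spec, T=40, seed=5)
        b = gen_synthetic_ei(array, spec, T=40, seed=5)
        np.testing.assert_array_equal(a.voltages, b.voltages)

    def test_too_short_window_raises(self, array, spec):
        with pytest.raises(InvalidArgumentError):
            gen_synthetic_ei(array, spec, T=8, seed=0)


class TestArtifactTruth:
    def test_stim_electrode_has_largest_trace(self, array):
        art = gen_artifact_truth(array, 14, T=55)
        norms = np.linalg.norm(art, axis=1)
        assert np.argmax(norms) == 14

    def test_linearity_in_amplitude(self, array):
        art = gen_artifact_truth(array, 14, T=55)
        np.testing.assert_allclose(2.0 * art, 2.0 * art)  # q-scaling is by definition
        # and the dataset generator applies it exactly (no neurons, no noise)
        protocol = StimulationProtocol(amplitudes=np.array([0.5, 1.0]), repeats=2)
        rec, _ = gen_stim_dataset(array, [], art, protocol, GroundTruth(),
                                  NoiseModel(std=0.0), seed=0, stim_electrode=14)
        np.testing.assert_allclose(rec.data[0].T, 0.5 * art)
        np.testing.assert_allclose(rec.data[2].T, 1.0 * art)

    def test_rank1_spatial_ratio_matches_exponential(self, array):
        # with a single spatial decay length the amplitude ratio between two
        # electrodes is exp(-(d1 - d2) / decay_length)
        art = gen_artifact_truth(array, 14, T=55, decay_length=40.0,
                                 slow_decay_scale=1.0)
        d = array.distances_from(14)
        e1, e2 = 15, 16  # distances 60 and 120 um
        ratio = art[e2, 5] / art[e1, 5]
        assert ratio == pytest.approx(np.exp(-(d[e2] - d[e1]) / 40.0), rel=1e-9)

    def test_trace_starts_at_zero_then_decays(self, array):
        art = gen_artifact_truth(array, 14, T=55)
        assert np.all(art[:, 0] == 0)
        # strictly decaying after the onset sample
        assert np.all(np.diff(art[14, 1:]) < 0)

    def test_unknown_stim_electrode_raises(self, array):
        with pytest.raises(LookupError_):
            gen_artifact_truth(array, 999, T=55)


class TestAmplitudeGrid:
    def test_paper_protocol_grid(self):
        amps = gen_amplitude_grid(39, 0.1, 4.1)
        assert amps.size == 39
        assert amps[0] == pytest.approx(0.1)
        assert amps[-1] == pytest.approx(4.1)
        ratios = amps[1:] / amps[:-1]
        np.testing.assert_allclose(ratios, ratios[0])

    def test_closed_form_log_spacing(self):
        np.testing.assert_allclose(gen_amplitude_grid(3, 1, 100), [1, 10, 100])
        np.testing.assert_allclose(gen_amplitude_grid(2, 1, 10), [1, 10])

    def test_nonpositive_lo_raises(self):
        with pytest.raises(InvalidArgumentError):
            gen_amplitude_grid(5, 0.0, 1.0)


class TestStimWaveform:
    def test_phase_ratios(self):
        protocol = StimulationProtocol(amplitudes=np.array([1.0, 2.0]))
        wave = gen_stim_waveform(3.0, protocol)
        spp = wave.size // 3
        np.testing.assert_allclose(wave.reshape(3, spp).mean(axis=1), [2.0, -3.0, 1.0])

    def test_second_phase_magnitude_and_first_phase(self):
        protocol = StimulationProtocol(amplitudes=np.array([1.0, 2.0]))
        wave = gen_stim_waveform(4.1, protocol)
        spp = wave.size // 3
        phases = wave.reshape(3, spp).mean(axis=1)
        assert abs(phases[1]) == pytest.approx(4.1)
        assert phases[0] == pytest.approx(2 * 4.1 / 3)

    @given(amp=st.floats(0, 10, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_charge_balance(self, amp):
        protocol = StimulationProtocol(amplitudes=np.array([1.0, 2.0]))
        assert gen_stim_waveform(amp, protocol).sum() == pytest.approx(0.0, abs=1e-9)


class TestStimDataset:
    def test_trial_count_matches_protocol(self, array):
        art = gen_artifact_truth(array, 14, T=55)
        protocol = StimulationProtocol(amplitudes=gen_amplitude_grid(39, 0.1, 4.1),
                                       repeats=25)
        rec, _ = gen_stim_dataset(array, [], art, protocol, GroundTruth(),
                                  NoiseModel(std=0.0), seed=0, stim_electrode=14)
        assert rec.n_trials == 975

    def test_never_activating_neuron_yields_no_spikes(self, array, spec):
        art = gen_artifact_truth(array, 14, T=55)
        ei = gen_synthetic_ei(array, spec, T=32, seed=0)
        protocol = StimulationProtocol(amplitudes=np.array([1.0, 2.0]), repeats=5)
        truth = GroundTruth(activation={0: (np.inf, 1.0)})
        _, realized = gen_stim_dataset(array, [ei], art, protocol, truth,
                                       NoiseModel(std=1.0), seed=0, stim_electrode=14)
        assert all(len(v) == 0 for v in realized.spikes.values())

    def test_seed_reproducibility(self, array, spec):
        art = gen_artifact_truth(array, 14, T=55)
        ei = gen_synthetic_ei(array, spec, T=32, seed=0)
        protocol = StimulationProtocol(amplitudes=np.array([1.0, 2.0]), repeats=3)
        truth = GroundTruth(activation={0: (1.0, 0.1)})
        r1, g1 = gen_stim_dataset(array, [ei], art, protocol, truth,
                                  NoiseModel(std=1.0), seed=42, stim_electrode=14)
        r2, g2 = gen_stim_dataset(array, [ei], art, protocol, truth,
                                  NoiseModel(std=1.0), seed=42, stim_electrode=14)
        np.testing.assert_array_equal(r1.data, r2.data)
        assert g1.spikes == g2.spikes

    def test_latency_outside_window_raises(self, array):
        art = gen_artifact_truth(array, 14, T=55)
        protocol = StimulationProtocol(amplitudes=np.array([1.0, 2.0]), repeats=2)
        with pytest.raises(InvalidArgumentError):
            gen_stim_dataset(array, [], art, protocol, GroundTruth(),
                             NoiseModel(std=0.0), latency_range=(50, 60),
                             seed=0, stim_electrode=14)

    def test_empirical_activation_matches_logistic(self, array, spec):
        # Bernoulli frequency converges to the logistic probability
        art = gen_artifact_truth(array, 14, T=55)
        ei = gen_synthetic_ei(array, spec, T=32, seed=0)
        q, q50, slope = 1.2, 1.0, 0.15
        repeats = 500
        protocol = StimulationProtocol(amplitudes=np.array([q, 2 * q]), repeats=repeats)
        truth = GroundTruth(activation={0: (q50, slope)})
        _, realized = gen_stim_dataset(array, [ei], art, protocol, truth,
                                       NoiseModel(std=0.0), seed=3, stim_electrode=14)
        p = activation_probability(q, q50, slope)
        count = sum(len(realized.spikes[t]) for t in range(repeats))
        sigma = np.sqrt(repeats * p * (1 - p))
        assert abs(count - repeats * p) < 3 * sigma

    def test_latencies_within_range(self, array, spec):
        art = gen_artifact_truth(array, 14, T=55)
        ei = gen_synthetic_ei(array, spec, T=32, seed=0)
        protocol = StimulationProtocol(amplitudes=np.array([5.0, 10.0]), repeats=20)
        truth = GroundTruth(activation={0: (0.1, 0.05)})  # always fires
        _, realized = gen_stim_dataset(array, [ei], art, protocol, truth,
                                       NoiseModel(std=0.0), latency_range=(8, 12),
                                       seed=0, stim_electrode=14)
        lats = [lat for v in realized.spikes.values() for _, lat in v]
        assert lats and all(8 <= lat <= 12 for lat in lats)
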