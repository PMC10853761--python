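import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dynsort.core import (
    ElectricalImage,
    InputTemplate,
    StateSpaceModel,
    StimulationProtocol,
    build_grid_geometry,
    neighbors_within,
    simulate_lds,
)
from dynsort.errors import InvalidArgumentError, LookupError_, ShapeError


class TestGridGeometry:
    def test_paper_scale_array(self):
        arr = build_grid_geometry(16, 32, 60.0)
        assert arr.n_electrodes == 512
        d = arr.distances_from(0)
        assert np.min(d[d > 0]) == pytest.approx(60.0)

    def test_single_electrode(self):
        arr = build_grid_geometry(1, 1, 60.0)
        assert arr.n_electrodes == 1
        assert neighbors_within(arr, 0, 1000.0).size == 0

    def test_interior_neighbor_count_matches_brute_force(self):
        arr = build_grid_geometry(4, 4, 60.0)
        center = 5  # interior site
        # independent oracle: full pairwise distance table
        pos = arr.positions
        d = np.linalg.norm(pos - pos[center], axis=1)
        expected = np.sort(arr.ids[(d <= 61.0) & (arr.ids != center)])
        got = neighbors_within(arr, center, 61.0)
        np.testing.assert_array_equal(got, expected)
        assert got.size == 4

    def test_corner_radius_90_includes_diagonal(self):
        arr = build_grid_geometry(4, 4, 60.0)
        got = neighbors_within(arr, 0, 90.0)
        # 60 (x2 axial) and 84.85 (diagonal) are within 90
        assert got.size == 3

    def test_radius_zero(self):
        arr = build_grid_geometry(3, 3, 60.0)
        assert neighbors_within(arr, 4, 0.0, include_center=True).tolist() == [4]
        assert neighbors_within(arr, 4, 0.0, include_center=False).size == 0

    def test_unknown_center_raises(self):
        arr = build_grid_geometry(2, 2, 60.0)
        with pytest.raises(LookupError_):
            neighbors_within(arr, 99, 60.0)

    def test_invalid_dimensions_raise(self):
        with pytest.raises(InvalidArgumentError):
            build_grid_geometry(0, 4, 60.0)
        with pytest.raises(InvalidArgumentError):
            build_grid_geometry(4, 4, -1.0)

    @given(rows=st.integers(1, 5), cols=st.integers(1, 5))
    @settings(deadline=None, derandomize=True)
    def test_geometry_deterministic(self, rows, cols):
        a = build_grid_geometry(rows, cols, 60.0)
        b = build_grid_geometry(rows, cols, 60.0)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.ids, b.ids)


def _toy_model(a=0.5, m=1):
    A = np.eye(m) * a
    B = np.zeros((m, 2))
    B[0, 0] = 1.0
    pulses = np.zeros((2, 8))
    pulses[0, 0] = 1.0
    pulses[1, 4] = 1.0
    tmpl = InputTemplate(pulses=pulses, pulse_times=np.array([0, 4]), role="ei")
    return StateSpaceModel(A=A, B=B, electrode_subset=np.arange(m), template=tmpl,
                           role="ei", neuron_id=0)


class TestSimulateLds:
    def test_zero_input_zero_state_gives_zero(self):
        mod = _toy_model()
        out = simulate_lds(mod, np.zeros((2, 10)), n_electrodes=3)
        assert np.all(out == 0)

    def test_geometric_decay_from_single_pulse(self):
        mod = _toy_model(a=0.5)
        u = np.zeros((2, 6))
        u[0, 0] = 1.0
        out = simulate_lds(mod, u, n_electrodes=2)
        np.testing.assert_allclose(out[0], [0, 1, 0.5, 0.25, 0.125, 0.0625])
        assert np.all(out[1] == 0)  # outside subset

    def test_output_rows_off_subset_are_zero(self, agg6, rng):
        mod = agg6.ei_models[0]
        u = rng.standard_normal((2, 20))
        out = simulate_lds(mod, u, n_electrodes=36)
        off = np.setdiff1d(np.arange(36), mod.electrode_subset)
        assert np.all(out[off] == 0)

    @given(c=st.floats(-3, 3, allow_nan=False))
    @settings(deadline=None, derandomize=True)
    def test_superposition_and_scaling(self, c):
        mod = _toy_model(a=0.9)
        rng = np.random.default_rng(7)
        u = rng.standard_normal((2, 12))
        v = rng.standard_normal((2, 12))
        lhs = simulate_lds(mod, u + c * v, n_electrodes=1)
        rhs = simulate_lds(mod, u, n_electrodes=1) + c * simulate_lds(mod, v, n_electrodes=1)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_dimension_mismatch_raises(self):
        mod = _toy_model()
        with pytest.raises(ShapeError):
            simulate_lds(mod, np.zeros((3, 10)), n_electrodes=2)


class TestProtocolAndTypes:
    def test_charge_balance_enforced(self):
        with pytest.raises(InvalidArgumentError):
            StimulationProtocol(amplitudes=np.array([1.0, 2.0]), phase_ratios=(2, -3, 2))

    def test_amplitudes_must_increase(self):
        with pytest.raises(InvalidArgumentError):
            StimulationProtocol(amplitudes=np.array([2.0, 1.0]))

    def test_peak_amplitude_derived(self):
        ei = ElectricalImage(neuron_id=0, voltages=np.array([[0.0, -7.5, 3.0]]))
        assert ei.peak_amplitude == 7.5

    def test_artifact_model_rejects_stim_electrode_state(self):
        pulses = np.zeros((3, 5))
        tmpl = InputTemplate(pulses=pulses, pulse_times=np.array([0, 1, 2]), role="artifact")
        with pytest.raises(InvalidArgumentError):
            StateSpaceModel(
                A=np.eye(2) * 0.5, B=np.zeros((2, 3)),
                electrode_subset=np.array([3, 5]), template=tmpl,
                role="artifact", stim_electrode=5,
            )

    def test_unstable_model_warns(self):
        pulses = np.zeros((2, 5))
        pulses[0, 0] = pulses[1, 1] = 1.0
        tmpl = InputTemplate(pulses=pulses, pulse_times=np.array([0, 1]), role="ei")
        with pytest.warns(UserWarning, match="spectral radius"):
            StateSpaceModel(A=np.array([[1.5]]), B=np.ones((1, 2)),
                            electrode_subset=np.array([0]), template=tmpl,
                            role="ei", neuron_id=0)
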