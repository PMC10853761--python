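"""Shared domain types, MEA geometry and generic linear-system simulation.

Conventions used throughout the package:

* voltages in microvolts, currents in microamps, positions in micrometers;
* time is an integer sample index at a declared sampling rate (default
  20 kHz); sample 0 of a post-stimulation recording is the first sample
  after stimulus offset;
* a model's output matrix ``C`` is a *selection*: each state maps one-to-one
  onto one electrode of the array, and electrodes outside the model's subset
  read exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    InvalidArgumentError,
    LookupError_,
    ShapeError,
)

DEFAULT_SAMPLING_RATE_HZ = 20_000.0

EI_ROLE = "ei"
ARTIFACT_ROLE = "artifact"


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeArray:
    """Planar MEA geometry: electrode ids and (x, y) positions in um."""

    ids: np.ndarray
    positions: np.ndarray
    pitch: float

    def __post_init__(self) -> None:
        ids = np.asarray(self.ids, dtype=np.int64)
        pos = np.asarray(self.positions, dtype=np.float64)
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "positions", pos)
        if ids.ndim != 1 or ids.size < 1:
            raise InvalidArgumentError("need at least one electrode")
        if len(np.unique(ids)) != len(ids):
            raise InvalidArgumentError("electrode ids must be unique")
        if pos.shape != (ids.size, 2):
            raise ShapeError(f"positions must be ({ids.size}, 2), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise InvalidArgumentError("positions must be finite")
        if self.pitch <= 0:
            raise InvalidArgumentError("pitch must be positive")

    @property
    def n_electrodes(self) -> int:
        return int(self.ids.size)

    def index_of(self, electrode_id: int) -> int:
        """Positional index of an electrode id."""
        hits = np.flatnonzero(self.ids == electrode_id)
        if hits.size == 0:
            raise LookupError_(f"unknown electrode id {electrode_id}")
        return int(hits[0])

    def distances_from(self, electrode_id: int) -> np.ndarray:
        """Euclidean distance (um) from one electrode to every electrode."""
        center = self.positions[self.index_of(electrode_id)]
        return np.linalg.norm(self.positions - center, axis=1)


def build_grid_geometry(rows: int, cols: int, pitch: float) -> ElectrodeArray:
    """Rectangular lattice of ``rows x cols`` electrodes, row-major ids 0..E-1."""
    if rows < 1 or cols < 1:
        raise InvalidArgumentError("rows and cols must be >= 1")
    if pitch <= 0:
        raise InvalidArgumentError("pitch must be positive")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    positions = np.column_stack([cc.ravel() * pitch, rr.ravel() * pitch]).astype(float)
    return ElectrodeArray(ids=np.arange(rows * cols), positions=positions, pitch=float(pitch))


def neighbors_within(
    array: ElectrodeArray,
    center: int,
    radius: float,
    include_center: bool = False,
) -> np.ndarray:
    """Electrode ids at distance <= ``radius`` of ``center``, ascending ids.

    The center electrode itself is excluded unless ``include_center``.
    """
    dist = array.distances_from(center)
    mask = dist <= radius
    if not include_center:
        mask[array.index_of(center)] = False
    return np.sort(array.ids[mask])


# ---------------------------------------------------------------------------
# Signals
# ---------------------------------------------------------------------------

@dataclass
class ElectricalImage:
    """One neuron's mean spatiotemporal spike footprint (E x T, uV)."""

    neuron_id: int
    voltages: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=np.float64)
        if self.voltages.ndim != 2 or self.voltages.shape[1] < 2:
            raise ShapeError("voltages must be E x T with T >= 2")
        if not np.all(np.isfinite(self.voltages)):
            raise InvalidArgumentError("voltages must be finite")

    @property
    def n_electrodes(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[1]

    @property
    def peak_amplitude(self) -> float:
        """Largest absolute voltage anywhere on the array (uV)."""
        return float(np.max(np.abs(self.voltages)))


@dataclass
class InputTemplate:
    """Predefined pulse channels that drive a state-space model.

    EI templates carry two unit-magnitude pulses (spike onset / repolarization);
    artifact templates carry three pulses at the stimulation onset which are
    scaled by the stimulus amplitude at use.
    """

    pulses: np.ndarray
    pulse_times: np.ndarray
    role: str

    def __post_init__(self) -> None:
        self.pulses = np.asarray(self.pulses, dtype=np.float64)
        self.pulse_times = np.asarray(self.pulse_times, dtype=np.int64)
        if self.pulses.ndim != 2:
            raise ShapeError("pulses must be P x T")
        if self.role not in (EI_ROLE, ARTIFACT_ROLE):
            raise InvalidArgumentError(f"unknown template role {self.role!r}")
        expected = {EI_ROLE: 2, ARTIFACT_ROLE: 3}[self.role]
        if self.pulses.shape[0] != expected:
            raise ShapeError(
                f"{self.role} template needs {expected} channels, got {self.pulses.shape[0]}"
            )

    @property
    def n_channels(self) -> int:
        return self.pulses.shape[0]

    @property
    def n_samples(self) -> int:
        return self.pulses.shape[1]

    def shifted(self, shift: int, n_samples: int | None = None) -> np.ndarray:
        """Pulse channels delayed by ``shift`` samples (content pushed right)."""
        T = self.n_samples if n_samples is None else int(n_samples)
        out = np.zeros((self.n_channels, T))
        src = self.pulses[:, : max(0, T - shift)]
        if shift < T:
            out[:, shift : shift + src.shape[1]] = src
        return out


@dataclass
class StateSpaceModel:
    """Linear recursion x^{t+1} = A x^t + B u^t with a selection output.

    ``electrode_subset`` holds the positional electrode indices observed by the
    states (one state per electrode); the output is zero elsewhere.
    """

    A: np.ndarray
    B: np.ndarray
    electrode_subset: np.ndarray
    template: InputTemplate
    role: str
    neuron_id: int | None = None
    stim_electrode: int | None = None
    stability_tol: float = 1e-6

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=np.float64)
        self.B = np.asarray(self.B, dtype=np.float64)
        self.electrode_subset = np.asarray(self.electrode_subset, dtype=np.int64)
        m = self.electrode_subset.size
        if self.A.shape != (m, m):
            raise ShapeError(f"A must be {m}x{m}, got {self.A.shape}")
        if self.B.ndim != 2 or self.B.shape[0] != m:
            raise ShapeError(f"B must have {m} rows, got {self.B.shape}")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.B))):
            raise InvalidArgumentError("A and B must be finite")
        if self.role == ARTIFACT_ROLE and self.stim_electrode is not None:
            if self.stim_electrode in self.electrode_subset:
                raise InvalidArgumentError(
                    "stimulating electrode may not be a state of the artifact model"
                )
        rho = self.spectral_radius
        if rho > 1.0 + self.stability_tol:
            warnings.warn(
                f"model {self.role}:{self.neuron_id if self.neuron_id is not None else self.stim_electrode} "
                f"has spectral radius {rho:.4f} > 1 (transient fit may diverge)",
                stacklevel=2,
            )

    @property
    def order(self) -> int:
        return self.electrode_subset.size

    @property
    def spectral_radius(self) -> float:
        if self.A.size == 0:
            return 0.0
        return float(np.max(np.abs(np.linalg.eigvals(self.A))))


def simulate_lds(
    model: StateSpaceModel,
    inputs: np.ndarray,
    x0: np.ndarray | None = None,
    n_electrodes: int | None = None,
) -> np.ndarray:
    """Run the recursion and scatter the states onto the full array output.

    Parameters
    ----------
    inputs
        P x T input channels.
    x0
        Initial state (default zero).
    n_electrodes
        Number of output rows E (default: max subset index + 1).

    Returns
    -------
    E x T output; rows outside the model's electrode subset are exactly zero.
    """
    inputs = np.asarray(inputs, dtype=np.float64)
    if inputs.ndim != 2 or inputs.shape[0] != model.B.shape[1]:
        raise ShapeError(
            f"inputs must be {model.B.shape[1]} x T, got {inputs.shape}"
        )
    m = model.order
    T = inputs.shape[1]
    if x0 is None:
        x = np.zeros(m)
    else:
        x = np.asarray(x0, dtype=np.float64)
        if x.shape != (m,):
            raise ShapeError(f"x0 must have length {m}")
    E = int(n_electrodes) if n_electrodes is not None else int(model.electrode_subset.max()) + 1
    out = np.zeros((E, T))
    for t in range(T):
        out[model.electrode_subset, t] = x
        x = model.A @ x + model.B @ inputs[:, t]
    return out


# ---------------------------------------------------------------------------
# Recordings and protocol
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Trial-structured post-stimulation voltages: trials x T x E (uV)."""

    data: np.ndarray
    amplitudes: np.ndarray
    stim_electrode: int
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError("data must be trials x T x E")
        if self.amplitudes.shape != (self.data.shape[0],):
            raise ShapeError("one amplitude per trial required")
        if np.any(self.amplitudes < 0):
            raise InvalidArgumentError("amplitudes must be >= 0")
        if not np.all(np.isfinite(self.data)):
            raise InvalidArgumentError("recording data must be finite")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_electrodes(self) -> int:
        return self.data.shape[2]

    def trials_at(self, amplitude: float, rtol: float = 1e-9) -> np.ndarray:
        """Trial indices whose stimulation current matches ``amplitude``."""
        mask = np.isclose(self.amplitudes, amplitude, rtol=rtol, atol=0.0)
        return np.flatnonzero(mask)


@dataclass
class StimulationProtocol:
    """Amplitude grid and pulse shape of the stimulation experiment.

    Defaults mirror a charge-balanced, positive-first triphasic pulse with
    50 us phases in current ratios 2:-3:1, amplitudes quoted on the second
    phase.
    """

    amplitudes: np.ndarray
    repeats: int = 25
    phase_ratios: tuple[float, float, float] = (2.0, -3.0, 1.0)
    phase_duration_us: float = 50.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        if self.amplitudes.ndim != 1 or self.amplitudes.size < 1:
            raise InvalidArgumentError("need at least one amplitude")
        if np.any(np.diff(self.amplitudes) <= 0):
            raise InvalidArgumentError("amplitudes must be strictly increasing")
        if self.repeats < 1:
            raise InvalidArgumentError("repeats must be >= 1")
        if abs(sum(self.phase_ratios)) > 1e-12:
            raise InvalidArgumentError("phase ratios must sum to zero (charge balance)")

    @property
    def n_trials(self) -> int:
        return int(self.amplitudes.size) * int(self.repeats)
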