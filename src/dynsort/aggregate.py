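"""Block composition of EI models and the artifact model.

The aggregate system stacks all sub-model states block-diagonally; its output
on each electrode is the *sum* of the sub-model contributions there plus
measurement noise (superposition of spikes and artifact on the array). Noise
enters only at the output; there is no process noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import block_diag

from .core import ARTIFACT_ROLE, EI_ROLE, StateSpaceModel
from .errors import InvalidArgumentError, ShapeError
from .synthetic import NoiseModel


@dataclass(frozen=True)
class CorruptedSet:
    """Electrode ids to exclude from input estimation (default: stim electrode)."""

    electrodes: frozenset[int] = field(default_factory=frozenset)

    @classmethod
    def of(cls, *electrodes: int) -> "CorruptedSet":
        return cls(frozenset(int(e) for e in electrodes))

    def as_index_array(self) -> np.ndarray:
        return np.asarray(sorted(self.electrodes), dtype=np.int64)


@dataclass
class AggregateModel:
    """N EI models plus (optionally) one artifact model, stacked.

    Sub-models are ordered canonically: EI models by ascending neuron id,
    artifact last. ``state_slices`` and ``input_slices`` address each
    sub-model's block of the aggregate state / EI-input vectors.
    """

    ei_models: list[StateSpaceModel]
    artifact: StateSpaceModel | None
    n_electrodes: int
    A: np.ndarray = field(init=False)
    B: np.ndarray = field(init=False)          # m~ x 2N, EI inputs
    B_prime: np.ndarray = field(init=False)    # m~ x 3, artifact input
    C: np.ndarray = field(init=False)          # E x m~ summing selection
    state_slices: list[slice] = field(init=False)
    input_slices: list[slice] = field(init=False)

    def __post_init__(self) -> None:
        models: list[StateSpaceModel] = list(self.ei_models)
        if self.artifact is not None:
            models = models + [self.artifact]
        if not models:
            raise InvalidArgumentError("need at least one sub-model")
        for mod in models:
            if mod.electrode_subset.max() >= self.n_electrodes:
                raise InvalidArgumentError(
                    "sub-model electrode subset exceeds the array size"
                )
        self.A = block_diag(*[m.A for m in models]) if models else np.zeros((0, 0))
        m_total = self.A.shape[0]

        # state slices
        self.state_slices = []
        start = 0
        for mod in models:
            self.state_slices.append(slice(start, start + mod.order))
            start += mod.order

        # EI input matrix: block diagonal over EI models only
        n_ei = len(self.ei_models)
        self.B = np.zeros((m_total, 2 * n_ei))
        self.input_slices = []
        for i, mod in enumerate(self.ei_models):
            sl_in = slice(2 * i, 2 * i + 2)
            self.input_slices.append(sl_in)
            self.B[self.state_slices[i], sl_in] = mod.B

        self.B_prime = np.zeros((m_total, 3))
        if self.artifact is not None:
            self.B_prime[self.state_slices[-1], :] = self.artifact.B

        self.C = np.zeros((self.n_electrodes, m_total))
        for mod, sl in zip(models, self.state_slices):
            self.C[mod.electrode_subset, np.arange(sl.start, sl.stop)] += 1.0

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_neurons(self) -> int:
        return len(self.ei_models)

    @property
    def neuron_ids(self) -> list[int]:
        return [m.neuron_id for m in self.ei_models]

    def neuron_input_slice(self, neuron_id: int) -> slice:
        for mod, sl in zip(self.ei_models, self.input_slices):
            if mod.neuron_id == neuron_id:
                return sl
        raise InvalidArgumentError(f"no EI model for neuron {neuron_id}")


def assemble(
    ei_models: list[StateSpaceModel],
    artifact: StateSpaceModel | None,
    n_electrodes: int,
) -> AggregateModel:
    """Compose sub-models into one block system (EI models sorted by id)."""
    for mod in ei_models:
        if mod.role != EI_ROLE:
            raise InvalidArgumentError("ei_models must all have the EI role")
    if artifact is not None and artifact.role != ARTIFACT_ROLE:
        raise InvalidArgumentError("artifact model must have the artifact role")
    ordered = sorted(ei_models, key=lambda m: m.neuron_id)
    return AggregateModel(ei_models=ordered, artifact=artifact, n_electrodes=n_electrodes)


def simulate_aggregate(
    agg: AggregateModel,
    ei_inputs: np.ndarray,
    artifact_input: np.ndarray | None = None,
    noise: NoiseModel | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Simulate the aggregate from zero state: y^t = C x^t (+ Gaussian noise).

    ``ei_inputs`` is 2N x T; ``artifact_input`` is 3 x T (zeros if omitted).
    """
    ei_inputs = np.asarray(ei_inputs, dtype=np.float64)
    if ei_inputs.shape[0] != agg.B.shape[1]:
        raise ShapeError(f"ei_inputs must have {agg.B.shape[1]} rows")
    T = ei_inputs.shape[1]
    if artifact_input is None:
        artifact_input = np.zeros((3, T))
    artifact_input = np.asarray(artifact_input, dtype=np.float64)
    if artifact_input.shape != (3, T):
        raise ShapeError(f"artifact_input must be 3 x {T}")

    x = np.zeros(agg.n_states)
    out = np.zeros((agg.n_electrodes, T))
    for t in range(T):
        out[:, t] = agg.C @ x
        x = agg.A @ x + agg.B @ ei_inputs[:, t] + agg.B_prime @ artifact_input[:, t]
    if noise is not None and noise.std > 0:
        rng = np.random.default_rng(seed)
        out = out + noise.std * rng.standard_normal(out.shape)
    return out


def template_inputs(
    agg: AggregateModel,
    spikes: dict[int, int],
    T: int,
) -> np.ndarray:
    """Stacked EI inputs (2N x T) with each firing neuron's template at its latency.

    ``spikes`` maps neuron_id -> latency in samples; silent neurons get zero
    input.
    """
    U = np.zeros((2 * agg.n_neurons, T))
    for neuron_id, lat in spikes.items():
        sl = agg.neuron_input_slice(neuron_id)
        mod = next(m for m in agg.ei_models if m.neuron_id == neuron_id)
        U[sl, :] = mod.template.shifted(int(lat), T)
    return U
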