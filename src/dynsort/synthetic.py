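"""Synthetic MEA data with known ground truth.

Everything downstream (model identification, input estimation, spike
detection, activation analysis) is validated against data from this module:
grid geometries, biphasic spikes propagating along an axon path with
exponential spatial decay, amplitude-scaled stimulation-artifact transients
decaying radially from the stimulating electrode, Bernoulli spike activation
governed by a logistic function of log stimulus amplitude, and additive
i.i.d. Gaussian measurement noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .core import (
    DEFAULT_SAMPLING_RATE_HZ,
    ElectricalImage,
    ElectrodeArray,
    Recording,
    StimulationProtocol,
)
from .errors import InvalidArgumentError, LookupError_


@dataclass
class SyntheticNeuronSpec:
    """Geometry and waveform parameters of one simulated neuron.

    The neuron has a soma and a polyline axon; the spike waveform travels
    along the axon at ``conduction_speed`` (um per sample) and its amplitude
    on an electrode decays as exp(-d / decay_length) with d the distance to
    the nearest axon point.
    """

    soma_position: tuple[float, float]
    axon_path: np.ndarray
    peak_amplitude: float = 60.0   # uV, global extremum of the EI
    spike_width: float = 6.0       # samples, FWHM-ish width of the trough
    conduction_speed: float = 30.0  # um per sample
    decay_length: float = 35.0     # um

    def __post_init__(self) -> None:
        self.axon_path = np.atleast_2d(np.asarray(self.axon_path, dtype=np.float64))
        if self.peak_amplitude <= 0:
            raise InvalidArgumentError("peak_amplitude must be > 0")
        if self.conduction_speed <= 0:
            raise InvalidArgumentError("conduction_speed must be > 0")
        if self.decay_length <= 0:
            raise InvalidArgumentError("decay_length must be > 0")


@dataclass
class NoiseModel:
    """Additive i.i.d. Gaussian measurement noise (uV)."""

    std: float = 1.0
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.std < 0:
            raise InvalidArgumentError("noise std must be >= 0")
        if self.kind != "gaussian":
            raise InvalidArgumentError("only gaussian noise is supported")


@dataclass
class GroundTruth:
    """Realized evoked spikes per trial plus the true activation parameters.

    ``spikes[trial]`` is a list of (neuron_id, latency_samples); ``activation``
    maps neuron_id -> (q50 in uA, logistic slope in log-amplitude units).
    A q50 of ``inf`` means the neuron never activates.
    """

    spikes: dict[int, list[tuple[int, int]]] = field(default_factory=dict)
    activation: dict[int, tuple[float, float]] = field(default_factory=dict)

    def evoked_set(self, trial: int) -> frozenset[int]:
        return frozenset(n for n, _ in self.spikes.get(trial, []))


def activation_probability(q: float, q50: float, slope: float) -> float:
    """Logistic spiking probability in log amplitude: p = sigma((ln q - ln q50)/slope)."""
    if not np.isfinite(q50):
        return 0.0
    if q <= 0:
        return 0.0
    return float(expit((np.log(q) - np.log(q50)) / slope))


# ---------------------------------------------------------------------------
# Electrical images
# ---------------------------------------------------------------------------

def _resample_path(soma: np.ndarray, path: np.ndarray, step: float = 5.0) -> np.ndarray:
    """Dense polyline (soma prepended) sampled every ``step`` um."""
    pts = np.vstack([soma[None, :], path])
    out = [pts[0]]
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        length = np.linalg.norm(seg)
        if length == 0:
            continue
        n = max(1, int(np.ceil(length / step)))
        for i in range(1, n + 1):
            out.append(a + seg * (i / n))
    return np.asarray(out)


def _biphasic_waveform(t: np.ndarray, center: float, width: float) -> np.ndarray:
    # Difference of Gaussians: dominant negative trough, smaller positive overshoot.
    sigma = width / 2.355
    trough = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    overshoot = np.exp(-0.5 * ((t - center - 2.2 * sigma) / (1.6 * sigma)) ** 2)
    return -trough + 0.45 * overshoot


def gen_synthetic_ei(
    array: ElectrodeArray,
    spec: SyntheticNeuronSpec,
    T: int,
    seed: int,
    neuron_id: int = 0,
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
) -> ElectricalImage:
    """Biphasic spike footprint propagating along the neuron's axon.

    Each electrode's onset latency grows with arc length along the axon from
    the soma; amplitude decays exponentially with distance to the nearest
    axon point; the global extremum magnitude equals ``spec.peak_amplitude``
    exactly. Deterministic given ``seed`` (a small per-electrode gain jitter
    is the only random element).
    """
    rng = np.random.default_rng(seed)
    soma = np.asarray(spec.soma_position, dtype=np.float64)
    path = _resample_path(soma, spec.axon_path)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(path, axis=0), axis=1))])

    d2 = ((array.positions[:, None, :] - path[None, :, :]) ** 2).sum(axis=2)
    nearest = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(array.n_electrodes), nearest])
    latency = arc[nearest] / spec.conduction_speed  # samples, float

    onset = 2.0 + spec.spike_width  # keep the waveform ~zero at t = 0
    span = onset + latency.max() + 2.5 * spec.spike_width
    if T < span:
        raise InvalidArgumentError(
            f"T={T} too small for propagation span ({span:.0f} samples needed)"
        )

    gains = np.exp(-dist / spec.decay_length) * (1.0 + 0.1 * rng.standard_normal(array.n_electrodes))
    t = np.arange(T, dtype=np.float64)
    volts = gains[:, None] * _biphasic_waveform(t[None, :], onset + latency[:, None], spec.spike_width)
    volts *= spec.peak_amplitude / np.max(np.abs(volts))
    return ElectricalImage(neuron_id=neuron_id, voltages=volts, sampling_rate=sampling_rate)


# ---------------------------------------------------------------------------
# Artifact ground truth
# ---------------------------------------------------------------------------

def gen_artifact_truth(
    array: ElectrodeArray,
    stim_electrode: int,
    T: int,
    decay_length: float = 40.0,
    time_constant: float = 5.0,
    slow_time_constant: float = 40.0,
    slow_weight: float = 0.25,
    slow_decay_scale: float = 1.6,
    peak_uV_per_uA: float = 100.0,
) -> np.ndarray:
    """Unit-amplitude stimulation artifact, E x T (uV per uA).

    Each electrode records a transient that is the sum of a fast and a slow
    geometric decay (time constants in samples), starting one sample after
    the window opens; the slow tail spans roughly 2 ms at 20 kHz defaults.
    Amplitudes decay radially as exp(-d / decay_length); the slow component
    spreads over ``slow_decay_scale`` times the fast decay length (set it to
    1.0 for a purely rank-1 spatial profile). The artifact at stimulus
    amplitude q is exactly q times this matrix.
    """
    if time_constant <= 0 or slow_time_constant <= 0:
        raise InvalidArgumentError("time constants must be > 0")
    if stim_electrode not in array.ids:
        raise LookupError_(f"unknown stim electrode {stim_electrode}")
    dist = array.distances_from(stim_electrode)
    w_fast = np.exp(-dist / decay_length)
    w_slow = slow_weight * np.exp(-dist / (decay_length * slow_decay_scale))

    t = np.arange(T, dtype=np.float64)
    k_fast = np.where(t >= 1, np.exp(-(t - 1) / time_constant), 0.0)
    k_slow = np.where(t >= 1, np.exp(-(t - 1) / slow_time_constant), 0.0)

    art = np.outer(w_fast, k_fast) + np.outer(w_slow, k_slow)
    art *= peak_uV_per_uA / np.max(np.abs(art))
    return art


# ---------------------------------------------------------------------------
# Stimulation protocol helpers
# ---------------------------------------------------------------------------

def gen_amplitude_grid(n: int, lo: float, hi: float) -> np.ndarray:
    """``n`` log-spaced current amplitudes from ``lo`` to ``hi`` inclusive."""
    if lo <= 0:
        raise InvalidArgumentError("lo must be > 0 for log spacing")
    if hi <= lo:
        raise InvalidArgumentError("need lo < hi")
    if n < 2:
        raise InvalidArgumentError("need n >= 2")
    return np.geomspace(lo, hi, n)


def gen_stim_waveform(
    amplitude: float,
    protocol: StimulationProtocol,
    sampling_rate: float = DEFAULT_SAMPLING_RATE_HZ,
) -> np.ndarray:
    """Triphasic current time series (uA) with the second-phase magnitude = amplitude.

    Phases have equal duration and currents in the protocol's ratios
    (default 2:-3:1), so the net injected charge is zero.
    """
    if amplitude < 0:
        raise InvalidArgumentError("amplitude must be >= 0")
    spp = max(1, int(round(protocol.phase_duration_us * 1e-6 * sampling_rate)))
    scale = amplitude / abs(protocol.phase_ratios[1])
    return np.concatenate([np.full(spp, r * scale) for r in protocol.phase_ratios])


# ---------------------------------------------------------------------------
# Trial-structured dataset
# ---------------------------------------------------------------------------

def gen_stim_dataset(
    array: ElectrodeArray,
    eis: list[ElectricalImage],
    artifact_truth: np.ndarray,
    protocol: StimulationProtocol,
    truth: GroundTruth,
    noise: NoiseModel,
    latency_range: tuple[int, int] = (8, 12),
    seed: int = 0,
    stim_electrode: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Simulate every trial of the stimulation protocol.

    For each amplitude x repeat, each neuron spikes with Bernoulli probability
    given by its logistic activation curve; spiking neurons get a latency
    drawn uniformly from ``latency_range`` (inclusive, samples) and their EI
    is added at that offset. The trace is q x artifact + spikes + noise.
    Returns the recording and the realized spike labels (activation
    parameters copied over). Deterministic given ``seed``.
    """
    T = artifact_truth.shape[1]
    lo, hi = latency_range
    if lo < 0 or hi >= T or lo > hi:
        raise InvalidArgumentError(f"latency_range {latency_range} outside window [0, {T})")
    for ei in eis:
        if ei.n_electrodes != array.n_electrodes:
            raise InvalidArgumentError("all EIs must live on the given array")

    rng = np.random.default_rng(seed)
    n_trials = protocol.n_trials
    data = np.zeros((n_trials, T, array.n_electrodes))
    amplitudes = np.repeat(protocol.amplitudes, protocol.repeats)
    realized = GroundTruth(activation=dict(truth.activation))

    for trial, q in enumerate(amplitudes):
        trace = q * artifact_truth  # E x T
        trace = trace.copy()
        labels: list[tuple[int, int]] = []
        for ei in eis:
            q50, slope = truth.activation.get(ei.neuron_id, (np.inf, 1.0))
            p = activation_probability(q, q50, slope)
            if p > 0 and rng.random() < p:
                lat = int(rng.integers(lo, hi + 1))
                span = min(T - lat, ei.n_samples)
                trace[:, lat : lat + span] += ei.voltages[:, :span]
                labels.append((ei.neuron_id, lat))
        if noise.std > 0:
            trace = trace + noise.std * rng.standard_normal(trace.shape)
        data[trial] = trace.T
        realized.spikes[trial] = labels

    rec = Recording(
        data=data,
        amplitudes=amplitudes,
        stim_electrode=stim_electrode,
        sampling_rate=eis[0].sampling_rate if eis else DEFAULT_SAMPLING_RATE_HZ,
    )
    return rec, realized
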