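"""Stimulation-artifact state-space model identification.

The artifact model lives on the electrodes closest to the stimulating
electrode, with the stimulating electrode itself structurally excluded (it is
never a state, never an output, and its trace never enters any error
metric). Identification pools trial-averaged recordings across a set of
low-contamination amplitudes; the input is a fixed three-pulse template at
the stimulation onset, scaled linearly by the stimulus amplitude q.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np
from scipy.stats import trim_mean

from .core import (
    ARTIFACT_ROLE,
    ElectrodeArray,
    InputTemplate,
    Recording,
    StateSpaceModel,
    neighbors_within,
    simulate_lds,
)
from .errors import (
    EmptySelectionError,
    InsufficientDataError,
    InvalidArgumentError,
    LookupError_,
)
from .ei import _refine_simulation, _solve_blocks


def average_trials(
    recording: Recording,
    amplitude: float,
    trim: float = 0.1,
    trials: np.ndarray | None = None,
) -> np.ndarray:
    """Per-electrode trimmed mean over the trials at one amplitude (E x T).

    Trimming discards the given fraction from each tail of the per-sample
    trial distribution, which suppresses contamination from occasionally
    evoked spikes. ``trials`` optionally restricts the trial pool (used by
    the K-fold harness).
    """
    if not (0 <= trim < 0.5):
        raise InvalidArgumentError("trim must be in [0, 0.5)")
    idx = recording.trials_at(amplitude)
    if trials is not None:
        idx = np.intersect1d(idx, np.asarray(trials, dtype=np.int64))
    if idx.size == 0:
        raise LookupError_(f"no trials at amplitude {amplitude}")
    block = recording.data[idx]  # n x T x E
    if trim == 0:
        avg = block.mean(axis=0)
    else:
        avg = trim_mean(block, proportiontocut=trim, axis=0)
    return avg.T  # E x T


def averaged_by_amplitude(
    recording: Recording,
    trim: float = 0.1,
    trials: np.ndarray | None = None,
) -> dict[float, np.ndarray]:
    """Trial-averaged E x T matrix for every distinct amplitude."""
    return {
        float(q): average_trials(recording, q, trim=trim, trials=trials)
        for q in np.sort(np.unique(recording.amplitudes))
    }


def select_artifact_electrodes(
    array: ElectrodeArray, stim_electrode: int, radius: float
) -> np.ndarray:
    """Electrodes within ``radius`` um of the stimulating electrode, which is
    itself always excluded."""
    if radius <= 0:
        raise InvalidArgumentError("radius must be > 0")
    sel = neighbors_within(array, stim_electrode, radius, include_center=False)
    if sel.size == 0:
        raise EmptySelectionError(
            f"no electrodes within {radius} um of electrode {stim_electrode}"
        )
    return sel


def fit_artifact_template(
    averaged: Mapping[float, np.ndarray] | Sequence[np.ndarray],
    subset: np.ndarray,
) -> InputTemplate:
    """Three-channel unit-pulse template at the stimulation onset.

    The three pulses sit at consecutive onset samples t = 0, 1, 2 (disjoint
    single-sample supports); their effective gains are absorbed into B_a
    during model identification. The template is amplitude independent and is
    scaled by q at use (u_a = q r_a).
    """
    mats = list(averaged.values()) if isinstance(averaged, Mapping) else list(averaged)
    if len(mats) < 2:
        raise InsufficientDataError("need averaged data at >= 2 amplitudes")
    T = mats[0].shape[1]
    if T < 4:
        raise InvalidArgumentError("need at least 3 usable onset samples")
    pulses = np.zeros((3, T))
    for ch in range(3):
        pulses[ch, ch] = 1.0
    return InputTemplate(pulses=pulses, pulse_times=np.array([0, 1, 2]), role=ARTIFACT_ROLE)


def fit_artifact_model(
    averaged: Mapping[float, np.ndarray],
    amplitudes: Sequence[float],
    subset: np.ndarray,
    template: InputTemplate,
    ridge: float = 1e-3,
    stim_electrode: int | None = None,
    stability_tol: float = 0.05,
    refine_iters: int = 1000,
) -> StateSpaceModel:
    """Identify (A_a, B_a) from trial-averaged data pooled over amplitudes.

    States are the averaged voltages on ``subset``; every fitting amplitude q
    contributes its transitions with input q x template. The recursion is
    linear in q, so the fitted artifact scales exactly with the amplitude.

    As with the EI models, the one-step regression is polished against the
    *simulated*-trajectory error (one-step residuals from noisy averages
    compound over the 2+ ms transient). Linearity in q reduces the pooled
    objective to a single unit-amplitude target: the amplitude-weighted
    average of avg_q / q with weights q^2. ``refine_iters = 0`` disables.
    """
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise EmptySelectionError("artifact electrode subset is empty")
    if stim_electrode is not None and stim_electrode in subset:
        raise InvalidArgumentError("stimulating electrode may not be in the subset")
    amplitudes = list(amplitudes)
    if not amplitudes:
        raise InsufficientDataError("no fitting amplitudes given")
    Zs, Ys = [], []
    for q in amplitudes:
        M = averaged[q][subset]  # m x T
        U = q * template.pulses
        Zs.append(np.vstack([M[:, :-1], U[:, :-1]]))
        Ys.append(M[:, 1:])
    Z = np.hstack(Zs)
    Y = np.hstack(Ys)
    A, B = _solve_blocks(Z, Y, subset.size, template.n_channels, ridge)
    if refine_iters > 0:
        qs = np.asarray(amplitudes, dtype=np.float64)
        unit_target = sum(
            q * averaged[q][subset] for q in amplitudes
        ) / np.sum(qs**2)
        A, B = _refine_simulation(
            unit_target, template.pulses, A, B, max_iter=refine_iters
        )
    return StateSpaceModel(
        A=A,
        B=B,
        electrode_subset=subset,
        template=template,
        role=ARTIFACT_ROLE,
        stim_electrode=stim_electrode,
        stability_tol=stability_tol,
    )


def predict_artifact(
    model: StateSpaceModel, amplitude: float, n_electrodes: int, T: int | None = None
) -> np.ndarray:
    """Simulate the fitted artifact at one amplitude (E x T)."""
    T = model.template.n_samples if T is None else T
    u = amplitude * model.template.shifted(0, T)
    return simulate_lds(model, u, n_electrodes=n_electrodes)


def anrmse(measured: np.ndarray, predicted: np.ndarray, subset: np.ndarray) -> float:
    """Artifact-normalized RMSE over the subset electrodes x samples."""
    subset = np.asarray(subset, dtype=np.int64)
    if measured.shape != predicted.shape:
        raise InvalidArgumentError(
            f"shape mismatch: {measured.shape} vs {predicted.shape}"
        )
    ref = measured[subset]
    denom = np.sqrt(np.mean(ref**2))
    if denom == 0:
        raise ZeroDivisionError("measured artifact has zero RMS on the subset")
    return float(np.sqrt(np.mean((ref - predicted[subset]) ** 2)) / denom)


def lower_half_amplitudes(amplitudes: np.ndarray) -> np.ndarray:
    """Default low-contamination fitting set: the lower half of the grid.

    Averaging only works as an artifact estimate where stimulation does not
    systematically evoke spikes, i.e. at low amplitudes.
    """
    amplitudes = np.sort(np.unique(np.asarray(amplitudes, dtype=np.float64)))
    return amplitudes[: max(1, amplitudes.size // 2)]


def anrmse_curve(
    recording: Recording,
    model: StateSpaceModel,
    trim: float = 0.1,
    trials: np.ndarray | None = None,
) -> "np.ndarray":
    """ANRMSE of the fitted model vs the trial average, per amplitude.

    Returns a structured (n_amp, 2) array of (amplitude_uA, anrmse) rows in
    ascending amplitude order.
    """
    amps = np.sort(np.unique(recording.amplitudes))
    rows = []
    for q in amps:
        avg = average_trials(recording, q, trim=trim, trials=trials)
        pred = predict_artifact(model, q, recording.n_electrodes, recording.n_samples)
        rows.append((float(q), anrmse(avg, pred, model.electrode_subset)))
    return np.asarray(rows)
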