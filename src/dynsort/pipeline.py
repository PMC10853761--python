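"""End-to-end orchestration: simulate -> fit -> estimate -> sort -> activation.

This module glues the library stages together with one hyperparameter
container. It also houses the K-fold activation harness, which refits the
artifact model on K-1 trial folds and sorts the held-out fold, so that the
activation curves are built from data unseen during artifact training.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import artifact as am
from . import ei as eim
from .activation import ActivationCurve, build_activation_curve, fit_sigmoid, kfold_split
from .aggregate import AggregateModel, CorruptedSet, assemble
from .core import ElectricalImage, ElectrodeArray, Recording, StateSpaceModel
from .detect import SpikeCall, build_references, detect
from .estimator import build_window_operator, estimate_inputs_batch


@dataclass
class PipelineConfig:
    """Every hyperparameter of the sorting pipeline in one place.

    Units: thresholds are fractions, radii in um, ridges in squared uV,
    window and latencies in samples.
    """

    frac_threshold: float = 0.1      # EI relevant-electrode fraction of global peak
    abs_threshold: float = 0.0       # EI relevant-electrode absolute floor (uV)
    ei_ridge: float = 1e-3
    artifact_radius: float = 240.0   # state-selection radius around stim electrode
    artifact_ridge: float = 1e-3
    trim: float = 0.1                # trimmed-mean fraction for trial averaging
    fit_amplitudes: str = "lower-half"  # or "all"
    window: int = 10                 # estimator forward window L (0.5 ms)
    est_ridge: float = 300.0         # input ridge (uV^2); see docs/methods.md
    state_ridge: float = 1.0         # innovation-correction ridge
    theta: float = 0.5               # similarity detection threshold
    latency_range: tuple[int, int] = (0, 30)
    kfold: int = 5
    exclude_stim: bool = True
    seed: int = 0


@dataclass
class EIFitResult:
    models: list[StateSpaceModel]
    snrmse: dict[int, float] = field(default_factory=dict)


def fit_all_eis(eis: list[ElectricalImage], cfg: PipelineConfig) -> EIFitResult:
    """Select electrodes, design templates and fit one model per neuron."""
    models, errs = [], {}
    for ei in eis:
        subset = eim.select_relevant_electrodes(
            ei, abs_threshold=cfg.abs_threshold, frac_threshold=cfg.frac_threshold
        )
        template = eim.design_ei_template(ei)
        model = eim.fit_ei_model(ei, subset, template, ridge=cfg.ei_ridge)
        pred = eim.predict_ei(model, ei.n_electrodes)
        errs[ei.neuron_id] = eim.snrmse(ei, pred, subset)
        models.append(model)
    return EIFitResult(models=models, snrmse=errs)


def fit_artifact_from_recording(
    recording: Recording,
    array: ElectrodeArray,
    cfg: PipelineConfig,
    trials: np.ndarray | None = None,
) -> StateSpaceModel:
    """Trial-average, select states around the stim electrode, identify (A_a, B_a)."""
    averaged = am.averaged_by_amplitude(recording, trim=cfg.trim, trials=trials)
    subset = am.select_artifact_electrodes(
        array, recording.stim_electrode, cfg.artifact_radius
    )
    template = am.fit_artifact_template(averaged, subset)
    if cfg.fit_amplitudes == "lower-half":
        fit_amps = am.lower_half_amplitudes(np.array(list(averaged.keys())))
    elif cfg.fit_amplitudes == "all":
        fit_amps = np.array(list(averaged.keys()))
    else:
        raise ValueError(f"unknown fit_amplitudes {cfg.fit_amplitudes!r}")
    return am.fit_artifact_model(
        averaged,
        [float(q) for q in fit_amps],
        subset,
        template,
        ridge=cfg.artifact_ridge,
        stim_electrode=recording.stim_electrode,
    )


def sort_recording(
    recording: Recording,
    agg: AggregateModel,
    cfg: PipelineConfig,
    trials: np.ndarray | None = None,
) -> list[SpikeCall]:
    """Estimate inputs for (a subset of) trials and emit spike calls.

    All selected trials are estimated in one vectorized batch; the known
    artifact input of trial i is its amplitude times the artifact template.
    """
    idx = np.arange(recording.n_trials) if trials is None else np.asarray(trials)
    Y = recording.data[idx].transpose(0, 2, 1)  # batch x E x T
    T = recording.n_samples
    if agg.artifact is not None:
        r_a = agg.artifact.template.shifted(0, T)
    else:
        r_a = np.zeros((3, T))
    Ua = recording.amplitudes[idx][:, None, None] * r_a[None, :, :]
    excluded = (
        CorruptedSet.of(recording.stim_electrode) if cfg.exclude_stim else CorruptedSet()
    )
    operator = build_window_operator(agg, cfg.window, excluded)
    references = build_references(
        agg, latency_range=cfg.latency_range, L=cfg.window, ridge=cfg.est_ridge,
        state_ridge=cfg.state_ridge, excluded=excluded, operator=operator,
    )
    estimates = estimate_inputs_batch(
        Y, agg, Ua, excluded=excluded, L=cfg.window, ridge=cfg.est_ridge,
        state_ridge=cfg.state_ridge, operator=operator,
    )
    calls: list[SpikeCall] = []
    for b, trial in enumerate(idx):
        calls.extend(
            detect(
                estimates[b],
                agg,
                threshold=cfg.theta,
                latency_range=cfg.latency_range,
                trial=int(trial),
                amplitude=float(recording.amplitudes[trial]),
                references=references,
            )
        )
    return calls


def sort_with_artifact_fit(
    recording: Recording,
    array: ElectrodeArray,
    ei_models: list[StateSpaceModel],
    cfg: PipelineConfig,
) -> tuple[list[SpikeCall], AggregateModel]:
    """Fit the artifact from the recording, assemble, and sort every trial."""
    art = fit_artifact_from_recording(recording, array, cfg)
    agg = assemble(ei_models, art, array.n_electrodes)
    return sort_recording(recording, agg, cfg), agg


def kfold_activation(
    recording: Recording,
    array: ElectrodeArray,
    ei_models: list[StateSpaceModel],
    neuron_id: int,
    cfg: PipelineConfig,
) -> tuple[list[ActivationCurve], ActivationCurve]:
    """Per-fold activation curves for one neuron-electrode pair, plus pooled.

    For each of K folds the artifact model is fit on the other K-1 folds and
    the held-out trials are sorted; every trial is therefore scored exactly
    once by a model that never saw it.
    """
    folds = kfold_split(recording, cfg.kfold, seed=cfg.seed)
    all_calls: list[SpikeCall] = []
    per_fold: list[ActivationCurve] = []
    for held_out in folds:
        train = np.setdiff1d(np.arange(recording.n_trials), held_out)
        art = fit_artifact_from_recording(recording, array, cfg, trials=train)
        agg = assemble(ei_models, art, array.n_electrodes)
        calls = sort_recording(recording, agg, cfg, trials=held_out)
        all_calls.extend(calls)
        curve = build_activation_curve(calls, neuron_id, recording.stim_electrode)
        fit_sigmoid(curve)
        per_fold.append(curve)
    pooled = build_activation_curve(all_calls, neuron_id, recording.stim_electrode)
    fit_sigmoid(pooled)
    return per_fold, pooled


def with_seed(cfg: PipelineConfig, seed: int) -> PipelineConfig:
    return replace(cfg, seed=seed)
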