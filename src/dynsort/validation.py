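"""Self-contained validation studies on synthetic ground truth.

Each study builds its own synthetic preparation (geometry, neurons, artifact,
protocol), runs the relevant pipeline stages and returns plain-number
summaries. The studies mirror the method's synthetic-validation logic:
noiseless round trips must be exact, detection must agree with brute-force
enumeration, artifact-model error must fall with stimulus amplitude, and
activation thresholds recovered by the full pipeline must track the ground
truth.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from . import artifact as am
from . import ei as eim
from .activation import build_activation_curve, compare_thresholds, fit_sigmoid
from .aggregate import CorruptedSet, assemble, simulate_aggregate, template_inputs
from .core import (
    ElectricalImage,
    ElectrodeArray,
    InputTemplate,
    StateSpaceModel,
    StimulationProtocol,
    build_grid_geometry,
    simulate_lds,
)
from .detect import build_hypothesis_bank, build_references, detect, oracle_enumerate, sorting_accuracy
from .estimator import estimate_inputs, estimate_inputs_batch, input_rmse
from .pipeline import (
    PipelineConfig,
    fit_all_eis,
    fit_artifact_from_recording,
    kfold_activation,
    sort_recording,
)
from .synthetic import (
    GroundTruth,
    NoiseModel,
    SyntheticNeuronSpec,
    gen_amplitude_grid,
    gen_artifact_truth,
    gen_stim_dataset,
    gen_stim_waveform,
    gen_synthetic_ei,
)

T_WINDOW = 55       # post-stimulus analysis window (2.75 ms at 20 kHz)
T_EI = 40           # synthetic EI duration used in the studies


def make_neurons(
    array: ElectrodeArray,
    n: int,
    seed: int,
    peak_range: tuple[float, float] = (40.0, 120.0),
) -> list[SyntheticNeuronSpec]:
    """Neurons with somas spread over the array interior and random axons."""
    rng = np.random.default_rng(seed)
    lo = array.positions.min(axis=0) + 1.2 * array.pitch
    hi = array.positions.max(axis=0) - 1.2 * array.pitch
    span = hi - lo
    specs = []
    # quasi-regular soma placement: jittered grid positions
    grid = int(np.ceil(np.sqrt(n)))
    cells = [(i, j) for i in range(grid) for j in range(grid)][:n]
    for k, (i, j) in enumerate(cells):
        soma = lo + span * (np.array([i, j]) + 0.5 + 0.3 * rng.uniform(-1, 1, 2)) / grid
        angle = rng.uniform(0, 2 * np.pi)
        direction = np.array([np.cos(angle), np.sin(angle)])
        axon = soma[None, :] + np.outer(np.linspace(40, 220, 4), direction)
        peak = rng.uniform(*peak_range)
        specs.append(
            SyntheticNeuronSpec(
                soma_position=tuple(soma),
                axon_path=axon,
                peak_amplitude=peak,
            )
        )
    return specs


def make_eis(
    array: ElectrodeArray, specs: list[SyntheticNeuronSpec], seed: int, T: int = T_EI
) -> list[ElectricalImage]:
    return [
        gen_synthetic_ei(array, spec, T=T, seed=seed + i, neuron_id=i)
        for i, spec in enumerate(specs)
    ]


def _fit_artifact_noiseless(
    array: ElectrodeArray,
    stim_electrode: int,
    cfg: PipelineConfig,
    amplitudes: np.ndarray,
    T: int = T_WINDOW,
    ridge: float = 1e-9,
) -> StateSpaceModel:
    """Identify the artifact model from noiseless spike-free averages."""
    truth = gen_artifact_truth(array, stim_electrode, T)
    averaged = {float(q): q * truth for q in amplitudes}
    subset = am.select_artifact_electrodes(array, stim_electrode, cfg.artifact_radius)
    template = am.fit_artifact_template(averaged, subset)
    return am.fit_artifact_model(
        averaged,
        list(averaged.keys()),
        subset,
        template,
        ridge=ridge,
        stim_electrode=stim_electrode,
    )


# ---------------------------------------------------------------------------
# Study 1 + 2: noiseless round trip, with and without electrode exclusion
# ---------------------------------------------------------------------------

def noiseless_roundtrip_study(seed: int = 0) -> dict:
    """Invert aggregate-simulated data for 1, 2 and 3 firing neurons, exactly.

    A 16 x 16 array with 8 fitted EI models and one artifact model; data are
    generated by injecting the neurons' own input templates plus the scaled
    artifact template, with zero noise. Reports the worst per-neuron input
    RMSE, the sorting accuracy, and whether excluding the stimulating
    electrode changes any spike call.
    """
    array = build_grid_geometry(16, 16, 60.0)
    cfg = PipelineConfig()
    specs = make_neurons(array, 8, seed=seed)
    eis = make_eis(array, specs, seed=seed)
    fit = fit_all_eis(eis, cfg)
    stim = array.ids[array.index_of(7 * 16 + 7)]
    art = _fit_artifact_noiseless(array, stim, cfg, gen_amplitude_grid(6, 0.1, 1.0))
    agg = assemble(fit.models, art, array.n_electrodes)

    q = 1.0
    u_a = q * art.template.shifted(0, T_WINDOW)
    firing_sets = [{0: 10}, {1: 9, 4: 11}, {2: 8, 5: 10, 7: 12}]
    worst_rmse = 0.0
    calls_plain, calls_excl = [], []
    truth = GroundTruth()
    for trial, spikes in enumerate(firing_sets):
        U_true = template_inputs(agg, spikes, T_WINDOW)
        y = simulate_aggregate(agg, U_true, u_a)
        for excl, sink in ((CorruptedSet(), calls_plain),
                           (CorruptedSet.of(stim), calls_excl)):
            est = estimate_inputs(y, agg, u_a, excluded=excl, L=cfg.window, ridge=0.0)
            if not excl.electrodes:
                worst_rmse = max(worst_rmse, max(input_rmse(est, U_true).values()))
            sink.extend(
                detect(est, agg, threshold=cfg.theta,
                       latency_range=cfg.latency_range, trial=trial, amplitude=q)
            )
        truth.spikes[trial] = list(spikes.items())

    acc = sorting_accuracy(calls_plain, truth)["accuracy"]
    same = all(
        a.neuron_id == b.neuron_id and a.trial == b.trial and a.detected == b.detected
        and (a.latency == b.latency)
        for a, b in zip(calls_plain, calls_excl)
    )
    return {
        "max_input_rmse": worst_rmse,
        "sorting_accuracy": acc,
        "exclusion_calls_identical": same,
    }


# ---------------------------------------------------------------------------
# Study 3: oracle agreement
# ---------------------------------------------------------------------------

def oracle_agreement_study(
    seed: int = 0,
    n_trials: int = 200,
    noise_std: float = 1.0,
    n_noiseless: int = 40,
) -> dict:
    """Detector vs exhaustive enumeration on a 36-electrode, 4-neuron fixture."""
    array = build_grid_geometry(6, 6, 60.0)
    cfg = PipelineConfig(artifact_radius=150.0, latency_range=(0, 10))
    specs = make_neurons(array, 4, seed=seed, peak_range=(40.0, 90.0))
    eis = make_eis(array, specs, seed=seed + 100, T=32)
    fit = fit_all_eis(eis, cfg)
    stim = array.ids[array.index_of(2 * 6 + 2)]
    art = _fit_artifact_noiseless(array, stim, cfg, gen_amplitude_grid(6, 0.1, 1.0), T=T_WINDOW)
    agg = assemble(fit.models, art, array.n_electrodes)

    rng = np.random.default_rng(seed + 7)
    q = 1.0
    u_a = q * art.template.shifted(0, T_WINDOW)

    bank = build_hypothesis_bank(agg, T_WINDOW, latency_range=cfg.latency_range,
                                 max_neurons=4)

    def run(n: int, std: float, ridge: float) -> float:
        agree = 0
        refs = build_references(
            agg, latency_range=cfg.latency_range, L=cfg.window, ridge=ridge,
            state_ridge=cfg.state_ridge,
        )
        Ys, spikes_list = [], []
        for _ in range(n):
            spikes = {
                nid: int(rng.integers(0, 11))
                for nid in agg.neuron_ids
                if rng.random() < 0.35
            }
            U = template_inputs(agg, spikes, T_WINDOW)
            y = simulate_aggregate(agg, U, u_a)
            if std > 0:
                y = y + std * rng.standard_normal(y.shape)
            Ys.append(y)
            spikes_list.append(spikes)
        ests = estimate_inputs_batch(
            np.stack(Ys), agg, np.tile(u_a, (n, 1, 1)),
            L=cfg.window, ridge=ridge, state_ridge=cfg.state_ridge,
        )
        for est, y, spikes in zip(ests, Ys, spikes_list):
            calls = detect(est, agg, threshold=cfg.theta,
                           latency_range=cfg.latency_range, references=refs)
            detected = {c.neuron_id for c in calls if c.detected}
            oracle = oracle_enumerate(
                y, agg, u_a, latency_range=cfg.latency_range, max_neurons=4,
                bank=bank,
            )
            agree += detected == {n_ for n_, _ in oracle}
        return agree / n

    return {
        "agreement_noisy": run(n_trials, noise_std, cfg.est_ridge),
        "agreement_noiseless": run(n_noiseless, 0.0, 0.0),
    }


# ---------------------------------------------------------------------------
# Study 4: identification round trips
# ---------------------------------------------------------------------------

def identification_roundtrip_study(seed: int = 0) -> dict:
    """Simulate-then-refit for both model families at ridge 0."""
    rng = np.random.default_rng(seed)

    # (a) EI model
    m, T = 6, 50
    A = rng.standard_normal((m, m))
    A *= 0.8 / np.max(np.abs(np.linalg.eigvals(A)))
    B = rng.standard_normal((m, 2))
    pulses = np.zeros((2, T))
    pulses[0, 3] = 1.0
    pulses[1, 9] = 1.0
    template = InputTemplate(pulses=pulses, pulse_times=np.array([3, 9]), role="ei")
    subset = np.arange(m)
    true_model = StateSpaceModel(A=A, B=B, electrode_subset=subset, template=template,
                                 role="ei", neuron_id=0)
    ei = ElectricalImage(neuron_id=0, voltages=simulate_lds(true_model, pulses, n_electrodes=m))
    refit = eim.fit_ei_model(ei, subset, template, ridge=0.0)
    ei_err = eim.snrmse(ei, eim.predict_ei(refit, m), subset)

    # (b) artifact model, linear in q
    array = build_grid_geometry(6, 6, 60.0)
    stim = 14
    sub = am.select_artifact_electrodes(array, stim, radius=100.0)
    ma = sub.size
    Aa = rng.standard_normal((ma, ma))
    Aa *= 0.75 / np.max(np.abs(np.linalg.eigvals(Aa)))
    Ba = rng.standard_normal((ma, 3))
    Tw = T_WINDOW
    r_a = np.zeros((3, Tw))
    for ch in range(3):
        r_a[ch, ch] = 1.0
    atemplate = InputTemplate(pulses=r_a, pulse_times=np.array([0, 1, 2]), role="artifact")
    true_art = StateSpaceModel(A=Aa, B=Ba, electrode_subset=sub, template=atemplate,
                               role="artifact", stim_electrode=stim)
    amps = gen_amplitude_grid(8, 0.1, 4.1)
    averaged = {
        float(q): simulate_lds(true_art, q * r_a, n_electrodes=array.n_electrodes)
        for q in amps
    }
    refit_a = am.fit_artifact_model(
        averaged, list(averaged.keys()), sub, atemplate, ridge=0.0, stim_electrode=stim
    )
    worst = max(
        am.anrmse(averaged[q], am.predict_artifact(refit_a, q, array.n_electrodes, Tw), sub)
        for q in averaged
    )
    pred1 = am.predict_artifact(refit_a, 1.3, array.n_electrodes, Tw)
    pred2 = am.predict_artifact(refit_a, 2.6, array.n_electrodes, Tw)
    scaling = float(np.max(np.abs(pred2 - 2 * pred1)) / np.max(np.abs(pred2)))
    return {
        "ei_roundtrip_snrmse": float(ei_err),
        "artifact_roundtrip_anrmse_max": float(worst),
        "artifact_doubling_relative_error": scaling,
    }


# ---------------------------------------------------------------------------
# Study 5: noise sensitivity of input retrieval
# ---------------------------------------------------------------------------

def make_clustered_neurons(
    array: ElectrodeArray,
    n: int,
    seed: int,
    cluster_radius: float = 130.0,
    peak_range: tuple[float, float] = (40.0, 120.0),
) -> list[SyntheticNeuronSpec]:
    """Neurons packed around the array center with overlapping footprints.

    Dense retinal preparations put many cells over shared electrodes; this
    layout exercises the regime where simultaneously firing neurons compete
    for the same measurements.
    """
    rng = np.random.default_rng(seed)
    center = array.positions.mean(axis=0)
    specs = []
    for k in range(n):
        ang = 2 * np.pi * k / n
        soma = center + (cluster_radius * rng.uniform(0.4, 1.0)) * np.array(
            [np.cos(ang), np.sin(ang)]
        )
        direction = np.array([np.cos(ang + rng.uniform(-0.6, 0.6)),
                              np.sin(ang + rng.uniform(-0.6, 0.6))])
        axon = soma[None, :] + np.outer(np.linspace(40, 220, 4), direction)
        specs.append(
            SyntheticNeuronSpec(
                soma_position=tuple(soma),
                axon_path=axon,
                peak_amplitude=rng.uniform(*peak_range),
            )
        )
    return specs


def noise_sensitivity_study(
    seed: int = 0,
    stds: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0),
    n_trials: int = 20,
) -> dict:
    """Input-estimation RMSE vs measurement-noise std, for 1 and 3 firing neurons.

    The RMSE is taken over the full stacked input vector (all neurons'
    channels x time) against its ground truth, so every firing neuron
    contributes its estimation error and cross-talk to the total. Uses a
    clustered-neuron preparation (overlapping electrical images), the regime
    where simultaneously firing cells compete for the same electrodes.
    """
    array = build_grid_geometry(16, 16, 60.0)
    cfg = PipelineConfig()
    specs = make_clustered_neurons(array, 8, seed=seed)
    eis = make_eis(array, specs, seed=seed)
    fit = fit_all_eis(eis, cfg)
    stim = array.ids[array.index_of(7 * 16 + 7)]
    art = _fit_artifact_noiseless(array, stim, cfg, gen_amplitude_grid(6, 0.1, 1.0))
    agg = assemble(fit.models, art, array.n_electrodes)
    u_a = 1.0 * art.template.shifted(0, T_WINDOW)

    # paired design: each base trial fixes 3 firing neurons, their latencies
    # and one noise field; the 1-neuron condition reuses the first neuron and
    # the identical noise, so the multi-vs-single comparison isolates
    # cross-talk rather than sampling fluctuation.
    rng = np.random.default_rng(seed + 13)
    trials = []
    for _ in range(n_trials):
        ids = rng.choice(agg.neuron_ids, size=3, replace=False)
        spikes3 = {int(i): int(rng.integers(8, 13)) for i in ids}
        noise_field = rng.standard_normal((agg.n_electrodes, T_WINDOW))
        trials.append((spikes3, noise_field))

    out: dict[float, dict[int, float]] = {}
    for std in stds:
        out[std] = {}
        for n_fire in (1, 3):
            Ys, Us = [], []
            for spikes3, noise_field in trials:
                spikes = spikes3 if n_fire == 3 else dict([next(iter(spikes3.items()))])
                U = template_inputs(agg, spikes, T_WINDOW)
                y = simulate_aggregate(agg, U, u_a) + std * noise_field
                Ys.append(y)
                Us.append((U, spikes))
            ests = estimate_inputs_batch(
                np.stack(Ys), agg, np.tile(u_a, (n_trials, 1, 1)),
                L=cfg.window, ridge=cfg.est_ridge, state_ridge=cfg.state_ridge,
            )
            rmses = [
                float(np.sqrt(np.mean((est.u_hat - U) ** 2)))
                for est, (U, spikes) in zip(ests, Us)
            ]
            out[std][n_fire] = float(np.mean(rmses))
    return {"rmse": out}


# ---------------------------------------------------------------------------
# Study 6: ANRMSE vs amplitude trend
# ---------------------------------------------------------------------------

def anrmse_trend_study(seed: int = 0) -> dict:
    """Spike-free noisy artifacts across the full 39-amplitude grid."""
    array = build_grid_geometry(10, 10, 60.0)
    cfg = PipelineConfig()
    stim = array.ids[array.index_of(4 * 10 + 4)]
    truth_art = gen_artifact_truth(array, stim, T_WINDOW)
    protocol = StimulationProtocol(amplitudes=gen_amplitude_grid(39, 0.1, 4.1), repeats=25)
    rec, _ = gen_stim_dataset(
        array, [], truth_art, protocol, GroundTruth(), NoiseModel(std=1.0),
        seed=seed, stim_electrode=stim,
    )
    model = fit_artifact_from_recording(rec, array, cfg)
    curve = am.anrmse_curve(rec, model, trim=cfg.trim)
    rho = spearmanr(curve[:, 0], curve[:, 1]).statistic
    return {
        "spearman": float(rho),
        "anrmse_low": float(curve[0, 1]),
        "anrmse_high": float(curve[-1, 1]),
    }


# ---------------------------------------------------------------------------
# Study 7: threshold recovery through the full pipeline
# ---------------------------------------------------------------------------

def threshold_recovery_study(
    seed: int = 0,
    n_pairs: int = 10,
    noise_std: float = 1.0,
    kfold_pairs: int = 3,
) -> dict:
    """Recover known logistic activation thresholds for 10 neuron-electrode pairs.

    One 16 x 16 preparation with ``n_pairs`` neurons; each pair stimulates
    the electrode nearest one neuron's soma with the full 39 x 25 protocol.
    The target neuron's true q50 values are log spaced over 0.8-3.2 uA
    (slope 0.1 in log amplitude); all other neurons stay silent. For the
    first ``kfold_pairs`` pairs a 5-fold analysis quantifies the per-fold
    threshold spread.
    """
    array = build_grid_geometry(16, 16, 60.0)
    cfg = PipelineConfig(seed=seed)
    specs = make_neurons(array, n_pairs, seed=seed)
    eis = make_eis(array, specs, seed=seed)
    fit = fit_all_eis(eis, cfg)
    protocol = StimulationProtocol(amplitudes=gen_amplitude_grid(39, 0.1, 4.1), repeats=25)
    true_q50 = gen_amplitude_grid(n_pairs, 0.8, 3.2)
    slope = 0.1

    recovered = np.full(n_pairs, np.nan)
    kfold_spread: list[float] = []
    for pair in range(n_pairs):
        target = pair
        soma = np.asarray(specs[pair].soma_position)
        stim = int(array.ids[np.argmin(np.linalg.norm(array.positions - soma, axis=1))])
        truth_art = gen_artifact_truth(array, stim, T_WINDOW)
        truth = GroundTruth(activation={
            nid: ((float(true_q50[pair]), slope) if nid == target else (np.inf, 1.0))
            for nid in range(n_pairs)
        })
        rec, realized = gen_stim_dataset(
            array, eis, truth_art, protocol, truth, NoiseModel(std=noise_std),
            seed=seed + 1000 + pair, stim_electrode=stim,
        )
        art = fit_artifact_from_recording(rec, array, cfg)
        agg = assemble(fit.models, art, array.n_electrodes)
        calls = sort_recording(rec, agg, cfg)
        curve = build_activation_curve(
            [c for c in calls if c.neuron_id == target], target, stim
        )
        q50, _, converged = fit_sigmoid(curve)
        if converged:
            recovered[pair] = q50
        if pair < kfold_pairs:
            per_fold, _ = kfold_activation(rec, array, fit.models, target, cfg)
            vals = [c.threshold for c in per_fold if np.isfinite(c.threshold)]
            if len(vals) == cfg.kfold:
                kfold_spread.append((max(vals) - min(vals)) / float(true_q50[pair]))
            else:
                kfold_spread.append(np.inf)

    rel_err = np.abs(recovered - true_q50) / true_q50
    r2, n_used = compare_thresholds(true_q50, recovered)
    return {
        "true_q50": true_q50.tolist(),
        "recovered_q50": recovered.tolist(),
        "median_rel_error": float(np.nanmedian(rel_err)),
        "r2": float(r2),
        "n_pairs_compared": int(n_used),
        "kfold_spread_frac": [float(s) for s in kfold_spread],
    }


# ---------------------------------------------------------------------------
# Study 8: protocol conformance
# ---------------------------------------------------------------------------

def protocol_conformance() -> dict:
    """Check the stimulus generator against the printed protocol."""
    amps = gen_amplitude_grid(39, 0.1, 4.1)
    protocol = StimulationProtocol(amplitudes=amps, repeats=25)
    wave = gen_stim_waveform(3.0, protocol)
    spp = wave.size // 3
    phases = wave.reshape(3, spp).mean(axis=1)
    ratios_ok = np.allclose(phases, [2.0, -3.0, 1.0])
    log_ratios = np.diff(np.log(amps))
    return {
        "n_amplitudes": int(amps.size),
        "first_uA": float(amps[0]),
        "last_uA": float(amps[-1]),
        "log_spacing_max_dev": float(np.max(np.abs(log_ratios - log_ratios[0]))),
        "repeats": int(protocol.repeats),
        "phase_ratio_ok": bool(ratios_ok),
        "net_charge": float(wave.sum() * protocol.phase_duration_us / spp),
        "n_trials": int(protocol.n_trials),
    }
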