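"""Template-similarity spike detection and a brute-force oracle.

Estimated input sequences are compared to each neuron's two-pulse template
with a shift-maximized cosine similarity; a spike is called when the score
reaches a threshold. For small instances an exhaustive enumeration oracle
(every neuron subset x every latency combination, scored by residual sum of
squares against the aggregate model) provides an independent check of the
detector.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .aggregate import AggregateModel, CorruptedSet, simulate_aggregate, template_inputs
from .core import InputTemplate, simulate_lds
from .errors import InvalidArgumentError, SizeError
from .estimator import InputEstimate, WindowOperator, estimate_inputs_batch
from .synthetic import GroundTruth


@dataclass
class SpikeCall:
    """One neuron's detection decision on one trial."""

    neuron_id: int
    trial: int
    amplitude: float
    detected: bool
    latency: int | None
    score: float


def similarity(
    u_hat_n: np.ndarray,
    template: InputTemplate,
    latency_range: tuple[int, int],
    zero_tol: float = 1e-8,
) -> tuple[float, int]:
    """Shift-maximized cosine between an estimated input block and a template.

    Returns (score, latency); score is in [-1, 1] and 0 by convention for a
    (numerically) zero estimate: cosine is scale invariant, so an estimate
    whose norm is below ``zero_tol`` times the template norm scores 0 rather
    than an arbitrary direction match. The template is shifted by every
    integer latency in the inclusive range and the best normalized inner
    product wins.
    """
    lo, hi = latency_range
    if hi < lo:
        raise InvalidArgumentError("latency_range is empty")
    u_hat_n = np.asarray(u_hat_n, dtype=np.float64)
    T = u_hat_n.shape[1]
    nu = np.linalg.norm(u_hat_n)
    if nu <= zero_tol * np.linalg.norm(template.pulses):
        return 0.0, int(lo)
    best_score, best_lat = -np.inf, lo
    for s in range(lo, hi + 1):
        shifted = template.shifted(s, T)
        nt = np.linalg.norm(shifted)
        if nt == 0:
            continue
        score = float(np.sum(u_hat_n * shifted) / (nu * nt))
        if score > best_score:
            best_score, best_lat = score, s
    if not np.isfinite(best_score):
        return 0.0, int(lo)
    return best_score, int(best_lat)


@dataclass
class DetectionReferences:
    """Estimate-domain spike signatures: the estimator's noiseless response
    to each neuron firing alone at each candidate latency.

    The estimator is linear in the measurements, so the systematic part of a
    noisy trial's input estimate is exactly the sum of these references for
    the neurons that fired. Scoring against them (rather than the raw pulse
    template) makes detection invariant to the ridge bias and temporal
    smearing the estimator itself introduces; with an exact (ridge 0)
    estimator each reference *is* the shifted input template.
    """

    refs: dict[tuple[int, int], np.ndarray]
    latency_range: tuple[int, int]


def build_references(
    agg: AggregateModel,
    latency_range: tuple[int, int] = (0, 30),
    L: int = 10,
    ridge: float = 300.0,
    state_ridge: float = 1.0,
    excluded: CorruptedSet | None = None,
    operator: WindowOperator | None = None,
) -> DetectionReferences:
    """Run the estimator on every clean single-spike response."""
    lo, hi = latency_range
    T = None
    keys, Ys = [], []
    for mod in agg.ei_models:
        for s in range(lo, hi + 1):
            U = template_inputs(agg, {mod.neuron_id: s}, _ref_T(agg))
            Ys.append(simulate_aggregate(agg, U, None))
            keys.append((mod.neuron_id, s))
    Y = np.stack(Ys)
    T = Y.shape[2]
    ests = estimate_inputs_batch(
        Y, agg, np.zeros((len(keys), 3, T)), excluded=excluded, L=L,
        ridge=ridge, state_ridge=state_ridge, operator=operator,
    )
    return DetectionReferences(
        refs={k: est.u_hat for k, est in zip(keys, ests)},
        latency_range=latency_range,
    )


def _ref_T(agg: AggregateModel) -> int:
    # reference duration: template length plus headroom for the longest latency
    return max(mod.template.n_samples for mod in agg.ei_models) + 15


def matched_similarity(
    u_hat: np.ndarray,
    neuron_id: int,
    agg: AggregateModel,
    references: DetectionReferences,
    zero_tol: float = 1e-8,
) -> tuple[float, int]:
    """Best cosine between a neuron's estimated-input block and its references."""
    sl = agg.neuron_input_slice(neuron_id)
    block = u_hat[sl]
    T = block.shape[1]
    nu = np.linalg.norm(block)
    lo, hi = references.latency_range
    if nu <= zero_tol:
        return 0.0, int(lo)
    best_score, best_lat = 0.0, int(lo)
    for s in range(lo, hi + 1):
        ref = references.refs[(neuron_id, s)][sl]
        rb = np.zeros_like(block)
        span = min(T, ref.shape[1])
        rb[:, :span] = ref[:, :span]
        nr = np.linalg.norm(rb)
        if nr == 0:
            continue
        score = float(np.sum(block * rb) / (nu * nr))
        if score > best_score:
            best_score, best_lat = score, s
    return best_score, best_lat


def detect(
    estimate: InputEstimate,
    agg: AggregateModel,
    threshold: float = 0.5,
    latency_range: tuple[int, int] = (0, 30),
    trial: int = 0,
    amplitude: float = 0.0,
    references: DetectionReferences | None = None,
) -> list[SpikeCall]:
    """One SpikeCall per neuron for a single trial's input estimate.

    With ``references`` the score is the matched, estimate-domain cosine
    (see :class:`DetectionReferences`); without, it is the raw shifted
    template cosine of :func:`similarity`. The two coincide for an exact
    estimator.
    """
    if not (0 < threshold <= 1):
        raise InvalidArgumentError("threshold must be in (0, 1]")
    calls = []
    for mod in agg.ei_models:
        block = estimate.neuron_block(mod.neuron_id, agg)
        if references is not None:
            score, lat = matched_similarity(
                estimate.u_hat, mod.neuron_id, agg, references
            )
        else:
            score, lat = similarity(block, mod.template, latency_range)
        hit = score >= threshold
        calls.append(
            SpikeCall(
                neuron_id=mod.neuron_id,
                trial=trial,
                amplitude=amplitude,
                detected=bool(hit),
                latency=lat if hit else None,
                score=score,
            )
        )
    return calls


@dataclass
class HypothesisBank:
    """All candidate spike hypotheses with precomputed predictions.

    Hypotheses are ordered by (spike count, latency tuple) so that a first
    minimum of the residual implements the tie-break toward fewer spikes and
    lower latencies.
    """

    hypotheses: list[tuple[tuple[int, int], ...]]
    predictions: np.ndarray  # n_hyp x (E' * T)
    kept_electrodes: np.ndarray
    T: int

    def __post_init__(self) -> None:
        self.prediction_norms_sq = np.einsum(
            "ij,ij->i", self.predictions, self.predictions
        )


def build_hypothesis_bank(
    agg: AggregateModel,
    T: int,
    excluded: CorruptedSet | None = None,
    latency_range: tuple[int, int] = (0, 10),
    max_neurons: int | None = None,
    max_hypotheses: int = 2_000_000,
) -> HypothesisBank:
    """Enumerate neuron subsets x latency combinations and their responses."""
    lo, hi = latency_range
    if hi < lo:
        raise InvalidArgumentError("latency_range is empty")
    n_lat = hi - lo + 1
    N = agg.n_neurons
    kmax = N if max_neurons is None else min(max_neurons, N)
    n_hyp = sum(n_lat**k * math.comb(N, k) for k in range(kmax + 1))
    if n_hyp > max_hypotheses:
        raise SizeError(f"{n_hyp} hypotheses exceed the limit {max_hypotheses}")

    excluded = excluded or CorruptedSet()
    keep = np.setdiff1d(np.arange(agg.n_electrodes), excluded.as_index_array())
    resp: dict[tuple[int, int], np.ndarray] = {}
    for mod in agg.ei_models:
        for s in range(lo, hi + 1):
            out = simulate_lds(mod, mod.template.shifted(s, T), n_electrodes=agg.n_electrodes)
            resp[(mod.neuron_id, s)] = out[keep].ravel()

    hyps: list[tuple[tuple[int, int], ...]] = []
    preds = np.zeros((n_hyp, keep.size * T))
    i = 0
    for k in range(kmax + 1):
        for subset in itertools.combinations(agg.neuron_ids, k):
            for lats in itertools.product(range(lo, hi + 1), repeat=k):
                hyp = tuple(zip(subset, lats))
                hyps.append(hyp)
                for n_, s_ in hyp:
                    preds[i] += resp[(n_, s_)]
                i += 1
    return HypothesisBank(hypotheses=hyps, predictions=preds, kept_electrodes=keep, T=T)


def oracle_enumerate(
    y: np.ndarray,
    agg: AggregateModel,
    u_a: np.ndarray | None = None,
    excluded: CorruptedSet | None = None,
    latency_range: tuple[int, int] = (0, 10),
    max_neurons: int | None = None,
    max_hypotheses: int = 2_000_000,
    bank: HypothesisBank | None = None,
) -> tuple[tuple[int, int], ...]:
    """Exhaustively find the spike hypothesis minimizing the residual.

    Enumerates every subset of at most ``max_neurons`` neurons and every
    latency combination, simulates the aggregate for each hypothesis and
    returns the (neuron_id, latency) tuples with the smallest residual sum of
    squares on non-excluded electrodes. Ties break toward fewer spikes, then
    lower latencies. Pass a precomputed ``bank`` to amortize the enumeration
    across trials.
    """
    y = np.asarray(y, dtype=np.float64)
    T = y.shape[1]
    if bank is None:
        bank = build_hypothesis_bank(
            agg, T, excluded=excluded, latency_range=latency_range,
            max_neurons=max_neurons, max_hypotheses=max_hypotheses,
        )
    base = np.zeros((agg.n_electrodes, T))
    if u_a is not None and agg.artifact is not None:
        base = simulate_aggregate(agg, np.zeros((2 * agg.n_neurons, T)), np.asarray(u_a))
    resid0 = (y - base)[bank.kept_electrodes].ravel()
    # ||r - p||^2 = ||p||^2 - 2 p.r + const; first minimum = tie-break order
    scores = bank.prediction_norms_sq - 2.0 * bank.predictions @ resid0
    return bank.hypotheses[int(np.argmin(scores))]


def sorting_accuracy(
    calls: list[SpikeCall],
    truth: GroundTruth,
) -> dict:
    """Per-trial set accuracy plus per-neuron precision/recall.

    A trial is correct iff the detected neuron set equals the true evoked
    set. Returns a dict with 'accuracy', 'n_trials' and a 'per_neuron' map of
    neuron_id -> (precision, recall).
    """
    trials_called = sorted({c.trial for c in calls})
    trials_true = sorted(truth.spikes.keys())
    if trials_called != trials_true:
        raise InvalidArgumentError("calls and truth must cover identical trials")

    by_trial: dict[int, set[int]] = {t: set() for t in trials_called}
    neurons = sorted({c.neuron_id for c in calls})
    for c in calls:
        if c.detected:
            by_trial[c.trial].add(c.neuron_id)

    correct = sum(
        1 for t in trials_called if by_trial[t] == set(truth.evoked_set(t))
    )
    per_neuron = {}
    for nid in neurons:
        tp = fp = fn = 0
        for t in trials_called:
            called = nid in by_trial[t]
            true = nid in truth.evoked_set(t)
            tp += called and true
            fp += called and not true
            fn += true and not called
        precision = tp / (tp + fp) if tp + fp else np.nan
        recall = tp / (tp + fn) if tp + fn else np.nan
        per_neuron[nid] = (precision, recall)
    return {
        "accuracy": correct / len(trials_called),
        "n_trials": len(trials_called),
        "per_neuron": per_neuron,
    }
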