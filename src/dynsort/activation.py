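"""Activation curves, sigmoid threshold fits, K-fold splits, threshold comparison.

An activation curve is the empirical spiking probability of one neuron as a
function of the stimulation current on one electrode. The 50% threshold is
extracted by a maximum-likelihood logistic fit in *log* amplitude (the
amplitude grid is log spaced): p(q) = 1 / (1 + exp(-(ln q - ln q50) / s)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit
from scipy.stats import pearsonr

from .core import Recording
from .detect import SpikeCall
from .errors import InvalidArgumentError, LookupError_


@dataclass
class ActivationCurve:
    """Per-amplitude spike counts for one neuron-electrode pair."""

    neuron_id: int
    stim_electrode: int
    amplitudes: np.ndarray
    spike_counts: np.ndarray
    trial_counts: np.ndarray
    q50: float = field(default=np.nan)
    slope: float = field(default=np.nan)
    converged: bool = field(default=False)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=np.float64)
        self.spike_counts = np.asarray(self.spike_counts, dtype=np.int64)
        self.trial_counts = np.asarray(self.trial_counts, dtype=np.int64)
        if not (self.amplitudes.shape == self.spike_counts.shape == self.trial_counts.shape):
            raise InvalidArgumentError("per-amplitude arrays must align")
        if np.any(self.spike_counts > self.trial_counts):
            raise InvalidArgumentError("spike counts cannot exceed trial counts")

    @property
    def probabilities(self) -> np.ndarray:
        return self.spike_counts / self.trial_counts

    @property
    def threshold(self) -> float:
        """50% amplitude; NaN unless the sigmoid fit converged and the curve
        actually reaches 50%."""
        if self.converged and np.max(self.probabilities) >= 0.5:
            return self.q50
        return np.nan


def build_activation_curve(
    calls: list[SpikeCall],
    neuron_id: int,
    stim_electrode: int,
) -> ActivationCurve:
    """Aggregate a neuron's spike calls into per-amplitude probabilities."""
    mine = [c for c in calls if c.neuron_id == neuron_id]
    if not mine:
        raise LookupError_(f"no calls for neuron {neuron_id}")
    amps = np.sort(np.unique([c.amplitude for c in mine]))
    if amps.size < 2:
        raise InvalidArgumentError("need calls at >= 2 amplitudes")
    spikes = np.zeros(amps.size, dtype=np.int64)
    trials = np.zeros(amps.size, dtype=np.int64)
    for c in mine:
        i = int(np.argmin(np.abs(amps - c.amplitude)))
        trials[i] += 1
        spikes[i] += int(c.detected)
    return ActivationCurve(
        neuron_id=neuron_id,
        stim_electrode=stim_electrode,
        amplitudes=amps,
        spike_counts=spikes,
        trial_counts=trials,
    )


def fit_sigmoid(curve: ActivationCurve) -> tuple[float, float, bool]:
    """Maximum-likelihood logistic fit on Bernoulli counts in log amplitude.

    Returns (q50, slope, converged) and stores them on the curve. Degenerate
    outcomes (all-0 or all-1 responses, non-positive steepness) are flagged
    as converged = False rather than raising.
    """
    k = curve.spike_counts
    n = curve.trial_counts
    if np.count_nonzero(n) < 2:
        raise InvalidArgumentError("need trials at >= 2 distinct amplitudes")
    if k.sum() == 0 or np.all(k == n):
        curve.q50, curve.slope, curve.converged = np.nan, np.nan, False
        return np.nan, np.nan, False

    lq = np.log(curve.amplitudes)

    def nll(theta: np.ndarray) -> float:
        log_q50, log_b = theta
        b = np.exp(log_b)
        p = expit(b * (lq - log_q50))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    # crude initialization: amplitude where the empirical curve crosses 0.5
    p_emp = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    above = np.flatnonzero(p_emp >= 0.5)
    x0 = lq[above[0]] if above.size else lq[-1]
    best = None
    for b0 in (np.log(2.0), np.log(10.0)):
        res = minimize(nll, np.array([x0, b0]), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    log_q50, log_b = best.x
    q50 = float(np.exp(log_q50))
    slope = float(np.exp(-log_b))  # s = 1/b
    converged = bool(np.isfinite(q50)) and q50 > 0
    curve.q50, curve.slope, curve.converged = q50, slope, converged
    return q50, slope, converged


def kfold_split(recording: Recording, K: int, seed: int = 0) -> list[np.ndarray]:
    """K disjoint, covering trial-index folds, stratified by amplitude."""
    if K < 2:
        raise InvalidArgumentError("K must be >= 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(K)]
    for q in np.sort(np.unique(recording.amplitudes)):
        idx = recording.trials_at(q)
        if idx.size < K:
            raise InvalidArgumentError(
                f"amplitude {q} has {idx.size} trials < K = {K}"
            )
        perm = rng.permutation(idx)
        for i, trial in enumerate(perm):
            folds[i % K].append(int(trial))
    return [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]


def compare_thresholds(
    set_a: np.ndarray,
    set_b: np.ndarray,
    method: str = "pearson",
) -> tuple[float, int]:
    """R^2 between two matched threshold sets.

    ``method='pearson'`` (default) returns the squared Pearson correlation;
    ``method='identity'`` returns 1 - SS_res/SS_tot about the identity line.
    Pairs with a NaN in either set (undefined thresholds) are dropped; the
    returned count is the number of pairs actually compared.
    """
    a = np.asarray(set_a, dtype=np.float64)
    b = np.asarray(set_b, dtype=np.float64)
    if a.shape != b.shape:
        raise InvalidArgumentError("threshold sets must be matched")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise InvalidArgumentError("need >= 2 matched finite pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise InvalidArgumentError("zero variance; R^2 undefined")
    if method == "pearson":
        r = pearsonr(a, b).statistic
        return float(r**2), int(a.size)
    if method == "identity":
        ss_res = np.sum((b - a) ** 2)
        ss_tot = np.sum((a - a.mean()) ** 2)
        return float(1.0 - ss_res / ss_tot), int(a.size)
    raise InvalidArgumentError(f"unknown method {method!r}")
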