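"""Per-neuron EI state-space model identification.

The states of an EI model are the EI voltages themselves on the neuron's
relevant electrodes (the output matrix is a selection), which turns system
identification into a multi-output ridge regression of x^{t+1} on
(x^t, u^t). Driving the fitted model with its two-pulse input template from
a zero initial state reproduces the neuron's electrical image.
"""

from __future__ import annotations

import numpy as np

from .core import EI_ROLE, ElectricalImage, InputTemplate, StateSpaceModel, simulate_lds
from .errors import (
    EmptySelectionError,
    InsufficientDataError,
    InvalidArgumentError,
    RankDeficiencyError,
    TemplateDesignError,
)


def select_relevant_electrodes(
    ei: ElectricalImage,
    abs_threshold: float = 0.0,
    frac_threshold: float = 0.1,
) -> np.ndarray:
    """Electrodes whose peak |EI| reaches max(abs_threshold, frac x global peak).

    The global-peak electrode always qualifies, so the result is non-empty
    for any non-zero EI.
    """
    if abs_threshold < 0 or frac_threshold < 0:
        raise InvalidArgumentError("thresholds must be >= 0")
    peaks = np.max(np.abs(ei.voltages), axis=1)
    global_peak = peaks.max()
    if global_peak == 0:
        raise EmptySelectionError("EI is identically zero")
    thr = max(abs_threshold, frac_threshold * global_peak)
    if thr == 0:
        sel = np.flatnonzero(peaks > 0)
    else:
        sel = np.flatnonzero(peaks >= thr)
    return sel


def design_ei_template(ei: ElectricalImage, onset_frac: float = 0.05) -> InputTemplate:
    """Two unit pulses that trigger the falling and rising spike phases.

    Channel 0 pulses one sample before the spike first emerges anywhere on
    the neuron's footprint (the earliest sample at which any relevant
    electrode exceeds ``onset_frac`` of the global peak); channel 1 pulses at
    the dominant-electrode trough, the onset of the repolarization rise.
    Placing each pulse *before* the phase it triggers lets the input matrix
    seed the model state while the true state is still near zero, so that
    simulation from rest reproduces the whole transient.
    """
    peaks = np.max(np.abs(ei.voltages), axis=1)
    dominant = int(np.argmax(peaks))
    trace = ei.voltages[dominant]
    d = np.diff(trace)
    if np.all(d >= 0) or np.all(d <= 0):
        raise TemplateDesignError("dominant trace is monotone; no trough to anchor pulses")
    global_peak = peaks[dominant]
    if np.min(trace) > -onset_frac * global_peak:
        raise TemplateDesignError("dominant trace has no negative trough")
    relevant = peaks >= 0.1 * global_peak
    envelope = np.max(np.abs(ei.voltages[relevant]), axis=0)
    above = np.flatnonzero(envelope >= onset_frac * global_peak)
    p0 = max(0, int(above[0]) - 1)
    trough = int(np.argmin(trace))
    rise_region = d[trough:] if trough < d.size else np.array([])
    if rise_region.size == 0 or np.max(rise_region) <= 0:
        raise TemplateDesignError("no rising phase after the trough")
    p1 = trough
    if p1 <= p0:
        p1 = p0 + 1
    pulses = np.zeros((2, ei.n_samples))
    pulses[0, p0] = 1.0
    pulses[1, p1] = 1.0
    return InputTemplate(pulses=pulses, pulse_times=np.array([p0, p1]), role=EI_ROLE)


def _ridge_identify(
    states: np.ndarray,
    inputs: np.ndarray,
    ridge: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve x^{t+1} ~ A x^t + B u^t by (ridge) least squares.

    ``states`` is m x T, ``inputs`` is P x T (or lists thereof stacked by the
    caller). Returns (A, B).
    """
    m = states.shape[0]
    P = inputs.shape[0]
    Z = np.vstack([states[:, :-1], inputs[:, :-1]])
    Y = states[:, 1:]
    return _solve_blocks(Z, Y, m, P, ridge)


def _solve_blocks(
    Z: np.ndarray, Y: np.ndarray, m: int, P: int, ridge: float
) -> tuple[np.ndarray, np.ndarray]:
    if ridge < 0:
        raise InvalidArgumentError("ridge must be >= 0")
    if ridge == 0:
        if np.linalg.matrix_rank(Z) < Z.shape[0]:
            raise RankDeficiencyError(
                "normal equations are singular at ridge = 0; pass ridge > 0"
            )
        W = np.linalg.lstsq(Z.T, Y.T, rcond=None)[0].T
    else:
        G = Z @ Z.T + ridge * np.eye(Z.shape[0])
        W = np.linalg.solve(G, Z @ Y.T).T
    return W[:, :m], W[:, m:]


def _refine_simulation(
    X: np.ndarray,
    U: np.ndarray,
    A0: np.ndarray,
    B0: np.ndarray,
    max_iter: int = 2000,
) -> tuple[np.ndarray, np.ndarray]:
    """Polish (A, B) by minimizing the *simulated*-trajectory error.

    The one-step regression minimizes transition residuals, but simulating
    from rest compounds those residuals over the whole transient. This stage
    runs L-BFGS on sum_t ||x_sim^t - x^t||^2 with gradients from the adjoint
    (backpropagation through the recursion), starting at the regression
    solution.
    """
    from scipy.optimize import minimize

    m, T = X.shape
    P = U.shape[0]

    def loss_grad(w: np.ndarray) -> tuple[float, np.ndarray]:
        A = w[: m * m].reshape(m, m)
        B = w[m * m :].reshape(m, P)
        xs = np.zeros((T, m))
        x = np.zeros(m)
        for t in range(T):
            xs[t] = x
            x = A @ xs[t] + B @ U[:, t]
        E = xs - X.T
        lam = np.zeros(m)
        gA = np.zeros((m, m))
        gB = np.zeros((m, P))
        for t in range(T - 1, -1, -1):
            lam = lam + 2 * E[t]
            if t > 0:
                gA += np.outer(lam, xs[t - 1])
                gB += np.outer(lam, U[:, t - 1])
            lam = A.T @ lam
        return float(np.sum(E * E)), np.concatenate([gA.ravel(), gB.ravel()])

    w0 = np.concatenate([A0.ravel(), B0.ravel()])
    f0, _ = loss_grad(w0)
    if f0 <= 1e-18 * max(1.0, float(np.sum(X * X))):
        return A0, B0
    res = minimize(
        loss_grad, w0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-15, "gtol": 1e-13},
    )
    if not np.all(np.isfinite(res.x)) or res.fun > f0:
        return A0, B0
    A = res.x[: m * m].reshape(m, m)
    B = res.x[m * m :].reshape(m, P)
    return A, B


def fit_ei_model(
    ei: ElectricalImage,
    subset: np.ndarray,
    template: InputTemplate,
    ridge: float = 1e-3,
    stability_tol: float = 0.05,
    refine_iters: int = 2000,
) -> StateSpaceModel:
    """Identify (A_n, B_n) for one neuron from its EI.

    The states are the EI voltages on ``subset``; the regression stacks all
    transitions t -> t+1 with the template as the known input. The EI is
    treated as causal with respect to its template: voltages up to the first
    pulse are clamped to zero in the fit, so the input matrix injects the
    full post-pulse state and simulation from rest reproduces the transient
    (instead of letting A "explain" growth out of the sub-threshold onset
    tail, which a zero-state simulation can never reproduce). The regression
    solution is then polished against the simulated-trajectory error
    (``refine_iters`` L-BFGS iterations; 0 disables). The returned model's
    simulated output is exactly zero off the subset.
    """
    subset = np.asarray(subset, dtype=np.int64)
    if subset.size == 0:
        raise EmptySelectionError("electrode subset is empty")
    if ei.n_samples < 3:
        raise InsufficientDataError("need at least 3 samples to identify dynamics")
    if template.n_samples != ei.n_samples:
        raise InvalidArgumentError("template must share the EI time base")
    X = ei.voltages[subset].copy()
    p0 = int(template.pulse_times.min())
    X[:, : p0 + 1] = 0.0
    A, B = _ridge_identify(X, template.pulses, ridge)
    if refine_iters > 0:
        A, B = _refine_simulation(X, template.pulses, A, B, max_iter=refine_iters)
    return StateSpaceModel(
        A=A,
        B=B,
        electrode_subset=subset,
        template=template,
        role=EI_ROLE,
        neuron_id=ei.neuron_id,
        stability_tol=stability_tol,
    )


def predict_ei(model: StateSpaceModel, n_electrodes: int) -> np.ndarray:
    """Simulate the model with its own template from zero state (E x T)."""
    return simulate_lds(model, model.template.pulses, n_electrodes=n_electrodes)


def snrmse(ei: ElectricalImage, predicted: np.ndarray, subset: np.ndarray) -> float:
    """Spike-normalized RMSE: RMS(ei - predicted) / RMS(ei) over the subset."""
    subset = np.asarray(subset, dtype=np.int64)
    if predicted.shape != ei.voltages.shape:
        raise InvalidArgumentError(
            f"predicted shape {predicted.shape} != EI shape {ei.voltages.shape}"
        )
    ref = ei.voltages[subset]
    denom = np.sqrt(np.mean(ref**2))
    if denom == 0:
        raise ZeroDivisionError("EI has zero RMS on the subset")
    err = ref - predicted[subset]
    return float(np.sqrt(np.mean(err**2)) / denom)
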