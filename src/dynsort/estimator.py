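"""Windowed input estimation: inverting the aggregate model.

Given post-stimulation measurements, the known artifact input (stimulation
timing and amplitude are known), and a set of corrupted electrodes to
ignore, the estimator recovers which EI inputs -- and hence which spikes --
produced the data. It is a receding-horizon regularized least-squares
reconstructor: at each step t it forms the residual of the measurement
window y^{t:t+L} after subtracting the free response of the propagated state
and the known artifact contribution, jointly solves for the unknown EI
inputs over the window, keeps the step-t estimate, and rolls the state
forward. With noiseless data and a full-column-rank window operator the
recovery is exact.

Under measurement noise, pure open-loop propagation of the estimated inputs
is unstable: input errors feed the state through B, corrupt the next
residual, and grow. A second, innovation-based stage therefore fits a state
correction to the *leftover* window residual (after the estimated-input
contribution is removed) and adds it before rolling forward. Because the
correction is fit to what the inputs could not explain, it is exactly zero
on noiseless data and does not disturb exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aggregate import AggregateModel, CorruptedSet
from .errors import (
    DataError,
    IdentifiabilityError,
    InvalidArgumentError,
    RankDeficiencyError,
    ShapeError,
)


@dataclass
class WindowOperator:
    """Stacked response maps of the aggregate model over a forward window.

    Rows run over window steps k = 0..L (outer) and kept electrodes (inner);
    corrupted-electrode rows are deleted.

    Phi : free-response map, rows x m~  (block k is C A^k)
    G   : EI-input map, rows x 2N*L    (block (k, j) is C A^{k-1-j} B, k > j)
    H   : artifact-input map, rows x 3L (same structure with B')
    """

    Phi: np.ndarray
    G: np.ndarray
    H: np.ndarray
    kept_electrodes: np.ndarray
    L: int
    n_inputs: int  # 2N

    @property
    def G_current(self) -> np.ndarray:
        """Columns of G for inputs at the current window step."""
        return self.G[:, : self.n_inputs]


def build_window_operator(
    agg: AggregateModel,
    L: int,
    excluded: CorruptedSet | None = None,
) -> WindowOperator:
    """Precompute the window response maps, dropping corrupted electrodes.

    Raises :class:`IdentifiabilityError` naming the offending neurons when the
    current-step input columns lose rank (2N needed).
    """
    if L < 1:
        raise InvalidArgumentError("window length L must be >= 1")
    excluded = excluded or CorruptedSet()
    keep = np.setdiff1d(np.arange(agg.n_electrodes), excluded.as_index_array())
    Ck = agg.C[keep]  # E' x m~
    n_in = agg.B.shape[1]

    # C A^k for k = 0..L
    CA = [Ck]
    for _ in range(L):
        CA.append(CA[-1] @ agg.A)

    Phi = np.vstack(CA)  # (L+1) E' x m~

    Ep = keep.size
    rows = (L + 1) * Ep
    G = np.zeros((rows, n_in * L))
    H = np.zeros((rows, 3 * L))
    for j in range(L):
        for k in range(j + 1, L + 1):
            r = slice(k * Ep, (k + 1) * Ep)
            G[r, j * n_in : (j + 1) * n_in] = CA[k - 1 - j] @ agg.B
            H[r, 3 * j : 3 * (j + 1)] = CA[k - 1 - j] @ agg.B_prime

    Gc = G[:, :n_in]
    if np.linalg.matrix_rank(Gc) < n_in:
        bad = _offending_neurons(agg, Gc)
        raise IdentifiabilityError(
            f"current-step input map is rank deficient; neurons {bad} are not "
            "identifiable from the remaining electrodes"
        )
    return WindowOperator(Phi=Phi, G=G, H=H, kept_electrodes=keep, L=L, n_inputs=n_in)


def _offending_neurons(agg: AggregateModel, Gc: np.ndarray) -> list[int]:
    """Neurons whose input columns are (nearly) linearly dependent on the rest."""
    bad = []
    scale = np.linalg.norm(Gc) + 1e-300
    for i, mod in enumerate(agg.ei_models):
        cols = Gc[:, 2 * i : 2 * i + 2]
        others = np.delete(Gc, [2 * i, 2 * i + 1], axis=1)
        proj, *_ = np.linalg.lstsq(others, cols, rcond=None)
        resid = cols - others @ proj
        if np.linalg.norm(resid) < 1e-9 * scale:
            bad.append(mod.neuron_id)
    return bad or agg.neuron_ids


@dataclass
class InputEstimate:
    """Estimated EI inputs and state trajectory for one trial."""

    u_hat: np.ndarray        # 2N x T
    x_hat: np.ndarray        # m~ x T
    excluded: CorruptedSet
    window: int
    ridge: float
    neuron_ids: list[int]

    def neuron_block(self, neuron_id: int, agg: AggregateModel) -> np.ndarray:
        return self.u_hat[agg.neuron_input_slice(neuron_id)]


def _window_solver(op: WindowOperator, ridge: float) -> np.ndarray:
    """(G^T G + ridge I)^-1 G^T, the joint window least-squares map."""
    G = op.G
    if ridge < 0:
        raise InvalidArgumentError("ridge must be >= 0")
    if ridge == 0:
        if np.linalg.matrix_rank(G) < G.shape[1]:
            raise RankDeficiencyError(
                "window input map is rank deficient at ridge = 0; pass ridge > 0"
            )
        return np.linalg.pinv(G)
    gram = G.T @ G + ridge * np.eye(G.shape[1])
    return np.linalg.solve(gram, G.T)


def _state_corrector(op: WindowOperator, state_ridge: float) -> np.ndarray:
    """(Phi^T Phi + ridge I)^-1 Phi^T for the innovation correction stage."""
    Phi = op.Phi
    if state_ridge < 0:
        raise InvalidArgumentError("state_ridge must be >= 0")
    if state_ridge == 0:
        return np.linalg.pinv(Phi)
    gram = Phi.T @ Phi + state_ridge * np.eye(Phi.shape[1])
    return np.linalg.solve(gram, Phi.T)


def estimate_inputs_batch(
    Y: np.ndarray,
    agg: AggregateModel,
    Ua: np.ndarray,
    excluded: CorruptedSet | None = None,
    L: int = 10,
    ridge: float = 300.0,
    state_ridge: float = 1.0,
    operator: WindowOperator | None = None,
) -> list[InputEstimate]:
    """Vectorized estimation over a batch of trials.

    ``Y`` is batch x E x T, ``Ua`` batch x 3 x T (known artifact inputs).
    All trials share the operator; the per-step window solves become
    matrix-matrix products over the batch. ``ridge`` is the input
    regularizer in squared uV (roughly measurement-noise variance divided by
    the prior input variance); ``state_ridge`` regularizes the innovation
    state correction.
    """
    Y = np.asarray(Y, dtype=np.float64)
    Ua = np.asarray(Ua, dtype=np.float64)
    if Y.ndim != 3:
        raise ShapeError("Y must be batch x E x T")
    if not np.all(np.isfinite(Y)):
        raise DataError("measurements contain non-finite values")
    batch, E, T = Y.shape
    if E != agg.n_electrodes:
        raise ShapeError(f"Y has {E} electrodes, aggregate expects {agg.n_electrodes}")
    if Ua.shape != (batch, 3, T):
        raise ShapeError(f"Ua must be {batch} x 3 x {T}")
    if T <= L:
        raise InvalidArgumentError(f"need T > L (T={T}, L={L})")
    excluded = excluded or CorruptedSet()
    op = operator if operator is not None else build_window_operator(agg, L, excluded)
    M = _window_solver(op, ridge)
    Mx = _state_corrector(op, state_ridge)
    n_in = op.n_inputs
    keep = op.kept_electrodes
    Ep = keep.size

    Yk = Y[:, keep, :]                      # batch x E' x T
    u_hat = np.zeros((batch, n_in, T))
    x_hat = np.zeros((batch, agg.n_states, T))

    x = np.zeros((agg.n_states, batch))
    u_prev = np.zeros((n_in, batch))
    ua_prev = np.zeros((3, batch))
    n_steps = T - L
    for t in range(n_steps):
        if t > 0:
            x = agg.A @ x + agg.B @ u_prev + agg.B_prime @ ua_prev

        # stacked window measurements: rows k-outer, electrode-inner
        Yw = (
            Yk[:, :, t : t + L + 1]
            .transpose(2, 1, 0)
            .reshape((L + 1) * Ep, batch)
        )
        Uaw = Ua[:, :, t : t + L].transpose(2, 1, 0).reshape(3 * L, batch)
        R = Yw - op.Phi @ x - op.H @ Uaw
        U_window = M @ R                    # (n_in * L) x batch
        u_t = U_window[:n_in]
        # innovation correction: absorb what the window inputs cannot explain
        x = x + Mx @ (R - op.G @ U_window)
        x_hat[:, :, t] = x.T
        u_hat[:, :, t] = u_t.T
        u_prev = u_t
        ua_prev = Ua[:, :, t].T

    return [
        InputEstimate(
            u_hat=u_hat[b],
            x_hat=x_hat[b],
            excluded=excluded,
            window=L,
            ridge=ridge,
            neuron_ids=agg.neuron_ids,
        )
        for b in range(batch)
    ]


def estimate_inputs(
    y: np.ndarray,
    agg: AggregateModel,
    u_a: np.ndarray,
    excluded: CorruptedSet | None = None,
    L: int = 10,
    ridge: float = 300.0,
    state_ridge: float = 1.0,
    operator: WindowOperator | None = None,
) -> InputEstimate:
    """Estimate the EI inputs that produced one trial's measurements.

    ``y`` is E x T; ``u_a`` is the known 3 x T artifact input (q-scaled
    template). See :func:`estimate_inputs_batch` for the mechanics.
    """
    y = np.asarray(y, dtype=np.float64)
    u_a = np.asarray(u_a, dtype=np.float64)
    if y.ndim != 2:
        raise ShapeError("y must be E x T")
    return estimate_inputs_batch(
        y[None, :, :], agg, u_a[None, :, :], excluded=excluded, L=L, ridge=ridge,
        state_ridge=state_ridge, operator=operator,
    )[0]


def input_rmse(estimate: InputEstimate, truth: np.ndarray) -> dict[int, float]:
    """Per-neuron RMS deviation between estimated and true input sequences."""
    truth = np.asarray(truth, dtype=np.float64)
    if truth.shape != estimate.u_hat.shape:
        raise ShapeError(
            f"truth shape {truth.shape} != estimate shape {estimate.u_hat.shape}"
        )
    out = {}
    for i, nid in enumerate(estimate.neuron_ids):
        block = slice(2 * i, 2 * i + 2)
        err = estimate.u_hat[block] - truth[block]
        out[nid] = float(np.sqrt(np.mean(err**2)))
    return out
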