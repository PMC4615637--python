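import numpy as np
import pytest

from granular_reservoir import NetworkParams, SignalProtocol


@pytest.fixture
def short_protocol() -> SignalProtocol:
    """Seconds-scale protocol for fast end-to-end tests."""
    return SignalProtocol(
        train_noise_s=1.0,
        train_silence_s=1.0,
        test_noise_s=1.0,
        test_silence_s=1.0,
        impulse_segment_s=0.5,
    )


@pytest.fixture
def tiny_params() -> NetworkParams:
    """Small populations for structural and dynamical unit tests."""
    return NetworkParams(n_granule=40, n_golgi=8, c_w=3, c_u=10)


def direct_one_population(params, W, I, noise=None):
    """O(T^2) reference evaluation of the one-population dynamics.

    Evaluates the synaptic kernel as the explicit double sum
    sum_{s=1..t} exp(-(t-s) dt / tau_w) z(s-1) at every step instead of the
    recursion, so it shares no state-update code with the simulator.
    """
    T, n = I.shape
    z = np.zeros((T, n))
    for t in range(T):
        kern = np.zeros(n)
        for s in range(1, t + 1):
            kern += np.exp(-(t - s) * params.dt_ms / params.tau_w) * z[s - 1]
        drive = I[t] - W @ kern
        if noise is not None:
            drive = drive + noise[t]
        z[t] = np.maximum(drive, 0.0)
    return z


def direct_two_population(params, W, U, M, Iz, Iq, feedback_z=None, feedback_q=None):
    """O(T^2) reference evaluation of the granule/Golgi dynamics."""
    T, nz = Iz.shape
    nq = Iq.shape[1]
    z = np.zeros((T, nz))
    q = np.zeros((T, nq))
    for t in range(T):
        kern_q = np.zeros(nq)
        kern_zu = np.zeros(nz)
        kern_zm = np.zeros(nz)
        for s in range(1, t + 1):
            kern_q += np.exp(-(t - s) * params.dt_ms / params.tau_w) * q[s - 1]
            kern_zu += np.exp(-(t - s) * params.dt_ms / params.tau_u) * z[s - 1]
            kern_zm += np.exp(-(t - s) * params.dt_ms / params.tau_m) * z[s - 1]
        dz = Iz[t] - W @ kern_q
        dq = params.g * Iq[t] + U @ kern_zu - M @ kern_zm
        if feedback_z is not None:
            dz = dz + feedback_z[t]
        if feedback_q is not None:
            dq = dq + feedback_q[t]
        z[t] = np.maximum(dz, 0.0)
        q[t] = np.maximum(dq, 0.0)
    return z, q


def prox_gradient_lasso(Z, y, alpha, n_iter=20000, nonneg=False):
    """Independent proximal-gradient (ISTA) solver for the LASSO objective.

    Minimizes (1/(2T)) ||y - Z b||^2 + alpha ||b||_1 by gradient steps on
    the smooth part followed by soft thresholding; step size from the
    spectral norm of the design. Used as the oracle against which the
    coordinate-descent fit is checked.
    """
    T, n = Z.shape
    L = np.linalg.norm(Z, 2) ** 2 / T  # Lipschitz constant of the gradient
    step = 1.0 / L
    b = np.zeros(n)
    for _ in range(n_iter):
        grad = Z.T @ (Z @ b - y) / T
        b = b - step * grad
        thr = alpha * step
        b = np.sign(b) * np.maximum(np.abs(b) - thr, 0.0)
        if nonneg:
            b = np.maximum(b, 0.0)
    return b


def lasso_objective(Z, y, b, alpha):
    T = Z.shape[0]
    return 0.5 / T * np.sum((y - Z @ b) ** 2) + alpha * np.sum(np.abs(b))
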