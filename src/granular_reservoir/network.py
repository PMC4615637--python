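"""Random connectivity and rate-network integration.

Two inhibition-dominated rate models of the cerebellar granular layer are
integrated with a fixed 1 ms step and synchronous (explicit) updates:

One population: granule cells inhibit each other directly,

    z_i(t) = [ I_i(t) - sum_j A_ij w_ij sum_{s=1..t} e^{-(t-s)/tau_w} z_j(s-1)
               + n N_i(t) ]^+

Two populations: inhibition is relayed through Golgi cells,

    z_i(t) = [ I_i(t) - sum_j W_ij w_ij K_w * q_j + L_i(t) ]^+
    q_i(t) = [ g I_i(t) + sum_j B_ij ( u_ij K_u * z_j - m_ij K_m * z_j )
               + L_i(t) ]^+

where K_tau * r denotes the exponential synaptic kernel sum
sum_{s=1..t} e^{-(t-s)/tau} r(s-1), evaluated with the O(T) recursion
c(t) = e^{-dt/tau} c(t-1) + r(t-1). The m-term models the slow inhibition
of Golgi cells by granule-cell glutamate through mGluR2-activated GIRK
channels; g scales direct mossy-fiber excitation of Golgi cells; L(t) is
an optional feedback injection (nucleocortical pathway). Rates are
rectified at zero, there are no membrane time constants, and weights are
normalized by the presynaptic pool size (population size Nz for the
one-population model, convergence c_w / c_u for the two-population model)
so that the total drive per cell is O(weight mean).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

from ._streams import CONNECTIVITY, NETWORK_NOISE, substream
from .errors import ConfigurationError, NetworkInstabilityError
from .signals import InputEnsemble

#: rates above this bound abort the run with an instability report
RATE_BOUND = 1e6

#: std of the intrinsic white-noise process N_i(t); the additive noise
#: n*N_i(t) is then smaller than the amplitude n 95% of the time
NOISE_STD = 0.5


@dataclass(frozen=True)
class NetworkParams:
    """Structural and synaptic parameters of both models.

    ``w, u, m`` are weight means with relative spreads ``v_w, v_u, v_m``;
    ``u = None`` applies the default normalization u = 0.1 / tau_u. Time
    constants are in ms. ``g`` scales direct afferent excitation of Golgi
    cells; ``noise`` is the intrinsic noise amplitude n; ``p_mglur_zero``
    is the probability that a Golgi cell lacks mGluR2 inhibition entirely.
    """

    n_granule: int = 1000
    n_golgi: int = 100
    conn_prob: float = 0.4
    c_w: int = 4
    c_u: int = 100
    w: float = 1.4
    v_w: float = 0.0
    u: float | None = None
    v_u: float = 0.0
    m: float = 0.0
    v_m: float = 0.0
    p_mglur_zero: float = 0.0
    tau_w: float = 50.0
    tau_u: float = 1.0
    tau_m: float = 50.0
    g: float = 0.0
    noise: float = 0.0
    dt_ms: float = 1.0
    allow_self: bool = True

    def __post_init__(self) -> None:
        if self.n_granule < 1 or self.n_golgi < 1:
            raise ConfigurationError("population sizes must be >= 1")
        if not 0.0 <= self.conn_prob <= 1.0:
            raise ConfigurationError("conn_prob must lie in [0, 1]")
        if min(self.tau_w, self.tau_u, self.tau_m, self.dt_ms) <= 0:
            raise ConfigurationError("time constants and dt must be positive")
        if min(self.w, self.m, self.g) < 0 or (self.u is not None and self.u < 0):
            raise ConfigurationError("weight means and g must be nonnegative")
        if not 0.0 <= self.p_mglur_zero <= 1.0:
            raise ConfigurationError("p_mglur_zero must lie in [0, 1]")

    @property
    def u_eff(self) -> float:
        """Excitatory weight mean; defaults to 0.1 / tau_u."""
        return 0.1 / self.tau_u if self.u is None else self.u

    def with_(self, **overrides) -> "NetworkParams":
        return replace(self, **overrides)


@dataclass
class Connectivity:
    """Binary adjacencies plus nonnegative weight matrices.

    One-population: ``W_adj`` is (Nz, Nz) and ``W_wt`` carries weights
    (2/Nz)(w + v_w w xi)^+ on the adjacency. Two-population: ``W_adj``
    is (Nz, Nq) with exactly c_w ones per granule row, ``B_adj`` is
    (Nq, Nz) with exactly c_u ones per Golgi row, and ``U_wt`` / ``M_wt``
    carry (2/c_u)(u +/- v_u u)^+ and (2/c_u)(m +/- v_m m)^+ on ``B_adj``.
    ``mglur_active`` marks Golgi cells whose incoming m-weights were not
    knocked out.
    """

    W_adj: np.ndarray
    W_wt: np.ndarray
    B_adj: np.ndarray | None = None
    U_wt: np.ndarray | None = None
    M_wt: np.ndarray | None = None
    mglur_active: np.ndarray | None = None

    @property
    def is_two_population(self) -> bool:
        return self.B_adj is not None


@dataclass
class RateTraces:
    """Time x cell firing-rate matrices with segment bookkeeping."""

    z: np.ndarray
    dt_ms: float
    bounds: dict[str, tuple[int, int]] | None = None
    q: np.ndarray | None = None

    def rows(self, *labels: str) -> np.ndarray:
        """Granule-rate rows belonging to the given signal segments."""
        if self.bounds is None:
            raise ValueError("traces carry no segment labels")
        idx = np.concatenate([np.arange(*self.bounds[lab]) for lab in labels])
        return self.z[idx]

    def save_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("z", data=self.z, compression="gzip")
            if self.q is not None:
                fh.create_dataset("q", data=self.q, compression="gzip")
            fh.attrs["dt_ms"] = self.dt_ms
            if self.bounds is not None:
                for lab, (lo, hi) in self.bounds.items():
                    fh.attrs[f"segment_{lab}"] = (lo, hi)

    @classmethod
    def load_hdf5(cls, path: str | Path) -> "RateTraces":
        with h5py.File(path, "r") as fh:
            z = fh["z"][...]
            q = fh["q"][...] if "q" in fh else None
            dt = float(fh.attrs["dt_ms"])
            bounds = {
                key[len("segment_"):]: (int(val[0]), int(val[1]))
                for key, val in fh.attrs.items()
                if key.startswith("segment_")
            } or None
        return cls(z=z, dt_ms=dt, bounds=bounds, q=q)


@dataclass
class FeedbackInjection:
    """Additive feedback L_i(t) = inj_i * s(t) entering both populations.

    ``granule_weights`` / ``golgi_weights`` hold the signed per-cell
    injection weights f * o_i (zero for non-recipients). The scalar s(t)
    is either a precomputed series (teacher forcing) or, in closed loop,
    the negated readout -(beta . z(t-1)) evaluated one step back, keeping
    the explicit update scheme causal.
    """

    granule_weights: np.ndarray
    golgi_weights: np.ndarray | None = None
    series: np.ndarray | None = None
    readout_beta: np.ndarray | None = None
    noise_granule: np.ndarray | None = None  # (T, Nz) multiplicative factors
    noise_golgi: np.ndarray | None = None    # (T, Nq) multiplicative factors

    def __post_init__(self) -> None:
        if (self.series is None) == (self.readout_beta is None):
            raise ConfigurationError("set exactly one of series / readout_beta")
        if self.readout_beta is not None and (
            self.noise_granule is not None or self.noise_golgi is not None
        ):
            raise ConfigurationError("per-cell noise applies to teacher series only")

    def scalar(self, t: int, z_prev: np.ndarray | None) -> float:
        if self.series is not None:
            return float(self.series[t])
        if z_prev is None:
            return 0.0
        return float(-(self.readout_beta @ z_prev))


def build_connectivity_onepop(params: NetworkParams, seed: int = 0) -> Connectivity:
    """Bernoulli(a) adjacency with weights (2/Nz)(w + v_w w xi)^+."""
    rng = substream(seed, CONNECTIVITY)
    nz = params.n_granule
    adj = rng.random((nz, nz)) < params.conn_prob
    if not params.allow_self:
        np.fill_diagonal(adj, False)
    xi = rng.standard_normal((nz, nz))
    wt = (2.0 / nz) * np.maximum(params.w + params.v_w * params.w * xi, 0.0)
    wt *= adj
    return Connectivity(W_adj=adj.astype(np.uint8), W_wt=np.ascontiguousarray(wt))


def _exact_convergence_rows(rng: np.random.Generator, n_rows: int, n_cols: int, k: int) -> np.ndarray:
    """Boolean (n_rows, n_cols) matrix with exactly k distinct ones per row."""
    scores = rng.random((n_rows, n_cols))
    picks = np.argpartition(scores, k - 1, axis=1)[:, :k]
    adj = np.zeros((n_rows, n_cols), dtype=bool)
    np.put_along_axis(adj, picks, True, axis=1)
    return adj


def build_connectivity_twopop(params: NetworkParams, seed: int = 0) -> Connectivity:
    """Exact-convergence wiring: c_w Golgi per granule, c_u granule per Golgi."""
    nz, nq = params.n_granule, params.n_golgi
    if params.c_w > nq or params.c_u > nz:
        raise ConfigurationError("convergence exceeds presynaptic population size")
    if params.c_w < 1 or params.c_u < 1:
        raise ConfigurationError("convergences must be >= 1")
    rng = substream(seed, CONNECTIVITY)
    w_adj = _exact_convergence_rows(rng, nz, nq, params.c_w)
    b_adj = _exact_convergence_rows(rng, nq, nz, params.c_u)

    xi_w = rng.standard_normal((nz, nq))
    w_wt = (2.0 / params.c_w) * np.maximum(params.w + params.v_w * params.w * xi_w, 0.0)
    w_wt = np.ascontiguousarray(w_wt * w_adj)

    u = params.u_eff
    xi_u = rng.standard_normal((nq, nz))
    u_wt = (2.0 / params.c_u) * np.maximum(u + params.v_u * u * xi_u, 0.0)
    u_wt = np.ascontiguousarray(u_wt * b_adj)

    xi_m = rng.standard_normal((nq, nz))
    m_wt = (2.0 / params.c_u) * np.maximum(params.m + params.v_m * params.m * xi_m, 0.0)
    m_wt = np.ascontiguousarray(m_wt * b_adj)
    # per-Golgi mGluR2 knockout: a knocked-out Golgi cell loses all its
    # incoming m-weights (cell-level expression of the receptor)
    active = rng.random(nq) >= params.p_mglur_zero
    m_wt[~active, :] = 0.0

    return Connectivity(
        W_adj=w_adj.astype(np.uint8),
        W_wt=w_wt,
        B_adj=b_adj.astype(np.uint8),
        U_wt=u_wt,
        M_wt=m_wt,
        mglur_active=active,
    )


def save_connectivity(conn: Connectivity, path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        for name in ("W_adj", "W_wt", "B_adj", "U_wt", "M_wt", "mglur_active"):
            val = getattr(conn, name)
            if val is not None:
                fh.create_dataset(name, data=val, compression="gzip")


def load_connectivity(path: str | Path) -> Connectivity:
    kwargs = {}
    with h5py.File(path, "r") as fh:
        for name in ("W_adj", "W_wt", "B_adj", "U_wt", "M_wt", "mglur_active"):
            if name in fh:
                kwargs[name] = fh[name][...]
    return Connectivity(**kwargs)


def _feedback_terms(feedback, t, z_prev):
    """(granule, golgi) additive feedback vectors at step t, or (0, 0)."""
    if feedback is None:
        return 0.0, 0.0
    if isinstance(feedback, FeedbackInjection):
        s = feedback.scalar(t, z_prev)
        gran = feedback.granule_weights * s
        gol = feedback.golgi_weights * s if feedback.golgi_weights is not None else 0.0
        if feedback.noise_granule is not None:
            gran = gran * feedback.noise_granule[t]
        if feedback.noise_golgi is not None:
            gol = gol * feedback.noise_golgi[t]
        return gran, gol
    return np.asarray(feedback)[t], 0.0


def simulate_one_population(
    params: NetworkParams,
    connectivity: Connectivity,
    inputs: InputEnsemble,
    seed: int = 0,
    feedback: FeedbackInjection | np.ndarray | None = None,
) -> RateTraces:
    """Integrate the one-population dynamics over the full input signal.

    ``feedback`` may be a FeedbackInjection or a plain (T, Nz)/(T,) array
    added to the drive before rectification. Bit-reproducible given the
    seed; rates above RATE_BOUND (or non-finite) abort with the step index.
    """
    if connectivity.is_two_population:
        raise ConfigurationError("one-population simulator needs one-population connectivity")
    nz = params.n_granule
    if connectivity.W_wt.shape != (nz, nz) or inputs.n_cells != nz:
        raise ConfigurationError("connectivity/inputs dimensioned inconsistently with params")
    T = inputs.x.size
    W = connectivity.W_wt
    decay = np.exp(-params.dt_ms / params.tau_w)
    n_amp = params.noise
    rng = substream(seed, NETWORK_NOISE) if n_amp > 0 else None

    base = inputs.I0
    mod = inputs.f * inputs.modulation * inputs.I0
    x = inputs.x
    z = np.empty((T, nz))
    c = np.zeros(nz)
    z_prev = None
    for t in range(T):
        if t > 0:
            c *= decay
            c += z_prev
        drive = np.maximum(base + mod * x[t], 0.0) - W @ c
        if n_amp > 0:
            drive += n_amp * (NOISE_STD * rng.standard_normal(nz))
        fb_z, _ = _feedback_terms(feedback, t, z_prev)
        if feedback is not None:
            drive = drive + fb_z
        np.maximum(drive, 0.0, out=drive)
        mx = drive.max()
        if not mx < RATE_BOUND:
            raise NetworkInstabilityError(step=t, max_rate=mx)
        z[t] = drive
        z_prev = z[t]
    return RateTraces(z=z, dt_ms=params.dt_ms, bounds=dict(inputs.signal.bounds))


def simulate_two_population(
    params: NetworkParams,
    connectivity: Connectivity,
    inputs_granule: InputEnsemble,
    inputs_golgi: InputEnsemble,
    seed: int = 0,
    feedback: FeedbackInjection | np.ndarray | None = None,
) -> RateTraces:
    """Integrate the granule/Golgi dynamics over the full input signal.

    Golgi cells receive the fast excitatory kernel (tau_u) and subtract the
    slow mGluR2 kernel (tau_m) of granule rates, plus direct afferent drive
    g * I_i(t); granule cells receive the tau_w kernel of Golgi rates as
    inhibition. Intrinsic noise of amplitude ``params.noise`` is added to
    both populations.
    """
    if not connectivity.is_two_population:
        raise ConfigurationError("two-population simulator needs two-population connectivity")
    nz, nq = params.n_granule, params.n_golgi
    if connectivity.W_wt.shape != (nz, nq) or connectivity.U_wt.shape != (nq, nz):
        raise ConfigurationError("connectivity dimensioned inconsistently with params")
    if inputs_granule.n_cells != nz or inputs_golgi.n_cells != nq:
        raise ConfigurationError("input ensembles dimensioned inconsistently with params")
    T = inputs_granule.x.size
    W, U, M = connectivity.W_wt, connectivity.U_wt, connectivity.M_wt
    has_m = M is not None and bool(M.any())
    d_w = np.exp(-params.dt_ms / params.tau_w)
    d_u = np.exp(-params.dt_ms / params.tau_u)
    d_m = np.exp(-params.dt_ms / params.tau_m)
    n_amp = params.noise
    rng = substream(seed, NETWORK_NOISE) if n_amp > 0 else None

    base_z = inputs_granule.I0
    mod_z = inputs_granule.f * inputs_granule.modulation * inputs_granule.I0
    base_q = inputs_golgi.I0
    mod_q = inputs_golgi.f * inputs_golgi.modulation * inputs_golgi.I0
    x = inputs_granule.x

    z = np.empty((T, nz))
    q = np.empty((T, nq))
    c_q = np.zeros(nq)   # Golgi-rate trace, tau_w kernel
    c_zu = np.zeros(nz)  # granule-rate trace, tau_u kernel
    c_zm = np.zeros(nz)  # granule-rate trace, tau_m kernel
    z_prev = None
    for t in range(T):
        if t > 0:
            c_q *= d_w
            c_q += q[t - 1]
            c_zu *= d_u
            c_zu += z_prev
            if has_m:
                c_zm *= d_m
                c_zm += z_prev
        fb_z, fb_q = _feedback_terms(feedback, t, z_prev)

        drive_z = np.maximum(base_z + mod_z * x[t], 0.0) - W @ c_q
        drive_q = U @ c_zu
        if has_m:
            drive_q = drive_q - M @ c_zm
        if params.g > 0:
            drive_q = drive_q + params.g * np.maximum(base_q + mod_q * x[t], 0.0)
        if n_amp > 0:
            drive_z += n_amp * (NOISE_STD * rng.standard_normal(nz))
            drive_q += n_amp * (NOISE_STD * rng.standard_normal(nq))
        if feedback is not None:
            drive_z = drive_z + fb_z
            drive_q = drive_q + fb_q
        np.maximum(drive_z, 0.0, out=drive_z)
        np.maximum(drive_q, 0.0, out=drive_q)
        mx = max(drive_z.max(), drive_q.max())
        if not mx < RATE_BOUND:
            raise NetworkInstabilityError(step=t, max_rate=mx)
        z[t] = drive_z
        q[t] = drive_q
        z_prev = z[t]
    return RateTraces(
        z=z, dt_ms=params.dt_ms, bounds=dict(inputs_granule.signal.bounds), q=q
    )
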