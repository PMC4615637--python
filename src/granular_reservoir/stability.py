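"""Empirical Lyapunov exponent and edge-of-chaos localization.

Stability is probed with the two-trajectory estimator: a baseline run with
x(t) = 0 is paired with a run whose input is disturbed by a tiny amount at
the first step only, x(0) = 1e-14 (the perturbation enters every cell
through its afferent mapping I_i(t)). The separation

    d(t) = || z(t) - z'(t) ||_2

over granule rates is averaged across randomly connected replicate
networks, and the exponent is the log-ratio of the mean separation in two
100 ms windows 2 s apart:

    lambda = log2( mean(d, 2.01-2.11 s) / mean(d, 0.01-0.11 s) ) / 2 s

in bits per second. Only the sign is interpreted: lambda > 0 marks chaos.
The edge of chaos is the first zero crossing of lambda when traversing a
weight grid from strong inhibition w to weak. No tangent-space or full
Lyapunov-spectrum machinery is used.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._streams import GOLGI_INPUT, replicate_seed
from .errors import ConfigurationError
from .network import (
    Connectivity,
    NetworkParams,
    build_connectivity_onepop,
    build_connectivity_twopop,
    simulate_one_population,
    simulate_two_population,
)
from .signals import LabeledSignal, expand_inputs

DEFAULT_PERTURBATION = 1e-14

#: separations below this are treated as exact zeros (double underflow floor)
UNDERFLOW_FLOOR = 1e-300

#: averaging windows of the exponent formula, in seconds (half-open)
EARLY_WINDOW_S = (0.01, 0.11)
LATE_WINDOW_S = (2.01, 2.11)


@dataclass
class LyapunovEstimate:
    """Exponent in bits/s with the two window means behind it.

    ``lam`` is -inf when the late separation underflows to zero and NaN
    (undefined) when the early separation is already zero.
    """

    lam: float
    d_mean_early: float
    d_mean_late: float
    n_networks: int
    d_bar: np.ndarray | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.lam)


def _silent_signal(n_steps: int, dt_ms: float, perturbation: float) -> LabeledSignal:
    x = np.zeros(n_steps)
    x[0] = perturbation
    return LabeledSignal(x=x, dt_ms=dt_ms, bounds={"probe": (0, n_steps)})


def state_separation(
    params: NetworkParams,
    connectivity: Connectivity,
    seed: int = 0,
    perturbation: float = DEFAULT_PERTURBATION,
    duration_s: float = LATE_WINDOW_S[1],
    *,
    model: str = "one",
    v_I: float = 0.1,
    push_pull: bool = True,
    feedback_builder=None,
) -> np.ndarray:
    """Euclidean granule-rate distance between perturbed and baseline runs.

    Both runs share the connectivity, afferent draws and (via common random
    numbers) any intrinsic-noise realization, so the separation reflects the
    dynamics rather than noise. ``feedback_builder``, if given, is called
    once per run with the silent signal and must return the feedback object
    to inject (used for closed-loop stability).
    """
    if perturbation < 0:
        raise ConfigurationError("perturbation must be nonnegative")
    n_steps = int(round(1000.0 * duration_s / params.dt_ms)) + 1
    runs = []
    for amp in (0.0, perturbation):
        sig = _silent_signal(n_steps, params.dt_ms, amp)
        inputs = expand_inputs(
            sig, params.n_granule, v_I=v_I, push_pull=push_pull, seed=seed
        )
        feedback = feedback_builder(sig) if feedback_builder is not None else None
        if model == "one":
            traces = simulate_one_population(params, connectivity, inputs, seed=seed,
                                             feedback=feedback)
        elif model == "two":
            inputs_q = expand_inputs(
                sig, params.n_golgi, v_I=v_I, push_pull=push_pull, seed=seed,
                stream_baseline=GOLGI_INPUT, stream_sign=GOLGI_INPUT + 100,
            )
            traces = simulate_two_population(
                params, connectivity, inputs, inputs_q, seed=seed, feedback=feedback
            )
        else:
            raise ConfigurationError(f"unknown model kind {model!r}")
        runs.append(traces.z)
    if runs[0].shape != runs[1].shape:
        raise RuntimeError("paired runs produced mismatched trace shapes")
    d = np.linalg.norm(runs[1] - runs[0], axis=1)
    d[d < UNDERFLOW_FLOOR] = 0.0
    return d


def lyapunov_from_distances(d_bar: np.ndarray, dt_ms: float = 1.0) -> tuple[float, float, float]:
    """(lambda, early mean, late mean) from an averaged separation series."""
    lo_e, hi_e = (int(round(1000.0 * s / dt_ms)) for s in EARLY_WINDOW_S)
    lo_l, hi_l = (int(round(1000.0 * s / dt_ms)) for s in LATE_WINDOW_S)
    if d_bar.size < hi_l:
        raise ConfigurationError("separation series shorter than the late window")
    early = float(d_bar[lo_e:hi_e].mean())
    late = float(d_bar[lo_l:hi_l].mean())
    span_s = LATE_WINDOW_S[0] - EARLY_WINDOW_S[0]
    if early <= 0.0:
        lam = math.nan  # undefined: nothing to amplify or contract
    elif late <= 0.0:
        lam = -math.inf
    else:
        lam = math.log2(late / early) / span_s
    return lam, early, late


def estimate_lyapunov(
    params: NetworkParams,
    n_networks: int = 10,
    seed: int = 0,
    perturbation: float = DEFAULT_PERTURBATION,
    *,
    model: str = "one",
    v_I: float = 0.1,
    push_pull: bool = True,
    keep_dbar: bool = False,
) -> LyapunovEstimate:
    """Average d(t) over replicate networks, then apply the exponent formula.

    The across-network mean separation is formed first and the log-ratio
    taken once (mean of distances, then ratio), matching the estimator's
    definition; per-network exponents are not averaged.
    """
    if n_networks < 1:
        raise ConfigurationError("n_networks must be >= 1")
    d_sum = None
    for rep in range(n_networks):
        rep_seed = replicate_seed(seed, rep)
        if model == "one":
            conn = build_connectivity_onepop(params, seed=rep_seed)
        else:
            conn = build_connectivity_twopop(params, seed=rep_seed)
        d = state_separation(
            params, conn, seed=rep_seed, perturbation=perturbation,
            model=model, v_I=v_I, push_pull=push_pull,
        )
        d_sum = d if d_sum is None else d_sum + d
    d_bar = d_sum / n_networks
    lam, early, late = lyapunov_from_distances(d_bar, params.dt_ms)
    return LyapunovEstimate(
        lam=lam,
        d_mean_early=early,
        d_mean_late=late,
        n_networks=n_networks,
        d_bar=d_bar if keep_dbar else None,
    )


def locate_edge_of_chaos(w_grid: np.ndarray, lam_per_w: np.ndarray) -> float | None:
    """First zero crossing of lambda scanning from strong inhibition to weak.

    Returns the midpoint of the bracketing grid interval where lambda drops
    from >= 0 to < 0, or None when lambda never crosses. Multiple crossings
    are resolved by the scan direction (first one from the high-w side);
    undefined (NaN) grid points are skipped.
    """
    w = np.asarray(w_grid, float)
    lam = np.asarray(lam_per_w, float)
    if w.size != lam.size:
        raise ConfigurationError("w_grid and lam_per_w must align")
    if w.size < 2 or np.any(np.diff(w) <= 0):
        raise ConfigurationError("w_grid must be sorted ascending with >= 2 points")
    ok = ~np.isnan(lam)
    w, lam = w[ok], lam[ok]
    for i in range(w.size - 1, 0, -1):
        if lam[i] >= 0 and lam[i - 1] < 0:
            return float(0.5 * (w[i - 1] + w[i]))
    return None
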