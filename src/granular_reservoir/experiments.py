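"""Experiment orchestration: weight sweeps, scenarios, output feedback.

Ties the other modules together into the study's experiment grid: for each
inhibitory weight w on a grid, estimate the Lyapunov exponent and the
replicate-mean construction quality of the three exponential target
filters; named scenarios apply the parameter variations of interest
(intrinsic noise, input/weight variability, sparseness, push-pull removal,
Golgi afferent excitation, mGluR2 inhibition, output feedback). The
output-feedback protocol models the nucleocortical pathway: the learned
slow-filter readout is injected back into 20% of granule and Golgi cells,
with the readout weights learned open loop by teacher forcing with noise.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._streams import FEEDBACK_WIRING, GOLGI_INPUT, TEACHER_NOISE, replicate_seed, substream
from .errors import ConfigurationError, NetworkInstabilityError
from .network import (
    FeedbackInjection,
    NetworkParams,
    build_connectivity_twopop,
    simulate_two_population,
)
from .readout import (
    DEFAULT_ALPHA,
    DEFAULT_TARGET_TAUS,
    FilterEvaluation,
    ReadoutFit,
    evaluate_filter_construction,
    fit_targets_from_traces,
    goodness_of_fit,
    target_response,
)
from .signals import SignalProtocol, build_signal_protocol, expand_inputs
from .stability import (
    LyapunovEstimate,
    estimate_lyapunov,
    locate_edge_of_chaos,
    lyapunov_from_distances,
    state_separation,
)


@dataclass(frozen=True)
class FeedbackSpec:
    """Wiring and training parameters of the output-feedback loop.

    The tau=500 ms readout is fed back to a fraction ``frac_cells`` of both
    populations with per-cell weight o_i = [N(o_mean, o_std)]^+ and a sign
    f = +1 with probability ``sign_split`` (50% excitation / inhibition by
    default). During teacher forcing the injected signal is the one-step
    delayed true target response times a multiplicative Gaussian noise of
    mean 1 and std ``teacher_noise_std``.

    The noise level sets the closed loop's memory: regressing on a noisy
    injection channel attenuates the learned loop gain by 1/(1 + sigma^2)
    (errors in variables), so the default sigma = sqrt(exp(dt/tau) - 1)
    ~ 0.045 makes the attenuated gain equal the fed-back filter's own
    per-step decay exp(-dt/tau) at tau = 500 ms, dt = 1 ms — the noise is
    calibrated to give the loop the memory of the filter it carries while
    keeping it on the stable side of unit gain.
    """

    target_tau: float = 500.0
    frac_cells: float = 0.2
    o_mean: float = 1e-4
    o_std: float = 1e-5
    sign_split: float = 0.5
    teacher_noise: bool = True
    teacher_noise_std: float = 0.045
    teacher_noise_per_cell: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.frac_cells <= 1:
            raise ConfigurationError("frac_cells must lie in (0, 1]")
        if self.o_mean < 0 or self.o_std < 0:
            raise ConfigurationError("feedback weight parameters must be nonnegative")
        if not 0 <= self.sign_split <= 1:
            raise ConfigurationError("sign_split must lie in [0, 1]")


def build_feedback_wiring(
    spec: FeedbackSpec, n_cells: int, seed: int, stream_offset: int = 0
) -> np.ndarray:
    """Signed injection weights f * o_i; zero outside the recipient set.

    Exactly round(frac_cells * n_cells) cells are drawn once per network
    and stay fixed across train and test.
    """
    rng = substream(seed, FEEDBACK_WIRING, stream_offset)
    n_recip = max(1, int(round(spec.frac_cells * n_cells)))
    recipients = rng.choice(n_cells, size=n_recip, replace=False)
    signs = np.where(rng.random(n_recip) < spec.sign_split, 1.0, -1.0)
    o = np.maximum(spec.o_mean + spec.o_std * rng.standard_normal(n_recip), 0.0)
    inj = np.zeros(n_cells)
    inj[recipients] = signs * o
    return inj


@dataclass
class SimulationConfig:
    """Fully serializable description of one experiment scenario."""

    scenario: str = "control"
    model: str = "one"
    network: NetworkParams = field(default_factory=NetworkParams)
    protocol: SignalProtocol = field(default_factory=SignalProtocol)
    push_pull: bool = True
    v_I: float = 0.1
    alpha: float = DEFAULT_ALPHA
    nonneg: bool = False
    target_taus: tuple[float, ...] = DEFAULT_TARGET_TAUS
    n_replicates: int = 10
    lyapunov_networks: int = 10
    w_grid: tuple[float, ...] = ()
    feedback: FeedbackSpec | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["target_taus"] = list(self.target_taus)
        d["w_grid"] = list(self.w_grid)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "network" in d and isinstance(d["network"], dict):
            d["network"] = NetworkParams(**d["network"])
        if "protocol" in d and isinstance(d["protocol"], dict):
            d["protocol"] = SignalProtocol(**d["protocol"])
        if d.get("feedback") is not None and isinstance(d["feedback"], dict):
            d["feedback"] = FeedbackSpec(**d["feedback"])
        if "target_taus" in d:
            d["target_taus"] = tuple(d["target_taus"])
        if "w_grid" in d:
            d["w_grid"] = tuple(d["w_grid"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_w_grid(n_points: int = 25, lo: float = 1e-3, hi: float = 5.0) -> tuple[float, ...]:
    """Log-spaced inhibitory-weight grid resolving the edge of chaos."""
    return tuple(float(w) for w in np.geomspace(lo, hi, n_points))


def scenario_config(name: str, **overrides) -> SimulationConfig:
    """Named scenario presets mapping to the study's figure conditions."""
    base: dict = dict(scenario=name)
    net: dict = {}
    if name == "control":
        pass
    elif name == "noise":
        net["noise"] = 0.01
    elif name == "input_variability":
        base["v_I"] = 2.0
    elif name == "weight_variability":
        net["v_w"] = 2.0
    elif name == "sparse":
        net["conn_prob"] = 0.04
    elif name == "no_pushpull":
        base["push_pull"] = False
    elif name == "twopop_control":
        base["model"] = "two"
    elif name == "golgi_afferent":
        base["model"] = "two"
        net["g"] = 1.0
    elif name == "mglur2":
        base["model"] = "two"
        net.update(m=0.003, v_m=0.1)
    elif name == "feedback":
        base["model"] = "two"
        base["feedback"] = FeedbackSpec()
    else:
        raise ConfigurationError(f"unknown scenario {name!r}")
    net_overrides = overrides.pop("network", {})
    if isinstance(net_overrides, NetworkParams):
        net_overrides = dataclasses.asdict(net_overrides)
    net.update(net_overrides)
    base.update(overrides)
    cfg = SimulationConfig(**base)
    if net:
        cfg = replace(cfg, network=cfg.network.with_(**net))
    if not cfg.w_grid:
        cfg = replace(cfg, w_grid=default_w_grid())
    return cfg


@dataclass
class SweepResult:
    """Per-weight Lyapunov exponents and filter qualities for one scenario."""

    config: SimulationConfig
    table: pd.DataFrame  # one row per w: lam, r2_tau*, frac_zero_tau*, n_failed
    edge_w: float | None

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def optima(self) -> dict[float, float]:
        """Best replicate-mean test R^2 per target filter over the grid."""
        out = {}
        for tau in self.config.target_taus:
            col = f"r2_tau{tau:g}"
            out[tau] = float(self.table[col].max())
        return out


def run_weight_sweep(config: SimulationConfig) -> SweepResult:
    """Lyapunov exponent and filter-construction quality across the w grid."""
    if not config.w_grid:
        raise ConfigurationError("w_grid must be nonempty")
    rows = []
    for iw, w in enumerate(config.w_grid):
        params = config.network.with_(w=float(w))
        if config.feedback is not None:
            row = _feedback_grid_point(config, params, iw)
        else:
            lyap = estimate_lyapunov(
                params,
                n_networks=config.lyapunov_networks,
                seed=config.seed,
                model=config.model,
                v_I=config.v_I,
                push_pull=config.push_pull,
            )
            ev = evaluate_filter_construction(
                params,
                config.protocol,
                taus=config.target_taus,
                n_replicates=config.n_replicates,
                seed=config.seed,
                model=config.model,
                push_pull=config.push_pull,
                v_I=config.v_I,
                alpha=config.alpha,
                nonneg=config.nonneg,
            )
            row = dict(w=float(w), lam=lyap.lam, n_failed=ev.n_failed)
            for tau in config.target_taus:
                sub = ev.table[ev.table["tau_ms"] == tau]
                row[f"r2_tau{tau:g}"] = float(sub["r2_test"].mean())
                row[f"r2_sd_tau{tau:g}"] = float(sub["r2_test"].std())
                row[f"frac_zero_tau{tau:g}"] = float(sub["frac_zero"].mean())
        rows.append(row)
    table = pd.DataFrame(rows)
    lam = table["lam"].to_numpy()
    edge = locate_edge_of_chaos(np.asarray(config.w_grid), lam) if len(rows) > 1 else None
    return SweepResult(config=config, table=table, edge_w=edge)


@dataclass
class TeacherForcedReadout:
    """Readouts learned open loop under teacher forcing, for one network."""

    fits: dict[float, ReadoutFit]
    feedback_spec: FeedbackSpec
    seed: int
    teacher_series: np.ndarray

    @property
    def beta(self) -> np.ndarray:
        return self.fits[self.feedback_spec.target_tau].beta


def _feedback_environment(params, protocol, feedback_spec, seed, push_pull, v_I):
    """Deterministically rebuild signal, inputs, wiring and connectivity."""
    signal = build_signal_protocol(protocol, seed=seed)
    inputs_z = expand_inputs(signal, params.n_granule, v_I=v_I, push_pull=push_pull, seed=seed)
    inputs_q = expand_inputs(
        signal, params.n_golgi, v_I=v_I, push_pull=push_pull, seed=seed,
        stream_baseline=GOLGI_INPUT, stream_sign=GOLGI_INPUT + 100,
    )
    conn = build_connectivity_twopop(params, seed=seed)
    inj_z = build_feedback_wiring(feedback_spec, params.n_granule, seed, stream_offset=0)
    inj_q = build_feedback_wiring(feedback_spec, params.n_golgi, seed, stream_offset=1)
    return signal, inputs_z, inputs_q, conn, inj_z, inj_q


def teacher_force_fit(
    params: NetworkParams,
    protocol: SignalProtocol,
    feedback_spec: FeedbackSpec,
    seed: int = 0,
    *,
    push_pull: bool = False,
    v_I: float = 0.1,
    alpha: float = DEFAULT_ALPHA,
    target_taus: tuple[float, ...] = DEFAULT_TARGET_TAUS,
) -> TeacherForcedReadout:
    """Learn readout weights open loop with the teacher signal injected.

    The network runs with L'(t) = f * o_i * (-y3(t) * N(t)) in place of the
    closed-loop feedback, where y3 is the true target response of the
    fed-back filter and N(t) a multiplicative Gaussian noise of mean 1.
    All target filters are then fitted on the training rows of this run.
    """
    if feedback_spec.target_tau not in target_taus:
        target_taus = tuple(target_taus) + (feedback_spec.target_tau,)
    signal, inputs_z, inputs_q, conn, inj_z, inj_q = _feedback_environment(
        params, protocol, feedback_spec, seed, push_pull, v_I
    )
    y_fb = target_response(signal.x, feedback_spec.target_tau, signal.dt_ms)
    # the closed loop feeds the readout of the PREVIOUS step into the update
    # (explicit scheme), so the consistent teacher is the one-step-delayed
    # target: the fit then learns the transition y(t) = decay*y(t-1) + x(t)
    # with the innovation supplied by the afferent x channels, instead of a
    # driverless unit-gain copy of the current target
    teacher = np.zeros_like(y_fb)
    teacher[1:] = -y_fb[:-1]
    noise_z = noise_q = None
    if feedback_spec.teacher_noise:
        rng = substream(seed, TEACHER_NOISE)
        sd = feedback_spec.teacher_noise_std
        if feedback_spec.teacher_noise_per_cell:
            T = signal.n_samples
            noise_z = 1.0 + sd * rng.standard_normal((T, params.n_granule))
            noise_q = 1.0 + sd * rng.standard_normal((T, params.n_golgi))
        else:
            teacher = teacher * (1.0 + sd * rng.standard_normal(signal.n_samples))
    fb = FeedbackInjection(
        granule_weights=inj_z, golgi_weights=inj_q, series=teacher,
        noise_granule=noise_z, noise_golgi=noise_q,
    )
    traces = simulate_two_population(params, conn, inputs_z, inputs_q, seed=seed, feedback=fb)
    fits = fit_targets_from_traces(traces, signal, target_taus, alpha=alpha)
    return TeacherForcedReadout(
        fits=fits, feedback_spec=feedback_spec, seed=seed, teacher_series=teacher
    )


@dataclass
class ClosedLoopResult:
    """Closed-loop construction quality and stability for one network."""

    r2: dict[float, float]
    lyapunov: LyapunovEstimate | None
    unstable: bool = False


def run_closed_loop(
    params: NetworkParams,
    protocol: SignalProtocol,
    feedback_spec: FeedbackSpec,
    beta: np.ndarray | TeacherForcedReadout,
    seed: int = 0,
    *,
    push_pull: bool = False,
    v_I: float = 0.1,
    score_fits: dict[float, ReadoutFit] | None = None,
    compute_lyapunov: bool = True,
) -> ClosedLoopResult:
    """Simulate with the loop closed through the learned slow readout.

    The injected signal is L(t) = f * o_i * (-sum_i beta_i z_i(t-1)); the
    same master seed as the teacher run reproduces the identical network,
    afferents and wiring. Scoring uses the teacher-learned coefficients on
    the test segment. Divergence is reported as an unstable outcome rather
    than raised.
    """
    if isinstance(beta, TeacherForcedReadout):
        score_fits = beta.fits if score_fits is None else score_fits
        beta = beta.beta
    if score_fits is None:
        raise ConfigurationError("score_fits (teacher-learned readouts) required")
    signal, inputs_z, inputs_q, conn, inj_z, inj_q = _feedback_environment(
        params, protocol, feedback_spec, seed, push_pull, v_I
    )
    fb = FeedbackInjection(granule_weights=inj_z, golgi_weights=inj_q, readout_beta=beta)
    try:
        traces = simulate_two_population(
            params, conn, inputs_z, inputs_q, seed=seed, feedback=fb
        )
    except NetworkInstabilityError:
        return ClosedLoopResult(
            r2={tau: np.nan for tau in score_fits}, lyapunov=None, unstable=True
        )
    test_idx = signal.indices("test_noise", "test_silence")
    r2 = {}
    for tau, fit in score_fits.items():
        y = target_response(signal.x, tau, signal.dt_ms)
        r2[tau] = goodness_of_fit(fit.predict(traces.z[test_idx]), y[test_idx])

    lyap = None
    if compute_lyapunov:
        def builder(sig):
            return FeedbackInjection(
                granule_weights=inj_z, golgi_weights=inj_q, readout_beta=beta
            )
        try:
            d = state_separation(
                params, conn, seed=seed, model="two", v_I=v_I,
                push_pull=push_pull, feedback_builder=builder,
            )
            lam, early, late = lyapunov_from_distances(d, params.dt_ms)
            lyap = LyapunovEstimate(lam=lam, d_mean_early=early, d_mean_late=late, n_networks=1)
        except NetworkInstabilityError:
            lyap = None
    return ClosedLoopResult(r2=r2, lyapunov=lyap, unstable=False)


def _feedback_grid_point(config: SimulationConfig, params: NetworkParams, iw: int) -> dict:
    """Replicate-mean closed-loop qualities at one w of a feedback sweep."""
    spec = config.feedback
    recs = []
    n_failed = 0
    lam_est = None
    for rep in range(config.n_replicates):
        rep_seed = replicate_seed(config.seed, rep)
        try:
            teacher = teacher_force_fit(
                params, config.protocol, spec, seed=rep_seed,
                push_pull=config.push_pull, v_I=config.v_I,
                alpha=config.alpha, target_taus=config.target_taus,
            )
        except NetworkInstabilityError:
            n_failed += 1
            continue
        # closed-loop stability measured once per grid point, on the first
        # replicate that trains successfully
        res = run_closed_loop(
            params, config.protocol, spec, teacher, seed=rep_seed,
            push_pull=config.push_pull, v_I=config.v_I,
            compute_lyapunov=(lam_est is None),
        )
        if res.lyapunov is not None and lam_est is None:
            lam_est = res.lyapunov
        if res.unstable:
            n_failed += 1
            continue
        recs.append(res.r2)
    row = dict(w=float(params.w), n_failed=n_failed)
    row["lam"] = lam_est.lam if lam_est is not None else np.nan
    for tau in config.target_taus:
        vals = [r[tau] for r in recs if tau in r]
        row[f"r2_tau{tau:g}"] = float(np.mean(vals)) if vals else np.nan
        row[f"r2_sd_tau{tau:g}"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        row[f"frac_zero_tau{tau:g}"] = np.nan
    return row


def write_manifest(path: str | Path, config: SimulationConfig, extra: dict | None = None) -> None:
    """JSON manifest (parameters, seeds, package version) for exact replay."""
    from . import __version__

    manifest = {"version": __version__, "config": config.to_dict()}
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
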