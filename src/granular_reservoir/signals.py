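"""Behavioral input signals and push-pull afferent coding.

The scalar signal x(t) mimics a behavioral variable such as head velocity:
band-limited (0-20 Hz) Gaussian noise for training and testing, silence
segments to anchor a zero baseline, and a 50 ms unit pulse probing the
impulse response. Each model cell i receives the rectified modulated drive

    I_i(t) = [I0_i + f_i * 0.1 * I0_i * x(t)]^+

with baseline I0_i ~ N(1, v_I) clipped at zero and a per-cell sign
f_i in {+1, -1}. With push-pull coding half the cells (f = +1, "type I")
are modulated in phase with the signal and half (f = -1, "type II") in
anti-phase, as in vestibular mossy fibers; without it every cell has
f = +1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._streams import INPUT_BASELINE, PUSH_PULL, TEST_NOISE, TRAIN_NOISE, substream
from .errors import ConfigurationError

SEGMENT_ORDER = ("train_noise", "train_silence", "test_noise", "test_silence", "impulse")

#: fractional modulation depth of the afferent drive around its baseline
MODULATION_DEPTH = 0.1


@dataclass(frozen=True)
class SignalProtocol:
    """Timing and amplitude parameters of the input signal x(t).

    Durations are in seconds except where the name says otherwise. The
    defaults give 5 s of colored noise plus 5 s of silence for training,
    the same again (with a fresh noise realization) for testing, and a
    final segment that is zero except for a 50 ms pulse of amplitude 1 at
    its start. The noise is low-passed at ``lowpass_hz`` and rescaled to
    ``target_std`` exactly.
    """

    dt_ms: float = 1.0
    train_noise_s: float = 5.0
    train_silence_s: float = 5.0
    test_noise_s: float = 5.0
    test_silence_s: float = 5.0
    impulse_segment_s: float = 2.0
    impulse_duration_ms: float = 50.0
    impulse_amplitude: float = 1.0
    lowpass_hz: float = 20.0
    target_std: float = 0.5

    def __post_init__(self) -> None:
        durations = (
            self.dt_ms,
            self.train_noise_s,
            self.train_silence_s,
            self.test_noise_s,
            self.test_silence_s,
            self.impulse_segment_s,
            self.impulse_duration_ms,
        )
        if any(d <= 0 for d in durations):
            raise ConfigurationError("all protocol durations must be positive")
        nyquist = 500.0 / self.dt_ms
        if not 0 < self.lowpass_hz < nyquist:
            raise ConfigurationError(
                f"lowpass_hz must lie in (0, {nyquist}) for dt={self.dt_ms} ms"
            )
        if self.target_std < 0:
            raise ConfigurationError("target_std must be nonnegative")
        if self.impulse_duration_ms > 1000.0 * self.impulse_segment_s:
            raise ConfigurationError("impulse pulse longer than its segment")

    def n_samples(self, duration_s: float) -> int:
        return int(round(1000.0 * duration_s / self.dt_ms))


@dataclass
class LabeledSignal:
    """Scalar time series with named, half-open segment index ranges."""

    x: np.ndarray
    dt_ms: float
    bounds: dict[str, tuple[int, int]]

    @property
    def n_samples(self) -> int:
        return self.x.size

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def segment(self, label: str) -> np.ndarray:
        lo, hi = self.bounds[label]
        return self.x[lo:hi]

    def indices(self, *labels: str) -> np.ndarray:
        """Concatenated sample indices of the given segments, in signal order."""
        idx = [np.arange(*self.bounds[lab]) for lab in labels]
        return np.concatenate(idx) if idx else np.empty(0, dtype=int)

    def labels_per_sample(self) -> np.ndarray:
        out = np.empty(self.n_samples, dtype=object)
        for lab, (lo, hi) in self.bounds.items():
            out[lo:hi] = lab
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time_ms, "segment_label": self.labels_per_sample(), "x": self.x}
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "LabeledSignal":
        df = pd.read_csv(path)
        x = df["x"].to_numpy(float)
        dt = float(df["time_ms"].iloc[1] - df["time_ms"].iloc[0]) if len(df) > 1 else 1.0
        bounds: dict[str, tuple[int, int]] = {}
        labs = df["segment_label"].to_numpy()
        for lab in pd.unique(labs):
            pos = np.flatnonzero(labs == lab)
            bounds[str(lab)] = (int(pos[0]), int(pos[-1]) + 1)
        return cls(x=x, dt_ms=dt, bounds=bounds)


def generate_colored_noise(
    duration_s: float,
    dt_ms: float = 1.0,
    lowpass_hz: float = 20.0,
    target_std: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Band-limited Gaussian noise with an exactly rescaled standard deviation.

    White Gaussian noise is filtered by zeroing every discrete Fourier
    component above ``lowpass_hz`` (brick-wall), then rescaled so that
    std(x) equals ``target_std`` exactly. Deterministic given the seed.
    """
    if duration_s <= 0:
        raise ConfigurationError("duration_s must be positive")
    if not 0 < lowpass_hz < 500.0 / dt_ms:
        raise ConfigurationError("lowpass_hz must lie below the Nyquist frequency")
    if target_std < 0:
        raise ConfigurationError("target_std must be nonnegative")
    n = int(round(1000.0 * duration_s / dt_ms))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    if target_std == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=dt_ms / 1000.0)
    spec[freqs > lowpass_hz] = 0.0
    spec[0] = 0.0  # band-pass: a behavioral velocity signal carries no DC
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    if sd == 0:
        raise ConfigurationError("degenerate noise realization (zero variance)")
    return x * (target_std / sd)


def build_signal_protocol(protocol: SignalProtocol, seed: int = 0) -> LabeledSignal:
    """Assemble x(t): train noise | train silence | test noise | test silence | impulse.

    The train and test noise segments are independent realizations (separate
    sub-streams of the master seed). The impulse segment is zero except for
    a pulse of ``impulse_duration_ms`` at ``impulse_amplitude`` placed at the
    start of the segment.
    """
    p = protocol
    train = generate_colored_noise(
        p.train_noise_s, p.dt_ms, p.lowpass_hz, p.target_std, substream(seed, TRAIN_NOISE)
    )
    test = generate_colored_noise(
        p.test_noise_s, p.dt_ms, p.lowpass_hz, p.target_std, substream(seed, TEST_NOISE)
    )
    pieces = {
        "train_noise": train,
        "train_silence": np.zeros(p.n_samples(p.train_silence_s)),
        "test_noise": test,
        "test_silence": np.zeros(p.n_samples(p.test_silence_s)),
    }
    impulse = np.zeros(p.n_samples(p.impulse_segment_s))
    n_pulse = int(round(p.impulse_duration_ms / p.dt_ms))
    impulse[:n_pulse] = p.impulse_amplitude
    pieces["impulse"] = impulse

    bounds: dict[str, tuple[int, int]] = {}
    cursor = 0
    chunks = []
    for lab in SEGMENT_ORDER:
        seg = pieces[lab]
        bounds[lab] = (cursor, cursor + seg.size)
        cursor += seg.size
        chunks.append(seg)
    return LabeledSignal(x=np.concatenate(chunks), dt_ms=p.dt_ms, bounds=bounds)


@dataclass
class InputEnsemble:
    """Per-cell afferent drive derived from the scalar signal.

    ``I0`` is the baseline drive (mean 1, std v_I, clipped nonnegative) and
    ``f`` the per-cell modulation sign. The full drive matrix I (time x
    cells) is materialized on demand; simulators compute rows on the fly.
    """

    signal: LabeledSignal
    I0: np.ndarray
    f: np.ndarray
    modulation: float = MODULATION_DEPTH

    @property
    def x(self) -> np.ndarray:
        return self.signal.x

    @property
    def n_cells(self) -> int:
        return self.I0.size

    def drive_row(self, t: int) -> np.ndarray:
        """Rectified afferent drive vector at time step t."""
        return np.maximum(self.I0 + self.f * self.modulation * self.I0 * self.x[t], 0.0)

    @property
    def I(self) -> np.ndarray:
        """Full (time x cells) rectified drive matrix."""
        raw = self.I0[None, :] + (self.f * self.modulation * self.I0)[None, :] * self.x[:, None]
        return np.maximum(raw, 0.0)


def expand_inputs(
    signal: LabeledSignal | np.ndarray,
    n_cells: int,
    v_I: float = 0.1,
    push_pull: bool = True,
    seed: int = 0,
    stream_baseline: int = INPUT_BASELINE,
    stream_sign: int = PUSH_PULL,
) -> InputEnsemble:
    """Expand the scalar signal into per-cell rectified afferent drives.

    ``stream_baseline``/``stream_sign`` select the sub-streams used for the
    baseline and sign draws, so an independent ensemble can be drawn for a
    second population (e.g. Golgi afferents) from the same master seed.
    """
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if v_I < 0:
        raise ConfigurationError("v_I must be nonnegative")
    if isinstance(signal, np.ndarray):
        signal = LabeledSignal(
            x=np.asarray(signal, float), dt_ms=1.0, bounds={"all": (0, signal.size)}
        )
    rng_base = substream(seed, stream_baseline)
    I0 = np.maximum(1.0 + v_I * rng_base.standard_normal(n_cells), 0.0)
    if push_pull:
        rng_sign = substream(seed, stream_sign)
        f = np.where(rng_sign.random(n_cells) < 0.5, 1.0, -1.0)
    else:
        f = np.ones(n_cells)
    return InputEnsemble(signal=signal, I0=I0, f=f)
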