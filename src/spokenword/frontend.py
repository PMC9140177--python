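"""Acoustic front end: waveforms, MFCC feature trajectories and segment noise.

The model's input representation is a trajectory of 39-dimensional feature
vectors (13 mel-frequency cepstral coefficients plus their first and second
time derivatives), computed over 25 ms windows every 10 ms, i.e. at 100
frames per second.  These vectors approximate the spectro-temporal receptive
field input that downstream state emission densities are matched against.

Degradation experiments superimpose white noise on a chosen segment of the
stimulus at a specified signal-to-noise ratio, leaving the rest of the
waveform untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct
from scipy.io import wavfile
from scipy.signal import resample_poly

__all__ = [
    "Waveform",
    "FeatureTrajectory",
    "NoiseSpec",
    "FrontendConfig",
    "extract_features",
    "compute_deltas",
    "add_segment_noise",
    "read_wav",
    "write_wav",
]

CANONICAL_RATE = 16_000


@dataclass(frozen=True)
class Waveform:
    """Mono PCM audio held as float samples in [-1, 1]."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(
                f"waveform must be mono (1-D); got shape {samples.shape}"
            )
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        object.__setattr__(self, "samples", samples)

    @property
    def duration_ms(self) -> float:
        return 1000.0 * len(self.samples) / self.rate


@dataclass(frozen=True)
class FeatureTrajectory:
    """T x 39 matrix of per-frame acoustic vectors.

    Columns 0-12 are static cepstra (c0 carries signal energy), 13-25 the
    first and 26-38 the second time derivatives.  Frames are ``frame_step_ms``
    apart; ``t0_ms`` is the centre time of the first frame.
    """

    frames: np.ndarray
    frame_step_ms: float = 10.0
    window_ms: float = 25.0
    t0_ms: float = 12.5

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.float64)
        if frames.ndim != 2 or frames.shape[1] != 39:
            raise ValueError(f"expected T x 39 frames, got shape {frames.shape}")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_times_ms(self) -> np.ndarray:
        return self.t0_ms + self.frame_step_ms * np.arange(self.n_frames)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-noise specification for a contiguous stimulus interval."""

    start_ms: float
    end_ms: float
    snr_db: float
    kind: str = "white"

    def __post_init__(self) -> None:
        if not 0 <= self.start_ms < self.end_ms:
            raise ValueError(
                f"need 0 <= start_ms < end_ms, got [{self.start_ms}, {self.end_ms})"
            )
        if self.kind != "white":
            raise ValueError(f"unsupported noise kind {self.kind!r}")


@dataclass(frozen=True)
class FrontendConfig:
    """MFCC analysis parameters.

    Defaults are the conventional speech-analysis settings: 25 ms Hamming
    windows every 10 ms, pre-emphasis 0.97, a 26-filter mel bank spanning
    0 Hz to Nyquist, 13 cepstra with the 0th term carrying energy, and
    derivative regression over +/-2 frames.
    """

    window_ms: float = 25.0
    step_ms: float = 10.0
    pre_emphasis: float = 0.97
    n_mel_filters: int = 26
    n_cepstra: int = 13
    delta_half_window: int = 2
    low_freq_hz: float = 0.0
    high_freq_hz: float | None = None  # None -> Nyquist


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(
    n_filters: int, n_fft: int, rate: int, low_hz: float, high_hz: float
) -> np.ndarray:
    """Triangular mel-spaced filterbank, shape (n_filters, n_fft//2 + 1)."""
    mel_points = np.linspace(_hz_to_mel(low_hz), _hz_to_mel(high_hz), n_filters + 2)
    hz_points = np.asarray(_mel_to_hz(mel_points))
    bins = np.floor((n_fft + 1) * hz_points / rate).astype(int)
    fbank = np.zeros((n_filters, n_fft // 2 + 1))
    for i in range(n_filters):
        left, centre, right = bins[i], bins[i + 1], bins[i + 2]
        for k in range(left, centre):
            if centre > left:
                fbank[i, k] = (k - left) / (centre - left)
        for k in range(centre, right):
            if right > centre:
                fbank[i, k] = (right - k) / (right - centre)
    return fbank


def _frame_signal(x: np.ndarray, window: int, step: int) -> np.ndarray:
    """Slice into overlapping frames; the last partial frame is zero-padded."""
    n = len(x)
    n_frames = 1 + int(np.ceil((n - window) / step))
    padded = np.zeros((n_frames - 1) * step + window)
    padded[:n] = x
    idx = np.arange(window)[None, :] + step * np.arange(n_frames)[:, None]
    return padded[idx]


def frame_count(n_samples: int, rate: int, window_ms: float = 25.0,
                step_ms: float = 10.0) -> int:
    """Closed-form number of analysis frames for a signal of given length."""
    window = int(round(window_ms * rate / 1000.0))
    step = int(round(step_ms * rate / 1000.0))
    if n_samples < window:
        raise ValueError("signal shorter than one analysis window")
    return 1 + int(np.ceil((n_samples - window) / step))


def compute_deltas(statics: np.ndarray, half_window: int = 2) -> np.ndarray:
    """Regression-based first and second derivatives of per-frame features.

    Returns a T x 2D matrix (first derivatives then second derivatives) for
    a T x D input.  The derivative at frame t is the least-squares slope of
    the feature over frames t-W .. t+W; edges are padded by replication, so
    a single-frame input has all-zero derivatives.
    """
    statics = np.atleast_2d(np.asarray(statics, dtype=np.float64))
    if half_window < 1:
        raise ValueError(f"half_window must be >= 1, got {half_window}")
    if statics.shape[0] < 1:
        raise ValueError("need at least one frame")

    def _delta(x: np.ndarray) -> np.ndarray:
        w = half_window
        padded = np.pad(x, ((w, w), (0, 0)), mode="edge")
        num = np.zeros_like(x)
        for n in range(1, w + 1):
            num += n * (padded[w + n : w + n + len(x)] - padded[w - n : w - n + len(x)])
        return num / (2.0 * sum(n * n for n in range(1, w + 1)))

    d1 = _delta(statics)
    d2 = _delta(d1)
    return np.hstack([d1, d2])


def extract_features(
    w: Waveform, config: FrontendConfig | None = None
) -> FeatureTrajectory:
    """Map a waveform to its 39-dimensional MFCC trajectory.

    Static cepstra are the first 13 DCT-II coefficients of the log mel-band
    energies of each pre-emphasised, Hamming-windowed 25 ms frame; the 0th
    coefficient therefore carries overall energy.  Derivatives are appended
    by :func:`compute_deltas`.
    """
    cfg = config or FrontendConfig()
    if w.rate < 8000:
        raise ValueError(f"sampling rate {w.rate} Hz too low; need >= 8000 Hz")
    if len(w.samples) == 0:
        raise ValueError("empty waveform")

    window = int(round(cfg.window_ms * w.rate / 1000.0))
    step = int(round(cfg.step_ms * w.rate / 1000.0))
    if len(w.samples) < window:
        raise ValueError(
            f"waveform of {len(w.samples)} samples shorter than one "
            f"{window}-sample analysis window"
        )

    x = np.append(w.samples[0], w.samples[1:] - cfg.pre_emphasis * w.samples[:-1])
    frames = _frame_signal(x, window, step)
    frames = frames * np.hamming(window)

    n_fft = int(2 ** np.ceil(np.log2(window)))
    power = np.abs(np.fft.rfft(frames, n_fft), dtype=np.float64) ** 2 / n_fft
    high = cfg.high_freq_hz if cfg.high_freq_hz is not None else w.rate / 2.0
    fbank = mel_filterbank(cfg.n_mel_filters, n_fft, w.rate, cfg.low_freq_hz, high)
    mel_energy = power @ fbank.T
    mel_energy = np.maximum(mel_energy, np.finfo(np.float64).tiny)
    cepstra = dct(np.log(mel_energy), type=2, axis=1, norm="ortho")[:, : cfg.n_cepstra]

    deltas = compute_deltas(cepstra, cfg.delta_half_window)
    return FeatureTrajectory(
        frames=np.hstack([cepstra, deltas]),
        frame_step_ms=cfg.step_ms,
        window_ms=cfg.window_ms,
        t0_ms=cfg.window_ms / 2.0,
    )


def add_segment_noise(w: Waveform, spec: NoiseSpec, seed: int) -> Waveform:
    """Superimpose white noise on [start_ms, end_ms) at the requested SNR.

    The noise is scaled so that 10*log10(segment signal power / noise power)
    equals ``spec.snr_db``, with both powers measured over the noised
    interval only.  Samples outside the interval are returned untouched.
    """
    i0 = int(round(spec.start_ms * w.rate / 1000.0))
    i1 = int(round(spec.end_ms * w.rate / 1000.0))
    if i1 > len(w.samples):
        raise ValueError(
            f"noise interval end {spec.end_ms} ms exceeds stimulus "
            f"duration {w.duration_ms:.1f} ms"
        )
    if i1 <= i0:
        raise ValueError("noise interval is empty at this sampling rate")

    rng = np.random.default_rng(seed)
    segment = w.samples[i0:i1]
    signal_power = float(np.mean(segment**2))
    noise = rng.standard_normal(i1 - i0)
    noise_power = float(np.mean(noise**2))
    target_noise_power = signal_power / (10.0 ** (spec.snr_db / 10.0))
    noise *= np.sqrt(target_noise_power / noise_power)

    out = w.samples.copy()
    out[i0:i1] = segment + noise
    return Waveform(out, w.rate)


def read_wav(path: str) -> Waveform:
    """Read a PCM WAV file as mono float samples, resampling to 16 kHz."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    else:
        samples = data.astype(np.float64)
    if rate != CANONICAL_RATE:
        g = np.gcd(int(rate), CANONICAL_RATE)
        samples = resample_poly(samples, CANONICAL_RATE // g, int(rate) // g)
        rate = CANONICAL_RATE
    return Waveform(samples, rate)


def write_wav(path: str, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    wavfile.write(path, w.rate, (clipped * 32767.0).astype(np.int16))


def trajectory_to_csv(ft: FeatureTrajectory, path: str) -> None:
    """Write one row per frame: time_ms then the 39 feature columns."""
    import pandas as pd

    cols = (
        [f"c{i}" for i in range(13)]
        + [f"d{i}" for i in range(13)]
        + [f"dd{i}" for i in range(13)]
    )
    df = pd.DataFrame(ft.frames, columns=cols)
    df.insert(0, "time_ms", ft.frame_times_ms())
    df.to_csv(path, index=False)
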