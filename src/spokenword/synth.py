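"""Synthetic speech worlds with known ground truth.

Generates toy phone inventories (per-phone stationary spectral profiles
plus matching three-state emission models), noise-excited waveforms
concatenating per-phone spectral segments, Zipf-distributed lexicons over
the inventory, and trial lists for identification / lexical-decision
experiments — so the whole recognition pipeline is testable end to end
without any external speech data.

A phone is defined by a smooth random log-energy profile over the mel
bands, scaled by a separation parameter; its head/body/tail states perturb
that profile slightly.  Waveform synthesis filters white noise through the
corresponding spectral envelope, which is sufficient to exercise an MFCC
front end (the model is insensitive to pitch, so no voicing source is
simulated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct
from scipy.signal import firwin2, lfilter

from .acoustic import (
    LabeledSegment,
    ModelSet,
    N_STATES,
    PhoneModel,
    StateModel,
)
from .frontend import (
    FeatureTrajectory,
    FrontendConfig,
    NoiseSpec,
    Waveform,
    add_segment_noise,
    extract_features,
)
from .lexicon import LexiconEntry, PseudoWordNetwork, build_pseudoword_network, entry_keys

__all__ = [
    "GroundTruth",
    "StimulusSpec",
    "Trial",
    "make_phone_inventory",
    "synthesize_word_waveform",
    "make_zipf_lexicon",
    "generate_experiment",
    "make_training_data",
    "segment_trajectory",
    "noise_over_phone",
]

PHONE_POOL = [
    "a", "e", "i", "o", "u", "p", "t", "k", "s", "m",
    "n", "l", "r", "f", "x", "b", "d", "g", "w", "j",
]

#: Study-condition defaults: per-phone durations drawn uniformly on this
#: range (ms), exercising the self-loop duration model.
DURATION_RANGE_MS = (60.0, 160.0)

#: Ground-truth emission variances in feature units (statics, derivatives).
STATIC_VAR = 1.0
DELTA_VAR = 0.25

#: Ground-truth self-loop probability; mean state dwell of 5 frames.
TRUE_SELF_LOOP = 0.8


@dataclass
class GroundTruth:
    """A generating world: spectral profiles, emission models, lexicon."""

    phones: list[str]
    spectral_profiles: dict[str, np.ndarray]  # phone -> (3, n_mel) log energies
    model_set: ModelSet  # keyed ('*', phone, '*')
    seed: int
    rate: int = 16_000
    separation: float = 4.0
    lexicon: list[LexiconEntry] = field(default_factory=list)

    def phone_model(self, phone: str) -> PhoneModel:
        return self.model_set[("*", phone, "*")]

    def model_set_for(self, entries: list[LexiconEntry]) -> ModelSet:
        """Context-dependent model set covering all sharing keys of entries,
        each key a copy of the phone's ground-truth model (the truth is
        context-independent, so copies are exact)."""
        ms = ModelSet()
        next_id = 0
        keys = []
        for e in entries:
            for key in entry_keys(e.phones):
                if key not in ms:
                    keys.append(key)
                    src = self.phone_model(key[1])
                    states = []
                    for s in src.states:
                        states.append(
                            StateModel(next_id, s.weights.copy(), s.means.copy(),
                                       s.variances.copy())
                        )
                        next_id += 1
                    ms.models[key] = PhoneModel(
                        phone=key[1],
                        left_ctx=key[0],
                        right_ctx=key[2],
                        states=states,
                        self_loop=src.self_loop.copy(),
                        advance=src.advance.copy(),
                    )
        return ms


@dataclass(frozen=True)
class StimulusSpec:
    """One stimulus to synthesize: phones, durations, optional noise."""

    target: tuple[str, ...]
    is_word: bool
    durations_ms: tuple[float, ...]
    noise: NoiseSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "target", tuple(self.target))
        object.__setattr__(self, "durations_ms", tuple(self.durations_ms))
        if len(self.target) != len(self.durations_ms):
            raise ValueError("need one duration per phone")
        if any(d <= 0 for d in self.durations_ms):
            raise ValueError("durations must be positive")

    @property
    def duration_ms(self) -> float:
        return float(sum(self.durations_ms))


@dataclass(frozen=True)
class Trial:
    stimulus_id: str
    spec: StimulusSpec
    truth_label: str  # orthography for words, "pseudo-word" for pseudo trials


def _smooth_profile(rng: np.random.Generator, n_mel: int, scale: float) -> np.ndarray:
    """Random smooth log-energy profile over the mel bands."""
    z = rng.standard_normal(n_mel + 8)
    kernel = np.exp(-0.5 * (np.arange(-4, 5) / 2.0) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(z, kernel, mode="valid")
    smooth = smooth / max(np.std(smooth), 1e-12)
    return scale * smooth


def make_phone_inventory(
    n_phones: int,
    separation: float = 4.0,
    seed: int = 0,
    n_mel: int = 26,
    rate: int = 16_000,
) -> GroundTruth:
    """Draw a phone inventory with controllable acoustic separation.

    Each phone gets a smooth random mel log-energy profile scaled by
    ``separation`` (0 makes all phones statistically identical), plus
    per-state perturbations a quarter of that size giving head-body-tail
    structure.  Ground-truth emission means are the first 13 DCT
    coefficients of the state profiles with zero derivative components.
    """
    if n_phones < 2:
        raise ValueError("need at least 2 phones")
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    phones = [
        PHONE_POOL[i] if i < len(PHONE_POOL) else f"q{i}" for i in range(n_phones)
    ]
    profiles: dict[str, np.ndarray] = {}
    ms = ModelSet()
    next_id = 0
    for phone in phones:
        base = _smooth_profile(rng, n_mel, separation)
        state_profiles = np.stack(
            [base + _smooth_profile(rng, n_mel, 0.25 * separation)
             for _ in range(N_STATES)]
        )
        profiles[phone] = state_profiles
        states = []
        for s in range(N_STATES):
            statics = dct(state_profiles[s], type=2, norm="ortho")[:13]
            mean = np.concatenate([statics, np.zeros(26)])
            var = np.concatenate(
                [np.full(13, STATIC_VAR), np.full(26, DELTA_VAR)]
            )
            states.append(StateModel(next_id, np.ones(1), mean[None, :], var[None, :]))
            next_id += 1
        ms.models[("*", phone, "*")] = PhoneModel(
            phone=phone,
            left_ctx="*",
            right_ctx="*",
            states=states,
            self_loop=np.full(N_STATES, TRUE_SELF_LOOP),
            advance=np.full(N_STATES, 1.0 - TRUE_SELF_LOOP),
        )
    return GroundTruth(
        phones=phones,
        spectral_profiles=profiles,
        model_set=ms,
        seed=seed,
        rate=rate,
        separation=separation,
    )


def _mel_band_freqs(n_mel: int, rate: int) -> np.ndarray:
    """Centre frequencies (Hz) of the mel bands, matching the front end."""
    from .frontend import _hz_to_mel, _mel_to_hz

    mel_points = np.linspace(_hz_to_mel(0.0), _hz_to_mel(rate / 2.0), n_mel + 2)
    return np.asarray(_mel_to_hz(mel_points))[1:-1]


def synthesize_word_waveform(spec: StimulusSpec, gt: GroundTruth) -> Waveform:
    """Noise-excited synthesis: concatenated per-phone spectral segments.

    Each phone's duration is split over its head/body/tail profiles; each
    third is white noise filtered through an FIR approximation of the
    profile's spectral envelope, normalised to a common RMS.  Segment
    noise, if specified, is superimposed afterwards.
    """
    for p in spec.target:
        if p not in gt.spectral_profiles:
            raise KeyError(f"phone {p!r} not in inventory")
    rng = np.random.default_rng(spec.seed)
    rate = gt.rate
    n_mel = gt.spectral_profiles[spec.target[0]].shape[1]
    freqs = _mel_band_freqs(n_mel, rate)
    nyq = rate / 2.0
    pieces = []
    for phone, dur in zip(spec.target, spec.durations_ms):
        n_total = int(round(dur * rate / 1000.0))
        cuts = [int(np.floor(s * n_total / N_STATES)) for s in range(N_STATES + 1)]
        prof = gt.spectral_profiles[phone]
        for s in range(N_STATES):
            n = cuts[s + 1] - cuts[s]
            if n == 0:
                continue
            gains = np.exp(prof[s] / 2.0)  # amplitude from log power
            f = np.concatenate([[0.0], freqs / nyq, [1.0]])
            g = np.concatenate([[gains[0]], gains, [gains[-1]]])
            taps = firwin2(129, f, g)
            seg = lfilter(taps, [1.0], rng.standard_normal(n + 129))[129 : 129 + n]
            rms = np.sqrt(np.mean(seg**2))
            pieces.append(0.1 * seg / max(rms, 1e-12))
    w = Waveform(np.concatenate(pieces), rate)
    if spec.noise is not None:
        w = add_segment_noise(w, spec.noise, seed=int(rng.integers(2**31 - 1)))
    return w


def segment_trajectory(
    ft: FeatureTrajectory, spec: StimulusSpec
) -> list[tuple[str, int, int]]:
    """Frame spans per phone: (phone, start frame, end frame) half-open.

    Frames are assigned to phones by frame-centre time; trailing frames go
    to the last phone.
    """
    bounds = np.cumsum([0.0, *spec.durations_ms])
    centers = ft.frame_times_ms()
    idx = np.clip(
        np.searchsorted(bounds, centers, side="right") - 1,
        0,
        len(spec.target) - 1,
    )
    out = []
    for i, phone in enumerate(spec.target):
        sel = np.flatnonzero(idx == i)
        if len(sel):
            out.append((phone, int(sel[0]), int(sel[-1]) + 1))
    return out


def make_zipf_lexicon(
    n_words: int,
    inventory: list[str],
    min_len: int = 3,
    max_len: int = 6,
    zipf_s: float = 1.0,
    seed: int = 0,
) -> list[LexiconEntry]:
    """Unique random phone strings with Zipf-distributed frequencies.

    Frequencies are proportional to rank^(-zipf_s) (rank 1 the most
    frequent), scaled to a top count of 1000 tokens; zipf_s = 0 gives a
    flat distribution.
    """
    if n_words < 1:
        raise ValueError("n_words must be >= 1")
    n_available = sum(len(inventory) ** L for L in range(min_len, max_len + 1))
    if n_words > n_available:
        raise ValueError(
            f"cannot draw {n_words} distinct strings from {n_available} available"
        )
    rng = np.random.default_rng(seed)
    strings: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    while len(strings) < n_words:
        L = int(rng.integers(min_len, max_len + 1))
        s = tuple(rng.choice(inventory, size=L))
        if s not in seen:
            seen.add(s)
            strings.append(s)
    entries = []
    for rank, phones in enumerate(strings, start=1):
        freq = max(1.0, np.round(1000.0 / rank**zipf_s))
        entries.append(LexiconEntry(f"w{rank:03d}", phones, freq))
    return entries


def sample_pseudo_string(
    pw: PseudoWordNetwork,
    rng: np.random.Generator,
    min_len: int = 3,
    max_len: int = 6,
    max_tries: int = 1000,
) -> tuple[str, ...]:
    """Random walk through the licensing network avoiding lexical strings."""
    starts = sorted(pw.starts())
    if not starts:
        raise ValueError("empty licensing network")
    for _ in range(max_tries):
        path = [starts[int(rng.integers(len(starts)))]]
        target_len = int(rng.integers(min_len, max_len + 1))
        while len(path) < target_len:
            succ = sorted(pw.successors(path[-1]))
            if not succ:
                break
            path.append(succ[int(rng.integers(len(succ)))])
        t = tuple(path)
        if pw.accepts(t) and t not in pw.lexical_strings:
            return t
    raise RuntimeError("could not sample a pseudo-word; network too constrained")


def generate_experiment(
    lexicon: list[LexiconEntry],
    gt: GroundTruth,
    n_trials: int,
    p_pseudo: float = 0.0,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> list[Trial]:
    """Trial list with ground-truth labels.

    Each trial is a pseudo-word with probability p_pseudo (drawn from the
    phonotactic network, never equal to an entry) and otherwise a word
    drawn uniformly from the lexicon; per-phone durations are uniform on
    the configured range.  Every trial carries its own waveform seed.
    """
    if not 0 <= p_pseudo <= 1:
        raise ValueError("p_pseudo must be in [0, 1]")
    pw = build_pseudoword_network(lexicon)
    if p_pseudo > 0 and not pw.starts():
        raise ValueError("pseudo trials requested but licensing network is empty")
    rng = np.random.default_rng(seed)
    lo, hi = DURATION_RANGE_MS
    trials = []
    for i in range(n_trials):
        if rng.random() < p_pseudo:
            phones = sample_pseudo_string(pw, rng)
            is_word, label = False, "pseudo-word"
        else:
            e = lexicon[int(rng.integers(len(lexicon)))]
            phones, is_word, label = e.phones, True, e.orthography
        durations = tuple(rng.uniform(lo, hi, size=len(phones)))
        trials.append(
            Trial(
                stimulus_id=f"trial{i:04d}",
                spec=StimulusSpec(
                    target=phones,
                    is_word=is_word,
                    durations_ms=durations,
                    noise=noise,
                    seed=int(rng.integers(2**31 - 1)),
                ),
                truth_label=label,
            )
        )
    return trials


def make_training_data(
    gt: GroundTruth,
    entries: list[LexiconEntry],
    n_tokens_per_word: int = 5,
    seed: int = 0,
    frontend: FrontendConfig | None = None,
) -> list[LabeledSegment]:
    """Labelled phone segments from synthesized tokens of every entry.

    Synthesizes ``n_tokens_per_word`` waveforms per lexicon entry with
    random durations, extracts features, and cuts them into per-phone
    segments labelled with the entry's context-dependent sharing keys —
    guaranteeing every key of the lexicon is attested.
    """
    rng = np.random.default_rng(seed)
    lo, hi = DURATION_RANGE_MS
    labeled: list[LabeledSegment] = []
    for e in entries:
        keys = entry_keys(e.phones)
        for _ in range(n_tokens_per_word):
            durations = tuple(rng.uniform(lo, hi, size=len(e.phones)))
            spec = StimulusSpec(
                target=e.phones,
                is_word=True,
                durations_ms=durations,
                seed=int(rng.integers(2**31 - 1)),
            )
            ft = extract_features(synthesize_word_waveform(spec, gt), frontend)
            for (phone, a, b), key in zip(segment_trajectory(ft, spec), keys):
                if b - a >= N_STATES:
                    labeled.append(LabeledSegment(key, ft.frames[a:b]))
    return labeled


def sample_feature_tokens(
    gt: GroundTruth,
    phone: str,
    n_tokens: int,
    seed: int = 0,
) -> list[LabeledSegment]:
    """Tokens sampled directly from a phone's ground-truth emission models.

    State dwell times follow the true self-loop probabilities (minimum one
    frame per state); frames are Gaussian draws from the state densities.
    Used for parameter-recovery experiments in feature space.
    """
    rng = np.random.default_rng(seed)
    pm = gt.phone_model(phone)
    out = []
    for _ in range(n_tokens):
        frames = []
        for s in range(N_STATES):
            dwell = int(rng.geometric(1.0 - pm.self_loop[s]))
            st = pm.states[s]
            comp = rng.choice(len(st.weights), p=st.weights)
            frames.append(
                st.means[comp]
                + np.sqrt(st.variances[comp]) * rng.standard_normal(
                    (dwell, st.dim)
                )
            )
        out.append(LabeledSegment(("*", phone, "*"), np.vstack(frames)))
    return out


def noise_over_phone(spec: StimulusSpec, phone_index: int, snr_db: float) -> StimulusSpec:
    """Return a copy of the stimulus with noise covering one phone's span."""
    bounds = np.cumsum([0.0, *spec.durations_ms])
    return StimulusSpec(
        target=spec.target,
        is_word=spec.is_word,
        durations_ms=spec.durations_ms,
        noise=NoiseSpec(
            start_ms=float(bounds[phone_index]),
            end_ms=float(bounds[phone_index + 1]),
            snr_db=snr_db,
        ),
        seed=spec.seed,
    )
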