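"""Context-dependent three-state phone models with STRF-like emissions.

Each phone, in a given left/right phone context, is modelled as a strictly
left-to-right three-state Markov chain (head, body, tail; no skips, no
backward transitions).  Each state carries a diagonal-covariance Gaussian
mixture density over the 39-dimensional feature space; these densities play
the role of spectro-temporal receptive fields: the bottom-up evidence for a
state at a frame is the statistical match between the frame's feature
vector and the state's density.

Self-loop probabilities absorb duration variation.  Models are trained by
hard-alignment (Viterbi) expectation-maximisation within labelled phone
segments, which keeps every step checkable against brute-force oracles.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "BOUNDARY",
    "StateModel",
    "PhoneModel",
    "ModelSet",
    "LabeledSegment",
    "init_models",
    "train_models",
    "state_loglik",
    "align_segment",
    "phone_state_correspondence",
]

#: Symbol standing in for a word edge in a sharing key.
BOUNDARY = "#"

N_STATES = 3
VARIANCE_FLOOR = 1e-3

SharingKey = tuple[str, str, str]


@dataclass
class StateModel:
    """One emission density: a diagonal-covariance Gaussian mixture.

    ``id`` is the global STRF index of this state within its model set.
    """

    id: int
    weights: np.ndarray  # (n_components,)
    means: np.ndarray  # (n_components, dim)
    variances: np.ndarray  # (n_components, dim)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.variances = np.atleast_2d(np.asarray(self.variances, dtype=np.float64))
        if not math.isclose(float(self.weights.sum()), 1.0, abs_tol=1e-9):
            raise ValueError(f"mixture weights sum to {self.weights.sum()}, not 1")
        if np.any(self.variances <= 0):
            raise ValueError("variances must be strictly positive")

    @property
    def dim(self) -> int:
        return self.means.shape[1]


@dataclass
class PhoneModel:
    """Three-state left-to-right model of one phone in one context."""

    phone: str
    left_ctx: str
    right_ctx: str
    states: list[StateModel]
    self_loop: np.ndarray  # (3,)
    advance: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        if len(self.states) != N_STATES:
            raise ValueError(f"expected {N_STATES} states, got {len(self.states)}")
        self.self_loop = np.asarray(self.self_loop, dtype=np.float64)
        self.advance = np.asarray(self.advance, dtype=np.float64)
        if not np.allclose(self.self_loop + self.advance, 1.0, atol=1e-9):
            raise ValueError("per-state self_loop + advance must equal 1")

    @property
    def key(self) -> SharingKey:
        return (self.left_ctx, self.phone, self.right_ctx)


@dataclass
class ModelSet:
    """Map from sharing key (left, phone, right) to its PhoneModel.

    Keying by the full triple enforces the model-sharing rule: two words
    re-use a phone model exactly when the phone occurs with the same pre-
    and post-context in both.
    """

    models: dict[SharingKey, PhoneModel] = field(default_factory=dict)

    def __getitem__(self, key: SharingKey) -> PhoneModel:
        return self.models[key]

    def __contains__(self, key: SharingKey) -> bool:
        return key in self.models

    def __len__(self) -> int:
        return len(self.models)

    @property
    def phones(self) -> set[str]:
        return {k[1] for k in self.models}

    def n_states(self) -> int:
        return N_STATES * len(self.models)

    def context_independent(self) -> dict[str, PhoneModel]:
        """Per-phone models pooled over contexts by parameter averaging.

        Used when the context of a phone is undetermined, e.g. while
        hypothesising pseudo-words on the fly.
        """
        by_phone: dict[str, list[PhoneModel]] = {}
        for pm in self.models.values():
            by_phone.setdefault(pm.phone, []).append(pm)
        pooled: dict[str, PhoneModel] = {}
        for phone, pms in sorted(by_phone.items()):
            states = []
            for s in range(N_STATES):
                states.append(
                    StateModel(
                        id=-1,
                        weights=np.mean([p.states[s].weights for p in pms], axis=0),
                        means=np.mean([p.states[s].means for p in pms], axis=0),
                        variances=np.mean(
                            [p.states[s].variances for p in pms], axis=0
                        ),
                    )
                )
            self_loop = np.mean([p.self_loop for p in pms], axis=0)
            pooled[phone] = PhoneModel(
                phone=phone,
                left_ctx="*",
                right_ctx="*",
                states=states,
                self_loop=self_loop,
                advance=1.0 - self_loop,
            )
        return pooled

    def with_backfilled_keys(self, keys: list[SharingKey]) -> "ModelSet":
        """Fill untrained sharing keys from the pooled per-phone models.

        A lexicon may contain phone contexts never attested in the training
        material; those keys back off to the context-independent pooled
        model of their centre phone.  Raises if a phone has no model at all.
        """
        pooled = self.context_independent()
        next_id = 1 + max(
            (s.id for pm in self.models.values() for s in pm.states), default=-1
        )
        out = ModelSet(models=dict(self.models))
        for key in keys:
            if key in out:
                continue
            phone = key[1]
            if phone not in pooled:
                raise ValueError(f"phone {phone!r} has no trained model")
            src = pooled[phone]
            states = []
            for s in src.states:
                states.append(
                    StateModel(next_id, s.weights.copy(), s.means.copy(),
                               s.variances.copy())
                )
                next_id += 1
            out.models[key] = PhoneModel(
                phone=phone,
                left_ctx=key[0],
                right_ctx=key[2],
                states=states,
                self_loop=src.self_loop.copy(),
                advance=src.advance.copy(),
            )
        return out

    def to_json(self, path: str) -> None:
        payload = []
        for key, pm in sorted(self.models.items()):
            payload.append(
                {
                    "left": key[0],
                    "phone": key[1],
                    "right": key[2],
                    "self_loop": pm.self_loop.tolist(),
                    "states": [
                        {
                            "id": s.id,
                            "weights": s.weights.tolist(),
                            "means": s.means.tolist(),
                            "variances": s.variances.tolist(),
                        }
                        for s in pm.states
                    ],
                }
            )
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "ModelSet":
        with open(path) as fh:
            payload = json.load(fh)
        ms = cls()
        for item in payload:
            key = (item["left"], item["phone"], item["right"])
            self_loop = np.asarray(item["self_loop"])
            ms.models[key] = PhoneModel(
                phone=item["phone"],
                left_ctx=item["left"],
                right_ctx=item["right"],
                states=[
                    StateModel(
                        id=s["id"],
                        weights=np.asarray(s["weights"]),
                        means=np.asarray(s["means"]),
                        variances=np.asarray(s["variances"]),
                    )
                    for s in item["states"]
                ],
                self_loop=self_loop,
                advance=1.0 - self_loop,
            )
        return ms


@dataclass(frozen=True)
class LabeledSegment:
    """Frames of one phone token together with its sharing key."""

    key: SharingKey
    frames: np.ndarray  # (n_frames, dim)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frames", np.atleast_2d(np.asarray(self.frames, dtype=np.float64))
        )


def state_loglik(s: StateModel, x: np.ndarray) -> float:
    """Log mixture density of a single feature vector under one state."""
    x = np.asarray(x, dtype=np.float64)
    if x.shape != (s.dim,):
        raise ValueError(f"expected vector of dim {s.dim}, got shape {x.shape}")
    return float(_state_loglik_rows(s, x[None, :])[0])


def _state_loglik_rows(s: StateModel, X: np.ndarray) -> np.ndarray:
    """Vectorised log mixture density for each row of X."""
    diff = X[None, :, :] - s.means[:, None, :]  # (k, n, dim)
    comp = -0.5 * (
        np.sum(np.log(2.0 * np.pi * s.variances), axis=1)[:, None]
        + np.sum(diff**2 / s.variances[:, None, :], axis=2)
    )
    return logsumexp(comp + np.log(s.weights)[:, None], axis=0)


def init_models(
    keys: list[SharingKey],
    labeled: list[LabeledSegment],
    n_components: int = 1,
) -> ModelSet:
    """Flat-start initialisation from a uniform three-way split of each token.

    Every labelled token of a key contributes its first/middle/last thirds of
    frames to the head/body/tail state respectively; state means and
    variances are the pooled moments.  Transition probabilities start at
    self_loop = 0.5.
    """
    by_key: dict[SharingKey, list[np.ndarray]] = {k: [] for k in keys}
    for seg in labeled:
        if seg.key in by_key:
            by_key[seg.key].append(seg.frames)
    missing = sorted(k for k, v in by_key.items() if not v)
    if missing:
        raise ValueError(f"no labelled frames for keys: {missing}")

    ms = ModelSet()
    next_id = 0
    for key in keys:
        per_state: list[list[np.ndarray]] = [[] for _ in range(N_STATES)]
        for frames in by_key[key]:
            L = len(frames)
            cuts = [int(np.floor(s * L / N_STATES)) for s in range(N_STATES + 1)]
            for s in range(N_STATES):
                if cuts[s + 1] > cuts[s]:
                    per_state[s].append(frames[cuts[s] : cuts[s + 1]])
        states = []
        for s in range(N_STATES):
            data = (
                np.vstack(per_state[s])
                if per_state[s]
                else np.vstack(by_key[key])
            )
            states.append(_fit_state(next_id, data, n_components, rng_seed=s))
            next_id += 1
        ms.models[key] = PhoneModel(
            phone=key[1],
            left_ctx=key[0],
            right_ctx=key[2],
            states=states,
            self_loop=np.full(N_STATES, 0.5),
            advance=np.full(N_STATES, 0.5),
        )
    return ms


def _fit_state(
    state_id: int, data: np.ndarray, n_components: int, rng_seed: int = 0
) -> StateModel:
    """Moment-match a state density to its assigned frames."""
    mean = data.mean(axis=0)
    var = np.maximum(data.var(axis=0), VARIANCE_FLOOR)
    if n_components == 1:
        return StateModel(state_id, np.ones(1), mean[None, :], var[None, :])
    # multi-component flat start: perturb the pooled mean
    rng = np.random.default_rng(rng_seed)
    means = mean[None, :] + 0.1 * np.sqrt(var)[None, :] * rng.standard_normal(
        (n_components, len(mean))
    )
    return StateModel(
        state_id,
        np.full(n_components, 1.0 / n_components),
        means,
        np.tile(var, (n_components, 1)),
    )


def align_segment(pm: PhoneModel, frames: np.ndarray) -> tuple[np.ndarray, float]:
    """Best left-to-right state alignment of a token through its 3 states.

    Returns (state index per frame, path log-likelihood incl. transitions).
    The path must start in the head state, end in the tail state, and visit
    every state at least once, so at least 3 frames are required.
    """
    L = len(frames)
    if L < N_STATES:
        raise ValueError(f"segment of {L} frames cannot traverse {N_STATES} states")
    emis = np.stack([_state_loglik_rows(s, frames) for s in pm.states], axis=1)
    log_self = np.log(np.maximum(pm.self_loop, 1e-300))
    log_adv = np.log(np.maximum(pm.advance, 1e-300))

    delta = np.full((L, N_STATES), -np.inf)
    back = np.zeros((L, N_STATES), dtype=int)
    delta[0, 0] = emis[0, 0]
    for t in range(1, L):
        for s in range(N_STATES):
            stay = delta[t - 1, s] + log_self[s]
            if s > 0:
                enter = delta[t - 1, s - 1] + log_adv[s - 1]
            else:
                enter = -np.inf
            if stay >= enter:
                delta[t, s] = stay + emis[t, s]
                back[t, s] = s
            else:
                delta[t, s] = enter + emis[t, s]
                back[t, s] = s - 1
    path = np.zeros(L, dtype=int)
    path[-1] = N_STATES - 1
    for t in range(L - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, float(delta[L - 1, N_STATES - 1])


def train_models(
    ms: ModelSet,
    labeled: list[LabeledSegment],
    n_iter: int = 10,
) -> tuple[ModelSet, list[float]]:
    """Hard-alignment EM over state alignments within labelled segments.

    Each iteration realigns every token by Viterbi through its model,
    re-estimates state densities from the hard assignments (one EM step for
    multi-component mixtures) and re-estimates transition probabilities
    from alignment counts.  Returns the updated set and the per-iteration
    total alignment log-likelihood, which is non-decreasing.
    """
    if n_iter < 1:
        raise ValueError(f"n_iter must be >= 1, got {n_iter}")
    logliks: list[float] = []
    for _ in range(n_iter):
        stats: dict[SharingKey, dict] = {
            key: {
                "frames": [[] for _ in range(N_STATES)],
                "self": np.zeros(N_STATES),
                "adv": np.zeros(N_STATES),
            }
            for key in ms.models
        }
        total = 0.0
        for seg in labeled:
            pm = ms.models[seg.key]
            path, ll = align_segment(pm, seg.frames)
            total += ll
            st = stats[seg.key]
            for s in range(N_STATES):
                sel = seg.frames[path == s]
                if len(sel):
                    st["frames"][s].append(sel)
            for t in range(1, len(path)):
                if path[t] == path[t - 1]:
                    st["self"][path[t]] += 1
                else:
                    st["adv"][path[t - 1]] += 1
            st["adv"][path[-1]] += 1  # exit at segment end
        logliks.append(total)

        for key, pm in ms.models.items():
            st = stats[key]
            new_states = []
            for s in range(N_STATES):
                if st["frames"][s]:
                    data = np.vstack(st["frames"][s])
                    new_states.append(_reestimate_state(pm.states[s], data))
                else:
                    new_states.append(pm.states[s])
            occ = st["self"] + st["adv"]
            self_loop = np.where(occ > 0, st["self"] / np.maximum(occ, 1), 0.5)
            self_loop = np.clip(self_loop, 1e-6, 1.0 - 1e-6)
            ms.models[key] = PhoneModel(
                phone=pm.phone,
                left_ctx=pm.left_ctx,
                right_ctx=pm.right_ctx,
                states=new_states,
                self_loop=self_loop,
                advance=1.0 - self_loop,
            )
    return ms, logliks


def _reestimate_state(s: StateModel, data: np.ndarray) -> StateModel:
    """M-step for one state given its hard-assigned frames."""
    k = len(s.weights)
    if k == 1:
        mean = data.mean(axis=0)
        var = data.var(axis=0)
        if np.any(var < VARIANCE_FLOOR):
            logger.warning("variance floored for state %d", s.id)
            var = np.maximum(var, VARIANCE_FLOOR)
        return StateModel(s.id, np.ones(1), mean[None, :], var[None, :])
    # one EM step on the within-state mixture
    diff = data[None, :, :] - s.means[:, None, :]
    comp_ll = -0.5 * (
        np.sum(np.log(2.0 * np.pi * s.variances), axis=1)[:, None]
        + np.sum(diff**2 / s.variances[:, None, :], axis=2)
    ) + np.log(s.weights)[:, None]
    log_r = comp_ll - logsumexp(comp_ll, axis=0, keepdims=True)
    r = np.exp(log_r)  # (k, n)
    nk = r.sum(axis=1) + 1e-12
    weights = nk / nk.sum()
    means = (r @ data) / nk[:, None]
    var = (r[:, :, None] * (data[None, :, :] - means[:, None, :]) ** 2).sum(
        axis=1
    ) / nk[:, None]
    if np.any(var < VARIANCE_FLOOR):
        logger.warning("variance floored for state %d", s.id)
        var = np.maximum(var, VARIANCE_FLOOR)
    return StateModel(s.id, weights, means, var)


def phone_state_correspondence(
    ms: ModelSet, labeled: list[LabeledSegment]
):
    """Row-normalised phone-by-STRF frame assignment frequencies.

    Each labelled token is force-aligned through its model; the matrix
    counts how often frames of each phone land in each global state (STRF)
    index, normalised per phone.  Phones with shared acoustic structure show
    off-diagonal mass on each other's states.
    """
    import pandas as pd

    phones = sorted({k[1] for k in ms.models})
    n_states = max(s.id for pm in ms.models.values() for s in pm.states) + 1
    counts = pd.DataFrame(
        np.zeros((len(phones), n_states)), index=phones, columns=range(n_states)
    )
    seen: set[str] = set()
    for seg in labeled:
        pm = ms.models.get(seg.key)
        if pm is None:
            continue
        seen.add(pm.phone)
        path, _ = align_segment(pm, seg.frames)
        for s in range(N_STATES):
            counts.loc[pm.phone, pm.states[s].id] += int(np.sum(path == s))
    for phone in phones:
        if phone not in seen:
            logger.warning("phone %s absent from evaluation set; zero row", phone)
    totals = counts.sum(axis=1)
    nonzero = totals > 0
    counts.loc[nonzero] = counts.loc[nonzero].div(totals[nonzero], axis=0)
    return counts
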