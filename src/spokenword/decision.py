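"""Task decisions and predicted reaction times from activation traces.

Word identification: the best word is selected at the earliest frame where
its activation exceeds the second-best word's by a threshold theta.  Lexical
decision: the judgment is made at the earliest frame where the activation
gap between the best real-word and best pseudo-word hypotheses reaches a
threshold theta_ld, the sign of the gap fixing the label.  If no threshold
is crossed by stimulus offset, the candidate with the highest activation is
selected at offset and the residual ambiguity is charged as a choice
reaction time following the Hick-Hyman law: candidates' activations are
softmax-normalised into choice probabilities, and the choice RT grows
linearly in their entropy H (bits).

The total predicted reaction time decomposes as

    rt_ms = decision_ms + choice_ms + exec_ms

with choice_ms = 0 whenever a threshold decision was reached before offset,
and a constant motor execution latency exec_ms (200 ms by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .activation import ActivationTrace, Hypothesis, remove_nested

__all__ = [
    "DecisionConfig",
    "Response",
    "decide_identification",
    "decide_lexical",
    "choice_rt",
]


@dataclass(frozen=True)
class DecisionConfig:
    """Decision parameters.

    theta and theta_ld are activation-gap thresholds (frame-normalised
    log-score units); raising theta trades speed for accuracy.  tau is the
    softmax temperature converting offset activations into choice
    probabilities; hick_a/hick_b are the intercept (ms) and slope (ms/bit)
    of the choice-RT line; exec_ms the constant execution latency.
    postpone_to_offset forces lexical decisions to wait for stimulus
    offset (the strategy listeners adopt when stimuli turn non-word only
    at their final segments).
    """

    theta: float = 8.0
    theta_ld: float = 8.0
    tau: float = 1.0
    hick_a: float = 0.0
    hick_b: float = 100.0
    exec_ms: float = 200.0
    word_class_prior: float = 0.5
    postpone_to_offset: bool = False

    def __post_init__(self) -> None:
        if self.theta < 0 or self.theta_ld < 0:
            raise ValueError("thresholds must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.hick_b < 0 or self.exec_ms < 0:
            raise ValueError("hick_b and exec_ms must be >= 0")
        if not 0 <= self.word_class_prior <= 1:
            raise ValueError("word_class_prior must be in [0, 1]")


@dataclass(frozen=True)
class Response:
    """A task decision with its decomposed reaction time."""

    task: str  # "identification" | "lexical_decision"
    label: str
    decided_before_offset: bool
    decision_ms: float
    choice_ms: float
    exec_ms: float
    entropy_bits: float

    @property
    def rt_ms(self) -> float:
        return self.decision_ms + self.choice_ms + self.exec_ms


def _nested_filter(
    cands: list[tuple[Hypothesis, float]]
) -> list[tuple[Hypothesis, float]]:
    keep = remove_nested([(h.phones, a) for h, a in cands])
    return [cands[i] for i in keep]


def _offset_choice_set(tr: ActivationTrace) -> list[tuple[tuple[str, ...], float]]:
    """All candidates competing at offset: words, word parts, pseudo-words."""
    cands = [
        (h.phones, a)
        for h, a in tr.candidates_at(tr.n_frames)
        if h.kind != "pseudo"
    ]
    cands.extend(tr.offset_pseudo)
    keep = remove_nested(cands)
    return [cands[i] for i in keep]


def choice_rt(
    candidates: list[tuple[tuple[str, ...], float]] | list[float],
    cfg: DecisionConfig,
) -> tuple[float, float]:
    """Hick-Hyman choice component from the offset candidate set.

    Activations (nested variants already removed) are softmax-normalised
    with temperature tau into probabilities p_i; H = -sum p_i log2 p_i and
    choice_ms = hick_a + hick_b * H.
    """
    if len(candidates) == 0:
        raise ValueError("empty candidate set")
    acts = np.asarray(
        [c[1] if isinstance(c, tuple) else c for c in candidates], dtype=np.float64
    )
    z = acts / cfg.tau
    logp = z - logsumexp(z)
    p = np.exp(logp)
    h_bits = float(-np.sum(p * logp) / math.log(2.0))
    h_bits = max(h_bits, 0.0)
    return h_bits, cfg.hick_a + cfg.hick_b * h_bits


def decide_identification(tr: ActivationTrace, cfg: DecisionConfig) -> Response:
    """Theta-gap word identification.

    At each frame the word candidates (after nested-variant removal) are
    ranked; the best word wins as soon as it leads the second-best word by
    at least theta.  Without a crossing by offset, the best offset
    candidate wins and the choice RT is added.  Ties are broken
    lexicographically by phone string, deterministically.
    """
    step = tr.frame_step_ms
    for t in range(1, tr.n_frames + 1):
        words = [
            (h, a) for h, a in tr.candidates_at(t) if h.kind == "word"
        ]
        if not words:
            continue
        words = _nested_filter(words)
        if not words:
            continue
        ranked = sorted(words, key=lambda ha: (-ha[1], ha[0].phones))
        gap = (
            ranked[0][1] - ranked[1][1] if len(ranked) > 1 else math.inf
        )
        # the winner must be unique: at theta = 0 a tie does not decide
        if gap >= cfg.theta and gap > 0:
            return Response(
                task="identification",
                label=ranked[0][0].label,
                decided_before_offset=True,
                decision_ms=t * step,
                choice_ms=0.0,
                exec_ms=cfg.exec_ms,
                entropy_bits=0.0,
            )
    # no threshold crossing: select at offset, charge the choice RT
    words = [
        (h, a) for h, a in tr.candidates_at(tr.n_frames) if h.kind == "word"
    ]
    if not words:
        raise ValueError("no word candidates at stimulus offset")
    words = _nested_filter(words)
    ranked = sorted(words, key=lambda ha: (-ha[1], ha[0].phones))
    h_bits, choice_ms = choice_rt(_offset_choice_set(tr), cfg)
    return Response(
        task="identification",
        label=ranked[0][0].label,
        decided_before_offset=False,
        decision_ms=tr.n_frames * step,
        choice_ms=choice_ms,
        exec_ms=cfg.exec_ms,
        entropy_bits=h_bits,
    )


def _class_bests(
    tr: ActivationTrace, t: int
) -> tuple[float | None, float | None]:
    best_word = None
    best_pseudo = None
    for h, a in tr.candidates_at(t):
        if h.kind == "word":
            if best_word is None or a > best_word:
                best_word = a
        elif h.kind == "pseudo":
            if best_pseudo is None or a > best_pseudo:
                best_pseudo = a
    return best_word, best_pseudo


def decide_lexical(tr: ActivationTrace, cfg: DecisionConfig) -> Response:
    """Theta_ld lexical decision between best word and best pseudo-word.

    The judgment is made at the earliest frame where the absolute gap
    between the best real-word and the best pseudo-word activation reaches
    theta_ld; the sign of the gap gives the label.  Otherwise the label is
    fixed by the offset comparison and the choice RT is charged.
    """
    has_word = any(h.kind == "word" for h in tr.hypotheses)
    has_pseudo = any(h.kind == "pseudo" for h in tr.hypotheses)
    if not (has_word and has_pseudo):
        raise ValueError("lexical decision needs word and pseudo hypotheses")

    step = tr.frame_step_ms
    if not cfg.postpone_to_offset:
        for t in range(1, tr.n_frames + 1):
            bw, bp = _class_bests(tr, t)
            if bw is None or bp is None:
                continue
            if abs(bw - bp) >= cfg.theta_ld and bw != bp:
                return Response(
                    task="lexical_decision",
                    label="word" if bw > bp else "pseudo-word",
                    decided_before_offset=True,
                    decision_ms=t * step,
                    choice_ms=0.0,
                    exec_ms=cfg.exec_ms,
                    entropy_bits=0.0,
                )
    bw, bp = _class_bests(tr, tr.n_frames)
    if bw is None or bp is None:
        raise ValueError("word or pseudo class missing at offset")
    h_bits, choice_ms = choice_rt(_offset_choice_set(tr), cfg)
    return Response(
        task="lexical_decision",
        label="word" if bw >= bp else "pseudo-word",
        decided_before_offset=False,
        decision_ms=tr.n_frames * step,
        choice_ms=choice_ms,
        exec_ms=cfg.exec_ms,
        entropy_bits=h_bits,
    )
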