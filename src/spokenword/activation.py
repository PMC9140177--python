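"""Time-synchronous activation of word, cohort and pseudo-word hypotheses.

As the feature trajectory unfolds, every hypothesis h receives, at each
frame t (1-based), the frame-normalised activation

    activation(h, t) = ( bestpath(h, 1..t) + lambda * log_prior(h) ) / t

where bestpath is the best left-to-right state-alignment log-likelihood of
frames 1..t through h's state sequence, ending in any state of h's final
phone, and the prior is the hypothesis's top-down support.  Dividing by the
frames decoded makes candidates of different lengths comparable.

Word/cohort hypotheses live on the cohort tree; each tree node's trace is
computed once by dynamic programming over the tree, so hypotheses sharing a
sharing-key prefix have bitwise-identical traces until they diverge, and a
full word's trace at t is the best over the nodes on its own path ("the
full form adopts its activation from its shorter cohorts underway").

Pseudo-word hypotheses are decoded on the fly by token passing over the
phonotactic network with context-independent pooled phone models; at each
frame the best-scoring token defines the currently best pseudo-word
hypothesis.

Beam pruning discards hypotheses whose activation falls more than ``beam``
below the frame-best activation; once discarded they are never revived.
Nested-candidate removal drops any candidate whose phone string is a
contiguous substring of a higher-activation candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .acoustic import ModelSet, PhoneModel, _state_loglik_rows
from .frontend import FeatureTrajectory
from .lexicon import (
    CohortNode,
    CohortTree,
    LanguageModel,
    LexiconEntry,
    PseudoWordNetwork,
    log_prior,
)

__all__ = [
    "DecoderConfig",
    "Hypothesis",
    "ActivationTrace",
    "compute_activation_traces",
    "prune_hypotheses",
    "remove_nested",
]

N_STATES = 3


@dataclass(frozen=True)
class DecoderConfig:
    """Decoding parameters.

    lm_weight scales the top-down log prior against the bottom-up
    log-likelihood ("the precise balance ... depends on the listener's
    task").  beam is the pruning margin in activation units; hypotheses
    more than beam below the frame best are discarded for good.
    """

    lm_weight: float = 1.0
    beam: float = np.inf
    max_pseudo_len: int = 6
    word_class_prior: float = 0.5
    pseudo_prior: float = 0.01
    context: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.beam <= 0:
            raise ValueError(f"beam must be > 0, got {self.beam}")
        if self.lm_weight < 0:
            raise ValueError(f"lm_weight must be >= 0, got {self.lm_weight}")


@dataclass(frozen=True)
class Hypothesis:
    """One competitor: a full word, a cohort (word part) or a pseudo-word."""

    kind: str  # "word" | "cohort" | "pseudo"
    phones: tuple[str, ...]
    entries: tuple[LexiconEntry, ...] = ()

    @property
    def label(self) -> str:
        if self.kind == "word":
            return self.entries[0].orthography
        return "/" + " ".join(self.phones) + "/"


@dataclass
class ActivationTrace:
    """Per-hypothesis, per-frame frame-normalised activations.

    ``values[i, t]`` is hypothesis i's activation at frame t+1; -inf marks
    frames where the hypothesis cannot yet have been traversed, NaN frames
    after the hypothesis was pruned.  ``pseudo_identity[t]`` names the phone
    path of the best pseudo-word token at each frame (when pseudo decoding
    is on), and ``offset_pseudo`` lists complete licensed pseudo-words with
    their offset activations.
    """

    hypotheses: list[Hypothesis]
    values: np.ndarray  # (n_hyp, T)
    frame_step_ms: float = 10.0
    pseudo_identity: list[tuple[str, ...]] | None = None
    offset_pseudo: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def offset_frame(self) -> int:
        return self.n_frames

    def duration_ms(self) -> float:
        return self.n_frames * self.frame_step_ms

    def candidates_at(self, t: int) -> list[tuple[Hypothesis, float]]:
        """Surviving hypotheses with finite activation at 1-based frame t."""
        col = self.values[:, t - 1]
        return [
            (h, float(a))
            for h, a in zip(self.hypotheses, col)
            if np.isfinite(a)
        ]

    def to_csv(self, path: str) -> None:
        """Long-format export: hypothesis, kind, frame, time_ms, activation."""
        import pandas as pd

        rows = []
        for h, vals in zip(self.hypotheses, self.values):
            for t, a in enumerate(vals, start=1):
                if np.isfinite(a):
                    rows.append(
                        (h.label, h.kind, t, t * self.frame_step_ms, a)
                    )
        pd.DataFrame(
            rows, columns=["hypothesis", "kind", "frame", "time_ms", "activation"]
        ).to_csv(path, index=False)


def _node_emissions(pm: PhoneModel, X: np.ndarray) -> np.ndarray:
    """(T, 3) per-frame log emission densities of one phone model."""
    return np.stack([_state_loglik_rows(s, X) for s in pm.states], axis=1)


def _decode_tree(
    tree: CohortTree, ms: ModelSet, X: np.ndarray
) -> dict[int, np.ndarray]:
    """Best-path score per tree node: V[node][t] = best log-lik of frames
    0..t through the node's full prefix chain, ending in any state of the
    node's final phone.  Computed by DP down the tree."""
    T = len(X)
    log0 = -np.inf
    scores: dict[int, np.ndarray] = {}

    def visit(node: CohortNode, parent_delta: np.ndarray | None,
              parent_logadv: float) -> None:
        pm = ms[node.model_key]
        emis = _node_emissions(pm, X)
        log_self = np.log(np.maximum(pm.self_loop, 1e-300))
        log_adv = np.log(np.maximum(pm.advance, 1e-300))
        delta = np.full((T, N_STATES), log0)
        if parent_delta is None:
            delta[0, 0] = emis[0, 0]
        for t in range(1, T):
            enter = (
                parent_delta[t - 1, N_STATES - 1] + parent_logadv
                if parent_delta is not None
                else log0
            )
            stay0 = delta[t - 1, 0] + log_self[0]
            delta[t, 0] = emis[t, 0] + max(stay0, enter)
            for s in range(1, N_STATES):
                delta[t, s] = emis[t, s] + max(
                    delta[t - 1, s] + log_self[s],
                    delta[t - 1, s - 1] + log_adv[s - 1],
                )
        scores[id(node)] = delta.max(axis=1)
        for child in node.children.values():
            visit(child, delta, log_adv[N_STATES - 1])

    for child in tree.root.children.values():
        visit(child, None, 0.0)
    return scores


def _decode_pseudo(
    pw: PseudoWordNetwork,
    ci_models: dict[str, PhoneModel],
    X: np.ndarray,
    max_len: int,
) -> tuple[np.ndarray, list[tuple[str, ...]], dict[tuple[str, ...], float]]:
    """Token passing over the phone network with pooled CI models.

    Returns (best token score per frame, best token path per frame, and the
    best complete (end-licensed) path score per final path at the offset).
    Tokens are merged per (phone, state), keeping the best-scoring path, so
    the per-frame best pseudo hypothesis is exact while the trace carries a
    single evolving identity.
    """
    T = len(X)
    emis = {p: _node_emissions(pm, X) for p, pm in ci_models.items()}
    logs = {
        p: (
            np.log(np.maximum(pm.self_loop, 1e-300)),
            np.log(np.maximum(pm.advance, 1e-300)),
        )
        for p, pm in ci_models.items()
    }

    # tokens: (phone, state) -> (score, path)
    tokens: dict[tuple[str, int], tuple[float, tuple[str, ...]]] = {}
    for p in pw.starts():
        if p in ci_models:
            tokens[(p, 0)] = (float(emis[p][0, 0]), (p,))

    best_score = np.full(T, -np.inf)
    best_path: list[tuple[str, ...]] = [()] * T
    final: dict[tuple[str, ...], float] = {}

    def note_frame(t: int) -> None:
        for (p, s), (score, path) in tokens.items():
            if score > best_score[t]:
                best_score[t] = score
                best_path[t] = path

    note_frame(0)
    for t in range(1, T):
        nxt: dict[tuple[str, int], tuple[float, tuple[str, ...]]] = {}

        def offer(key: tuple[str, int], score: float, path: tuple[str, ...]) -> None:
            cur = nxt.get(key)
            if cur is None or score > cur[0]:
                nxt[key] = (score, path)

        for (p, s), (score, path) in tokens.items():
            log_self, log_adv = logs[p]
            e = emis[p]
            offer((p, s), score + log_self[s] + e[t, s], path)
            if s < N_STATES - 1:
                offer((p, s + 1), score + log_adv[s] + e[t, s + 1], path)
            else:
                if len(path) < max_len:
                    for q in pw.successors(p):
                        if q in ci_models:
                            offer(
                                (q, 0),
                                score + log_adv[s] + emis[q][t, 0],
                                path + (q,),
                            )
        tokens = nxt
        note_frame(t)

    for (p, s), (score, path) in tokens.items():
        if s == N_STATES - 1 and pw.can_end(p):
            if path not in final or score > final[path]:
                final[path] = score
    return best_score, best_path, final


def compute_activation_traces(
    ft: FeatureTrajectory,
    tree: CohortTree,
    ms: ModelSet,
    pw: PseudoWordNetwork | None = None,
    lm: LanguageModel | None = None,
    cfg: DecoderConfig | None = None,
) -> ActivationTrace:
    """Decode a feature trajectory against the lexicon (and pseudo network).

    Produces one hypothesis per cohort node (kind ``cohort`` for word
    parts, ``word`` for complete entries, with the word's trace being the
    running best over its prefix nodes), plus a single running best
    ``pseudo`` hypothesis when a pseudo-word network is supplied.
    """
    cfg = cfg or DecoderConfig()
    lm = lm or LanguageModel.from_entries(tree.entries)
    X = ft.frames
    T = len(X)
    if T < 1:
        raise ValueError("empty feature trajectory")

    node_scores = _decode_tree(tree, ms, X)
    t_axis = np.arange(1, T + 1, dtype=np.float64)

    hypotheses: list[Hypothesis] = []
    rows: list[np.ndarray] = []

    # cohort hypotheses: every non-word tree node
    node_activation: dict[int, np.ndarray] = {}
    for node in tree.nodes():
        prior = log_prior(
            node, lm, cfg.context, cfg.word_class_prior, cfg.pseudo_prior
        )
        act = (node_scores[id(node)] + cfg.lm_weight * prior) / t_axis
        node_activation[id(node)] = act
        if not node.is_word:
            hypotheses.append(Hypothesis("cohort", node.prefix))
            rows.append(act)

    # word hypotheses: running best over the entry's own prefix nodes
    for entry in tree.entries:
        path = tree.path_nodes(entry)
        act = np.maximum.reduce([node_activation[id(n)] for n in path])
        final_node = path[-1]
        hypotheses.append(
            Hypothesis("word", entry.phones, tuple(final_node.word_entries))
        )
        rows.append(act)

    pseudo_identity = None
    offset_pseudo: list[tuple[tuple[str, ...], float]] = []
    if pw is not None:
        ci = ms.context_independent()
        p_score, p_path, finals = _decode_pseudo(pw, ci, X, cfg.max_pseudo_len)
        p_prior = log_prior(
            "pseudo", lm, cfg.context, cfg.word_class_prior, pw.pseudo_prior
        )
        act = (p_score + cfg.lm_weight * p_prior) / t_axis
        hypotheses.append(Hypothesis("pseudo", ()))
        rows.append(act)
        pseudo_identity = p_path
        for path, score in sorted(finals.items()):
            if path not in pw.lexical_strings:
                offset_pseudo.append(
                    (path, float((score + cfg.lm_weight * p_prior) / T))
                )

    values = np.vstack(rows)
    values = prune_hypotheses(values, cfg.beam)
    if not np.any(np.isfinite(values[:, -1])):
        raise RuntimeError("all hypotheses pruned; beam too tight")
    return ActivationTrace(
        hypotheses=hypotheses,
        values=values,
        frame_step_ms=ft.frame_step_ms,
        pseudo_identity=pseudo_identity,
        offset_pseudo=offset_pseudo,
    )


def prune_hypotheses(values: np.ndarray, beam: float) -> np.ndarray:
    """Apply beam pruning frame by frame; pruned hypotheses stay pruned.

    A hypothesis is discarded at the first frame where it is active
    (finite) and more than ``beam`` below the frame-best activation;
    its activations from that frame on are NaN.  Hypotheses that have not
    yet become active (-inf) are not considered prunable.
    """
    if beam <= 0:
        raise ValueError("beam must be > 0")
    out = values.copy()
    if not np.isfinite(beam):
        return out
    n, T = out.shape
    dead = np.zeros(n, dtype=bool)
    for t in range(T):
        col = out[:, t]
        col[dead] = np.nan
        active = np.isfinite(col)
        if not np.any(active):
            continue
        best = np.nanmax(col[active])
        newly = active & (best - col > beam)
        dead |= newly
        col[newly] = np.nan
    return out


def remove_nested(
    candidates: list[tuple[tuple[str, ...], float]]
) -> list[int]:
    """Indices of candidates surviving nested-variant removal.

    A candidate is removed iff its phone string is a proper contiguous
    substring of another candidate's string and its activation is lower
    (ties keep the longer candidate): nested parts "lead to the
    recognition of the same longer candidate" and are not competitors.
    """

    def is_substring(short: tuple[str, ...], long: tuple[str, ...]) -> bool:
        ns, nl = len(short), len(long)
        return any(long[i : i + ns] == short for i in range(nl - ns + 1))

    keep = []
    for i, (pi, ai) in enumerate(candidates):
        removed = False
        for j, (pj, aj) in enumerate(candidates):
            if i == j or len(pj) <= len(pi):
                continue
            if is_substring(pi, pj) and (aj > ai or aj == ai):
                removed = True
                break
        if not removed:
            keep.append(i)
    return keep
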