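"""Lexicon, cohort prefix tree, phonotactic pseudo-word network and priors.

Words are stored as SAMPA phone strings with occurrence frequencies.  The
cohort tree compiles entries into a prefix tree whose branching follows the
context-dependent model-sharing rule: two words share a node path exactly
as far as their (left-context, phone, right-context) sharing keys agree,
so e.g. 'ham' and 'hamster' share their /h/ and vowel nodes but split at
/m/ because the post-contexts differ.

Pseudo-word hypotheses are licensed by a phone network whose paths are the
strings all of whose adjacent phone pairs (including word-boundary pairs)
are attested in the lexicon.  Top-down support is a word's (class-weighted)
probability: its N-gram/unigram probability for words, the summed
completion probability for cohorts, and a stimulus-independent constant for
pseudo-words.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

from .acoustic import BOUNDARY, ModelSet, SharingKey

logger = logging.getLogger(__name__)

__all__ = [
    "LexiconEntry",
    "CohortNode",
    "CohortTree",
    "PseudoWordNetwork",
    "LanguageModel",
    "sharing_key",
    "entry_keys",
    "compile_cohort_tree",
    "build_pseudoword_network",
    "log_prior",
    "read_lexicon",
    "write_lexicon",
]


@dataclass(frozen=True)
class LexiconEntry:
    """One word: orthography, SAMPA phone string and token frequency."""

    orthography: str
    phones: tuple[str, ...]
    frequency: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "phones", tuple(self.phones))
        if not self.phones:
            raise ValueError(f"entry {self.orthography!r} has no phones")
        if self.frequency < 0:
            raise ValueError(f"entry {self.orthography!r} has negative frequency")


def sharing_key(phones: tuple[str, ...] | list[str], i: int) -> SharingKey:
    """Sharing key (left, phone, right) of position i; word edges -> boundary."""
    if not 0 <= i < len(phones):
        raise IndexError(f"position {i} out of range for {len(phones)} phones")
    left = phones[i - 1] if i > 0 else BOUNDARY
    right = phones[i + 1] if i < len(phones) - 1 else BOUNDARY
    return (left, phones[i], right)


def entry_keys(phones: tuple[str, ...] | list[str]) -> list[SharingKey]:
    """Sharing keys of every position of a phone string."""
    return [sharing_key(phones, i) for i in range(len(phones))]


@dataclass
class CohortNode:
    """A cohort hypothesis: a sharing-key prefix and its possible completions."""

    prefix: tuple[str, ...]
    model_key: SharingKey | None  # None only at the root
    children: dict[SharingKey, "CohortNode"] = field(default_factory=dict)
    completions: set[LexiconEntry] = field(default_factory=set)
    word_entries: list[LexiconEntry] = field(default_factory=list)

    @property
    def is_word(self) -> bool:
        return bool(self.word_entries)


@dataclass
class CohortTree:
    root: CohortNode
    entries: list[LexiconEntry]

    def nodes(self) -> list[CohortNode]:
        """All non-root nodes, depth-first in insertion order."""
        out: list[CohortNode] = []
        stack = list(self.root.children.values())[::-1]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(list(node.children.values())[::-1])
        return out

    def path_nodes(self, entry: LexiconEntry) -> list[CohortNode]:
        """The chain of cohort nodes spelling out one entry."""
        node = self.root
        out = []
        for key in entry_keys(entry.phones):
            node = node.children[key]
            out.append(node)
        return out


def compile_cohort_tree(entries: list[LexiconEntry], ms: ModelSet) -> CohortTree:
    """Compile entries into the sharing-key prefix tree.

    Two entries share a node path exactly as far as their per-position
    sharing keys agree.  Raises on phones without any model and on
    duplicate (orthography, phones) pairs.
    """
    seen: set[tuple[str, tuple[str, ...]]] = set()
    known_phones = ms.phones
    for e in entries:
        ident = (e.orthography, e.phones)
        if ident in seen:
            raise ValueError(f"duplicate lexicon entry {ident}")
        seen.add(ident)
        for p in e.phones:
            if p not in known_phones:
                raise ValueError(f"phone {p!r} of entry {e.orthography!r} has no model")
        for key in entry_keys(e.phones):
            if key not in ms:
                raise ValueError(f"no model for sharing key {key}")

    root = CohortNode(prefix=(), model_key=None)
    for e in entries:
        node = root
        node.completions.add(e)
        for i, key in enumerate(entry_keys(e.phones)):
            child = node.children.get(key)
            if child is None:
                child = CohortNode(prefix=e.phones[: i + 1], model_key=key)
                node.children[key] = child
            child.completions.add(e)
            node = child
        node.word_entries.append(e)
    return CohortTree(root=root, entries=list(entries))


@dataclass
class PseudoWordNetwork:
    """Phone graph of phonotactically licensed transitions.

    A phone string is licensed iff every adjacent pair, including its
    (boundary, first) and (last, boundary) pairs, is attested in the
    lexicon.  Licensed strings equal to a lexical entry's phones are
    lexical, never pseudo-words.
    """

    phones: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    lexical_strings: set[tuple[str, ...]] = field(default_factory=set)
    pseudo_prior: float = 0.01

    def accepts(self, phones: tuple[str, ...] | list[str]) -> bool:
        seq = (BOUNDARY, *phones, BOUNDARY)
        if len(seq) == 2:
            return False
        return all((a, b) in self.edges for a, b in zip(seq, seq[1:]))

    def is_pseudo(self, phones: tuple[str, ...] | list[str]) -> bool:
        return self.accepts(phones) and tuple(phones) not in self.lexical_strings

    def starts(self) -> set[str]:
        return {b for a, b in self.edges if a == BOUNDARY}

    def successors(self, phone: str) -> set[str]:
        return {b for a, b in self.edges if a == phone and b != BOUNDARY}

    def can_end(self, phone: str) -> bool:
        return (phone, BOUNDARY) in self.edges

    def enumerate_licensed(self, max_len: int) -> list[tuple[str, ...]]:
        """All licensed strings up to max_len phones (small alphabets only)."""
        out: list[tuple[str, ...]] = []
        frontier: list[tuple[str, ...]] = [(p,) for p in sorted(self.starts())]
        while frontier:
            path = frontier.pop()
            if self.can_end(path[-1]):
                out.append(path)
            if len(path) < max_len:
                for nxt in sorted(self.successors(path[-1])):
                    frontier.append(path + (nxt,))
        return sorted(out)


def build_pseudoword_network(
    entries: list[LexiconEntry], pseudo_prior: float = 0.01
) -> PseudoWordNetwork:
    """Licensing network from attested phone bigrams, boundaries included."""
    net = PseudoWordNetwork(pseudo_prior=pseudo_prior)
    for e in entries:
        net.phones.update(e.phones)
        seq = (BOUNDARY, *e.phones, BOUNDARY)
        net.edges.update(zip(seq, seq[1:]))
        net.lexical_strings.add(e.phones)
    return net


class LanguageModel:
    """Word probabilities: unigram relative frequencies, optional N-grams.

    ``ngrams`` maps a context tuple of up to N-1 preceding words to a
    word -> probability table.  Contexts without a table back off to the
    unigram distribution.
    """

    def __init__(
        self,
        unigram: dict[str, float],
        ngrams: dict[tuple[str, ...], dict[str, float]] | None = None,
        order: int = 1,
    ):
        total = sum(unigram.values())
        if total <= 0:
            raise ValueError("unigram distribution has no mass")
        self.unigram = {w: p / total for w, p in unigram.items()}
        self.ngrams = ngrams or {}
        self.order = order

    @classmethod
    def from_entries(cls, entries: list[LexiconEntry]) -> "LanguageModel":
        counts: dict[str, float] = {}
        for e in entries:
            counts[e.orthography] = counts.get(e.orthography, 0.0) + e.frequency
        return cls(counts)

    @classmethod
    def from_json(cls, path: str) -> "LanguageModel":
        with open(path) as fh:
            payload = json.load(fh)
        ngrams = {
            tuple(ctx.split()) if ctx else (): table
            for ctx, table in payload.get("ngrams", {}).items()
        }
        return cls(payload["unigram"], ngrams, payload.get("order", 1))

    def prob(self, word: str, context: tuple[str, ...] = ()) -> float:
        if context:
            ctx = tuple(context[-(self.order - 1) :]) if self.order > 1 else ()
            table = self.ngrams.get(ctx)
            if table is None:
                logger.warning(
                    "unknown context %s; backing off to unigram", context
                )
            elif word in table:
                return table[word]
        return self.unigram.get(word, 0.0)


def log_prior(
    obj,
    lm: LanguageModel,
    context: tuple[str, ...] = (),
    word_class_prior: float = 0.5,
    pseudo_prior: float = 0.01,
) -> float:
    """Log top-down support for a hypothesis.

    Words get their class-weighted (N-gram or unigram) probability; cohorts
    the summed probability of their completions; pseudo-word paths the
    stimulus-independent constant weighted by the pseudo-class mass.
    """
    if isinstance(obj, CohortNode):
        # a full-word node's completions are exactly its word entries, so the
        # cohort sum covers both cases
        p = word_class_prior * sum(
            lm.prob(e.orthography, context) for e in obj.completions
        )
    elif isinstance(obj, LexiconEntry):
        p = word_class_prior * lm.prob(obj.orthography, context)
    else:  # pseudo-word phone path
        p = (1.0 - word_class_prior) * pseudo_prior
    if p <= 0:
        return -math.inf
    return math.log(p)


def read_lexicon(path: str) -> list[LexiconEntry]:
    """Read a tab-separated lexicon: orthography, space-joined phones, frequency."""
    entries = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            orth, phones, freq = parts
            entries.append(LexiconEntry(orth, tuple(phones.split()), float(freq)))
    return entries


def write_lexicon(entries: list[LexiconEntry], path: str) -> None:
    with open(path, "w") as fh:
        for e in entries:
            fh.write(f"{e.orthography}\t{' '.join(e.phones)}\t{e.frequency:g}\n")
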