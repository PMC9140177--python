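"""Shared fixtures: small seeded synthetic worlds used across the suite."""

import logging

import numpy as np
import pytest

import spokenword as sw

logging.getLogger("spokenword").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_world():
    """A well-separated 6-phone, 8-word world with trained models."""
    gt = sw.make_phone_inventory(6, separation=4.0, seed=0)
    lex = sw.make_zipf_lexicon(8, gt.phones, seed=1)
    ms, logliks = sw.train_from_synth(gt, lex, n_tokens_per_word=4, n_iter=4, seed=2)
    tree = sw.compile_cohort_tree(lex, ms)
    return {"gt": gt, "lexicon": lex, "models": ms, "tree": tree,
            "logliks": logliks}


@pytest.fixture(scope="session")
def minimal_pair_world():
    """Two words differing only in their medial vowel, plus trained models."""
    gt = sw.make_phone_inventory(8, separation=4.0, seed=0)
    p = gt.phones
    lex = [
        sw.LexiconEntry("wordA", (p[5], p[0], p[3], p[6], p[1]), 100),
        sw.LexiconEntry("wordB", (p[5], p[0], p[4], p[6], p[1]), 100),
    ]
    ms, _ = sw.train_from_synth(gt, lex, n_tokens_per_word=8, n_iter=5, seed=2)
    tree = sw.compile_cohort_tree(lex, ms)
    return {"gt": gt, "lexicon": lex, "models": ms, "tree": tree,
            "diverge_index": 2}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
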