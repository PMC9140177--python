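"""Decoder tests: oracle equivalence on tiny instances, prefix identity,
pruning semantics, nested-candidate removal and prior monotonicity."""

import itertools

import numpy as np
import pytest

import spokenword as sw
from spokenword.acoustic import _state_loglik_rows
from spokenword.activation import prune_hypotheses, remove_nested
from spokenword.lexicon import LanguageModel, entry_keys, log_prior


def _tiny_world(seed=0, n_phones=2):
    gt = sw.make_phone_inventory(n_phones, separation=2.0, seed=seed)
    return gt


def _chain_for(ms, keys):
    """Flatten a sharing-key path into (emission models, self, adv) chains."""
    states, log_self, log_adv = [], [], []
    for key in keys:
        pm = ms[key]
        states.extend(pm.states)
        log_self.extend(np.log(pm.self_loop))
        log_adv.extend(np.log(pm.advance))
    return states, np.array(log_self), np.array(log_adv)


def _oracle_best_path(states, log_self, log_adv, X, allowed_final):
    """Max alignment score over all explicit monotone state paths.

    Enumerates every no-skip step sequence for every prefix length t,
    keeping paths that start in state 0 and end in an allowed final state.
    """
    T = len(X)
    S = len(states)
    emis = np.stack([_state_loglik_rows(s, X) for s in states], axis=1)
    best = np.full(T, -np.inf)
    for t in range(1, T + 1):
        for steps in itertools.product([0, 1], repeat=t - 1):
            path = np.concatenate([[0], np.cumsum(steps)])
            if path[-1] >= S or path[-1] not in allowed_final:
                continue
            score = emis[0, 0]
            for i in range(1, t):
                prev, cur = path[i - 1], path[i]
                score += (
                    log_self[prev] if cur == prev else log_adv[prev]
                ) + emis[i, cur]
            if score > best[t - 1]:
                best[t - 1] = score
    return best


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_decoder_matches_exhaustive_alignment_enumeration(self, seed):
        """On T <= 8 instances every hypothesis activation equals the
        brute-force maximum over explicit state alignments within 1e-9."""
        gt = _tiny_world(seed=seed, n_phones=2)
        a, b = gt.phones
        lex = [
            sw.LexiconEntry("A", (a,), 3),
            sw.LexiconEntry("B", (b,), 1),
            sw.LexiconEntry("AB", (a, b), 2),
        ]
        ms = gt.model_set_for(lex)
        tree = sw.compile_cohort_tree(lex, ms)
        lm = LanguageModel.from_entries(lex)
        rng = np.random.default_rng(100 + seed)
        X = rng.standard_normal((8, 39))
        ft = sw.FeatureTrajectory(np.hstack([X[:, :13], X[:, 13:]]))
        cfg = sw.DecoderConfig(lm_weight=1.0)
        tr = sw.compute_activation_traces(ft, tree, ms, lm=lm, cfg=cfg)

        t_axis = np.arange(1, 9, dtype=float)
        node_by_prefix = {}
        for node in tree.nodes():
            # reconstruct the node's sharing-key path from any completion
            e = next(iter(node.completions))
            keys = entry_keys(e.phones)[: len(node.prefix)]
            node_by_prefix[id(node)] = keys

        def oracle_node(node):
            keys = node_by_prefix[id(node)]
            states, ls, la = _chain_for(ms, keys)
            allowed = set(range(len(states) - 3, len(states)))
            V = _oracle_best_path(states, ls, la, X, allowed)
            prior = log_prior(node, lm, (), cfg.word_class_prior, cfg.pseudo_prior)
            return (V + cfg.lm_weight * prior) / t_axis

        expected = {}
        for node in tree.nodes():
            expected[id(node)] = oracle_node(node)

        for hyp, vals in zip(tr.hypotheses, tr.values):
            if hyp.kind == "cohort":
                node = next(
                    n for n in tree.nodes()
                    if n.prefix == hyp.phones and not n.is_word
                )
                np.testing.assert_allclose(vals, expected[id(node)], atol=1e-9)
            elif hyp.kind == "word":
                entry = hyp.entries[0]
                path = tree.path_nodes(entry)
                exp = np.maximum.reduce([expected[id(n)] for n in path])
                np.testing.assert_allclose(vals, exp, atol=1e-9)

    def test_infeasible_frames_are_minus_inf(self):
        gt = _tiny_world(0)
        a, b = gt.phones
        lex = [sw.LexiconEntry("ABA", (a, b, a), 1)]
        ms = gt.model_set_for(lex)
        tree = sw.compile_cohort_tree(lex, ms)
        X = np.random.default_rng(0).standard_normal((10, 39))
        tr = sw.compute_activation_traces(
            sw.FeatureTrajectory(X), tree, ms
        )
        # the depth-2 cohort needs at least 4 frames (3 to traverse its
        # first phone, 1 to enter its second phone's head state)
        depth2 = next(
            i for i, h in enumerate(tr.hypotheses)
            if h.kind == "cohort" and len(h.phones) == 2
        )
        assert np.all(np.isneginf(tr.values[depth2, :3]))
        assert np.all(np.isfinite(tr.values[depth2, 3:]))
        # the full word adopts its activation from its shorter cohorts, so
        # its trace is defined from the very first frame
        word = next(i for i, h in enumerate(tr.hypotheses) if h.kind == "word")
        assert np.all(np.isfinite(tr.values[word]))


class TestTopDownWeight:
    def test_zero_weight_makes_activations_frequency_independent(self):
        gt = _tiny_world(3)
        a, b = gt.phones
        lex1 = [sw.LexiconEntry("A", (a, b), 1), sw.LexiconEntry("B", (b, a), 1)]
        lex2 = [sw.LexiconEntry("A", (a, b), 50), sw.LexiconEntry("B", (b, a), 1)]
        ms = gt.model_set_for(lex1)
        X = np.random.default_rng(1).standard_normal((10, 39))
        ft = sw.FeatureTrajectory(X)
        cfg = sw.DecoderConfig(lm_weight=0.0)
        tr1 = sw.compute_activation_traces(
            ft, sw.compile_cohort_tree(lex1, ms), ms, cfg=cfg
        )
        tr2 = sw.compute_activation_traces(
            ft, sw.compile_cohort_tree(lex2, ms), ms, cfg=cfg
        )
        np.testing.assert_array_equal(tr1.values, tr2.values)

    def test_raising_frequency_never_lowers_own_cohort_activation(self):
        gt = _tiny_world(4)
        a, b = gt.phones
        base = [sw.LexiconEntry("A", (a, b), 5), sw.LexiconEntry("B", (b, a), 5)]
        boosted = [sw.LexiconEntry("A", (a, b), 50), sw.LexiconEntry("B", (b, a), 5)]
        ms = gt.model_set_for(base)
        X = np.random.default_rng(2).standard_normal((10, 39))
        ft = sw.FeatureTrajectory(X)
        tr1 = sw.compute_activation_traces(ft, sw.compile_cohort_tree(base, ms), ms)
        tr2 = sw.compute_activation_traces(
            ft, sw.compile_cohort_tree(boosted, ms), ms
        )
        for i, h in enumerate(tr1.hypotheses):
            if h.phones[:1] == (a,):  # hypotheses on A's path
                mask = np.isfinite(tr1.values[i])
                assert np.all(tr2.values[i][mask] >= tr1.values[i][mask] - 1e-12)


class TestPrefixIdentity:
    def test_shared_prefix_traces_identical_until_divergence(self, minimal_pair_world):
        """Minimal-pair words have bitwise-equal traces while the input's
        best alignment lies within the shared prefix, and diverge after."""
        w = minimal_pair_world
        gt, lex, ms, tree = w["gt"], w["lexicon"], w["models"], w["tree"]
        durs = (100.0, 100.0, 120.0, 100.0, 100.0)
        spec = sw.StimulusSpec(lex[0].phones, True, durs, seed=21)
        ft = sw.extract_features(sw.synthesize_word_waveform(spec, gt))
        tr = sw.compute_activation_traces(ft, tree, ms)
        iA = next(i for i, h in enumerate(tr.hypotheses)
                  if h.kind == "word" and h.entries[0].orthography == "wordA")
        iB = next(i for i, h in enumerate(tr.hypotheses)
                  if h.kind == "word" and h.entries[0].orthography == "wordB")
        # the pair's sharing keys agree up to the second phone, so until a
        # divergent (depth >= 3) node is feasible — which takes at least
        # 3 + 3 + 1 = 7 frames — both word traces adopt from the same shared
        # cohort nodes and are bitwise equal
        shared = slice(0, 6)
        np.testing.assert_array_equal(tr.values[iA, shared], tr.values[iB, shared])
        assert tr.values[iA, -1] != tr.values[iB, -1]
        assert tr.values[iA, -1] > tr.values[iB, -1]  # input was wordA


class TestPruning:
    def test_infinite_beam_discards_nothing(self, rng):
        vals = rng.standard_normal((5, 10))
        out = prune_hypotheses(vals, np.inf)
        np.testing.assert_array_equal(out, vals)

    def test_tiny_beam_keeps_only_top_and_ties(self, rng):
        vals = np.array([[1.0, 2.0], [1.0, 0.5], [0.0, 2.0]])
        out = prune_hypotheses(vals, 1e-9)
        # frame 0: rows 0,1 tie at 1.0, row 2 pruned for good
        assert np.isfinite(out[0, 0]) and np.isfinite(out[1, 0])
        assert np.isnan(out[2, 0]) and np.isnan(out[2, 1])

    def test_no_revival_matches_posthoc_filter_oracle(self, rng):
        """Surviving sets equal an independently coded frame-by-frame
        filter applied to the unpruned trace."""
        vals = rng.standard_normal((10, 30))
        vals[3, :5] = -np.inf  # a late-starting hypothesis
        beam = 1.0
        out = prune_hypotheses(vals, beam)

        alive = [True] * 10
        for t in range(30):
            finite = [
                i for i in range(10) if alive[i] and np.isfinite(vals[i, t])
            ]
            if not finite:
                continue
            best = max(vals[i, t] for i in finite)
            for i in finite:
                if best - vals[i, t] > beam:
                    alive[i] = False
            for i in range(10):
                expect_dead = not alive[i] and np.isfinite(vals[i, t])
                assert np.isnan(out[i, t]) == (not alive[i]) or not np.isfinite(
                    vals[i, t]
                )

    def test_rejects_nonpositive_beam(self):
        with pytest.raises(ValueError):
            prune_hypotheses(np.zeros((2, 2)), 0.0)


class TestRemoveNested:
    def test_partial_input_example(self):
        """/k @ T/ and /@ T i/ are parts of the better /k @ T i/ and are
        dropped; only the long candidate survives."""
        cands = [
            (("k", "@", "T"), -2.0),
            (("k", "@", "T", "i"), -1.5),
            (("@", "T", "i"), -1.8),
        ]
        keep = remove_nested(cands)
        assert keep == [1]

    def test_singleton_unchanged(self):
        assert remove_nested([(("a",), 0.0)]) == [0]

    def test_higher_part_survives_whole(self):
        cands = [(("a", "b"), -1.0), (("a", "b", "c"), -2.0)]
        assert remove_nested(cands) == [0, 1]  # part has HIGHER activation

    def test_tie_keeps_longer(self):
        cands = [(("a", "b"), -1.0), (("a", "b", "c"), -1.0)]
        assert remove_nested(cands) == [1]

    def test_matches_bruteforce_substring_filter(self, rng):
        """Random sets of <= 8 strings against an independent string-join
        based substring oracle."""
        for trial in range(20):
            n = int(rng.integers(2, 9))
            cands = []
            for _ in range(n):
                L = int(rng.integers(1, 5))
                phones = tuple(rng.choice(["a", "b", "c"], size=L))
                cands.append((phones, float(rng.standard_normal())))
            keep = remove_nested(cands)

            def nested_in(x, y):
                return len(x[0]) < len(y[0]) and ",".join(x[0]) in ",".join(y[0])

            expected = [
                i
                for i, c in enumerate(cands)
                if not any(
                    nested_in(c, other) and other[1] >= c[1]
                    for j, other in enumerate(cands)
                    if j != i
                )
            ]
            assert keep == expected


class TestNoiseEffects:
    def test_noise_on_discriminating_vowel(self, minimal_pair_world):
        """-5 dB noise on the discriminating vowel (i) depresses the target
        word's activation after noise onset and (ii) shrinks and delays the
        minimal-pair activation gap, while the word is still recognized."""
        w = minimal_pair_world
        gt, lex, ms, tree = w["gt"], w["lexicon"], w["models"], w["tree"]
        durs = (100.0, 100.0, 120.0, 100.0, 100.0)
        spec = sw.StimulusSpec(lex[0].phones, True, durs, seed=7)
        spec_noisy = sw.noise_over_phone(spec, w["diverge_index"], -5.0)
        ft_c = sw.extract_features(sw.synthesize_word_waveform(spec, gt))
        ft_n = sw.extract_features(sw.synthesize_word_waveform(spec_noisy, gt))
        tr_c = sw.compute_activation_traces(ft_c, tree, ms)
        tr_n = sw.compute_activation_traces(ft_n, tree, ms)
        idx = {
            h.entries[0].orthography: i
            for i, h in enumerate(tr_c.hypotheses)
            if h.kind == "word"
        }
        iA, iB = idx["wordA"], idx["wordB"]
        onset_f = int(200.0 / 10.0)  # noise begins at the third phone
        post = slice(onset_f + 3, tr_c.n_frames)
        # (i) target activation drops relative to clean after noise onset
        assert np.all(tr_n.values[iA, post] < tr_c.values[iA, post])
        # activations identical before the noise can reach any frame: the
        # 25 ms analysis window plus the +/-4-frame delta-delta context
        # smear the onset ~52 ms backwards
        np.testing.assert_array_equal(
            tr_n.values[iA, : onset_f - 6], tr_c.values[iA, : onset_f - 6]
        )
        # (ii) the pair gap is reduced ...
        gap_c = tr_c.values[iA] - tr_c.values[iB]
        gap_n = tr_n.values[iA] - tr_n.values[iB]
        assert gap_n[-1] < gap_c[-1]
        # ... and delayed: every gap level is reached no earlier in noise
        for level in (2.0, 4.0, 8.0):
            t_c = np.argmax(gap_c >= level)
            t_n = np.argmax(gap_n >= level)
            if gap_n.max() >= level:
                assert t_n >= t_c
        # still recognized correctly at offset
        assert gap_n[-1] > 0
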