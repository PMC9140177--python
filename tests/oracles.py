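"""Independent brute-force oracles shared by the test suite.

These deliberately re-derive quantities by exhaustive enumeration or direct
formula, independent of the library's dynamic-programming implementations.
"""

import itertools

import numpy as np

from spokenword.acoustic import _state_loglik_rows


def chain_for(ms, keys):
    """Flatten a sharing-key path into (emission states, log self, log adv)."""
    states, log_self, log_adv = [], [], []
    for key in keys:
        pm = ms[key]
        states.extend(pm.states)
        log_self.extend(np.log(pm.self_loop))
        log_adv.extend(np.log(pm.advance))
    return states, np.array(log_self), np.array(log_adv)


def oracle_best_path(states, log_self, log_adv, X, allowed_final):
    """Max alignment score over all explicit monotone no-skip state paths,
    for every prefix length t; paths start in state 0 and end in an allowed
    final state."""
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


def bruteforce_nested_filter(candidates):
    """Pairwise substring filter over (phones, activation) candidates."""

    def nested_in(x, y):
        return len(x[0]) < len(y[0]) and ",".join(x[0]) in ",".join(y[0])

    return [
        i
        for i, c in enumerate(candidates)
        if not any(
            nested_in(c, other) and other[1] >= c[1]
            for j, other in enumerate(candidates)
            if j != i
        )
    ]


def direct_entropy_bits(activations, tau):
    """Entropy of explicitly normalised exponentials, in bits."""
    z = np.exp(np.asarray(activations, dtype=float) / tau)
    p = z / z.sum()
    return float(-sum(pi * np.log2(pi) for pi in p if pi > 0))
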