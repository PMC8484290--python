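"""Independent oracles used by the suite, kept separate from the code they check."""

import itertools

import numpy as np


def brute_force_marginals(log_lik, transition, initial):
    """Posterior state marginals by explicit summation over all 5^T paths."""
    T = log_lik.shape[0]
    lik = np.exp(log_lik)
    marginals = np.zeros((T, 5))
    total = 0.0
    for path in itertools.product(range(5), repeat=T):
        p = initial[path[0]] * lik[0, path[0]]
        for t in range(1, T):
            p *= transition[path[t - 1], path[t]] * lik[t, path[t]]
        total += p
        for t, state in enumerate(path):
            marginals[t, state] += p
    return marginals / total
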