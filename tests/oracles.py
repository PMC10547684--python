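"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the package's pruning/sampling code paths: the
likelihood oracle enumerates every internal-state assignment with per-branch
matrix exponentials from scipy, and the path-law oracle simulates the chain
on a fine time grid with rejection on the endpoint.
"""

import itertools
import math

import numpy as np
from scipy.linalg import expm


def enumeration_loglik(tree, tip_state_of, Q, prior):
    """Sum over all internal-state assignments; any alphabet size.

    ``tip_state_of`` maps tip label -> state int, or None for ambiguous.
    """
    k = Q.shape[0]
    P = [expm(Q * b) for b in tree.blen]
    internals = list(tree.postorder_internal)
    tip_choices = []
    for i in range(tree.n_tips):
        s = tip_state_of.get(tree.tip_labels[i])
        tip_choices.append(range(k) if s is None else [int(s)])
    total = 0.0
    for tip_assign in itertools.product(*tip_choices):
        for int_assign in itertools.product(range(k), repeat=len(internals)):
            full = list(tip_assign) + list(int_assign)
            p = prior[full[tree.root]]
            for i in range(tree.n_nodes - 1):
                p *= P[i][full[tree.parent[i]], full[i]]
            total += p
    return math.log(total) if total > 0 else -math.inf


def enumeration_marginals(tree, tip_state_of, Q, prior):
    """Bayes-rule node marginals by the same enumeration."""
    k = Q.shape[0]
    P = [expm(Q * b) for b in tree.blen]
    internals = list(tree.postorder_internal)
    tip_assign = [int(tip_state_of[tree.tip_labels[i]]) for i in range(tree.n_tips)]
    post = np.zeros((tree.n_nodes, k))
    for int_assign in itertools.product(range(k), repeat=len(internals)):
        full = tip_assign + list(int_assign)
        p = prior[full[tree.root]]
        for i in range(tree.n_nodes - 1):
            p *= P[i][full[tree.parent[i]], full[i]]
        for j, node in enumerate(internals):
            post[node, int_assign[j]] += p
    post[tree.n_tips:] /= post[tree.n_tips:].sum(axis=1, keepdims=True)
    return post


def discretized_event_counts(q01, q10, t, a, b, n_draws, n_steps, seed):
    """Event-count distribution of a 2-state chain on a fine grid,
    rejection-conditioned on ending in state ``b``."""
    rng = np.random.default_rng(seed)
    dt = t / n_steps
    p = (q01 * dt, q10 * dt)
    counts = {}
    accepted = 0
    while accepted < n_draws:
        m = min(n_draws - accepted, 2000)
        u = rng.random((m, n_steps))
        s = np.full(m, a)
        nev = np.zeros(m, dtype=int)
        for j in range(n_steps):
            flip = u[:, j] < np.where(s == 0, p[0], p[1])
            s = np.where(flip, 1 - s, s)
            nev += flip
        ok = s == b
        for c in nev[ok]:
            counts[int(c)] = counts.get(int(c), 0) + 1
        accepted += int(ok.sum())
    return counts


def brute_force_node_ages(tree):
    """Per-node age as the path length down to any descendant tip,
    walking paths explicitly."""
    ages = np.zeros(tree.n_nodes)
    for i in range(tree.n_nodes):
        node, dist = i, 0.0
        # walk to the leftmost descendant tip
        while tree.children[node]:
            child = tree.children[node][0]
            dist += tree.blen[child]
            node = child
        ages[i] = dist
    return ages
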