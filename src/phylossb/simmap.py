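"""Stochastic character mapping: sampling histories conditional on tip data.

Given a fitted Mk generator, full character histories are drawn in three
steps: a pruning pass gives conditional node distributions; node states are
drawn root-down (root from its marginal under the configured prior, each
child conditional on its parent and the data below it); and within-branch
event paths are drawn conditional on the branch's endpoint states by
uniformization - the jump count comes from the Poisson-subordinated jump
chain conditioned on the endpoints, jump times are uniform order statistics,
and the jump-state sequence is a discrete Markov bridge.  Uniformization
remains exact and efficient on low-rate branches where naive rejection
sampling stalls.

Gain (0->1) and loss (1->0) counts per sampled history summarise how many
times a binary trait arose and disappeared.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .mk import MkFit, _pruning_partials, _resolve_root_prior, transition_matrices, validate_rate_matrix
from .simulate import CharacterHistory
from .trees import Phylogeny

__all__ = ["SimmapSummary", "sample_histories", "sample_branch_path", "transition_counts_summary"]


_TABLE_CACHE: dict[tuple, tuple] = {}


def _uniformization_tables(Q: np.ndarray, n_max: int = 256):
    key = (Q.tobytes(), min(n_max, 4096))
    hit = _TABLE_CACHE.get(key)
    if hit is not None:
        return hit
    out = _build_uniformization_tables(Q, n_max)
    if len(_TABLE_CACHE) > 32:
        _TABLE_CACHE.clear()
    _TABLE_CACHE[key] = out
    return out


def _build_uniformization_tables(Q: np.ndarray, n_max: int = 256):
    # powers of the jump chain R converge to the stationary projector, so the
    # table is capped and the last entry stands in for all higher powers
    n_max = min(n_max, 4096)
    mu = float(np.max(-np.diag(Q)))
    k = Q.shape[0]
    if mu <= 0:
        return mu, np.eye(k)[None, :, :]
    R = np.eye(k) + Q / mu
    powers = np.empty((n_max + 1, k, k))
    powers[0] = np.eye(k)
    for n in range(1, n_max + 1):
        powers[n] = powers[n - 1] @ R
    return mu, powers


def sample_branch_path(
    a: int,
    b: int,
    t: float,
    Q: np.ndarray,
    rng: np.random.Generator,
    *,
    _tables=None,
    p_ab: float | None = None,
) -> list[tuple[float, int, int]]:
    """Events on one branch of length ``t`` conditioned on endpoints a -> b.

    Returns (time offset, from-state, to-state) for each real state change.
    """
    Q = np.asarray(Q, dtype=float)
    mu, powers = _tables if _tables is not None else _uniformization_tables(Q)
    if mu <= 0:
        if a != b:
            raise ValueError("zero-rate generator cannot connect different endpoints")
        return []
    n_pow = powers.shape[0] - 1
    if p_ab is None:
        p_ab = float(transition_matrices(Q, np.array([t]))[0, a, b])
    if p_ab <= 0:
        raise ValueError(f"endpoint pair ({a}->{b}) impossible on branch of length {t}")
    # jump count N | endpoints: P(N=n) ~ Poisson(mu t)(n) * R^n[a,b] / P_ab
    u = rng.random()
    lam = mu * t
    cap = int(lam + 12.0 * math.sqrt(lam + 1.0) + 50.0)
    log_pois = -lam
    cum = 0.0
    n_jumps = None
    for n in range(cap + 1):
        if n > 0:
            log_pois += math.log(lam) - math.log(n)
        w = math.exp(log_pois) * powers[min(n, n_pow), a, b] / p_ab
        cum += w
        if u <= cum:
            n_jumps = n
            break
    if n_jumps is None:
        n_jumps = cap  # astronomically unlikely given the 12-sigma cap
    if n_jumps == 0:
        return []
    times = np.sort(rng.random(n_jumps)) * t
    # Markov-bridge state sequence through the jump chain R; scalar
    # arithmetic because histories under fast rates contain thousands of
    # virtual jumps
    k = powers.shape[1]
    R_rows = powers[1].tolist()
    idx = np.minimum(np.arange(n_jumps), n_pow)
    tail = powers[idx, :, b]  # tail[j, s] = R^j [s, b] (capped)
    us = rng.random(n_jumps - 1)
    states = [a]
    prev = a
    if k == 2:
        t0 = tail[:, 0].tolist()
        t1 = tail[:, 1].tolist()
        for i in range(1, n_jumps):
            r = R_rows[prev]
            w0 = r[0] * t0[n_jumps - i]
            w1 = r[1] * t1[n_jumps - i]
            prev = 0 if us[i - 1] * (w0 + w1) < w0 else 1
            states.append(prev)
    else:
        for i in range(1, n_jumps):
            w = np.asarray(R_rows[prev]) * tail[n_jumps - i]
            cw = np.cumsum(w)
            prev = int(np.searchsorted(cw, us[i - 1] * cw[-1], side="right"))
            prev = min(prev, k - 1)
            states.append(prev)
    states.append(b)
    events = []
    for i in range(n_jumps):
        if states[i] != states[i + 1]:
            events.append((float(times[i]), states[i], states[i + 1]))
    return events


def sample_histories(
    tree: Phylogeny,
    tip_states: Mapping[str, object] | np.ndarray,
    fit: MkFit | None = None,
    n: int = 1000,
    seed: int | None = None,
    *,
    Q: np.ndarray | None = None,
    root_prior=None,
) -> list[CharacterHistory]:
    """Draw ``n`` character histories consistent with the tips.

    The generator is taken from ``fit`` (the "empirical" mode: rates fixed at
    their ML estimates) or given directly as ``Q``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if fit is not None:
        if not fit.converged:
            raise ValueError("fit did not converge")
        Q = fit.rate_matrix
        prior = fit.root_prior if root_prior is None else _resolve_root_prior(root_prior, Q)
    else:
        if Q is None:
            raise ValueError("either fit or Q must be given")
        Q = validate_rate_matrix(Q)
        prior = _resolve_root_prior(root_prior, Q)
    k = Q.shape[0]
    tips = tip_states if isinstance(tip_states, np.ndarray) else tree.states_array(tip_states, k)
    rng = np.random.default_rng(seed)
    P = transition_matrices(Q, tree.blen)
    L, log_scale = _pruning_partials(tree, tips, P)
    root_post = prior * L[tree.root]
    z = root_post.sum()
    if not np.isfinite(log_scale) or z <= 0:
        raise ValueError("tip states impossible under the supplied generator")
    root_post = root_post / z

    # vectorised root-down draws of node states for all n maps at once
    node_states = np.empty((tree.n_nodes, n), dtype=np.int64)
    node_states[tree.root] = rng.choice(k, size=n, p=root_post)
    # per-branch conditional tables: cond[i][s] = P(child i = j | parent = s)
    cond = np.empty((tree.n_nodes - 1, k, k))
    for i in range(tree.n_nodes - 1):
        w = P[i] * L[i][None, :]
        rs = w.sum(axis=1, keepdims=True)
        rs[rs == 0] = 1.0
        cond[i] = w / rs
    cum = np.cumsum(cond, axis=2)
    for i in range(tree.n_nodes - 2, -1, -1):  # preorder below root
        par = node_states[tree.parent[i]]
        u = rng.random(n)
        node_states[i] = (u[:, None] > cum[i][par]).sum(axis=1)

    mu_tables = _uniformization_tables(Q, n_max=max(64, int(np.ceil(
        np.max(-np.diag(Q)) * tree.blen.max() * 5 + 32))))
    histories: list[CharacterHistory] = []
    for j in range(n):
        events: list[list[tuple[float, int, int]]] = [[] for _ in range(tree.n_nodes)]
        for i in range(tree.n_nodes - 1):
            a = int(node_states[tree.parent[i], j])
            b = int(node_states[i, j])
            events[i] = sample_branch_path(
                a, b, float(tree.blen[i]), Q, rng,
                _tables=mu_tables, p_ab=float(P[i, a, b]),
            )
        histories.append(CharacterHistory(
            tree=tree,
            node_states=node_states[:, j].copy(),
            events=events,
            root_state=int(node_states[tree.root, j]),
        ))
    return histories


@dataclass
class SimmapSummary:
    """Gain/loss counts across sampled histories."""

    n_iterations: int
    gains: np.ndarray   # per-iteration 0->1 counts
    losses: np.ndarray  # per-iteration 1->0 counts
    mean_gains: float
    mean_losses: float
    sd_gains: float
    sd_losses: float
    q_gains: tuple[float, float]   # 2.5 / 97.5 percentiles
    q_losses: tuple[float, float]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "iteration": np.arange(self.n_iterations),
            "gains": self.gains,
            "losses": self.losses,
        })


def transition_counts_summary(
    histories: Sequence[CharacterHistory],
    *,
    gain: tuple[int, int] = (0, 1),
    loss: tuple[int, int] = (1, 0),
) -> SimmapSummary:
    if not histories:
        raise ValueError("no histories supplied")
    gains = np.array([h.transition_count(*gain) for h in histories], dtype=float)
    losses = np.array([h.transition_count(*loss) for h in histories], dtype=float)
    return SimmapSummary(
        n_iterations=len(histories),
        gains=gains,
        losses=losses,
        mean_gains=float(gains.mean()),
        mean_losses=float(losses.mean()),
        sd_gains=float(gains.std(ddof=1)) if len(histories) > 1 else 0.0,
        sd_losses=float(losses.std(ddof=1)) if len(histories) > 1 else 0.0,
        q_gains=(float(np.percentile(gains, 2.5)), float(np.percentile(gains, 97.5))),
        q_losses=(float(np.percentile(losses, 2.5)), float(np.percentile(losses, 97.5))),
    )
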