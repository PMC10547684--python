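"""Fritz-Purvis D: phylogenetic signal for binary traits.

The observed quantity d is the sum, over every branch, of the absolute
difference between the trait values at the branch's two ends, where internal
(nodal) values are estimated tipward-to-rootward as the mean of the daughter
values.  d is standardised between two nulls sharing the observed prevalence:

* random null - tip states shuffled across the tips (phylogenetically random);
* Brownian-threshold null - a Brownian liability evolves on the tree from a
  root value of 0 with unit rate, and the tips with the top-m liabilities
  (m = observed number of 1s) are assigned state 1.

D = (d_obs - mean d_Brownian) / (mean d_random - mean d_Brownian), so that a
random trait has D ~ 1 and a threshold-Brownian trait D ~ 0; D < 0 indicates
stronger clumping than Brownian expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .mk import NoVariationError
from .trees import Phylogeny

__all__ = ["DStatResult", "sister_diff_sum", "d_statistic", "brownian_threshold_states"]


@dataclass
class DStatResult:
    d_obs: float
    mean_d_random: float
    mean_d_brownian: float
    D: float | None  # None when the two null means coincide
    p_random: float
    p_brownian: float
    n_permutations: int
    n_simulations: int
    seed: int | None
    degenerate: bool = False


def _states_vector(tree: Phylogeny, tip_states: Mapping[str, object] | np.ndarray) -> np.ndarray:
    if isinstance(tip_states, np.ndarray):
        v = np.asarray(tip_states, dtype=float)
        if v.shape != (tree.n_tips,):
            raise ValueError("state vector length must equal the number of tips")
    else:
        missing = [l for l in tree.tip_labels if l not in tip_states]
        if missing:
            raise ValueError(f"tips without a state: {missing[:5]}{'...' if len(missing) > 5 else ''}")
        v = np.array([float(tip_states[l]) for l in tree.tip_labels])
    if not np.all(np.isin(v, (0.0, 1.0))):
        raise ValueError("trait must be binary 0/1")
    if v.min() == v.max():
        raise NoVariationError("trait is monomorphic; D is undefined")
    return v


def _branch_change_sums(tree: Phylogeny, states: np.ndarray) -> np.ndarray:
    """d for each column of ``states`` (n_tips, m) -> (m,)."""
    n, m = tree.n_nodes, states.shape[1]
    v = np.empty((n, m))
    v[: tree.n_tips] = states
    for i in tree.postorder_internal:
        kids = tree.children[i]
        acc = v[kids[0]].copy()
        for c in kids[1:]:
            acc += v[c]
        v[i] = acc / len(kids)
    d = np.zeros(m)
    for i in range(n - 1):  # every branch: node -> parent
        d += np.abs(v[i] - v[tree.parent[i]])
    return d


def sister_diff_sum(tree: Phylogeny, tip_states: Mapping[str, object] | np.ndarray) -> float:
    """Observed sum of nodal-value changes along all branches."""
    v = _states_vector(tree, tip_states)
    return float(_branch_change_sums(tree, v[:, None])[0])


def brownian_liabilities(tree: Phylogeny, rng: np.random.Generator, m: int = 1) -> np.ndarray:
    """Brownian motion from root value 0 with unit rate -> (n_tips, m)."""
    x = np.zeros((tree.n_nodes, m))
    sd = np.sqrt(tree.blen)
    for i in range(tree.n_nodes - 2, -1, -1):  # preorder below root
        x[i] = x[tree.parent[i]] + rng.standard_normal(m) * sd[i]
    return x[: tree.n_tips]


def brownian_threshold_states(
    tree: Phylogeny, n_ones: int, rng: np.random.Generator, m: int = 1
) -> np.ndarray:
    """Threshold-by-rank Brownian traits: top ``n_ones`` liabilities -> 1.

    Rank thresholding preserves the observed prevalence exactly in every
    simulation.
    """
    liab = brownian_liabilities(tree, rng, m)
    out = np.zeros_like(liab)
    if n_ones <= 0:
        return out
    if n_ones >= tree.n_tips:
        out[:] = 1.0
        return out
    part = np.argpartition(-liab, n_ones - 1, axis=0)[:n_ones]
    np.put_along_axis(out, part, 1.0, axis=0)
    return out


def d_statistic(
    tree: Phylogeny,
    tip_states: Mapping[str, object] | np.ndarray,
    n_permutations: int = 1000,
    n_simulations: int = 1000,
    seed: int | None = None,
) -> DStatResult:
    """D with permutation and Brownian-threshold nulls.

    ``p_random`` is the fraction of shuffled traits with d <= d_obs (small
    values mean the trait is more clumped than random); ``p_brownian`` the
    fraction of threshold-Brownian traits with d >= d_obs.
    """
    v = _states_vector(tree, tip_states)
    n_ones = int(v.sum())
    rng = np.random.default_rng(seed)
    d_obs = float(_branch_change_sums(tree, v[:, None])[0])

    perm = np.empty((tree.n_tips, n_permutations))
    for j in range(n_permutations):
        perm[:, j] = rng.permutation(v)
    d_rand = _branch_change_sums(tree, perm)

    brown = brownian_threshold_states(tree, n_ones, rng, n_simulations)
    d_brown = _branch_change_sums(tree, brown)

    mean_r = float(d_rand.mean())
    mean_b = float(d_brown.mean())
    denom = mean_r - mean_b
    degenerate = abs(denom) < 1e-12
    D = None if degenerate else (d_obs - mean_b) / denom
    p_random = float(np.mean(d_rand <= d_obs))
    p_brownian = float(np.mean(d_brown >= d_obs))
    return DStatResult(
        d_obs=d_obs,
        mean_d_random=mean_r,
        mean_d_brownian=mean_b,
        D=D,
        p_random=p_random,
        p_brownian=p_brownian,
        n_permutations=n_permutations,
        n_simulations=n_simulations,
        seed=seed,
        degenerate=degenerate,
    )
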