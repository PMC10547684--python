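"""Synthetic trees and trait data with recorded ground truth.

The generators emulate the statistical structure of a species-level
comparative dataset on a dated mammal-like phylogeny: an ultrametric
birth-death tree, rare binary behavioural traits (~4% prevalence for
same-sex sexual behaviour, matching its reported rarity in mammals),
sociality and sex-specific adulticide evolving as Mk characters, heavy-tailed
per-species citation counts, and captivity-only observation flags.

Character evolution is simulated by exact Gillespie event sampling down the
tree, so every dataset carries its true character history — the ground truth
the stochastic-mapping and rate-recovery tests compare against.  All
randomness flows from one seed.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .mk import validate_rate_matrix
from .trees import Phylogeny

__all__ = [
    "CharacterHistory",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_mk",
    "simulate_dependent_pair",
    "simulate_threshold_trait",
    "make_fixture_dataset",
    "jitter_tree_ensemble",
]


@dataclass
class CharacterHistory:
    """A complete character history on a tree.

    ``events[i]`` lists (time offset from the start of branch i, from-state,
    to-state) in order; ``node_states`` holds the state at every node.
    """

    tree: Phylogeny
    node_states: np.ndarray
    events: list[list[tuple[float, int, int]]]
    root_state: int

    @property
    def n_events(self) -> int:
        return sum(len(e) for e in self.events)

    def transition_count(self, from_state: int, to_state: int) -> int:
        return sum(1 for ev in self.events for (_, a, b) in ev
                   if a == from_state and b == to_state)

    def tip_states(self) -> dict[str, int]:
        return {self.tree.tip_labels[i]: int(self.node_states[i])
                for i in range(self.tree.n_tips)}


def simulate_tree(
    n_tips: int,
    model: str = "yule",
    *,
    birth_rate: float = 1.0,
    death_rate: float = 0.0,
    scale_root_age: float | None = None,
    seed: int | None = None,
) -> Phylogeny:
    """Ultrametric birth-death tree with exactly ``n_tips`` extant tips.

    ``model`` is "yule" (pure birth) or "birth_death" (requires
    birth_rate > death_rate >= 0).  Tips are labelled s0001..sN.  The root age
    is optionally rescaled to ``scale_root_age`` (Myr).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if model == "yule":
        death_rate = 0.0
    elif model != "birth_death":
        raise ValueError(f"unknown model {model!r}")
    if not birth_rate > death_rate >= 0:
        raise ValueError("need birth_rate > death_rate >= 0")
    rng = _random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_tips,
        rng=rng,
    )
    # the simulator stops exactly at the n-th speciation, leaving the newest
    # cherry with zero-length branches; run the clock forward by the waiting
    # time to the next event so every terminal branch is positive
    residual = rng.expovariate(n_tips * (birth_rate + death_rate))
    for leaf in dtree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + residual
    width = max(4, len(str(n_tips)))
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"s{i:0{width}d}"
    tree = Phylogeny(dtree)
    if scale_root_age is not None:
        if scale_root_age <= 0:
            raise ValueError("scale_root_age must be > 0")
        factor = scale_root_age / tree.root_age()
        tree.blen *= factor
        for edge in tree._dendropy.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
    return tree


def simulate_mk(
    tree: Phylogeny,
    Q: np.ndarray,
    root_state_policy="stationary",
    seed: int | None = None,
) -> CharacterHistory:
    """Exact Gillespie simulation of a k-state Mk character down the tree.

    ``root_state_policy`` is "stationary", a fixed integer state, or a
    probability vector.  Every transition event is recorded.
    """
    Q = validate_rate_matrix(Q)
    k = Q.shape[0]
    rng = np.random.default_rng(seed)
    if isinstance(root_state_policy, (int, np.integer)):
        root_state = int(root_state_policy)
    else:
        if isinstance(root_state_policy, str) and root_state_policy == "stationary":
            from .mk import stationary_distribution

            p = stationary_distribution(Q)
        else:
            p = np.asarray(root_state_policy, dtype=float)
        root_state = int(rng.choice(k, p=p / p.sum()))
    states = np.empty(tree.n_nodes, dtype=int)
    states[tree.root] = root_state
    events: list[list[tuple[float, int, int]]] = [[] for _ in range(tree.n_nodes)]
    out_rate = -np.diag(Q)
    for i in range(tree.n_nodes - 2, -1, -1):  # preorder below the root
        s = states[tree.parent[i]]
        t = 0.0
        length = tree.blen[i]
        while True:
            r = out_rate[s]
            if r <= 0:
                break
            t += rng.exponential(1.0 / r)
            if t >= length:
                break
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = probs / probs.sum()
            new = int(rng.choice(k, p=probs))
            events[i].append((t, s, new))
            s = new
        states[i] = s
    return CharacterHistory(tree=tree, node_states=states, events=events,
                            root_state=root_state)


def simulate_dependent_pair(
    tree: Phylogeny,
    rates: Mapping[str, float],
    seed: int | None = None,
    root_state_policy="stationary",
) -> tuple[dict[str, int], dict[str, int], CharacterHistory]:
    """Joint simulation of two binary traits on the 4-state dependency chain.

    ``rates`` uses the eight named single-change rates of
    :mod:`phylossb.pagel`; double transitions have rate 0 by construction.
    Returns the two marginal tip-state maps plus the true joint history.
    """
    from .pagel import PAIR_OF_STATE, pagel_rate_matrix

    Q = pagel_rate_matrix(rates)
    hist = simulate_mk(tree, Q, root_state_policy=root_state_policy, seed=seed)
    x = {}
    y = {}
    for label, s in hist.tip_states().items():
        xs, ys = PAIR_OF_STATE[s]
        x[label] = xs
        y[label] = ys
    return x, y, hist


def simulate_threshold_trait(
    tree: Phylogeny,
    prevalence: float,
    seed: int | None = None,
) -> np.ndarray:
    """Brownian-liability trait thresholded by rank to a target prevalence.

    The top ceil(prevalence * n_tips) liabilities become state 1; boundaries
    0 and 1 give monomorphic traits.
    """
    if not 0.0 <= prevalence <= 1.0:
        raise ValueError("prevalence must be in [0, 1]")
    from .signal import brownian_threshold_states

    rng = np.random.default_rng(seed)
    n_ones = int(np.ceil(prevalence * tree.n_tips))
    return brownian_threshold_states(tree, n_ones, rng, 1)[:, 0].astype(int)


def _newick_from_arrays(tree: Phylogeny, blen: np.ndarray) -> str:
    parts: dict[int, str] = {}
    for i in range(tree.n_tips):
        parts[i] = f"{tree.tip_labels[i]}:{blen[i]:.12g}"
    for i in tree.postorder_internal:
        inner = ",".join(parts[c] for c in tree.children[i])
        if i == tree.root:
            parts[i] = f"({inner});"
        else:
            parts[i] = f"({inner}):{blen[i]:.12g}"
    return parts[tree.root]


def jitter_tree_ensemble(
    tree: Phylogeny, n: int, rel_sd: float = 0.1, seed: int | None = None
):
    """An ensemble of dated-tree variants: same topology, perturbed node ages.

    Emulates draws from a posterior over divergence times: each internal
    node's height above its tallest child is multiplied by an independent
    log-normal factor, which preserves ultrametricity and parent-older-than-
    child ordering.  The observed tree is included as member 0.
    """
    from .trees import TreeEnsemble

    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    ages = tree.node_ages()
    out = [tree]
    for _ in range(n - 1):
        new_ages = ages.copy()
        for i in tree.postorder_internal:
            cmax_new = max(new_ages[c] for c in tree.children[i])
            gap = ages[i] - max(ages[c] for c in tree.children[i])
            new_ages[i] = cmax_new + gap * rng.lognormal(0.0, rel_sd)
        blen = np.zeros(tree.n_nodes)
        for i in range(tree.n_nodes - 1):
            blen[i] = new_ages[tree.parent[i]] - new_ages[i]
        out.append(Phylogeny.from_newick(_newick_from_arrays(tree, blen)))
    return TreeEnsemble(out)


@dataclass
class SyntheticDataset:
    """Tree + trait table + the ground truth that generated them."""

    tree: Phylogeny
    table: "pd.DataFrame"  # noqa: F821 - see traits.TraitTable for schema
    truth: dict = field(default_factory=dict)
    histories: dict[str, CharacterHistory] = field(default_factory=dict)

    def trait_table(self, provenance: str = "synthetic"):
        from .traits import TraitTable

        return TraitTable(self.table, provenance=provenance)


def _standard_phylo_liability(tree: Phylogeny, rng: np.random.Generator) -> np.ndarray:
    """Brownian liability standardised to unit marginal variance per tip."""
    from .signal import brownian_liabilities

    liab = brownian_liabilities(tree, rng, 1)[:, 0]
    sd = np.sqrt(np.maximum(tree.node_ages()[tree.root], 1e-12))
    return liab / sd


def _phylogenetic_bernoulli(
    tree: Phylogeny,
    logits: np.ndarray,
    rng: np.random.Generator,
    *,
    phylo_weight: float = 0.6,
    shared: np.ndarray | None = None,
    shared_weight: float = 0.0,
) -> np.ndarray:
    """Bernoulli draws with the target marginal probabilities and
    phylogenetically correlated noise (Gaussian copula on a Brownian
    liability standardised per tip).  ``shared`` mixes in a common latent
    field so that two traits drawn with the same field co-occur more often
    than independence predicts (the marginals are unchanged)."""
    from scipy.special import expit
    from scipy.stats import norm as _norm

    p = expit(logits)
    z_phy = _standard_phylo_liability(tree, rng)
    z = (np.sqrt(phylo_weight) * z_phy
         + np.sqrt(max(0.0, 1.0 - phylo_weight - shared_weight))
         * rng.standard_normal(tree.n_tips))
    if shared is not None and shared_weight > 0:
        z = z + np.sqrt(shared_weight) * shared
    u = _norm.cdf(z)
    return (u < p).astype(int)


def make_fixture_dataset(
    n_species: int = 500,
    *,
    ssb_prevalence: float = 0.04,
    sociality_rates: tuple[float, float] | None = None,
    adulticide_rates: tuple[float, float] | None = None,
    ssb_sociality_effect: float = 1.2,
    ssb_phylo_weight: float = 0.0,
    captivity_only_fraction: float = 0.2,
    citation_lognormal: tuple[float, float] = (np.log(200.0), 1.5),
    root_age: float = 150.0,
    seed: int | None = None,
) -> SyntheticDataset:
    """A full synthetic comparative dataset.

    * tree: Yule, rescaled to ``root_age`` Myr;
    * sociality and sex-specific adulticide: binary Mk characters (defaults:
      gain/loss 2/150 and 1.5/150 per Myr — a handful of expected changes per
      root-to-tip path);
    * male/female SSB: Bernoulli with logit = b0 + effect * sociality plus
      phylogenetically correlated noise; b0 is calibrated so the expected
      prevalence equals ``ssb_prevalence``;
    * captivity-only observation flags on a fraction of SSB-positive species;
    * citations: log-normal (median ~200, heavy tail);
    * multi-year/site study flag: more likely for heavily cited species.

    The ground truth (parameters, histories, per-species latent logits) is
    recorded for downstream recovery tests.
    """
    from scipy.special import expit, logit

    rng = np.random.default_rng(seed)
    tree = simulate_tree(n_species, "yule", scale_root_age=root_age,
                         seed=int(rng.integers(2**31)))
    if sociality_rates is None:
        sociality_rates = (2.0 / root_age, 2.0 / root_age)
    if adulticide_rates is None:
        adulticide_rates = (1.5 / root_age, 1.5 / root_age)
    from .mk import binary_rate_matrix

    hist_soc = simulate_mk(tree, binary_rate_matrix(*sociality_rates),
                           seed=int(rng.integers(2**31)))
    hist_am = simulate_mk(tree, binary_rate_matrix(*adulticide_rates),
                          seed=int(rng.integers(2**31)))
    hist_af = simulate_mk(tree, binary_rate_matrix(*adulticide_rates),
                          seed=int(rng.integers(2**31)))
    soc = np.array([hist_soc.node_states[i] for i in range(tree.n_tips)])
    # calibrate the intercept so the expected prevalence of SSB in EITHER sex
    # hits the target; the two sexes' latent liabilities are correlated
    # (shared + phylo components below), so P(both absent) is a bivariate-
    # normal orthant probability, not (1-p)^2
    from scipy.stats import multivariate_normal, norm as _norm

    sex_corr = 0.7  # weight of the shared latent field; male and female SSB
    # co-occur in the same species far more often than at random
    cov = [[1.0, sex_corr], [sex_corr, 1.0]]

    def _union_prevalence(b0: float) -> float:
        p = expit(b0 + ssb_sociality_effect * soc)
        out = np.empty_like(p)
        for val in np.unique(p):
            q = _norm.ppf(1.0 - val)
            both_absent = float(multivariate_normal.cdf([q, q], mean=[0, 0], cov=cov))
            out[p == val] = 1.0 - both_absent
        return float(out.mean())

    target = float(np.clip(ssb_prevalence, 1e-6, 1 - 1e-6))
    lo, hi = -30.0, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _union_prevalence(mid) < target:
            lo = mid
        else:
            hi = mid
    b0 = 0.5 * (lo + hi)
    logits = b0 + ssb_sociality_effect * soc
    # the two sexes share a latent liability: SSB in males and females
    # co-occurs in the same species far more often than at random
    # by default the residual copula is independent across species (so the
    # SSB-positive count is binomial and its phylogenetic clustering comes
    # entirely from the conserved sociality predictor); ``ssb_phylo_weight``
    # mixes in a Brownian liability for explicitly clumped residuals
    shared = rng.standard_normal(tree.n_tips)
    male = _phylogenetic_bernoulli(tree, logits, rng,
                                   phylo_weight=ssb_phylo_weight,
                                   shared=shared, shared_weight=sex_corr)
    female = _phylogenetic_bernoulli(tree, logits, rng,
                                     phylo_weight=ssb_phylo_weight,
                                     shared=shared, shared_weight=sex_corr)
    ssb_any = (male | female).astype(bool)

    context = np.array(["unknown"] * tree.n_tips, dtype=object)
    capt_only = np.zeros(tree.n_tips, dtype=bool)
    for i in np.flatnonzero(ssb_any):
        if rng.random() < captivity_only_fraction:
            context[i] = "captivity"
            capt_only[i] = True
        else:
            context[i] = "wild" if rng.random() < 0.8 else "both"

    mu, sigma = citation_lognormal
    citations = np.maximum(1, np.round(rng.lognormal(mu, sigma, tree.n_tips))).astype(int)
    p_multi = expit(1.2 * (np.log(citations) - mu) / sigma)
    multi = (rng.random(tree.n_tips) < p_multi).astype(int)

    display_pool = ("mounting_genital", "courtship", "pair_bonding", "copulation")
    display_p = (0.87, 0.27, 0.24, 0.15)
    displays = []
    for i in range(tree.n_tips):
        if not ssb_any[i]:
            displays.append("")
            continue
        chosen = [d for d, pd_ in zip(display_pool, display_p) if rng.random() < pd_]
        if not chosen:
            chosen = ["mounting_genital"]
        displays.append(";".join(chosen))

    import pandas as pd

    table = pd.DataFrame({
        "species": tree.tip_labels,
        "male_ssb": male,
        "female_ssb": female,
        "observed_context": context,
        "display_types": displays,
        "age_class": np.where(ssb_any, "adult", "unknown"),
        "sociality": soc,
        "adulticide_male": [hist_am.node_states[i] for i in range(tree.n_tips)],
        "adulticide_female": [hist_af.node_states[i] for i in range(tree.n_tips)],
        "citations": citations,
        "studied_multi_year_site": multi,
    })
    truth = {
        "seed": seed,
        "n_species": n_species,
        "root_age": root_age,
        "ssb_prevalence": ssb_prevalence,
        "ssb_intercept": float(b0),
        "ssb_sociality_effect": float(ssb_sociality_effect),
        "sociality_rates": tuple(sociality_rates),
        "adulticide_rates": tuple(adulticide_rates),
        "captivity_only_fraction": captivity_only_fraction,
        "n_ssb_positive": int(ssb_any.sum()),
        "n_captivity_only_ssb": int(capt_only.sum()),
        "n_male_ssb": int(male.sum()),
        "n_female_ssb": int(female.sum()),
        "n_multi_year_site": int(multi.sum()),
        "logits": logits,
    }
    return SyntheticDataset(
        tree=tree,
        table=table,
        truth=truth,
        histories={"sociality": hist_soc, "adulticide_male": hist_am,
                   "adulticide_female": hist_af},
    )
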