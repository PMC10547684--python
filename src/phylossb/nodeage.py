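"""Node classification against a tip-reshuffling null, and node-age tests.

For a binary trait on a dated tree, each internal node's marginal presence
probability (from the Mk reconstruction) is compared with the distribution
of the same quantity under a null in which the tip states are randomly
reshuffled across the tips (topology and prevalence fixed).  A node whose
observed probability exceeds the null's upper bound is classified
``present``; below the lower bound, ``absent``; inside the null envelope,
``equivocal`` — the conservative reading of an ambiguous reconstruction.

The ages of present vs absent nodes are then compared with a Welch t-test:
a significantly younger present group indicates the trait is concentrated
in recent clades rather than being ancestral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .mk import MkFit, fit_mk, marginal_ancestral_states
from .trees import Phylogeny

__all__ = [
    "NodeClassification",
    "AgeComparison",
    "classify_nodes_vs_null",
    "compare_age_distributions",
]


@dataclass
class NodeClassification:
    """One internal node's verdict against the reshuffling null."""

    node: frozenset          # descendant tip set
    age: float               # Myr above the tips
    observed: float          # marginal presence probability
    null_lower: float
    null_upper: float
    label: str               # "present" | "absent" | "equivocal"


def _presence_probabilities(
    tree: Phylogeny,
    states_vec: np.ndarray,
    *,
    fit: MkFit | None,
    refit: bool,
    state: int,
    seed,
) -> tuple[np.ndarray, MkFit]:
    tips = np.zeros((tree.n_tips, 2))
    tips[np.arange(tree.n_tips), states_vec.astype(int)] = 1.0
    if refit or fit is None:
        fit = fit_mk(tree, tips, "ARD", n_restarts=1, seed=seed)
    rec = marginal_ancestral_states(tree, tips, fit)
    return rec.probabilities[tree.n_tips:, state], fit


def classify_nodes_vs_null(
    tree: Phylogeny,
    tip_states: Mapping[str, object] | np.ndarray,
    n_shuffles: int = 100,
    *,
    rule: str = "percentile",
    percentile: float = 95.0,
    refit: bool = True,
    state: int = 1,
    seed: int | None = None,
) -> list[NodeClassification]:
    """Classify every internal node as present / absent / equivocal.

    ``rule`` is "percentile" (default: per-node 2.5th/97.5th percentiles of
    the null, for ``percentile=95``) or "envelope" (per-node min/max of the
    null — maximally conservative).  ``refit=True`` re-estimates the rates on
    every reshuffled dataset (each null replicate gets its own ML fit);
    ``refit=False`` reuses the observed-data rates — faster, approximate.
    """
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    if rule not in ("percentile", "envelope"):
        raise ValueError(f"unknown rule {rule!r}")
    if isinstance(tip_states, np.ndarray):
        v = np.asarray(tip_states, dtype=int)
    else:
        v = np.array([int(tip_states[l]) for l in tree.tip_labels])
    if v.min() == v.max():
        raise ValueError("trait is monomorphic; classification undefined")
    rng = np.random.default_rng(seed)

    obs, obs_fit = _presence_probabilities(
        tree, v, fit=None, refit=True, state=state, seed=int(rng.integers(2**31))
    )
    n_internal = obs.size
    null = np.empty((n_shuffles, n_internal))
    for s in range(n_shuffles):
        shuffled = rng.permutation(v)
        null[s], _ = _presence_probabilities(
            tree, shuffled,
            fit=None if refit else obs_fit,
            refit=refit, state=state, seed=int(rng.integers(2**31)),
        )
    if rule == "percentile":
        tail = (100.0 - percentile) / 2.0
        lower = np.percentile(null, tail, axis=0)
        upper = np.percentile(null, 100.0 - tail, axis=0)
    else:
        lower = null.min(axis=0)
        upper = null.max(axis=0)

    ages = tree.node_ages()
    keys = tree.clade_keys()
    out: list[NodeClassification] = []
    for j, i in enumerate(tree.postorder_internal):
        if obs[j] > upper[j]:
            label = "present"
        elif obs[j] < lower[j]:
            label = "absent"
        else:
            label = "equivocal"
        out.append(NodeClassification(
            node=keys[i], age=float(ages[i]), observed=float(obs[j]),
            null_lower=float(lower[j]), null_upper=float(upper[j]), label=label,
        ))
    return out


@dataclass
class AgeComparison:
    """Welch t-test of present-node ages vs absent-node ages."""

    mean_present: float
    sem_present: float
    n_present: int
    mean_absent: float
    sem_absent: float
    n_absent: int
    t: float
    df: float
    p_value: float
    testable: bool

    def to_dict(self) -> dict:
        return {
            "mean_present": self.mean_present, "sem_present": self.sem_present,
            "n_present": self.n_present, "mean_absent": self.mean_absent,
            "sem_absent": self.sem_absent, "n_absent": self.n_absent,
            "t": self.t, "df": self.df, "p_value": self.p_value,
            "testable": self.testable,
        }


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else float("nan")


def compare_age_distributions(
    classifications: Sequence[NodeClassification] | tuple[np.ndarray, np.ndarray],
) -> AgeComparison:
    """Welch (unequal-variance) t-test on present vs absent node ages.

    Equivocal nodes are excluded.  A group with fewer than 2 nodes makes the
    comparison not-testable (reported, not raised).  Accepts either a list of
    classifications or a prebuilt (present_ages, absent_ages) pair.
    """
    if isinstance(classifications, tuple):
        present = np.asarray(classifications[0], dtype=float)
        absent = np.asarray(classifications[1], dtype=float)
    else:
        present = np.array([c.age for c in classifications if c.label == "present"])
        absent = np.array([c.age for c in classifications if c.label == "absent"])
    testable = present.size >= 2 and absent.size >= 2
    if testable:
        t, p = stats.ttest_ind(present, absent, equal_var=False)
        # Welch-Satterthwaite df
        v1, v2 = present.var(ddof=1) / present.size, absent.var(ddof=1) / absent.size
        if v1 + v2 > 0:
            df = (v1 + v2) ** 2 / (
                v1 ** 2 / (present.size - 1) + v2 ** 2 / (absent.size - 1)
            )
        else:
            t, p, df = 0.0, 1.0, float(present.size + absent.size - 2)
    else:
        t, p, df = float("nan"), float("nan"), float("nan")
    return AgeComparison(
        mean_present=float(present.mean()) if present.size else float("nan"),
        sem_present=_sem(present) if present.size else float("nan"),
        n_present=int(present.size),
        mean_absent=float(absent.mean()) if absent.size else float("nan"),
        sem_absent=_sem(absent) if absent.size else float("nan"),
        n_absent=int(absent.size),
        t=float(t), df=float(df), p_value=float(p), testable=testable,
    )
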