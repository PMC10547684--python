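"""Pagel-style correlated and directional evolution of two binary traits.

A pair of binary traits (X, Y) is recoded as one 4-state character
(0,0), (0,1), (1,0), (1,1); simultaneous changes of both traits have rate 0.
Four nested models constrain the eight single-change rates:

==================  ====================================================  ==
model               constraint                                            k
==================  ====================================================  ==
independent         each trait's gain/loss rate ignores the other trait    4
x_depends_on_y      X's rates differ by Y's state; Y's rates do not        6
y_depends_on_x      Y's rates differ by X's state; X's rates do not        6
interdependent      all eight rates free                                   8
==================  ====================================================  ==

Likelihood-ratio tests against the independent model ask whether there is
correlated evolution at all; Akaike weights across all four models ask which
dependency direction the data support.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .mk import MkFit, NoVariationError, aic, fit_mk, make_rate_matrix, mk_loglik
from .trees import Phylogeny

__all__ = [
    "PAGEL_MODELS",
    "PagelModelFit",
    "ModelComparison",
    "pair_states",
    "pagel_rate_matrix",
    "fit_pagel_model",
    "fit_all_pagel_models",
    "compare_models",
    "correlation_test",
]

# state order: index = 2*x + y
STATE_OF_PAIR = {(0, 0): 0, (0, 1): 1, (1, 0): 2, (1, 1): 3}
PAIR_OF_STATE = {v: k for k, v in STATE_OF_PAIR.items()}

# the eight single-change rates, in a fixed parameter order
RATE_NAMES = (
    "x_gain_y0",  # (0,0)->(1,0)
    "x_gain_y1",  # (0,1)->(1,1)
    "x_loss_y0",  # (1,0)->(0,0)
    "x_loss_y1",  # (1,1)->(0,1)
    "y_gain_x0",  # (0,0)->(0,1)
    "y_gain_x1",  # (1,0)->(1,1)
    "y_loss_x0",  # (0,1)->(0,0)
    "y_loss_x1",  # (1,1)->(1,0)
)

_TRANSITIONS = {
    "x_gain_y0": (0, 2),
    "x_gain_y1": (1, 3),
    "x_loss_y0": (2, 0),
    "x_loss_y1": (3, 1),
    "y_gain_x0": (0, 1),
    "y_gain_x1": (2, 3),
    "y_loss_x0": (1, 0),
    "y_loss_x1": (3, 2),
}

# free-parameter layout per model: list of tied groups (each group shares one
# free rate)
PAGEL_MODELS: dict[str, list[tuple[str, ...]]] = {
    "independent": [
        ("x_gain_y0", "x_gain_y1"),
        ("x_loss_y0", "x_loss_y1"),
        ("y_gain_x0", "y_gain_x1"),
        ("y_loss_x0", "y_loss_x1"),
    ],
    "x_depends_on_y": [
        ("x_gain_y0",), ("x_gain_y1",), ("x_loss_y0",), ("x_loss_y1",),
        ("y_gain_x0", "y_gain_x1"), ("y_loss_x0", "y_loss_x1"),
    ],
    "y_depends_on_x": [
        ("x_gain_y0", "x_gain_y1"), ("x_loss_y0", "x_loss_y1"),
        ("y_gain_x0",), ("y_gain_x1",), ("y_loss_x0",), ("y_loss_x1",),
    ],
    "interdependent": [(name,) for name in RATE_NAMES],
}


def pagel_rate_matrix(rates: Mapping[str, float] | Sequence[float]) -> np.ndarray:
    """4x4 generator from the eight named single-change rates."""
    if not isinstance(rates, Mapping):
        rates = dict(zip(RATE_NAMES, rates))
    off = np.zeros((4, 4))
    for name, (i, j) in _TRANSITIONS.items():
        off[i, j] = float(rates[name])
    return make_rate_matrix(off)


def pair_states(
    tree: Phylogeny,
    x_states: Mapping[str, object],
    y_states: Mapping[str, object],
) -> np.ndarray:
    """Tip partial matrix (n_tips, 4) for the joint character.

    A species missing one trait is ambiguous over that trait's axis.
    """
    tips = np.ones((tree.n_tips, 4))

    def known(m, label):
        v = m.get(label)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return int(v)

    for label, i in tree.tip_index.items():
        x = known(x_states, label)
        y = known(y_states, label)
        row = np.zeros(4)
        for s, (xs, ys) in PAIR_OF_STATE.items():
            if (x is None or xs == x) and (y is None or ys == y):
                row[s] = 1.0
        tips[i] = row
    return tips


def _check_polymorphic(states: Mapping[str, object], name: str) -> None:
    vals = {int(v) for v in states.values()
            if v is not None and not (isinstance(v, float) and np.isnan(v))}
    if len(vals) < 2:
        raise NoVariationError(f"trait {name} is monomorphic")


@dataclass
class PagelModelFit:
    """ML fit of one of the four dependency models."""

    model: str
    rates: dict[str, float]
    rate_matrix: np.ndarray
    log_likelihood: float
    n_free_params: int
    converged: bool
    tree_id: int | str | None = None

    @property
    def aic(self) -> float:
        return aic(self.log_likelihood, self.n_free_params)


def fit_pagel_model(
    tree: Phylogeny,
    x_states: Mapping[str, object],
    y_states: Mapping[str, object],
    model: str = "interdependent",
    root_prior="flat",
    *,
    n_restarts: int = 3,
    seed: int | None = None,
    tree_id=None,
    init_rates: Mapping[str, float] | None = None,
) -> PagelModelFit:
    if model not in PAGEL_MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {sorted(PAGEL_MODELS)}")
    _check_polymorphic(x_states, "x")
    _check_polymorphic(y_states, "y")
    groups = PAGEL_MODELS[model]
    n_par = len(groups)
    tips = pair_states(tree, x_states, y_states)

    def builder(free: np.ndarray) -> np.ndarray:
        rates = {}
        for g, val in zip(groups, free):
            for name in g:
                rates[name] = val
        return pagel_rate_matrix(rates)

    init = None
    if init_rates is not None:
        if isinstance(init_rates, Mapping):
            init_rates = [init_rates]
        # tied groups start from the mean of the rates they collapse
        init = [np.array([np.mean([ir[name] for name in g]) for g in groups])
                for ir in init_rates]
    fit = fit_mk(
        tree, tips, root_prior=root_prior, n_restarts=n_restarts, seed=seed,
        rate_builder=builder, n_free_params=n_par, n_states=4,
        init_params=init,
    )
    # recover named rates from the fitted generator
    rates = {name: float(fit.rate_matrix[i, j]) for name, (i, j) in _TRANSITIONS.items()}
    return PagelModelFit(
        model=model,
        rates=rates,
        rate_matrix=fit.rate_matrix,
        log_likelihood=fit.log_likelihood,
        n_free_params=n_par,
        converged=fit.converged,
        tree_id=tree_id,
    )


def fit_all_pagel_models(
    tree: Phylogeny,
    x_states,
    y_states,
    root_prior="flat",
    *,
    n_restarts: int = 3,
    seed: int | None = None,
    tree_id=None,
) -> dict[str, PagelModelFit]:
    rng = np.random.default_rng(seed)
    fits: dict[str, PagelModelFit] = {}
    # sandwich warm-starting: constrained -> full -> constrained again.  The
    # independent optimum seeds the full model; the full optimum (collapsed
    # onto each constraint pattern) seeds the directional models, which are
    # otherwise prone to local maxima on ridge-shaped likelihoods.  This also
    # keeps the nested likelihoods monotone.
    fits["independent"] = fit_pagel_model(
        tree, x_states, y_states, "independent", root_prior,
        n_restarts=n_restarts, seed=int(rng.integers(2**31)), tree_id=tree_id,
    )
    fits["interdependent"] = fit_pagel_model(
        tree, x_states, y_states, "interdependent", root_prior,
        n_restarts=n_restarts, seed=int(rng.integers(2**31)), tree_id=tree_id,
        init_rates=fits["independent"].rates,
    )
    for m in ("x_depends_on_y", "y_depends_on_x"):
        fits[m] = fit_pagel_model(
            tree, x_states, y_states, m, root_prior,
            n_restarts=n_restarts, seed=int(rng.integers(2**31)), tree_id=tree_id,
            init_rates=[fits["independent"].rates, fits["interdependent"].rates],
        )
    # if a directional model now beats the full model numerically, re-polish
    # the full model from that point
    best_dir = max(("x_depends_on_y", "y_depends_on_x"),
                   key=lambda m: fits[m].log_likelihood)
    if fits[best_dir].log_likelihood > fits["interdependent"].log_likelihood:
        fits["interdependent"] = fit_pagel_model(
            tree, x_states, y_states, "interdependent", root_prior,
            n_restarts=1, seed=int(rng.integers(2**31)), tree_id=tree_id,
            init_rates=fits[best_dir].rates,
        )
    return {m: fits[m] for m in PAGEL_MODELS}


def akaike_weights(aics: np.ndarray) -> np.ndarray:
    delta = aics - aics.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


@dataclass
class ModelComparison:
    """Across-ensemble summary of the four dependency models."""

    models: list[str]
    mean_loglik: dict[str, float]
    sem_loglik: dict[str, float]
    mean_aic: dict[str, float]
    sem_aic: dict[str, float]
    mean_weight: dict[str, float]
    sem_weight: dict[str, float]
    lrt: dict[str, float]          # 2*(lnL_alt - lnL_indep), ensemble mean
    lrt_df: dict[str, int]
    lrt_p: dict[str, float]        # chi2 tail at the mean LRT
    n_trees: int

    def best_model(self) -> str:
        return max(self.mean_weight, key=self.mean_weight.get)

    def to_frame(self):
        import pandas as pd

        rows = []
        for m in self.models:
            rows.append({
                "model": m,
                "mean_loglik": self.mean_loglik[m],
                "sem_loglik": self.sem_loglik[m],
                "mean_aic": self.mean_aic[m],
                "sem_aic": self.sem_aic[m],
                "lrt": self.lrt.get(m, np.nan),
                "lrt_df": self.lrt_df.get(m, 0),
                "lrt_p": self.lrt_p.get(m, np.nan),
                "mean_aic_weight": self.mean_weight[m],
                "sem_aic_weight": self.sem_weight[m],
            })
        return pd.DataFrame(rows)


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def compare_models(fits_per_tree: Sequence[Mapping[str, PagelModelFit]]) -> ModelComparison:
    """Summarise per-tree fits of all four models (Table-2-shaped output)."""
    if not fits_per_tree:
        raise ValueError("no fits supplied")
    models = list(PAGEL_MODELS)
    for fits in fits_per_tree:
        if set(fits) != set(models):
            raise ValueError("each tree needs all four model fits")
    ids = [
        {m: fits[m].tree_id for m in models} for fits in fits_per_tree
    ]
    for d in ids:
        if len({v if v is not None else id(d) for v in d.values()}) > 1:
            raise ValueError(f"mismatched tree ids within one entry: {d}")
    ll = {m: np.array([f[m].log_likelihood for f in fits_per_tree]) for m in models}
    aics = {m: np.array([f[m].aic for f in fits_per_tree]) for m in models}
    W = np.stack([akaike_weights(np.array([aics[m][i] for m in models]))
                  for i in range(len(fits_per_tree))])
    weights = {m: W[:, j] for j, m in enumerate(models)}
    k = {m: fits_per_tree[0][m].n_free_params for m in models}
    lrt, lrt_df, lrt_p = {}, {}, {}
    for m in models:
        if m == "independent":
            continue
        stat = float(np.mean(2.0 * (ll[m] - ll["independent"])))
        df = k[m] - k["independent"]
        lrt[m] = stat
        lrt_df[m] = df
        lrt_p[m] = float(chi2_dist.sf(max(stat, 0.0), df))
    return ModelComparison(
        models=models,
        mean_loglik={m: float(ll[m].mean()) for m in models},
        sem_loglik={m: _sem(ll[m]) for m in models},
        mean_aic={m: float(aics[m].mean()) for m in models},
        sem_aic={m: _sem(aics[m]) for m in models},
        mean_weight={m: float(weights[m].mean()) for m in models},
        sem_weight={m: _sem(weights[m]) for m in models},
        lrt=lrt,
        lrt_df=lrt_df,
        lrt_p=lrt_p,
        n_trees=len(fits_per_tree),
    )


@dataclass
class CorrelationTest:
    log_likelihood_uncorrelated: float
    log_likelihood_correlated: float
    chi2: float
    df: int
    p_value: float


def correlation_test(
    tree: Phylogeny,
    x_states,
    y_states,
    root_prior="flat",
    *,
    n_restarts: int = 3,
    seed: int | None = None,
) -> CorrelationTest:
    """LRT of correlated evolution: 4-rate independent vs 8-rate dependent."""
    rng = np.random.default_rng(seed)
    indep = fit_pagel_model(tree, x_states, y_states, "independent", root_prior,
                            n_restarts=n_restarts, seed=int(rng.integers(2**31)))
    dep = fit_pagel_model(tree, x_states, y_states, "interdependent", root_prior,
                          n_restarts=n_restarts, seed=int(rng.integers(2**31)),
                          init_rates=indep.rates)
    chi2 = max(0.0, 2.0 * (dep.log_likelihood - indep.log_likelihood))
    df = dep.n_free_params - indep.n_free_params
    return CorrelationTest(
        log_likelihood_uncorrelated=indep.log_likelihood,
        log_likelihood_correlated=dep.log_likelihood,
        chi2=chi2,
        df=df,
        p_value=float(chi2_dist.sf(chi2, df)),
    )
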