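"""Continuous-time Markov (Mk) models of discrete characters on trees.

Implements the Felsenstein pruning likelihood for k-state characters
(polytomies allowed; per-node rescaling against underflow), maximum-
likelihood rate fitting for equal-rates (ER), all-rates-different (ARD)
and arbitrarily constrained generators, marginal ancestral-state
reconstruction by an inside-outside pass, and across-tree z-tests of a
node's presence probability against the neutral value 0.5.

Rates are transitions per Myr on a dated tree.  The 2-state transition
probability matrix is computed in closed form; larger alphabets use the
eigendecomposition of the generator (with a scaling-and-squaring fallback
when the generator is defective).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import norm

from .trees import Phylogeny

__all__ = [
    "RateMatrix",
    "MkFit",
    "AncestralReconstruction",
    "NodeStateTest",
    "make_rate_matrix",
    "binary_rate_matrix",
    "mk_loglik",
    "fit_mk",
    "marginal_ancestral_states",
    "node_state_ztest",
    "aic",
]

RATE_LO, RATE_HI = 1e-8, 1e3  # per-Myr bounds; ARD likelihoods are ridge-prone
_LOG_ZERO = -np.inf


class NoVariationError(ValueError):
    """Raised when a trait is monomorphic across the observed tips."""


def make_rate_matrix(off_diagonal: np.ndarray) -> np.ndarray:
    """Assemble a CTMC generator from off-diagonal rates (diagonal = -row sum)."""
    Q = np.asarray(off_diagonal, dtype=float).copy()
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("rate matrix must be square")
    np.fill_diagonal(Q, 0.0)
    if np.any(Q < 0):
        raise ValueError("off-diagonal rates must be >= 0")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def binary_rate_matrix(q01: float, q10: float) -> np.ndarray:
    return make_rate_matrix(np.array([[0.0, q01], [q10, 0.0]]))


def validate_rate_matrix(Q: np.ndarray) -> np.ndarray:
    Q = np.asarray(Q, dtype=float)
    off = Q - np.diag(np.diag(Q))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be >= 0")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-8 * max(1.0, np.abs(Q).max())):
        raise ValueError("rate matrix rows must sum to 0")
    return Q


RateMatrix = np.ndarray  # alias; validated ndarray with zero row sums


# --------------------------------------------------------------------------
# transition probabilities
# --------------------------------------------------------------------------

def _transition_matrices_uniformization(
    Q: np.ndarray, times: np.ndarray, mu: float
) -> np.ndarray:
    """exp(Qt) by the uniformization series e^{-mu t} sum (mu t)^n/n! R^n.

    Every term is non-negative, so genuinely tiny probabilities (e.g. a
    double transition on a short branch) come out positive instead of being
    swamped by the ~1e-16 absolute error of an eigendecomposition.
    """
    k = Q.shape[0]
    R = np.eye(k) + Q / mu
    lam = mu * times
    lmax = float(lam.max())
    N = int(math.ceil(lmax + 10.0 * math.sqrt(lmax + 1.0) + 15.0))
    powers = np.empty((N + 1, k, k))
    powers[0] = np.eye(k)
    for n in range(1, N + 1):
        powers[n] = powers[n - 1] @ R
    W = np.empty((times.size, N + 1))
    W[:, 0] = np.exp(-lam)
    for n in range(1, N + 1):
        W[:, n] = W[:, n - 1] * lam / n
    P = np.einsum("bn,nij->bij", W, powers)
    return P


def _transition_matrices_eig(Q: np.ndarray, times: np.ndarray) -> np.ndarray:
    try:
        lam, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) > 1e8:
            raise np.linalg.LinAlgError("ill-conditioned eigenvectors")
        E = np.exp(np.multiply.outer(times, lam))  # (n, k)
        P = np.einsum("ij,nj,jl->nil", V, E, Vinv)
        P = np.real(P)
    except np.linalg.LinAlgError:
        uniq, inv = np.unique(times, return_inverse=True)
        Ps = np.stack([expm(Q * t) for t in uniq])
        P = Ps[inv]
    np.clip(P, 0.0, 1.0, out=P)
    return P


def transition_matrices(Q: np.ndarray, times: np.ndarray) -> np.ndarray:
    """P(t) = exp(Q t) for every t in ``times`` -> (len(times), k, k).

    2x2 uses the closed form (with expm1 against cancellation); otherwise
    uniformization on branches with moderate mu*t and eigendecomposition on
    the fast-mixing remainder, where small entries are no longer delicate.
    """
    times = np.asarray(times, dtype=float)
    k = Q.shape[0]
    if k == 2:
        a, b = Q[0, 1], Q[1, 0]
        s = a + b
        P = np.empty((times.size, 2, 2))
        if s <= 0:
            P[:] = np.eye(2)
            return P
        e = np.exp(-s * times)
        em1 = -np.expm1(-s * times)  # 1 - e, accurate for small s*t
        pi0, pi1 = b / s, a / s
        P[:, 0, 0] = pi0 + pi1 * e
        P[:, 0, 1] = pi1 * em1
        P[:, 1, 0] = pi0 * em1
        P[:, 1, 1] = pi1 + pi0 * e
        return P
    mu = float(np.max(-np.diag(Q)))
    if mu <= 0:
        return np.broadcast_to(np.eye(k), (times.size, k, k)).copy()
    P = np.empty((times.size, k, k))
    lam = mu * times
    small = lam <= 256.0
    if small.any():
        P[small] = _transition_matrices_uniformization(Q, times[small], mu)
    if (~small).any():
        P[~small] = _transition_matrices_eig(Q, times[~small])
    P /= P.sum(axis=2, keepdims=True)
    return P


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    return np.clip(pi, 0, None) / np.clip(pi, 0, None).sum()


def _resolve_root_prior(policy, Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    if policy is None or (isinstance(policy, str) and policy == "flat"):
        return np.full(k, 1.0 / k)
    if isinstance(policy, str) and policy == "stationary":
        return stationary_distribution(Q)
    p = np.asarray(policy, dtype=float)
    if p.shape != (k,) or p.min() < 0 or not math.isclose(p.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("root prior must be a probability vector of length k")
    return p


# --------------------------------------------------------------------------
# pruning likelihood
# --------------------------------------------------------------------------

def _pruning_partials(
    tree: Phylogeny, tips: np.ndarray, P: np.ndarray
) -> tuple[np.ndarray, float]:
    """Postorder partial likelihoods with per-node rescaling.

    Returns (partials (n_nodes, k), log scale factor).  ``P[i]`` is the
    transition matrix along the branch above node ``i``.
    """
    n, k = tree.n_nodes, tips.shape[1]
    nt = tree.n_tips
    L = np.empty((n, k))
    L[:nt] = tips
    # per-branch messages M[c] = P_c @ L_c; the tip block is vectorised, the
    # internal block is filled as the postorder sweep reaches each node
    M = np.empty((n, k))
    M[:nt] = np.einsum("nij,nj->ni", P[:nt], tips)
    log_scale = 0.0
    root = tree.root
    for i in tree.postorder_internal:
        kids = tree.children[i]
        if len(kids) == 2:
            acc = M[kids[0]] * M[kids[1]]
        else:
            acc = M[kids[0]].copy()
            for c in kids[1:]:
                acc *= M[c]
        m = acc.max()
        if m <= 0:
            return L, _LOG_ZERO
        # rescale at every node: partials can shrink by many orders per
        # level, and a product of two un-rescaled subtrees must not underflow
        if m != 1.0:
            acc = acc / m
            log_scale += math.log(m)
        L[i] = acc
        if i != root:
            M[i] = P[i] @ acc
    return L, log_scale


def mk_loglik(
    tree: Phylogeny,
    tip_states: Mapping[str, object] | np.ndarray,
    Q: np.ndarray,
    root_prior="flat",
) -> float:
    """Log-likelihood of the tip data under exp(Q t) along each branch.

    ``tip_states`` maps species to integer states; missing/None/NaN entries
    are treated as ambiguous (partial likelihood 1 for every state).  A tip
    configuration impossible under the model returns ``-inf`` rather than
    raising.
    """
    Q = validate_rate_matrix(Q)
    k = Q.shape[0]
    tips = tip_states if isinstance(tip_states, np.ndarray) else tree.states_array(tip_states, k)
    P = transition_matrices(Q, tree.blen)
    L, log_scale = _pruning_partials(tree, tips, P)
    if not np.isfinite(log_scale):
        return _LOG_ZERO
    prior = _resolve_root_prior(root_prior, Q)
    lik = float(prior @ L[tree.root])
    if lik <= 0:
        return _LOG_ZERO
    return math.log(lik) + log_scale


# fast path for binary characters: plain-float pruning, closed-form P; used
# heavily by the optimizer and the node-age reshuffling null
def _binary_loglik_fast(
    tree: Phylogeny, tips01: np.ndarray, q01: float, q10: float, prior: np.ndarray
) -> float:
    s = q01 + q10
    bl = tree.blen
    if s > 0:
        e = np.exp(-s * bl)
        pi0 = q10 / s
        pi1 = q01 / s
        P00 = pi0 + pi1 * e
        P01 = 1.0 - P00
        P11 = pi1 + pi0 * e
        P10 = 1.0 - P11
    else:
        P00 = P11 = np.ones_like(bl)
        P01 = P10 = np.zeros_like(bl)
    L0 = np.empty(tree.n_nodes)
    L1 = np.empty(tree.n_nodes)
    nt = tree.n_tips
    L0[:nt] = tips01[:, 0]
    L1[:nt] = tips01[:, 1]
    l0 = L0.tolist()
    l1 = L1.tolist()
    p00 = P00.tolist()
    p01 = P01.tolist()
    p10 = P10.tolist()
    p11 = P11.tolist()
    log_scale = 0.0
    children = tree.children
    for i in tree.postorder_internal:
        a0 = 1.0
        a1 = 1.0
        for c in children[i]:
            c0 = l0[c]
            c1 = l1[c]
            a0 *= p00[c] * c0 + p01[c] * c1
            a1 *= p10[c] * c0 + p11[c] * c1
        if a0 <= 0.0 and a1 <= 0.0:
            return _LOG_ZERO
        m = a0 if a0 > a1 else a1
        if m < 1e-140:
            a0 /= m
            a1 /= m
            log_scale += math.log(m)
        l0[i] = a0
        l1[i] = a1
    lik = prior[0] * l0[tree.root] + prior[1] * l1[tree.root]
    if lik <= 0.0:
        return _LOG_ZERO
    return math.log(lik) + log_scale


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class MkFit:
    """Maximum-likelihood fit of an Mk generator."""

    rate_matrix: np.ndarray
    root_prior: np.ndarray
    log_likelihood: float
    n_free_params: int
    converged: bool
    model: str
    n_restarts: int
    trace: list[float] = field(default_factory=list)  # best logLik per restart
    optimizer_message: str = ""

    @property
    def aic(self) -> float:
        return aic(self.log_likelihood, self.n_free_params)


def aic(log_likelihood: float, n_free_params: int) -> float:
    """Akaike information criterion, AIC = 2k - 2 lnL."""
    return 2.0 * n_free_params - 2.0 * log_likelihood


def _ard_mask(k: int) -> np.ndarray:
    m = np.ones((k, k), dtype=bool)
    np.fill_diagonal(m, False)
    return m


def fit_mk(
    tree: Phylogeny,
    tip_states: Mapping[str, object] | np.ndarray,
    model: str | np.ndarray = "ARD",
    root_prior="flat",
    *,
    n_restarts: int = 5,
    seed: int | None = None,
    rate_builder: Callable[[np.ndarray], np.ndarray] | None = None,
    n_free_params: int | None = None,
    n_states: int | None = None,
    init_params: Sequence[np.ndarray] | None = None,
    tol: float = 1e-8,
) -> MkFit:
    """Fit transition rates by maximum likelihood.

    ``model`` is ``"ER"`` (one rate), ``"ARD"`` (all off-diagonals free), or a
    boolean k x k mask of free off-diagonal entries (constrained model); a
    custom ``rate_builder`` mapping a parameter vector to a generator can be
    supplied instead (used by the Pagel models).  Optimization is bounded
    quasi-Newton on log-rates with random restarts.
    """
    if rate_builder is not None:
        if n_free_params is None or n_states is None:
            raise ValueError("rate_builder requires n_free_params and n_states")
        k = n_states
        n_par = n_free_params
        build = rate_builder
        model_name = "custom"
    else:
        if isinstance(tip_states, np.ndarray):
            k = tip_states.shape[1]
        else:
            observed = {int(v) for v in tip_states.values()
                        if v is not None and not (isinstance(v, float) and np.isnan(v))}
            k = max(observed) + 1 if observed else 2
            k = max(k, 2)
        if isinstance(model, str) and model.upper() == "ER":
            n_par = 1
            mask = None
            model_name = "ER"
        elif isinstance(model, str) and model.upper() == "ARD":
            mask = _ard_mask(k)
            n_par = int(mask.sum())
            model_name = "ARD"
        else:
            mask = np.asarray(model, dtype=bool)
            np.fill_diagonal(mask, False)
            n_par = int(mask.sum())
            model_name = "constrained"

        if model_name == "ER":
            def build(rates: np.ndarray) -> np.ndarray:
                off = np.full((k, k), rates[0])
                return make_rate_matrix(off)
        else:
            def build(rates: np.ndarray) -> np.ndarray:
                off = np.zeros((k, k))
                off[mask] = rates
                return make_rate_matrix(off)

    tips = tip_states if isinstance(tip_states, np.ndarray) else tree.states_array(tip_states, k)
    # variation check: a state column observed with certainty
    fixed = tips[(tips.sum(axis=1) == 1.0)]
    if fixed.shape[0] and np.unique(np.argmax(fixed, axis=1)).size < 2:
        raise NoVariationError("tip states are monomorphic; no variation to fit")

    use_fast = k == 2 and rate_builder is None and model_name in ("ER", "ARD")
    prior_fixed = None
    if not (isinstance(root_prior, str) and root_prior == "stationary"):
        prior_fixed = _resolve_root_prior(root_prior, np.zeros((k, k)))

    def nll(log_rates: np.ndarray) -> float:
        rates = np.exp(log_rates)
        if use_fast:
            q01 = rates[0]
            q10 = rates[0] if model_name == "ER" else rates[1]
            if prior_fixed is not None:
                prior = prior_fixed
            else:
                s = q01 + q10
                prior = np.array([q10 / s, q01 / s]) if s > 0 else np.array([0.5, 0.5])
            ll = _binary_loglik_fast(tree, tips, q01, q10, prior)
        else:
            Q = build(rates)
            prior = prior_fixed if prior_fixed is not None else stationary_distribution(Q)
            ll = mk_loglik(tree, tips, Q, prior)
        return 1e10 if not np.isfinite(ll) else -ll

    # scale heuristic: roughly (minimum changes) / total branch length
    total_bl = float(tree.blen.sum())
    base_rate = max(1.0 / max(total_bl, 1e-9), 1e-4)
    rng = np.random.default_rng(seed)
    bounds = [(math.log(RATE_LO), math.log(RATE_HI))] * n_par
    starts: list[np.ndarray] = []
    if init_params is not None:
        starts.extend(np.log(np.clip(np.asarray(p, dtype=float), RATE_LO, RATE_HI))
                      for p in init_params)
    starts.append(np.full(n_par, math.log(base_rate)))
    while len(starts) < max(1, n_restarts) + (len(init_params) if init_params else 0):
        starts.append(np.log(base_rate) + rng.normal(0.0, 1.5, size=n_par))
    best = None
    trace: list[float] = []
    for x0 in starts:
        x0 = np.clip(x0, bounds[0][0], bounds[0][1])
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": tol, "gtol": 1e-8, "maxiter": 500})
        trace.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    rates = np.exp(best.x)
    Q = build(rates)
    prior = prior_fixed if prior_fixed is not None else stationary_distribution(Q)
    ll = mk_loglik(tree, tips, Q, prior)
    # a fit is usable when the likelihood is finite; optimizer line-search
    # warnings at the rate bounds are recorded, not fatal
    converged = bool(np.isfinite(ll))
    message = "" if best.success else str(best.message)
    return MkFit(
        rate_matrix=Q,
        root_prior=prior,
        log_likelihood=float(ll),
        n_free_params=n_par,
        converged=converged,
        model=model_name,
        n_restarts=max(1, n_restarts),
        trace=trace,
        optimizer_message=message,
    )


# --------------------------------------------------------------------------
# marginal ancestral states
# --------------------------------------------------------------------------

@dataclass
class AncestralReconstruction:
    """Marginal state probabilities at every node of one tree."""

    tree: Phylogeny
    probabilities: np.ndarray  # (n_nodes, k); rows sum to 1
    tree_id: int | str | None = None

    def internal_probabilities(self) -> np.ndarray:
        return self.probabilities[self.tree.n_tips:]

    def by_clade(self, state: int = 1) -> dict[frozenset, float]:
        """Map descendant-tip set -> P(state) for every internal node."""
        keys = self.tree.clade_keys()
        return {
            keys[i]: float(self.probabilities[i, state])
            for i in self.tree.postorder_internal
        }

    def to_frame(self):
        import pandas as pd

        keys = self.tree.clade_keys()
        rows = []
        for i in self.tree.postorder_internal:
            row = {"node": "|".join(sorted(keys[i])), "tree_id": self.tree_id}
            for s in range(self.probabilities.shape[1]):
                row[f"p_state{s}"] = self.probabilities[i, s]
            rows.append(row)
        return pd.DataFrame(rows)


def marginal_ancestral_states(
    tree: Phylogeny,
    tip_states: Mapping[str, object] | np.ndarray,
    fit: MkFit | None = None,
    *,
    Q: np.ndarray | None = None,
    root_prior=None,
    tree_id=None,
) -> AncestralReconstruction:
    """Marginal (per-node) state probabilities by an inside-outside pass.

    Equivalent to the re-rooting method: the inside pass is the pruning
    recursion; the outside pass propagates the root prior and sibling
    contributions tipward, and the product of the two, renormalised, is the
    exact marginal at each node.
    """
    if fit is not None:
        Q = fit.rate_matrix
        prior = fit.root_prior if root_prior is None else _resolve_root_prior(root_prior, Q)
        if not fit.converged:
            raise ValueError("fit did not converge; refusing to reconstruct")
    else:
        if Q is None:
            raise ValueError("either fit or Q must be given")
        Q = validate_rate_matrix(Q)
        prior = _resolve_root_prior(root_prior, Q)
    k = Q.shape[0]
    tips = tip_states if isinstance(tip_states, np.ndarray) else tree.states_array(tip_states, k)
    P = transition_matrices(Q, tree.blen)
    L, log_scale = _pruning_partials(tree, tips, P)
    if not np.isfinite(log_scale) or prior @ L[tree.root] <= 0:
        raise ValueError("tip configuration impossible under the model")
    # outside pass (preorder); U[i] already includes the root prior
    U = np.empty_like(L)
    U[tree.root] = prior
    # cache per-child "message into parent": M[c] = P[c] @ L[c]
    M = np.empty_like(L)
    for i in range(tree.n_nodes - 1):
        M[i] = P[i] @ L[i]
    for i in range(tree.n_nodes - 1, -1, -1):  # preorder
        kids = tree.children[i]
        if not kids:
            continue
        for c in kids:
            sib = U[i].copy()
            for c2 in kids:
                if c2 != c:
                    sib = sib * M[c2]
            U[c] = sib @ P[c]
            m = U[c].max()
            if m > 0:
                U[c] /= m
    post = L * U
    Z = post.sum(axis=1, keepdims=True)
    if np.any(Z <= 0):
        raise ValueError("degenerate marginal normalisation")
    post /= Z
    return AncestralReconstruction(tree=tree, probabilities=post, tree_id=tree_id)


# --------------------------------------------------------------------------
# across-tree z-test of node state
# --------------------------------------------------------------------------

@dataclass
class NodeStateTest:
    """One-sided z-test of a node's mean presence probability against 0.5."""

    node: frozenset
    n_trees: int
    mean_probability: float
    sem: float
    z: float
    p_value: float
    verdict: str  # "present" | "absent" | "equivocal"


def node_state_ztest(
    reconstructions: Sequence[AncestralReconstruction],
    node: frozenset | Sequence[str],
    *,
    state: int = 1,
    null_value: float = 0.5,
    alpha: float = 0.05,
) -> NodeStateTest:
    """Test whether a node's presence probability differs from 0.5 across trees.

    The node is matched across trees by its descendant tip set; trees in which
    the clade does not occur are excluded.  Dispersion is the s.e.m. of the
    per-tree probabilities (the spread of a derived quantity across the tree
    ensemble, not independent sampling replicates).
    """
    key = frozenset(node)
    values = []
    for rec in reconstructions:
        table = rec.by_clade(state=state)
        if key in table:
            values.append(table[key])
    if len(values) < 2:
        raise ValueError(
            f"node matched in {len(values)} tree(s); need >= 2 for a dispersion estimate"
        )
    vals = np.asarray(values)
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size))
    if sem == 0.0:
        z = 0.0 if mean == null_value else math.copysign(math.inf, mean - null_value)
    else:
        z = (mean - null_value) / sem
    # one-sided p in the direction of the deviation
    if z > 0:
        p = float(norm.sf(z))
        verdict = "present" if p < alpha else "equivocal"
    elif z < 0:
        p = float(norm.cdf(z))
        verdict = "absent" if p < alpha else "equivocal"
    else:
        p = 0.5
        verdict = "equivocal"
    return NodeStateTest(
        node=key, n_trees=vals.size, mean_probability=mean, sem=sem,
        z=float(z), p_value=p, verdict=verdict,
    )
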