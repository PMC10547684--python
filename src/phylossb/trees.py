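"""Dated phylogenies and tree ensembles.

Trees are parsed and written with dendropy but held in a flat, indexed
representation (postorder node arrays) that the likelihood, signal and
simulation code iterates over directly.  Node indices are stable for the
lifetime of a :class:`Phylogeny`; across trees, internal nodes are matched
by their descendant-tip set (:meth:`Phylogeny.clade_key`).

Branch lengths are interpreted as time (Myr on a dated tree); node ages are
heights above the tips and require the tree to be ultrametric within a
tolerance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "TreeEnsemble",
    "read_tree_ensemble",
    "write_tree_ensemble",
]


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural invariant."""


class NotUltrametricError(TreeValidationError):
    """Raised when node ages are requested on a non-ultrametric tree."""


@dataclass
class SubstitutionReport:
    """Record of closest-relative substitutions made during pruning."""

    pairs: list[tuple[str, str]] = field(default_factory=list)  # (requested, substitute)
    missing: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # truthy if anything happened
        return bool(self.pairs or self.missing)


class Phylogeny:
    """A rooted tree with branch lengths, indexed in postorder.

    Attributes
    ----------
    n_nodes, n_tips : int
    parent : (n_nodes,) int array; parent[root] == -1
    children : list of int lists, per node
    blen : (n_nodes,) float array, branch length above each node (root: 0)
    tip_labels : list of str, in tip-index order (tip i is node i)
    """

    def __init__(self, tree: dendropy.Tree, *, validate: bool = True):
        tree = tree.clone(depth=1)
        tree.suppress_unifurcations()
        self._dendropy = tree
        self._build_index()
        if validate:
            self._validate()

    # ------------------------------------------------------------------ build

    def _build_index(self) -> None:
        nodes = list(self._dendropy.postorder_node_iter())
        # tips first (postorder already yields each tip before its ancestors,
        # but we renumber so that tips occupy indices 0..n_tips-1)
        tips = [nd for nd in nodes if nd.is_leaf()]
        internals = [nd for nd in nodes if not nd.is_leaf()]
        ordered = tips + internals
        index = {id(nd): i for i, nd in enumerate(ordered)}
        n = len(ordered)
        self.n_nodes = n
        self.n_tips = len(tips)
        self.parent = np.full(n, -1, dtype=np.int64)
        self.blen = np.zeros(n, dtype=float)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.tip_labels: list[str] = []
        for nd in ordered:
            i = index[id(nd)]
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.blen[i] = nd.edge.length if nd.edge.length is not None else 0.0
        for nd in tips:
            label = nd.taxon.label if nd.taxon is not None else (nd.label or "")
            self.tip_labels.append(label)
        self.tip_index: dict[str, int] = {lab: i for i, lab in enumerate(self.tip_labels)}
        # postorder over internal nodes only; internals are already in
        # postorder relative to one another, and all tips precede them
        self.postorder_internal = np.arange(self.n_tips, n, dtype=np.int64)
        self.root = int(n - 1)
        self._clade_keys: list[frozenset[str]] | None = None

    def _validate(self) -> None:
        if self.n_tips < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        if len(self.tip_index) != self.n_tips:
            seen: set[str] = set()
            dup = next(l for l in self.tip_labels if l in seen or seen.add(l))
            raise TreeValidationError(f"duplicate tip label: {dup!r}")
        if np.any(self.blen < 0):
            raise TreeValidationError("negative branch length")

    # ------------------------------------------------------------- constructors

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            raise ValueError(f"failed to parse newick: {exc}") from exc
        return cls(tree)

    def to_newick(self, *, precision: int = 12) -> str:
        s = self._dendropy.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=f".{precision}g",
        )
        return s.strip() + ("\n" if not s.endswith("\n") else "")

    # ----------------------------------------------------------------- queries

    def states_array(
        self, tip_states: Mapping[str, object], n_states: int, *,
        ambiguous: object = None,
    ) -> np.ndarray:
        """Tip partial-likelihood matrix (n_tips, n_states) from a species map.

        Missing species or values equal to ``ambiguous`` (also None/NaN) get a
        row of ones (uninformative).
        """
        out = np.ones((self.n_tips, n_states), dtype=float)
        for label, i in self.tip_index.items():
            if label not in tip_states:
                continue
            s = tip_states[label]
            if s is None or s == ambiguous or (isinstance(s, float) and np.isnan(s)):
                continue
            s = int(s)
            if not 0 <= s < n_states:
                raise ValueError(f"state {s} for tip {label!r} outside alphabet 0..{n_states-1}")
            out[i] = 0.0
            out[i, s] = 1.0
        return out

    def node_depths(self) -> np.ndarray:
        """Distance of every node from the root."""
        depth = np.zeros(self.n_nodes)
        for i in range(self.n_nodes - 2, -1, -1):  # preorder = reverse postorder
            depth[i] = depth[self.parent[i]] + self.blen[i]
        return depth

    def root_age(self) -> float:
        depth = self.node_depths()
        return float(depth[: self.n_tips].max())

    def node_ages(self, tolerance: float | None = None) -> np.ndarray:
        """Node heights above the tips (Myr); requires ultrametricity.

        ``tolerance`` defaults to 1e-6 x root age (published dated trees carry
        rounding error).  Raises :class:`NotUltrametricError` naming the two
        most discordant tips otherwise.
        """
        depth = self.node_depths()
        tip_depth = depth[: self.n_tips]
        t_max = float(tip_depth.max())
        if tolerance is None:
            tolerance = 1e-6 * t_max if t_max > 0 else 1e-12
        spread = t_max - float(tip_depth.min())
        if spread > tolerance:
            hi = int(np.argmax(tip_depth))
            lo = int(np.argmin(tip_depth))
            raise NotUltrametricError(
                f"tree not ultrametric within {tolerance:g}: root-to-tip depth differs by "
                f"{spread:g} between {self.tip_labels[hi]!r} and {self.tip_labels[lo]!r}"
            )
        ages = t_max - depth
        ages[: self.n_tips] = 0.0
        return ages

    def clade_keys(self) -> list[frozenset[str]]:
        """Per-node frozenset of descendant tip labels (tips: singleton)."""
        if self._clade_keys is None:
            keys: list[frozenset[str] | None] = [None] * self.n_nodes
            for i in range(self.n_tips):
                keys[i] = frozenset((self.tip_labels[i],))
            for i in self.postorder_internal:
                acc: set[str] = set()
                for c in self.children[i]:
                    acc |= keys[c]  # type: ignore[arg-type]
                keys[i] = frozenset(acc)
            self._clade_keys = keys  # type: ignore[assignment]
        return self._clade_keys  # type: ignore[return-value]

    def patristic_distances(self, labels: Sequence[str] | None = None) -> np.ndarray:
        """Pairwise tip-to-tip path-length matrix."""
        if labels is None:
            labels = self.tip_labels
        idx = [self.tip_index[l] for l in labels]
        n = len(idx)
        dist = np.zeros((n, n))
        # accumulate: for each node with branch, the branch separates the tips
        # below it from the rest: d_ij += blen for pairs split by the branch
        below = np.zeros((self.n_nodes, n), dtype=bool)
        for k, i in enumerate(idx):
            below[i, k] = True
        for i in self.postorder_internal:
            for c in self.children[i]:
                below[i] |= below[c]
        for i in range(self.n_nodes - 1):  # all non-root
            b = below[i]
            if b.any() and not b.all():
                dist[np.ix_(b, ~b)] += self.blen[i]
                dist[np.ix_(~b, b)] += self.blen[i]
        return dist

    # ----------------------------------------------------------------- pruning

    def prune_to_taxa(
        self,
        names: Iterable[str],
        *,
        substitute_closest_relative: bool = False,
        candidate_pool: Mapping[str, Sequence[str]] | None = None,
    ) -> tuple["Phylogeny", SubstitutionReport]:
        """Restrict the tree to ``names``.

        Degree-2 nodes are suppressed with branch lengths summed, so patristic
        distances between retained tips are preserved.  Missing species are
        either reported (default) or replaced by the closest relative: the tip
        minimising the mean patristic distance to the species' stated
        genus-mates (``candidate_pool``), ties broken alphabetically.
        """
        names = list(dict.fromkeys(names))
        if not names:
            raise ValueError("names must be non-empty")
        report = SubstitutionReport()
        present = [n for n in names if n in self.tip_index]
        missing = [n for n in names if n not in self.tip_index]
        keep = set(present)
        if missing and substitute_closest_relative:
            if candidate_pool is None:
                raise ValueError("substitution enabled but no candidate pool supplied")
            for sp in missing:
                mates = [m for m in candidate_pool.get(sp, ()) if m in self.tip_index]
                if not mates:
                    report.missing.append(sp)
                    continue
                cand = [l for l in self.tip_labels if l not in keep]
                if not cand:
                    report.missing.append(sp)
                    continue
                d = self.patristic_distances(cand + mates)
                k = len(cand)
                mean_d = d[:k, k:].mean(axis=1)
                best = min(
                    (float(mean_d[j]), cand[j]) for j in range(k)
                )[1]
                keep.add(best)
                report.pairs.append((sp, best))
        else:
            report.missing.extend(missing)
        if not keep:
            raise ValueError("none of the requested species are present in the tree")
        sub = self._dendropy.extract_tree_with_taxa_labels(labels=keep)
        sub.suppress_unifurcations()
        return Phylogeny(sub), report


class TreeEnsemble:
    """An ordered list of phylogenies sharing a tip-label universe."""

    def __init__(self, trees: Sequence[Phylogeny]):
        if not trees:
            raise ValueError("ensemble must contain at least one tree")
        self.trees = list(trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self.trees[i]

    def subsample(self, n: int) -> "TreeEnsemble":
        """First ``n`` trees (per-stage ensemble sizes differ by cost)."""
        if n < 1:
            raise ValueError("n must be >= 1")
        return TreeEnsemble(self.trees[: n])


def read_tree_ensemble(paths: str | Sequence[str], *, schema: str = "newick") -> TreeEnsemble:
    """Read one or more (possibly multi-tree) Newick/NEXUS files.

    NEXUS trees blocks are accepted read-only (``schema="nexus"``).
    """
    if isinstance(paths, (str, bytes)):
        paths = [paths]
    trees: list[Phylogeny] = []
    for path in paths:
        try:
            tl = dendropy.TreeList.get(
                path=str(path), schema=schema, preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"failed to parse {path}: {exc}") from exc
        for t in tl:
            trees.append(Phylogeny(t))
    if not trees:
        raise ValueError(f"no trees found in {paths}")
    return TreeEnsemble(trees)


def write_tree_ensemble(ensemble: TreeEnsemble | Sequence[Phylogeny], path: str) -> None:
    with io.open(path, "w", encoding="utf-8") as fh:
        for t in ensemble:
            fh.write(t.to_newick())
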