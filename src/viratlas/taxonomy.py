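"""Rooted ultrametric aggregate-protein-similarity (APS) trees and rank cutting.

Genomes are tips of an average-linkage (UPGMA) tree built from APS distances
``d = 1 - s``.  Because UPGMA trees are ultrametric and rooted by
construction, taxonomic ranks can be read off by cutting the tree at fixed
*root distances* (path length from the root): deep cuts yield fine clades
(genera), shallow cuts yield coarse ones (orders).  The default cut levels
are 0.250 / 0.125 / 0.04 / 0.025 for genus / subfamily / family / order,
which correspond to average amino-acid identity and coverage of roughly
70% / 50% / 28% / 22%.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "APSNode",
    "APSTree",
    "TaxonomyConfig",
    "upgma",
    "clade_root_distance",
    "cut_at",
    "assign_ranks",
    "APSTaxonomy",
]

RANKS = ("order", "family", "subfamily", "genus")
_RANK_PREFIX = {"order": "VOC", "family": "VFC", "subfamily": "VSF", "genus": "VGC"}

_ULTRAMETRIC_TOL = 1e-9


@dataclass
class APSNode:
    """A node of an ultrametric tree; ``height`` is measured from the tips."""

    name: str | None = None
    height: float = 0.0
    children: list["APSNode"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children

    def tips(self) -> list[str]:
        if self.is_tip:
            return [self.name]
        stack = [self]
        order: list[str] = []
        while stack:
            n = stack.pop()
            if n.is_tip:
                order.append(n.name)
            else:
                stack.extend(reversed(n.children))
        return order


class APSTree:
    """Rooted ultrametric tree with root-distance semantics.

    The root is at root distance 0; every tip sits at root distance equal to
    the tree height (within 1e-9 by construction).
    """

    def __init__(self, root: APSNode):
        self.root = root
        self.height = root.height
        spread = self._tip_height_spread()
        if spread > _ULTRAMETRIC_TOL:
            raise ValueError(f"tree is not ultrametric: tip spread {spread:g}")

    # -- basic structure ---------------------------------------------------
    def _tip_height_spread(self) -> float:
        depths = []

        def walk(node: APSNode, d: float) -> None:
            if node.is_tip:
                depths.append(d)
            for c in node.children:
                walk(c, d + (node.height - c.height))

        walk(self.root, 0.0)
        return max(depths) - min(depths) if depths else 0.0

    @property
    def tips(self) -> list[str]:
        return self.root.tips()

    def root_distance(self, node: APSNode) -> float:
        return self.height - node.height

    def mrca(self, tips: Iterable[str]) -> APSNode:
        wanted = set(tips)
        unknown = wanted - set(self.tips)
        if unknown:
            raise KeyError(f"unknown tips: {sorted(unknown)}")
        node = self.root
        while not node.is_tip:
            covering = [c for c in node.children if wanted <= set(c.tips())]
            if len(covering) != 1:
                break
            node = covering[0]
        return node

    # -- serialisation -----------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: APSNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_tip:
                return f"{node.name}:{bl:.6f}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6f}"

        if self.root.is_tip:
            return f"{self.root.name}:0.0;"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def upgma(dist: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> APSTree:
    """Average-linkage agglomeration into a rooted ultrametric tree.

    Node heights equal half the merge distance, so the root distance of a
    clade's ancestor is ``tree_height - merge_distance / 2``.  Ties are
    broken on the lexicographically lowest pair of cluster labels (a cluster
    is labelled by its smallest tip), making the tree independent of input
    order.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"g{i}" for i in range(D.shape[0])]
        labels = list(labels)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n == 0:
        raise ValueError("empty distance matrix")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")

    if n == 1:
        return APSTree(APSNode(name=labels[0], height=0.0))

    # active clusters: key -> (node, size, label=min tip)
    nodes = {i: APSNode(name=labels[i], height=0.0) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    tag = {i: labels[i] for i in range(n)}
    d = {frozenset((i, j)): D[i, j] for i, j in itertools.combinations(range(n), 2)}
    nxt = n

    while len(nodes) > 1:
        best = None
        for key, val in d.items():
            i, j = sorted(key, key=lambda k: tag[k])
            cand = (val, tag[i], tag[j])
            if best is None or cand < best[0]:
                best = (cand, i, j)
        (dij, _, _), i, j = best
        node = APSNode(height=dij / 2.0, children=[nodes[i], nodes[j]])
        nodes[nxt] = node
        sizes[nxt] = sizes[i] + sizes[j]
        tag[nxt] = min(tag[i], tag[j])
        for k in list(nodes):
            if k in (i, j, nxt):
                continue
            dik = d.pop(frozenset((i, k)))
            djk = d.pop(frozenset((j, k)))
            d[frozenset((nxt, k))] = (sizes[i] * dik + sizes[j] * djk) / (sizes[i] + sizes[j])
        d.pop(frozenset((i, j)))
        for k in (i, j):
            del nodes[k], sizes[k], tag[k]
        nxt += 1

    return APSTree(next(iter(nodes.values())))


def clade_root_distance(tree: APSTree, tips: Iterable[str]) -> float:
    """Root distance of the most recent common ancestor of ``tips``."""
    tips = list(tips)
    if not tips:
        raise ValueError("empty tip set")
    return tree.root_distance(tree.mrca(tips))


def cut_at(tree: APSTree, d: float) -> list[list[str]]:
    """Partition tips at root-distance level ``d``.

    Clusters are the maximal subtrees whose root node sits at root distance
    >= ``d`` while the parent sits below it (nodes exactly at ``d`` fall
    below the cut).  ``d = 0`` returns a single cluster; ``d`` beyond the
    tree height returns singletons.
    """
    if d < 0:
        raise ValueError("cut level must be non-negative")
    clusters: list[list[str]] = []
    eps = 1e-12  # nodes exactly at the cut level belong below it

    def walk(node: APSNode) -> None:
        if tree.root_distance(node) >= d - eps:
            clusters.append(node.tips())
        elif node.is_tip:  # d beyond the tip level
            clusters.append([node.name])
        else:
            for c in node.children:
                walk(c)

    walk(tree.root)
    return clusters


@dataclass
class TaxonomyConfig:
    """Per-rank cut distances, ordered order < family < subfamily < genus.

    ``aai_correspondence`` records the approximate average amino-acid
    identity/coverage each level corresponds to; it is documentation only
    and is never recomputed.
    """

    cuts: Mapping[str, float] = field(
        default_factory=lambda: {
            "genus": 0.250,
            "subfamily": 0.125,
            "family": 0.04,
            "order": 0.025,
        }
    )
    aai_correspondence: Mapping[str, float] = field(
        default_factory=lambda: {"genus": 70.0, "subfamily": 50.0, "family": 28.0, "order": 22.0}
    )

    def validate(self) -> None:
        c = self.cuts
        missing = set(RANKS) - set(c)
        if missing:
            raise ValueError(f"missing cut levels for ranks: {sorted(missing)}")
        if not (c["order"] < c["family"] < c["subfamily"] < c["genus"]):
            raise ValueError("cut distances must satisfy order < family < subfamily < genus")


def assign_ranks(
    tree: APSTree,
    config: TaxonomyConfig | None = None,
    reference_labels: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Cut the tree at every rank level and emit nested clade assignments.

    Returns a DataFrame indexed by genome with columns order/family/
    subfamily/genus holding candidate clade names (``VOC_001`` ...).  Clades
    in which labelled reference genomes hold a majority inherit the majority
    reference name.
    """
    config = config or TaxonomyConfig()
    config.validate()
    out = pd.DataFrame(index=pd.Index(tree.tips, name="genome"))
    for rank in RANKS:
        clusters = cut_at(tree, config.cuts[rank])
        clusters.sort(key=lambda c: min(c))
        col = {}
        for k, members in enumerate(clusters, start=1):
            name = f"{_RANK_PREFIX[rank]}_{k:03d}"
            if reference_labels:
                tagged = [reference_labels[m] for m in members if m in reference_labels]
                if tagged:
                    top, cnt = pd.Series(tagged).value_counts().pipe(lambda s: (s.index[0], s.iloc[0]))
                    if cnt * 2 > len(tagged):
                        name = top
            for m in members:
                col[m] = name
        out[rank] = out.index.map(col)
    return out


class APSTaxonomy(BaseEstimator):
    """Estimator wrapper: fit an APS distance matrix, expose rank labels.

    Parameters mirror :class:`TaxonomyConfig`.  After ``fit``, ``tree_``
    holds the UPGMA tree, ``assignment_`` the nested rank table and
    ``labels_`` the family-level labels in input order.
    """

    def __init__(self, genus_cut=0.250, subfamily_cut=0.125, family_cut=0.04, order_cut=0.025):
        self.genus_cut = genus_cut
        self.subfamily_cut = subfamily_cut
        self.family_cut = family_cut
        self.order_cut = order_cut

    def _config(self) -> TaxonomyConfig:
        return TaxonomyConfig(
            cuts={
                "genus": self.genus_cut,
                "subfamily": self.subfamily_cut,
                "family": self.family_cut,
                "order": self.order_cut,
            }
        )

    def fit(self, X, y=None, ids: Sequence[str] | None = None):
        if isinstance(X, pd.DataFrame):
            ids = list(X.index)
        elif ids is None:
            ids = [f"g{i}" for i in range(np.asarray(X).shape[0])]
        self.tree_ = upgma(np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X, ids)
        self.assignment_ = assign_ranks(self.tree_, self._config())
        self.labels_ = self.assignment_.loc[list(ids), "family"].to_numpy()
        return self

    def fit_predict(self, X, y=None, **kw):
        return self.fit(X, **kw).labels_
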