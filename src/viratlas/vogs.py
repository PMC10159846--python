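"""Viral orthologue gene clusters (VOGs) via Markov clustering (MCL).

Proteins are nodes of a weighted graph whose edges are the bitscores of
orthology-filtered hits.  MCL alternates expansion (matrix power) and
inflation (elementwise power followed by column renormalisation) on the
column-stochastic transition matrix until the flow stabilises; clusters are
read off the attractor structure, with overlapping clusters merged
transitively so the result is a strict partition.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin

__all__ = [
    "MarkovClustering",
    "mcl",
    "vogs_from_hits",
    "label_vogs",
    "integrase_vog_set",
    "INTEGRASE_KEYWORDS",
    "STRUCTURAL_KEYWORDS",
]

INTEGRASE_KEYWORDS = ("integrase", "serine recombinase")
STRUCTURAL_KEYWORDS = (
    "capsid",
    "portal",
    "tail",
    "baseplate",
    "spike",
    "head",
    "collar",
    "sheath",
    "neck",
)

_PRUNE = 1e-12
_ATTRACTOR_THRESHOLD = 1e-5


class MarkovClustering(BaseEstimator, ClusterMixin):
    """MCL on a non-negative affinity matrix.

    Parameters
    ----------
    inflation : float, default 2.0
        Elementwise power applied after each expansion; must be > 1.
    expansion : int, default 2
        Matrix power (random-walk step count) per iteration.
    max_iter, tol :
        Iteration stops when the largest entry change drops below ``tol``;
        hitting ``max_iter`` first sets ``converged_ = False`` and returns
        the current partition with a warning.
    add_self_loops : bool, default True
        Give every node a self-loop equal to its largest incident weight
        (1.0 for isolated nodes), the usual MCL regularisation.

    Attributes
    ----------
    labels_ : integer cluster label per node, deterministic for a fixed
        node order.
    converged_, n_iter_
    """

    def __init__(self, inflation: float = 2.0, expansion: int = 2,
                 max_iter: int = 100, tol: float = 1e-6, add_self_loops: bool = True):
        self.inflation = inflation
        self.expansion = expansion
        self.max_iter = max_iter
        self.tol = tol
        self.add_self_loops = add_self_loops

    def fit(self, X, y=None):
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.expansion < 2 or int(self.expansion) != self.expansion:
            raise ValueError("expansion must be an integer >= 2")
        A = np.asarray(X, dtype=float)
        n = A.shape[0]
        if A.shape != (n, n):
            raise ValueError("affinity matrix must be square")
        if np.any(A < 0):
            raise ValueError("edge weights must be non-negative")
        A = (A + A.T) / 2.0
        if self.add_self_loops:
            loops = A.max(axis=0)
            loops[loops <= 0] = 1.0
            np.fill_diagonal(A, loops)
        M = _normalize_columns(A)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            prev = M
            M = np.linalg.matrix_power(M, int(self.expansion))
            M = _normalize_columns(M ** self.inflation)
            M[M < _PRUNE] = 0.0
            M = _normalize_columns(M)
            if np.max(np.abs(M - prev)) < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(f"MCL did not converge within {self.max_iter} iterations")
        self.converged_ = converged
        self.n_iter_ = it
        self.matrix_ = M
        self.labels_ = _read_clusters(M)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _normalize_columns(M: np.ndarray) -> np.ndarray:
    sums = M.sum(axis=0)
    sums[sums == 0] = 1.0
    return M / sums


def _read_clusters(M: np.ndarray) -> np.ndarray:
    """Attractor-overlap interpretation: clusters from converged MCL flow."""
    n = M.shape[0]
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    attractors = np.where(M.max(axis=1) > _ATTRACTOR_THRESHOLD)[0]
    for a in attractors:
        members = np.where(M[a] > _ATTRACTOR_THRESHOLD)[0]
        for m in members:
            union(a, m)
    roots = [find(i) for i in range(n)]
    # relabel deterministically by first occurrence
    remap: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        labels[i] = remap.setdefault(r, len(remap))
    return labels


def mcl(
    graph: pd.DataFrame | np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> dict[str, int]:
    """Cluster a weighted graph; returns node -> cluster index.

    ``graph`` is a square affinity matrix (DataFrame index = node ids) or a
    numpy array (nodes named by position).
    """
    if isinstance(graph, pd.DataFrame):
        ids = list(graph.index)
        A = graph.to_numpy(dtype=float)
    else:
        A = np.asarray(graph, dtype=float)
        ids = list(range(A.shape[0]))
    est = MarkovClustering(inflation=inflation, expansion=expansion, max_iter=max_iter, tol=tol)
    labels = est.fit_predict(A)
    return dict(zip(ids, labels))


def vogs_from_hits(
    hits: pd.DataFrame,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> dict[str, str]:
    """Markov-cluster the orthology-filtered hit graph into VOG ids.

    Edge weight is the hit bitscore.  Node order is canonical (sorted ids)
    so the partition is invariant to input order; VOG ids are assigned by
    each cluster's lexicographically smallest member.
    """
    nodes = sorted(set(hits["query"]) | set(hits["subject"]))
    if not nodes:
        return {}
    idx = {p: i for i, p in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for q, s, b in zip(hits["query"], hits["subject"], hits["bitscore"]):
        i, j = idx[q], idx[s]
        A[i, j] = max(A[i, j], b)
        A[j, i] = A[i, j]
    part = mcl(pd.DataFrame(A, index=nodes, columns=nodes),
               inflation=inflation, expansion=expansion, max_iter=max_iter, tol=tol)
    clusters: dict[int, list[str]] = {}
    for p, c in part.items():
        clusters.setdefault(c, []).append(p)
    ordered = sorted(clusters.values(), key=min)
    out: dict[str, str] = {}
    for k, members in enumerate(ordered, start=1):
        for p in members:
            out[p] = f"VOG_{k:04d}"
    return out


def label_vogs(
    partition: Mapping[str, str] | Mapping[str, int],
    annotations: Mapping[str, str],
) -> pd.DataFrame:
    """Label each VOG by the majority annotation of its members.

    Returns a table (protein_id, vog_id, label, is_integrase,
    is_structural).  VOGs with no annotated member get an empty label and
    false flags; ties break to the lexicographically smallest label.
    """
    rows = []
    byvog: dict[str, list[str]] = {}
    for p, v in partition.items():
        byvog.setdefault(str(v), []).append(p)
    for vog_id in sorted(byvog):
        members = sorted(byvog[vog_id])
        tags = [annotations[p] for p in members if p in annotations and annotations[p]]
        if tags:
            counts = pd.Series(tags).value_counts()
            top = counts[counts == counts.max()].index.min()
        else:
            top = ""
        low = top.lower()
        is_int = any(k in low for k in INTEGRASE_KEYWORDS)
        is_struct = any(k in low for k in STRUCTURAL_KEYWORDS)
        for p in members:
            rows.append((p, vog_id, top, is_int, is_struct))
    return pd.DataFrame(rows, columns=["protein_id", "vog_id", "label", "is_integrase", "is_structural"])


def integrase_vog_set(
    vogs: pd.DataFrame,
    keywords: Sequence[str] = INTEGRASE_KEYWORDS,
) -> set[str]:
    """VOG ids whose label contains any keyword (case-insensitive substring).

    The default keyword list covers integrases and large serine
    recombinases, the two curated marker classes of a temperate lifestyle.
    """
    if not keywords:
        raise ValueError("keyword list must not be empty")
    kws = [k.lower() for k in keywords]
    sel = vogs["label"].str.lower().apply(lambda s: any(k in s for k in kws))
    return set(vogs.loc[sel, "vog_id"])
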