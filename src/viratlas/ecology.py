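"""Abundance estimation, neutral community model fitting and comparative statistics.

Read counts are redistributed (ambiguous reads proportionally to unique
ones), length-normalised into relative abundances and aggregated along the
viral taxonomy.  Clade prevalence is confronted with the Sloan neutral
community model: a clade of source mean relative abundance p is predicted
present in a local community of size N with probability
``1 - I_d(N m p, N m (1 - p))`` where ``I`` is the regularised incomplete
beta function, d = 1/N the one-read detection limit and m the migration
(immigration) probability estimated by least squares.  Residuals on
log10-prevalence measure each clade's departure from neutrality.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .taxonomy import APSTree

__all__ = [
    "redistribute",
    "rel_abundance",
    "aggregate",
    "taxon_stats",
    "NeutralCommunityModel",
    "ncm_fit",
    "unique_branch_fraction",
    "rank_sum_test",
    "phage_host_correlation",
]


def redistribute(
    unique_counts: Mapping[str, float] | pd.Series,
    ambiguity: Iterable[tuple[float, Sequence[str]]],
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[pd.Series, bool]:
    """Iteratively share ambiguous reads proportionally to current totals.

    ``ambiguity`` yields (read_count, candidate contigs) groups, each
    mapping to >= 2 contigs.  Totals start at the unique counts; each round
    splits every group across its candidates in proportion to the current
    totals (uniformly when all candidates are at zero) until the largest
    per-contig change drops below ``tol``.  Returns (totals, converged);
    total mass is conserved.
    """
    unique = pd.Series(dict(unique_counts), dtype=float)
    groups = [(float(c), list(members)) for c, members in ambiguity]
    for c, members in groups:
        if len(members) < 2:
            raise ValueError("every ambiguous read group must map to >= 2 contigs")
        for m in members:
            if m not in unique.index:
                unique[m] = 0.0
    totals = unique.copy()
    converged = not groups
    for _ in range(max_iter):
        new = unique.copy()
        for c, members in groups:
            w = totals[members].to_numpy()
            ws = w.sum()
            share = (w / ws) if ws > 0 else np.full(len(members), 1.0 / len(members))
            new[members] += c * share
        delta = float((new - totals).abs().max())
        totals = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("redistribution did not converge; returning current totals")
    return totals, converged


def rel_abundance(counts: pd.DataFrame, lengths: Mapping[str, float]) -> pd.DataFrame:
    """Depth- and length-normalised relative abundances, one row per sample.

    a_i = (c_i / L_i) / sum_j (c_j / L_j); all-zero samples stay zero.
    """
    lengths = pd.Series(dict(lengths), dtype=float).reindex(counts.columns)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise KeyError(f"missing lengths for: {missing}")
    if (lengths <= 0).any():
        raise ValueError("contig lengths must be positive")
    dens = counts.astype(float) / lengths
    row_sums = dens.sum(axis=1)
    ra = dens.div(row_sums.where(row_sums > 0, 1.0), axis=0)
    return ra


def aggregate(
    ra: pd.DataFrame,
    taxonomy: pd.DataFrame | Mapping[str, str],
    rank: str = "family",
) -> pd.DataFrame:
    """Sum member-vOTU abundances into clade abundances; row sums preserved.

    vOTUs absent from the taxonomy fall into an ``unassigned`` clade.
    """
    if isinstance(taxonomy, pd.DataFrame):
        if rank not in taxonomy.columns:
            raise ValueError(f"rank {rank!r} not in taxonomy columns")
        clade_of = taxonomy[rank].to_dict()
    else:
        clade_of = dict(taxonomy)
    groups = [clade_of.get(v, "unassigned") for v in ra.columns]
    return ra.T.groupby(pd.Index(groups, name=rank)).sum().T


def taxon_stats(
    ra_clades: pd.DataFrame,
    richness: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-clade mean relative abundance (zeros included), prevalence, richness."""
    mra = ra_clades.mean(axis=0)
    prevalence = (ra_clades > 0).mean(axis=0)
    out = pd.DataFrame({"mra": mra, "prevalence": prevalence})
    out.index.name = "clade"
    if richness is not None:
        out["richness"] = pd.Series(dict(richness)).reindex(out.index).fillna(0).astype(int)
    return out


class NeutralCommunityModel(BaseEstimator):
    """Sloan neutral community model fitted on (MRA, prevalence) pairs.

    Parameters
    ----------
    N : int
        Local community (read) size; the detection threshold is d = 1/N.
    n_samples : int or None
        Number of samples behind the observed prevalences; used to clamp
        prevalences to [1/n_samples, 1] before the log10 residual
        transform.

    Attributes
    ----------
    m_ : fitted migration probability in (0, 1)
    predicted_ : per-clade predicted prevalence
    residuals_ : log10(observed) - log10(predicted), clamped
    r2_ : goodness of fit on the prevalence scale
    boundary_ : True when the optimum pinned at the (0, 1) boundary
    """

    def __init__(self, N: int = 30000, n_samples: int | None = None):
        self.N = N
        self.n_samples = n_samples

    def _predict_prevalence(self, m: float, p: np.ndarray) -> np.ndarray:
        N = self.N
        d = 1.0 / N
        a = np.maximum(N * m * p, 1e-12)
        b = np.maximum(N * m * (1.0 - p), 1e-12)
        return 1.0 - special.betainc(a, b, d)

    def fit(self, mra, prevalence=None, y=None):
        if prevalence is None:
            prevalence = y
        p = np.asarray(mra, dtype=float)
        obs = np.asarray(prevalence, dtype=float)
        if self.N < 2:
            raise ValueError("community size N must be >= 2")
        mask = p > 0
        if mask.sum() < 5:
            raise ValueError("need at least 5 clades with positive abundance")
        if np.all(obs[mask] >= 1.0):
            warnings.warn("all prevalences are 1; migration estimate degenerate at boundary")

        def sse(m):
            return float(np.sum((obs[mask] - self._predict_prevalence(m, p[mask])) ** 2))

        res = optimize.minimize_scalar(sse, bounds=(1e-6, 1 - 1e-6), method="bounded")
        self.m_ = float(res.x)
        self.boundary_ = bool(self.m_ < 1e-4 or self.m_ > 1 - 1e-4)
        if self.boundary_:
            warnings.warn("fitted migration rate at parameter boundary")
        pred = np.full_like(p, np.nan)
        pred[mask] = self._predict_prevalence(self.m_, p[mask])
        self.predicted_ = pred
        floor = 1.0 / self.n_samples if self.n_samples else 1e-6
        obs_c = np.clip(obs, floor, 1.0)
        pred_c = np.clip(pred, floor, 1.0)
        self.residuals_ = np.log10(obs_c) - np.log10(pred_c)
        ss_tot = float(np.sum((obs[mask] - obs[mask].mean()) ** 2))
        self.r2_ = 1.0 - sse(self.m_) / ss_tot if ss_tot > 0 else float("nan")
        return self

    def predict(self, mra) -> np.ndarray:
        p = np.asarray(mra, dtype=float)
        return self._predict_prevalence(self.m_, p)


def ncm_fit(
    stats_table: pd.DataFrame,
    N: int,
    n_samples: int | None = None,
) -> tuple[NeutralCommunityModel, pd.DataFrame]:
    """Fit the neutral model on a taxon_stats table (columns mra, prevalence)."""
    model = NeutralCommunityModel(N=N, n_samples=n_samples)
    model.fit(stats_table["mra"].to_numpy(), stats_table["prevalence"].to_numpy())
    out = stats_table.copy()
    out["predicted_prevalence"] = model.predicted_
    out["ncm_residual"] = model.residuals_
    return model, out


def unique_branch_fraction(tree: APSTree, tips: Sequence[str]) -> float:
    """Pendant branch length as a fraction of a clade's induced subtree length.

    The induced subtree spans the tip set and its MRCA, with pass-through
    nodes collapsed.  Pendant (tip-leading) branches are the genetic
    material unique to single members; a star yields 1.0.  A single tip
    returns 1.0 by convention (flagged with a warning).
    """
    tips = list(tips)
    if not tips:
        raise ValueError("empty tip set")
    if len(tips) == 1:
        warnings.warn("unique branch fraction of a single tip is 1.0 by convention")
        return 1.0
    wanted = set(tips)
    mrca = tree.mrca(tips)

    pendant = 0.0
    total = 0.0

    def walk(node, height_above: float):
        # height_above: branch length accumulated through collapsed nodes
        nonlocal pendant, total
        if node.is_tip:
            if node.name in wanted:
                pendant += height_above
                total += height_above
            return
        live = [c for c in node.children if wanted & set(c.tips())]
        if len(live) == 1:
            c = live[0]
            walk(c, height_above + (node.height - c.height))
            return
        total += height_above
        for c in live:
            walk(c, node.height - c.height)

    for c in (mrca.children if not mrca.is_tip else []):
        if wanted & set(c.tips()):
            walk(c, mrca.height - c.height)
    return pendant / total if total > 0 else 1.0


def rank_sum_test(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p value.

    Exact enumeration when the smaller group has <= 8 values and there are
    no ties; normal approximation with tie correction otherwise.  Two
    identical constant groups give p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def phage_host_correlation(
    host_mra: Mapping[str, float] | pd.Series,
    phage_mra_by_host: Mapping[str, float] | pd.Series,
) -> tuple[float, float]:
    """Spearman correlation between host genus MRA and cognate phage MRA.

    Pairs on the shared host genera (>= 3 required); ties are mid-ranked.
    A constant vector leaves rho undefined (NaN, with a warning).
    """
    h = pd.Series(dict(host_mra), dtype=float)
    v = pd.Series(dict(phage_mra_by_host), dtype=float)
    shared = sorted(set(h.index) & set(v.index))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared host genera")
    x, y = h[shared].to_numpy(), v[shared].to_numpy()
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant abundance vector; Spearman rho undefined")
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
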