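"""Host prediction: CRISPR spacer matching, composition scoring, LCA merging.

Three predictors attach a bacterial lineage to a vOTU: spacers mined from
cohort MAGs, spacers from an external database, and a k-order Markov model
of host genome composition.  Discordant predictions are merged by taking
the last common ancestor of the two most closely matching predictions
(deepest pairwise LCA), an error-correction step for occasional
mispredictions by any single method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "HostLineage",
    "HostPrediction",
    "match_spacers",
    "predict_by_spacers",
    "MarkovHostClassifier",
    "train_markov",
    "score_markov",
    "lca_merge",
    "family_host_range",
    "LINEAGE_RANKS",
    "SOURCE_PRIORITY",
]

LINEAGE_RANKS = ("phylum", "order", "family", "genus", "species")
SOURCE_PRIORITY = ("mag_spacers", "spacer_db", "markov")

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class HostLineage:
    """Ranked bacterial lineage; any suffix of ranks may be absent.

    Assigned ranks must be contiguous (a genus implies its family and
    order); a missing phylum ahead of an assigned order is tolerated since
    nothing above order is implied by it.
    """

    phylum: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def __post_init__(self):
        vals = [getattr(self, r) for r in LINEAGE_RANKS]
        seen_gap = False
        started = False
        for v in vals:
            if v is None:
                if started:
                    seen_gap = True
            else:
                if seen_gap:
                    raise ValueError(f"lineage has an internal gap: {vals}")
                started = True

    @property
    def depth(self) -> int:
        return sum(getattr(self, r) is not None for r in LINEAGE_RANKS)

    @property
    def deepest_rank(self) -> str | None:
        for r in reversed(LINEAGE_RANKS):
            if getattr(self, r) is not None:
                return r
        return None

    def truncate(self, rank: str) -> "HostLineage":
        keep = LINEAGE_RANKS[: LINEAGE_RANKS.index(rank) + 1]
        return HostLineage(**{r: getattr(self, r) if r in keep else None for r in LINEAGE_RANKS})

    def lca(self, other: "HostLineage") -> "HostLineage":
        vals = {}
        for r in LINEAGE_RANKS:
            a, b = getattr(self, r), getattr(other, r)
            if a is None and b is None:
                vals[r] = None
            elif a == b:
                vals[r] = a
            else:
                for deeper in LINEAGE_RANKS[LINEAGE_RANKS.index(r):]:
                    vals[deeper] = None
                break
        return HostLineage(**{r: vals.get(r) for r in LINEAGE_RANKS})

    def to_string(self) -> str:
        return ";".join(getattr(self, r) or "" for r in LINEAGE_RANKS)

    @classmethod
    def from_string(cls, s: str) -> "HostLineage":
        parts = (s.split(";") + [""] * len(LINEAGE_RANKS))[: len(LINEAGE_RANKS)]
        return cls(**{r: (p or None) for r, p in zip(LINEAGE_RANKS, parts)})


@dataclass(frozen=True)
class HostPrediction:
    votu: str
    source: str
    lineage: HostLineage
    score: float = 0.0


# ---------------------------------------------------------------------------
# spacer matching


def match_spacers(
    spacers: Mapping[str, str],
    genomes: Mapping[str, str],
    max_mismatches: int = 2,
    min_length: int = 20,
) -> pd.DataFrame:
    """Ungapped occurrences of each spacer in each genome, both strands.

    Every placement with at most ``max_mismatches`` substitutions (no
    indels) is reported as (spacer, genome, pos, strand, mismatches).
    Candidate positions come from exact matches of pigeonhole chunks: a
    spacer split into ``max_mismatches + 1`` pieces must place at least one
    piece exactly.  Spacers shorter than ``min_length`` are skipped with a
    warning.
    """
    rows = []
    for gid, genome in genomes.items():
        g = genome.upper()
        for sid, spacer in spacers.items():
            s = spacer.upper()
            if len(s) < min_length:
                warnings.warn(f"spacer {sid!r} shorter than {min_length} nt; skipped")
                continue
            for strand, query in (("+", s), ("-", _revcomp(s))):
                for pos in _hamming_occurrences(query, g, max_mismatches):
                    mm = sum(a != b for a, b in zip(query, g[pos : pos + len(query)]))
                    rows.append((sid, gid, pos, strand, mm))
    return pd.DataFrame(rows, columns=["spacer", "genome", "pos", "strand", "mismatches"])


def _hamming_occurrences(query: str, text: str, k: int) -> list[int]:
    L = len(query)
    if L > len(text):
        return []
    nchunks = k + 1
    bounds = np.linspace(0, L, nchunks + 1).astype(int)
    candidates: set[int] = set()
    for c in range(nchunks):
        lo, hi = bounds[c], bounds[c + 1]
        chunk = query[lo:hi]
        start = text.find(chunk)
        while start != -1:
            p = start - lo
            if 0 <= p <= len(text) - L:
                candidates.add(p)
            start = text.find(chunk, start + 1)
    hits = []
    for p in sorted(candidates):
        window = text[p : p + L]
        mm = 0
        for a, b in zip(query, window):
            if a != b:
                mm += 1
                if mm > k:
                    break
        if mm <= k:
            hits.append(p)
    return hits


def predict_by_spacers(
    hits: pd.DataFrame,
    spacer_hosts: Mapping[str, HostLineage],
    source: str = "mag_spacers",
) -> dict[str, HostPrediction]:
    """Per-vOTU host call: deepest rank where a strict majority of spacers agree.

    A spacer counts once per vOTU no matter how many placements it has.
    The score is the number of supporting spacers; vOTUs whose spacers
    reach no majority at any rank get no prediction.
    """
    preds: dict[str, HostPrediction] = {}
    if hits.empty:
        return preds
    for votu, grp in hits.groupby("genome"):
        sids = sorted(set(grp["spacer"]) & set(spacer_hosts))
        if not sids:
            continue
        n = len(sids)
        lineages = [spacer_hosts[s] for s in sids]
        for rank in reversed(LINEAGE_RANKS):
            tallies: dict[str, int] = {}
            rep: dict[str, HostLineage] = {}
            for lin in lineages:
                if getattr(lin, rank) is None:
                    continue
                key = lin.truncate(rank).to_string()
                tallies[key] = tallies.get(key, 0) + 1
                rep[key] = lin.truncate(rank)
            if not tallies:
                continue
            top = sorted(tallies.items(), key=lambda kv: (-kv[1], kv[0]))[0]
            if top[1] * 2 > n:
                preds[votu] = HostPrediction(votu, source, rep[top[0]], float(top[1]))
                break
    return preds


# ---------------------------------------------------------------------------
# composition (k-order Markov) scoring

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for b, i in _BASE_IDX.items():
        out[arr == ord(b)] = i
    return out


@dataclass
class MarkovModel:
    """k-order nucleotide transition model with additive smoothing."""

    taxon: str
    k: int
    log_trans: np.ndarray  # (4**k, 4), rows sum to 1 in probability space

    def per_nt_loglik(self, seq: str) -> float:
        enc = _encode(seq)
        k = self.k
        if len(enc) < k + 1:
            raise ValueError("sequence shorter than model order + 1")
        valid = np.ones(len(enc) - k, dtype=bool)
        ctx = np.zeros(len(enc) - k, dtype=np.int64)
        for j in range(k):
            sl = enc[j : len(enc) - k + j]
            valid &= sl >= 0
            ctx = ctx * 4 + np.maximum(sl, 0)
        nxt = enc[k:]
        valid &= nxt >= 0
        if not valid.any():
            raise ValueError("no scoreable positions (non-ACGT sequence)")
        ll = self.log_trans[ctx[valid], nxt[valid]]
        return float(ll.mean())


class MarkovHostClassifier(BaseEstimator, ClassifierMixin):
    """Predict a phage's host taxon from genome composition.

    Fit on host genome sequences grouped by taxon; each taxon gets a
    k-order Markov model (default k=4) over nucleotide contexts with
    additive smoothing.  A phage is assigned the taxon whose model gives
    the highest mean log-likelihood per nucleotide; the decision score is
    the log-likelihood gap to the runner-up (0 for an exact tie, which
    breaks to the lexicographically smallest taxon).
    """

    def __init__(self, k: int = 4, pseudocount: float = 1.0):
        self.k = k
        self.pseudocount = pseudocount

    def fit(self, X: Iterable[str], y: Iterable[str]):
        k = int(self.k)
        if k < 0:
            raise ValueError("order k must be >= 0")
        grouped: dict[str, list[str]] = {}
        for seq, taxon in zip(list(X), list(y)):
            grouped.setdefault(str(taxon), []).append(str(seq))
        self.models_ = {}
        for taxon in sorted(grouped):
            counts = np.full((4 ** k, 4), float(self.pseudocount))
            for seq in grouped[taxon]:
                enc = _encode(seq)
                if len(enc) < k + 1:
                    continue
                valid = np.ones(len(enc) - k, dtype=bool)
                ctx = np.zeros(len(enc) - k, dtype=np.int64)
                for j in range(k):
                    sl = enc[j : len(enc) - k + j]
                    valid &= sl >= 0
                    ctx = ctx * 4 + np.maximum(sl, 0)
                nxt = enc[k:]
                valid &= nxt >= 0
                np.add.at(counts, (ctx[valid], nxt[valid]), 1.0)
            log_trans = np.log(counts) - np.log(counts.sum(axis=1, keepdims=True))
            self.models_[taxon] = MarkovModel(taxon, k, log_trans)
        self.classes_ = np.array(sorted(self.models_))
        return self

    def decision_table(self, X: Iterable[str]) -> pd.DataFrame:
        rows = []
        for seq in X:
            rows.append({t: m.per_nt_loglik(seq) for t, m in self.models_.items()})
        return pd.DataFrame(rows)

    def predict(self, X: Iterable[str]) -> np.ndarray:
        tab = self.decision_table(X)
        # ties break to the lexicographically smallest taxon (column order is sorted)
        return tab.idxmax(axis=1).to_numpy()

    def predict_with_gap(self, X: Iterable[str]) -> list[tuple[str, float]]:
        tab = self.decision_table(X)
        out = []
        for _, row in tab.iterrows():
            ordered = row.sort_values(ascending=False)
            gap = float(ordered.iloc[0] - ordered.iloc[1]) if len(ordered) > 1 else float("inf")
            best = row[row == row.max()].index.min()
            out.append((best, gap))
        return out


def train_markov(
    host_genomes: Mapping[str, Sequence[str] | str],
    k: int = 4,
    pseudocount: float = 1.0,
) -> MarkovHostClassifier:
    """Fit per-taxon composition models from host genomes grouped by taxon."""
    X, y = [], []
    for taxon, seqs in host_genomes.items():
        if isinstance(seqs, str):
            seqs = [seqs]
        for s in seqs:
            X.append(s)
            y.append(taxon)
    return MarkovHostClassifier(k=k, pseudocount=pseudocount).fit(X, y)


def score_markov(
    votu: str,
    sequence: str,
    clf: MarkovHostClassifier,
    taxon_lineages: Mapping[str, HostLineage],
    min_gap: float = 0.0,
) -> HostPrediction | None:
    """Best-scoring host taxon for one phage sequence, or None if unscoreable."""
    if len(sequence) < clf.k + 1:
        return None
    try:
        (best, gap), = clf.predict_with_gap([sequence])
    except ValueError:
        return None
    if gap < min_gap:
        return None
    return HostPrediction(votu, "markov", taxon_lineages[best], gap)


# ---------------------------------------------------------------------------
# merging and summaries


def lca_merge(
    preds: Sequence[HostPrediction],
    priority: Sequence[str] = SOURCE_PRIORITY,
) -> HostLineage | None:
    """Merge up to three predictions by the deepest pairwise LCA.

    A single prediction is returned unchanged.  With several, every
    unordered pair's LCA depth is computed and the deepest wins; depth ties
    prefer the pair with higher-priority sources.  If every pairwise LCA is
    at the root, the vOTU stays unassigned (None).
    """
    preds = list(preds)
    if not preds:
        raise ValueError("need at least one prediction")
    if len(preds) == 1:
        return preds[0].lineage
    rank_of = {s: i for i, s in enumerate(priority)}
    best: tuple | None = None
    for i in range(len(preds)):
        for j in range(i + 1, len(preds)):
            anc = preds[i].lineage.lca(preds[j].lineage)
            pr = tuple(sorted((rank_of.get(preds[i].source, len(priority)),
                               rank_of.get(preds[j].source, len(priority)))))
            cand = (-anc.depth, pr)
            if best is None or cand < best[0]:
                best = (cand, anc)
    anc = best[1]
    return anc if anc.depth > 0 else None


def family_host_range(
    family_of: Mapping[str, str],
    merged_hosts: Mapping[str, HostLineage | None],
) -> pd.DataFrame:
    """Distinct host species and genus counts per viral family.

    Counting is rank-specific: a genus-level lineage contributes to the
    genus count but not the species count.
    """
    rows: dict[str, dict[str, set]] = {}
    for votu, fam in family_of.items():
        d = rows.setdefault(fam, {"species": set(), "genus": set()})
        lin = merged_hosts.get(votu)
        if lin is None:
            continue
        if lin.species is not None:
            d["species"].add((lin.genus, lin.species))
        if lin.genus is not None:
            d["genus"].add(lin.genus)
    out = pd.DataFrame(
        [(f, len(d["species"]), len(d["genus"])) for f, d in sorted(rows.items())],
        columns=["family", "n_host_species", "n_host_genera"],
    )
    return out
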