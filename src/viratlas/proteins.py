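"""All-vs-all protein scoring, orthology filtering and APS similarity.

The aggregate protein similarity (APS) between two genomes is the summed
bitscore of their orthologous protein pairs, normalised by the mean of the
two genomes' total self-scores.  Orthologues are reciprocal best hits
between genomes.  Local alignment uses BLOSUM62 with affine gaps; raw
Smith-Waterman scores are converted to bits with the standard
Karlin-Altschul parameters for that scoring scheme.
"""

from __future__ import annotations

import itertools
import math
import warnings
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "all_vs_all",
    "orthology_filter",
    "aps_similarity",
    "self_score_totals",
    "default_genome_of",
]

# gapped Karlin-Altschul parameters for BLOSUM62, open 11 / extend 1
_KA_LAMBDA = 0.267
_KA_K = 0.041

HIT_COLUMNS = ["query", "subject", "bitscore", "qcov", "scov"]


def default_genome_of(protein_id: str) -> str:
    """Genome of a protein whose id follows the ``<genome>|<gene_index>`` convention."""
    return protein_id.rsplit("|", 1)[0]


def _make_aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _bits(raw_score: float) -> float:
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / math.log(2.0)


def all_vs_all(
    proteins: Mapping[str, str],
    score_floor: float = 50.0,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> pd.DataFrame:
    """Local-alignment bitscores for all ordered protein pairs above a floor.

    Returns a hit table with columns query/subject/bitscore/qcov/scov,
    including self-hits.  Scores are symmetric, so each unordered pair is
    aligned once and emitted in both directions.  Empty sequences are
    skipped with a warning.
    """
    if not proteins:
        raise ValueError("empty protein set")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    ids = sorted(proteins)
    seqs = {}
    for pid in ids:
        s = str(proteins[pid]).strip().upper()
        if not s:
            warnings.warn(f"skipping empty protein record {pid!r}")
            continue
        seqs[pid] = s
    rows = []

    def coverage(a: str, b: str) -> tuple[float, float]:
        aln = aligner.align(a, b)[0]
        qseg, sseg = aln.aligned
        qlen = sum(e - s for s, e in qseg)
        slen = sum(e - s for s, e in sseg)
        return qlen / len(a), slen / len(b)

    kept = [pid for pid in ids if pid in seqs]
    for i, q in enumerate(kept):
        for s in kept[i:]:
            raw = aligner.score(seqs[q], seqs[s])
            bits = _bits(raw)
            if bits < score_floor:
                continue
            qcov, scov = coverage(seqs[q], seqs[s])
            rows.append((q, s, bits, qcov, scov))
            if s != q:
                rows.append((s, q, bits, scov, qcov))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def orthology_filter(
    hits: pd.DataFrame,
    genome_of: Callable[[str], str] | Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Retain reciprocal best hits between genomes.

    For each genome pair (A, B), the hit (p in A, q in B) survives iff q is
    p's best-scoring protein in B and p is q's best in A.  Within-genome
    hits (including self-hits) are removed.  Ties on bitscore break to the
    lexicographically smallest subject id, so the result is independent of
    input order.
    """
    if hits.empty:
        return hits.iloc[0:0]
    gm = _genome_mapper(genome_of)
    h = hits.copy()
    h["qg"] = h["query"].map(gm)
    h["sg"] = h["subject"].map(gm)
    h = h[h["qg"] != h["sg"]]
    if h.empty:
        return hits.iloc[0:0]
    # best subject per (query, subject genome): highest bitscore, then lex id
    h = h.sort_values(["query", "sg", "bitscore", "subject"], ascending=[True, True, False, True])
    best = h.groupby(["query", "sg"], sort=False).first().reset_index()
    best_of = {(q, g): s for q, g, s in zip(best["query"], best["sg"], best["subject"])}
    keep = [
        best_of.get((row.query, row.sg)) == row.subject
        and best_of.get((row.subject, row.qg)) == row.query
        for row in h.itertuples()
    ]
    return h[keep][HIT_COLUMNS].reset_index(drop=True)


def _genome_mapper(genome_of) -> Callable[[str], str]:
    if genome_of is None:
        return default_genome_of
    if isinstance(genome_of, Mapping):
        return genome_of.__getitem__
    return genome_of


def self_score_totals(
    hits: pd.DataFrame,
    genome_of: Callable[[str], str] | Mapping[str, str] | None = None,
) -> pd.Series:
    """Per-genome summed self-hit bitscores from an unfiltered hit table."""
    gm = _genome_mapper(genome_of)
    selfs = hits[hits["query"] == hits["subject"]]
    totals = selfs.groupby(selfs["query"].map(gm))["bitscore"].sum()
    totals.index.name = "genome"
    return totals


def aps_similarity(
    hits: pd.DataFrame,
    self_scores: Mapping[str, float] | pd.Series,
    genomes: list[str] | None = None,
    genome_of: Callable[[str], str] | Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Aggregate protein similarity matrix from orthology-filtered hits.

    ``s(A, B)`` is the summed bitscore of retained A-B orthologue pairs
    divided by the mean of the two self-score totals, clamped to [0, 1].
    The diagonal is 1; a genome with zero proteins gets similarity 0 to all
    others (with a warning).
    """
    self_scores = pd.Series(dict(self_scores), dtype=float)
    if genomes is None:
        genomes = sorted(self_scores.index)
    genomes = list(genomes)
    empty = [g for g in genomes if self_scores.get(g, 0.0) <= 0.0]
    if empty:
        warnings.warn(f"genomes with no self-score (zero proteins): {empty}")
    n = len(genomes)
    S = np.eye(n)
    idx = {g: i for i, g in enumerate(genomes)}
    if not hits.empty:
        gm = _genome_mapper(genome_of)
        h = hits.copy()
        h["qg"] = h["query"].map(gm)
        h["sg"] = h["subject"].map(gm)
        # each orthologue pair appears in both directions with equal score:
        # halving the directed sum counts every pair once
        summed = h.groupby(["qg", "sg"])["bitscore"].sum()
        for (a, b), tot in summed.items():
            if a >= b or a not in idx or b not in idx:
                continue
            other = summed.get((b, a), 0.0)
            pair_sum = (tot + other) / 2.0
            denom = (self_scores.get(a, 0.0) + self_scores.get(b, 0.0)) / 2.0
            s = min(1.0, pair_sum / denom) if denom > 0 else 0.0
            i, j = idx[a], idx[b]
            S[i, j] = S[j, i] = s
    for g in empty:
        i = idx[g]
        S[i, :] = 0.0
        S[:, i] = 0.0
        S[i, i] = 1.0
    return pd.DataFrame(S, index=genomes, columns=genomes)
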