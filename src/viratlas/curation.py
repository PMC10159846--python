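"""Species de-replication, completeness bounds, family curation and decontamination.

vOTUs are 95%-ANI species representatives.  A family's completeness bound
comes from the size histogram of its members (5 kb bins): the bin edge just
before the right-most peak is the smallest size accepted as a complete or
near-complete genome.  Weak families (too few vOTUs or too few complete
ones) are dropped, and decontamination clusters are ranked by CRISPR
targeting times sample prevalence.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

__all__ = [
    "dereplicate_ani",
    "size_lower_bound",
    "flag_complete",
    "weak_family_filter",
    "decon_rank",
    "contamination_ratio",
]

_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _identity(short: str, long_: str) -> float:
    """Best-strand infix alignment identity of ``short`` against ``long_``."""
    best = 0.0
    for q in (short, _revcomp(short)):
        res = edlib.align(q, long_, mode="HW", task="distance")
        d = res["editDistance"]
        if d >= 0:
            best = max(best, 1.0 - d / len(short))
    return best


def dereplicate_ani(
    contigs: Mapping[str, str],
    ani: float = 0.95,
    af: float = 0.85,
    k: int = 15,
    prefilter: float = 0.05,
) -> tuple[list[str], dict[str, str]]:
    """Greedy longest-first clustering of contigs into ANI species.

    A contig joins the first existing representative against which its
    estimated identity over the aligned fraction of the shorter sequence
    meets the thresholds; otherwise it founds a new representative.  The
    identity estimate is an infix alignment of the shorter sequence (both
    strands), preceded by a k-mer containment prefilter; the infix mode
    aligns the whole shorter sequence, so the aligned fraction requirement
    is enforced structurally.

    Returns (representative ids in creation order, contig -> representative).
    """
    if not contigs:
        return [], {}
    del af  # aligned fraction == 1 under infix alignment of the shorter
    order = sorted(contigs, key=lambda c: (-len(contigs[c]), c))
    reps: list[str] = []
    rep_kmers: dict[str, set[str]] = {}
    membership: dict[str, str] = {}
    for cid in order:
        seq = contigs[cid].upper()
        kms = _kmer_set(seq, k) | _kmer_set(_revcomp(seq), k)
        home = None
        for rid in reps:
            if kms and len(kms & rep_kmers[rid]) / len(kms) < prefilter:
                continue
            if _identity(seq, contigs[rid].upper()) >= ani:
                home = rid
                break
        if home is None:
            reps.append(cid)
            rep_kmers[cid] = kms
            membership[cid] = cid
        else:
            membership[cid] = home
    return reps, membership


def size_lower_bound(sizes: Sequence[int], step: int = 5000) -> int:
    """Completeness bound from the right-most peak of a 5 kb size histogram.

    The histogram uses bins [k*step, (k+1)*step); the peak is the right-most
    non-empty bin whose count is >= both neighbours.  The returned bound is
    the left edge of the bin immediately preceding the peak (0 when the
    peak is the first bin).
    """
    sizes = list(sizes)
    if not sizes:
        raise ValueError("empty size list")
    if step <= 0:
        raise ValueError("step must be positive")
    kmax = max(int(s) // step for s in sizes)
    counts = np.zeros(kmax + 1, dtype=int)
    for s in sizes:
        counts[int(s) // step] += 1
    for kbin in range(kmax, -1, -1):
        c = counts[kbin]
        left = counts[kbin - 1] if kbin > 0 else 0
        right = counts[kbin + 1] if kbin < kmax else 0
        if c > 0 and c >= left and c >= right:
            return max(kbin - 1, 0) * step
    raise AssertionError("unreachable: non-empty histogram has a peak")


def flag_complete(
    lengths: Mapping[str, int],
    family_of: Mapping[str, str],
    bounds: Mapping[str, int],
) -> dict[str, bool | None]:
    """Complete iff length >= the family bound (inclusive); None if no bound."""
    flags: dict[str, bool | None] = {}
    for votu, length in lengths.items():
        fam = family_of.get(votu)
        if fam is None or fam not in bounds:
            flags[votu] = None
        else:
            flags[votu] = length >= bounds[fam]
    return flags


def weak_family_filter(
    members: pd.DataFrame,
    min_votus: int = 5,
    min_complete: int = 2,
) -> set[str]:
    """Families with >= ``min_votus`` members and >= ``min_complete`` complete ones.

    ``members`` needs columns ``family`` and boolean ``complete``.
    """
    kept = set()
    for fam, grp in members.groupby("family"):
        if len(grp) >= min_votus and int(grp["complete"].fillna(False).sum()) >= min_complete:
            kept.add(fam)
    return kept


def decon_rank(
    spacer_hits: Mapping[str, int],
    prevalence: Mapping[str, float],
) -> pd.DataFrame:
    """Rank decontamination clusters by distinct-spacer count x prevalence.

    Descending score, ties broken by cluster id; clusters missing from
    either input count as 0.
    """
    clusters = sorted(set(spacer_hits) | set(prevalence))
    rows = []
    for c in clusters:
        prev = float(prevalence.get(c, 0.0))
        if not 0.0 <= prev <= 1.0:
            raise ValueError(f"prevalence outside [0, 1] for cluster {c!r}")
        rows.append((c, int(spacer_hits.get(c, 0)), prev, spacer_hits.get(c, 0) * prev))
    out = pd.DataFrame(rows, columns=["cluster", "n_spacers", "prevalence", "score"])
    return out.sort_values(["score", "cluster"], ascending=[False, True]).reset_index(drop=True)


def contamination_ratio(
    virome_marker_cpm: Mapping[str, float] | float,
    metagenome_marker_cpm: Mapping[str, float] | float,
) -> tuple[dict[str, float], float]:
    """Per-marker virome/metagenome marker-gene rate ratios and their mean.

    Marker rates are bacterial marker-gene read rates (e.g. 16S rRNA,
    cpn60) in each fraction; the ratio estimates residual bacterial
    contamination of the virome.  A zero metagenome rate is undefined and
    yields NaN with a warning.
    """
    if not isinstance(virome_marker_cpm, Mapping):
        virome_marker_cpm = {"marker": float(virome_marker_cpm)}
    if not isinstance(metagenome_marker_cpm, Mapping):
        metagenome_marker_cpm = {m: float(metagenome_marker_cpm) for m in virome_marker_cpm}
    ratios: dict[str, float] = {}
    for marker, v in virome_marker_cpm.items():
        m = metagenome_marker_cpm.get(marker, 0.0)
        if m <= 0:
            warnings.warn(f"zero metagenome rate for marker {marker!r}; ratio undefined")
            ratios[marker] = float("nan")
        else:
            ratios[marker] = float(v) / float(m)
    finite = [r for r in ratios.values() if np.isfinite(r)]
    mean = float(np.mean(finite)) if finite else float("nan")
    return ratios, mean
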