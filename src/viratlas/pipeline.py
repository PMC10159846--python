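"""End-to-end cohort analysis: proteins -> tree -> taxonomy -> hosts -> ecology.

`analyze_cohort` runs the full resolution pipeline on an in-memory cohort
(synthetic or loaded from files) and returns every intermediate artifact;
`run_cohort` generates a synthetic cohort first.  The command-line
interface and the acceptance machinery are thin wrappers over these two
functions.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from . import curation, ecology, hosts, lifestyle, proteins, synthetic, taxonomy, vogs

__all__ = ["run_cohort", "analyze_cohort", "family_recovery_ari"]


def family_recovery_ari(assignment: pd.DataFrame, truth_taxonomy: pd.DataFrame,
                        rank: str = "family") -> float:
    """Adjusted Rand index between recovered and planted partitions at a rank."""
    shared = assignment.index.intersection(truth_taxonomy.index)
    return float(adjusted_rand_score(
        truth_taxonomy.loc[shared, rank], assignment.loc[shared, rank]))


def analyze_cohort(
    genomes: Mapping[str, str],
    proteomes: Mapping[str, list[tuple[str, str]]],
    annotations: Mapping[str, str],
    spacers: pd.DataFrame | None = None,
    host_genomes: Mapping[str, str] | None = None,
    host_taxonomy: synthetic.HostTaxonomy | None = None,
    counts: pd.DataFrame | None = None,
    ambiguity: pd.DataFrame | None = None,
    taxonomy_config: taxonomy.TaxonomyConfig | None = None,
    lifestyle_config: lifestyle.LifestyleConfig | None = None,
    markov_k: int = 4,
    max_mismatches: int = 2,
    score_floor: float = 30.0,
    inflation: float = 2.0,
) -> dict:
    """Run the full analysis and return a dict of artifacts.

    Stages: all-vs-all protein alignment, orthology filter, APS similarity,
    UPGMA tree, rank cutting, VOG clustering and labelling, per-family
    completeness bounds and weak-family filter, lifestyle calls, host
    prediction (two spacer sources + composition model) merged by LCA, and
    abundance/NCM ecology when counts are given.
    """
    protein_seqs = {gid: seq for genes in proteomes.values() for gid, seq in genes}
    genome_of = {gid: votu for votu, genes in proteomes.items() for gid, _ in genes}

    hits = proteins.all_vs_all(protein_seqs, score_floor=score_floor)
    self_scores = proteins.self_score_totals(hits, genome_of)
    filtered = proteins.orthology_filter(hits, genome_of)
    sim = proteins.aps_similarity(filtered, self_scores, genomes=sorted(genomes))
    dist = 1.0 - sim

    tree = taxonomy.upgma(dist)
    assignment = taxonomy.assign_ranks(tree, taxonomy_config)

    partition = vogs.vogs_from_hits(filtered, inflation=inflation)
    # proteins with no surviving orthologue hit become singleton VOGs
    for gid in protein_seqs:
        partition.setdefault(gid, f"VOG_s_{gid}")
    vog_table = vogs.label_vogs(partition, annotations)
    integrase_set = vogs.integrase_vog_set(vog_table)

    lengths = {v: len(s) for v, s in genomes.items()}
    fam_of = assignment["family"].to_dict()
    bounds = {
        fam: curation.size_lower_bound([lengths[v] for v in members])
        for fam, members in assignment.groupby("family").groups.items()
    }
    complete = curation.flag_complete(lengths, fam_of, bounds)

    votu_integrase = {
        v: lifestyle.votu_has_integrase((partition[gid] for gid, _ in genes), integrase_set)
        for v, genes in proteomes.items()
    }
    members = pd.DataFrame({
        "votu": list(genomes),
        "family": [fam_of[v] for v in genomes],
        "complete": [complete[v] for v in genomes],
        "integrase": [votu_integrase[v] for v in genomes],
    })
    lifestyle_calls = lifestyle.classify_families(members, lifestyle_config)
    retained_families = curation.weak_family_filter(members)

    out: dict = {
        "hits": hits,
        "filtered_hits": filtered,
        "similarity": sim,
        "tree": tree,
        "assignment": assignment,
        "vog_partition": partition,
        "vog_table": vog_table,
        "integrase_vogs": integrase_set,
        "bounds": bounds,
        "complete": complete,
        "members": members,
        "lifestyle": lifestyle_calls,
        "retained_families": retained_families,
    }

    if spacers is not None:
        spacer_seqs = dict(zip(spacers["spacer_id"], spacers["sequence"]))
        spacer_lineage = {
            r.spacer_id: hosts.HostLineage.from_string(r.host_lineage)
            for r in spacers.itertuples()
        }
        spacer_hits = hosts.match_spacers(spacer_seqs, genomes, max_mismatches=max_mismatches)
        preds: dict[str, list[hosts.HostPrediction]] = {v: [] for v in genomes}
        for source in ("mag_spacers", "spacer_db"):
            ids = set(spacers.loc[spacers["source"] == source, "spacer_id"])
            sub = spacer_hits[spacer_hits["spacer"].isin(ids)]
            for votu, pred in hosts.predict_by_spacers(sub, spacer_lineage, source).items():
                preds[votu].append(pred)
        if host_genomes and host_taxonomy is not None:
            grouped: dict[str, list[str]] = {}
            for sp, seq in host_genomes.items():
                genus = host_taxonomy.lineage_of_species(sp).genus
                grouped.setdefault(genus, []).append(seq)
            clf = hosts.train_markov(grouped, k=markov_k)
            lineages = {g: host_taxonomy.lineage_of_genus(g) for g in grouped}
            for votu, seq in genomes.items():
                pred = hosts.score_markov(votu, seq, clf, lineages)
                if pred is not None:
                    preds[votu].append(pred)
        merged = {
            v: (hosts.lca_merge(pl) if pl else None) for v, pl in preds.items()
        }
        out["host_predictions"] = preds
        out["spacer_hits"] = spacer_hits
        out["merged_hosts"] = merged
        out["host_range"] = hosts.family_host_range(fam_of, merged)

    if counts is not None:
        if ambiguity is not None and not ambiguity.empty:
            unique, groups = synthetic.split_unique(counts, ambiguity)
            totals = pd.DataFrame(
                {s: ecology.redistribute(unique.loc[s], groups[s])[0] for s in counts.index}
            ).T.reindex(columns=counts.columns)
        else:
            totals = counts.astype(float)
        ra = ecology.rel_abundance(totals, lengths)
        ra_family = ecology.aggregate(ra, assignment, "family")
        richness = assignment.groupby("family").size().to_dict()
        stats = ecology.taxon_stats(ra_family, richness)
        out["abundance_votu"] = ra
        out["abundance_family"] = ra_family
        out["taxon_stats"] = stats
    return out


def run_cohort(
    config: synthetic.SyntheticConfig | None = None,
    seed: int | None = None,
    n_spacers_per_votu: int = 4,
    decoy_count: int = 10,
    spacer_mismatch_rate: float = 0.0,
    with_counts: bool = True,
    **analysis_kwargs,
) -> dict:
    """Generate a synthetic cohort and analyse it; returns truth + artifacts."""
    config = config or synthetic.SyntheticConfig()
    if seed is not None:
        config.seed = seed
    genomes, proteomes, truth = synthetic.make_virome(config)
    spacers = synthetic.make_spacer_set(
        truth, n_per_target=n_spacers_per_votu, decoy_count=decoy_count,
        mismatch_rate=spacer_mismatch_rate, seed=config.seed + 1)
    counts = ambiguity = None
    if with_counts:
        counts, ambiguity = synthetic.make_count_matrix(truth, config)
    result = analyze_cohort(
        genomes, proteomes, truth.annotations,
        spacers=spacers, host_genomes=truth.host_genomes,
        host_taxonomy=truth.host_taxonomy,
        counts=counts, ambiguity=ambiguity, **analysis_kwargs)
    result["truth"] = truth
    result["config"] = config
    result["genomes"] = genomes
    result["proteomes"] = proteomes
    result["counts"] = counts
    result["ambiguity"] = ambiguity
    result["family_ari"] = family_recovery_ari(result["assignment"], truth.taxonomy)
    return result
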