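"""Ground-truthed synthetic virome cohort generator.

Emulates the statistical structure the downstream stages assume: phage
proteomes with rank-calibrated divergence (so planted genera / families /
orders separate at the default APS-tree cut distances), complete genomes
plus sub-complete fragments, integrase carriage tied to a planted family
lifestyle, CRISPR spacers cut from planted host-phage pairs plus decoys,
and sample x vOTU counts drawn from the neutral (Sloan) community model
with a configurable share of ambiguously mapped reads.

Every phage family is assigned a bacterial host genus; phage and host
nucleotide sequences are drawn from a genus-specific composition model so
that composition-based host prediction has signal to find.  Proteomes are
generated independently of the nucleotide sequences (genes are not
back-translated), which none of the downstream stages require.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .hosts import HostLineage, match_spacers

__all__ = [
    "NCMParams",
    "SyntheticConfig",
    "TruthTables",
    "HostTaxonomy",
    "make_host_taxonomy",
    "make_virome",
    "make_spacer_set",
    "make_count_matrix",
    "split_unique",
    "write_cohort",
]

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# host taxonomy


class HostTaxonomy:
    """Ranked order/family/genus/species lineage table forming a tree."""

    def __init__(self, table: pd.DataFrame):
        self.table = table.reset_index(drop=True)

    @property
    def genera(self) -> list[str]:
        return sorted(self.table["genus"].unique())

    @property
    def species(self) -> list[str]:
        return sorted(self.table["species"].unique())

    def lineage_of_species(self, species: str) -> HostLineage:
        row = self.table[self.table["species"] == species].iloc[0]
        return HostLineage(order=row["order"], family=row["family"],
                           genus=row["genus"], species=row["species"])

    def lineage_of_genus(self, genus: str) -> HostLineage:
        row = self.table[self.table["genus"] == genus].iloc[0]
        return HostLineage(order=row["order"], family=row["family"], genus=row["genus"])

    def species_in_genus(self, genus: str) -> list[str]:
        return sorted(self.table.loc[self.table["genus"] == genus, "species"])


def make_host_taxonomy(
    n_orders: int,
    genera_per_order: int,
    species_per_genus: int,
    seed: int = 0,
) -> HostTaxonomy:
    """Build a nested bacterial taxonomy (orders > families > genera > species).

    Genera are grouped pairwise into families within each order.  Naming is
    deterministic; the seed is accepted for interface symmetry with the
    other generators and reserved for future stochastic features.
    """
    del seed
    if min(n_orders, genera_per_order, species_per_genus) < 1:
        raise ValueError("all counts must be >= 1")
    rows = []
    for o in range(n_orders):
        order = f"HostOrder_{o + 1}"
        for g in range(genera_per_order):
            family = f"HostFamily_{o + 1}_{g // 2 + 1}"
            genus = f"HostGenus_{o + 1}_{g + 1}"
            for s in range(species_per_genus):
                rows.append((order, family, genus, f"{genus}_sp{s + 1}"))
    return HostTaxonomy(pd.DataFrame(rows, columns=["order", "family", "genus", "species"]))


# ---------------------------------------------------------------------------
# configuration and truth


@dataclass
class NCMParams:
    """Neutral-model sampling conditions for the count matrix."""

    N_reads: int = 30000
    m: float = 0.1
    n_samples: int = 40
    source_logmean: float = 0.0
    source_logsd: float = 1.0


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic cohort.

    ``rank_divergence`` holds the expected pairwise protein divergence
    (substitutions per site) between two genomes related at each rank; the
    levels must increase strictly with rank coarseness and are calibrated
    so that the planted ranks separate at the default taxonomy cut
    distances.
    """

    n_orders: int = 3
    families_per_order: int = 2
    genera_per_family: int = 3
    votus_per_genus: int = 5
    genome_size_mean_bp: float = 37500.0
    genome_size_sd_bp: float = 2000.0
    fragment_fraction: float = 0.25
    integrase_carriage_prob: Mapping[str, float] = field(
        default_factory=lambda: {"virulent": 0.0, "temperate": 0.9}
    )
    rank_divergence: Mapping[str, float] = field(
        default_factory=lambda: {"genus": 0.30, "family": 0.68, "order": 0.88}
    )
    n_order_core: int = 3
    n_family_core: int = 3
    n_genus_core: int = 6
    protein_length: int = 90
    host_genome_length: int = 20000
    ncm: NCMParams = field(default_factory=NCMParams)
    ambiguous_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in ("fragment_fraction", "ambiguous_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for v in self.integrase_carriage_prob.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("integrase carriage probabilities must lie in [0, 1]")
        if min(self.n_orders, self.families_per_order, self.genera_per_family,
               self.votus_per_genus) < 1:
            raise ValueError("taxon counts must be >= 1")
        rd = self.rank_divergence
        if not (0 < rd["genus"] < rd["family"] < rd["order"]):
            raise ValueError("rank divergence levels must increase strictly with rank coarseness")
        if not 0.0 < self.ncm.m < 1.0:
            raise ValueError("migration probability m must lie in (0, 1)")


@dataclass
class TruthTables:
    """Planted ground truth plus the sequence payload downstream generators need."""

    taxonomy: pd.DataFrame  # index votu: genus, family, order
    hosts: dict[str, HostLineage]
    votu_lifestyle: dict[str, str]
    family_lifestyle: dict[str, str]
    is_fragment: dict[str, bool]
    has_integrase: dict[str, bool]
    annotations: dict[str, str]  # gene id -> functional label
    lengths: dict[str, int]
    genomes: dict[str, str]
    host_genomes: dict[str, str]  # host species -> sequence
    host_taxonomy: HostTaxonomy
    spacers: pd.DataFrame | None = None
    source_abundance: pd.Series | None = None

    def votus(self) -> list[str]:
        return list(self.taxonomy.index)


# ---------------------------------------------------------------------------
# sequence helpers


def _rand_protein(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_AA, n)


def _mutate_protein(rng: np.random.Generator, seq: np.ndarray, q: float) -> np.ndarray:
    out = seq.copy()
    hit = np.where(rng.random(len(seq)) < q)[0]
    for i in hit:
        choices = _AA[_AA != out[i]]
        out[i] = rng.choice(choices)
    return out


def _markov_sequence(rng: np.random.Generator, trans: np.ndarray, length: int) -> str:
    """Order-1 nucleotide chain from a 4x4 transition matrix."""
    cum = np.cumsum(trans, axis=1)
    draws = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    state = int(rng.integers(4))
    for i in range(length):
        state = int(np.searchsorted(cum[state], draws[i]))
        out[i] = state
    return "".join(_NT[out])


# ---------------------------------------------------------------------------
# virome generation


def make_virome(
    config: SyntheticConfig,
    host_taxonomy: HostTaxonomy | None = None,
) -> tuple[dict[str, str], dict[str, list[tuple[str, str]]], TruthTables]:
    """Generate genomes, proteomes and truth tables for one cohort.

    Families alternate virulent/temperate; each family is bound to one host
    genus (round-robin over the host taxonomy).  Proteomes carry three
    conservation tiers — order-core proteins shared (diverged) across the
    order, family-core proteins shared across the family, and genus-core
    proteins private to each genus — with per-branch substitution rates
    derived from ``rank_divergence`` so aggregate similarity decays in
    calibrated steps across ranks.  Temperate genomes additionally carry a
    recognisable integrase gene with the configured probability.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if host_taxonomy is None:
        n_gen = max(2, -(-config.n_orders * config.families_per_order // 2))
        host_taxonomy = make_host_taxonomy(2, n_gen, 2, seed=config.seed)

    rd = config.rank_divergence
    q_votu = rd["genus"] / 2.0
    q_genus = (rd["family"] - rd["genus"]) / 2.0
    q_ocore = (rd["order"] - rd["family"]) / 2.0
    L = config.protein_length

    canonical_integrase = _rand_protein(rng, L)
    genera_pool = host_taxonomy.genera
    comp_models = {
        g: rng.dirichlet(np.full(4, 2.0), size=4) for g in sorted(genera_pool)
    }
    host_genomes = {
        sp: _markov_sequence(rng, comp_models[host_taxonomy.lineage_of_species(sp).genus],
                             config.host_genome_length)
        for sp in host_taxonomy.species
    }

    genomes: dict[str, str] = {}
    proteomes: dict[str, list[tuple[str, str]]] = {}
    tax_rows = []
    hosts: dict[str, HostLineage] = {}
    votu_lifestyle: dict[str, str] = {}
    family_lifestyle: dict[str, str] = {}
    is_fragment: dict[str, bool] = {}
    has_integrase: dict[str, bool] = {}
    annotations: dict[str, str] = {}
    lengths: dict[str, int] = {}

    fam_counter = 0
    struct_labels = {0: "major capsid protein", 1: "portal protein", 2: "terminase large subunit"}
    for o in range(config.n_orders):
        order_id = f"TO_{o + 1}"
        order_core = [_rand_protein(rng, L) for _ in range(config.n_order_core)]
        for f in range(config.families_per_order):
            fam_id = f"TF_{o + 1}_{f + 1}"
            lifestyle = "virulent" if fam_counter % 2 == 0 else "temperate"
            family_lifestyle[fam_id] = lifestyle
            host_genus = genera_pool[fam_counter % len(genera_pool)]
            host_species = host_taxonomy.species_in_genus(host_genus)
            fam_counter += 1

            fam_core = [_mutate_protein(rng, p, q_ocore) for p in order_core]
            fam_core += [_rand_protein(rng, L) for _ in range(config.n_family_core)]
            fam_integrase = _mutate_protein(rng, canonical_integrase, 0.6)
            carriage = config.integrase_carriage_prob.get(lifestyle, 0.0)
            fam_mean = config.genome_size_mean_bp
            fam_sd = config.genome_size_sd_bp

            for g in range(config.genera_per_family):
                genus_id = f"TG_{o + 1}_{f + 1}_{g + 1}"
                gen_core = [_mutate_protein(rng, p, q_genus) for p in fam_core]
                gen_core += [_rand_protein(rng, L) for _ in range(config.n_genus_core)]
                gen_integrase = _mutate_protein(rng, fam_integrase, q_genus)
                for v in range(config.votus_per_genus):
                    votu = f"vOTU_{o + 1}_{f + 1}_{g + 1}_{v + 1}"
                    tax_rows.append((votu, genus_id, fam_id, order_id))
                    sp = host_species[int(rng.integers(len(host_species)))]
                    hosts[votu] = host_taxonomy.lineage_of_species(sp)
                    votu_lifestyle[votu] = lifestyle

                    genes = [(f"{votu}|{i + 1}",
                              "".join(_mutate_protein(rng, p, q_votu)))
                             for i, p in enumerate(gen_core)]
                    carries = bool(rng.random() < carriage)
                    if carries:
                        seq = "".join(_mutate_protein(rng, gen_integrase, q_votu))
                        genes.append((f"{votu}|{len(genes) + 1}", seq))
                    has_integrase[votu] = carries
                    proteomes[votu] = genes
                    for i, (gid, _) in enumerate(genes):
                        if carries and i == len(genes) - 1:
                            annotations[gid] = "tyrosine integrase"
                        else:
                            annotations[gid] = struct_labels.get(
                                i - config.n_order_core, "hypothetical protein")

                    frag = bool(rng.random() < config.fragment_fraction)
                    is_fragment[votu] = frag
                    if frag:
                        glen = int(fam_mean * rng.uniform(0.25, 0.55))
                    else:
                        glen = int(np.clip(rng.normal(fam_mean, fam_sd),
                                           fam_mean - fam_sd, fam_mean + fam_sd))
                    genomes[votu] = _markov_sequence(rng, comp_models[host_genus], glen)
                    lengths[votu] = glen

    taxonomy = pd.DataFrame(tax_rows, columns=["votu", "genus", "family", "order"]).set_index("votu")
    truth = TruthTables(
        taxonomy=taxonomy,
        hosts=hosts,
        votu_lifestyle=votu_lifestyle,
        family_lifestyle=family_lifestyle,
        is_fragment=is_fragment,
        has_integrase=has_integrase,
        annotations=annotations,
        lengths=lengths,
        genomes=genomes,
        host_genomes=host_genomes,
        host_taxonomy=host_taxonomy,
    )
    return genomes, proteomes, truth


# ---------------------------------------------------------------------------
# spacers


def make_spacer_set(
    truth: TruthTables,
    n_per_target: int = 4,
    decoy_count: int = 10,
    mismatch_rate: float = 0.0,
    seed: int = 0,
    max_mismatches_checked: int = 2,
    max_retries: int = 20,
) -> pd.DataFrame:
    """Cut spacers from planted target genomes plus non-matching decoys.

    Each vOTU receives ``n_per_target`` spacers (25-45 nt substrings,
    either strand, mutated at ``mismatch_rate`` per site) annotated with
    the planted host lineage, alternating between the two spacer sources
    (cohort MAGs and the external database).  Decoys are random sequences
    verified not to match any genome at <= ``max_mismatches_checked``
    mismatches; their host annotation is a random lineage.
    """
    rng = np.random.default_rng(seed)
    rows = []
    comp = str.maketrans("ACGT", "TGCA")
    for votu in truth.votus():
        genome = truth.genomes[votu]
        for i in range(n_per_target):
            slen = int(rng.integers(25, 46))
            pos = int(rng.integers(0, max(1, len(genome) - slen)))
            seq = genome[pos : pos + slen]
            if rng.random() < 0.5:
                seq = seq.translate(comp)[::-1]
            seq = list(seq)
            for j in range(len(seq)):
                if rng.random() < mismatch_rate:
                    seq[j] = str(rng.choice(_NT[_NT != seq[j]]))
            source = "mag_spacers" if i % 2 == 0 else "spacer_db"
            rows.append((f"sp_{votu}_{i + 1}", "".join(seq), source,
                         truth.hosts[votu].to_string(), votu, False))
    lineages = [truth.hosts[v] for v in truth.votus()]
    for d in range(decoy_count):
        for attempt in range(max_retries):
            slen = int(rng.integers(25, 46))
            seq = "".join(rng.choice(_NT, slen))
            hits = match_spacers({"d": seq}, truth.genomes,
                                 max_mismatches=max_mismatches_checked)
            if hits.empty:
                break
        else:
            raise RuntimeError("could not draw a non-matching decoy spacer")
        lin = lineages[int(rng.integers(len(lineages)))]
        source = "mag_spacers" if d % 2 == 0 else "spacer_db"
        rows.append((f"decoy_{d + 1}", seq, source, lin.to_string(), "", True))
    spacers = pd.DataFrame(
        rows, columns=["spacer_id", "sequence", "source", "host_lineage", "target_votu", "is_decoy"]
    )
    truth.spacers = spacers
    return spacers


# ---------------------------------------------------------------------------
# counts


def make_count_matrix(
    truth: TruthTables,
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x vOTU counts from the neutral model, plus an ambiguity table.

    Source relative abundances p_i are lognormal, normalised.  Each
    sample's community composition is drawn from the neutral stationary
    distribution Dirichlet(N m p) and its reads multinomially — the finite
    local community whose marginal occupancies follow the Sloan
    Beta(N m p_i, N m (1 - p_i)) curve.  ``ambiguous_fraction`` of each
    vOTU's reads are flagged as multi-mapping to the vOTU's planted genus
    siblings.
    """
    config.validate()
    ncm = config.ncm
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    votus = truth.votus()
    S = len(votus)
    p = rng.lognormal(ncm.source_logmean, ncm.source_logsd, S)
    p /= p.sum()
    truth.source_abundance = pd.Series(p, index=votus, name="p")

    alpha = ncm.N_reads * ncm.m * p
    f = rng.gamma(np.broadcast_to(alpha, (ncm.n_samples, S)))
    f = f / f.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(ncm.N_reads, fi) for fi in f])
    samples = [f"sample_{i + 1}" for i in range(ncm.n_samples)]
    counts_df = pd.DataFrame(counts, index=samples, columns=votus)

    amb_rows = []
    if config.ambiguous_fraction > 0:
        sib = {
            v: sorted(truth.taxonomy.index[truth.taxonomy["genus"] == truth.taxonomy.loc[v, "genus"]])
            for v in votus
        }
        for sample in samples:
            for v in votus:
                c = int(counts_df.loc[sample, v])
                group = sib[v]
                if c == 0 or len(group) < 2:
                    continue
                namb = int(np.floor(c * config.ambiguous_fraction))
                if namb > 0:
                    amb_rows.append((sample, v, ";".join(group), namb))
    ambiguity = pd.DataFrame(amb_rows, columns=["sample", "source_votu", "members", "count"])
    return counts_df, ambiguity


def split_unique(counts: pd.DataFrame, ambiguity: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Separate counts into unique counts and per-sample ambiguous read groups.

    Returns (unique counts, {sample: [(count, members), ...]}) suitable for
    :func:`viratlas.ecology.redistribute`; unique + ambiguous mass equals
    the input counts.
    """
    unique = counts.astype(float).copy()
    groups: dict[str, list[tuple[float, list[str]]]] = {s: [] for s in counts.index}
    for row in ambiguity.itertuples(index=False):
        unique.loc[row.sample, row.source_votu] -= row.count
        groups[row.sample].append((float(row.count), row.members.split(";")))
    if (unique.to_numpy() < -1e-9).any():
        raise ValueError("ambiguity table removes more reads than counted")
    return unique, groups


# ---------------------------------------------------------------------------
# writers


def write_cohort(
    outdir,
    genomes: dict[str, str],
    proteomes: dict[str, list[tuple[str, str]]],
    truth: TruthTables,
    counts: pd.DataFrame | None = None,
    ambiguity: pd.DataFrame | None = None,
    config: SyntheticConfig | None = None,
) -> None:
    """Write the cohort as FASTA/TSV/YAML files under ``outdir``."""
    import yaml
    from pathlib import Path

    out = Path(outdir)
    (out / "truth").mkdir(parents=True, exist_ok=True)
    _write_fasta(out / "genomes.fna", genomes.items())
    _write_fasta(out / "proteins.faa",
                 ((gid, seq) for genes in proteomes.values() for gid, seq in genes))
    _write_fasta(out / "host_genomes.fna", truth.host_genomes.items())
    truth.taxonomy.to_csv(out / "truth" / "taxonomy.tsv", sep="\t")
    pd.Series({v: l.to_string() for v, l in truth.hosts.items()}, name="lineage") \
        .rename_axis("votu").to_csv(out / "truth" / "hosts.tsv", sep="\t")
    pd.DataFrame({
        "votu": truth.votus(),
        "lifestyle": [truth.votu_lifestyle[v] for v in truth.votus()],
        "is_fragment": [truth.is_fragment[v] for v in truth.votus()],
        "has_integrase": [truth.has_integrase[v] for v in truth.votus()],
        "length": [truth.lengths[v] for v in truth.votus()],
    }).to_csv(out / "truth" / "votus.tsv", sep="\t", index=False)
    truth.host_taxonomy.table.to_csv(out / "truth" / "host_taxonomy.tsv", sep="\t", index=False)
    pd.Series(truth.annotations, name="label").rename_axis("gene") \
        .to_csv(out / "truth" / "annotations.tsv", sep="\t")
    if truth.spacers is not None:
        _write_fasta(out / "spacers.fna",
                     zip(truth.spacers["spacer_id"], truth.spacers["sequence"]))
        truth.spacers.drop(columns=["sequence"]).to_csv(
            out / "spacer_hosts.tsv", sep="\t", index=False)
    if counts is not None:
        counts.rename_axis("sample").to_csv(out / "counts.tsv", sep="\t")
    if ambiguity is not None:
        ambiguity.to_csv(out / "ambiguity.tsv", sep="\t", index=False)
    if config is not None:
        cfg = asdict(config)
        cfg["integrase_carriage_prob"] = dict(config.integrase_carriage_prob)
        cfg["rank_divergence"] = dict(config.rank_divergence)
        with open(out / "config.yaml", "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def _write_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")
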