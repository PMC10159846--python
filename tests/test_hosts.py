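"""Spacer matching, composition-based host scoring and LCA merging."""

import numpy as np
import pytest

from viratlas import hosts
from viratlas.hosts import HostLineage, HostPrediction


def lin(**kw):
    return HostLineage(**kw)


B_FRAGILIS = lin(phylum="Bacteroidota", order="Bacteroidales", family="Bacteroidaceae",
                 genus="Bacteroides", species="fragilis")
B_DOREI = lin(phylum="Bacteroidota", order="Bacteroidales", family="Bacteroidaceae",
              genus="Bacteroides", species="dorei")
PREVOTELLA = lin(phylum="Bacteroidota", order="Bacteroidales", family="Prevotellaceae",
                 genus="Prevotella")
BLAUTIA = lin(phylum="Bacillota", order="Eubacteriales", family="Lachnospiraceae",
              genus="Blautia")


class TestHostLineage:
    def test_internal_gap_rejected(self):
        with pytest.raises(ValueError):
            lin(order="Bacteroidales", genus="Bacteroides")  # family missing

    def test_depth_and_truncate(self):
        assert B_FRAGILIS.depth == 5
        assert PREVOTELLA.depth == 4
        t = B_FRAGILIS.truncate("genus")
        assert t.species is None and t.genus == "Bacteroides"

    def test_lca_same_genus_different_species(self):
        anc = B_FRAGILIS.lca(B_DOREI)
        assert anc.genus == "Bacteroides" and anc.species is None

    def test_lca_disjoint_is_empty(self):
        assert B_FRAGILIS.lca(BLAUTIA).depth == 0

    def test_string_roundtrip(self):
        assert HostLineage.from_string(B_FRAGILIS.to_string()) == B_FRAGILIS


class TestMatchSpacers:
    GENOME = "ATGCGTACGTTAGCATCGATCGGATCCGTAGCTAGCTAACGTATCGATGCATCGATCG" * 3

    def test_exact_substring_zero_mismatches(self):
        sp = self.GENOME[20:55]
        hits = hosts.match_spacers({"s": sp}, {"g": self.GENOME})
        exact = hits[(hits["strand"] == "+") & (hits["mismatches"] == 0)]
        assert 20 in set(exact["pos"])

    def test_reverse_complement_found_on_minus_strand(self):
        sp = self.GENOME[10:45]
        rc = sp.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        hits = hosts.match_spacers({"s": rc}, {"g": self.GENOME})
        minus = hits[hits["strand"] == "-"]
        assert 10 in set(minus["pos"])
        assert (minus["mismatches"] == 0).any()

    def test_three_mismatches_rejected_at_max_two(self):
        rng = np.random.default_rng(0)
        genome = "".join(rng.choice(list("ACGT"), 400))
        sp = list(genome[100:135])
        for i in (2, 17, 30):
            sp[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[sp[i]]
        hits = hosts.match_spacers({"s": "".join(sp)}, {"g": genome}, max_mismatches=2)
        assert not ((hits["pos"] == 100) & (hits["strand"] == "+")).any()
        hits3 = hosts.match_spacers({"s": "".join(sp)}, {"g": genome}, max_mismatches=3)
        assert ((hits3["pos"] == 100) & (hits3["mismatches"] == 3)).any()

    def test_short_spacer_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            hits = hosts.match_spacers({"s": "ACGTACGTACGT"}, {"g": self.GENOME})
        assert hits.empty

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_bruteforce_hamming_scan(self, seed):
        rng = np.random.default_rng(seed)
        genome = "".join(rng.choice(list("ACGT"), 300))
        comp = str.maketrans("ACGT", "TGCA")
        spacers = {}
        for i in range(6):
            pos = int(rng.integers(0, 270))
            s = list(genome[pos:pos + 28])
            for j in rng.choice(28, rng.integers(0, 3), replace=False):
                s[j] = rng.choice([b for b in "ACGT" if b != s[j]])
            spacers[f"s{i}"] = "".join(s)
        got = hosts.match_spacers(spacers, {"g": genome}, max_mismatches=2)
        got_set = set(zip(got["spacer"], got["pos"], got["strand"], got["mismatches"]))
        expected = set()
        for sid, sp in spacers.items():
            for strand, q in (("+", sp), ("-", sp.translate(comp)[::-1])):
                for pos in range(len(genome) - len(q) + 1):
                    mm = sum(a != b for a, b in zip(q, genome[pos:pos + len(q)]))
                    if mm <= 2:
                        expected.add((sid, pos, strand, mm))
        assert got_set == expected


class TestPredictBySpacers:
    def hits_for(self, pairs):
        import pandas as pd

        return pd.DataFrame(
            [(s, v, 0, "+", 0) for s, v in pairs],
            columns=["spacer", "genome", "pos", "strand", "mismatches"],
        )

    def test_unanimous_species_level_call(self):
        hits = self.hits_for([("a", "v1"), ("b", "v1"), ("c", "v1")])
        preds = hosts.predict_by_spacers(hits, {"a": B_FRAGILIS, "b": B_FRAGILIS, "c": B_FRAGILIS})
        assert preds["v1"].lineage == B_FRAGILIS
        assert preds["v1"].score == 3

    def test_majority_resolves_at_genus(self):
        hits = self.hits_for([("a", "v1"), ("b", "v1"), ("c", "v1")])
        preds = hosts.predict_by_spacers(hits, {"a": B_FRAGILIS, "b": B_DOREI, "c": PREVOTELLA})
        assert preds["v1"].lineage.deepest_rank == "genus"
        assert preds["v1"].lineage.genus == "Bacteroides"
        assert preds["v1"].score == 2

    def test_no_majority_anywhere_no_prediction(self):
        hits = self.hits_for([("a", "v1"), ("b", "v1")])
        preds = hosts.predict_by_spacers(hits, {"a": B_FRAGILIS, "b": BLAUTIA})
        assert "v1" not in preds

    def test_multiple_placements_count_once(self):
        import pandas as pd

        hits = pd.DataFrame(
            [("a", "v1", 0, "+", 0), ("a", "v1", 50, "-", 1), ("b", "v1", 5, "+", 0)],
            columns=["spacer", "genome", "pos", "strand", "mismatches"],
        )
        preds = hosts.predict_by_spacers(hits, {"a": B_FRAGILIS, "b": BLAUTIA})
        assert "v1" not in preds  # 1 vs 1, not 2 vs 1


class TestMarkovScoring:
    def test_order_zero_all_A_closed_form(self):
        clf = hosts.MarkovHostClassifier(k=0, pseudocount=1.0).fit(["A" * 5000], ["taxA"])
        ll = clf.models_["taxA"].per_nt_loglik("A" * 200)
        assert ll == pytest.approx(0.0, abs=0.01)

    def test_identical_models_tie_breaks_lexicographically_gap_zero(self):
        seq = "ACGT" * 2000
        clf = hosts.MarkovHostClassifier(k=2).fit([seq, seq], ["zeta", "alpha"])
        (best, gap), = clf.predict_with_gap(["ACGT" * 50])
        assert best == "alpha"
        assert gap == pytest.approx(0.0)

    def test_discriminates_compositionally_distinct_hosts(self):
        """Phages sampled from host A's chain score higher under A's model."""
        rng = np.random.default_rng(0)
        tA = rng.dirichlet([1, 1, 1, 1], 4)
        tB = rng.dirichlet([1, 1, 1, 1], 4)

        def chain(t, n):
            cum = np.cumsum(t, axis=1)
            s = 0
            out = []
            for u in rng.random(n):
                s = int(np.searchsorted(cum[s], u))
                out.append("ACGT"[s])
            return "".join(out)

        clf = hosts.MarkovHostClassifier(k=2).fit([chain(tA, 20000), chain(tB, 20000)],
                                                  ["A", "B"])
        correct = sum(clf.predict([chain(tA, 3000)])[0] == "A" for _ in range(10))
        assert correct >= 9

    def test_short_sequence_no_prediction(self):
        clf = hosts.MarkovHostClassifier(k=4).fit(["ACGT" * 100], ["A"])
        assert hosts.score_markov("v", "ACG", clf, {"A": BLAUTIA}) is None


class TestLCAMerge:
    def test_deepest_pair_wins_truth_table(self):
        preds = [
            HostPrediction("v", "mag_spacers", B_FRAGILIS, 3),
            HostPrediction("v", "spacer_db", B_FRAGILIS.truncate("genus"), 2),
            HostPrediction("v", "markov", BLAUTIA, 0.1),
        ]
        merged = hosts.lca_merge(preds)
        assert merged.deepest_rank == "genus"
        assert merged.genus == "Bacteroides"

    def test_order_level_agreement(self):
        merged = hosts.lca_merge([
            HostPrediction("v", "mag_spacers", B_FRAGILIS, 1),
            HostPrediction("v", "spacer_db", PREVOTELLA, 1),
        ])
        assert merged.deepest_rank == "order"
        assert merged.order == "Bacteroidales"

    def test_single_prediction_unchanged(self):
        merged = hosts.lca_merge([HostPrediction("v", "markov", B_FRAGILIS, 1)])
        assert merged == B_FRAGILIS

    def test_all_root_level_returns_none(self):
        merged = hosts.lca_merge([
            HostPrediction("v", "mag_spacers", B_FRAGILIS, 1),
            HostPrediction("v", "markov", BLAUTIA, 1),
        ])
        assert merged is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            hosts.lca_merge([])

    @pytest.mark.parametrize("seed", range(10))
    def test_pairwise_merge_never_shallower_than_global_lca(self, seed):
        rng = np.random.default_rng(seed)
        pool = [B_FRAGILIS, B_DOREI, PREVOTELLA, BLAUTIA,
                B_FRAGILIS.truncate("genus"), PREVOTELLA.truncate("order")]
        chosen = [pool[i] for i in rng.integers(0, len(pool), 3)]
        preds = [HostPrediction("v", s, l, 1.0)
                 for s, l in zip(("mag_spacers", "spacer_db", "markov"), chosen)]
        merged = hosts.lca_merge(preds)
        global_lca = chosen[0].lca(chosen[1]).lca(chosen[2])
        merged_depth = merged.depth if merged is not None else 0
        assert merged_depth >= global_lca.depth


class TestFamilyHostRange:
    def test_rank_specific_counting(self):
        fam_of = {"v1": "F", "v2": "F", "v3": "F", "v4": "F", "v5": "G"}
        merged = {"v1": B_FRAGILIS, "v2": B_FRAGILIS, "v3": B_DOREI,
                  "v4": B_FRAGILIS.truncate("genus"), "v5": None}
        out = hosts.family_host_range(fam_of, merged).set_index("family")
        assert out.loc["F", "n_host_species"] == 2
        assert out.loc["F", "n_host_genera"] == 1
        assert out.loc["G", "n_host_species"] == 0
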