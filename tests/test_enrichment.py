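"""Feature annotation, chi-square enrichment, GO SNP-permutation test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from erps.enrichment import (
    FeatureCall,
    GeneIndex,
    annotate_snp,
    feature_enrichment,
    go_permutation_test,
    naive_go_fisher,
    read_go_map,
    region_enrichment,
    snp_gene_index,
)


@pytest.fixture(scope="module")
def index(toy_annotation):
    return GeneIndex(toy_annotation, flank=200)


class TestAnnotate:
    def test_synonymous_third_position(self, index):
        # codon GAT -> GAC, both Asp
        call = annotate_snp("2L", 1026, "T", "C", index)
        assert "synonymous" in call.features and "gA" in call.gene_ids

    def test_nonsynonymous_second_position(self, index):
        # GAT (Asp) -> GCT (Ala)
        call = annotate_snp("2L", 1025, "A", "C", index)
        assert "nonsynonymous" in call.features

    def test_utrs(self, index):
        assert "utr5" in annotate_snp("2L", 1010, "A", "G", index).features
        assert "utr3" in annotate_snp("2L", 1150, "A", "G", index).features

    def test_upstream_downstream_and_intergenic(self, index):
        assert "upstream" in annotate_snp("2L", 900, "A", "G", index).features
        # 150 bp past the gene end: downstream; 250 bp past: intergenic
        assert "downstream" in annotate_snp("2L", 1340, "A", "G", index).features
        call = annotate_snp("2L", 1440, "A", "G", index)
        assert call.features == {"intergenic"} and not call.gene_ids

    def test_overlapping_genes_collect_both_features(self, index):
        # intron of gA, coding exon of gB (minus strand)
        call = annotate_snp("2L", 1070, "A", "G", index)
        assert "intron" in call.features
        assert call.features & {"synonymous", "nonsynonymous"}
        assert call.gene_ids == {"gA", "gB"}

    def test_order_independence(self, toy_annotation):
        calls = []
        for models in (toy_annotation, toy_annotation[::-1]):
            idx = GeneIndex(models, flank=200)
            calls.append(annotate_snp("2L", 1070, "A", "G", idx))
        assert calls[0].features == calls[1].features


class TestFeatureEnrichment:
    def _calls(self, n, feature, chrom="2L"):
        return [FeatureCall(chrom, i + 1, {feature}, {"g"}) for i in range(n)]

    def test_proportional_candidates_not_enriched(self, rng):
        calls = (self._calls(400, "intron") +
                 [FeatureCall("2L", 1000 + i, {"intergenic"}, set()) for i in range(600)])
        cand = {(c.chrom, c.pos) for c in rng.choice(calls, 100, replace=False)}
        out = feature_enrichment(cand, calls)
        assert (out["p_value"] > 0.001).all()

    def test_chi_square_matches_hand_table(self):
        # candidates: 30 intron / 70 not; others: 100 intron / 900 not
        calls = (self._calls(30, "intron") +
                 [FeatureCall("2L", 10_000 + i, {"intergenic"}, set()) for i in range(70)] +
                 [FeatureCall("3R", i + 1, "intron" in "intron" and {"intron"}, {"g"})
                  for i in range(100)] +
                 [FeatureCall("3R", 10_000 + i, {"intergenic"}, set()) for i in range(900)])
        cand = {(c.chrom, c.pos) for c in calls if c.chrom == "2L"}
        out = feature_enrichment(cand, calls).set_index("feature")
        expected = stats.chi2_contingency([[30, 70], [100, 900]], correction=False)[0]
        assert out.loc["intron", "chi2"] == pytest.approx(expected)
        assert out.loc["intron", "direction"] == "over"

    def test_construction_recovers_planted_feature(self, rng):
        # all candidates intronic by construction
        intron = self._calls(200, "intron")
        other = [FeatureCall("2L", 5000 + i, {"intergenic"}, set()) for i in range(800)]
        cand = {(c.chrom, c.pos) for c in intron[:100]}
        out = feature_enrichment(cand, intron + other).set_index("feature")
        assert out.loc["intron", "p_value"] < 1e-6
        assert out.loc["intron", "direction"] == "over"


class TestRegionEnrichment:
    def test_whole_genome_degenerate_flagged(self):
        keys = [("2L", i + 1) for i in range(50)]
        out = region_enrichment(set(keys[:10]), keys, [("2L", 0, 10**6)])
        assert bool(out.loc[0, "flagged"])

    def test_constructed_overrepresentation(self):
        keys = [("2L", i + 1) for i in range(1000)]
        cand = set(keys[:100])  # all candidates in the first 500 bp... positions 1..100
        out = region_enrichment(cand, keys, [("2L", 0, 500)])
        assert out.loc[0, "p_value"] < 1e-10
        assert out.loc[0, "frac_candidates_in"] == 1.0
        assert not bool(out.loc[0, "flagged"])

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            region_enrichment(set(), [("2L", 1)], [])


TOY_SNP_GENES = [("g1",), ("g1",), ("g2",), ("g3",), ("g3", "g4"), ()]
TOY_KEYS = [("c", i + 1) for i in range(6)]
TOY_GO = {"g1": {"GO:A"}, "g2": {"GO:A", "GO:B"}, "g3": {"GO:B"}, "g4": {"GO:B"}}


def exhaustive_go_p(candidate_keys):
    """Exact permutation distribution by enumerating all SNP orderings."""
    cand_idx = [i for i, k in enumerate(TOY_KEYS) if k in candidate_keys]
    cand_genes = sorted({g for i in cand_idx for g in TOY_SNP_GENES[i]})
    target = len(cand_genes)
    obs = {t: sum(t in TOY_GO[g] for g in cand_genes) for t in ("GO:A", "GO:B")}
    exceed = {t: 0 for t in obs}
    total = 0
    for perm in itertools.permutations(range(6)):
        genes: list[str] = []
        for i in perm:
            for g in TOY_SNP_GENES[i]:
                if g not in genes:
                    genes.append(g)
            if len(genes) >= target:
                break
        total += 1
        for t in obs:
            if sum(t in TOY_GO[g] for g in genes) >= obs[t]:
                exceed[t] += 1
    return {t: exceed[t] / total for t in obs}


class TestGoPermutation:
    def test_matches_exhaustive_enumeration(self, rng):
        cand = {("c", 1), ("c", 2), ("c", 3)}
        exact = exhaustive_go_p(cand)
        out = go_permutation_test(cand, TOY_KEYS, TOY_SNP_GENES, TOY_GO,
                                  n_perm=40_000, rng=rng).set_index("go_term")
        for term, p_exact in exact.items():
            mc_se = 3 * np.sqrt(p_exact * (1 - p_exact) / 40_000) + 1e-4
            assert abs(out.loc[term, "p_empirical"] - p_exact) < mc_se + 0.01

    def test_p_floor(self, rng):
        out = go_permutation_test({("c", 1), ("c", 2)}, TOY_KEYS, TOY_SNP_GENES,
                                  TOY_GO, n_perm=500, rng=rng)
        assert (out["p_empirical"] >= 1 / 501).all()

    def test_length_bias_corrected(self, rng):
        """Random candidates among length-skewed genes: the SNP-permutation
        test stays null while a gene-level Fisher test is fooled."""
        snp_genes = [(f"L{g}",) for g in range(20) for _ in range(50)]
        snp_genes += [(f"S{g}",) for g in range(180) for _ in range(2)]
        keys = [("c", i + 1) for i in range(len(snp_genes))]
        go = {f"L{g}": {"GO:long"} for g in range(20)}
        go.update({f"S{g}": {"GO:short"} for g in range(180)})
        cand_idx = rng.choice(len(keys), 100, replace=False)
        cand = {keys[i] for i in cand_idx}
        out = go_permutation_test(cand, keys, snp_genes, go, n_perm=3000,
                                  rng=rng).set_index("go_term")
        assert out.loc["GO:long", "p_empirical"] > 0.01
        cand_genes = {g for i in cand_idx for g in snp_genes[i]}
        fisher = naive_go_fisher(cand_genes, set(go), go).set_index("go_term")
        assert fisher.loc["GO:long", "p_fisher"] < 1e-6


def test_read_go_map(tmp_path):
    p = tmp_path / "go.tsv"
    p.write_text("g1\tGO:0001 GO:0002\ng2\tGO:0002,GO:0003\n# comment\n")
    m = read_go_map(p)
    assert m == {"g1": {"GO:0001", "GO:0002"}, "g2": {"GO:0002", "GO:0003"}}


def test_snp_gene_index_flank_rule(toy_annotation):
    hits = snp_gene_index([("2L", 850), ("2L", 1440), ("2L", 1070)],
                          toy_annotation, flank=200)
    assert hits[0] == ("gA",)
    assert hits[1] == ()
    assert set(hits[2]) == {"gA", "gB"}
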