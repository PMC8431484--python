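"""Feature/TF enrichment, chromosomal density, subtelomeres, enhancer links."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import medipdm as m
from medipdm.enrich import (
    annotate_dmrs,
    chromosome_density,
    enrichment_batch,
    feature_enrichment,
    link_enhancer_dmrs,
    most_variable_cgi_windows,
    significance_stars,
    subtelomere_summary,
    tf_enrichment,
)
from medipdm.intervals import FeatureSet


def fisher_two_sided_by_enumeration(a, b, c, d):
    """Two-sided Fisher p as the sum of hypergeometric point masses <= pmf(a)."""
    n1, n0 = a + b, c + d
    k = a + c  # feature-overlapping windows
    rv = stats.hypergeom(n1 + n0, n1, k)
    support = np.arange(max(0, k - n0), min(k, n1) + 1)
    pmf = rv.pmf(support)
    return float(pmf[pmf <= rv.pmf(a) * (1 + 1e-9)].sum())


@pytest.fixture(scope="module")
def grid1000():
    """A single-contig grid with exactly 1000 windows."""
    return m.tile_genome(m.GenomeLayout([("c", 250_000)]), 250)


class TestContingency:
    def make_windows(self, n_bg=1000, n_dmr=20):
        bg = np.arange(n_bg)
        return bg[:n_dmr], bg

    def test_odds_ratio_closed_form(self, grid1000):
        # a=10 b=10 c=90 d=890 -> OR = (10*890)/(10*90)
        feature = grid1000.as_featureset(np.r_[np.arange(10), np.arange(20, 110)], "f")
        dmr, bg = self.make_windows()
        res = feature_enrichment(dmr, bg, feature, grid1000)
        assert (res.a, res.b, res.c, res.d) == (10, 10, 90, 890)
        assert np.isclose(res.odds_ratio, (10 * 890) / (10 * 90))
        assert np.isclose(res.odds_ratio, 9.889, atol=0.001)

    def test_zero_cell_haldane_correction(self, grid1000):
        feature = grid1000.as_featureset(np.arange(20, 110), "f")  # no DMR overlap
        dmr, bg = self.make_windows()
        res = feature_enrichment(dmr, bg, feature, grid1000)
        assert res.a == 0
        assert np.isclose(res.odds_ratio, (0.5 * 890.5) / (20.5 * 90.5))

    def test_fisher_p_equals_hypergeometric_enumeration(self, grid1000):
        rng = np.random.default_rng(7)
        dmr, bg = self.make_windows(n_bg=400, n_dmr=30)
        for _ in range(20):
            widx = rng.choice(bg, size=rng.integers(10, 200), replace=False)
            feature = grid1000.as_featureset(widx, "f")
            res = feature_enrichment(dmr, bg, feature, grid1000)
            assert np.isclose(
                res.p, fisher_two_sided_by_enumeration(res.a, res.b, res.c, res.d),
                rtol=1e-8,
            )

    def test_cells_sum_to_background(self, grid1000):
        dmr, bg = self.make_windows()
        feature = grid1000.as_featureset(np.arange(5, 300), "f")
        res = feature_enrichment(dmr, bg, feature, grid1000)
        assert res.a + res.b + res.c + res.d == len(bg)
        assert res.a + res.b == len(dmr)

    def test_dmrs_must_be_subset_of_background(self, grid1000):
        feature = grid1000.as_featureset(np.arange(10), "f")
        with pytest.raises(ValueError, match="subset"):
            feature_enrichment(np.array([700]), np.arange(100), feature, grid1000)
        with pytest.raises(ValueError, match="background"):
            feature_enrichment(np.array([]), np.array([]), feature, grid1000)

    def test_stars_convention(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.00009) == "****"
        assert significance_stars(0.05) == "ns"


class TestTfEnrichment:
    def test_planted_tf_ranks_first(self, small_cohort, small_quantified):
        cfg, layout, grid, truth, counts, _ = small_cohort
        mask, _, _ = small_quantified
        bg = np.flatnonzero(mask)
        table = tf_enrichment(truth.dmr_windows, bg, truth.feature_sets["tfbs"], grid)
        assert table.iloc[0]["feature"] == cfg.plant_tf
        assert table.iloc[0]["q"] < 0.05

    def test_tf_without_background_sites_skipped(self, toy_grid):
        tfbs = FeatureSet.from_intervals(
            "tfbs", [("chr1", 0, 200), ("chrX", 0, 200)], labels=["TFA", "TFB"]
        )
        bg = np.arange(100)  # chr1 windows only
        table = tf_enrichment(np.arange(10), bg, tfbs, toy_grid)
        assert "TFB" in table.attrs["skipped"]
        assert set(table["feature"]) == {"TFA"}

    def test_shuffled_dmr_labels_yield_no_significant_tf(self, small_cohort, small_quantified):
        cfg, layout, grid, truth, counts, _ = small_cohort
        mask, _, _ = small_quantified
        bg = np.flatnonzero(mask)
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            fake = rng.choice(bg, size=len(truth.dmr_windows), replace=False)
            table = tf_enrichment(fake, bg, truth.feature_sets["tfbs"], grid)
            if (table["q"] < 0.05).any():
                hits += 1
        assert hits <= 1


class TestChromosomeDensity:
    def test_proportional_distribution_gives_p_one(self, toy_grid):
        bg = np.arange(toy_grid.n_windows)
        names = toy_grid.contig_names
        dmr = np.r_[np.flatnonzero(names == "chr1")[:20], np.flatnonzero(names == "chr2")[:10],
                    np.flatnonzero(names == "chrX")[:4]]
        # observed proportional to background windows per contig (400/200/80 -> 20/10/4)
        table, stat, p = chromosome_density(dmr, bg, toy_grid)
        assert np.isclose(stat, 0.0, atol=1e-12)
        assert np.isclose(p, 1.0)

    def test_statistic_matches_hand_arithmetic(self, toy_grid):
        bg = np.arange(toy_grid.n_windows)  # 400 + 200 + 80 windows
        names = toy_grid.contig_names
        dmr = np.r_[np.flatnonzero(names == "chr1")[:30], np.flatnonzero(names == "chr2")[:4]]
        table, stat, p = chromosome_density(dmr, bg, toy_grid)
        exp = np.array([400, 200, 80]) / 680 * 34
        hand = ((np.array([30, 4, 0]) - exp) ** 2 / exp).sum()
        assert np.isclose(stat, hand)
        assert np.isclose(p, stats.chi2.sf(hand, df=2))

    def test_cgi_correction_changes_only_expectations(self, toy_grid, toy_layout):
        bg = np.arange(toy_grid.n_windows)
        cgis = FeatureSet.from_intervals("cgis", [("chr1", 0, 30_000), ("chr2", 0, 5_000)])
        names = toy_grid.contig_names
        dmr = np.r_[np.flatnonzero(names == "chr1")[:10], np.flatnonzero(names == "chr2")[:10]]
        t0, s0, _ = chromosome_density(dmr, bg, toy_grid)
        t1, s1, _ = chromosome_density(dmr, bg, toy_grid, correction="cgi", cgis=cgis)
        assert (t0["observed"].tolist()[:2] == t1["observed"].tolist()[:2])
        assert not np.isclose(s0, s1)  # expectations moved


class TestSubtelomere:
    def test_fractions_and_monotonicity(self, toy_grid, toy_layout):
        bg = np.arange(toy_grid.n_windows)
        dmr = bg[:67]
        table = subtelomere_summary(dmr, bg, toy_grid, toy_layout,
                                    cutoffs=(5_000, 10_000, 25_000))
        frac = table["fraction"].to_numpy()
        assert (np.diff(frac) >= 0).all()

    def test_reported_fraction_is_count_over_total(self, toy_grid, toy_layout):
        # 43 of 67 within cutoff -> 64%; 28 of 67 -> 42%
        assert np.isclose(43 / 67, 0.642, atol=5e-4)
        assert np.isclose(28 / 67, 0.418, atol=5e-4)
        bg = np.arange(toy_grid.n_windows)
        d = m.intervals.distances_to_nearest_end(toy_grid.as_featureset(bg), toy_layout)
        cutoff = int(np.quantile(d[:67], 43 / 67))
        table = subtelomere_summary(bg[:67], bg, toy_grid, toy_layout, cutoffs=(cutoff,))
        assert table.loc[0, "n_within"] == (d[:67] <= cutoff).sum()
        assert np.isclose(table.loc[0, "fraction"], table.loc[0, "n_within"] / 67)

    def test_everything_subtelomeric_on_tiny_genome(self, toy_grid, toy_layout):
        bg = np.arange(toy_grid.n_windows)
        with pytest.warns(UserWarning, match="exceeds half"):
            table = subtelomere_summary(bg[:10], bg, toy_grid, toy_layout,
                                        cutoffs=(200_000,))
        assert table.loc[0, "fraction"] == 1.0
        assert table.loc[0, "binomial_p"] == 1.0


class TestEnhancerLinks:
    def setup_case(self, toy_grid):
        enh = FeatureSet.from_intervals("enh", [("chr1", 0, 250)])
        tss = pd.DataFrame({"contig": ["chr1", "chr1", "chr1"],
                            "pos": [90_000, 95_000, 99_000],
                            "gene": ["NEAR", "FAR", "NOTDE"]})
        de = pd.DataFrame({"gene": ["NEAR", "FAR", "NOTDE"],
                           "log2fc": [1.0, -2.0, 0.5],
                           "fdr": [0.04, 0.04, 0.06]})
        return enh, tss, de

    def test_distance_and_fdr_rules(self, toy_grid):
        enh, tss, de = self.setup_case(toy_grid)
        # DMR window 0 = chr1:[0,250), midpoint 125
        links = link_enhancer_dmrs(np.array([0]), toy_grid, enh, tss, de,
                                   max_dist=90_000, de_fdr=0.05)
        assert links["gene"].tolist() == ["NEAR"]  # FAR at 94875 > 90k; NOTDE fdr 0.06
        links2 = link_enhancer_dmrs(np.array([0]), toy_grid, enh, tss, de,
                                    max_dist=99_000, de_fdr=0.05)
        assert sorted(links2["gene"]) == ["FAR", "NEAR"]

    def test_dmr_outside_enhancer_never_linked(self, toy_grid):
        enh, tss, de = self.setup_case(toy_grid)
        links = link_enhancer_dmrs(np.array([10]), toy_grid, enh, tss, de)
        assert links.empty


class TestMostVariable:
    def test_injected_variance_ranks_first_and_ties_deterministic(self, toy_grid):
        nw = toy_grid.n_windows
        betas = pd.DataFrame(np.full((nw, 4), 0.5), columns=list("abcd"))
        betas.iloc[7] = [0.1, 0.9, 0.1, 0.9]
        cgis = FeatureSet.from_intervals("cgis", [("chr1", 0, 25_000)])
        top = most_variable_cgi_windows(betas, toy_grid, cgis, n=10)
        assert top[0] == 7
        assert top[1:].tolist() == sorted(top[1:].tolist())  # genomic order on ties

    def test_matches_exhaustive_variance_sort(self, toy_grid):
        rng = np.random.default_rng(21)
        nw = toy_grid.n_windows
        betas = pd.DataFrame(rng.random((nw, 6)), columns=list("abcdef"))
        cgis = FeatureSet.from_intervals("cgis", [("chr1", 0, 100_000)])
        n = 50
        top = most_variable_cgi_windows(betas, toy_grid, cgis, n=n)
        cand = np.arange(400)  # chr1 windows
        var = betas.iloc[cand].var(axis=1, ddof=1).to_numpy()
        naive = cand[np.lexsort((cand, -var))][:n]
        assert np.array_equal(top, naive)

    def test_short_supply_warns_and_returns_all(self, toy_grid):
        betas = pd.DataFrame(np.random.default_rng(0).random((toy_grid.n_windows, 3)),
                             columns=list("abc"))
        cgis = FeatureSet.from_intervals("cgis", [("chr1", 0, 2_500)])
        with pytest.warns(UserWarning, match="only"):
            top = most_variable_cgi_windows(betas, toy_grid, cgis, n=1000)
        assert len(top) == 10


class TestAnnotation:
    def make_features(self):
        genes = FeatureSet.from_intervals("genes", [("chr1", 1_000, 21_000)], labels=["G1"])
        exons = FeatureSet.from_intervals("exons", [("chr1", 1_000, 1_200)], labels=["G1"])
        cgis = FeatureSet.from_intervals("cgis", [("chr1", 5_000, 5_400), ("chr1", 40_000, 40_400)])
        return {"genes": genes, "exons": exons, "cgis": cgis}

    def test_intron_and_distal_cgi_logic(self, toy_grid, toy_layout):
        features = self.make_features()
        promoters = m.promoter_regions([("chr1", 5_100, "G1")], toy_layout)
        # window 20 = chr1:[5000,5250): in gene, in CGI, not exon, in promoter
        # window 160 = chr1:[40000,40250): distal CGI, outside gene
        ann = annotate_dmrs(np.array([20, 160]), features, toy_grid, toy_layout, promoters)
        w = ann.loc[20]
        assert w["gene_body"] and w["intron"] and not w["exon"]
        assert w["cgi"] and w["promoter"] and not w["distal_cgi"]
        v = ann.loc[160]
        assert v["cgi"] and v["distal_cgi"] and not v["gene_body"] and not v["promoter"]

    def test_window_overlapping_nothing_has_all_flags_false(self, toy_grid, toy_layout):
        ann = annotate_dmrs(np.array([300]), self.make_features(), toy_grid, toy_layout)
        row = ann.loc[300]
        assert not (row["gene_body"] or row["exon"] or row["intron"] or row["cgi"])

    def test_mandatory_sets_required(self, toy_grid, toy_layout):
        with pytest.raises(ValueError, match="genes"):
            annotate_dmrs(np.array([0]), {"cgis": self.make_features()["cgis"]},
                          toy_grid, toy_layout)

    def test_batch_bh_family_is_per_batch(self, toy_grid):
        bg = np.arange(500)
        dmr = bg[:25]
        feats = {
            "f1": toy_grid.as_featureset(np.arange(0, 30), "f1"),
            "f2": toy_grid.as_featureset(np.arange(400, 450), "f2"),
        }
        table = enrichment_batch(dmr, bg, feats, toy_grid)
        assert len(table) == 2
        q = m.bh_adjust(table["p"].to_numpy())
        assert np.allclose(np.sort(table["q"]), np.sort(q))
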