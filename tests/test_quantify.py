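"""Counting, calibration, beta estimation and CNV tracks."""

import numpy as np
import pandas as pd
import pytest

import medipdm as m
from medipdm.quantify import CountMatrix, count_reads_in_windows, estimate_cnv


def meta_for(samples, genotypes):
    return pd.DataFrame({"genotype": genotypes}, index=pd.Index(samples, name="sample"))


class TestCounting:
    def make_grid(self):
        return m.tile_genome(m.GenomeLayout([("c", 1000)]), 250)

    def test_read_assigned_by_midpoint(self):
        grid = self.make_grid()
        reads = {"s1": (["c", "c"], [100, 240], [150, 290])}
        cm = count_reads_in_windows(reads, grid, meta_for(["s1"], ["WT"]))
        # read [100,150) midpoint 125 -> window 0; [240,290) midpoint 265 -> window 1
        assert cm.counts["s1"].tolist() == [1, 1, 0, 0]

    def test_totals_conserved(self):
        grid = self.make_grid()
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 900, 500)
        reads = {"s1": (["c"] * 500, starts, starts + 50)}
        cm = count_reads_in_windows(reads, grid, meta_for(["s1"], ["WT"]))
        assert cm.counts["s1"].sum() == 500
        assert np.isclose(cm.library_scale["s1"], 500 / 1e6)

    def test_zero_reads_rejected(self):
        grid = self.make_grid()
        with pytest.raises(ValueError, match="zero reads"):
            count_reads_in_windows({"s1": ([], [], [])}, grid, meta_for(["s1"], ["WT"]))


class TestFilterAnalyzable:
    def test_cpg_and_sex_rules(self, toy_grid, toy_layout):
        mask = m.filter_analyzable(toy_grid, toy_layout, min_cpg=4)
        names = toy_grid.contig_names
        g = toy_grid.cpg_count
        # boundary: exactly 4 CpGs on an autosome is retained, 3 is not
        assert mask[(g == 4) & (names != "chrX")].all()
        assert not mask[g == 3].any()
        # any CpG count on the sex contig is excluded
        assert not mask[names == "chrX"].any()


class TestCalibrationSelection:
    def test_thresholds_are_strict(self):
        # 100 reference samples; window 0: beta .85 in all -> selected
        # window 1: .85 in 94 of 100 -> rejected; window 2: exactly .80 -> rejected
        ref = np.full((3, 100), 0.85)
        ref[1, :6] = 0.5
        ref[2] = 0.80
        sel = m.select_calibration_windows(ref)
        assert sel.tolist() == [0]

    def test_empty_selection_is_an_error(self):
        with pytest.raises(ValueError, match="no calibration windows"):
            m.select_calibration_windows(np.full((5, 10), 0.5))


class TestCalibrationFit:
    def test_noise_free_round_trip_recovers_model_exactly(self, small_cohort):
        cfg, layout, grid, truth, _, _ = small_cohort
        counts, params = m.simulate_counts(truth, grid, cfg, noise="none")
        mask = m.filter_analyzable(grid, layout)
        calib = m.select_calibration_windows(truth.true_beta_frame(), candidate_mask=mask)
        model = m.fit_calibration(counts, grid, calib)
        # the sample carrying the planted deletion has genuinely shifted
        # background depth; exactness holds for the diploid samples
        diploid = [s for s in counts.sample_ids
                   if s not in set(truth.cnv_segments["sample"])]
        lam_gen = params.library_size / 1e6
        scale = lam_gen / counts.library_scale
        # gamma_s recovered exactly (up to the common library-scale factor)
        for s in diploid:
            assert np.isclose(model.gamma[s], cfg.background_gamma * scale[s], atol=1e-9)
        # enrichment profile equals alpha * f(g) + gamma on the same scale
        g = model.g_grid.astype(float)
        f = g / (g + cfg.saturation_k)
        for s in diploid:
            expected = (params.alpha[s] * f + cfg.background_gamma) * scale[s]
            assert np.allclose(model.profile[s].to_numpy(), expected, atol=1e-9)

    def test_all_zero_counts_rejected(self, toy_grid):
        counts = CountMatrix(
            pd.DataFrame(np.zeros((toy_grid.n_windows, 3)), columns=["a", "b", "c"]),
            meta_for(["a", "b", "c"], ["WT", "WT", "mut"]),
            library_scale=pd.Series([1.0, 1.0, 1.0], index=["a", "b", "c"]),
        )
        with pytest.raises(ValueError, match="zero"):
            m.fit_calibration(counts, toy_grid, np.array([0, 1, 2]))

    def test_profile_error_small_under_nb_noise(self, small_cohort):
        # depth >= 30: relative enrichment-profile error <= 10% wherever the
        # CpG-count stratum has enough calibration windows for the NB noise
        # floor (sd ~ sqrt(phi/n)) to sit well below that bound; the sparse
        # CGI tail of a desk-scale genome carries proportionally more noise
        cfg, layout, grid, truth, counts, params = small_cohort
        mask = m.filter_analyzable(grid, layout)
        calib = m.select_calibration_windows(truth.true_beta_frame(), candidate_mask=mask)
        model = m.fit_calibration(counts, grid, calib, min_windows_per_bin=10)
        lam_gen = params.library_size / 1e6
        scale = lam_gen / counts.library_scale
        g = model.g_grid.astype(float)
        f = g / (g + cfg.saturation_k)
        supported = model.bin_support >= 200
        assert supported.sum() >= 5
        diploid = [s for s in counts.sample_ids
                   if s not in set(truth.cnv_segments["sample"])]
        rel_err = []
        for s in diploid:
            truth_prof = (params.alpha[s] * f + cfg.background_gamma) * scale[s]
            rel_err.append(
                (np.abs(model.profile[s].to_numpy() - truth_prof) / truth_prof)[supported]
            )
        assert np.max(rel_err) <= 0.10


class TestBetaEstimation:
    def test_noise_free_inversion_identity(self, small_cohort):
        cfg, layout, grid, truth, _, _ = small_cohort
        counts, _ = m.simulate_counts(truth, grid, cfg, noise="none")
        mask = m.filter_analyzable(grid, layout)
        calib = m.select_calibration_windows(truth.true_beta_frame(), candidate_mask=mask)
        model = m.fit_calibration(counts, grid, calib)
        betas = m.estimate_beta(counts, model, grid, mask)
        got = betas.to_numpy()[mask]
        # the deleted sample's background estimate is genuinely shifted by the
        # planted CNV; exactness is the contract for the diploid samples
        diploid = np.array([s not in set(truth.cnv_segments["sample"])
                            for s in counts.sample_ids])
        err = np.abs(got[:, diploid] - truth.true_beta[mask][:, diploid])
        assert np.nanmax(err) < 1e-9

    def test_counts_below_background_clip_to_zero(self, small_cohort):
        cfg, layout, grid, truth, counts, _ = small_cohort
        mask = m.filter_analyzable(grid, layout)
        calib = m.select_calibration_windows(truth.true_beta_frame(), candidate_mask=mask)
        model = m.fit_calibration(counts, grid, calib)
        low = counts.counts.copy()
        low.iloc[np.flatnonzero(mask)[0]] = 0.0  # below background for every sample
        cm = CountMatrix(low, counts.meta, counts.library_scale)
        betas = m.estimate_beta(cm, model, grid, mask)
        assert (betas.iloc[np.flatnonzero(mask)[0]] == 0.0).all()

    def test_monotone_in_window_count(self, small_cohort, small_quantified):
        cfg, layout, grid, truth, counts, _ = small_cohort
        mask, model, betas = small_quantified
        w = int(np.flatnonzero(mask)[10])
        bumped = counts.counts.copy()
        bumped.iloc[w, 0] += 5
        cm = CountMatrix(bumped, counts.meta, counts.library_scale)
        betas2 = m.estimate_beta(cm, model, grid, mask)
        assert betas2.iloc[w, 0] >= betas.iloc[w, 0]

    def test_nan_exactly_outside_mask(self, small_quantified):
        mask, model, betas = small_quantified
        vals = betas.to_numpy()
        assert np.isnan(vals[~mask]).all()
        assert not np.isnan(vals[mask]).any()

    def test_degenerate_calibration_rejected(self, small_cohort, small_quantified):
        cfg, layout, grid, truth, counts, _ = small_cohort
        mask, model, _ = small_quantified
        broken = model.profile.copy()
        broken.iloc[:, :] = 0.0  # E(g) below gamma everywhere
        bad = m.CalibrationModel(model.gamma, model.g_grid, broken)
        with pytest.raises(ValueError, match="degenerate"):
            m.estimate_beta(counts, bad, grid, mask)


class TestCnv:
    def test_identical_profiles_give_zero_ratio(self, toy_grid, toy_layout):
        one = np.ones(toy_grid.n_windows) * 7
        counts = CountMatrix(
            pd.DataFrame({s: one for s in ["a", "b", "c"]}),
            meta_for(["a", "b", "c"], ["WT", "WT", "mut"]),
        )
        cnv = estimate_cnv(counts, toy_grid, toy_layout, bin_size=20_000)
        vals = cnv.log2_ratio.to_numpy()
        assert np.allclose(vals[np.isfinite(vals)], 0.0)

    def test_bin_without_cpg_free_windows_is_missing(self):
        # every position is a CpG start -> no zero-CpG window on contig "b"
        layout = m.GenomeLayout(
            [("a", 4000), ("b", 4000)],
            {"b": np.arange(0, 3998, 2), "a": np.array([10])},
        )
        grid = m.tile_genome(layout, 250)
        counts = CountMatrix(
            pd.DataFrame(np.ones((grid.n_windows, 3)) * 5, columns=["x", "y", "z"]),
            meta_for(["x", "y", "z"], ["WT", "mut", "WT"]),
        )
        cnv = estimate_cnv(counts, grid, layout, bin_size=4000)
        b_bin = np.flatnonzero(cnv.bins.contigs == "b")
        assert np.isnan(cnv.log2_ratio.iloc[b_bin].to_numpy()).all()
        a_bin = np.flatnonzero(cnv.bins.contigs == "a")
        assert np.isfinite(cnv.log2_ratio.iloc[a_bin].to_numpy()).all()

    def test_fewer_than_three_samples_rejected(self, toy_grid, toy_layout):
        counts = CountMatrix(
            pd.DataFrame(np.ones((toy_grid.n_windows, 2)), columns=["a", "b"]),
            meta_for(["a", "b"], ["WT", "mut"]),
        )
        with pytest.raises(ValueError, match="3 samples"):
            estimate_cnv(counts, toy_grid, toy_layout)

    def test_invariant_to_library_rescaling(self, small_cohort):
        cfg, layout, grid, truth, counts, _ = small_cohort
        cnv1 = estimate_cnv(counts, grid, layout, bin_size=1_000_000)
        scaled = counts.counts.copy()
        scaled.iloc[:, 0] = scaled.iloc[:, 0] * 3
        cnv2 = estimate_cnv(
            CountMatrix(scaled, counts.meta), grid, layout, bin_size=1_000_000
        )
        a, b = cnv1.log2_ratio.to_numpy(), cnv2.log2_ratio.to_numpy()
        ok = np.isfinite(a)
        assert np.allclose(a[ok], b[ok])

    def test_deletion_recovered(self, small_cohort):
        cfg, layout, grid, truth, counts, _ = small_cohort
        cnv = estimate_cnv(counts, grid, layout, bin_size=1_000_000)
        s0 = truth.cnv_segments.iloc[0]["sample"]
        inside = np.asarray(
            (cnv.bins.contigs == "chr2")
            & (cnv.bins.starts >= 500_000)
            & (cnv.bins.ends <= 2_500_000)
        )
        lr = cnv.log2_ratio[s0].to_numpy()[inside]
        assert (lr < -0.6).all()
        calls = cnv.calls(threshold=0.4)
        assert (calls[s0].to_numpy()[inside] == "loss").all()
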