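"""Shared fixtures: small deterministic genomes and simulated cohorts."""

import numpy as np
import pandas as pd
import pytest

import medipdm as m


@pytest.fixture(scope="session")
def toy_layout() -> m.GenomeLayout:
    """Two small contigs plus a sex contig, with hand-placed CpGs."""
    rng = np.random.default_rng(11)
    cpgs = {
        "chr1": np.unique(rng.integers(0, 100_000, 2_000)),
        "chr2": np.unique(rng.integers(0, 50_000, 600)),
        "chrX": np.unique(rng.integers(0, 20_000, 300)),
    }
    return m.GenomeLayout(
        [("chr1", 100_000), ("chr2", 50_000), ("chrX", 20_000)],
        cpgs,
        sex_contigs={"chrX"},
    )


@pytest.fixture(scope="session")
def toy_grid(toy_layout) -> m.WindowGrid:
    return m.tile_genome(toy_layout, 250)


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort with NB counts at moderate depth.

    Session-scoped: simulation is deterministic and read-only in tests.
    """
    cfg = m.SimulationConfig(
        seed=5,
        contigs=(("chr1", 3_000_000), ("chr2", 3_000_000), ("chrX", 1_000_000)),
        n_true_dmrs=60,
        n_dev_lp_ip=20,
        n_dev_ip_hp=8,
        library_size_range=(40e6, 50e6),
        cnv_segments=((0, "chr2", 500_000, 2_500_000, 0.5),),
    )
    layout, grid, truth = m.simulate_cohort(cfg)
    counts, params = m.simulate_counts(truth, grid, cfg, noise="nb")
    return cfg, layout, grid, truth, counts, params


@pytest.fixture(scope="session")
def small_quantified(small_cohort):
    """Calibrated betas for the small cohort."""
    cfg, layout, grid, truth, counts, params = small_cohort
    mask = m.filter_analyzable(grid, layout)
    calib = m.select_calibration_windows(truth.true_beta_frame(), candidate_mask=mask)
    model = m.fit_calibration(counts, grid, calib)
    betas = m.estimate_beta(counts, model, grid, mask)
    return mask, model, betas


def naive_overlap(query_fs, feature_fs, min_overlap=1):
    """O(n*m) double-loop interval overlap oracle."""
    hits = []
    for qi in range(len(query_fs)):
        for fi in range(len(feature_fs)):
            if str(query_fs.contigs[qi]) != str(feature_fs.contigs[fi]):
                continue
            ov = min(query_fs.ends[qi], feature_fs.ends[fi]) - max(
                query_fs.starts[qi], feature_fs.starts[fi]
            )
            if ov >= min_overlap:
                hits.append((qi, fi, int(ov)))
    return pd.DataFrame(hits, columns=["query_idx", "feature_idx", "overlap_bp"]).astype(
        {"query_idx": "int64", "feature_idx": "int64", "overlap_bp": "int64"}
    )
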