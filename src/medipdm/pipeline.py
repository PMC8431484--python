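"""End-to-end orchestration: simulate/load -> quantify -> test -> enrich ->
program -> validate, with a structured run report.

Each stage writes plain-text outputs (TSV/BED) into the run directory and
records a summary in the report (JSON).  Inputs can come either from the
synthetic cohort generator (``simulate`` block in the config) or from files
(counts matrix, contig lengths, CpG positions, sample metadata, feature
BEDs, classifier panel).  All randomness is derived from one top-level seed
via independent substreams, so re-running with the same seed and inputs
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dmr as dmr_mod
from . import enrich as enrich_mod
from . import programming as prog_mod
from . import quantify as quant_mod
from . import validation as val_mod
from .intervals import (
    FeatureSet,
    GenomeLayout,
    cgi_shores,
    promoter_regions,
    read_contig_lengths,
    read_cpg_positions,
    tile_genome,
)
from .simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_counts,
    simulate_de_table,
    simulate_epityper,
    simulate_external_classes,
    write_cohort,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("medipdm")

ALL_STAGES = ("simulate", "quantify", "test", "enrich", "program", "validate")


class PipelineError(RuntimeError):
    """Raised with the failing stage name attached."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, thresholds and stage toggles of one pipeline run."""

    outdir: str = "medipdm_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # synthetic mode (used when counts_tsv is None)
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    noise: str = "nb"
    # file mode
    counts_tsv: str | None = None
    meta_tsv: str | None = None
    contigs_tsv: str | None = None
    cpgs_bed: str | None = None
    sex_contigs: tuple[str, ...] = ("chrX", "chrY")
    features_dir: str | None = None
    tss_tsv: str | None = None
    panel_loci_bed: str | None = None
    panel_betas_tsv: str | None = None
    panel_labels_tsv: str | None = None
    de_genes_tsv: str | None = None
    external_classes_tsv: str | None = None
    epityper_tsv: str | None = None
    reference_betas_tsv: str | None = None
    # thresholds (the quantification/testing contract)
    window_size: int = 250
    min_cpg: int = 4
    calib_min_meth: float = 0.8
    calib_min_sample_frac: float = 0.95
    fdr_max: float = 0.05
    min_abs_lfc: float = 1.0
    pseudocount: float = 0.01
    cnv_bin_size: int = 2_000_000
    min_locus_overlap: int = 145
    programming_delta: float = 0.20
    subtelomere_cutoffs: tuple[int, ...] = (5_000_000, 10_000_000, 15_000_000)
    de_fdr: float = 0.05
    link_max_dist: int = 1_000_000
    n_variable_windows: int = 1000
    promoter_flank: int = 2000
    shore_flank: int = 2000

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if isinstance(self.simulate, dict):
            self.simulate = SimulationConfig.from_dict(self.simulate)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}

        def detuple(v):
            return tuple(v) if isinstance(v, list) else v

        raw = {k: detuple(v) for k, v in raw.items()}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(fmt)
        log.addHandler(handler)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; return the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    report: dict = {
        "seed": config.seed,
        "version": _package_version(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    state: dict = {}
    stage_order = [s for s in ALL_STAGES if s in config.stages]
    for stage in ALL_STAGES:
        if stage not in stage_order:
            report["stages"][stage] = {"status": "skipped"}
    runners = {
        "simulate": _stage_simulate,
        "quantify": _stage_quantify,
        "test": _stage_test,
        "enrich": _stage_enrich,
        "program": _stage_program,
        "validate": _stage_validate,
    }
    for stage in stage_order:
        t0 = time.time()
        log.info("stage %s: start", stage)
        try:
            summary = runners[stage](config, state, outdir)
        except PipelineError:
            raise
        except Exception as exc:  # annotate with the failing stage
            raise PipelineError(stage, str(exc)) from exc
        summary["status"] = "ok"
        summary["seconds"] = round(time.time() - t0, 2)
        report["stages"][stage] = summary
        log.info("stage %s: done in %.1fs", stage, summary["seconds"])
    report["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _package_version() -> str:
    from . import __version__

    return __version__


def _stage_simulate(config: RunConfig, state: dict, outdir: Path) -> dict:
    if config.counts_tsv is not None:
        _load_inputs(config, state)
        return {"mode": "load", "n_windows": state["grid"].n_windows,
                "n_samples": len(state["counts"].sample_ids)}
    sim = dataclasses.replace(config.simulate, seed=config.seed)
    layout, grid, truth = simulate_cohort(sim)
    counts, params = simulate_counts(truth, grid, sim, noise=config.noise)
    state.update(layout=layout, grid=grid, truth=truth, counts=counts, sim=sim,
                 gen_params=params)
    state["features"] = dict(truth.feature_sets)
    state["tss"] = truth.tss
    state["panel"] = truth.panel
    state["reference_betas"] = truth.true_beta_frame()
    write_cohort(outdir / "cohort", layout, grid, truth, counts=counts, config=sim)
    return {
        "mode": "simulate",
        "n_windows": grid.n_windows,
        "n_samples": len(counts.sample_ids),
        "n_true_dmrs": len(truth.dmr_windows),
    }


def _load_inputs(config: RunConfig, state: dict) -> None:
    for name in ("counts_tsv", "meta_tsv", "contigs_tsv", "cpgs_bed"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise PipelineError("simulate", f"file-mode input {name} missing: {path}")
    layout = GenomeLayout(
        read_contig_lengths(config.contigs_tsv),
        read_cpg_positions(config.cpgs_bed),
        sex_contigs=[c for c in config.sex_contigs
                     if c in [n for n, _ in read_contig_lengths(config.contigs_tsv)]],
    )
    grid = tile_genome(layout, config.window_size)
    counts = quant_mod.CountMatrix.from_tsv(config.counts_tsv, config.meta_tsv)
    if counts.n_windows != grid.n_windows:
        raise PipelineError("simulate", "counts rows do not match the window grid")
    state.update(layout=layout, grid=grid, counts=counts)
    features = {}
    if config.features_dir:
        for bed in sorted(Path(config.features_dir).glob("*.bed")):
            features[bed.stem] = FeatureSet.from_bed(bed)
    state["features"] = features
    if config.tss_tsv:
        state["tss"] = pd.read_csv(config.tss_tsv, sep="\t")
    if config.panel_loci_bed:
        state["panel"] = prog_mod.ClassifierPanel.from_files(
            config.panel_loci_bed, config.panel_betas_tsv, config.panel_labels_tsv
        )
    if config.reference_betas_tsv:
        state["reference_betas"] = pd.read_csv(
            config.reference_betas_tsv, sep="\t", index_col="window"
        )
    if config.de_genes_tsv:
        state["de_genes"] = pd.read_csv(config.de_genes_tsv, sep="\t")
    if config.external_classes_tsv:
        state["external"] = pd.read_csv(config.external_classes_tsv, sep="\t")
    if config.epityper_tsv:
        state["epityper"] = val_mod.EpiTyperDataset.from_tsv(config.epityper_tsv)


def _require(state: dict, key: str, stage: str):
    if key not in state:
        raise PipelineError(stage, f"missing upstream artifact {key!r}; run earlier stages")
    return state[key]


def _stage_quantify(config: RunConfig, state: dict, outdir: Path) -> dict:
    grid = _require(state, "grid", "quantify")
    counts = _require(state, "counts", "quantify")
    layout = state["layout"]
    mask = quant_mod.filter_analyzable(grid, layout, min_cpg=config.min_cpg)
    reference = _require(state, "reference_betas", "quantify")
    calib = quant_mod.select_calibration_windows(
        reference,
        min_meth=config.calib_min_meth,
        min_sample_frac=config.calib_min_sample_frac,
        candidate_mask=mask,
    )
    model = quant_mod.fit_calibration(counts, grid, calib)
    betas = quant_mod.estimate_beta(counts, model, grid, mask)
    cnv = quant_mod.estimate_cnv(counts, grid, layout, bin_size=config.cnv_bin_size)
    state.update(mask=mask, calibration=model, betas=betas, cnv=cnv)
    betas.iloc[np.flatnonzero(mask)].to_csv(
        outdir / "betas.tsv", sep="\t", index_label="window", float_format="%.6g"
    )
    model.to_tsv(outdir / "calibration_gamma.tsv", outdir / "calibration_profile.tsv")
    cnv.to_tsv(outdir / "cnv_log2.tsv")
    return {
        "n_analyzable": int(mask.sum()),
        "n_calibration": int(len(calib)),
        "cnv_bins": len(cnv.bins),
    }


def _stage_test(config: RunConfig, state: dict, outdir: Path) -> dict:
    counts = _require(state, "counts", "test")
    model = _require(state, "calibration", "test")
    grid, mask = state["grid"], _require(state, "mask", "test")
    wt, mut = counts.genotype_groups()
    disp = dmr_mod.estimate_dispersion(counts, model, grid, mask, groups=[wt, mut])
    tests = dmr_mod.test_windows(counts, model, grid, mask, disp,
                                 pseudocount=config.pseudocount)
    dmrs = dmr_mod.call_dmrs(tests, fdr_max=config.fdr_max, min_abs_lfc=config.min_abs_lfc)
    state.update(dispersion=disp, tests=tests, dmrs=dmrs)
    tests.to_csv(outdir / "window_tests.tsv", sep="\t", float_format="%.6g")
    dmrs.to_bed(outdir / "dmrs.bed", grid)
    dmrs.table.to_csv(outdir / "dmrs.tsv", sep="\t", float_format="%.6g")
    by_dir = dmrs.counts_by_direction()
    return {"n_tested": int(tests["p"].notna().sum()), "n_dmrs": len(dmrs), **by_dir}


def _stage_enrich(config: RunConfig, state: dict, outdir: Path) -> dict:
    grid, layout = state["grid"], state["layout"]
    mask = _require(state, "mask", "enrich")
    dmrs = _require(state, "dmrs", "enrich")
    features = dict(_require(state, "features", "enrich"))
    background = np.flatnonzero(mask)
    dmr_windows = dmrs.windows

    promoters = None
    if "tss" in state:
        promoters = promoter_regions(state["tss"], layout, flank=config.promoter_flank)
        features["promoters"] = promoters
    if "cgis" in features:
        features["cgi_shores"] = cgi_shores(features["cgis"], layout, flank=config.shore_flank)

    annotation = enrich_mod.annotate_dmrs(dmr_windows, features, grid, layout, promoters)
    annotation.to_csv(outdir / "dmr_annotation.tsv", sep="\t")

    batch = {
        name: features[name]
        for name in ("genes", "exons", "cgis", "cgi_shores", "promoters", "enhancers")
        if name in features
    }
    feat_table = enrich_mod.enrichment_batch(dmr_windows, background, batch, grid)
    feat_table.to_csv(outdir / "enrich_features.tsv", sep="\t", index=False, float_format="%.6g")

    summary = {"n_dmrs": int(len(dmr_windows)), "n_background": int(len(background))}
    if "tfbs" in features and features["tfbs"].labels is not None:
        tf_table = enrich_mod.tf_enrichment(dmr_windows, background, features["tfbs"], grid)
        tf_table.to_csv(outdir / "enrich_tfbs.tsv", sep="\t", index=False, float_format="%.6g")
        summary["n_tfs"] = len(tf_table)
    if "chromatin_states" in features and features["chromatin_states"].labels is not None:
        st = features["chromatin_states"]
        by_state = {
            lab: st.subset(np.flatnonzero(st.labels == lab))
            for lab in sorted(set(st.labels.tolist()))
        }
        st_table = enrich_mod.enrichment_batch(dmr_windows, background, by_state, grid)
        st_table.to_csv(outdir / "enrich_states.tsv", sep="\t", index=False, float_format="%.6g")

    if len(dmr_windows):
        dens, stat, p = enrich_mod.chromosome_density(dmr_windows, background, grid)
        if "cgis" in features:
            dens_cgi, stat_c, p_c = enrich_mod.chromosome_density(
                dmr_windows, background, grid, correction="cgi", cgis=features["cgis"]
            )
            dens = dens.merge(dens_cgi, on="contig", suffixes=("", "_cgi_corrected"))
        dens.to_csv(outdir / "chrom_density.tsv", sep="\t", index=False, float_format="%.6g")
        summary["chrom_density_p"] = p

        sub = enrich_mod.subtelomere_summary(
            dmr_windows, background, grid, layout, cutoffs=config.subtelomere_cutoffs
        )
        sub.to_csv(outdir / "subtelomere.tsv", sep="\t", index=False, float_format="%.6g")

    if "de_genes" not in state and "sim" in state:
        state["de_genes"] = simulate_de_table(state["truth"], state["sim"])
    if "enhancers" in features and "tss" in state and "de_genes" in state:
        links = enrich_mod.link_enhancer_dmrs(
            dmr_windows, grid, features["enhancers"], state["tss"], state["de_genes"],
            max_dist=config.link_max_dist, de_fdr=config.de_fdr,
        )
        links.to_csv(outdir / "enhancer_links.tsv", sep="\t", index=False)
        summary["n_enhancer_links"] = len(links)

    if "cgis" in features:
        betas = _require(state, "betas", "enrich")
        top = enrich_mod.most_variable_cgi_windows(
            betas, grid, features["cgis"], n=config.n_variable_windows, candidate_mask=mask
        )
        pd.Series(top, name="window").to_csv(outdir / "variable_cgi_windows.tsv",
                                             sep="\t", index=False)
        summary["n_variable_windows"] = len(top)
    return summary


def _stage_program(config: RunConfig, state: dict, outdir: Path) -> dict:
    grid = state["grid"]
    betas = _require(state, "betas", "program")
    panel = _require(state, "panel", "program")
    counts = state["counts"]
    lb = prog_mod.locus_betas(betas, grid, panel.loci, min_overlap=config.min_locus_overlap)
    assignment = prog_mod.assign_subtypes(lb, panel)
    lb.to_csv(outdir / "locus_betas.tsv", sep="\t", index_label="sample", float_format="%.6g")
    assignment.labels.to_frame().to_csv(outdir / "subtypes.tsv", sep="\t", index_label="sample")
    summary: dict = {
        "subtype_tally": assignment.tally(counts.meta["genotype"]).to_dict(),
    }
    if "dmrs" in state and len(state["dmrs"]):
        dmr_betas = betas.iloc[state["dmrs"].windows]
        calls = prog_mod.programming_decomposition(
            dmr_betas, assignment.labels, counts.meta["genotype"], delta=config.programming_delta
        )
        calls.to_csv(outdir / "programming_calls.tsv", sep="\t", index_label="window",
                     float_format="%.6g")
        state["programming_calls"] = calls
        summary["class_tally"] = calls["klass"].value_counts().to_dict()
        if "external" not in state and "sim" in state:
            state["external"] = simulate_external_classes(state["truth"], grid, state["sim"])
        if "external" in state:
            ext = prog_mod.overlap_external_classes(
                state["dmrs"].as_featureset(grid), state["external"]
            )
            ext.to_csv(outdir / "external_overlap.tsv", sep="\t", index=False,
                       float_format="%.6g")
    state["assignment"] = assignment
    return summary


def _stage_validate(config: RunConfig, state: dict, outdir: Path) -> dict:
    grid = state["grid"]
    betas = _require(state, "betas", "validate")
    counts = state["counts"]
    if "epityper" not in state and "sim" in state:
        state["epityper"] = simulate_epityper(state["truth"], grid, state["sim"])
    data = _require(state, "epityper", "validate")
    retained, exclusions = val_mod.epityper_qc(data)
    means = val_mod.region_means(retained)
    exclusions.to_csv(outdir / "epityper_exclusions.tsv", sep="\t", index=False)
    means.to_csv(outdir / "epityper_region_means.tsv", sep="\t", float_format="%.6g")

    # pipeline beta per validated region: mean over overlapped windows
    from .intervals import overlap as _ov

    regions = retained.units.drop_duplicates("amplicon")
    fs = FeatureSet(
        "validated",
        regions["contig"].to_numpy(dtype=object),
        regions["start"].to_numpy(dtype=np.int64),
        regions["end"].to_numpy(dtype=np.int64),
    )
    hits = _ov(fs, grid)
    rows = {}
    for ri, amp in enumerate(regions["amplicon"]):
        widx = hits.loc[hits["query_idx"] == ri, "feature_idx"].to_numpy()
        rows[amp] = betas.iloc[widx].mean(axis=0)
    pipeline_means = pd.DataFrame(rows).T.rename_axis("region")
    r, p, n = val_mod.concordance(pipeline_means, means)
    diffs = val_mod.group_difference_table(means, pipeline_means, counts.meta["genotype"])
    diffs.to_csv(outdir / "platform_group_diffs.tsv", sep="\t", float_format="%.6g")
    state.update(epityper_means=means, epityper_exclusions=exclusions)
    return {
        "n_units_retained": len(retained.units),
        "n_units_excluded": len(exclusions),
        "concordance_r": round(r, 4),
        "concordance_p": p,
        "n_pairs": n,
    }
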