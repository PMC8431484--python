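"""Synthetic CLL cohort generator with known ground truth.

No patient MeDIP-seq data is publicly deposited for this problem, so every
pipeline stage is exercised against a simulated cohort whose truth is
known.  The generator emulates, on a small multi-contig toy genome:

- a CpG landscape from an inhomogeneous point process with CpG-island
  hotspots, so the window grid contains CpG-free, CpG-poor and island
  windows;
- a 14 wild-type / 13 mutant cohort whose samples carry one of three
  B-cell programming subtypes (LP/IP/HP), with no mutant sample in HP by
  default;
- genotype-linked hypomethylation (effect size ``effect_delta``) at
  planted DMR windows;
- developmental programming windows whose methylation shifts between
  subtypes, plus an 18-locus classifier panel separating the subtypes;
- library-size- and CpG-density-dependent MeDIP enrichment with
  negative-binomial noise: counts are drawn with mean
  ``mu = lambda_s * c * (alpha_s * f(g) * beta + gamma)`` where
  ``f(g) = g / (g + k)`` is a saturating enrichment curve, ``c`` the local
  copy ratio and ``gamma`` the CpG-independent background;
- CpG-free windows carrying pure background depth, hence copy-number
  signal (a hemizygous 4-Mb deletion is planted by default);
- noisy per-CpG-unit validation measurements mimicking a bisulfite
  mass-spectrometry assay.

Everything is deterministic given the seed; distinct stages draw from
independent substreams so toggling one stage does not shift another's
randomness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .intervals import FeatureSet, GenomeLayout, WindowGrid, tile_genome, write_contig_lengths, write_cpg_positions
from .programming import SUBTYPES, ClassifierPanel
from .quantify import CountMatrix
from .validation import EpiTyperDataset

__all__ = [
    "SimulationConfig",
    "CohortTruth",
    "simulate_cohort",
    "simulate_counts",
    "simulate_epityper",
    "simulate_de_table",
    "simulate_external_classes",
    "write_cohort",
]

_CHROMATIN_STATES = (
    "Active_Promoter",
    "Weak_Enhancer",
    "Strong_Enhancer",
    "Transcribed",
    "Repressed",
    "Heterochromatin",
)


@dataclass
class SimulationConfig:
    """All knobs of the synthetic world, with cohort-realistic defaults.

    Defaults mirror the study design this package targets: 14 wild-type
    and 13 mutant samples; mutants occur only in the LP and IP programming
    subtypes; planted DMRs are hypomethylated in mutants by 0.3 (beta
    units) from a 0.5 baseline, so the expected log2 fold change of
    pseudocount-stabilized beta means (~-1.3) clears the |lfc| >= 1 call
    threshold; negative-binomial dispersion 0.05 (variance = mu + phi mu^2).
    """

    seed: int = 0
    # cohort
    n_wt: int = 14
    n_mut: int = 13
    subtype_mix_wt: tuple[float, float, float] = (0.4, 0.3, 0.3)
    subtype_mix_mut: tuple[float, float, float] = (0.6, 0.4, 0.0)
    # genome
    contigs: tuple[tuple[str, int], ...] = (
        ("chr1", 10_000_000),
        ("chr2", 10_000_000),
        ("chr3", 10_000_000),
        ("chr4", 10_000_000),
        ("chrX", 5_000_000),
    )
    sex_contigs: tuple[str, ...] = ("chrX",)
    window_size: int = 250
    cpg_background_rate: float = 0.02  # CpGs per bp outside islands
    cgi_per_mb: float = 2.0
    cgi_width_range: tuple[int, int] = (500, 1500)
    cgi_cpg_rate: float = 0.12
    # methylation landscape
    beta_high_fraction: float = 0.6  # fully methylated bulk genome
    beta_mid_fraction: float = 0.25  # intermediate, U(0.3, 0.7)
    beta_low_range: tuple[float, float] = (0.02, 0.2)  # island-like lows
    beta_mid_range: tuple[float, float] = (0.3, 0.7)
    # planted signal
    n_true_dmrs: int = 100
    effect_delta: float = 0.3
    dmr_baseline_beta: float = 0.5
    n_dev_lp_ip: int = 30
    n_dev_ip_hp: int = 10
    dev_shift: float = 0.25
    dev_baseline_range: tuple[float, float] = (0.15, 0.45)
    n_classifier_loci: int = 18
    classifier_baselines: tuple[float, float, float] = (0.15, 0.5, 0.85)
    classifier_jitter: float = 0.05
    n_reference_per_subtype: int = 12
    reference_noise_sd: float = 0.03
    # enrichment / counts
    library_size_range: tuple[float, float] = (6e6, 9e6)
    alpha_range: tuple[float, float] = (2.0, 3.0)
    background_gamma: float = 0.3
    saturation_k: float = 10.0
    dispersion_phi: float = 0.05
    # copy number: (sample index, contig, start, end, copy ratio)
    cnv_segments: tuple[tuple[int, str, int, int, float], ...] = (
        (0, "chr2", 2_000_000, 6_000_000, 0.5),
    )
    # validation assay
    n_epityper_regions: int = 16
    epityper_noise_sd: float = 0.05
    epityper_missing_rate: float = 0.1
    epityper_units_range: tuple[int, int] = (2, 5)
    plant_qc_violations: bool = False
    # annotation planting
    n_genes: int = 60
    n_enhancers: int = 150
    n_tfs: int = 12
    tf_sites_per_tf: int = 80
    plant_tf: str | None = "TF01"
    plant_tf_fraction: float = 0.3
    plant_enhancer_fraction: float = 0.3
    # guarantees a calibration window at every CpG-count stratum so the
    # noise-free calibration/estimation round trip is exact
    ensure_calibration_coverage: bool = True

    def __post_init__(self) -> None:
        for mix in (self.subtype_mix_wt, self.subtype_mix_mut):
            if abs(sum(mix) - 1.0) > 1e-9 or any(p < 0 for p in mix):
                raise ValueError("subtype mixes must be non-negative and sum to 1")
        if not 0.0 <= self.effect_delta <= 1.0:
            raise ValueError("effect_delta must lie in [0, 1]")
        if self.dispersion_phi <= 0:
            raise ValueError("dispersion_phi must be positive")
        if self.background_gamma < 0:
            raise ValueError("background_gamma must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        def detuple(v):
            if isinstance(v, list):
                return tuple(detuple(x) for x in v)
            return v

        return cls(**{k: detuple(v) for k, v in d.items()})


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort."""

    samples: pd.DataFrame  # id-indexed: genotype, subtype
    true_beta: np.ndarray  # windows x samples
    dmr_windows: np.ndarray  # indices of planted DMRs (hypomethylated in mut)
    dev_lp_ip_windows: np.ndarray
    dev_ip_hp_windows: np.ndarray
    classifier_windows: np.ndarray  # (n_loci, 2) adjacent window pairs
    cnv_segments: pd.DataFrame  # sample, contig, start, end, ratio
    feature_sets: dict[str, FeatureSet]
    tss: pd.DataFrame  # contig, pos, gene
    panel: ClassifierPanel

    @property
    def sample_ids(self) -> list[str]:
        return list(self.samples.index)

    def true_beta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.true_beta, columns=self.sample_ids)

    def copy_ratio(self, grid: WindowGrid) -> np.ndarray:
        """Windows x samples copy-ratio matrix expanded from segments."""
        c = np.ones((grid.n_windows, len(self.samples)))
        sample_pos = {s: j for j, s in enumerate(self.samples.index)}
        for row in self.cnv_segments.itertuples(index=False):
            first, n = grid._offsets[row.contig]
            widx = np.arange(first, first + n)
            sel = (grid.starts[widx] < row.end) & (grid.ends[widx] > row.start)
            c[widx[sel], sample_pos[row.sample]] = row.ratio
        return c


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), int(stream)]))


def _largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    raw = [n * p for p in proportions]
    base = [int(np.floor(x)) for x in raw]
    rem = n - sum(base)
    order = np.argsort([b - x for b, x in zip(base, raw)], kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base


def _simulate_genome(config: SimulationConfig, rng: np.random.Generator):
    cpgs: dict[str, np.ndarray] = {}
    cgi_contig, cgi_start, cgi_end = [], [], []
    for name, length in config.contigs:
        n_cgi = max(1, int(round(length / 1e6 * config.cgi_per_mb)))
        widths = rng.integers(config.cgi_width_range[0], config.cgi_width_range[1] + 1, n_cgi)
        starts = np.sort(rng.integers(0, length - int(widths.max()), n_cgi))
        # drop overlapping islands (keep the earlier one)
        keep_s, keep_e = [], []
        for s, w in zip(starts, widths):
            if keep_e and s < keep_e[-1]:
                continue
            keep_s.append(int(s))
            keep_e.append(int(s + w))
        n_bg = rng.poisson(length * config.cpg_background_rate)
        pos = rng.integers(0, length - 1, n_bg)
        extra = []
        for s, e in zip(keep_s, keep_e):
            n_in = rng.poisson((e - s) * config.cgi_cpg_rate)
            extra.append(rng.integers(s, e, n_in))
        allpos = np.unique(np.concatenate([pos] + extra)) if (len(pos) or extra) else np.array([], np.int64)
        cpgs[name] = allpos
        cgi_contig.extend([name] * len(keep_s))
        cgi_start.extend(keep_s)
        cgi_end.extend(keep_e)
    layout = GenomeLayout(list(config.contigs), cpgs, sex_contigs=config.sex_contigs)
    cgis = FeatureSet(
        "cgis",
        np.array(cgi_contig, dtype=object),
        np.array(cgi_start, dtype=np.int64),
        np.array(cgi_end, dtype=np.int64),
    )
    return layout, cgis


def _simulate_samples(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for genotype, n, mix in (
        ("WT", config.n_wt, config.subtype_mix_wt),
        ("mut", config.n_mut, config.subtype_mix_mut),
    ):
        counts = _largest_remainder(n, mix)
        subtypes = sum(([st] * c for st, c in zip(SUBTYPES, counts)), [])
        subtypes = [subtypes[i] for i in rng.permutation(n)]
        prefix = "WT" if genotype == "WT" else "MU"
        for i, st in enumerate(subtypes):
            rows.append({"sample": f"{prefix}{i + 1:02d}", "genotype": genotype, "subtype": st})
    return pd.DataFrame(rows).set_index("sample")


def _place_features(config: SimulationConfig, layout: GenomeLayout, rng: np.random.Generator):
    """Random genes (with exons), enhancers, TFBS and chromatin states."""
    gene_c, gene_s, gene_e, gene_id = [], [], [], []
    exon_c, exon_s, exon_e, exon_id = [], [], [], []
    tss_rows = []
    gi = 0
    total_len = sum(l for _, l in layout.contigs)
    for name, length in layout.contigs:
        n_here = max(1, int(round(config.n_genes * length / total_len)))
        pos = int(rng.integers(10_000, 100_000))
        placed = 0
        while placed < n_here:
            glen = int(rng.integers(20_000, 80_000))
            if pos + glen >= length - 1000:
                break
            gi += 1
            gid = f"G{gi:04d}"
            gene_c.append(name), gene_s.append(pos), gene_e.append(pos + glen), gene_id.append(gid)
            tss_rows.append({"contig": name, "pos": pos, "gene": gid})
            for _ in range(int(rng.integers(3, 7))):
                es = pos + int(rng.integers(0, glen - 400))
                ew = int(rng.integers(150, 300))
                exon_c.append(name), exon_s.append(es), exon_e.append(es + ew), exon_id.append(gid)
            pos += glen + int(rng.integers(50_000, 200_000))
            placed += 1
    genes = FeatureSet("genes", np.array(gene_c, dtype=object), np.array(gene_s), np.array(gene_e),
                       np.array(gene_id, dtype=object))
    exons = FeatureSet("exons", np.array(exon_c, dtype=object), np.array(exon_s), np.array(exon_e),
                       np.array(exon_id, dtype=object))
    tss = pd.DataFrame(tss_rows)

    def random_sites(n: int, width_lo: int, width_hi: int):
        cs, ss, es = [], [], []
        lens = np.array([l for _, l in layout.contigs], dtype=float)
        probs = lens / lens.sum()
        picks = rng.choice(len(layout.contigs), size=n, p=probs)
        for k in picks:
            name, length = layout.contigs[k]
            w = int(rng.integers(width_lo, width_hi + 1))
            s = int(rng.integers(0, length - w))
            cs.append(name), ss.append(s), es.append(s + w)
        return np.array(cs, dtype=object), np.array(ss, np.int64), np.array(es, np.int64)

    ec, es_, ee = random_sites(config.n_enhancers, 800, 1200)
    enhancers = FeatureSet("enhancers", ec, es_, ee)

    tf_c, tf_s, tf_e, tf_l = [], [], [], []
    for t in range(config.n_tfs):
        cs, ss, es2 = random_sites(config.tf_sites_per_tf, 150, 250)
        tf_c.extend(cs), tf_s.extend(ss), tf_e.extend(es2)
        tf_l.extend([f"TF{t + 1:02d}"] * len(cs))
    tfbs = FeatureSet("tfbs", np.array(tf_c, dtype=object), np.array(tf_s), np.array(tf_e),
                      np.array(tf_l, dtype=object))

    st_c, st_s, st_e, st_l = [], [], [], []
    for name, length in layout.contigs:
        pos = 0
        while pos < length:
            w = int(rng.integers(50_000, 200_000))
            end = min(pos + w, length)
            st_c.append(name), st_s.append(pos), st_e.append(end)
            st_l.append(str(rng.choice(_CHROMATIN_STATES)))
            pos = end
    states = FeatureSet("chromatin_states", np.array(st_c, dtype=object), np.array(st_s),
                        np.array(st_e), np.array(st_l, dtype=object))
    return genes, exons, tss, enhancers, tfbs, states


def simulate_cohort(config: SimulationConfig) -> tuple[GenomeLayout, WindowGrid, CohortTruth]:
    """Build the genome, the cohort and the true methylation landscape."""
    layout, cgis = _simulate_genome(config, _rng(config.seed, 1))
    grid = tile_genome(layout, config.window_size)
    samples = _simulate_samples(config, _rng(config.seed, 2))
    rng = _rng(config.seed, 3)

    analyzable = (grid.cpg_count >= 4) & grid.autosomal_mask()
    analyzable_idx = np.flatnonzero(analyzable)
    n_special = config.n_true_dmrs + config.n_dev_lp_ip + config.n_dev_ip_hp
    if n_special + 2 * config.n_classifier_loci > len(analyzable_idx):
        raise ValueError(
            f"infeasible config: {n_special} planted windows plus classifier loci "
            f"exceed the {len(analyzable_idx)} analyzable windows"
        )

    # classifier loci first: pairs of adjacent analyzable windows
    same_contig = grid.contig_index[:-1] == grid.contig_index[1:]
    pair_ok = analyzable[:-1] & analyzable[1:] & same_contig
    pair_first = np.flatnonzero(pair_ok)
    rng.shuffle(pair_first)
    chosen_pairs: list[int] = []
    used: set[int] = set()
    for w in pair_first:
        if len(chosen_pairs) == config.n_classifier_loci:
            break
        if w in used or (w + 1) in used or (w - 1) in chosen_pairs:
            continue
        chosen_pairs.append(int(w))
        used.update((int(w), int(w + 1)))
    if len(chosen_pairs) < config.n_classifier_loci:
        raise ValueError("not enough adjacent analyzable window pairs for classifier loci")
    classifier_windows = np.array(
        [[w, w + 1] for w in sorted(chosen_pairs)], dtype=np.int64
    ).reshape(-1, 2)

    free = np.setdiff1d(analyzable_idx, np.fromiter(used, dtype=np.int64))
    picks = rng.choice(free, size=n_special, replace=False)
    dmr_windows = np.sort(picks[: config.n_true_dmrs])
    dev_lp_ip = np.sort(picks[config.n_true_dmrs : config.n_true_dmrs + config.n_dev_lp_ip])
    dev_ip_hp = np.sort(picks[config.n_true_dmrs + config.n_dev_lp_ip :])

    # baseline methylation landscape
    W = grid.n_windows
    u = rng.random(W)
    baseline = np.ones(W)
    mid = (u >= config.beta_high_fraction) & (
        u < config.beta_high_fraction + config.beta_mid_fraction
    )
    low = u >= config.beta_high_fraction + config.beta_mid_fraction
    baseline[mid] = rng.uniform(*config.beta_mid_range, size=int(mid.sum()))
    baseline[low] = rng.uniform(*config.beta_low_range, size=int(low.sum()))
    baseline[dmr_windows] = config.dmr_baseline_beta

    # developmental programming: per-window subtype values
    lp_val = baseline.copy()
    ip_val = baseline.copy()
    hp_val = baseline.copy()
    b1 = rng.uniform(*config.dev_baseline_range, size=len(dev_lp_ip))
    lp_val[dev_lp_ip] = b1
    ip_val[dev_lp_ip] = np.clip(b1 + config.dev_shift, 0, 1)
    hp_val[dev_lp_ip] = np.clip(b1 + config.dev_shift, 0, 1)
    b2 = rng.uniform(*config.dev_baseline_range, size=len(dev_ip_hp))
    lp_val[dev_ip_hp] = b2
    ip_val[dev_ip_hp] = b2
    hp_val[dev_ip_hp] = np.clip(b2 + config.dev_shift, 0, 1)
    jitter = rng.uniform(-config.classifier_jitter, config.classifier_jitter,
                         size=config.n_classifier_loci)
    for li, (w1, w2) in enumerate(classifier_windows):
        for arr, base in zip((lp_val, ip_val, hp_val), config.classifier_baselines):
            arr[[w1, w2]] = np.clip(base + jitter[li], 0, 1)

    subtype_vals = {"LP": lp_val, "IP": ip_val, "HP": hp_val}
    true_beta = np.empty((W, len(samples)))
    for j, (sid, row) in enumerate(samples.iterrows()):
        col = subtype_vals[row["subtype"]].copy()
        if row["genotype"] == "mut":
            col[dmr_windows] = np.clip(col[dmr_windows] - config.effect_delta, 0, 1)
        true_beta[:, j] = col

    if config.ensure_calibration_coverage:
        special = np.zeros(W, dtype=bool)
        special[dmr_windows] = True
        special[dev_lp_ip] = True
        special[dev_ip_hp] = True
        special[classifier_windows.ravel()] = True
        fully = np.all(true_beta == 1.0, axis=1)
        for g in np.unique(grid.cpg_count[analyzable]):
            stratum = analyzable & (grid.cpg_count == g)
            if not (stratum & fully).any():
                cand = np.flatnonzero(stratum & ~special)
                if len(cand):
                    true_beta[cand[0], :] = 1.0

    # CNV segments (sample index resolved to id)
    seg_rows = []
    for sidx, contig, start, end, ratio in config.cnv_segments:
        seg_rows.append(
            {
                "sample": samples.index[int(sidx)],
                "contig": contig,
                "start": int(start),
                "end": int(end),
                "ratio": float(ratio),
            }
        )
    cnv_segments = pd.DataFrame(seg_rows, columns=["sample", "contig", "start", "end", "ratio"])

    # annotations
    genes, exons, tss, enhancers, tfbs, states = _place_features(config, layout, _rng(config.seed, 4))
    dmr_fs = grid.as_featureset(dmr_windows, name="true_dmrs")
    if config.plant_tf is not None and len(dmr_windows):
        n_plant = int(np.ceil(config.plant_tf_fraction * len(dmr_windows)))
        plant = dmr_windows[:n_plant]
        tfbs = FeatureSet(
            "tfbs",
            np.concatenate([tfbs.contigs, grid.contig_names[plant]]),
            np.concatenate([tfbs.starts, grid.starts[plant]]),
            np.concatenate([tfbs.ends, grid.ends[plant]]),
            np.concatenate([tfbs.labels, np.full(n_plant, config.plant_tf, dtype=object)]),
        )
    if config.plant_enhancer_fraction > 0 and len(dmr_windows):
        n_plant = int(np.ceil(config.plant_enhancer_fraction * len(dmr_windows)))
        plant = dmr_windows[-n_plant:]
        enhancers = FeatureSet(
            "enhancers",
            np.concatenate([enhancers.contigs, grid.contig_names[plant]]),
            np.concatenate([enhancers.starts, grid.starts[plant]]),
            np.concatenate([enhancers.ends, grid.ends[plant]]),
        )

    loci_fs = FeatureSet(
        "classifier_loci",
        grid.contig_names[classifier_windows[:, 0]],
        grid.starts[classifier_windows[:, 0]],
        grid.ends[classifier_windows[:, 1]],
        np.array([f"L{i + 1:02d}" for i in range(len(classifier_windows))], dtype=object),
    )

    # reference panel: per-subtype locus baselines + small noise
    prng = _rng(config.seed, 5)
    ref_rows, ref_labels = {}, {}
    locus_lp = lp_val[classifier_windows[:, 0]]
    locus_ip = ip_val[classifier_windows[:, 0]]
    locus_hp = hp_val[classifier_windows[:, 0]]
    per_subtype = {"LP": locus_lp, "IP": locus_ip, "HP": locus_hp}
    for st in SUBTYPES:
        for r in range(config.n_reference_per_subtype):
            rid = f"REF_{st}{r + 1:02d}"
            ref_rows[rid] = np.clip(
                per_subtype[st] + prng.normal(0, config.reference_noise_sd, len(loci_fs)), 0, 1
            )
            ref_labels[rid] = st
    ref_betas = pd.DataFrame.from_dict(ref_rows, orient="index",
                                       columns=[f"L{i + 1:02d}" for i in range(len(loci_fs))])
    panel = ClassifierPanel(loci_fs, ref_betas, pd.Series(ref_labels, name="subtype"))

    feature_sets = {
        "cgis": cgis,
        "genes": genes,
        "exons": exons,
        "enhancers": enhancers,
        "tfbs": tfbs,
        "chromatin_states": states,
        "classifier_loci": loci_fs,
        "true_dmrs": dmr_fs,
    }
    truth = CohortTruth(
        samples=samples,
        true_beta=true_beta,
        dmr_windows=dmr_windows,
        dev_lp_ip_windows=dev_lp_ip,
        dev_ip_hp_windows=dev_ip_hp,
        classifier_windows=classifier_windows,
        cnv_segments=cnv_segments,
        feature_sets=feature_sets,
        tss=tss,
        panel=panel,
    )
    return layout, grid, truth


@dataclass
class GenerativeParams:
    """Realized per-sample enrichment parameters of a counts draw."""

    library_size: pd.Series
    alpha: pd.Series
    gamma: float
    saturation_k: float
    dispersion_phi: float


def simulate_counts(
    truth: CohortTruth,
    grid: WindowGrid,
    config: SimulationConfig,
    noise: str = "nb",
) -> tuple[CountMatrix, GenerativeParams]:
    """Draw MeDIP window counts from the generative enrichment model.

    ``noise``: "nb" (negative binomial via gamma-Poisson, variance
    mu + phi mu^2), "poisson", or "none" (counts equal their expectation
    exactly — fractional, used for round-trip identities).
    """
    if truth.true_beta.shape[0] != grid.n_windows:
        raise ValueError("truth and grid are inconsistent")
    rng = _rng(config.seed, 6)
    S = len(truth.samples)
    lib = rng.uniform(*config.library_size_range, size=S)
    alpha = rng.uniform(*config.alpha_range, size=S)
    lam = lib / 1e6
    g = grid.cpg_count.astype(np.float64)
    f = g / (g + config.saturation_k)
    c = truth.copy_ratio(grid)
    mu = lam[None, :] * c * (
        alpha[None, :] * f[:, None] * truth.true_beta + config.background_gamma
    )
    if noise == "none":
        counts = mu
    elif noise == "poisson":
        counts = rng.poisson(mu).astype(np.float64)
    elif noise == "nb":
        r = 1.0 / config.dispersion_phi
        lam_mix = mu * rng.gamma(r, 1.0 / r, size=mu.shape)
        counts = rng.poisson(lam_mix).astype(np.float64)
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    counts_df = pd.DataFrame(counts, columns=truth.sample_ids)
    cm = CountMatrix(counts_df, truth.samples.copy())
    params = GenerativeParams(
        library_size=pd.Series(lib, index=truth.sample_ids),
        alpha=pd.Series(alpha, index=truth.sample_ids),
        gamma=config.background_gamma,
        saturation_k=config.saturation_k,
        dispersion_phi=config.dispersion_phi,
    )
    return cm, params


def simulate_epityper(
    truth: CohortTruth,
    grid: WindowGrid,
    config: SimulationConfig,
    regions: FeatureSet | None = None,
) -> EpiTyperDataset:
    """Per-CpG-unit validation measurements over (by default) DMR windows.

    Unit values are the true regional methylation plus Gaussian noise
    clipped to [0, 1], missing completely at random at the configured rate.
    With ``plant_qc_violations`` the first amplicon receives three planted
    units: one failing the 50%-presence rule, one spanning 4 CpGs, and one
    sharing that unit's fragment mass (a mass collision pair).
    """
    rng = _rng(config.seed, 7)
    if regions is None:
        take = truth.dmr_windows[: config.n_epityper_regions]
        regions = grid.as_featureset(take, name="epityper_regions")
    sample_ids = truth.sample_ids
    # true regional beta: mean over overlapped windows
    from .intervals import overlap as _ov

    hits = _ov(regions, grid, min_overlap=1)
    rows, values = [], []
    unit_no = 0
    for ri in range(len(regions)):
        widx = hits.loc[hits["query_idx"] == ri, "feature_idx"].to_numpy()
        if len(widx) == 0:
            continue
        true_b = truth.true_beta[widx].mean(axis=0)
        amp = f"R{ri + 1:02d}"
        n_units = int(rng.integers(*config.epityper_units_range))
        masses: set[float] = set()
        for _ in range(n_units):
            mass = round(float(rng.uniform(1500, 7000)), 1)
            while mass in masses:
                mass = round(float(rng.uniform(1500, 7000)), 1)
            masses.add(mass)
            unit_no += 1
            vals = np.clip(true_b + rng.normal(0, config.epityper_noise_sd, len(sample_ids)), 0, 1)
            miss = rng.random(len(sample_ids)) < config.epityper_missing_rate
            vals = np.where(miss, np.nan, vals)
            rows.append(
                {
                    "amplicon": amp,
                    "unit": f"U{unit_no:03d}",
                    "contig": regions.contigs[ri],
                    "start": int(regions.starts[ri]),
                    "end": int(regions.ends[ri]),
                    "mass_da": mass,
                    "n_cpgs": int(rng.integers(1, 4)),
                }
            )
            values.append(vals)
        if config.plant_qc_violations and ri == 0:
            base = dict(contig=regions.contigs[0], start=int(regions.starts[0]),
                        end=int(regions.ends[0]))
            # (i) low coverage: values in fewer than half the samples
            vals = np.clip(true_b + rng.normal(0, config.epityper_noise_sd, len(sample_ids)), 0, 1)
            n_keep = max(1, len(sample_ids) // 2 - 1)
            vals[n_keep:] = np.nan
            rows.append({"amplicon": amp, "unit": "BAD_COVERAGE", "mass_da": 9000.0,
                         "n_cpgs": 2, **base})
            values.append(vals)
            # (iii) too many CpGs, sharing a mass with the next unit -> (ii)
            for uname, ncpg in (("BAD_CPGS", 4), ("BAD_MASS", 2)):
                vals = np.clip(true_b + rng.normal(0, config.epityper_noise_sd, len(sample_ids)), 0, 1)
                rows.append({"amplicon": amp, "unit": uname, "mass_da": 9100.0,
                             "n_cpgs": ncpg, **base})
                values.append(vals)
    units = pd.DataFrame(rows, columns=["amplicon", "unit", "contig", "start", "end",
                                        "mass_da", "n_cpgs"])
    vals_df = pd.DataFrame(np.vstack(values), columns=sample_ids)
    return EpiTyperDataset(units, vals_df)


def simulate_de_table(truth: CohortTruth, config: SimulationConfig) -> pd.DataFrame:
    """A differential-expression result table (gene, log2fc, fdr).

    Consumed — never fitted — by the enhancer-to-gene linking stage; about
    30% of genes are made significant at FDR < 0.05.
    """
    rng = _rng(config.seed, 8)
    genes = truth.feature_sets["genes"].labels
    n = len(genes)
    fdr = rng.uniform(0, 1, n)
    sig = rng.random(n) < 0.3
    fdr[sig] = rng.uniform(0, 0.049, int(sig.sum()))
    return pd.DataFrame(
        {"gene": genes, "log2fc": rng.normal(0, 1.5, n), "fdr": fdr}
    )


def simulate_external_classes(
    truth: CohortTruth, grid: WindowGrid, config: SimulationConfig
) -> pd.DataFrame:
    """External CpG catalog with classes A-D and methylation directions.

    Classes mimic published cell-of-origin catalogs: A/B are B-cell
    developmental sites (hypo-/hypermethylated during maturation), C/D are
    disease-specific sites.  A handful of class-B records are planted
    inside true DMR windows so overlap counting has signal.
    """
    rng = _rng(config.seed, 9)
    rows = []
    spec = {"A": (60, "hypo"), "B": (20, "hyper"), "C": (40, "hypo"), "D": (20, "hyper")}
    autosomes = truth.feature_sets["genes"]  # reuse contig universe
    names = grid.layout.autosomes
    for klass, (n, direction) in spec.items():
        for _ in range(n):
            contig = str(rng.choice(names))
            pos = int(rng.integers(0, grid.layout.length_of(contig) - 2))
            rows.append({"contig": contig, "pos": pos, "class": klass, "direction": direction})
    # plant 8 class-B records inside DMR windows
    for w in truth.dmr_windows[:8]:
        rows.append(
            {
                "contig": str(grid.contig_names[w]),
                "pos": int(grid.starts[w]) + 10,
                "class": "B",
                "direction": "hyper",
            }
        )
    return pd.DataFrame(rows)


def write_cohort(
    outdir: str | Path,
    layout: GenomeLayout,
    grid: WindowGrid,
    truth: CohortTruth,
    counts: CountMatrix | None = None,
    config: SimulationConfig | None = None,
) -> None:
    """Persist the full fixture as plain-text files under one directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_contig_lengths(layout, outdir / "contigs.tsv")
    write_cpg_positions(layout, outdir / "cpgs.bed")
    truth.samples.to_csv(outdir / "samples.tsv", sep="\t", index_label="sample")
    truth.true_beta_frame().to_csv(outdir / "true_beta.tsv", sep="\t",
                                   index_label="window", float_format="%.6g")
    truth.cnv_segments.to_csv(outdir / "cnv_truth.tsv", sep="\t", index=False)
    feat_dir = outdir / "features"
    feat_dir.mkdir(exist_ok=True)
    for name, fs in truth.feature_sets.items():
        fs.to_bed(feat_dir / f"{name}.bed")
    truth.tss.to_csv(outdir / "tss.tsv", sep="\t", index=False)
    truth.panel.to_files(
        outdir / "panel_loci.bed", outdir / "panel_betas.tsv", outdir / "panel_labels.tsv"
    )
    if counts is not None:
        counts.to_tsv(outdir / "counts.tsv", outdir / "samples.tsv")
    if config is not None:
        config.to_yaml(outdir / "config.yaml")
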