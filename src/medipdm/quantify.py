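"""MeDIP window counts -> calibrated methylation (beta) values and CNV tracks.

MeDIP read density in a window scales with both methylation and local CpG
density, so raw counts are not comparable across windows.  The model here
is an explicit, invertible contract: the expected library-normalized count
at a window with g CpGs is

    E[y/lambda] = (E(g) - gamma) * beta + gamma

where gamma is the per-sample background rate (normalized depth at
CpG-free windows, i.e. antibody-independent carry-over) and E(g) is the
per-sample enrichment profile — the expected normalized depth of a *fully
methylated* window with g CpGs.  E(g) is estimated nonparametrically from
highly methylated calibration regions (per-CpG-count means followed by
weighted isotonic regression), so no parametric enrichment curve is
assumed; beta follows by background subtraction and profile division,
clipped to [0, 1].

Copy number is estimated independently of methylation from CpG-free
windows only: their counts carry no immunoprecipitation signal, so depth
ratios across samples in large (default 2 Mb) bins reflect copy ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .intervals import FeatureSet, GenomeLayout, WindowGrid

__all__ = [
    "CountMatrix",
    "CalibrationModel",
    "CnvTrack",
    "count_reads_in_windows",
    "filter_analyzable",
    "select_calibration_windows",
    "fit_calibration",
    "estimate_beta",
    "estimate_cnv",
]


@dataclass
class CountMatrix:
    """Windows x samples MeDIP read counts plus sample metadata.

    ``counts`` rows are aligned to a :class:`WindowGrid` (integer window
    index); columns are sample ids.  ``meta`` is indexed by sample id and
    carries at least a ``genotype`` column with values in
    ``{"WT", "mut", "unknown"}`` (optionally ``ighv``).  ``library_scale``
    is counts-per-million over *all* windows: lambda_s = total counts / 1e6.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    library_scale: pd.Series | None = None

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(pd.Index(self.meta.index)):
            if set(self.counts.columns) != set(self.meta.index):
                raise ValueError("counts columns and metadata index disagree")
            self.meta = self.meta.loc[self.counts.columns]
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.library_scale is None:
            self.library_scale = self.counts.sum(axis=0) / 1e6
        else:
            self.library_scale = self.library_scale.loc[self.counts.columns]
        if (self.library_scale <= 0).any():
            bad = list(self.library_scale.index[self.library_scale <= 0])
            raise ValueError(f"non-positive library scale for samples {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_windows(self) -> int:
        return len(self.counts)

    def genotype_groups(self) -> tuple[np.ndarray, np.ndarray]:
        """(WT column positions, mut column positions)."""
        geno = self.meta["genotype"].to_numpy()
        return np.flatnonzero(geno == "WT"), np.flatnonzero(geno == "mut")

    def normalized(self) -> np.ndarray:
        """counts / lambda_s, float64 array."""
        return self.counts.to_numpy(dtype=np.float64) / self.library_scale.to_numpy()

    def to_tsv(self, counts_path: str | Path, meta_path: str | Path | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="window")
        if meta_path is not None:
            self.meta.to_csv(meta_path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, counts_path: str | Path, meta_path: str | Path) -> "CountMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col="window")
        meta = pd.read_csv(meta_path, sep="\t", index_col="sample")
        return cls(counts, meta)


def count_reads_in_windows(
    reads: Mapping[str, tuple[Sequence[str], Sequence[int], Sequence[int]]],
    grid: WindowGrid,
    meta: pd.DataFrame,
) -> CountMatrix:
    """Assign each read to the single window containing its midpoint.

    ``reads`` maps sample id to (contigs, starts, ends) arrays of aligned
    read intervals (BED-style, 0-based half-open).  A sample with zero
    reads is an error; lambda_s is set to assigned reads / 1e6.
    """
    data = {}
    name_to_idx = {n: i for i, n in enumerate(grid.layout.names)}
    for sample, (contigs, starts, ends) in reads.items():
        contigs = np.asarray(contigs, dtype=str)
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if len(starts) == 0:
            raise ValueError(f"sample {sample} has zero reads")
        unknown = set(np.unique(contigs)) - set(name_to_idx)
        if unknown:
            raise ValueError(f"reads on unknown contigs: {sorted(unknown)}")
        counts = np.zeros(grid.n_windows, dtype=np.int64)
        mid = (starts + ends) // 2
        for contig in np.unique(contigs):
            sel = contigs == contig
            first, n = grid._offsets[contig]
            k = mid[sel] // grid.window_size
            if (k < 0).any() or (k >= n).any():
                raise ValueError(f"read midpoint outside contig {contig}")
            counts[first : first + n] += np.bincount(k, minlength=n)
        data[sample] = counts
    counts_df = pd.DataFrame(data, index=np.arange(grid.n_windows))
    return CountMatrix(counts_df, meta)


def filter_analyzable(
    grid: WindowGrid, layout: GenomeLayout | None = None, min_cpg: int = 4
) -> np.ndarray:
    """Analyzability mask: CpG count >= ``min_cpg`` and autosomal.

    Windows with an expected CpG density below 4 per 250-bp fragment and
    all windows on sex contigs are excluded from methylation analysis.
    """
    layout = layout or grid.layout
    return (grid.cpg_count >= min_cpg) & grid.autosomal_mask()


def select_calibration_windows(
    reference_betas: pd.DataFrame | np.ndarray,
    min_meth: float = 0.8,
    min_sample_frac: float = 0.95,
    candidate_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Window indices that are highly methylated in a reference cohort.

    A window qualifies iff beta > ``min_meth`` (strict) in at least
    ``min_sample_frac`` of the reference samples.  Missing values count as
    failures.  In synthetic closed-loop runs the simulator's true beta
    matrix plays the role of the external reference.
    """
    values = np.asarray(reference_betas, dtype=np.float64)
    if values.size == 0:
        raise ValueError("reference beta matrix is empty")
    frac = np.mean(np.nan_to_num(values, nan=-1.0) > min_meth, axis=1)
    sel = frac >= min_sample_frac
    if candidate_mask is not None:
        sel &= np.asarray(candidate_mask, dtype=bool)
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        raise ValueError(
            "no calibration windows selected: no window exceeds "
            f"beta > {min_meth} in >= {min_sample_frac:.0%} of reference samples"
        )
    return idx


@dataclass
class CalibrationModel:
    """Per-sample background gamma_s and enrichment profile E_s(g).

    ``profile`` is tabulated at the unique CpG counts present among the
    calibration windows and is monotone non-decreasing in g after weighted
    isotonic smoothing; evaluation at other g interpolates linearly and
    clamps at the tabulated range ends.
    """

    gamma: pd.Series  # per sample
    g_grid: np.ndarray  # unique CpG counts (ascending)
    profile: pd.DataFrame  # g_grid x samples, normalized depth at beta = 1
    calibration_windows: np.ndarray = field(default_factory=lambda: np.array([], dtype=np.int64))
    bin_support: np.ndarray | None = None  # calibration windows per g stratum

    def enrichment(self, sample: str, g: np.ndarray) -> np.ndarray:
        """E_s evaluated at CpG counts ``g`` (clamped linear interpolation)."""
        return np.interp(np.asarray(g, dtype=np.float64), self.g_grid,
                         self.profile[sample].to_numpy())

    def enrichment_matrix(self, g: np.ndarray) -> pd.DataFrame:
        """E_s(g) for every sample: len(g) x samples."""
        out = {s: self.enrichment(s, g) for s in self.profile.columns}
        return pd.DataFrame(out)

    def to_tsv(self, gamma_path: str | Path, profile_path: str | Path) -> None:
        self.gamma.rename("gamma").to_csv(gamma_path, sep="\t", index_label="sample")
        prof = self.profile.copy()
        prof.insert(0, "cpg_count", self.g_grid)
        prof.to_csv(profile_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, gamma_path: str | Path, profile_path: str | Path) -> "CalibrationModel":
        gamma = pd.read_csv(gamma_path, sep="\t", index_col="sample")["gamma"]
        prof = pd.read_csv(profile_path, sep="\t")
        g = prof.pop("cpg_count").to_numpy()
        return cls(gamma, g, prof)


def fit_calibration(
    counts: CountMatrix,
    grid: WindowGrid,
    calibration_windows: np.ndarray,
    min_windows_per_bin: int = 1,
) -> CalibrationModel:
    """Fit background and enrichment profile from highly methylated windows.

    gamma_s is the mean normalized count over CpG-free autosomal windows.
    E_s(g) is the mean normalized count of calibration windows grouped by
    exact CpG count, then smoothed by isotonic regression weighted by the
    number of windows per CpG-count stratum.  The isotonic fit pools sparse
    strata with their neighbors whenever noise makes them non-monotone,
    which stabilizes them without destroying the exact noise-free round
    trip; ``min_windows_per_bin`` > 1 additionally forces adjacent strata
    to be merged until each holds that many windows.
    """
    calibration_windows = np.asarray(calibration_windows, dtype=np.int64)
    if len(calibration_windows) == 0:
        raise ValueError("empty calibration window set")
    norm = counts.normalized()
    if not norm.any():
        raise ValueError("all counts are zero; cannot calibrate")
    zero_cpg = np.flatnonzero((grid.cpg_count == 0) & grid.autosomal_mask())
    if len(zero_cpg) == 0:
        raise ValueError("no CpG-free autosomal windows; background undefined")
    gamma = pd.Series(
        norm[zero_cpg].mean(axis=0), index=counts.sample_ids, name="gamma"
    )

    g_calib = grid.cpg_count[calibration_windows]
    g_grid, inverse, bin_n = np.unique(g_calib, return_inverse=True, return_counts=True)
    # per-stratum mean normalized count, each sample
    sums = np.zeros((len(g_grid), norm.shape[1]))
    np.add.at(sums, inverse, norm[calibration_windows])
    means = sums / bin_n[:, None]

    if min_windows_per_bin > 1:
        g_grid, means, bin_n = _merge_sparse_bins(g_grid, means, bin_n, min_windows_per_bin)

    profile = {}
    for j, sample in enumerate(counts.sample_ids):
        iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
        fitted = iso.fit_transform(g_grid.astype(float), means[:, j], sample_weight=bin_n)
        profile[sample] = fitted
    profile_df = pd.DataFrame(profile)
    return CalibrationModel(
        gamma, np.asarray(g_grid), profile_df, calibration_windows, bin_n.astype(np.int64)
    )


def _merge_sparse_bins(g_grid, means, bin_n, min_n):
    """Greedy left-to-right merge of CpG-count strata below ``min_n`` windows."""
    g_out, m_out, n_out = [], [], []
    acc_w, acc_m, acc_g = 0, None, 0.0
    for g, m, n in zip(g_grid, means, bin_n):
        if acc_w == 0:
            acc_m, acc_g, acc_w = m * n, float(g) * n, n
        else:
            acc_m = acc_m + m * n
            acc_g += float(g) * n
            acc_w += n
        if acc_w >= min_n:
            g_out.append(acc_g / acc_w)
            m_out.append(acc_m / acc_w)
            n_out.append(acc_w)
            acc_w = 0
    if acc_w:  # trailing sparse bin merged into the last emitted one
        if g_out:
            tot = n_out[-1] + acc_w
            m_out[-1] = (m_out[-1] * n_out[-1] + acc_m) / tot
            g_out[-1] = (g_out[-1] * n_out[-1] + acc_g) / tot
            n_out[-1] = tot
        else:
            g_out, m_out, n_out = [acc_g / acc_w], [acc_m / acc_w], [acc_w]
    return np.array(g_out), np.vstack(m_out), np.array(n_out)


def estimate_beta(
    counts: CountMatrix,
    model: CalibrationModel,
    grid: WindowGrid,
    mask: np.ndarray,
    clip: bool = True,
) -> pd.DataFrame:
    """Calibrated methylation estimates, NaN outside the analyzable mask.

    beta_hat = clip((y/lambda - gamma_s) / (E_s(g) - gamma_s), 0, 1).

    With ``clip=False`` raw (possibly out-of-range) per-sample estimates are
    returned; averaging those across samples *before* clipping gives
    unbiased window-level methylation even at fully (un)methylated windows,
    where per-sample clipping would bias the mean inward.
    """
    mask = np.asarray(mask, dtype=bool)
    widx = np.flatnonzero(mask)
    norm = counts.normalized()
    g = grid.cpg_count[widx]
    beta = np.full((grid.n_windows, len(counts.sample_ids)), np.nan)
    for j, sample in enumerate(counts.sample_ids):
        denom = model.enrichment(sample, g) - model.gamma[sample]
        if (denom <= 0).any():
            bad_g = sorted(set(g[denom <= 0].tolist()))
            raise ValueError(
                f"degenerate calibration for sample {sample}: "
                f"E(g) <= gamma at CpG counts {bad_g[:5]}"
            )
        est = (norm[widx, j] - model.gamma[sample]) / denom
        beta[widx, j] = np.clip(est, 0.0, 1.0) if clip else est
    return pd.DataFrame(beta, index=np.arange(grid.n_windows), columns=counts.sample_ids)


@dataclass
class CnvTrack:
    """Per-sample log2 copy-ratio over large autosomal bins.

    Ratios derive exclusively from CpG-free windows (no methylation
    signal), normalized per sample and referenced to the cross-sample
    median of each bin.  NaN where a bin holds no CpG-free window.
    """

    bins: FeatureSet
    log2_ratio: pd.DataFrame  # bins x samples

    def calls(self, threshold: float = 0.4) -> pd.DataFrame:
        """Advisory gain/loss calls at |log2 ratio| > ``threshold``."""
        lr = self.log2_ratio
        out = pd.DataFrame("neutral", index=lr.index, columns=lr.columns)
        out = out.mask(lr > threshold, "gain").mask(lr < -threshold, "loss")
        return out.mask(lr.isna(), "missing")

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "contig": self.bins.contigs,
                "start": self.bins.starts,
                "end": self.bins.ends,
            }
        )
        out = pd.concat([df, self.log2_ratio.reset_index(drop=True)], axis=1)
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def estimate_cnv(
    counts: CountMatrix,
    grid: WindowGrid,
    layout: GenomeLayout | None = None,
    bin_size: int = 2_000_000,
) -> CnvTrack:
    """Copy-number track from CpG-free fragments in large autosomal bins.

    Per sample: sum counts of zero-CpG windows per bin, divide by the
    sample's total zero-CpG count, and take log2 against the cross-sample
    median of the bin.  Requires >= 3 samples for a robust median.
    """
    layout = layout or grid.layout
    if len(counts.sample_ids) < 3:
        raise ValueError("CNV estimation needs at least 3 samples")
    zero = (grid.cpg_count == 0) & grid.autosomal_mask()
    if not zero.any():
        raise ValueError("grid has no CpG-free autosomal windows")

    bin_contig, bin_start, bin_end = [], [], []
    bin_of_window = np.full(grid.n_windows, -1, dtype=np.int64)
    nbin = 0
    for name in layout.autosomes:
        length = layout.length_of(name)
        first, nwin = grid._offsets[name]
        n = -(-length // bin_size)
        starts = np.arange(n, dtype=np.int64) * bin_size
        bin_contig.extend([name] * n)
        bin_start.extend(starts.tolist())
        bin_end.extend(np.minimum(starts + bin_size, length).tolist())
        widx = np.arange(first, first + nwin)
        mids = (grid.starts[widx] + grid.ends[widx]) // 2
        bin_of_window[widx] = nbin + mids // bin_size
        nbin += n

    zidx = np.flatnonzero(zero)
    zbin = bin_of_window[zidx]
    raw = counts.counts.to_numpy(dtype=np.float64)
    per_bin = np.zeros((nbin, len(counts.sample_ids)))
    np.add.at(per_bin, zbin, raw[zidx])
    has_zero = np.zeros(nbin, dtype=bool)
    has_zero[np.unique(zbin)] = True

    totals = per_bin.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("a sample has zero counts at CpG-free windows")
    frac = per_bin / totals
    with np.errstate(divide="ignore", invalid="ignore"):
        ref = np.median(frac, axis=1)
        log2 = np.log2(frac / ref[:, None])
    log2[~has_zero] = np.nan
    log2[ref == 0] = np.nan
    bins = FeatureSet(
        "cnv_bins",
        np.array(bin_contig, dtype=object),
        np.array(bin_start, dtype=np.int64),
        np.array(bin_end, dtype=np.int64),
    )
    return CnvTrack(bins, pd.DataFrame(log2, columns=counts.sample_ids))
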