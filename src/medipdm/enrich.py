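"""Genomic-context annotation and enrichment statistics for DMRs.

The enrichment unit is the 250-bp window and the universe is the set of
analyzable (tested) windows.  For each feature class a 2x2 table — DMR
status x feature overlap (>= 1 bp) — yields a Fisher exact two-sided p and
an odds ratio (with the Haldane-Anscombe +0.5 correction when a cell is
zero); Benjamini-Hochberg adjustment runs within each batch of features
tested together (genomic features, transcription factors, chromatin
states), and significance stars follow the usual convention
(* < 0.05, ** < 0.01, *** < 0.001, **** < 0.0001, ns otherwise).

Also here: chromosomal DMR density with optional CpG-island correction
(chi-squared goodness of fit), subtelomeric proximity summaries at 5/10/15
Mb cutoffs (exact binomial against the background fraction), linking of
enhancer DMRs to differentially expressed genes within 1 Mb of their
promoter, and selection of the most variable CpG-island windows (the PCA
input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import bh_adjust
from .intervals import (
    FeatureSet,
    GenomeLayout,
    WindowGrid,
    distances_to_nearest_end,
    overlap,
    overlap_mask,
)

__all__ = [
    "ContingencyResult",
    "significance_stars",
    "feature_enrichment",
    "enrichment_batch",
    "tf_enrichment",
    "annotate_dmrs",
    "chromosome_density",
    "subtelomere_summary",
    "link_enhancer_dmrs",
    "most_variable_cgi_windows",
]


def significance_stars(q: float) -> str:
    if not np.isfinite(q) or q >= 0.05:
        return "ns"
    for cut, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*")):
        if q < cut:
            return stars
    return "*"


@dataclass
class ContingencyResult:
    """2x2 window-level enrichment of a feature among DMRs.

    a: DMR windows overlapping the feature; b: DMR windows not overlapping;
    c: non-DMR background windows overlapping; d: the rest.  ``odds_ratio``
    is ad/bc, +0.5 in every cell when any cell is zero.
    """

    feature: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float = np.nan

    @property
    def stars(self) -> str:
        return significance_stars(self.q)

    def as_row(self) -> dict:
        return {
            "feature": self.feature,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "odds_ratio": self.odds_ratio,
            "p": self.p,
            "q": self.q,
            "stars": self.stars,
        }


def _contingency(
    dmr_windows: np.ndarray, background: np.ndarray, in_feature: np.ndarray, name: str
) -> ContingencyResult:
    is_dmr = np.isin(background, dmr_windows)
    a = int(np.sum(is_dmr & in_feature))
    b = int(np.sum(is_dmr & ~in_feature))
    c = int(np.sum(~is_dmr & in_feature))
    d = int(np.sum(~is_dmr & ~in_feature))
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return ContingencyResult(name, a, b, c, d, float(orr), float(p))


def feature_enrichment(
    dmr_windows: np.ndarray,
    background: np.ndarray,
    feature: FeatureSet,
    grid: WindowGrid,
    min_overlap: int = 1,
) -> ContingencyResult:
    """Fisher exact enrichment of one feature set among DMR windows."""
    background = np.asarray(background, dtype=np.int64)
    dmr_windows = np.asarray(dmr_windows, dtype=np.int64)
    if len(background) == 0:
        raise ValueError("empty background window set")
    if not np.isin(dmr_windows, background).all():
        raise ValueError("DMR windows must be a subset of the background")
    in_feat = overlap_mask(grid.as_featureset(background), feature, min_overlap=min_overlap)
    return _contingency(dmr_windows, background, in_feat, feature.name)


def enrichment_batch(
    dmr_windows: np.ndarray,
    background: np.ndarray,
    features: dict[str, FeatureSet],
    grid: WindowGrid,
) -> pd.DataFrame:
    """One ContingencyResult per feature set, BH-adjusted within the batch."""
    results = [
        feature_enrichment(dmr_windows, background, fs, grid) for name, fs in features.items()
    ]
    q = bh_adjust(np.array([r.p for r in results]))
    for r, qi in zip(results, q):
        r.q = float(qi)
    return pd.DataFrame([r.as_row() for r in results])


def tf_enrichment(
    dmr_windows: np.ndarray,
    background: np.ndarray,
    tfbs: FeatureSet,
    grid: WindowGrid,
) -> pd.DataFrame:
    """Per-transcription-factor enrichment, BH across TFs, ordered by odds ratio.

    A TF without any binding site overlapping the background is skipped
    (reported with NaN statistics and a notice column).
    """
    if tfbs.labels is None:
        raise ValueError("TFBS feature set needs per-site TF labels")
    background = np.asarray(background, dtype=np.int64)
    bg_fs = grid.as_featureset(background)
    results, skipped = [], []
    for tf in sorted(set(tfbs.labels.tolist())):
        sites = tfbs.subset(np.flatnonzero(tfbs.labels == tf))
        in_feat = overlap_mask(bg_fs, sites)
        if not in_feat.any():
            skipped.append(tf)
            continue
        results.append(_contingency(np.asarray(dmr_windows, np.int64), background, in_feat, tf))
    q = bh_adjust(np.array([r.p for r in results]))
    for r, qi in zip(results, q):
        r.q = float(qi)
    df = pd.DataFrame([r.as_row() for r in results])
    if len(df):
        df = df.sort_values("odds_ratio", ascending=False, kind="stable").reset_index(drop=True)
    df.attrs["skipped"] = skipped
    return df


def annotate_dmrs(
    dmr_windows: np.ndarray,
    features: dict[str, FeatureSet],
    grid: WindowGrid,
    layout: GenomeLayout,
    promoters: FeatureSet | None = None,
) -> pd.DataFrame:
    """Per-DMR genomic-context flags at 1-bp overlap.

    Mandatory feature sets: ``genes`` and ``cgis``.  A window inside a gene
    but outside every exon is intronic; a distal CGI is any CGI outside the
    promoter regions; shore and island are disjoint by construction of
    :func:`medipdm.intervals.cgi_shores`.  The distance to the nearest
    chromosome end is attached for subtelomere summaries.
    """
    for mandatory in ("genes", "cgis"):
        if mandatory not in features:
            raise ValueError(f"annotation requires a {mandatory!r} feature set")
    dmr_windows = np.asarray(dmr_windows, dtype=np.int64)
    dmr_fs = grid.as_featureset(dmr_windows)

    genes = features["genes"]
    cgis = features["cgis"]
    gene_body = overlap_mask(dmr_fs, genes)
    exon = overlap_mask(dmr_fs, features["exons"]) if "exons" in features else np.zeros(len(dmr_windows), bool)
    exon &= gene_body
    intron = gene_body & ~exon
    cgi = overlap_mask(dmr_fs, cgis)

    out = pd.DataFrame(
        {
            "gene_body": gene_body,
            "exon": exon,
            "intron": intron,
            "cgi": cgi,
        },
        index=pd.Index(dmr_windows, name="window"),
    )
    if promoters is not None:
        out["promoter"] = overlap_mask(dmr_fs, promoters)
        distal_idx = np.flatnonzero(~overlap_mask(cgis, promoters))
        out["distal_cgi"] = overlap_mask(dmr_fs, cgis.subset(distal_idx)) if len(distal_idx) else False
    if "cgi_shores" in features:
        out["cgi_shore"] = overlap_mask(dmr_fs, features["cgi_shores"])
    if "enhancers" in features:
        out["enhancer"] = overlap_mask(dmr_fs, features["enhancers"])
    if "tfbs" in features and features["tfbs"].labels is not None:
        tfbs = features["tfbs"]
        hits = overlap(dmr_fs, tfbs)
        tf_names = []
        for i in range(len(dmr_windows)):
            labs = tfbs.labels[hits.loc[hits["query_idx"] == i, "feature_idx"].to_numpy()]
            tf_names.append(",".join(sorted(set(labs.tolist()))))
        out["tfbs"] = tf_names
    if "chromatin_states" in features and features["chromatin_states"].labels is not None:
        st = features["chromatin_states"]
        hits = overlap(dmr_fs, st)
        labels = []
        for i in range(len(dmr_windows)):
            labs = st.labels[hits.loc[hits["query_idx"] == i, "feature_idx"].to_numpy()]
            labels.append(",".join(sorted(set(labs.tolist()))))
        out["chromatin_state"] = labels
    out["dist_to_chrom_end"] = distances_to_nearest_end(dmr_fs, layout)
    return out


def chromosome_density(
    dmr_windows: np.ndarray,
    background: np.ndarray,
    grid: WindowGrid,
    correction: str = "none",
    cgis: FeatureSet | None = None,
) -> tuple[pd.DataFrame, float, float]:
    """Observed vs expected DMRs per contig with a chi-squared fit test.

    Expected counts are proportional to the analyzable windows per contig,
    or — with ``correction="cgi"`` — to the CGI-overlapping analyzable
    windows, which deflates the expectation of CpG-poor contigs.  Contigs
    with expected < 1 are dropped from the statistic (expected counts are
    renormalized over the kept contigs).
    """
    dmr_windows = np.asarray(dmr_windows, dtype=np.int64)
    background = np.asarray(background, dtype=np.int64)
    if correction not in ("none", "cgi"):
        raise ValueError("correction must be 'none' or 'cgi'")
    if correction == "cgi":
        if cgis is None:
            raise ValueError("cgi correction needs a CGI feature set")
        in_cgi = overlap_mask(grid.as_featureset(background), cgis)
        weight_windows = background[in_cgi]
    else:
        weight_windows = background

    names = np.array(grid.layout.names, dtype=object)
    obs_contig = names[grid.contig_index[dmr_windows]]
    bg_contig = names[grid.contig_index[weight_windows]]
    contigs = [c for c in grid.layout.names if (bg_contig == c).any() or (obs_contig == c).any()]
    if len(contigs) < 2:
        raise ValueError("chromosome density needs >= 2 contigs with tested windows")
    obs = np.array([(obs_contig == c).sum() for c in contigs], dtype=float)
    weights = np.array([(bg_contig == c).sum() for c in contigs], dtype=float)
    if weights.sum() == 0:
        raise ValueError("background weights are all zero")
    expected = weights / weights.sum() * obs.sum()
    keep = expected >= 1.0
    o, w = obs[keep], weights[keep]
    e = w / w.sum() * o.sum()
    statistic = float(np.sum((o - e) ** 2 / e))
    pval = float(stats.chi2.sf(statistic, df=max(int(keep.sum()) - 1, 1)))
    table = pd.DataFrame(
        {"contig": contigs, "observed": obs.astype(int), "expected": expected, "kept": keep}
    )
    return table, statistic, pval


def subtelomere_summary(
    dmr_windows: np.ndarray,
    background: np.ndarray,
    grid: WindowGrid,
    layout: GenomeLayout | None = None,
    cutoffs: tuple[int, ...] = (5_000_000, 10_000_000, 15_000_000),
) -> pd.DataFrame:
    """DMR proximity to chromosome ends at each distance cutoff.

    A window falls in the subtelomeric zone of a cutoff when its distance
    to the nearest contig end is <= the cutoff.  The DMR fraction is
    compared to the background fraction with an exact binomial test.
    Fractions are monotone non-decreasing in the cutoff by construction.
    """
    layout = layout or grid.layout
    dmr_windows = np.asarray(dmr_windows, dtype=np.int64)
    background = np.asarray(background, dtype=np.int64)
    half_max = max(l for _, l in layout.contigs) / 2
    d_dmr = distances_to_nearest_end(grid.as_featureset(dmr_windows), layout)
    d_bg = distances_to_nearest_end(grid.as_featureset(background), layout)
    rows = []
    for cutoff in cutoffs:
        if cutoff > half_max:
            warnings.warn(
                f"cutoff {cutoff} exceeds half the longest contig; start/end zones overlap"
            )
        k = int((d_dmr <= cutoff).sum())
        bg_frac = float((d_bg <= cutoff).mean()) if len(background) else np.nan
        if len(dmr_windows) and 0.0 < bg_frac < 1.0:
            p = float(stats.binomtest(k, len(dmr_windows), bg_frac).pvalue)
        elif len(dmr_windows) and bg_frac in (0.0, 1.0):
            p = 1.0 if (k / len(dmr_windows)) == bg_frac else 0.0
        else:
            p = np.nan
        rows.append(
            {
                "cutoff_bp": cutoff,
                "n_dmrs": len(dmr_windows),
                "n_within": k,
                "fraction": k / len(dmr_windows) if len(dmr_windows) else np.nan,
                "background_fraction": bg_frac,
                "binomial_p": p,
            }
        )
    return pd.DataFrame(rows)


def link_enhancer_dmrs(
    dmr_windows: np.ndarray,
    grid: WindowGrid,
    enhancers: FeatureSet,
    tss: pd.DataFrame,
    de_genes: pd.DataFrame,
    max_dist: int = 1_000_000,
    de_fdr: float = 0.05,
) -> pd.DataFrame:
    """Link enhancer-overlapping DMRs to nearby differentially expressed genes.

    A link is a pair (DMR overlapping an enhancer, gene) where the gene's
    expression FDR < ``de_fdr`` (no fold-change threshold) and the distance
    from the DMR midpoint to the gene's TSS is <= ``max_dist``.
    """
    if "fdr" not in de_genes.columns:
        raise ValueError("DE table lacks an 'fdr' column")
    dmr_windows = np.asarray(dmr_windows, dtype=np.int64)
    dmr_fs = grid.as_featureset(dmr_windows)
    in_enh = overlap_mask(dmr_fs, enhancers)
    sig = de_genes[de_genes["fdr"] < de_fdr].set_index("gene")
    tss_sig = tss[tss["gene"].isin(sig.index)]
    rows = []
    for i in np.flatnonzero(in_enh):
        w = dmr_windows[i]
        contig = grid.contig_names[w]
        mid = (int(grid.starts[w]) + int(grid.ends[w])) // 2
        near = tss_sig[tss_sig["contig"] == contig]
        dist = (near["pos"] - mid).abs()
        for gene, d in dist[dist <= max_dist].groupby(near["gene"]).min().items():
            rows.append(
                {
                    "window": int(w),
                    "region": grid.window(int(w)).region_id,
                    "gene": gene,
                    "distance_bp": int(d),
                    "de_fdr": float(sig.loc[gene, "fdr"]),
                    "de_log2fc": float(sig.loc[gene, "log2fc"]) if "log2fc" in sig else np.nan,
                }
            )
    return pd.DataFrame(rows, columns=["window", "region", "gene", "distance_bp", "de_fdr", "de_log2fc"])


def most_variable_cgi_windows(
    betas: pd.DataFrame,
    grid: WindowGrid,
    cgis: FeatureSet,
    n: int = 1000,
    candidate_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Top-``n`` CGI-overlapping windows by across-sample beta variance.

    Ties (and the ordering generally) are broken by genomic order, so the
    output is deterministic.  Returns fewer than ``n`` windows with a
    warning when not enough candidates exist.
    """
    values = betas.to_numpy(dtype=float)
    have = ~np.isnan(values).all(axis=1)
    if candidate_mask is not None:
        have &= np.asarray(candidate_mask, dtype=bool)
    cand = np.flatnonzero(have)
    in_cgi = overlap_mask(grid.as_featureset(cand), cgis)
    cand = cand[in_cgi]
    if len(cand) == 0:
        warnings.warn("no CGI-overlapping windows with beta values")
        return cand
    var = np.nanvar(values[cand], axis=1, ddof=1)
    order = np.lexsort((cand, -var))  # variance desc, genomic order tie-break
    if len(cand) < n:
        warnings.warn(f"only {len(cand)} CGI windows available (requested {n})")
        return cand[order]
    return cand[order[:n]]
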