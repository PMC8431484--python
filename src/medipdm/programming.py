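"""B-cell epigenetic programming: subtype assignment and DMR decomposition.

CLL methylomes retain the programming state of the B cell of origin; three
subtypes — low- (LP), intermediate- (IP) and high-programmed (HP) — are
distinguished by methylation at a fixed panel of classifier loci.  Query
samples are assigned by clustering them jointly with a labeled reference
cohort (Euclidean distance, complete linkage, tree cut at three clusters;
clusters inherit the majority label of their reference members, with a
nearest-reference-centroid fallback for clusters that contain no reference
sample).

Differentially methylated regions are then decomposed into
development-related vs. mutation-specific classes: a DMR whose methylation
shifts by at least ``delta`` (default 0.20, absolute beta, inclusive)
between LP and IP wild-type samples follows the normal maturation program;
likewise for IP vs. HP; everything else is ``stable``, i.e. attributable to
the mutation itself rather than to the cell of origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .intervals import FeatureSet, WindowGrid, overlap

__all__ = [
    "SUBTYPES",
    "ClassifierPanel",
    "SubtypeAssignment",
    "locus_betas",
    "assign_subtypes",
    "programming_decomposition",
    "overlap_external_classes",
]

SUBTYPES = ("LP", "IP", "HP")


@dataclass
class ClassifierPanel:
    """Classifier loci plus a labeled reference beta matrix.

    ``loci`` is the interval panel (18 loci in the standard set);
    ``reference_betas`` is reference-samples x loci; ``reference_labels``
    maps each reference sample to LP/IP/HP.  Each subtype must be
    represented by at least two reference samples.
    """

    loci: FeatureSet
    reference_betas: pd.DataFrame
    reference_labels: pd.Series

    def __post_init__(self) -> None:
        if not self.reference_betas.index.equals(pd.Index(self.reference_labels.index)):
            if set(self.reference_betas.index) != set(self.reference_labels.index):
                raise ValueError("reference beta rows and labels disagree")
            self.reference_labels = self.reference_labels.loc[self.reference_betas.index]
        bad = set(self.reference_labels) - set(SUBTYPES)
        if bad:
            raise ValueError(f"unknown subtype labels: {sorted(bad)}")
        counts = self.reference_labels.value_counts()
        for st in SUBTYPES:
            if counts.get(st, 0) < 2:
                raise ValueError(f"subtype {st} has fewer than 2 reference samples")
        if self.reference_betas.shape[1] != len(self.loci):
            raise ValueError("reference beta columns must align with loci")

    @property
    def locus_names(self) -> list[str]:
        return list(self.reference_betas.columns)

    def to_files(self, loci_bed: str | Path, betas_tsv: str | Path, labels_tsv: str | Path) -> None:
        self.loci.to_bed(loci_bed)
        self.reference_betas.to_csv(betas_tsv, sep="\t", index_label="sample")
        self.reference_labels.rename("subtype").to_csv(labels_tsv, sep="\t", index_label="sample")

    @classmethod
    def from_files(cls, loci_bed, betas_tsv, labels_tsv) -> "ClassifierPanel":
        loci = FeatureSet.from_bed(loci_bed, name="classifier_loci")
        betas = pd.read_csv(betas_tsv, sep="\t", index_col="sample")
        labels = pd.read_csv(labels_tsv, sep="\t", index_col="sample")["subtype"]
        return cls(loci, betas, labels)


@dataclass
class SubtypeAssignment:
    """Sample -> subtype labels plus clustering provenance."""

    labels: pd.Series  # sample -> LP/IP/HP
    cluster_of: pd.Series  # sample -> cluster id (query samples only)
    centroid_distance: pd.DataFrame  # samples x subtypes, Euclidean
    fallback_samples: tuple[str, ...] = ()

    def tally(self, genotype: pd.Series | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"subtype": self.labels})
        if genotype is not None:
            df["genotype"] = genotype.loc[df.index]
            return df.groupby(["genotype", "subtype"]).size().unstack(fill_value=0)
        return df.value_counts("subtype").to_frame("n")


def locus_betas(
    betas: pd.DataFrame,
    grid: WindowGrid,
    loci: FeatureSet,
    min_overlap: int = 145,
) -> pd.DataFrame:
    """Per-locus methylation: mean beta of the grid bins overlapping a locus.

    Only bins overlapping the locus by at least ``min_overlap`` bp (145 bp,
    i.e. more than half a 250-bp bin) contribute; the locus value is the
    mean of the qualifying bins' beta values per sample.  NaN where no bin
    qualifies or all qualifying bins are NaN.
    """
    hits = overlap(loci, grid, min_overlap=min_overlap)
    locus_labels = (
        loci.labels
        if loci.labels is not None
        else np.array([f"L{i + 1:02d}" for i in range(len(loci))], dtype=object)
    )
    values = np.full((len(betas.columns), len(loci)), np.nan)
    bmat = betas.to_numpy()
    for li in range(len(loci)):
        bins = hits.loc[hits["query_idx"] == li, "feature_idx"].to_numpy()
        if len(bins) == 0:
            continue
        with np.errstate(invalid="ignore"):
            values[:, li] = np.nanmean(bmat[bins], axis=0)
    out = pd.DataFrame(values, index=betas.columns, columns=locus_labels)
    empty = out.index[out.isna().all(axis=1)]
    if len(empty):
        raise ValueError(f"all loci missing for samples {list(empty)}")
    return out


def assign_subtypes(query: pd.DataFrame, panel: ClassifierPanel) -> SubtypeAssignment:
    """Assign LP/IP/HP by joint clustering with the reference cohort.

    Query and reference rows are clustered together (Euclidean distance,
    complete linkage), the tree is cut into three clusters and each cluster
    is labeled by the majority subtype of its reference members.  A query
    landing in a cluster without any reference sample falls back to the
    nearest reference-subtype centroid.
    """
    ref = panel.reference_betas
    if list(query.columns) != list(ref.columns):
        if set(query.columns) != set(ref.columns):
            raise ValueError("query loci do not match panel loci")
        query = query[ref.columns]
    frac_missing = query.isna().mean(axis=0)
    bad = frac_missing.index[frac_missing > 0.5]
    if len(bad):
        raise ValueError(f"loci missing in >50% of query samples: {list(bad)}")
    # impute residual missing locus values with the reference mean
    query = query.fillna(ref.mean(axis=0))

    combined = pd.concat([query, ref], axis=0)
    z = linkage(combined.to_numpy(), method="complete", metric="euclidean")
    clusters = fcluster(z, t=3, criterion="maxclust")
    is_query = np.arange(len(combined)) < len(query)

    centroids = ref.groupby(panel.reference_labels).mean().reindex(list(SUBTYPES))
    qarr = query.to_numpy()
    dist = pd.DataFrame(
        {st: np.linalg.norm(qarr - centroids.loc[st].to_numpy(), axis=1) for st in SUBTYPES},
        index=query.index,
    )

    cluster_label: dict[int, str] = {}
    for cid in np.unique(clusters):
        ref_members = panel.reference_labels.to_numpy()[clusters[~is_query] == cid]
        if len(ref_members):
            vals, counts = np.unique(ref_members, return_counts=True)
            winners = sorted(vals[counts == counts.max()])
            cluster_label[cid] = winners[0]

    labels = {}
    fallback = []
    for i, sample in enumerate(query.index):
        cid = clusters[i]
        if cid in cluster_label:
            labels[sample] = cluster_label[cid]
        else:
            labels[sample] = dist.loc[sample].idxmin()
            fallback.append(sample)
    return SubtypeAssignment(
        labels=pd.Series(labels, name="subtype"),
        cluster_of=pd.Series(clusters[: len(query)], index=query.index, name="cluster"),
        centroid_distance=dist,
        fallback_samples=tuple(fallback),
    )


def programming_decomposition(
    dmr_betas: pd.DataFrame,
    subtype: pd.Series,
    genotype: pd.Series,
    delta: float = 0.20,
) -> pd.DataFrame:
    """Classify each DMR as development-related or mutation-specific.

    ``dmr_betas`` is DMR windows x samples.  Deltas are later-stage minus
    earlier-stage means among wild-type samples (IP - LP, HP - IP), so a
    developmental gain of methylation is positive.  Classes:

    - ``development_LP_IP`` if |IP - LP| >= delta (wild type),
    - else ``development_IP_HP`` if |HP - IP| >= delta (wild type, only
      evaluable when wild-type HP samples exist),
    - else ``stable`` — the methylation difference is genotype-specific.

    The mutant LP->IP delta is reported alongside for contrast.
    """
    samples = dmr_betas.columns
    subtype = subtype.loc[samples]
    genotype = genotype.loc[samples]

    def group_cols(st: str, gt: str) -> np.ndarray:
        return np.flatnonzero((subtype.to_numpy() == st) & (genotype.to_numpy() == gt))

    wt_lp, wt_ip, wt_hp = (group_cols(st, "WT") for st in SUBTYPES)
    mut_lp, mut_ip = group_cols("LP", "mut"), group_cols("IP", "mut")
    if len(wt_lp) == 0 or len(wt_ip) == 0:
        raise ValueError("decomposition requires wild-type samples in both LP and IP")

    arr = dmr_betas.to_numpy()

    def gmean(cols):
        if len(cols) == 0:
            return np.full(arr.shape[0], np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(arr[:, cols], axis=1)

    d_lp_ip_wt = gmean(wt_ip) - gmean(wt_lp)
    d_ip_hp_wt = gmean(wt_hp) - gmean(wt_ip)
    d_lp_ip_mut = gmean(mut_ip) - gmean(mut_lp)

    cls = np.where(
        np.abs(d_lp_ip_wt) >= delta,
        "development_LP_IP",
        np.where(
            ~np.isnan(d_ip_hp_wt) & (np.abs(d_ip_hp_wt) >= delta),
            "development_IP_HP",
            "stable",
        ),
    )
    return pd.DataFrame(
        {
            "delta_lp_ip_wt": d_lp_ip_wt,
            "delta_ip_hp_wt": d_ip_hp_wt,
            "delta_lp_ip_mut": d_lp_ip_mut,
            "klass": cls,
            "delta_threshold": delta,
        },
        index=dmr_betas.index,
    )


def overlap_external_classes(
    dmrs: FeatureSet,
    external: pd.DataFrame,
    dmr_direction: str | np.ndarray = "hypo",
) -> pd.DataFrame:
    """Overlap DMRs with an external per-CpG/region class catalog.

    ``external`` needs ``contig`` plus either ``pos`` (a single CpG) or
    ``start``/``end`` columns, a ``class`` column, and optionally a
    ``direction`` column ("hyper"/"hypo": the methylation change of the
    site during normal development or in disease).  Returns one row per
    class: the number of DMRs overlapping at least one record, the DMR
    fraction, and — where directions are given — the fraction of overlap
    pairs whose directions are concordant.  A hypomethylated DMR pairs
    concordantly with an external "hyper" site (loss in the mutant of
    methylation that is normally gained), and vice versa.
    """
    external = external.copy()
    if "pos" in external.columns and "start" not in external.columns:
        external["start"] = external["pos"].astype(int)
        external["end"] = external["start"] + 1
    for col in ("contig", "start", "end", "class"):
        if col not in external.columns:
            raise ValueError(f"external table lacks column {col!r}")
    bad = external.index[
        (external["start"].astype(float) < 0)
        | (external["end"].astype(float) <= external["start"].astype(float))
    ]
    if len(bad):
        raise ValueError(f"malformed coordinates in external table rows {list(bad[:5])}")

    if isinstance(dmr_direction, str):
        dmr_dir = np.full(len(dmrs), dmr_direction, dtype=object)
    else:
        dmr_dir = np.asarray(dmr_direction, dtype=object)

    ext_fs = FeatureSet(
        "external",
        external["contig"].to_numpy(dtype=object),
        external["start"].to_numpy(dtype=np.int64),
        external["end"].to_numpy(dtype=np.int64),
    )
    hits = overlap(dmrs, ext_fs, min_overlap=1) if len(dmrs) and len(ext_fs) else None

    rows = []
    classes = sorted(external["class"].astype(str).unique())
    for klass in classes:
        kidx = np.flatnonzero(external["class"].astype(str).to_numpy() == klass)
        if hits is not None and len(hits):
            sub = hits[np.isin(hits["feature_idx"].to_numpy(), kidx)]
        else:
            sub = pd.DataFrame({"query_idx": [], "feature_idx": []})
        n_dmrs = sub["query_idx"].nunique()
        concord = np.nan
        if "direction" in external.columns and len(sub):
            ext_dir = external["direction"].to_numpy(dtype=object)[
                sub["feature_idx"].to_numpy(dtype=int)
            ]
            dd = dmr_dir[sub["query_idx"].to_numpy(dtype=int)]
            known = pd.notna(ext_dir)
            if known.any():
                opposite = (dd[known] == "hypo") & (ext_dir[known] == "hyper") | (
                    dd[known] == "hyper"
                ) & (ext_dir[known] == "hypo")
                concord = float(np.mean(opposite))
        rows.append(
            {
                "class": klass,
                "n_records": len(kidx),
                "n_dmrs_overlapping": int(n_dmrs),
                "dmr_fraction": (n_dmrs / len(dmrs)) if len(dmrs) else 0.0,
                "direction_concordance": concord,
            }
        )
    return pd.DataFrame(rows)
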