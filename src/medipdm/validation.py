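"""Bisulfite mass-spectrometry (EpiTYPER-style) QC and concordance checks.

EpiTYPER quantifies methylation of CpG *units* — one or more CpGs sharing
a cleavage fragment — within PCR amplicons.  Units are unreliable when the
fragment mass is ambiguous or too many CpGs share a fragment, so a unit is
excluded when

- (i)   fewer than 50% of samples yielded a value (exactly 50% is kept),
- (ii)  another unit in the same amplicon has an identical fragment mass
        (all colliding units are dropped; masses compare equal after
        rounding to 0.1 Da), or
- (iii) the unit spans more than 3 CpGs.

Region-level methylation is the per-sample mean of the retained units, and
concordance with the sequencing-based beta estimates is summarized by a
Pearson correlation over all complete (region, sample) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EpiTyperDataset",
    "epityper_qc",
    "region_means",
    "concordance",
    "group_difference_table",
]

REASON_LOW_COVERAGE = "low_coverage"
REASON_MASS_COLLISION = "mass_collision"
REASON_TOO_MANY_CPGS = "too_many_cpgs"


@dataclass
class EpiTyperDataset:
    """Per-CpG-unit methylation values.

    ``units`` has one row per unit: ``amplicon`` (the region id),
    ``unit`` (unique unit id), ``contig``/``start``/``end`` (the amplicon
    interval), ``mass_da`` and ``n_cpgs``.  ``values`` aligns row-wise with
    ``units``; columns are sample ids; entries are methylation fractions in
    [0, 1] or NaN for failed measurements.
    """

    units: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.units) != len(self.values):
            raise ValueError("units and values are not aligned")
        v = self.values.to_numpy(dtype=float)
        finite = np.isfinite(v)
        if ((v[finite] < 0) | (v[finite] > 1)).any():
            raise ValueError("unit methylation values must lie in [0, 1]")
        if (self.units["n_cpgs"] < 1).any():
            raise ValueError("units must span at least one CpG")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        out = pd.concat(
            [self.units.reset_index(drop=True), self.values.reset_index(drop=True)], axis=1
        )
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EpiTyperDataset":
        df = pd.read_csv(path, sep="\t")
        unit_cols = ["amplicon", "unit", "contig", "start", "end", "mass_da", "n_cpgs"]
        sample_cols = [c for c in df.columns if c not in unit_cols]
        return cls(df[unit_cols], df[sample_cols])


def epityper_qc(data: EpiTyperDataset) -> tuple[EpiTyperDataset, pd.DataFrame]:
    """Apply the three unit exclusion rules.

    Returns the retained dataset and an exclusion log with one row per
    dropped unit listing every violated rule (comma-joined).  The operation
    is idempotent: re-applying it to the retained set drops nothing.
    """
    if len(data.values.columns) < 1:
        raise ValueError("dataset has no samples")
    units = data.units.reset_index(drop=True)
    values = data.values.reset_index(drop=True)
    n_samples = values.shape[1]

    reasons: list[list[str]] = [[] for _ in range(len(units))]

    present_frac = values.notna().sum(axis=1) / n_samples
    for i in np.flatnonzero((present_frac < 0.5).to_numpy()):
        reasons[i].append(REASON_LOW_COVERAGE)

    rounded = units["mass_da"].astype(float).round(1)
    key = pd.DataFrame({"amp": units["amplicon"], "mass": rounded})
    dup = key.duplicated(keep=False)
    for i in np.flatnonzero(dup.to_numpy()):
        reasons[i].append(REASON_MASS_COLLISION)

    for i in np.flatnonzero((units["n_cpgs"] > 3).to_numpy()):
        reasons[i].append(REASON_TOO_MANY_CPGS)

    drop = np.array([bool(r) for r in reasons])
    log = pd.DataFrame(
        {
            "amplicon": units.loc[drop, "amplicon"].to_numpy(),
            "unit": units.loc[drop, "unit"].to_numpy(),
            "reason": [",".join(r) for r, d in zip(reasons, drop) if d],
        }
    )
    retained = EpiTyperDataset(units[~drop].reset_index(drop=True), values[~drop].reset_index(drop=True))
    return retained, log


def region_means(data: EpiTyperDataset) -> pd.DataFrame:
    """Region (amplicon) x sample means over retained unit values.

    NaN where a sample has no value at any retained unit of the region.
    """
    merged = data.values.copy()
    merged["__amp"] = data.units["amplicon"].to_numpy()
    return merged.groupby("__amp").mean().rename_axis("region")


def concordance(
    pipeline_betas: pd.DataFrame, epityper_means: pd.DataFrame
) -> tuple[float, float, int]:
    """Pearson correlation between platform estimates over complete pairs.

    Both inputs are region x sample matrices; only regions and samples
    present in both are paired.  Returns (r, two-sided p, n pairs); fewer
    than 3 complete pairs is an error.
    """
    regions = pipeline_betas.index.intersection(epityper_means.index)
    samples = pipeline_betas.columns.intersection(epityper_means.columns)
    a = pipeline_betas.loc[regions, samples].to_numpy(dtype=float).ravel()
    b = epityper_means.loc[regions, samples].to_numpy(dtype=float).ravel()
    ok = np.isfinite(a) & np.isfinite(b)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 complete (region, sample) pairs")
    r, p = stats.pearsonr(a[ok], b[ok])
    return float(r), float(p), n


def group_difference_table(
    epityper_means: pd.DataFrame,
    pipeline_betas: pd.DataFrame,
    genotype: pd.Series,
) -> pd.DataFrame:
    """Per-region mutant-minus-wild-type mean difference on each platform.

    Used for the platform-concordance scatter of group effects; both inputs
    are region x sample.  Requires both genotypes among the shared samples.
    """
    regions = epityper_means.index.intersection(pipeline_betas.index)
    samples = epityper_means.columns.intersection(pipeline_betas.columns)
    geno = genotype.loc[samples]
    wt = samples[geno.to_numpy() == "WT"]
    mut = samples[geno.to_numpy() == "mut"]
    if len(wt) == 0 or len(mut) == 0:
        raise ValueError("both genotypes must be present among validated samples")
    return pd.DataFrame(
        {
            "delta_epityper": epityper_means.loc[regions, mut].mean(axis=1)
            - epityper_means.loc[regions, wt].mean(axis=1),
            "delta_pipeline": pipeline_betas.loc[regions, mut].mean(axis=1)
            - pipeline_betas.loc[regions, wt].mean(axis=1),
        },
        index=regions,
    )
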