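"""Genome layout, fixed-width window grids and interval arithmetic.

All coordinates are 0-based, half-open ``[start, end)``, in base pairs —
internally and in every BED file this package reads or writes.  Human
readable region ids are rendered 1-based inclusive (``chrom:start+1-end``)
for display only and are never parsed back.

The window grid is the unit of every downstream analysis: fixed-width
(default 250 bp) windows tile each contig, the final window of a contig is
truncated at the contig end (kept, not discarded), and each window carries
the exact count of CpG dinucleotide starts falling inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Interval",
    "GenomeLayout",
    "WindowGrid",
    "FeatureSet",
    "tile_genome",
    "overlap",
    "overlap_mask",
    "distance_to_nearest_end",
    "distances_to_nearest_end",
    "promoter_regions",
    "cgi_shores",
    "read_contig_lengths",
    "write_contig_lengths",
    "read_cpg_positions",
    "write_cpg_positions",
]


@dataclass(frozen=True)
class Interval:
    """A 0-based half-open genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    @property
    def region_id(self) -> str:
        """1-based inclusive display id."""
        return f"{self.contig}:{self.start + 1}-{self.end}"


class GenomeLayout:
    """Contig lengths, CpG dinucleotide positions and sex-contig exclusions.

    Parameters
    ----------
    contigs
        Ordered ``(name, length)`` pairs.
    cpg_positions
        Per-contig sorted array of 0-based CpG start positions.  Contigs
        without an entry are treated as CpG-free.
    sex_contigs
        Contig names excluded from differential testing and CNV binning
        (e.g. ``{"chrX", "chrY"}``).
    """

    def __init__(
        self,
        contigs: Sequence[tuple[str, int]],
        cpg_positions: Mapping[str, Iterable[int]] | None = None,
        sex_contigs: Iterable[str] = (),
    ) -> None:
        if not contigs:
            raise ValueError("genome layout needs at least one contig")
        self.contigs: list[tuple[str, int]] = [(str(n), int(l)) for n, l in contigs]
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names")
        for name, length in self.contigs:
            if length <= 0:
                raise ValueError(f"contig {name} has non-positive length")
        self._lengths = dict(self.contigs)
        cpg_positions = cpg_positions or {}
        unknown = set(cpg_positions) - set(names)
        if unknown:
            raise ValueError(f"CpG positions on unknown contigs: {sorted(unknown)}")
        self.cpg_positions: dict[str, np.ndarray] = {}
        for name, _ in self.contigs:
            pos = np.asarray(list(cpg_positions.get(name, ())), dtype=np.int64)
            if pos.size:
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"CpG positions on {name} not strictly increasing")
                if pos[0] < 0 or pos[-1] >= self._lengths[name]:
                    raise ValueError(f"CpG position outside contig {name}")
            self.cpg_positions[name] = pos
        self.sex_contigs = frozenset(str(c) for c in sex_contigs)
        if not self.sex_contigs <= set(names):
            raise ValueError("sex_contigs contains unknown contig names")

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    @property
    def autosomes(self) -> list[str]:
        return [n for n, _ in self.contigs if n not in self.sex_contigs]

    def length_of(self, contig: str) -> int:
        try:
            return self._lengths[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None

    def __contains__(self, contig: str) -> bool:
        return contig in self._lengths

    def validate_interval(self, contig: str, start: int, end: int) -> None:
        length = self.length_of(contig)
        if not (0 <= start < end <= length):
            raise ValueError(
                f"interval {contig}:{start}-{end} outside contig of length {length}"
            )


@dataclass
class FeatureSet:
    """A named collection of intervals with optional per-interval labels.

    Labels carry the transcription-factor name, chromatin-state name, gene
    id or sub-feature tag; strand is deliberately absent (MeDIP enrichment
    is strand-symmetric and all overlaps here are strand-agnostic).
    """

    name: str
    contigs: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.contigs = np.asarray(self.contigs, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.contigs) == len(self.starts) == len(self.ends)):
            raise ValueError("feature arrays have inconsistent lengths")
        if np.any(self.starts < 0) or np.any(self.ends <= self.starts):
            raise ValueError(f"feature set {self.name!r} has invalid intervals")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.starts):
                raise ValueError("labels must align 1:1 with intervals")

    @classmethod
    def from_intervals(
        cls,
        name: str,
        intervals: Iterable[Interval | tuple[str, int, int]],
        labels: Iterable[str] | None = None,
    ) -> "FeatureSet":
        contigs, starts, ends = [], [], []
        for iv in intervals:
            if isinstance(iv, Interval):
                contigs.append(iv.contig), starts.append(iv.start), ends.append(iv.end)
            else:
                c, s, e = iv
                contigs.append(c), starts.append(int(s)), ends.append(int(e))
        lab = None if labels is None else list(labels)
        return cls(name, np.array(contigs, dtype=object), np.array(starts or [0][:0]),
                   np.array(ends or [0][:0]), None if lab is None else np.array(lab, dtype=object))

    def __len__(self) -> int:
        return len(self.starts)

    def interval(self, i: int) -> Interval:
        return Interval(str(self.contigs[i]), int(self.starts[i]), int(self.ends[i]))

    def subset(self, index: np.ndarray | Sequence[int]) -> "FeatureSet":
        idx = np.asarray(index)
        return FeatureSet(
            self.name,
            self.contigs[idx],
            self.starts[idx],
            self.ends[idx],
            None if self.labels is None else self.labels[idx],
        )

    def validate_against(self, layout: GenomeLayout) -> None:
        for c, s, e in zip(self.contigs, self.starts, self.ends):
            layout.validate_interval(str(c), int(s), int(e))

    def sorted_by_position(self, layout: GenomeLayout | None = None) -> "FeatureSet":
        if layout is not None:
            order_key = {n: i for i, n in enumerate(layout.names)}
            contig_rank = np.array([order_key[str(c)] for c in self.contigs])
        else:
            contig_rank = self.contigs.astype(str)
        idx = np.lexsort((self.starts, contig_rank))
        return self.subset(idx)

    def to_bed(self, path: str | Path) -> None:
        """Write BED3 (unlabeled) or BED6 (labeled) with deterministic order."""
        with open(path, "w") as fh:
            for i in range(len(self)):
                if self.labels is None:
                    fh.write(f"{self.contigs[i]}\t{self.starts[i]}\t{self.ends[i]}\n")
                else:
                    fh.write(
                        f"{self.contigs[i]}\t{self.starts[i]}\t{self.ends[i]}"
                        f"\t{self.labels[i]}\t0\t.\n"
                    )

    @classmethod
    def from_bed(cls, path: str | Path, name: str | None = None) -> "FeatureSet":
        contigs, starts, ends, labels = [], [], [], []
        any_label = False
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                contigs.append(parts[0])
                starts.append(int(parts[1]))
                ends.append(int(parts[2]))
                if len(parts) > 3:
                    labels.append(parts[3])
                    any_label = True
                else:
                    labels.append("")
        return cls(
            name or Path(path).stem,
            np.array(contigs, dtype=object),
            np.array(starts, dtype=np.int64),
            np.array(ends, dtype=np.int64),
            np.array(labels, dtype=object) if any_label else None,
        )


@dataclass
class WindowGrid:
    """Fixed-width windows tiling every contig of a layout.

    ``cpg_count`` holds the exact per-window CpG count g_w, the CpG-density
    covariate of the enrichment calibration and the analyzability filter.
    """

    layout: GenomeLayout
    window_size: int
    contig_index: np.ndarray  # per-window index into layout.names
    starts: np.ndarray
    ends: np.ndarray
    cpg_count: np.ndarray
    _offsets: dict[str, tuple[int, int]] = field(default_factory=dict)  # name -> (first, count)

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def __len__(self) -> int:
        return self.n_windows

    @property
    def contig_names(self) -> np.ndarray:
        names = np.array(self.layout.names, dtype=object)
        return names[self.contig_index]

    def window(self, i: int) -> Interval:
        return Interval(
            self.layout.names[self.contig_index[i]], int(self.starts[i]), int(self.ends[i])
        )

    def ids(self) -> np.ndarray:
        names = self.contig_names
        return np.array(
            [f"{c}:{s}-{e}" for c, s, e in zip(names, self.starts, self.ends)],
            dtype=object,
        )

    def autosomal_mask(self) -> np.ndarray:
        sex = {self.layout.names.index(c) for c in self.layout.sex_contigs}
        return ~np.isin(self.contig_index, list(sex)) if sex else np.ones(self.n_windows, bool)

    def window_of(self, contig: str, pos: int) -> int:
        """Global index of the window containing ``pos`` on ``contig``."""
        first, count = self._offsets[contig]
        k = int(pos) // self.window_size
        if not 0 <= k < count:
            raise ValueError(f"position {pos} outside contig {contig}")
        return first + k

    def contig_slice(self, contig: str) -> slice:
        first, count = self._offsets[contig]
        return slice(first, first + count)

    def as_featureset(self, index: np.ndarray | None = None, name: str = "windows") -> FeatureSet:
        if index is None:
            index = np.arange(self.n_windows)
        index = np.asarray(index)
        return FeatureSet(
            name, self.contig_names[index], self.starts[index], self.ends[index]
        )

    def to_bed(self, path: str | Path) -> None:
        self.as_featureset().to_bed(path)


def tile_genome(layout: GenomeLayout, window_size: int = 250) -> WindowGrid:
    """Tile each contig with adjacent ``window_size`` windows.

    The final window of a contig is truncated at the contig end and kept;
    it is only ever removed later by the CpG-density filter.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    ci, starts, ends, cpg = [], [], [], []
    offsets: dict[str, tuple[int, int]] = {}
    first = 0
    for idx, (name, length) in enumerate(layout.contigs):
        n = -(-length // window_size)  # ceil division
        s = np.arange(n, dtype=np.int64) * window_size
        e = np.minimum(s + window_size, length)
        pos = layout.cpg_positions[name]
        counts = np.bincount(pos // window_size, minlength=n) if pos.size else np.zeros(n, np.int64)
        ci.append(np.full(n, idx, dtype=np.int32))
        starts.append(s)
        ends.append(e)
        cpg.append(counts.astype(np.int64))
        offsets[name] = (first, n)
        first += n
    return WindowGrid(
        layout,
        window_size,
        np.concatenate(ci),
        np.concatenate(starts),
        np.concatenate(ends),
        np.concatenate(cpg),
        offsets,
    )


def _as_arrays(obj) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(obj, FeatureSet):
        return obj.contigs.astype(str), obj.starts, obj.ends
    if isinstance(obj, WindowGrid):
        return obj.contig_names.astype(str), obj.starts, obj.ends
    contigs, starts, ends = obj
    return (
        np.asarray(contigs, dtype=str),
        np.asarray(starts, dtype=np.int64),
        np.asarray(ends, dtype=np.int64),
    )


def overlap(
    query,
    features,
    min_overlap: int = 1,
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """All (query, feature) pairs whose intersection spans >= ``min_overlap`` bp.

    Returns a DataFrame with columns ``query_idx``, ``feature_idx``,
    ``overlap_bp``, ordered by query then feature index.  When ``layout``
    is given, intervals on unknown contigs raise ``ValueError``.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    qc, qs, qe = _as_arrays(query)
    fc, fs, fe = _as_arrays(features)
    if layout is not None:
        for arr in (qc, fc):
            unknown = set(np.unique(arr)) - set(layout.names)
            if unknown:
                raise ValueError(f"intervals on unknown contigs: {sorted(unknown)}")
    out_q, out_f, out_o = [], [], []
    if len(qs) and len(fs):
        for contig in np.unique(qc):
            qi = np.flatnonzero(qc == contig)
            fi = np.flatnonzero(fc == contig)
            if not len(fi):
                continue
            # chunked dense scan; sizes here are modest (<= ~10^4 x 10^4)
            chunk = max(1, 4_000_000 // len(fi))
            for lo in range(0, len(qi), chunk):
                qq = qi[lo : lo + chunk]
                ov = np.minimum(qe[qq][:, None], fe[fi][None, :]) - np.maximum(
                    qs[qq][:, None], fs[fi][None, :]
                )
                hit_q, hit_f = np.nonzero(ov >= min_overlap)
                out_q.append(qq[hit_q])
                out_f.append(fi[hit_f])
                out_o.append(ov[hit_q, hit_f])
    if out_q:
        df = pd.DataFrame(
            {
                "query_idx": np.concatenate(out_q),
                "feature_idx": np.concatenate(out_f),
                "overlap_bp": np.concatenate(out_o).astype(np.int64),
            }
        )
        df = df.sort_values(["query_idx", "feature_idx"], kind="stable").reset_index(drop=True)
    else:
        df = pd.DataFrame(
            {
                "query_idx": np.array([], dtype=np.int64),
                "feature_idx": np.array([], dtype=np.int64),
                "overlap_bp": np.array([], dtype=np.int64),
            }
        )
    return df


def overlap_mask(query, features, min_overlap: int = 1) -> np.ndarray:
    """Boolean per-query flag: overlaps any feature by >= ``min_overlap`` bp."""
    qc, qs, qe = _as_arrays(query)
    hits = overlap(query, features, min_overlap=min_overlap)
    mask = np.zeros(len(qs), dtype=bool)
    mask[np.unique(hits["query_idx"].to_numpy())] = True
    return mask


def distance_to_nearest_end(iv: Interval, layout: GenomeLayout) -> int:
    """Distance (bp) from the interval to the closer contig end; 0 if touching."""
    length = layout.length_of(iv.contig)
    layout.validate_interval(iv.contig, iv.start, iv.end)
    return min(iv.start, length - iv.end)


def distances_to_nearest_end(features, layout: GenomeLayout) -> np.ndarray:
    fc, fs, fe = _as_arrays(features)
    lengths = np.array([layout.length_of(str(c)) for c in fc], dtype=np.int64)
    return np.minimum(fs, lengths - fe)


def promoter_regions(
    tss: Iterable[tuple[str, int, str]] | pd.DataFrame,
    layout: GenomeLayout,
    flank: int = 2000,
) -> FeatureSet:
    """Promoters as symmetric ``flank`` bp around each TSS, clipped to contig bounds.

    The default 2 kb flank makes the promoter a 4-kb window centered on the
    TSS; strand does not matter because the flank is symmetric.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    if isinstance(tss, pd.DataFrame):
        rows = list(tss[["contig", "pos", "gene"]].itertuples(index=False, name=None))
    else:
        rows = list(tss)
    contigs, starts, ends, labels = [], [], [], []
    for contig, pos, gene in rows:
        length = layout.length_of(str(contig))
        if not 0 <= pos < length:
            raise ValueError(f"TSS {contig}:{pos} outside contig")
        contigs.append(str(contig))
        starts.append(max(0, int(pos) - flank))
        ends.append(min(length, int(pos) + flank))
        labels.append(str(gene))
    return FeatureSet(
        "promoters",
        np.array(contigs, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        np.array(labels, dtype=object),
    )


def _merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if not len(starts):
        return starts, ends
    order = np.argsort(starts, kind="stable")
    ms, me = [], []
    for s, e in zip(starts[order], ends[order]):
        if ms and s <= me[-1]:
            me[-1] = max(me[-1], e)
        else:
            ms.append(s)
            me.append(e)
    return np.array(ms, dtype=np.int64), np.array(me, dtype=np.int64)


def _subtract(start: int, end: int, ms: np.ndarray, me: np.ndarray) -> list[tuple[int, int]]:
    """Pieces of [start, end) not covered by the merged intervals (ms, me)."""
    pieces = []
    cur = start
    for s, e in zip(ms, me):
        if e <= cur:
            continue
        if s >= end:
            break
        if s > cur:
            pieces.append((cur, min(s, end)))
        cur = max(cur, e)
        if cur >= end:
            break
    if cur < end:
        pieces.append((cur, end))
    return pieces


def cgi_shores(cgis: FeatureSet, layout: GenomeLayout, flank: int = 2000) -> FeatureSet:
    """CpG-island shores: ``flank`` bp up- and downstream of each CGI.

    Shores are clipped to contig bounds and any base overlapping a CGI
    (including a neighboring one) is removed, so shore and island are
    disjoint base sets.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for contig in np.unique(cgis.contigs.astype(str)):
        sel = cgis.contigs.astype(str) == contig
        merged[contig] = _merge_intervals(cgis.starts[sel], cgis.ends[sel])
    contigs, starts, ends = [], [], []
    for i in range(len(cgis)):
        contig = str(cgis.contigs[i])
        length = layout.length_of(contig)
        ms, me = merged[contig]
        for lo, hi in (
            (max(0, cgis.starts[i] - flank), cgis.starts[i]),
            (cgis.ends[i], min(length, cgis.ends[i] + flank)),
        ):
            if lo >= hi:
                continue
            for s, e in _subtract(int(lo), int(hi), ms, me):
                contigs.append(contig)
                starts.append(s)
                ends.append(e)
    return FeatureSet(
        "cgi_shores",
        np.array(contigs, dtype=object),
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
    )


# ---------------------------------------------------------------------------
# plain-text readers/writers


def write_contig_lengths(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in layout.contigs:
            fh.write(f"{name}\t{length}\n")


def read_contig_lengths(path: str | Path) -> list[tuple[str, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                name, length = line.split("\t")[:2]
                out.append((name, int(length)))
    return out


def write_cpg_positions(layout: GenomeLayout, path: str | Path) -> None:
    """CpG positions as BED3 (each CpG start, 2-bp footprint)."""
    with open(path, "w") as fh:
        for name, _ in layout.contigs:
            for p in layout.cpg_positions[name]:
                fh.write(f"{name}\t{p}\t{p + 2}\n")


def read_cpg_positions(path: str | Path) -> dict[str, np.ndarray]:
    pos: dict[str, list[int]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            pos.setdefault(parts[0], []).append(int(parts[1]))
    return {c: np.array(sorted(v), dtype=np.int64) for c, v in pos.items()}
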