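"""Interval arithmetic, coordinate conventions, and signal quantification.

All coordinates are 0-based half-open ``[start, end)`` throughout the
package; BED output is written as-is and files carry a header comment
declaring the convention.  Adjacent intervals ``[a, b)`` and ``[b, c)``
do not overlap but are *book-ended*, which is the adjacency relation
used when interaction clusters are collapsed into subdomains.

ChIP-seq tags are directionally extended to the original fragment
length (200 bp by default) before any overlap counting, and coverage
tracks are averaged per 10 bp bin, matching common practice for
single-end ChIP-seq signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

BED_HEADER = "# coordinates: 0-based, half-open [start, end)"


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Tag:
    """A sequenced tag: an interval plus a strand.

    The interval length equals the sequenced tag length; directional
    extension to the fragment length happens at quantification time.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")

    def extend(self, extension: int) -> GenomicInterval:
        """Directionally extend to `extension` bp (3' of the 5' tag end)."""
        if extension < self.end - self.start:
            raise ValueError("extension must be >= tag length")
        if self.strand == "+":
            return GenomicInterval(self.chrom, self.start, self.start + extension)
        return GenomicInterval(self.chrom, max(0, self.end - extension), self.end)


@dataclass
class GeneRecord:
    """Gene model with the POLII gene-body density read-out.

    ``polii_density`` maps condition name -> gene-body density (RPKM).
    The body used for density excludes the first kilobase downstream of
    the TSS so that the promoter-proximal POLII peak does not dominate.
    """

    id: str
    chrom: str
    strand: str
    tss: int
    tes: int
    polii_density: dict = field(default_factory=dict)
    active: bool = True

    def body(self, offset: int = 1000) -> GenomicInterval:
        if self.strand == "+":
            start = self.tss + offset
            end = self.tes
        else:
            start = self.tes
            end = self.tss - offset
        if start >= end:  # very short gene: keep at least 1 bp of body
            start = min(start, end - 1) if end > 0 else 0
            end = start + 1
        return GenomicInterval(self.chrom, start, end)


def quantify_rpkm(
    region: GenomicInterval,
    tags: Iterable[Tag],
    library_size: int,
    extension: int = 200,
) -> float:
    """Reads per kilobase per million for `region`.

    Counts tags whose directionally extended interval overlaps the
    region, divided by region length in kb times library size in
    millions.
    """
    if library_size <= 0:
        raise ValueError("library_size must be > 0")
    if region.length <= 0:
        raise ValueError("region must have positive length")
    n = sum(1 for t in tags if t.extend(extension).overlaps(region))
    return n / (region.length / 1e3) / (library_size / 1e6)


def log2_rpkm_from_counts(
    counts: np.ndarray, lengths_bp: np.ndarray, library_size: float, pseudocount: float = 0.5
) -> np.ndarray:
    """Vectorized log2 RPKM from per-region tag counts (pseudocount guards 0)."""
    counts = np.maximum(np.asarray(counts, dtype=float), pseudocount)
    return np.log2(counts / (np.asarray(lengths_bp, dtype=float) / 1e3) / (library_size / 1e6))


def coverage_profile(
    tags: Sequence[Tag], extension: int = 200, binsize: int = 10
) -> dict[str, tuple[int, np.ndarray]]:
    """Per-bin mean coverage of directionally extended tags.

    Returns ``{chrom: (grid_start, values)}`` where ``values[i]`` is the
    per-base coverage averaged over the bin starting at
    ``grid_start + i * binsize``.  The grid is aligned to ``binsize``
    and spans all extended tags, so total mass is conserved:
    ``sum(values) * binsize == n_tags * extension``.
    """
    if extension < 0:
        raise ValueError("extension must be non-negative")
    per_chrom: dict[str, list[GenomicInterval]] = {}
    for t in tags:
        per_chrom.setdefault(t.chrom, []).append(t.extend(extension))
    out = {}
    for chrom, ivs in per_chrom.items():
        lo = min(iv.start for iv in ivs)
        hi = max(iv.end for iv in ivs)
        grid_start = (lo // binsize) * binsize
        grid_end = -(-hi // binsize) * binsize
        base = np.zeros(grid_end - grid_start, dtype=np.int64)
        for iv in ivs:  # difference-array accumulation
            base[iv.start - grid_start] += 1
            if iv.end - grid_start < base.size:
                base[iv.end - grid_start] -= 1
        cov = np.cumsum(base)
        out[chrom] = (grid_start, cov.reshape(-1, binsize).mean(axis=1))
    return out


def nearest_position(query: GenomicInterval, targets: Sequence[int]) -> tuple[int, int]:
    """Nearest target to the query midpoint: ``(target, distance)``.

    Distance is 0 whenever a target lies inside the query.  Ties are
    broken toward the smaller coordinate for determinism.
    """
    if len(targets) == 0:
        raise ValueError("targets must be nonempty")
    pos = np.sort(np.asarray(targets, dtype=np.int64))
    inside = pos[(pos >= query.start) & (pos < query.end)]
    if inside.size:
        return int(inside[0]), 0
    mid = query.midpoint
    d = np.abs(pos - mid)
    best = int(np.flatnonzero(d == d.min())[0])  # sorted -> smallest coordinate
    return int(pos[best]), int(d[best])


def distance_to_nearest(query: GenomicInterval, targets: Sequence[int]) -> int:
    """Minimal distance from the query midpoint to any target (0 if inside)."""
    return nearest_position(query, targets)[1]


def distances_to_nearest(midpoints: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Vectorized |midpoint - nearest target| (targets on one chromosome)."""
    t = np.sort(np.asarray(targets, dtype=np.int64))
    if t.size == 0:
        raise ValueError("targets must be nonempty")
    m = np.asarray(midpoints, dtype=np.int64)
    idx = np.searchsorted(t, m)
    left = np.abs(m - t[np.clip(idx - 1, 0, t.size - 1)])
    right = np.abs(t[np.clip(idx, 0, t.size - 1)] - m)
    return np.minimum(left, right)


def assign_points_to_intervals(
    points: pd.DataFrame, intervals: pd.DataFrame
) -> np.ndarray:
    """Index (into `intervals`) of the interval containing each point's
    (chrom, pos); -1 when no interval contains it.

    Intervals must be non-overlapping within each chromosome.
    """
    result = np.full(len(points), -1, dtype=np.int64)
    for chrom, sub in intervals.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if (starts[1:] < ends[:-1]).any():
            raise ValueError("intervals overlap within a chromosome")
        mask = (points["chrom"] == chrom).to_numpy()
        pos = points.loc[mask, "pos"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        local = np.full(pos.size, -1, dtype=np.int64)
        local[ok] = sub.index.to_numpy()[idx[ok]]
        result[mask] = local
    return result


def assign_points_smallest_interval(
    points: pd.DataFrame, intervals: pd.DataFrame
) -> np.ndarray:
    """Like :func:`assign_points_to_intervals` but tolerant of
    overlapping intervals: each point goes to the smallest containing
    interval (ties to the first row).  Meant for subdomain footprints,
    which can nest when components interleave."""
    n = len(points)
    result = np.full(n, -1, dtype=np.int64)
    best_width = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    chroms = points["chrom"].to_numpy()
    pos = points["pos"].to_numpy()
    for i, row in intervals.iterrows():
        width = int(row["end"] - row["start"])
        m = (chroms == row["chrom"]) & (pos >= row["start"]) & (pos < row["end"])
        take = m & (width < best_width)
        result[take] = i
        best_width[take] = width
    return result


# ---------------------------------------------------------------------------
# plain-text I/O


def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6 (tab-separated, '#' comment lines allowed)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    df.columns = names[: df.shape[1]]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df


def write_bed(df: pd.DataFrame, path, columns: Sequence[str] | None = None) -> None:
    cols = list(columns) if columns else [c for c in df.columns]
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False, columns=cols,
                  float_format="%.6g")


def read_gene_table(path) -> pd.DataFrame:
    """Read a gene table: id, chrom, strand, tss, tes (+ extra columns).

    1-based inputs can be converted by the caller; files written by this
    package are 0-based like everything else.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "chrom", "strand", "tss", "tes"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def write_gene_table(df: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(BED_HEADER + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def classify_active_genes(
    densities: np.ndarray, quantile: float = 0.5
) -> np.ndarray:
    """Active-gene flags: body density above the given quantile of the
    nonzero densities (default: their median)."""
    d = np.asarray(densities, dtype=float)
    nz = d[d > 0]
    if nz.size == 0:
        return np.zeros(d.size, dtype=bool)
    cutoff = np.quantile(nz, quantile)
    return d > cutoff
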