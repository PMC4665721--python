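"""From barcoded single-end ChIA-PET reads to anchored paired-end tags.

A ChIA-PET read carries 20 bp of genomic DNA on either side of a 36 bp
composite linker made of two ligated half-linkers, each with a 4 bp
barcode (A: TAAG, B: ATGT).  Reads are split at the linker-linker
junction and the downstream tag flipped back into genomic orientation;
mixed (AB) barcode pairs mark chimeric, non-specific ligations and
yield the library's random-ligation noise estimate (2 * AB fraction,
since AA/BB chimeras are invisible).

PET categories follow the standard span rules: same chromosome and
span < 5 kb => self-ligation; 5 kb..1 Mb => inter-ligation (the input
to interaction calling); > 1 Mb => distal intra-chromosomal; different
chromosomes => trans.  Span is measured between the 5' positions of
the two tags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import seqtools
from .seqtools import GenomeIndex, encode
from .simulate import BARCODE_A, BARCODE_B, half_linker

SELF_SPAN_MAX = 5000
UPPER_SPAN = 1_000_000
TAG_EXTENSION = 200


@dataclass
class LinkerReport:
    """Per-library accounting of linker classes and the chimera-based
    random-ligation estimate."""

    counts: dict = field(default_factory=dict)
    n_reads: int = 0
    n_identified: int = 0
    n_short: int = 0

    @property
    def chimeric_fraction(self) -> float:
        if self.n_identified == 0:
            return 0.0
        return self.counts.get("AB", 0) / self.n_identified

    @property
    def estimated_random_ligation(self) -> float:
        return min(1.0, 2.0 * self.chimeric_fraction)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("reads_total", self.n_reads),
            ("reads_identified", self.n_identified),
            ("reads_short_tag", self.n_short),
            *[(f"linker_{k}", v) for k, v in sorted(self.counts.items())],
            ("chimeric_fraction", self.chimeric_fraction),
            ("estimated_random_ligation", self.estimated_random_ligation),
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def _composites(linker_a: str, linker_b: str):
    """The four observable 36 bp composite linkers and their classes."""
    combos = {"AA": (linker_a, linker_a), "AB": (linker_a, linker_b),
              "BA": (linker_b, linker_a), "BB": (linker_b, linker_b)}
    out = []
    for name, (x, y) in combos.items():
        cls = "AB" if name in ("AB", "BA") else name
        out.append((name, cls, encode(x + seqtools.revcomp(y))))
    return out


def _barcode_mask(linker_a: str, linker_b: str) -> np.ndarray:
    """True at composite positions where the two half-linkers differ
    (the barcode); exact match is required there."""
    comps = [c for _, _, c in _composites(linker_a, linker_b)]
    stack = np.stack(comps)
    return (stack != stack[0]).any(axis=0)


def split_linker_reads(
    reads,
    linker_a: str = half_linker(BARCODE_A),
    linker_b: str = half_linker(BARCODE_B),
    tag_len: int = 20,
    max_mismatch: int = 1,
) -> tuple[pd.DataFrame, LinkerReport]:
    """Split reads at the linker ligation junction into tag pairs.

    Each read is scanned for the best-matching composite linker at any
    offset, allowing up to `max_mismatch` mismatches per half-linker
    outside the barcode and none inside it.  The flanking `tag_len`
    sequences become the PET tags (the downstream one is flipped back
    to its own 5'->3' orientation).  Reads without an acceptable linker
    are counted as unidentifiable; reads whose flanks are shorter than
    `tag_len` are counted as short and dropped.

    Returns (pets, report); `pets` has columns ``read_id, seq_a, seq_b,
    linker_class`` for the usable reads.
    """
    if linker_a == linker_b:
        raise ValueError("half-linkers must differ at the barcode")
    reads = list(reads)
    n = len(reads)
    report = LinkerReport(counts={"AA": 0, "BB": 0, "AB": 0, "unidentifiable": 0},
                          n_reads=n)
    if n == 0:
        return (
            pd.DataFrame(columns=["read_id", "seq_a", "seq_b", "linker_class"]),
            report,
        )
    comp_list = _composites(linker_a, linker_b)
    mask = _barcode_mask(linker_a, linker_b)
    lw = 2 * len(linker_a)

    lmax = max(len(r) for r in reads)
    arr = np.full((n, lmax), 255, dtype=np.uint8)
    for i, r in enumerate(reads):
        arr[i, : len(r)] = encode(r)
    if lmax < lw:
        report.counts["unidentifiable"] = n
        return (
            pd.DataFrame(columns=["read_id", "seq_a", "seq_b", "linker_class"]),
            report,
        )

    windows = np.lib.stride_tricks.sliding_window_view(arr, lw, axis=1)
    n_pos = windows.shape[1]
    half = len(linker_a)
    big = np.int32(1 << 20)
    best_score = np.full(n, big, dtype=np.int64)
    best_pos = np.zeros(n, dtype=np.int64)
    best_cls = np.full(n, -1, dtype=np.int64)
    cls_names = [c[1] for c in comp_list]
    for ci, (_, _, codes) in enumerate(comp_list):
        diff = windows != codes
        bc_bad = (diff & mask).any(axis=2)
        out_diff = diff & ~mask
        mm1 = out_diff[:, :, :half].sum(axis=2)
        mm2 = out_diff[:, :, half:].sum(axis=2)
        ok = ~bc_bad & (mm1 <= max_mismatch) & (mm2 <= max_mismatch)
        # deterministic preference: fewer mismatches, then leftmost, then class order
        score = np.where(ok, (mm1 + mm2) * (4 * n_pos) + np.arange(n_pos) * 4 + ci, big)
        pos = score.argmin(axis=1)
        sc = score[np.arange(n), pos]
        upd = sc < best_score
        best_score[upd] = sc[upd]
        best_pos[upd] = pos[upd]
        best_cls[upd] = ci

    identified = best_score < big
    rows = []
    for i in np.flatnonzero(identified):
        p = int(best_pos[i])
        cls = cls_names[best_cls[i]]
        report.counts[cls] += 1
        r = reads[i]
        if p < tag_len or len(r) < p + lw + tag_len:
            report.n_short += 1
            continue
        seq_a = r[p - tag_len : p]
        seq_b = seqtools.revcomp(r[p + lw : p + lw + tag_len])
        rows.append((i, seq_a, seq_b, cls))
    report.counts["unidentifiable"] += int(n - identified.sum())
    report.n_identified = int(identified.sum())
    pets = pd.DataFrame(rows, columns=["read_id", "seq_a", "seq_b", "linker_class"])
    return pets, report


def map_pets(pets: pd.DataFrame, index: GenomeIndex) -> tuple[pd.DataFrame, dict]:
    """Map both tags of each PET by unique exact search; order tag a
    before tag b by (chrom, start).  Unmappable PETs are dropped and
    counted."""
    if len(pets) == 0:
        empty = pets.copy()
        for c in ("chrom_a", "start_a", "end_a", "strand_a",
                  "chrom_b", "start_b", "end_b", "strand_b"):
            empty[c] = []
        return empty, {"pets_in": 0, "pets_mapped": 0, "pets_unmapped": 0}
    ma = index.map_tags(pets["seq_a"].tolist())
    mb = index.map_tags(pets["seq_b"].tolist())
    ok = (ma["mapped"] & mb["mapped"]).to_numpy()
    out = pets.loc[ok].reset_index(drop=True).copy()
    for side, m in (("a", ma), ("b", mb)):
        m = m.loc[ok].reset_index(drop=True)
        out[f"chrom_{side}"] = m["chrom"]
        out[f"start_{side}"] = m["start"]
        out[f"end_{side}"] = m["end"]
        out[f"strand_{side}"] = m["strand"]
    flip = (out["chrom_a"] > out["chrom_b"]) | (
        (out["chrom_a"] == out["chrom_b"]) & (out["start_a"] > out["start_b"])
    )
    for col in ("chrom", "start", "end", "strand", "seq"):
        a = out[f"{col}_a"].copy()
        out.loc[flip, f"{col}_a"] = out.loc[flip, f"{col}_b"]
        out.loc[flip, f"{col}_b"] = a[flip]
    counts = {
        "pets_in": int(len(pets)),
        "pets_mapped": int(ok.sum()),
        "pets_unmapped": int((~ok).sum()),
    }
    return out, counts


def five_prime(start: np.ndarray, end: np.ndarray, strand: np.ndarray) -> np.ndarray:
    return np.where(strand == "+", start, end)


def classify_pets(
    pets: pd.DataFrame,
    self_span_max: int = SELF_SPAN_MAX,
    upper_span: int = UPPER_SPAN,
) -> pd.DataFrame:
    """Assign span-based categories to mapped PETs.

    span < `self_span_max` => self; `self_span_max` <= span <=
    `upper_span` => intra_inter; span > `upper_span` => distal_intra;
    different chromosomes => trans.  Boundary values follow the strict-
    lower / inclusive-upper convention (exactly 5 kb is inter-ligation,
    exactly 1 Mb is retained).
    """
    out = pets.copy()
    p5a = five_prime(out["start_a"].to_numpy(), out["end_a"].to_numpy(),
                     out["strand_a"].to_numpy())
    p5b = five_prime(out["start_b"].to_numpy(), out["end_b"].to_numpy(),
                     out["strand_b"].to_numpy())
    span = np.abs(p5b - p5a)
    same = (out["chrom_a"] == out["chrom_b"]).to_numpy()
    cat = np.where(
        ~same, "trans",
        np.where(span < self_span_max, "self",
                 np.where(span <= upper_span, "intra_inter", "distal_intra")),
    )
    out["span"] = np.where(same, span, -1)
    out["category"] = cat
    return out


def dedup_pets(pets: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Collapse PETs with identical coordinate pairs (keep first)."""
    key = ["chrom_a", "start_a", "strand_a", "chrom_b", "start_b", "strand_b"]
    out = pets.drop_duplicates(subset=key).reset_index(drop=True)
    return out, int(len(pets) - len(out))


def assign_anchors(
    pets: pd.DataFrame,
    anchors: pd.DataFrame,
    window: int = 0,
    extension: int = TAG_EXTENSION,
) -> pd.DataFrame:
    """Assign each tag to the binding-site anchor its directionally
    extended interval overlaps (anchor grown by `window` bp each side).

    Anchors must be non-overlapping (merge first); overlapping anchors
    raise.  Ambiguous tags go to the anchor with the larger overlap,
    ties to the smaller coordinate.  Adds ``anchor_a``/``anchor_b``
    (-1 = unanchored) and ``anchored`` (both tags assigned).
    """
    anchors = anchors.reset_index(drop=True)
    out = pets.copy()
    anchor_cols = {}
    for side in ("a", "b"):
        n = len(out)
        assigned = np.full(n, -1, dtype=np.int64)
        starts = out[f"start_{side}"].to_numpy()
        ends = out[f"end_{side}"].to_numpy()
        strands = out[f"strand_{side}"].to_numpy()
        ext_start = np.where(strands == "+", starts, np.maximum(0, ends - extension))
        ext_end = np.where(strands == "+", starts + extension, ends)
        chroms = out[f"chrom_{side}"].to_numpy()
        for chrom in pd.unique(anchors["chrom"]):
            sub = anchors[anchors["chrom"] == chrom].sort_values("start")
            a_start = sub["start"].to_numpy() - window
            a_end = sub["end"].to_numpy() + window
            if (a_start[1:] < a_end[:-1]).any():
                raise ValueError("anchors overlap after windowing; merge them first")
            idx_global = sub.index.to_numpy()
            m = chroms == chrom
            if not m.any():
                continue
            s, e = ext_start[m], ext_end[m]
            best_ov = np.zeros(s.size, dtype=np.int64)
            best_ix = np.full(s.size, -1, dtype=np.int64)
            hi = np.searchsorted(a_start, e)  # anchors with start < e
            for back in range(1, 4):
                j = hi - back
                valid = j >= 0
                jj = np.clip(j, 0, None)
                ov = np.minimum(e, a_end[jj]) - np.maximum(s, a_start[jj])
                ov = np.where(valid, ov, 0)
                # scanning right-to-left: equal overlap at smaller coordinate wins
                take = (ov > 0) & (ov >= best_ov)
                best_ix = np.where(take, idx_global[jj], best_ix)
                best_ov = np.where(take, ov, best_ov)
            assigned[m] = best_ix
        anchor_cols[side] = assigned
    out["anchor_a"] = anchor_cols["a"]
    out["anchor_b"] = anchor_cols["b"]
    out["anchored"] = (out["anchor_a"] >= 0) & (out["anchor_b"] >= 0)
    return out


def pets_to_bedpe(pets: pd.DataFrame, path) -> None:
    cols = ["chrom_a", "start_a", "end_a", "chrom_b", "start_b", "end_b",
            "read_id", "linker_class", "strand_a", "strand_b", "category"]
    with open(path, "w") as fh:
        fh.write("# BEDPE; coordinates 0-based half-open\n")
        pets.to_csv(fh, sep="\t", header=False, index=False, columns=cols)
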