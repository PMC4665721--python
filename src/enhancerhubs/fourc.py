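"""4C-seq processing on a reduced genome of restriction-fragment ends.

The reduced genome holds, for every restriction-site occurrence (DpnII,
GATC, by default), the 30 bases immediately 3' of the site on each
strand -- the sequence a 4C read runs into after the bait primer.
Only fragment ends whose sequence is unique across all ends and their
reverse complements are mappable.  Reads are parsed by the bait primer
prefix and assigned to mappable ends by exact (optionally <=1-mismatch)
lookup.  The per-end signal is smoothed with a 10 kb sliding window
(+/-5 kb of each site), normalized to reads per million, and the
condition difference is reported per 10 kb genomic bin (delta-4C,
treated minus vehicle).

Fragment ends within +/-2 ends of the viewpoint are masked from signal
by default (self-ligation / undigested artifacts dominate there);
masking can be disabled.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import seqtools
from .seqtools import encode, find_motif


def build_reduced_genome(
    genome: dict[str, np.ndarray],
    site_motif: str = "GATC",
    flank: int = 30,
    include_site: bool = False,
) -> pd.DataFrame:
    """Fragment ends for every motif occurrence.

    The + strand end is the `flank` bases immediately 3' of the site on
    the forward strand; the - strand end is the reverse complement of
    the `flank` bases immediately 5' of the site.  With
    ``include_site=True`` the flank starts at the site boundary and
    contains the motif itself.  Occurrences too close to a contig edge
    for a full flank are dropped (and counted in
    ``.attrs['n_dropped']``).
    """
    if len(set(site_motif)) == 0 or any(c not in "ACGT" for c in site_motif):
        raise ValueError("site motif must be a nondegenerate ACGT string")
    mlen = len(site_motif) if not include_site else 0
    rows = []
    dropped = 0
    for chrom, arr in genome.items():
        if arr.dtype != np.uint8:
            arr = encode(arr)
        for s in find_motif(arr, site_motif):
            s = int(s)
            plus_from = s + mlen
            minus_to = s + (len(site_motif) - mlen)
            if plus_from + flank <= arr.size:
                seq = seqtools.decode(arr[plus_from : plus_from + flank])
                rows.append((chrom, s, "+", seq))
            else:
                dropped += 1
            if minus_to - flank >= 0:
                seq = seqtools.decode((3 - arr[minus_to - flank : minus_to])[::-1])
                rows.append((chrom, s, "-", seq))
            else:
                dropped += 1
    ends = pd.DataFrame(rows, columns=["chrom", "site_pos", "strand", "seq"])
    ends.attrs["n_dropped"] = dropped
    ends.attrs["flank"] = flank
    if len(ends) == 0:
        import warnings

        warnings.warn("no restriction-site occurrences found genome-wide")
    return ends


def filter_mappable(ends: pd.DataFrame) -> pd.DataFrame:
    """Flag ends whose sequence occurs exactly once across all end
    sequences and their reverse complements."""
    out = ends.copy()
    if len(out) == 0:
        out["mappable"] = []
        return out
    seqs = out["seq"].tolist()
    codes = np.array([seqtools.kmer_code(s) for s in seqs], dtype=np.uint64)
    rc_codes = np.array(
        [seqtools.kmer_code(seqtools.revcomp(s)) for s in seqs], dtype=np.uint64
    )
    combined = np.concatenate([codes, rc_codes])
    uniq, counts = np.unique(combined, return_counts=True)
    occ = counts[np.searchsorted(uniq, codes)]
    out["mappable"] = occ == 1
    return out


def assign_reads(
    reads,
    bait_primer: str,
    ends: pd.DataFrame,
    max_mismatch: int = 0,
) -> tuple[np.ndarray, dict]:
    """Per-fragment-end read counts.

    Reads lacking the bait primer prefix are discarded (counted);
    the remainder of each read is matched against mappable fragment-end
    sequences, exactly or with up to one mismatch (ambiguous matches
    discarded).  Returns (counts aligned with `ends`, tally).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    mappable = ends["mappable"].to_numpy() if "mappable" in ends else np.ones(len(ends), bool)
    flank = len(ends["seq"].iloc[0]) if len(ends) else 0
    lookup: dict[str, int] = {}
    ambiguous: set[str] = set()
    for i in np.flatnonzero(mappable):
        s = ends["seq"].iloc[int(i)]
        if s in lookup:
            ambiguous.add(s)
        lookup[s] = int(i)
    counts = np.zeros(len(ends), dtype=np.int64)
    tally = {"reads_total": 0, "no_primer": 0, "assigned": 0,
             "unmatched": 0, "ambiguous": 0}
    plen = len(bait_primer)
    for read in reads:
        tally["reads_total"] += 1
        if not read.startswith(bait_primer):
            tally["no_primer"] += 1
            continue
        frag = read[plen : plen + flank]
        if len(frag) < flank:
            tally["unmatched"] += 1
            continue
        hit = lookup.get(frag)
        if hit is not None and frag not in ambiguous:
            counts[hit] += 1
            tally["assigned"] += 1
            continue
        if max_mismatch == 1:
            hits = set()
            for pos in range(flank):
                for base in "ACGT":
                    if base == frag[pos]:
                        continue
                    v = lookup.get(frag[:pos] + base + frag[pos + 1 :])
                    if v is not None:
                        hits.add(v)
            if len(hits) == 1:
                counts[hits.pop()] += 1
                tally["assigned"] += 1
            elif len(hits) > 1:
                tally["ambiguous"] += 1
            else:
                tally["unmatched"] += 1
        else:
            tally["ambiguous" if frag in ambiguous else "unmatched"] += 1
    return counts, tally


def mask_viewpoint_ends(
    ends: pd.DataFrame, viewpoint_chrom: str, viewpoint_site: int, n_flanking: int = 2
) -> np.ndarray:
    """Boolean mask of ends to EXCLUDE: the viewpoint site and its
    `n_flanking` neighboring sites on each side."""
    sites = np.sort(ends.loc[ends["chrom"] == viewpoint_chrom, "site_pos"].unique())
    i = int(np.searchsorted(sites, viewpoint_site))
    keep_out = set(sites[max(0, i - n_flanking) : i + n_flanking + 1])
    return ((ends["chrom"] == viewpoint_chrom)
            & ends["site_pos"].isin(keep_out)).to_numpy()


def windowed_signal(
    counts: np.ndarray,
    ends: pd.DataFrame,
    total_reads: int,
    window: int = 10_000,
    binsize: int = 10_000,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sliding-window, depth-normalized 4C signal.

    ``s(i)`` sums the counts at all ends within +/- window/2 of end i's
    site (site i included) and normalizes to reads per million of
    `total_reads`.  The binned track averages s over the ends in each
    `binsize` genomic bin.  Doubling all counts and the total leaves s
    unchanged.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    counts = np.asarray(counts, dtype=float)
    s = np.zeros(len(ends), dtype=float)
    half = window // 2
    for chrom in pd.unique(ends["chrom"]):
        m = (ends["chrom"] == chrom).to_numpy()
        pos = ends.loc[m, "site_pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        p_sorted = pos[order]
        c_sorted = counts[m][order]
        csum = np.concatenate([[0.0], np.cumsum(c_sorted)])
        lo = np.searchsorted(p_sorted, p_sorted - half, side="left")
        hi = np.searchsorted(p_sorted, p_sorted + half, side="right")
        w = csum[hi] - csum[lo]
        out = np.empty_like(w)
        out[order] = w
        s[m] = out
    s = s / (total_reads / 1e6)
    bins = pd.DataFrame(
        {
            "chrom": ends["chrom"].to_numpy(),
            "bin_start": (ends["site_pos"].to_numpy() // binsize) * binsize,
            "s": s,
        }
    )
    track = (
        bins.groupby(["chrom", "bin_start"], as_index=False)
        .agg(signal=("s", "mean"), n_ends=("s", "size"))
        .sort_values(["chrom", "bin_start"])
        .reset_index(drop=True)
    )
    return s, track


def delta_4c(track_vehicle: pd.DataFrame, track_treated: pd.DataFrame) -> pd.DataFrame:
    """Per-bin treated - vehicle signal difference.

    Both tracks must be on the identical bin grid; a mismatch raises
    rather than silently zero-filling.
    """
    key = ["chrom", "bin_start"]
    v = track_vehicle.sort_values(key).reset_index(drop=True)
    t = track_treated.sort_values(key).reset_index(drop=True)
    if len(v) != len(t) or not (
        (v["chrom"].to_numpy() == t["chrom"].to_numpy()).all()
        and (v["bin_start"].to_numpy() == t["bin_start"].to_numpy()).all()
    ):
        raise ValueError("bin grids differ between conditions")
    out = v[key].copy()
    out["delta"] = t["signal"].to_numpy() - v["signal"].to_numpy()
    return out


def write_bedgraph(track: pd.DataFrame, path, value_col: str = "signal",
                   binsize: int = 10_000) -> None:
    with open(path, "w") as fh:
        fh.write("# bedGraph; coordinates 0-based half-open\n")
        df = track.copy()
        df["end"] = df["bin_start"] + binsize
        df.to_csv(fh, sep="\t", header=False, index=False,
                  columns=["chrom", "bin_start", "end", value_col],
                  float_format="%.6g")
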