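"""Ground-truth simulator for enhancer-hub ChIA-PET / 4C experiments.

The generator emulates the statistical structure the downstream
analysis assumes: a multi-chromosome genome carrying DpnII (GATC)
sites; disjoint interaction subdomains, each a block of co-factor
(P300-like) peaks with log-normal occupancy measured in two conditions
(vehicle vs. ligand-treated); an induced-peak subset whose occupancy
gains ``induction_effect`` log2 units upon treatment and whose
interaction edges are sampled ``interaction_enrichment`` (rho) times
more frequently in the treated library; barcoded single-end ChIA-PET
reads comprising self-ligation, true inter-ligation, chimeric-linker
and random-noise products; 4C reads with power-law distance decay plus
spikes at fragment ends of edge-connected peaks; and genes whose
POLII gene-body density is coupled to the induction of their connected
enhancers.

Null model
----------
Condition-to-condition log2 occupancy drift is uniform on
``+/- condition_wobble`` at every peak; induced peaks additionally gain
``induction_effect`` log2 units.  A bounded (platykurtic) drift is what
makes the median +/- 2*MAD dynamic-site rule a calibrated test: for
any Gaussian-tailed drift that rule flags a fixed ~18 % of null sites
(2*MAD = 1.35 sigma), which no sequencing depth can repair, whereas a
bounded drift places 2*MAD at the support edge and only measurement
noise leaks across it.

Reproducibility: the seed fully determines all outputs, and each output
uses an independent random stream, so e.g. changing the number of PETs
requested does not perturb the landscape.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import seqtools
from .seqtools import _BASES, encode, find_motif

# fixed 18 bp half-linkers differing only at the 4 bp barcode
HALF_LINKER_PREFIX = "GTCGGAG"
HALF_LINKER_SUFFIX = "CTAGCGA"
BARCODE_A = "TAAG"
BARCODE_B = "ATGT"
BAIT_PRIMER = "CAGTGCTTGAACCTGGCTAA"

CONDITIONS = ("vehicle", "treated")

# independent random streams (mixed with the user seed)
_STREAM_LANDSCAPE = 11
_STREAM_CHIAPET = {"vehicle": 21, "treated": 22}
_STREAM_FOURC = 31


def half_linker(barcode: str) -> str:
    return HALF_LINKER_PREFIX + barcode + HALF_LINKER_SUFFIX


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic landscape.

    Defaults describe a genome large enough that interaction clusters
    stay sparse at the simulated sequencing depths (1-3 inter-ligation
    PETs per true edge), which is the regime in which count-based
    differential hub analysis is informative.
    """

    n_chroms: int = 4
    chrom_length: int = 4_500_000
    n_subdomains: int = 128
    peaks_per_subdomain: int = 10
    induced_fraction: float = 0.12
    occupancy_log2_mean: float = 3.0
    occupancy_log2_sd: float = 1.0
    induction_effect: float = 2.0
    interaction_enrichment: float = 2.0  # rho; 1 => null
    chimeric_rate: float = 0.10  # q: PETs with mixed half-linker barcodes
    noise_rate: float = 0.05  # fraction of iPETs from random anchor pairs
    self_pet_fraction: float = 0.15
    self_pet_span_sd: float = 1000.0
    condition_wobble: float = 0.2  # half-width of uniform null log2 drift
    chip_count_scale: float = 2000.0  # expected ChIP tags per unit occupancy
    fourc_decay_exponent: float = 1.0
    fourc_spike_weight: float = 0.5
    gatc_spacing: int = 2000
    peak_width: int = 400
    peak_spacing: int = 12000
    tag_jitter_sd: float = 150.0  # tag placement around an anchor peak
    genes_per_subdomain: int = 2
    gene_length: int = 20000
    gene_active_fraction: float = 0.8
    expression_coupling: float = 0.5  # gamma
    tag_len: int = 20
    seed: int = 0

    _MARGIN = 6000
    _JITTER = 2000

    def validate(self) -> None:
        for name in ("induced_fraction", "chimeric_rate", "noise_rate",
                     "self_pet_fraction", "gene_active_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.interaction_enrichment < 0:
            raise ValueError("interaction_enrichment must be >= 0")
        if self.n_chroms < 1 or self.n_subdomains < 1:
            raise ValueError("need at least one chromosome and one subdomain")
        if self.peaks_per_subdomain < 2:
            raise ValueError("need >= 2 peaks per subdomain to form edges")
        if self.genes_per_subdomain > self.peaks_per_subdomain:
            raise ValueError("genes_per_subdomain cannot exceed peaks_per_subdomain")
        subs = self._subdomains_per_chrom()
        block = self.chrom_length // max(subs)
        needed = (2 * self._MARGIN + 2 * self._JITTER + self.peak_width
                  + (self.peaks_per_subdomain - 1) * self.peak_spacing)
        if block < needed:
            raise ValueError(
                f"chrom_length {self.chrom_length} too small for "
                f"{max(subs)} subdomains of {self.peaks_per_subdomain} peaks "
                f"(need >= {needed} bp per subdomain block)"
            )

    def _subdomains_per_chrom(self) -> list[int]:
        base = self.n_subdomains // self.n_chroms
        extra = self.n_subdomains % self.n_chroms
        return [base + (1 if i < extra else 0) for i in range(self.n_chroms)]

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class Landscape:
    """A simulated landscape plus its truth tables.

    ``peaks``, ``subdomains``, ``genes`` and ``edges`` are the truth
    tables; every emitted read produced from this landscape maps back
    to exactly one row of the read-level truth returned alongside it.
    """

    config: SimulationConfig
    genome: dict[str, np.ndarray]  # chrom -> uint8 codes
    peaks: pd.DataFrame
    subdomains: pd.DataFrame
    genes: pd.DataFrame
    edges: pd.DataFrame
    library_size: dict[str, int]
    _sites_cache: dict | None = None

    def chrom_seq(self, chrom: str, start: int, end: int) -> str:
        return seqtools.decode(self.genome[chrom][start:end])

    def fragment_sites(self, motif: str = "GATC") -> dict[str, np.ndarray]:
        """Restriction-site start positions per chromosome (cached)."""
        if self._sites_cache is None:
            self._sites_cache = {
                c: find_motif(arr, motif) for c, arr in self.genome.items()
            }
        return self._sites_cache

    def peak_bed(self) -> pd.DataFrame:
        return self.peaks[["chrom", "start", "end", "peak_id"]].copy()


def simulate_landscape(config: SimulationConfig) -> Landscape:
    """Generate genome, subdomain-structured peaks, genes and edge truth."""
    config.validate()
    rng = np.random.default_rng([config.seed, _STREAM_LANDSCAPE])
    L = config.chrom_length
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]

    genome: dict[str, np.ndarray] = {}
    gatc = encode("GATC")
    for chrom in chroms:
        arr = rng.integers(0, 4, size=L, dtype=np.int64).astype(np.uint8)
        pos = np.arange(config.gatc_spacing, L - 10, config.gatc_spacing)
        pos = pos + rng.integers(-500, 501, size=pos.size)
        for off in range(4):
            arr[pos + off] = gatc[off]
        genome[chrom] = arr

    # --- subdomain blocks and member peaks -------------------------------
    sub_rows, peak_rows = [], []
    sub_id = 0
    per_chrom = config._subdomains_per_chrom()
    for ci, chrom in enumerate(chroms):
        n_sub = per_chrom[ci]
        if n_sub == 0:
            continue
        block = L // n_sub
        for b in range(n_sub):
            lead = b * block + config._MARGIN
            jit = rng.integers(-config._JITTER, config._JITTER + 1,
                               size=config.peaks_per_subdomain)
            starts = lead + np.arange(config.peaks_per_subdomain) * config.peak_spacing + jit
            for s in starts:
                peak_rows.append((chrom, int(s), int(s) + config.peak_width, sub_id))
            sub_rows.append((sub_id, chrom, b * block, (b + 1) * block))
            sub_id += 1
    peaks = pd.DataFrame(peak_rows, columns=["chrom", "start", "end", "subdomain"])
    peaks.insert(0, "peak_id", np.arange(len(peaks)))
    subdomains = pd.DataFrame(sub_rows, columns=["subdomain", "chrom", "start", "end"])

    # guarantee a restriction-fragment end near every peak
    for chrom, sub in peaks.groupby("chrom", sort=False):
        arr = genome[chrom]
        for s in sub["start"].to_numpy():
            p = int(s) - 150
            arr[p : p + 4] = gatc

    # --- occupancy in two conditions -------------------------------------
    n = len(peaks)
    occ_v = rng.normal(config.occupancy_log2_mean, config.occupancy_log2_sd, size=n)
    induced = rng.random(n) < config.induced_fraction
    wobble = rng.uniform(-config.condition_wobble, config.condition_wobble, size=n)
    occ_t = occ_v + wobble + np.where(induced, config.induction_effect, 0.0)
    lam_v = (2.0 ** occ_v) * config.chip_count_scale
    lam_t = (2.0 ** occ_t) * config.chip_count_scale
    peaks["induced"] = induced
    peaks["occ_log2_vehicle"] = occ_v
    peaks["occ_log2_treated"] = occ_t
    peaks["count_vehicle"] = rng.poisson(lam_v)
    peaks["count_treated"] = rng.poisson(lam_t)
    library_size = {
        "vehicle": int(peaks["count_vehicle"].sum()),
        "treated": int(peaks["count_treated"].sum()),
    }

    # --- intra-subdomain edge truth --------------------------------------
    occ_lin_v = 2.0 ** occ_v
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    edge_rows = []
    for sid, sub in peaks.groupby("subdomain", sort=True):
        ids = sub["peak_id"].to_numpy()
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a, b = int(ids[i]), int(ids[j])
                span = abs(int(mids[b]) - int(mids[a]))
                w = float(np.sqrt(occ_lin_v[a] * occ_lin_v[b]) / max(span / 1e4, 0.1))
                edge_rows.append(
                    (a, b, sub["chrom"].iloc[0], span, w,
                     bool(induced[a] or induced[b]), sid)
                )
    edges = pd.DataFrame(
        edge_rows,
        columns=["peak_a", "peak_b", "chrom", "span", "weight",
                 "touches_induced", "subdomain"],
    )

    # --- genes coupled to connected enhancers ----------------------------
    gene_rows = []
    for sid, sub in peaks.groupby("subdomain", sort=True):
        ids = sub["peak_id"].to_numpy()
        chosen = rng.choice(ids, size=config.genes_per_subdomain, replace=False)
        for pid in np.sort(chosen):
            pid = int(pid)
            chrom = peaks.at[pid, "chrom"]
            mid = int(mids[pid])
            offset = int(rng.integers(500, 3000))
            strand = "+" if rng.random() < 0.5 else "-"
            tss = mid + offset
            tes = tss + config.gene_length if strand == "+" else tss - config.gene_length
            if tes < 1000 or tes > L - 1000:
                strand = "+" if strand == "-" else "-"
                tes = tss + config.gene_length if strand == "+" else tss - config.gene_length
            active = bool(rng.random() < config.gene_active_fraction)
            # connected enhancers = edge-linked peaks = the other members
            others = sub.loc[sub["peak_id"] != pid]
            gain = float((others["occ_log2_treated"] - others["occ_log2_vehicle"]).mean())
            ratio = max(0.05, 1.0 + config.expression_coupling * gain)
            if active:
                dens_v = float(2.0 ** rng.normal(2.0, 0.8))
            else:
                dens_v = float(2.0 ** rng.normal(-3.0, 0.5))
            dens_t = dens_v * ratio * float(2.0 ** rng.uniform(-0.1, 0.1))
            gene_rows.append(
                (f"gene_{sid}_{pid}", chrom, strand, tss, tes, sid, pid,
                 active, dens_v, dens_t, ratio, gain)
            )
    genes = pd.DataFrame(
        gene_rows,
        columns=["id", "chrom", "strand", "tss", "tes", "subdomain",
                 "promoter_peak", "active", "density_vehicle",
                 "density_treated", "expected_ratio", "connected_gain"],
    )

    return Landscape(config, genome, peaks, subdomains, genes, edges, library_size)


# ---------------------------------------------------------------------------
# ChIA-PET reads


def _place_tags(rng, mids: np.ndarray, jitter_sd: float, tag_len: int):
    """Tag coordinates near peak midpoints, extension pointing at the peak."""
    o = rng.normal(0.0, jitter_sd, size=mids.size).round().astype(np.int64)
    plus = o <= 0
    start = np.where(plus, mids + o - tag_len, mids + o)
    strand = np.where(plus, "+", "-")
    return start, strand


def _extract_oriented(genome, chrom_arr, starts, strands, tag_len):
    """(n, tag_len) uint8 matrix of tag sequences, oriented 5'->3'."""
    out = np.empty((starts.size, tag_len), dtype=np.uint8)
    for chrom in np.unique(chrom_arr):
        m = chrom_arr == chrom
        idx = starts[m][:, None] + np.arange(tag_len)[None, :]
        out[m] = genome[chrom][idx]
    neg = strands == "-"
    out[neg] = (3 - out[neg])[:, ::-1]
    return out


def simulate_chiapet_reads(
    landscape: Landscape,
    condition: str,
    n_pets: int,
    rho: float | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Single-end ChIA-PET reads with embedded half-linkers, plus truth.

    Each read is ``tag_a + half_linker(b1) + revcomp(half_linker(b2)) +
    revcomp(tag_b)`` -- 20 bp of genomic sequence on either side of the
    36 bp composite linker.  A fraction ``chimeric_rate`` carries mixed
    (AB) barcodes and joins random anchor pairs; ``self_pet_fraction``
    are self-ligations around single peaks; of the remaining
    inter-ligations, ``noise_rate`` join random anchor pairs and the
    rest are drawn from the edge truth, with edges touching induced
    peaks upweighted by rho in the treated condition.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if n_pets <= 0:
        raise ValueError("n_pets must be > 0")
    cfg = landscape.config
    if rho is None:
        rho = cfg.interaction_enrichment
    rng = np.random.default_rng([cfg.seed, _STREAM_CHIAPET[condition]])

    peaks = landscape.peaks
    n_peaks = len(peaks)
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    chrom_of = peaks["chrom"].to_numpy()
    occ_col = f"occ_log2_{condition}"
    occ_lin = 2.0 ** peaks[occ_col].to_numpy()

    u = rng.random(n_pets)
    chimeric = u < cfg.chimeric_rate
    u2 = rng.random(n_pets)
    is_self = ~chimeric & (u2 < cfg.self_pet_fraction)
    inter = ~chimeric & ~is_self
    u3 = rng.random(n_pets)
    is_noise = inter & (u3 < cfg.noise_rate)
    is_true = inter & ~is_noise

    prov = np.empty(n_pets, dtype=object)
    prov[chimeric] = "chimeric"
    prov[is_self] = "self"
    prov[is_noise] = "noise"
    prov[is_true] = "inter"

    peak_a = np.full(n_pets, -1, dtype=np.int64)
    peak_b = np.full(n_pets, -1, dtype=np.int64)
    edge_idx = np.full(n_pets, -1, dtype=np.int64)
    start_a = np.zeros(n_pets, dtype=np.int64)
    start_b = np.zeros(n_pets, dtype=np.int64)
    strand_a = np.empty(n_pets, dtype=object)
    strand_b = np.empty(n_pets, dtype=object)

    # self-ligations: symmetric tags around one peak
    m = int(is_self.sum())
    if m:
        p = occ_lin / occ_lin.sum()
        sel = rng.choice(n_peaks, size=m, p=p)
        centers = mids[sel] + rng.normal(0, cfg.tag_jitter_sd, m).round().astype(np.int64)
        span = np.abs(rng.normal(0, cfg.self_pet_span_sd, m)).round().astype(np.int64)
        span = np.maximum(span, 2 * cfg.tag_len)
        peak_a[is_self] = peak_b[is_self] = sel
        start_a[is_self] = centers - span // 2
        strand_a[is_self] = "+"
        start_b[is_self] = centers + (span - span // 2) - cfg.tag_len
        strand_b[is_self] = "-"

    # true inter-ligations from edge truth
    m = int(is_true.sum())
    if m:
        w = landscape.edges["weight"].to_numpy().copy()
        if condition == "treated":
            w = w * np.where(landscape.edges["touches_induced"].to_numpy(), rho, 1.0)
        ei = rng.choice(len(w), size=m, p=w / w.sum())
        edge_idx[is_true] = ei
        pa = landscape.edges["peak_a"].to_numpy()[ei]
        pb = landscape.edges["peak_b"].to_numpy()[ei]
        peak_a[is_true], peak_b[is_true] = pa, pb
        sa, qa = _place_tags(rng, mids[pa], cfg.tag_jitter_sd, cfg.tag_len)
        sb, qb = _place_tags(rng, mids[pb], cfg.tag_jitter_sd, cfg.tag_len)
        start_a[is_true], strand_a[is_true] = sa, qa
        start_b[is_true], strand_b[is_true] = sb, qb

    # noise and chimeric products join random anchor pairs
    rand = is_noise | chimeric
    m = int(rand.sum())
    if m:
        pa = rng.integers(0, n_peaks, m)
        pb = (pa + rng.integers(1, n_peaks, m)) % n_peaks
        peak_a[rand], peak_b[rand] = pa, pb
        sa, qa = _place_tags(rng, mids[pa], cfg.tag_jitter_sd, cfg.tag_len)
        sb, qb = _place_tags(rng, mids[pb], cfg.tag_jitter_sd, cfg.tag_len)
        start_a[rand], strand_a[rand] = sa, qa
        start_b[rand], strand_b[rand] = sb, qb

    chrom_a = chrom_of[peak_a]
    chrom_b = chrom_of[peak_b]

    # barcodes: AA/BB for genuine products, AB/BA for chimeras
    half = rng.random(n_pets) < 0.5
    b1 = np.where(chimeric, np.where(half, "A", "B"), np.where(half, "A", "B"))
    b2 = np.where(chimeric, np.where(half, "B", "A"), b1)

    tag_len = cfg.tag_len
    mat_a = _extract_oriented(landscape.genome, chrom_a, start_a, strand_a.astype(str), tag_len)
    mat_b = _extract_oriented(landscape.genome, chrom_b, start_b, strand_b.astype(str), tag_len)

    linker_codes = {
        (x, y): encode(half_linker(BARCODE_A if x == "A" else BARCODE_B)
                       + seqtools.revcomp(half_linker(BARCODE_A if y == "A" else BARCODE_B)))
        for x in "AB" for y in "AB"
    }
    read_len = 2 * tag_len + 36
    reads_mat = np.empty((n_pets, read_len), dtype=np.uint8)
    reads_mat[:, :tag_len] = mat_a
    for (x, y), codes in linker_codes.items():
        rows = (b1 == x) & (b2 == y)
        reads_mat[rows, tag_len : tag_len + 36] = codes
    reads_mat[:, tag_len + 36 :] = (3 - mat_b)[:, ::-1]
    blob = _BASES[reads_mat].tobytes().decode("ascii")
    reads = [blob[i * read_len : (i + 1) * read_len] for i in range(n_pets)]

    truth = pd.DataFrame(
        {
            "provenance": prov,
            "barcodes": np.char.add(b1.astype(str), b2.astype(str)),
            "chrom_a": chrom_a, "start_a": start_a, "strand_a": strand_a.astype(str),
            "chrom_b": chrom_b, "start_b": start_b, "strand_b": strand_b.astype(str),
            "peak_a": peak_a, "peak_b": peak_b, "edge": edge_idx,
        }
    )
    return reads, truth


# ---------------------------------------------------------------------------
# 4C reads


def nearest_site_index(sites: np.ndarray, pos: int) -> int:
    """Index of the restriction site nearest to `pos` (smaller wins ties)."""
    if sites.size == 0:
        raise ValueError("no restriction sites on this chromosome")
    i = int(np.searchsorted(sites, pos))
    cands = [j for j in (i - 1, i) if 0 <= j < sites.size]
    return min(cands, key=lambda j: (abs(int(sites[j]) - pos), sites[j]))


def simulate_fourc_reads(
    landscape: Landscape,
    viewpoint_peak: int,
    condition: str,
    n_reads: int,
    rho: float | None = None,
    flank: int = 30,
) -> tuple[list[str], pd.DataFrame]:
    """Bait-primed 4C reads for one viewpoint, plus per-end truth.

    Capture probability per cis restriction site follows a power-law
    distance decay ``d^-alpha`` (distance floored at 1 kb) with additive
    spikes at the fragment sites nearest to edge-connected peaks; spikes
    on edges touching induced peaks are multiplied by rho in the treated
    condition.  Each read is the bait primer followed by the captured
    fragment-end sequence; strands are sampled evenly per site.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    cfg = landscape.config
    if rho is None:
        rho = cfg.interaction_enrichment
    rng = np.random.default_rng(
        [cfg.seed, _STREAM_FOURC, int(viewpoint_peak), CONDITIONS.index(condition)]
    )

    peaks = landscape.peaks
    chrom = peaks.at[int(viewpoint_peak), "chrom"]
    vp_mid = int((peaks.at[int(viewpoint_peak), "start"] + peaks.at[int(viewpoint_peak), "end"]) // 2)
    sites = landscape.fragment_sites()[chrom]
    if sites.size == 0:
        raise ValueError("viewpoint has no restriction-fragment end")
    vp_site = int(sites[nearest_site_index(sites, vp_mid)])
    if abs(vp_site - vp_mid) > 5000:
        raise ValueError("viewpoint has no restriction-fragment end within 5 kb")

    arr = landscape.genome[chrom]
    # sites whose both flanks fit inside the contig are capturable
    ok = (sites - flank >= 0) & (sites + 4 + flank <= arr.size)
    sites_ok = sites[ok]

    d_kb = np.maximum(np.abs(sites_ok - vp_site), 1000) / 1000.0
    weight = d_kb ** (-cfg.fourc_decay_exponent)

    e = landscape.edges
    touching = e[(e["peak_a"] == viewpoint_peak) | (e["peak_b"] == viewpoint_peak)]
    partners = np.where(
        touching["peak_a"].to_numpy() == viewpoint_peak,
        touching["peak_b"].to_numpy(), touching["peak_a"].to_numpy(),
    )
    mids = ((peaks["start"] + peaks["end"]) // 2).to_numpy()
    connected = np.zeros(sites_ok.size, dtype=bool)
    induced_edge = np.zeros(sites_ok.size, dtype=bool)
    for pid, boost in zip(partners, touching["touches_induced"].to_numpy()):
        j = nearest_site_index(sites_ok, int(mids[pid]))
        spike = cfg.fourc_spike_weight
        if condition == "treated" and boost:
            spike *= rho
        weight[j] += spike
        connected[j] = True
        induced_edge[j] |= bool(boost)

    p = weight / weight.sum()
    counts = rng.multinomial(n_reads, p) if n_reads > 0 else np.zeros(p.size, dtype=np.int64)
    plus_counts = rng.binomial(counts, 0.5)
    minus_counts = counts - plus_counts

    reads: list[str] = []
    rows = []
    for j in np.flatnonzero(counts):
        s = int(sites_ok[j])
        fplus = seqtools.decode(arr[s + 4 : s + 4 + flank])
        fminus = seqtools.revcomp(seqtools.decode(arr[s - flank : s]))
        reads.extend([BAIT_PRIMER + fplus] * int(plus_counts[j]))
        reads.extend([BAIT_PRIMER + fminus] * int(minus_counts[j]))
        rows.append((chrom, s, "+", int(plus_counts[j]), bool(connected[j]), bool(induced_edge[j])))
        rows.append((chrom, s, "-", int(minus_counts[j]), bool(connected[j]), bool(induced_edge[j])))
    truth = pd.DataFrame(
        rows, columns=["chrom", "site_pos", "strand", "count", "connected", "induced_edge"]
    )
    return reads, truth


# ---------------------------------------------------------------------------
# plain-text output


def write_fasta(genome: dict[str, np.ndarray], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, arr in genome.items():
            fh.write(f">{chrom}\n")
            s = _BASES[arr].tobytes().decode("ascii")
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def write_fastq(reads: Sequence[str], path, prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[str]:
    from Bio import SeqIO

    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta(path) -> dict[str, np.ndarray]:
    from Bio import SeqIO

    return {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
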