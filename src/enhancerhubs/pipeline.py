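"""End-to-end orchestration: simulate -> PETs -> call -> hubs -> diff -> 4C.

All stages are pure functions over in-memory tables; `run_pipeline`
wires them together from a config mapping, writes every stage artifact
as plain text, and records a run manifest with per-stage record counts
so that each input read is attributable to exactly one outcome.
Re-running with the same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import calling, differential, fourc, hubs, pets as pets_mod
from .intervals import classify_active_genes, log2_rpkm_from_counts, write_bed, write_gene_table
from .seqtools import GenomeIndex
from .simulate import (
    BAIT_PRIMER,
    CONDITIONS,
    Landscape,
    SimulationConfig,
    simulate_chiapet_reads,
    simulate_fourc_reads,
    simulate_landscape,
    write_fasta,
    write_fastq,
)


@dataclass
class PipelineParams:
    """Analysis thresholds (defaults mirror the published values)."""

    n_pets: int = 10_000
    tag_len: int = 20
    linker_max_mismatch: int = 1
    dedup: bool = True
    anchor_window: int = 0
    tag_extension: int = 200
    min_pet: int = 2           # P300-type libraries; use 3 for POLII-type
    fdr_max: float = 0.05
    span_min: int = 5000
    span_max: int = 1_000_000
    distal_threshold: int = 5000
    min_peaks: int = 5
    max_abs_dc: float = 0.3
    n_bins: int = 10
    run_fourc: bool = True
    fourc_reads: int = 100_000
    fourc_window: int = 10_000
    fourc_flank: int = 30
    fourc_motif: str = "GATC"
    fourc_mask_viewpoint: int = 2

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown pipeline parameter(s): {sorted(unknown)}")
        return cls(**d)


@dataclass
class ConditionResult:
    """Per-condition intermediate products and accounting."""

    condition: str
    pets: pd.DataFrame
    report: pets_mod.LinkerReport
    candidates: pd.DataFrame
    clusters: pd.DataFrame
    counts: dict = field(default_factory=dict)


def build_index(landscape: Landscape, tag_len: int = 20) -> GenomeIndex:
    return GenomeIndex(landscape.genome, k=tag_len)


def process_reads(
    reads, index: GenomeIndex, anchors: pd.DataFrame, params: PipelineParams
) -> tuple[pd.DataFrame, pets_mod.LinkerReport, dict]:
    """Reads -> classified, deduplicated, anchored PETs."""
    split, report = pets_mod.split_linker_reads(
        reads, tag_len=params.tag_len, max_mismatch=params.linker_max_mismatch
    )
    mapped, map_counts = pets_mod.map_pets(split, index)
    classified = pets_mod.classify_pets(
        mapped, self_span_max=params.span_min, upper_span=params.span_max
    )
    n_dups = 0
    if params.dedup:
        classified, n_dups = pets_mod.dedup_pets(classified)
    anchored = pets_mod.assign_anchors(
        classified, anchors, window=params.anchor_window, extension=params.tag_extension
    )
    counts = dict(map_counts)
    counts["pets_deduplicated"] = n_dups
    counts["pets_after_dedup"] = int(len(anchored))
    for cat, cnt in anchored["category"].value_counts().items():
        counts[f"pets_{cat}"] = int(cnt)
    counts["pets_both_anchored"] = int(anchored["anchored"].sum())
    return anchored, report, counts


def call_condition(
    anchored: pd.DataFrame, anchors: pd.DataFrame, params: PipelineParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate clusters (scored) and the high-confidence subset.

    Chimeric (AB-barcode) PETs are excluded from calling; they only
    inform the noise estimate.
    """
    usable = anchored[anchored["linker_class"].isin(["AA", "BB"])]
    cand = calling.cluster_ipets(usable)
    cand = calling.attach_anchor_intervals(cand, anchors)
    cand = calling.score_clusters(cand)
    filtered = calling.filter_clusters(
        cand,
        min_pet=params.min_pet,
        fdr_max=params.fdr_max,
        span_limits=(params.span_min, params.span_max),
    )
    return cand, filtered


def run_condition(
    landscape: Landscape,
    index: GenomeIndex,
    condition: str,
    params: PipelineParams,
    rho: float | None = None,
) -> tuple[ConditionResult, pd.DataFrame]:
    """Simulate one ChIA-PET library and process it fully.

    Returns the condition result plus the read-level truth table (kept
    separate so analysis stays truth-blind).
    """
    reads, truth = simulate_chiapet_reads(landscape, condition, params.n_pets, rho=rho)
    anchors = landscape.peak_bed()
    anchored, report, counts = process_reads(reads, index, anchors, params)
    cand, filtered = call_condition(anchored, anchors, params)
    counts["clusters_candidate"] = int(len(cand))
    counts["clusters_filtered"] = int(len(filtered))
    counts["reads_in"] = len(reads)
    return ConditionResult(condition, anchored, report, cand, filtered, counts), truth


def make_site_table(landscape: Landscape) -> pd.DataFrame:
    """Binding sites with per-condition log2 RPKM from the peak table."""
    p = landscape.peaks
    widths = (p["end"] - p["start"]).to_numpy()
    out = p[["peak_id", "chrom", "start", "end"]].copy()
    for cond in CONDITIONS:
        out[f"log2_rpkm_{cond}"] = log2_rpkm_from_counts(
            p[f"count_{cond}"].to_numpy(), widths, landscape.library_size[cond]
        )
    return out


def tss_by_chrom(genes: pd.DataFrame) -> dict[str, np.ndarray]:
    return {
        chrom: np.sort(sub["tss"].to_numpy())
        for chrom, sub in genes.groupby("chrom", sort=False)
    }


def analyze_hubs_and_differential(
    landscape: Landscape,
    res_vehicle: ConditionResult,
    res_treated: ConditionResult,
    params: PipelineParams,
) -> dict:
    """Subdomains, concentration gates, and the hub comparison."""
    anchors = landscape.peak_bed()
    both = pd.concat(
        [
            res_vehicle.clusters.assign(condition="vehicle"),
            res_treated.clusters.assign(condition="treated"),
        ],
        ignore_index=True,
    )
    subdomains, clusters_assigned = hubs.collapse_subdomains(both, anchors)

    sites = make_site_table(landscape)
    sites = differential.classify_dynamic_sites(sites)
    genes = landscape.genes.copy()
    genes["active_measured"] = classify_active_genes(genes["density_vehicle"].to_numpy())
    tss = tss_by_chrom(genes)
    sites = differential.site_locality(sites, tss, params.distal_threshold)

    out: dict = {
        "subdomains": None, "sites": sites, "genes": genes,
        "clusters": clusters_assigned, "comparison": None,
        "typed_treated": None, "proportions_treated": None,
    }
    if len(subdomains) == 0:
        return out
    for cond in CONDITIONS:
        col = f"n_clusters_{cond}"
        if col not in subdomains:
            subdomains[col] = 0
    subdomains = differential.subdomain_concentration(subdomains, sites)
    induced_g, constitutive_g, excluded_g = differential.select_matched_subdomains(
        subdomains, min_peaks=params.min_peaks, max_abs_dc=params.max_abs_dc
    )
    comparison = None
    comparison_by_density = None
    if len(induced_g) and len(constitutive_g):
        comparison = differential.compare_interaction_gain(induced_g, constitutive_g)
        if len(induced_g) + len(constitutive_g) >= 9:
            comparison_by_density = differential.compare_interaction_gain_by_density(
                induced_g, constitutive_g
            )
    typed, props = hubs.annotate_interaction_types(
        res_treated.clusters, tss, params.distal_threshold
    )
    out.update(
        subdomains=subdomains,
        induced_group=induced_g,
        constitutive_group=constitutive_g,
        excluded_group=excluded_g,
        comparison=comparison,
        comparison_by_density=comparison_by_density,
        typed_treated=typed,
        proportions_treated=props,
    )
    return out


def dbs_gene_links(
    typed_clusters: pd.DataFrame, genes: pd.DataFrame, distal_threshold: int = 5000
) -> pd.DataFrame:
    """site_id -> gene_id links from DBS-promoter clusters.

    The linked gene is the one whose TSS is nearest to the promoter
    anchor midpoint (must be within the distal threshold).
    """
    rows = []
    gsort = {
        chrom: sub.sort_values("tss").reset_index(drop=True)
        for chrom, sub in genes.groupby("chrom", sort=False)
    }
    sel = typed_clusters[typed_clusters["interaction_type"] == "DBS-promoter"]
    for _, row in sel.iterrows():
        if row["anchor_a_label"] == "DBS":
            dbs, prom = row["anchor_a"], (row["start_b"] + row["end_b"]) // 2
        else:
            dbs, prom = row["anchor_b"], (row["start_a"] + row["end_a"]) // 2
        sub = gsort.get(row["chrom"])
        if sub is None or len(sub) == 0:
            continue
        tss = sub["tss"].to_numpy()
        j = int(np.argmin(np.abs(tss - prom)))
        if abs(int(tss[j]) - int(prom)) <= distal_threshold:
            rows.append({"site_id": int(dbs), "gene_id": sub.at[j, "id"]})
    return pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)


def run_fourc_stage(
    landscape: Landscape, params: PipelineParams, rho: float | None = None
) -> dict:
    """4C at one automatically chosen viewpoint, both conditions."""
    edges = landscape.edges
    peaks = landscape.peaks
    # deterministic viewpoint: the constitutive peak touching the most
    # induced edges (a pre-existing site looking at induced partners)
    score = pd.concat(
        [
            edges.loc[edges["touches_induced"], "peak_a"],
            edges.loc[edges["touches_induced"], "peak_b"],
        ]
    ).value_counts()
    constitutive = set(peaks.loc[~peaks["induced"], "peak_id"])
    vp = None
    for pid in score.index:
        if int(pid) in constitutive:
            vp = int(pid)
            break
    if vp is None:
        vp = int(peaks["peak_id"].iloc[0])

    ends = fourc.build_reduced_genome(
        landscape.genome, site_motif=params.fourc_motif, flank=params.fourc_flank
    )
    ends = fourc.filter_mappable(ends)
    vp_chrom = peaks.at[vp, "chrom"]
    vp_mid = int((peaks.at[vp, "start"] + peaks.at[vp, "end"]) // 2)
    sites_chr = np.sort(ends.loc[ends["chrom"] == vp_chrom, "site_pos"].unique())
    vp_site = int(sites_chr[np.argmin(np.abs(sites_chr - vp_mid))])
    mask = fourc.mask_viewpoint_ends(ends, vp_chrom, vp_site, params.fourc_mask_viewpoint)

    out = {"viewpoint_peak": vp, "viewpoint_site": vp_site, "ends": ends, "tracks": {},
           "signals": {}, "counts": {}, "tallies": {}, "truths": {}}
    for cond in CONDITIONS:
        reads, truth = simulate_fourc_reads(
            landscape, vp, cond, params.fourc_reads, rho=rho, flank=params.fourc_flank
        )
        counts, tally = fourc.assign_reads(reads, BAIT_PRIMER, ends)
        use = counts.copy()
        use[mask] = 0
        total = int(tally["assigned"])
        s, track = fourc.windowed_signal(use, ends, max(total, 1), window=params.fourc_window)
        out["tracks"][cond] = track
        out["signals"][cond] = s
        out["counts"][cond] = counts
        out["tallies"][cond] = tally
        out["truths"][cond] = truth
    out["delta"] = fourc.delta_4c(out["tracks"]["vehicle"], out["tracks"]["treated"])
    return out


# ---------------------------------------------------------------------------
# truth-aware read-outs (used for reporting parameter recovery)


def induced_recall(sites: pd.DataFrame, peaks_truth: pd.DataFrame) -> float:
    truly = peaks_truth["induced"].to_numpy()
    if truly.sum() == 0:
        return float("nan")
    called = (sites["dynamic_class"] == "induced").to_numpy()
    return float(called[truly].mean())


def dynamic_false_positive_rate(sites: pd.DataFrame, peaks_truth: pd.DataFrame) -> float:
    null = ~peaks_truth["induced"].to_numpy()
    flagged = (sites["dynamic_class"] != "constitutive").to_numpy()
    return float(flagged[null].mean())


def noise_pair_pass_fraction(
    anchored: pd.DataFrame,
    truth: pd.DataFrame,
    candidates: pd.DataFrame,
    filtered: pd.DataFrame,
) -> tuple[int, int]:
    """(noise-only candidate pairs passing the filter, all noise-only pairs)."""
    sel = anchored[(anchored["category"] == "intra_inter") & anchored["anchored"]
                   & anchored["linker_class"].isin(["AA", "BB"])]
    prov = truth["provenance"].to_numpy()[sel["read_id"].to_numpy()]
    a = np.minimum(sel["anchor_a"].to_numpy(), sel["anchor_b"].to_numpy())
    b = np.maximum(sel["anchor_a"].to_numpy(), sel["anchor_b"].to_numpy())
    df = pd.DataFrame({"a": a, "b": b, "noise": prov == "noise"})
    grp = df.groupby(["a", "b"])["noise"].agg(["all", "size"])
    noise_pairs = set(grp[grp["all"]].index)
    if not noise_pairs:
        return 0, 0
    passed = set(zip(filtered["anchor_a"], filtered["anchor_b"]))
    n_pass = sum(1 for pair in noise_pairs if pair in passed)
    return n_pass, len(noise_pairs)


# ---------------------------------------------------------------------------
# file-level pipeline


_CONFIG_SECTIONS = {"seed", "simulate", "pipeline"}


def load_config(source) -> dict:
    import yaml

    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = dict(source)
    unknown = set(cfg) - _CONFIG_SECTIONS
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    return cfg


def run_pipeline(config, outdir) -> dict:
    """Full run from a config mapping/path; returns the manifest."""
    cfg = load_config(config)
    seed = int(cfg.get("seed", 0))
    sim_cfg = SimulationConfig(**{"seed": seed, **cfg.get("simulate", {})})
    params = PipelineParams.from_dict(cfg.get("pipeline", {}))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    landscape = simulate_landscape(sim_cfg)
    index = build_index(landscape, params.tag_len)
    manifest: dict = {
        "config": {
            "seed": seed,
            "simulate": dataclasses.asdict(sim_cfg),
            "pipeline": dataclasses.asdict(params),
        },
        "stages": {},
    }

    write_fasta(landscape.genome, outdir / "genome.fa")
    write_bed(landscape.peak_bed(), outdir / "peaks.bed")
    write_bed(
        landscape.subdomains[["chrom", "start", "end", "subdomain"]],
        outdir / "subdomain_blocks.bed",
    )
    write_gene_table(landscape.genes, outdir / "genes.tsv")

    results: dict[str, ConditionResult] = {}
    for cond in CONDITIONS:
        reads, _truth = simulate_chiapet_reads(landscape, cond, params.n_pets)
        write_fastq(reads, outdir / f"chiapet_{cond}.fastq", prefix=cond)
        anchored, report, counts = process_reads(
            reads, index, landscape.peak_bed(), params
        )
        cand, filtered = call_condition(anchored, landscape.peak_bed(), params)
        results[cond] = ConditionResult(cond, anchored, report, cand, filtered, counts)
        counts["reads_in"] = len(reads)
        counts["clusters_candidate"] = int(len(cand))
        counts["clusters_filtered"] = int(len(filtered))
        manifest["stages"][f"chiapet_{cond}"] = counts
        report.to_frame().to_csv(
            outdir / f"linker_report_{cond}.tsv", sep="\t", index=False
        )
        pets_mod.pets_to_bedpe(anchored, outdir / f"pets_{cond}.bedpe")
        filtered.to_csv(
            outdir / f"clusters_{cond}.bedpe", sep="\t", index=False,
            float_format="%.6g",
        )

    analysis = analyze_hubs_and_differential(
        landscape, results["vehicle"], results["treated"], params
    )
    analysis["sites"].to_csv(outdir / "site_classes.tsv", sep="\t", index=False,
                             float_format="%.6g")
    summary: dict = {"proportions_treated": analysis["proportions_treated"]}
    if analysis["subdomains"] is not None:
        sub_out = analysis["subdomains"].drop(columns=["anchor_ids"])
        sub_out.to_csv(outdir / "subdomains.tsv", sep="\t", index=False,
                       float_format="%.6g")
        analysis["clusters"][
            ["condition", "anchor_a", "anchor_b", "k", "subdomain"]
        ].to_csv(outdir / "cluster_subdomain_map.tsv", sep="\t", index=False)
        manifest["stages"]["hubs"] = {
            "n_subdomains": int(len(analysis["subdomains"])),
            "n_gated_induced": int(len(analysis.get("induced_group", []))),
            "n_gated_constitutive": int(len(analysis.get("constitutive_group", []))),
            "n_excluded_reduced": int(len(analysis.get("excluded_group", []))),
        }
        summary["mean_subdomain_width_kb"] = float(
            analysis["subdomains"]["width"].mean() / 1e3
        )
    if analysis["comparison"] is not None:
        comp = analysis["comparison"].summary()
        summary["hub_comparison"] = comp
        report = dict(comp)
        if analysis.get("comparison_by_density") is not None:
            report["by_density_bin"] = analysis["comparison_by_density"].to_dict(
                orient="records"
            )
        with open(outdir / "hub_comparison.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
    if analysis["typed_treated"] is not None and len(analysis["genes"]):
        links = dbs_gene_links(
            analysis["typed_treated"], landscape.genes, params.distal_threshold
        )
        if len(links) and len(analysis["sites"]) >= params.n_bins:
            sites = analysis["sites"].rename(columns={"peak_id": "site_id"})
            bins = differential.bin_sites_by_induction(
                sites, links, landscape.genes, n_bins=params.n_bins
            )
            bins.to_csv(outdir / "induction_bins.tsv", sep="\t", index=False,
                        float_format="%.6g")

    if params.run_fourc:
        fc = run_fourc_stage(landscape, params)
        for cond in CONDITIONS:
            fourc.write_bedgraph(
                fc["tracks"][cond], outdir / f"fourc_{cond}.bedgraph"
            )
            manifest["stages"][f"fourc_{cond}"] = fc["tallies"][cond]
        fourc.write_bedgraph(fc["delta"], outdir / "delta4c.bedgraph",
                             value_col="delta")
        manifest["stages"]["fourc_viewpoint"] = {
            "peak": fc["viewpoint_peak"], "site": fc["viewpoint_site"],
        }

    manifest["summary"] = summary
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return manifest
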