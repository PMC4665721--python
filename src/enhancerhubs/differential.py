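"""Dynamic binding sites and concentration-matched differential hubs.

Dynamic-site rule: per-site delta = treated - vehicle log2 RPKM; with
population median m and MAD = median(|delta - m|) (no consistency
constant), a site is induced when delta > m + 2*MAD, reduced when
delta < m - 2*MAD, constitutive otherwise (strict inequalities).  An
empirical two-sided p per site (the fraction of sites at least as far
from the median) is reported for transparency.

Hub comparison: subdomains are gated to >= 5 member co-factor peaks
and |concentration change| < 0.3 (concentration = mean member log2
RPKM), split into the group containing at least one induced site
versus the group with only constitutive sites, and their per-subdomain
interaction ratios r = treated / vehicle cluster count are compared
with a one-sided Mann-Whitney U test (induced stochastically greater).
The concentration gate matches the ChIP-enrichment bias of the two
libraries before counts are compared; the rank test absorbs their
coverage difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import assign_points_smallest_interval


def classify_dynamic_sites(
    sites: pd.DataFrame,
    vehicle_col: str = "log2_rpkm_vehicle",
    treated_col: str = "log2_rpkm_treated",
) -> pd.DataFrame:
    """Classify sites as induced / constitutive / reduced by the
    median +/- 2*MAD rule on delta log2 RPKM."""
    if len(sites) < 5:
        raise ValueError("need >= 5 sites; MAD is not meaningful below that")
    out = sites.copy()
    delta = out[treated_col].to_numpy(dtype=float) - out[vehicle_col].to_numpy(dtype=float)
    m = float(np.median(delta))
    mad = float(np.median(np.abs(delta - m)))
    if mad == 0.0:
        raise ValueError(
            "MAD of the delta distribution is 0 (degenerate population); "
            "the +/-2*MAD rule cannot classify; check for duplicated inputs"
        )
    out["delta"] = delta
    out["dynamic_class"] = np.where(
        delta > m + 2 * mad, "induced",
        np.where(delta < m - 2 * mad, "reduced", "constitutive"),
    )
    dev = np.abs(delta - m)
    order = np.argsort(dev, kind="stable")
    # empirical two-sided p: fraction of sites at least as deviant
    ranks = np.empty(len(dev), dtype=np.int64)
    ranks[order] = np.arange(len(dev))
    out["empirical_p"] = 1.0 - ranks / len(dev)
    out.attrs["median_delta"] = m
    out.attrs["mad_delta"] = mad
    return out


def site_locality(
    sites: pd.DataFrame, tss_by_chrom: dict[str, np.ndarray], distal_threshold: int = 5000
) -> pd.DataFrame:
    """Label each site distal (>threshold from every TSS) or promoter."""
    from .intervals import distances_to_nearest

    out = sites.copy()
    mids = ((out["start"] + out["end"]) // 2).to_numpy()
    chroms = out["chrom"].to_numpy()
    lab = np.empty(len(out), dtype=object)
    for chrom in np.unique(chroms):
        m = chroms == chrom
        tss = np.asarray(tss_by_chrom.get(chrom, np.empty(0, dtype=np.int64)))
        if tss.size == 0:
            lab[m] = "distal"
            continue
        d = distances_to_nearest(mids[m], tss)
        lab[m] = np.where(d > distal_threshold, "distal", "promoter")
    out["locality"] = lab
    return out


def subdomain_concentration(
    subdomains: pd.DataFrame,
    sites: pd.DataFrame,
    vehicle_col: str = "log2_rpkm_vehicle",
    treated_col: str = "log2_rpkm_treated",
) -> pd.DataFrame:
    """Per-subdomain co-factor concentration and its change.

    Membership is site midpoint within the subdomain footprint.
    Concentration per condition is the mean member log2 RPKM (the
    linear RPKM sum is also emitted); dC = treated - vehicle.
    """
    pts = pd.DataFrame(
        {"chrom": sites["chrom"], "pos": (sites["start"] + sites["end"]) // 2}
    )
    foot = subdomains[["subdomain", "chrom", "start", "end"]].reset_index(drop=True)
    idx = assign_points_smallest_interval(pts, foot)
    member_of = np.full(len(sites), -1, dtype=np.int64)
    ok = idx >= 0
    member_of[ok] = foot["subdomain"].to_numpy()[idx[ok]]

    out = subdomains.copy()
    rows = {}
    site_class = sites["dynamic_class"] if "dynamic_class" in sites else None
    for sid in out["subdomain"]:
        m = member_of == sid
        nm = int(m.sum())
        if nm == 0:
            rows[sid] = dict(n_sites=0, conc_vehicle=np.nan, conc_treated=np.nan,
                             dc=np.nan, sum_rpkm_vehicle=0.0, sum_rpkm_treated=0.0,
                             has_induced=False, has_reduced=False)
            continue
        cv = float(sites.loc[m, vehicle_col].mean())
        ct = float(sites.loc[m, treated_col].mean())
        rows[sid] = dict(
            n_sites=nm, conc_vehicle=cv, conc_treated=ct, dc=ct - cv,
            sum_rpkm_vehicle=float((2.0 ** sites.loc[m, vehicle_col]).sum()),
            sum_rpkm_treated=float((2.0 ** sites.loc[m, treated_col]).sum()),
            has_induced=bool((site_class[m] == "induced").any()) if site_class is not None else False,
            has_reduced=bool((site_class[m] == "reduced").any()) if site_class is not None else False,
        )
    extra = pd.DataFrame.from_dict(rows, orient="index")
    extra.index.name = "subdomain"
    return out.merge(extra, on="subdomain")


def select_matched_subdomains(
    subdomains: pd.DataFrame, min_peaks: int = 5, max_abs_dc: float = 0.3
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Concentration-matched induced / constitutive subdomain groups.

    Keeps subdomains with >= `min_peaks` member sites and
    -max_abs_dc < dC < max_abs_dc (strict).  The induced group contains
    at least one induced site; the constitutive group only constitutive
    sites; subdomains containing reduced sites are excluded and
    returned separately.
    """
    gated = subdomains[
        (subdomains["n_sites"] >= min_peaks)
        & (subdomains["dc"] > -max_abs_dc)
        & (subdomains["dc"] < max_abs_dc)
    ]
    induced = gated[gated["has_induced"]]
    excluded = gated[~gated["has_induced"] & gated["has_reduced"]]
    constitutive = gated[~gated["has_induced"] & ~gated["has_reduced"]]
    return (
        induced.reset_index(drop=True),
        constitutive.reset_index(drop=True),
        excluded.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U (exact for small untied samples, tie-corrected normal
# approximation otherwise)


@lru_cache(maxsize=None)
def _u_distribution(n1: int, n2: int) -> np.ndarray:
    """Counts of rank configurations per U value.

    Classic recursion on the largest rank: if it belongs to group 1 it
    contributes n2 wins, c(u; m, n) = c(u - n; m-1, n) + c(u; m, n-1).
    """
    size = n1 * n2 + 1
    # prev[m] = counts for (m, n-1); start at n = 0 where U must be 0
    prev = [np.zeros(size) for _ in range(n1 + 1)]
    for m in range(n1 + 1):
        prev[m][0] = 1.0
    for n in range(1, n2 + 1):
        cur = [np.zeros(size) for _ in range(n1 + 1)]
        cur[0][0] = 1.0
        for m in range(1, n1 + 1):
            shifted = np.zeros(size)
            if n < size:
                shifted[n:] = cur[m - 1][: size - n]
            cur[m] = shifted + prev[m]
        prev = cur
    return prev[n1]


def exact_mannwhitney_sf(u_obs: float, n1: int, n2: int) -> float:
    """P(U >= u_obs) under the null, by exact enumeration of rank sets."""
    dist = _u_distribution(n1, n2)
    total = dist.sum()
    u0 = int(np.ceil(u_obs - 1e-12))
    return float(dist[u0:].sum() / total)


def mannwhitney_one_sided(
    greater: np.ndarray, lesser: np.ndarray, exact_max_n: int = 20
) -> tuple[float, float, str]:
    """One-sided Mann-Whitney U: H1 = `greater` stochastically greater.

    Exact null distribution when combined n <= `exact_max_n` and there
    are no ties; otherwise normal approximation with tie correction and
    continuity correction.  Returns (U, p, method).
    """
    x = np.asarray(greater, dtype=float)
    y = np.asarray(lesser, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be nonempty")
    u = 0.0
    for xi in x:  # pair counting handles ties as 1/2
        u += float((xi > y).sum()) + 0.5 * float((xi == y).sum())
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    if n1 + n2 <= exact_max_n and not has_ties:
        return u, exact_mannwhitney_sf(u, n1, n2), "exact"
    combined = np.concatenate([x, y])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    mu = n1 * n2 / 2.0
    tie_term = float(((counts ** 3 - counts).sum())) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 0.5, "degenerate"
    z = (u - mu - 0.5) / np.sqrt(var)
    return u, float(stats.norm.sf(z)), "normal"


@dataclass
class HubComparison:
    """Result of the induced-vs-constitutive interaction-gain test."""

    induced_ids: list
    constitutive_ids: list
    induced_ratios: np.ndarray
    constitutive_ratios: np.ndarray
    u_statistic: float
    p_value: float
    method: str
    n_pseudocounted: int = 0
    notes: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "n_induced": len(self.induced_ids),
            "n_constitutive": len(self.constitutive_ids),
            "median_ratio_induced": float(np.median(self.induced_ratios)),
            "median_ratio_constitutive": float(np.median(self.constitutive_ratios)),
            "U": self.u_statistic,
            "p_one_sided": self.p_value,
            "method": self.method,
            "n_pseudocounted": self.n_pseudocounted,
        }


def interaction_ratios(
    subdomains: pd.DataFrame,
    treated_col: str = "n_clusters_treated",
    vehicle_col: str = "n_clusters_vehicle",
) -> tuple[np.ndarray, int]:
    """Per-subdomain treated/vehicle interaction ratio.

    Zero vehicle counts get a pseudocount of 1 on both numerator and
    denominator (flagged via the returned count), preserving ordering.
    """
    t = subdomains[treated_col].to_numpy(dtype=float)
    v = subdomains[vehicle_col].to_numpy(dtype=float)
    zero = v == 0
    r = np.where(zero, (t + 1) / (v + 1), t / np.where(zero, 1, v))
    return r, int(zero.sum())


def compare_interaction_gain(
    induced_group: pd.DataFrame, constitutive_group: pd.DataFrame
) -> HubComparison:
    """One-sided Mann-Whitney on per-subdomain interaction ratios."""
    if len(induced_group) == 0 or len(constitutive_group) == 0:
        raise ValueError("both subdomain groups must be nonempty")
    ri, zi = interaction_ratios(induced_group)
    rc, zc = interaction_ratios(constitutive_group)
    u, p, method = mannwhitney_one_sided(ri, rc)
    return HubComparison(
        induced_ids=list(induced_group["subdomain"]),
        constitutive_ids=list(constitutive_group["subdomain"]),
        induced_ratios=ri,
        constitutive_ratios=rc,
        u_statistic=u,
        p_value=p,
        method=method,
        n_pseudocounted=zi + zc,
    )


def compare_interaction_gain_by_density(
    induced_group: pd.DataFrame,
    constitutive_group: pd.DataFrame,
    n_bins: int = 3,
) -> pd.DataFrame:
    """The hub comparison repeated within co-factor density bins.

    Subdomains are pooled, ranked by average concentration across
    conditions, and cut into `n_bins` quantile bins; the one-sided
    Mann-Whitney runs within each bin that holds members of both
    groups.  Guards against residual density confounding beyond the
    |dC| gate.
    """
    ind = induced_group.assign(_grp="induced")
    con = constitutive_group.assign(_grp="constitutive")
    both = pd.concat([ind, con], ignore_index=True)
    dens = (both["conc_vehicle"] + both["conc_treated"]) / 2.0
    both["_bin"] = pd.qcut(dens.rank(method="first"), n_bins, labels=False)
    rows = []
    for b, grp in both.groupby("_bin", sort=True):
        gi = grp[grp["_grp"] == "induced"]
        gc = grp[grp["_grp"] == "constitutive"]
        if len(gi) == 0 or len(gc) == 0:
            rows.append({"bin": int(b), "n_induced": len(gi),
                         "n_constitutive": len(gc), "U": np.nan,
                         "p_one_sided": np.nan, "method": "skipped"})
            continue
        ri, _ = interaction_ratios(gi)
        rc, _ = interaction_ratios(gc)
        u, p, method = mannwhitney_one_sided(ri, rc)
        rows.append({"bin": int(b), "n_induced": len(gi),
                     "n_constitutive": len(gc), "U": u,
                     "p_one_sided": p, "method": method})
    return pd.DataFrame(rows)


def compare_4c_at_sites(
    site_signals: pd.DataFrame,
    class_col: str = "dynamic_class",
    vehicle_col: str = "signal_vehicle",
    treated_col: str = "signal_treated",
) -> pd.DataFrame:
    """Per-class mean 4C signals with a paired one-sided t-test.

    Tests treated > vehicle within each dynamic class (>= 3 sites per
    class required).  Zero-variance differences are guarded: all-zero
    differences give p = 0.5, constant nonzero differences give 0 or 1.
    """
    rows = []
    for cls, grp in site_signals.groupby(class_col, sort=True):
        if len(grp) < 3:
            raise ValueError(f"class {cls!r} has fewer than 3 sites")
        v = grp[vehicle_col].to_numpy(dtype=float)
        t = grp[treated_col].to_numpy(dtype=float)
        d = t - v
        sd = d.std(ddof=1)
        if sd == 0.0:
            tstat = 0.0 if d[0] == 0 else np.inf * np.sign(d[0])
            p = 0.5 if d[0] == 0 else (0.0 if d[0] > 0 else 1.0)
        else:
            tstat = d.mean() / (sd / np.sqrt(d.size))
            p = float(stats.t.sf(tstat, df=d.size - 1))
        rows.append(
            {
                "class": cls, "n_sites": len(grp),
                "mean_vehicle": float(v.mean()), "mean_treated": float(t.mean()),
                "mean_diff": float(d.mean()), "t": float(tstat), "p_one_sided": p,
            }
        )
    return pd.DataFrame(rows)


def bin_sites_by_induction(
    sites: pd.DataFrame,
    links: pd.DataFrame,
    genes: pd.DataFrame,
    n_bins: int = 10,
    vehicle_col: str = "density_vehicle",
    treated_col: str = "density_treated",
) -> pd.DataFrame:
    """Order DBSs by induction and average looped-gene expression change.

    `links` maps site ids to gene ids (DBS-promoter contacts); genes
    without a looped DBS never enter a bin.  Sites are sorted by delta
    (ascending) and split into `n_bins` nearly equal bins (earlier bins
    take the extras).  Per-bin output: mean site delta and the mean
    log2 expression change of linked genes (unique per bin).
    """
    if len(sites) < n_bins:
        raise ValueError("fewer sites than bins")
    s = sites.sort_values(["delta", "site_id"], kind="stable").reset_index(drop=True)
    gexpr = genes.set_index("id")
    chunks = np.array_split(np.arange(len(s)), n_bins)
    link_map = links.groupby("site_id")["gene_id"].apply(list)
    rows = []
    for b, idx in enumerate(chunks):
        bin_sites = s.loc[idx, "site_id"]
        gene_ids: set = set()
        for sid in bin_sites:
            gene_ids.update(link_map.get(sid, []))
        if gene_ids:
            gg = gexpr.loc[sorted(gene_ids)]
            change = float(
                np.log2(gg[treated_col].to_numpy() / gg[vehicle_col].to_numpy()).mean()
            )
        else:
            change = np.nan
        rows.append(
            {
                "bin": b, "n_sites": len(idx), "n_genes": len(gene_ids),
                "mean_site_delta": float(s.loc[idx, "delta"].mean()),
                "mean_expression_change": change,
            }
        )
    return pd.DataFrame(rows)


def subdomain_expression_change(
    induced_group: pd.DataFrame,
    constitutive_group: pd.DataFrame,
    genes: pd.DataFrame,
    vehicle_col: str = "density_vehicle",
    treated_col: str = "density_treated",
) -> dict:
    """Expression change of genes inside each subdomain group.

    A gene belongs to a subdomain when its TSS lies inside the
    footprint.  Returns group means of log2 density change and a
    one-sided Mann-Whitney p (induced greater).
    """
    def _changes(group):
        foot = group[["subdomain", "chrom", "start", "end"]].reset_index(drop=True)
        pts = pd.DataFrame({"chrom": genes["chrom"], "pos": genes["tss"]})
        idx = assign_points_smallest_interval(pts, foot)
        sel = genes[idx >= 0]
        return np.log2(
            sel[treated_col].to_numpy(dtype=float) / sel[vehicle_col].to_numpy(dtype=float)
        )

    ci = _changes(induced_group)
    cc = _changes(constitutive_group)
    if ci.size == 0 or cc.size == 0:
        raise ValueError("a subdomain group contains no genes")
    u, p, method = mannwhitney_one_sided(ci, cc)
    return {
        "n_genes_induced": int(ci.size),
        "n_genes_constitutive": int(cc.size),
        "mean_change_induced": float(ci.mean()),
        "mean_change_constitutive": float(cc.mean()),
        "U": u, "p_one_sided": p, "method": method,
    }
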