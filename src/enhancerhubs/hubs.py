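"""Interaction subdomains (hubs) and their structural annotations.

Clusters whose anchors overlap by at least 1 bp or are book-ended
(half-open adjacency, end == start) belong to the same subdomain; a
subdomain is a connected component of clusters under that relation.
The subdomain footprint spans from the smallest anchor start to the
largest anchor end of its members, and is the unit of the differential
hub analysis.

Annotation read-outs mirror the standard descriptive statistics of
enhancer-centric interactomes: DBS/promoter interaction-type
proportions (an anchor is a promoter if within 5 kb of a TSS),
P300-rich / POLII-rich / shared subdomain classes, confinement of
interactions within externally supplied domains (e.g. replication
timing), and the fraction of distal sites that skip their nearest
active TSS.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import assign_points_to_intervals, distances_to_nearest


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def collapse_subdomains(
    clusters: pd.DataFrame, anchors: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse clusters into subdomains by anchor interconnectivity.

    Two clusters are connected when any anchor of one overlaps (>= 1 bp)
    or book-ends any anchor of the other; shared anchors connect
    trivially.  Returns ``(subdomains, clusters_with_subdomain)`` where
    subdomains carry id, footprint, width, member counts and (if the
    clusters have a ``condition`` column) per-condition cluster counts.
    """
    clusters = clusters.reset_index(drop=True)
    if len(clusters) == 0:
        cols = ["subdomain", "chrom", "start", "end", "width",
                "n_clusters", "n_anchors"]
        return pd.DataFrame(columns=cols), clusters.assign(subdomain=[])

    anchors = anchors.reset_index(drop=True)
    used = np.unique(
        np.concatenate([clusters["anchor_a"].to_numpy(), clusters["anchor_b"].to_numpy()])
    )
    sub_a = anchors.loc[used]
    # merge overlapping/book-ended anchor intervals into adjacency groups;
    # within a chromosome, sorted intervals chain transitively
    group_of: dict[int, int] = {}
    gid = 0
    for chrom, sub in sub_a.groupby("chrom", sort=False):
        sub = sub.sort_values(["start", "end"])
        cur_end = None
        for aid, s, e in zip(sub.index, sub["start"], sub["end"]):
            if cur_end is None or s > cur_end:  # strict gap: book-end (s==end) joins
                gid += 1
                cur_end = e
            else:
                cur_end = max(cur_end, e)
            group_of[int(aid)] = gid
    ga = clusters["anchor_a"].map(group_of).to_numpy()
    gb = clusters["anchor_b"].map(group_of).to_numpy()

    uf = _UnionFind(len(clusters))
    first_in_group: dict[int, int] = {}
    for ci in range(len(clusters)):
        for g in (ga[ci], gb[ci]):
            if g in first_in_group:
                uf.union(first_in_group[g], ci)
            else:
                first_in_group[g] = ci
    roots = np.array([uf.find(i) for i in range(len(clusters))])
    _, comp = np.unique(roots, return_inverse=True)

    out = clusters.copy()
    out["subdomain"] = comp
    rows = []
    for sid, grp in out.groupby("subdomain", sort=True):
        aids = np.unique(np.concatenate([grp["anchor_a"].to_numpy(), grp["anchor_b"].to_numpy()]))
        a_int = anchors.loc[aids]
        start = int(a_int["start"].min())
        end = int(a_int["end"].max())
        row = {
            "subdomain": int(sid),
            "chrom": grp["chrom"].iloc[0],
            "start": start,
            "end": end,
            "width": end - start,
            "n_clusters": int(len(grp)),
            "n_anchors": int(len(aids)),
            "anchor_ids": tuple(int(x) for x in aids),
        }
        if "condition" in grp.columns:
            for cond, cnt in grp["condition"].value_counts().items():
                row[f"n_clusters_{cond}"] = int(cnt)
        rows.append(row)
    subdomains = pd.DataFrame(rows)
    if "condition" in out.columns:
        for cond in out["condition"].unique():
            col = f"n_clusters_{cond}"
            if col not in subdomains:
                subdomains[col] = 0
            subdomains[col] = subdomains[col].fillna(0).astype(int)
    return subdomains, out


def annotate_interaction_types(
    clusters: pd.DataFrame,
    tss_by_chrom: dict[str, np.ndarray],
    distal_threshold: int = 5000,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Type each cluster as DBS-DBS / DBS-promoter / promoter-promoter.

    An anchor is a promoter anchor when its midpoint lies within
    `distal_threshold` of some TSS (distance 0 if a TSS falls inside
    the anchor, which midpoint distance approximates for peak-scale
    anchors); otherwise it is a distal binding site (DBS).
    """
    if not tss_by_chrom or all(len(v) == 0 for v in tss_by_chrom.values()):
        raise ValueError("gene TSS list is empty")
    out = clusters.copy()
    labels = {}
    for side in ("a", "b"):
        mids = ((out[f"start_{side}"] + out[f"end_{side}"]) // 2).to_numpy()
        chroms = out["chrom"].to_numpy()
        lab = np.empty(len(out), dtype=object)
        for chrom in np.unique(chroms):
            m = chroms == chrom
            tss = tss_by_chrom.get(chrom, np.empty(0, dtype=np.int64))
            if len(tss) == 0:
                lab[m] = "DBS"
                continue
            d = distances_to_nearest(mids[m], np.asarray(tss))
            lab[m] = np.where(d <= distal_threshold, "promoter", "DBS")
        labels[side] = lab
    pair = np.sort(np.stack([labels["a"], labels["b"]]), axis=0)
    type_name = np.where(
        (pair[0] == "DBS") & (pair[1] == "DBS"), "DBS-DBS",
        np.where((pair[0] == "DBS"), "DBS-promoter", "promoter-promoter"),
    )
    out["anchor_a_label"] = labels["a"]
    out["anchor_b_label"] = labels["b"]
    out["interaction_type"] = type_name
    n = max(len(out), 1)
    props = {
        t: float((type_name == t).sum()) / n
        for t in ("DBS-DBS", "DBS-promoter", "promoter-promoter")
    }
    return out, props


def classify_subdomain_sharing(
    p300_subdomains: pd.DataFrame,
    polii_subdomains: pd.DataFrame,
    p300_anchors: pd.DataFrame | None = None,
    polii_anchors: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Label subdomains P300-rich / POLII-rich / shared by footprint overlap.

    Shared means footprints overlap by >= 1 bp (book-ended footprints
    are not shared).  For each shared pair the anchor-share percentage
    is |anchors overlapping reciprocally >= 1 bp| / |union of anchors|,
    when anchor tables are supplied.
    """
    def _label(subs, others, rich_label):
        subs = subs.copy()
        lab = []
        partners = []
        for _, row in subs.iterrows():
            m = others[
                (others["chrom"] == row["chrom"])
                & (others["start"] < row["end"])
                & (others["end"] > row["start"])
            ]
            if len(m):
                lab.append("shared")
                partners.append(tuple(int(x) for x in m["subdomain"]))
            else:
                lab.append(rich_label)
                partners.append(())
        subs["share_class"] = lab
        subs["partners"] = partners
        return subs

    p300 = _label(p300_subdomains, polii_subdomains, "P300-rich")
    polii = _label(polii_subdomains, p300_subdomains, "POLII-rich")

    pair_rows = []
    if p300_anchors is not None and polii_anchors is not None:
        pa = p300_anchors.reset_index(drop=True)
        qa = polii_anchors.reset_index(drop=True)
        for _, row in p300[p300["share_class"] == "shared"].iterrows():
            for sid in row["partners"]:
                other = polii.loc[polii["subdomain"] == sid].iloc[0]
                ids_p = list(row["anchor_ids"])
                ids_q = list(other["anchor_ids"])
                iv_p = pa.loc[ids_p]
                iv_q = qa.loc[ids_q]
                shared_p = set()
                shared_q = set()
                for i, (s1, e1) in zip(iv_p.index, zip(iv_p["start"], iv_p["end"])):
                    hit = iv_q[(iv_q["start"] < e1) & (iv_q["end"] > s1)]
                    if len(hit):
                        shared_p.add(int(i))
                        shared_q.update(int(x) for x in hit.index)
                n_shared = len(shared_p) + len(shared_q)
                n_union = len(ids_p) + len(ids_q)
                pair_rows.append(
                    {
                        "p300_subdomain": int(row["subdomain"]),
                        "polii_subdomain": int(sid),
                        "n_shared_anchors": n_shared,
                        "n_union_anchors": n_union,
                        "anchor_share_pct": 100.0 * n_shared / n_union if n_union else 0.0,
                    }
                )
    return p300, polii, pd.DataFrame(pair_rows)


def domain_containment(
    clusters: pd.DataFrame, domains: pd.DataFrame
) -> tuple[float, pd.DataFrame]:
    """Fraction of clusters whose two anchors lie inside one domain.

    Domains must be non-overlapping; overlap raises.  Returns the
    confined fraction and per-domain cluster counts.
    """
    for chrom, sub in domains.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
            raise ValueError("domains overlap")
    domains = domains.reset_index(drop=True)
    n = len(clusters)
    if n == 0:
        return 0.0, pd.DataFrame(columns=["domain", "n_confined"])
    dom = {}
    for side in ("a", "b"):
        pts_start = pd.DataFrame(
            {"chrom": clusters["chrom"], "pos": clusters[f"start_{side}"]}
        )
        pts_end = pd.DataFrame(
            {"chrom": clusters["chrom"], "pos": clusters[f"end_{side}"] - 1}
        )
        d1 = assign_points_to_intervals(pts_start, domains)
        d2 = assign_points_to_intervals(pts_end, domains)
        dom[side] = np.where(d1 == d2, d1, -1)  # whole anchor inside one domain
    confined = (dom["a"] >= 0) & (dom["a"] == dom["b"])
    frac = float(confined.sum()) / n
    per = (
        pd.Series(dom["a"][confined]).value_counts().rename_axis("domain")
        .reset_index(name="n_confined")
    )
    return frac, per


def nearest_tss_fraction(
    typed_clusters: pd.DataFrame, genes: pd.DataFrame, distal_threshold: int = 5000
) -> tuple[float, pd.DataFrame]:
    """Fraction of DBS-promoter contacts that skip the nearest active TSS.

    For each DBS-promoter cluster, the contacted TSS is the active TSS
    nearest to the promoter anchor midpoint; it is compared with the
    active TSS nearest to the DBS anchor midpoint.
    """
    active = genes[genes["active"].astype(bool)]
    if len(active) == 0:
        raise ValueError("no active genes")
    sel = typed_clusters[typed_clusters["interaction_type"] == "DBS-promoter"]
    rows = []
    for _, row in sel.iterrows():
        if row["anchor_a_label"] == "DBS":
            dbs_mid = (row["start_a"] + row["end_a"]) // 2
            prom_mid = (row["start_b"] + row["end_b"]) // 2
        else:
            dbs_mid = (row["start_b"] + row["end_b"]) // 2
            prom_mid = (row["start_a"] + row["end_a"]) // 2
        tss = active.loc[active["chrom"] == row["chrom"], "tss"].to_numpy()
        if tss.size == 0:
            continue
        tss = np.sort(tss)
        contacted = tss[np.argmin(np.abs(tss - prom_mid))]
        nearest = tss[np.argmin(np.abs(tss - dbs_mid))]
        rows.append(
            {
                "chrom": row["chrom"], "dbs_mid": int(dbs_mid),
                "contacted_tss": int(contacted), "nearest_active_tss": int(nearest),
                "skips_nearest": bool(contacted != nearest),
            }
        )
    detail = pd.DataFrame(rows)
    frac = float(detail["skips_nearest"].mean()) if len(detail) else 0.0
    return frac, detail


def site_distribution_by_class(
    sites: pd.DataFrame, labeled_subdomains: pd.DataFrame
) -> dict[str, float]:
    """Proportion of binding sites per subdomain share-class.

    Each site goes to the class of the subdomain footprint containing
    its midpoint ('outside' if none; 'shared' if footprints of several
    classes contain it).  Proportions over all sites sum to 1; the
    inside-only renormalization is reported under ``*_of_inside``.
    """
    mids = ((sites["start"] + sites["end"]) // 2).to_numpy()
    chroms = sites["chrom"].to_numpy()
    classes = []
    subs = labeled_subdomains
    for mid, chrom in zip(mids, chroms):
        hit = subs[(subs["chrom"] == chrom) & (subs["start"] <= mid) & (mid < subs["end"])]
        found = set(hit["share_class"]) if len(hit) else set()
        if not found:
            classes.append("outside")
        elif len(found) == 1:
            classes.append(next(iter(found)))
        else:
            classes.append("shared")
    counts = pd.Series(classes).value_counts()
    n = len(sites)
    out = {k: float(v) / n for k, v in counts.items()}
    inside = n - counts.get("outside", 0)
    if inside:
        for k, v in counts.items():
            if k != "outside":
                out[f"{k}_of_inside"] = float(v) / inside
    return out
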