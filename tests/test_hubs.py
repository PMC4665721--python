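"""Subdomain collapsing and the structural annotation read-outs."""

import numpy as np
import pandas as pd
import pytest

from enhancerhubs.hubs import (
    annotate_interaction_types,
    classify_subdomain_sharing,
    collapse_subdomains,
    domain_containment,
    nearest_tss_fraction,
    site_distribution_by_class,
)
from tests.conftest import make_anchors, make_pets


def clusters_from(anchor_pairs, anchors, chrom="chr1", condition=None):
    rows = []
    for i, (a, b) in enumerate(anchor_pairs):
        row = {
            "anchor_a": a, "anchor_b": b,
            "chrom": anchors.loc[a, "chrom"],
            "start_a": anchors.loc[a, "start"], "end_a": anchors.loc[a, "end"],
            "start_b": anchors.loc[b, "start"], "end_b": anchors.loc[b, "end"],
            "k": 2,
        }
        if condition is not None:
            row["condition"] = condition[i]
        rows.append(row)
    return pd.DataFrame(rows)


def brute_force_components(clusters, anchors):
    """Independent oracle: pairwise overlap/book-end graph, components
    via networkx."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(clusters)))
    ivs = [
        [
            (anchors.loc[r["anchor_a"], "chrom"],
             anchors.loc[r["anchor_a"], "start"], anchors.loc[r["anchor_a"], "end"]),
            (anchors.loc[r["anchor_b"], "chrom"],
             anchors.loc[r["anchor_b"], "start"], anchors.loc[r["anchor_b"], "end"]),
        ]
        for _, r in clusters.iterrows()
    ]
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            for (c1, s1, e1) in ivs[i]:
                for (c2, s2, e2) in ivs[j]:
                    if c1 == c2 and s1 <= e2 and s2 <= e1:  # overlap or book-end
                        g.add_edge(i, j)
    return list(nx.connected_components(g))


class TestCollapseSubdomains:
    def test_overlapping_anchors_merge(self):
        anchors = make_anchors((100, 200), (5000, 5100), (150, 300), (9000, 9100))
        clusters = clusters_from([(0, 1), (2, 3)], anchors)
        subs, assigned = collapse_subdomains(clusters, anchors)
        assert len(subs) == 1
        assert subs["width"].iloc[0] == 9100 - 100

    def test_bookended_anchors_connect(self):
        anchors = make_anchors((100, 200), (5000, 5100), (200, 300), (9000, 9100))
        clusters = clusters_from([(0, 1), (2, 3)], anchors)
        subs, _ = collapse_subdomains(clusters, anchors)
        assert len(subs) == 1

    def test_gap_of_one_bp_does_not_connect(self):
        anchors = make_anchors((100, 200), (5000, 5100), (201, 300), (9000, 9100))
        clusters = clusters_from([(0, 1), (2, 3)], anchors)
        subs, _ = collapse_subdomains(clusters, anchors)
        assert len(subs) == 2

    def test_different_chromosomes_stay_apart(self):
        anchors = make_anchors((100, 200), (5000, 5100),
                               (100, 200, "chr2"), (5000, 5100, "chr2"))
        clusters = clusters_from([(0, 1), (2, 3)], anchors)
        subs, _ = collapse_subdomains(clusters, anchors)
        assert len(subs) == 2

    def test_matches_brute_force_on_random_instances(self, rng):
        """Oracle equivalence on 100 random instances of <= 50 clusters."""
        for _ in range(100):
            n_anchors = int(rng.integers(4, 30))
            starts = rng.integers(0, 200_000, size=n_anchors)
            widths = rng.integers(50, 3000, size=n_anchors)
            chroms = rng.choice(["chr1", "chr2"], size=n_anchors)
            anchors = pd.DataFrame(
                {"chrom": chroms, "start": starts, "end": starts + widths}
            )
            n_clusters = int(rng.integers(1, 51))
            pair_pool = [
                (a, b)
                for a in range(n_anchors)
                for b in range(n_anchors)
                if a < b and chroms[a] == chroms[b]
            ]
            if not pair_pool:
                continue
            idx = rng.integers(0, len(pair_pool), size=n_clusters)
            clusters = clusters_from([pair_pool[i] for i in idx], anchors)
            subs, assigned = collapse_subdomains(clusters, anchors)
            ours = {}
            for ci, sid in enumerate(assigned["subdomain"]):
                ours.setdefault(sid, set()).add(ci)
            expected = brute_force_components(clusters, anchors)
            assert sorted(map(sorted, ours.values())) == sorted(
                map(sorted, expected)
            )

    def test_width_at_least_widest_member_span(self, rng):
        anchors = make_anchors(*[(i * 7000, i * 7000 + 500) for i in range(10)])
        pairs = [tuple(sorted(rng.choice(10, 2, replace=False))) for _ in range(15)]
        clusters = clusters_from(pairs, anchors)
        subs, assigned = collapse_subdomains(clusters, anchors)
        merged = assigned.merge(subs[["subdomain", "width"]], on="subdomain")
        span = merged["end_b"].to_numpy() - merged["start_a"].to_numpy()
        assert (merged["width"].to_numpy() >= span).all()

    def test_per_condition_counts(self):
        anchors = make_anchors((0, 100), (10_000, 10_100))
        clusters = clusters_from(
            [(0, 1), (0, 1), (0, 1)], anchors,
            condition=["vehicle", "treated", "treated"],
        )
        subs, _ = collapse_subdomains(clusters, anchors)
        assert subs["n_clusters_vehicle"].iloc[0] == 1
        assert subs["n_clusters_treated"].iloc[0] == 2


class TestInteractionTypes:
    def _setup(self):
        anchors = make_anchors((10_000, 10_400), (50_000, 50_400),
                               (120_000, 120_400))
        tss = {"chr1": np.array([51_000, 300_000])}
        return anchors, tss

    def test_rule_application(self):
        anchors, tss = self._setup()
        clusters = clusters_from([(0, 2), (0, 1)], anchors)
        typed, props = annotate_interaction_types(clusters, tss)
        assert list(typed["interaction_type"]) == ["DBS-DBS", "DBS-promoter"]

    def test_proportions_counting(self):
        anchors, tss = self._setup()
        pairs = [(0, 2)] * 6 + [(0, 1)] * 2 + [(1, 1)] * 2
        typed, props = annotate_interaction_types(clusters_from(pairs, anchors), tss)
        assert props == {"DBS-DBS": 0.6, "DBS-promoter": 0.2,
                         "promoter-promoter": 0.2}
        assert sum(props.values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_gene_list_rejected(self):
        anchors, _ = self._setup()
        with pytest.raises(ValueError):
            annotate_interaction_types(clusters_from([(0, 1)], anchors), {})


class TestSubdomainSharing:
    def _subs(self, rows, anchor_ids):
        df = pd.DataFrame(rows, columns=["subdomain", "chrom", "start", "end"])
        df["anchor_ids"] = anchor_ids
        return df

    def test_disjoint_footprints_get_rich_labels(self):
        p = self._subs([(0, "chr1", 0, 100_000)], [(0,)])
        q = self._subs([(0, "chr1", 200_000, 300_000)], [(0,)])
        lp, lq, pairs = classify_subdomain_sharing(p, q)
        assert lp["share_class"].iloc[0] == "P300-rich"
        assert lq["share_class"].iloc[0] == "POLII-rich"
        assert len(pairs) == 0

    def test_identical_anchor_sets_share_everything(self):
        anchors = make_anchors((0, 100), (10_000, 10_100))
        p = self._subs([(0, "chr1", 0, 10_100)], [(0, 1)])
        q = self._subs([(0, "chr1", 0, 10_100)], [(0, 1)])
        lp, lq, pairs = classify_subdomain_sharing(p, q, anchors, anchors)
        assert lp["share_class"].iloc[0] == "shared"
        assert pairs["anchor_share_pct"].iloc[0] == pytest.approx(100.0)

    def test_three_shared_of_six_union(self):
        # P300 anchors 0..3 ; POLII anchors overlap only the first two
        pa = make_anchors((0, 100), (10_000, 10_100), (20_000, 20_100))
        qa = make_anchors((50, 150), (30_000, 30_100), (40_000, 40_100))
        p = self._subs([(0, "chr1", 0, 20_100)], [(0, 1, 2)])
        q = self._subs([(0, "chr1", 50, 40_100)], [(0, 1, 2)])
        _, _, pairs = classify_subdomain_sharing(p, q, pa, qa)
        # anchors pa0 and qa0 overlap reciprocally: 2 shared of 6 union
        assert pairs["n_shared_anchors"].iloc[0] == 2
        assert pairs["n_union_anchors"].iloc[0] == 6
        assert pairs["anchor_share_pct"].iloc[0] == pytest.approx(100 * 2 / 6)


class TestDomainContainment:
    def _domains(self):
        return pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 100_000],
             "end": [50_000, 150_000]}
        )

    def test_confined_and_split_clusters(self):
        anchors = make_anchors((1000, 1400), (30_000, 30_400), (120_000, 120_400))
        clusters = clusters_from([(0, 1), (0, 2)], anchors)
        frac, per = domain_containment(clusters, self._domains())
        assert frac == pytest.approx(0.5)

    def test_overlapping_domains_rejected(self):
        doms = pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [0, 40_000], "end": [50_000, 90_000]}
        )
        anchors = make_anchors((1000, 1400), (30_000, 30_400))
        with pytest.raises(ValueError):
            domain_containment(clusters_from([(0, 1)], anchors), doms)

    def test_simulated_edges_confined_to_true_blocks(self, small_landscape):
        """True edges live inside subdomain blocks by construction."""
        peaks = small_landscape.peaks
        e = small_landscape.edges
        anchors = small_landscape.peak_bed().rename(columns={"peak_id": "name"})
        clusters = clusters_from(
            list(zip(e["peak_a"], e["peak_b"])), anchors[["chrom", "start", "end"]]
        )
        frac, _ = domain_containment(
            clusters, small_landscape.subdomains[["chrom", "start", "end"]]
        )
        assert frac == 1.0


class TestNearestTss:
    def _genes(self, tss_list, active=None):
        n = len(tss_list)
        return pd.DataFrame({
            "id": [f"g{i}" for i in range(n)], "chrom": "chr1",
            "strand": "+", "tss": tss_list, "tes": [t + 10_000 for t in tss_list],
            "active": active if active is not None else [True] * n,
        })

    def _typed(self, dbs_iv, prom_iv):
        return pd.DataFrame([{
            "chrom": "chr1",
            "start_a": dbs_iv[0], "end_a": dbs_iv[1], "anchor_a_label": "DBS",
            "start_b": prom_iv[0], "end_b": prom_iv[1],
            "anchor_b_label": "promoter",
            "interaction_type": "DBS-promoter",
        }])

    def test_skipping_nearest_active_tss(self):
        # DBS at 10,000; active TSSs at 12,000 and 50,000; contacted 50,000
        typed = self._typed((9900, 10_100), (49_800, 50_200))
        frac, detail = nearest_tss_fraction(typed, self._genes([12_000, 50_000]))
        assert frac == 1.0
        assert detail["nearest_active_tss"].iloc[0] == 12_000

    def test_contacting_nearest_counts_as_nearest(self):
        typed = self._typed((9900, 10_100), (11_800, 12_200))
        frac, _ = nearest_tss_fraction(typed, self._genes([12_000, 50_000]))
        assert frac == 0.0

    def test_single_active_gene_forces_zero(self):
        typed = self._typed((9900, 10_100), (49_800, 50_200))
        frac, _ = nearest_tss_fraction(
            typed, self._genes([50_000, 80_000], active=[True, False])
        )
        assert frac == 0.0

    def test_no_active_genes_rejected(self):
        typed = self._typed((9900, 10_100), (49_800, 50_200))
        with pytest.raises(ValueError):
            nearest_tss_fraction(typed, self._genes([50_000], active=[False]))


class TestSiteDistribution:
    def test_counting(self):
        subs = pd.DataFrame(
            {"subdomain": [0], "chrom": ["chr1"], "start": [0], "end": [100_000],
             "share_class": ["P300-rich"]}
        )
        sites = make_anchors(*(
            [(i * 10_000, i * 10_000 + 400) for i in range(6)]
            + [(200_000 + i * 10_000, 200_400 + i * 10_000) for i in range(4)]
        ))
        props = site_distribution_by_class(sites, subs)
        assert props["P300-rich"] == pytest.approx(0.6)
        assert props["outside"] == pytest.approx(0.4)
        assert props["P300-rich_of_inside"] == pytest.approx(1.0)
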