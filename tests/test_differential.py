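"""Dynamic-site classification, Mann-Whitney machinery, gating,
4C paired comparison and expression linkage."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from enhancerhubs.differential import (
    bin_sites_by_induction,
    classify_dynamic_sites,
    compare_4c_at_sites,
    compare_interaction_gain,
    exact_mannwhitney_sf,
    interaction_ratios,
    mannwhitney_one_sided,
    select_matched_subdomains,
    subdomain_concentration,
    subdomain_expression_change,
)


def sites_from_deltas(deltas):
    n = len(deltas)
    return pd.DataFrame({
        "chrom": "chr1",
        "start": np.arange(n) * 10_000,
        "end": np.arange(n) * 10_000 + 400,
        "log2_rpkm_vehicle": np.zeros(n),
        "log2_rpkm_treated": np.asarray(deltas, dtype=float),
    })


class TestClassifyDynamicSites:
    def test_worked_seven_value_vector(self):
        out = classify_dynamic_sites(
            sites_from_deltas([-0.2, -0.1, 0.0, 0.0, 0.1, 0.2, 3.0])
        )
        # m = 0.0, MAD = 0.1, bounds +/-0.2; boundary values stay constitutive
        assert out.attrs["median_delta"] == pytest.approx(0.0)
        assert out.attrs["mad_delta"] == pytest.approx(0.1)
        assert list(out["dynamic_class"]) == ["constitutive"] * 6 + ["induced"]

    def test_symmetric_outliers(self):
        out = classify_dynamic_sites(
            sites_from_deltas([0.0, -0.1, 0.1, 0.0, 0.0, 5.0, -5.0])
        )
        cls = out["dynamic_class"]
        assert (cls == "induced").sum() == 1 and (cls == "reduced").sum() == 1

    def test_degenerate_population_rejected(self):
        with pytest.raises(ValueError, match="MAD"):
            classify_dynamic_sites(sites_from_deltas([0.3] * 8))

    def test_too_few_sites_rejected(self):
        with pytest.raises(ValueError):
            classify_dynamic_sites(sites_from_deltas([0.1, 0.2, 0.3, 0.4]))

    def test_empirical_p_ranks_extremes_lowest(self):
        out = classify_dynamic_sites(
            sites_from_deltas([-0.2, -0.1, 0.0, 0.0, 0.1, 0.2, 3.0])
        )
        assert out["empirical_p"].idxmin() == 6


class TestMannWhitney:
    def test_complete_separation_three_vs_three(self):
        u, p, method = mannwhitney_one_sided([2.0, 3.0, 2.5], [1.0, 0.9, 1.1])
        assert u == 9
        assert p == pytest.approx(1 / 20)
        assert method == "exact"

    def test_single_pair(self):
        _, p, _ = mannwhitney_one_sided([2.0], [1.0])
        assert p == pytest.approx(0.5)

    def test_identical_multisets_not_significant(self):
        _, p, _ = mannwhitney_one_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.5

    def test_exact_matches_full_enumeration(self):
        """All group sizes with combined n <= 8 against rank enumeration."""
        for n1 in range(1, 8):
            for n2 in range(1, 9 - n1):
                ranks = range(n1 + n2)
                us = []
                for grp1 in itertools.combinations(ranks, n1):
                    grp2 = [r for r in ranks if r not in grp1]
                    u = sum(1 for a in grp1 for b in grp2 if a > b)
                    us.append(u)
                us = np.asarray(us)
                for u_obs in range(n1 * n2 + 1):
                    assert exact_mannwhitney_sf(u_obs, n1, n2) == pytest.approx(
                        (us >= u_obs).mean()
                    ), (n1, n2, u_obs)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        x=st.lists(st.integers(0, 1000), min_size=2, max_size=9, unique=True),
        y=st.lists(st.integers(1001, 2000), min_size=2, max_size=9, unique=True),
    )
    def test_exact_agrees_with_scipy(self, x, y):
        x = [v + 0.5 for v in x]  # no ties with y by construction
        u, p, method = mannwhitney_one_sided(x, y, exact_max_n=20)
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="exact")
        assert u == ref.statistic
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_large_samples_use_tie_corrected_normal(self, rng):
        x = rng.integers(0, 5, 30).astype(float)
        y = rng.integers(0, 5, 30).astype(float)
        _, p, method = mannwhitney_one_sided(x, y)
        assert method == "normal"
        ref = stats.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestConcentrationAndGates:
    def _subdomains(self, rows):
        return pd.DataFrame(
            rows,
            columns=["subdomain", "chrom", "start", "end", "n_sites", "dc",
                     "has_induced", "has_reduced",
                     "n_clusters_vehicle", "n_clusters_treated"],
        )

    def test_concentration_arithmetic(self):
        subs = pd.DataFrame(
            {"subdomain": [0], "chrom": ["chr1"], "start": [0], "end": [100_000]}
        )
        sites = pd.DataFrame({
            "chrom": "chr1", "start": [10_000, 20_000], "end": [10_400, 20_400],
            "log2_rpkm_vehicle": [2.0, 4.0], "log2_rpkm_treated": [2.6, 4.6],
        })
        out = subdomain_concentration(subs, sites)
        assert out["conc_vehicle"].iloc[0] == pytest.approx(3.0)
        assert out["dc"].iloc[0] == pytest.approx(0.6)
        assert out["n_sites"].iloc[0] == 2

    def test_single_site_subdomain(self):
        subs = pd.DataFrame(
            {"subdomain": [0], "chrom": ["chr1"], "start": [0], "end": [100_000]}
        )
        sites = pd.DataFrame({
            "chrom": "chr1", "start": [10_000], "end": [10_400],
            "log2_rpkm_vehicle": [2.0], "log2_rpkm_treated": [2.0],
        })
        out = subdomain_concentration(subs, sites)
        assert out["conc_vehicle"].iloc[0] == pytest.approx(2.0)
        assert out["dc"].iloc[0] == pytest.approx(0.0)

    def test_peak_and_dc_gates(self):
        subs = self._subdomains([
            (0, "chr1", 0, 1000, 4, 0.1, True, False, 3, 6),    # too few peaks
            (1, "chr1", 0, 1000, 6, 0.3, True, False, 3, 6),    # dC boundary
            (2, "chr1", 0, 1000, 6, 0.1, True, False, 3, 6),    # induced
            (3, "chr1", 0, 1000, 6, -0.1, False, False, 3, 3),  # constitutive
            (4, "chr1", 0, 1000, 6, 0.0, False, True, 3, 3),    # reduced
        ])
        ind, con, excl = select_matched_subdomains(subs)
        assert list(ind["subdomain"]) == [2]
        assert list(con["subdomain"]) == [3]
        assert list(excl["subdomain"]) == [4]

    def test_pseudocount_on_zero_vehicle(self):
        subs = self._subdomains([
            (0, "chr1", 0, 1000, 6, 0.1, True, False, 0, 4),
        ])
        r, n_flagged = interaction_ratios(subs)
        assert r[0] == pytest.approx(5 / 1)
        assert n_flagged == 1

    def test_compare_interaction_gain(self):
        # ratios 2.0/3.0/2.5 vs 1.0/0.9/1.1: complete separation, p = 1/20
        ind = self._subdomains([
            (i, "chr1", 0, 1000, 6, 0.1, True, False, 10, v)
            for i, v in enumerate([20, 30, 25])
        ])
        con = self._subdomains([
            (i + 3, "chr1", 0, 1000, 6, 0.1, False, False, 10, v)
            for i, v in enumerate([10, 9, 11])
        ])
        comp = compare_interaction_gain(ind, con)
        assert comp.p_value == pytest.approx(1 / 20)
        with pytest.raises(ValueError):
            compare_interaction_gain(ind.iloc[:0], con)


class TestDensityBinnedComparison:
    def test_within_bin_tests_run_and_detect_gain(self, rng):
        from enhancerhubs.differential import compare_interaction_gain_by_density

        def group(n, ratio, tag, offset=0):
            v = rng.integers(8, 15, n)
            return pd.DataFrame({
                "subdomain": np.arange(n) + offset, "chrom": "chr1",
                "start": 0, "end": 1000, "n_sites": 6, "dc": 0.0,
                "has_induced": tag, "has_reduced": False,
                "conc_vehicle": rng.normal(3, 1, n),
                "conc_treated": rng.normal(3, 1, n),
                "n_clusters_vehicle": v,
                "n_clusters_treated": (v * ratio).astype(int),
            })

        ind = group(30, 2.0, True)
        con = group(30, 1.0, False, offset=100)
        out = compare_interaction_gain_by_density(ind, con, n_bins=3)
        assert len(out) == 3
        ran = out[out["method"] != "skipped"]
        assert len(ran) >= 2
        assert (ran["p_one_sided"] < 0.05).all()


class TestPaired4C:
    def _signals(self, vehicle, treated, cls="induced"):
        return pd.DataFrame({
            "dynamic_class": cls, "signal_vehicle": vehicle,
            "signal_treated": treated,
        })

    def test_textbook_paired_t(self):
        out = compare_4c_at_sites(self._signals([10, 12, 11], [20, 25, 22]))
        row = out.iloc[0]
        # differences {10, 13, 11}: t = 11.333 / (1.5275/sqrt(3)) ~ 12.85
        assert row["t"] == pytest.approx(12.85, abs=0.01)
        assert row["p_one_sided"] == pytest.approx(0.003, abs=0.001)

    def test_no_change_gives_half(self):
        out = compare_4c_at_sites(self._signals([5, 6, 7], [5, 6, 7]))
        assert out["t"].iloc[0] == 0.0
        assert out["p_one_sided"].iloc[0] == 0.5

    def test_constant_positive_shift(self):
        out = compare_4c_at_sites(self._signals([5, 6, 7], [6, 7, 8]))
        assert out["p_one_sided"].iloc[0] == 0.0

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            compare_4c_at_sites(self._signals([1, 2], [2, 3]))


def test_fourc_paired_t_null_calibration():
    """Under rho=1, the paired t-test at constitutive connected sites
    produces approximately uniform p-values across 50 seeds."""
    from enhancerhubs.simulate import (
        SimulationConfig, simulate_fourc_reads, simulate_landscape,
    )

    tiny = dict(n_chroms=1, chrom_length=600_000, n_subdomains=2,
                peaks_per_subdomain=6)
    ps = []
    for seed in range(50):
        cfg = SimulationConfig(**tiny, seed=seed, interaction_enrichment=1.0)
        land = simulate_landscape(cfg)
        vp = int(land.peaks["peak_id"].iloc[0])
        sigs = {}
        for cond in ("vehicle", "treated"):
            _, truth = simulate_fourc_reads(land, vp, cond, 20_000)
            conn = truth[truth["connected"]]
            sigs[cond] = conn.groupby("site_pos")["count"].sum()
        idx = sorted(set(sigs["vehicle"].index) | set(sigs["treated"].index))
        df = pd.DataFrame({
            "dynamic_class": "constitutive",
            "signal_vehicle": sigs["vehicle"].reindex(idx).fillna(0).to_numpy(),
            "signal_treated": sigs["treated"].reindex(idx).fillna(0).to_numpy(),
        })
        if len(df) >= 3:
            out = compare_4c_at_sites(df)
            ps.append(float(out["p_one_sided"].iloc[0]))
    assert len(ps) >= 45
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01, f"KS p = {ks.pvalue:.4f}"


class TestInductionBins:
    def _sites(self, n):
        return pd.DataFrame({
            "site_id": np.arange(n),
            "delta": np.linspace(-1, 1, n),
        })

    def _genes(self, ids, ratios):
        return pd.DataFrame({
            "id": ids, "density_vehicle": 10.0,
            "density_treated": [10.0 * r for r in ratios],
        })

    def test_equal_partition_order_preserving(self):
        sites = self._sites(20)
        links = pd.DataFrame({"site_id": [0, 19], "gene_id": ["a", "b"]})
        genes = self._genes(["a", "b"], [1.0, 2.0])
        out = bin_sites_by_induction(sites, links, genes, n_bins=10)
        assert list(out["n_sites"]) == [2] * 10
        assert out["mean_site_delta"].is_monotonic_increasing
        assert out["mean_expression_change"].iloc[0] == pytest.approx(0.0)
        assert out["mean_expression_change"].iloc[-1] == pytest.approx(1.0)

    def test_remainder_goes_to_earlier_bins(self):
        out = bin_sites_by_induction(
            self._sites(23), pd.DataFrame({"site_id": [], "gene_id": []}),
            self._genes(["a"], [1.0]), n_bins=10,
        )
        assert list(out["n_sites"]) == [3, 3, 3] + [2] * 7

    def test_unlooped_genes_excluded(self):
        sites = self._sites(10)
        links = pd.DataFrame({"site_id": [5], "gene_id": ["a"]})
        genes = self._genes(["a", "orphan"], [1.5, 9.0])
        out = bin_sites_by_induction(sites, links, genes, n_bins=10)
        assert out["n_genes"].sum() == 1

    def test_fewer_sites_than_bins_rejected(self):
        with pytest.raises(ValueError):
            bin_sites_by_induction(
                self._sites(5), pd.DataFrame({"site_id": [], "gene_id": []}),
                self._genes(["a"], [1.0]), n_bins=10,
            )


class TestSubdomainExpression:
    def _group(self, sid, start, end):
        return pd.DataFrame(
            {"subdomain": [sid], "chrom": ["chr1"], "start": [start], "end": [end]}
        )

    def _genes(self, tss_list, ratios):
        return pd.DataFrame({
            "id": [f"g{i}" for i in range(len(tss_list))],
            "chrom": "chr1", "tss": tss_list,
            "density_vehicle": 10.0,
            "density_treated": [10.0 * r for r in ratios],
        })

    def test_unchanged_genes_not_significant(self):
        genes = self._genes([5_000, 15_000, 105_000, 115_000], [1, 1, 1, 1])
        out = subdomain_expression_change(
            self._group(0, 0, 50_000), self._group(1, 100_000, 150_000), genes
        )
        assert out["mean_change_induced"] == pytest.approx(0.0)
        assert out["p_one_sided"] >= 0.5

    def test_induced_group_higher(self):
        genes = self._genes(
            [5_000, 15_000, 105_000, 115_000], [2.0, 2.2, 1.0, 1.0]
        )
        out = subdomain_expression_change(
            self._group(0, 0, 50_000), self._group(1, 100_000, 150_000), genes
        )
        assert out["mean_change_induced"] > out["mean_change_constitutive"]

    def test_gene_outside_all_footprints_unassigned(self):
        genes = self._genes([5_000, 900_000], [1.0, 1.0])
        with pytest.raises(ValueError):
            subdomain_expression_change(
                self._group(0, 0, 50_000), self._group(1, 100_000, 150_000), genes
            )
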