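"""Interaction-cluster calling from anchored inter-ligation PETs.

Candidate clusters are unordered anchor pairs with their supporting
iPET count k.  Significance against non-specific ligation noise uses
the hypergeometric tail: conditional on the anchor degrees n_a and n_b
(iPETs touching each anchor, over the whole library) and the library
total N, the null number of iPETs joining the pair is
Hypergeometric(N, n_a, n_b) and p = P(X >= k).  Benjamini-Hochberg FDR
is computed over all candidates; high-confidence clusters additionally
require k >= min_pet (2 for P300-type libraries, 3 for POLII-type) and
a genomic span within [5 kb, 1 Mb].

A permutation alternative (shuffle which anchor each PET end hits,
recount, empirical tail) is provided as a model-misspecification
cross-check; it is never the default scoring path.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

MIN_PET_DEFAULTS = {"P300": 2, "POLII": 3}


def score_cluster(k: int, n_a: int, n_b: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k) for one anchor pair.

    X ~ Hypergeometric(population N, successes n_a, draws n_b).
    """
    if n_a > N or n_b > N:
        raise ValueError("anchor degrees cannot exceed the library total")
    if k > min(n_a, n_b):
        raise ValueError("k cannot exceed min(n_a, n_b)")
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, n_a, n_b))


def cluster_ipets(pets: pd.DataFrame) -> pd.DataFrame:
    """Collapse anchored inter-ligation PETs into candidate clusters.

    One cluster per unordered anchor pair with its supporting count k.
    Requires columns produced by `classify_pets` and `assign_anchors`.
    """
    sel = pets[(pets["category"] == "intra_inter") & pets["anchored"]]
    if len(sel) == 0:
        return pd.DataFrame(
            columns=["anchor_a", "anchor_b", "chrom", "k", "span", "n_a", "n_b", "N"]
        )
    a = np.minimum(sel["anchor_a"].to_numpy(), sel["anchor_b"].to_numpy())
    b = np.maximum(sel["anchor_a"].to_numpy(), sel["anchor_b"].to_numpy())
    df = pd.DataFrame({"anchor_a": a, "anchor_b": b, "chrom": sel["chrom_a"].to_numpy()})
    clusters = (
        df.groupby(["anchor_a", "anchor_b", "chrom"], as_index=False)
        .size()
        .rename(columns={"size": "k"})
    )
    # anchor degree: each supporting iPET counted once per anchor, over
    # the whole library (degrees describe the library, not the call set)
    degree = pd.concat([pd.Series(a), pd.Series(b)]).value_counts()
    N = int(len(sel))
    clusters["n_a"] = degree.reindex(clusters["anchor_a"]).to_numpy()
    clusters["n_b"] = degree.reindex(clusters["anchor_b"]).to_numpy()
    clusters["N"] = N
    return clusters


def attach_anchor_intervals(clusters: pd.DataFrame, anchors: pd.DataFrame) -> pd.DataFrame:
    """Add anchor interval columns and the anchor-midpoint span."""
    out = clusters.copy()
    anchors = anchors.reset_index(drop=True)
    for side in ("a", "b"):
        ids = out[f"anchor_{side}"].to_numpy()
        out[f"start_{side}"] = anchors["start"].to_numpy()[ids]
        out[f"end_{side}"] = anchors["end"].to_numpy()[ids]
    mid_a = (out["start_a"] + out["end_a"]) // 2
    mid_b = (out["start_b"] + out["end_b"]) // 2
    out["span"] = np.abs(mid_b - mid_a)
    return out


def score_clusters(clusters: pd.DataFrame) -> pd.DataFrame:
    """Vectorized hypergeometric tail over all candidate clusters."""
    out = clusters.copy()
    if len(out) == 0:
        out["p_value"] = []
        return out
    out["p_value"] = stats.hypergeom.sf(
        out["k"].to_numpy() - 1, out["N"].to_numpy(),
        out["n_a"].to_numpy(), out["n_b"].to_numpy(),
    )
    return out


def filter_clusters(
    clusters: pd.DataFrame,
    min_pet: int = 2,
    fdr_max: float = 0.05,
    span_limits: tuple[int, int] = (5000, 1_000_000),
) -> pd.DataFrame:
    """BH-correct p-values over all candidates, then gate.

    Retains clusters with k >= min_pet AND q < fdr_max AND span within
    `span_limits` (inclusive).  q-values are computed over the full
    candidate set before any gating, so the FDR refers to the library.
    """
    if not (0.0 < fdr_max <= 1.0):
        raise ValueError("fdr_max must be in (0, 1]")
    out = clusters.copy()
    if len(out) == 0:
        out["q_value"] = []
        return out
    out["q_value"] = multipletests(out["p_value"].to_numpy(), method="fdr_bh")[1]
    keep = (
        (out["k"] >= min_pet)
        & (out["q_value"] < fdr_max)
        & (out["span"] >= span_limits[0])
        & (out["span"] <= span_limits[1])
    )
    return out[keep].reset_index(drop=True)


def permutation_pvalues(
    pets: pd.DataFrame, n_perm: int = 200, seed: int = 0
) -> pd.DataFrame:
    """Empirical cluster p-values by shuffling anchor assignments.

    The second anchor of every anchored iPET is permuted across PETs,
    pair counts are recomputed, and each observed pair's p-value is the
    fraction of permutations in which a random pairing of that anchor
    pair reaches the observed count (add-one corrected).  Quadratic-ish
    and meant for small cross-checks only.
    """
    sel = pets[(pets["category"] == "intra_inter") & pets["anchored"]]
    obs = cluster_ipets(pets)
    rng = np.random.default_rng(seed)
    a = np.minimum(sel["anchor_a"].to_numpy(), sel["anchor_b"].to_numpy())
    b = np.maximum(sel["anchor_a"].to_numpy(), sel["anchor_b"].to_numpy())
    key_obs = list(zip(obs["anchor_a"], obs["anchor_b"]))
    hits = np.zeros(len(obs), dtype=np.int64)
    for _ in range(n_perm):
        perm_b = rng.permutation(b)
        lo = np.minimum(a, perm_b)
        hi = np.maximum(a, perm_b)
        counts: dict = {}
        for x, y in zip(lo, hi):
            counts[(x, y)] = counts.get((x, y), 0) + 1
        for i, key in enumerate(key_obs):
            if counts.get(key, 0) >= obs["k"].iloc[i]:
                hits[i] += 1
    out = obs.copy()
    out["p_perm"] = (hits + 1) / (n_perm + 1)
    return out


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (exposed for reporting)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]
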