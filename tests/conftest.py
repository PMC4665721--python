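"""Shared fixtures: small simulated landscapes built once per session."""

import numpy as np
import pandas as pd
import pytest

from enhancerhubs.pipeline import PipelineParams, build_index
from enhancerhubs.simulate import SimulationConfig, simulate_landscape

SMALL = dict(
    n_chroms=2,
    chrom_length=600_000,
    n_subdomains=4,
    peaks_per_subdomain=6,
    seed=7,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_landscape(small_config):
    return simulate_landscape(small_config)


@pytest.fixture(scope="session")
def small_index(small_landscape):
    return build_index(small_landscape)


@pytest.fixture(scope="session")
def small_params():
    return PipelineParams(n_pets=2000, fourc_reads=20_000)


def make_anchors(*intervals, chrom="chr1"):
    """Anchor table helper: make_anchors((s, e), ...)."""
    rows = [
        {"chrom": iv[2] if len(iv) > 2 else chrom, "start": iv[0], "end": iv[1]}
        for iv in intervals
    ]
    return pd.DataFrame(rows)


PET_COLUMNS = [
    "read_id", "linker_class", "chrom_a", "start_a", "end_a", "strand_a",
    "chrom_b", "start_b", "end_b", "strand_b", "category", "anchored",
    "anchor_a", "anchor_b",
]


def make_pets(pairs, chrom="chr1", category="intra_inter"):
    """PET table helper from (anchor_a, anchor_b) index pairs."""
    if not pairs:
        return pd.DataFrame(columns=PET_COLUMNS)
    rows = []
    for i, (a, b) in enumerate(pairs):
        rows.append(
            {
                "read_id": i, "linker_class": "AA",
                "chrom_a": chrom, "start_a": 0, "end_a": 20, "strand_a": "+",
                "chrom_b": chrom, "start_b": 100, "end_b": 120, "strand_b": "-",
                "category": category, "anchored": True,
                "anchor_a": a, "anchor_b": b,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
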