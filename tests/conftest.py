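"""Shared fixtures: tiny hand-built designs and small simulated datasets."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from redoxquant import (
    ChannelDesign,
    SimConfig,
    simulate_ground_truth,
)


@pytest.fixture
def redox_design_1rep() -> ChannelDesign:
    """Single-replicate 4-channel differential-labeling design."""
    frame = pd.DataFrame(
        {
            "channel_id": ["ht_l", "lt_l", "ht_h", "lt_h"],
            "strain": ["HT", "LT", "HT", "LT"],
            "replicate": pd.array([1, 1, 1, 1], dtype="Int64"),
            "role": ["reduced", "reduced",
                     "oxidized-complement", "oxidized-complement"],
        }
    )
    return ChannelDesign(frame)


@pytest.fixture
def abundance_design_3v3() -> ChannelDesign:
    """Six-sample abundance design used for exhaustive permutation checks."""
    frame = pd.DataFrame(
        {
            "channel_id": [f"ht{i}" for i in range(1, 4)] + [f"lt{i}" for i in range(1, 4)],
            "strain": ["HT"] * 3 + ["LT"] * 3,
            "replicate": pd.array([1, 2, 3, 1, 2, 3], dtype="Int64"),
            "role": ["abundance"] * 6,
        }
    )
    return ChannelDesign(frame)


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(n_proteins=300, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_config):
    return simulate_ground_truth(small_config)


def make_psms(design: ChannelDesign, rows: list[tuple]) -> pd.DataFrame:
    """Build a PSM table from (protein, peptide, run, *intensities) tuples."""
    cols = ["protein_id", "peptide_id", "run_id"] + design.channels
    return pd.DataFrame(rows, columns=cols)
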