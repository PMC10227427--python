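"""Shared fixtures: hand-built plexes/designs and one default simulation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from tmtdyn.io_formats import ChannelDesign, DESIGN_COLUMNS, PlexTable
from tmtdyn.synthetic_data import SimConfig, simulate_experiment

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def make_plex(
    intensities: dict[str, list[float | None]],
    channels: tuple[str, ...],
    plex_id: str = "plexA",
    n_unique: dict[str, int] | None = None,
) -> PlexTable:
    """Build a PlexTable from {accession: per-channel intensities}."""
    data = pd.DataFrame(index=pd.Index(list(intensities), name="accession"))
    data["gene"] = ""
    data["description"] = ""
    uniques = n_unique or {}
    data["n_unique_peptides"] = [uniques.get(acc, 2) for acc in intensities]
    data["n_peptides"] = data["n_unique_peptides"] + 1
    for i, channel in enumerate(channels):
        data[channel] = [
            np.nan if row[i] is None else float(row[i])
            for row in intensities.values()
        ]
    return PlexTable(plex_id, data, tuple(channels)).validate()


def make_design(entries: list[tuple], plex_id: str = "plexA") -> ChannelDesign:
    """entries: (channel, strain, condition, phase, bio, tech, is_bridge)."""
    rows = [(plex_id, *entry) for entry in entries]
    return ChannelDesign(pd.DataFrame(rows, columns=DESIGN_COLUMNS))


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic study design (1000 proteins, fixed seed)."""
    return simulate_experiment(SimConfig(seed=0))


@pytest.fixture()
def two_channel_plex():
    """Two channels with complete-row totals 100 and 300."""
    return make_plex(
        {"P1": [40, 120], "P2": [60, 180]},
        channels=("126", "131"),
    )


@pytest.fixture()
def bridge_plex_design():
    """Four-channel plex: two bridges (126, 131) and two samples."""
    plex = make_plex(
        {
            "P1": [100, 200, 300, 100],
            "P2": [50, 10, 20, 50],
            "P3": [None, 4, 8, None],  # missing in both bridges
        },
        channels=("126", "127N", "127C", "131"),
    )
    design = make_design(
        [
            ("126", "MG", "aerobic", "MS", 0, 1, True),
            ("127N", "CTRL", "aerobic", "ME", 1, 1, False),
            ("127C", "CTRL", "aerobic", "ME", 1, 2, False),
            ("131", "MG", "aerobic", "MS", 0, 2, True),
        ]
    )
    return plex, design
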