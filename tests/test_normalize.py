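"""Channel scaling, bridge normalization and replicate summarization."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tmtdyn.exceptions import ConfigurationError, ValidationError
from tmtdyn.normalize import (
    BridgeRelativeMatrix,
    average_technical,
    bridge_normalize,
    combine_plexes,
    scale_channels,
    summarize_replicates,
)

from conftest import make_design, make_plex


class TestScaleChannels:
    def test_equal_totals_identity(self):
        plex = make_plex({"P1": [10, 10], "P2": [20, 20]}, channels=("126", "131"))
        out = scale_channels(plex)
        pd.testing.assert_frame_equal(out.intensities, plex.intensities)

    def test_totals_100_and_300(self, two_channel_plex):
        out = scale_channels(two_channel_plex)
        scalars = out.data.attrs["channel_scalars"]
        assert scalars["126"] == pytest.approx(2.0)
        assert scalars["131"] == pytest.approx(2.0 / 3.0)
        totals = out.intensities.sum(axis=0)
        assert totals["126"] == pytest.approx(200.0)
        assert totals["131"] == pytest.approx(200.0)

    def test_incomplete_row_excluded_from_estimation_but_scaled(self):
        plex = make_plex(
            {"P1": [40, 120], "P2": [60, 180], "P3": [77, None]},
            channels=("126", "131"),
        )
        out = scale_channels(plex)
        scalars = out.data.attrs["channel_scalars"]
        # P3 excluded: totals still 100 vs 300 over complete rows
        assert scalars["126"] == pytest.approx(2.0)
        assert out.data.loc["P3", "126"] == pytest.approx(154.0)
        assert np.isnan(out.data.loc["P3", "131"])

    def test_entirely_missing_channel_named_in_error(self):
        plex = make_plex({"P1": [1, None], "P2": [2, None]}, channels=("126", "131"))
        with pytest.raises(ValidationError, match="131"):
            scale_channels(plex)

    def test_median_ratio_recovers_loading_factors(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(10, 1000, 30)
        loads = {"a": 1.5, "b": 0.8, "c": 1.0}
        plex = make_plex(
            {f"P{i}": [base[i] * loads[c] for c in loads] for i in range(30)},
            channels=tuple(loads),
        )
        out = scale_channels(plex, method="median_ratio")
        corrected = out.intensities
        # after correction every row is flat across channels
        ratio = corrected.max(axis=1) / corrected.min(axis=1)
        assert float(ratio.max()) == pytest.approx(1.0, abs=1e-9)

    def test_ranking_within_channel_preserved(self):
        rng = np.random.default_rng(7)
        plex = make_plex(
            {f"P{i}": list(rng.uniform(1, 100, 3)) for i in range(12)},
            channels=("a", "b", "c"),
        )
        out = scale_channels(plex)
        for channel in ("a", "b", "c"):
            assert (
                plex.intensities[channel].rank() == out.intensities[channel].rank()
            ).all()


class TestBridgeNormalize:
    def test_forced_arithmetic(self, bridge_plex_design):
        plex, design = bridge_plex_design
        matrix = bridge_normalize(plex, design)
        # P1: bridges 100, 100 -> reference 100; sample 200 -> fold change 2
        col = ("CTRL", "aerobic", "ME", 1, 1)
        assert matrix.values.loc["P1", col] == pytest.approx(2.0)
        assert matrix.values.loc["P1", ("CTRL", "aerobic", "ME", 1, 2)] == pytest.approx(3.0)

    def test_bridge_against_itself_is_one(self, bridge_plex_design):
        plex, design = bridge_plex_design
        matrix = bridge_normalize(plex, design, keep_bridge=True)
        bridge_col = ("bridge", "pool", "pool", 0, 0)
        assert (matrix.values[bridge_col].dropna() == 1.0).all()

    def test_missing_bridge_flagged(self, bridge_plex_design):
        plex, design = bridge_plex_design
        matrix = bridge_normalize(plex, design)
        assert bool(matrix.bridge_missing["P3"])
        assert matrix.values.loc["P3"].isna().all()
        assert not matrix.bridge_missing["P1"]

    def test_no_bridge_is_configuration_error(self):
        plex = make_plex({"P1": [1, 2]}, channels=("126", "131"))
        design = make_design(
            [
                ("126", "CTRL", "aerobic", "ME", 1, 1, False),
                ("131", "CTRL", "aerobic", "ME", 1, 2, False),
            ]
        )
        with pytest.raises(ConfigurationError):
            bridge_normalize(plex, design)

    def test_geomean_combiner(self, bridge_plex_design):
        plex, design = bridge_plex_design
        matrix = bridge_normalize(plex, design, combiner="geomean")
        # P2 bridges 50, 50 -> geometric mean 50
        assert matrix.values.loc["P2", ("CTRL", "aerobic", "ME", 1, 1)] == pytest.approx(0.2)


class TestTechnicalAveraging:
    def _matrix(self, values):
        cols = pd.MultiIndex.from_tuples(
            [
                ("CTRL", "aerobic", "ME", 1, 1),
                ("CTRL", "aerobic", "ME", 1, 2),
            ],
            names=["strain", "condition", "phase", "bio_replicate", "tech_replicate"],
        )
        frame = pd.DataFrame(values, columns=cols,
                             index=pd.Index([f"P{i}" for i in range(len(values))],
                                            name="accession"))
        return BridgeRelativeMatrix(values=frame)

    def test_arithmetic_mean(self):
        out = average_technical(self._matrix([[1.8, 2.2]]))
        assert out.values.loc["P0", ("CTRL", "aerobic", "ME", 1)] == pytest.approx(2.0)

    def test_single_tech_rep_passthrough(self):
        cols = pd.MultiIndex.from_tuples(
            [("CTRL", "aerobic", "ME", 1, 1)],
            names=["strain", "condition", "phase", "bio_replicate", "tech_replicate"],
        )
        frame = pd.DataFrame([[1.5]], columns=cols,
                             index=pd.Index(["P0"], name="accession"))
        out = average_technical(BridgeRelativeMatrix(values=frame))
        assert out.values.iloc[0, 0] == pytest.approx(1.5)

    def test_partial_coverage_flagged(self):
        out = average_technical(self._matrix([[np.nan, 1.5]]))
        assert out.values.iloc[0, 0] == pytest.approx(1.5)
        assert bool(out.tech_coverage.iloc[0, 0])


class TestSummarizeReplicates:
    def _summary(self, rows):
        cols = pd.MultiIndex.from_tuples(
            [("CTRL", "aerobic", "ME", b) for b in (1, 2, 3)],
            names=["strain", "condition", "phase", "bio_replicate"],
        )
        frame = pd.DataFrame(rows, columns=cols,
                             index=pd.Index([f"P{i}" for i in range(len(rows))],
                                            name="accession"))
        return summarize_replicates(BridgeRelativeMatrix(values=frame))

    def test_constant_replicates(self):
        s = self._summary([[1.0, 1.0, 1.0]]).get(("CTRL", "aerobic", "ME"))
        assert s.loc["P0", "mean"] == 1.0
        assert s.loc["P0", "sd"] == 0.0
        assert s.loc["P0", "rsd"] == 0.0
        assert s.loc["P0", "n"] == 3

    def test_sample_sd_uses_n_minus_one(self):
        s = self._summary([[0.8, 1.0, 1.2]]).get(("CTRL", "aerobic", "ME"))
        assert s.loc["P0", "mean"] == pytest.approx(1.0)
        assert s.loc["P0", "sd"] == pytest.approx(0.2)
        assert s.loc["P0", "rsd"] == pytest.approx(20.0)

    def test_single_replicate_has_no_sd(self):
        s = self._summary([[1.4, np.nan, np.nan]]).get(("CTRL", "aerobic", "ME"))
        assert s.loc["P0", "mean"] == pytest.approx(1.4)
        assert np.isnan(s.loc["P0", "sd"])
        assert s.loc["P0", "n"] == 1

    def test_matches_brute_force_two_pass(self):
        rng = np.random.default_rng(11)
        raw = rng.lognormal(0, 0.3, (40, 3))
        raw[rng.random((40, 3)) < 0.15] = np.nan
        s = self._summary(raw.tolist()).get(("CTRL", "aerobic", "ME"))
        for i in range(40):
            values = raw[i][~np.isnan(raw[i])]
            if len(values) == 0:
                assert np.isnan(s.iloc[i]["mean"])
                continue
            mean = sum(values) / len(values)
            assert s.iloc[i]["mean"] == pytest.approx(mean, rel=1e-12)
            if len(values) >= 2:
                var = sum((v - mean) ** 2 for v in values) / (len(values) - 1)
                assert s.iloc[i]["sd"] == pytest.approx(np.sqrt(var), rel=1e-12)
            assert s.iloc[i]["n"] == len(values)


class TestCrossPlexAssembly:
    def test_union_of_proteins_with_missingness_preserved(self, bridge_plex_design):
        plex, design = bridge_plex_design
        m1 = bridge_normalize(plex, design)
        other = make_plex(
            {"P1": [100, 40, 100], "P9": [10, 5, 10]},
            channels=("126", "127N", "131"),
            plex_id="plexB",
        )
        design2 = make_design(
            [
                ("126", "MG", "aerobic", "MS", 0, 1, True),
                ("127N", "CTRL", "aerobic", "MS", 1, 1, False),
                ("131", "MG", "aerobic", "MS", 0, 2, True),
            ],
            plex_id="plexB",
        )
        m2 = bridge_normalize(other, design2)
        combined = combine_plexes([m1, m2])
        assert set(combined.values.index) == {"P1", "P2", "P3", "P9"}
        assert np.isnan(
            combined.values.loc["P9", ("CTRL", "aerobic", "ME", 1, 1)]
        )

    def test_duplicate_sample_assignment_rejected(self, bridge_plex_design):
        plex, design = bridge_plex_design
        m1 = bridge_normalize(plex, design)
        with pytest.raises(ConfigurationError):
            combine_plexes([m1, m1])
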