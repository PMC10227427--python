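"""Channel scaling, bridging-channel normalization and replicate summarization.

Cross-plex comparability in a multi-plex TMT design comes from the bridging
sample: a common reference pool occupying dedicated channels in every plex.
Each protein's quantity in a sample channel is expressed as a fold change
relative to the plex's bridge reference, which cancels any plex-wide
multiplicative batch factor exactly.  Technical replicates are then averaged
and biological replicates summarized into mean / SD / RSD / n per
strain×condition×phase.

All averaging is on the linear fold-change scale (the same scale the
downstream Welch tests consume); log-scale averaging is available behind a
flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .io_formats import ChannelDesign, PlexTable, SAMPLE_LEVELS

logger = logging.getLogger(__name__)

GROUP_LEVELS = ("strain", "condition", "phase")
STATS = ("mean", "sd", "n", "rsd")


@dataclass
class BridgeRelativeMatrix:
    """Protein × sample matrix of fold changes relative to the bridge.

    Columns are a MultiIndex over (strain, condition, phase, bio_replicate[,
    tech_replicate]).  ``bridge_missing`` flags proteins whose bridge
    reference was missing in a plex; ``tech_coverage`` flags values carried
    from a single technical replicate after averaging.
    """

    values: pd.DataFrame
    bridge_missing: pd.Series | None = None
    tech_coverage: pd.DataFrame | None = None
    plex_id: str | None = None


@dataclass
class ReplicateSummary:
    """Per protein × strain×condition×phase: mean, SD, n, RSD (%).

    ``table`` columns form a MultiIndex (strain, condition, phase, stat);
    SD uses the n−1 denominator and is absent (NaN) when n < 2.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        # keep the column MultiIndex lexsorted for efficient group lookup
        self.table = self.table.sort_index(axis=1)

    @property
    def groups(self) -> list[tuple]:
        cols = self.table.columns.droplevel("stat").unique()
        return list(cols)

    def get(self, group: tuple) -> pd.DataFrame:
        """Mean/sd/n/rsd frame for one (strain, condition, phase) group."""
        strain, condition, phase = group
        try:
            sub = self.table.loc[:, (strain, condition, phase)]
        except KeyError as exc:
            raise ConfigurationError(f"unknown group {group!r}") from exc
        sub.columns.name = "stat"
        return sub


# ---------------------------------------------------------------------------
# channel scaling
# ---------------------------------------------------------------------------

def scale_channels(plex: PlexTable, method: str = "total") -> PlexTable:
    """Correct per-channel loading differences within a plex.

    ``method='total'`` multiplies each channel by a scalar so that all
    channel totals (over proteins present in every channel) equal the
    plex-wide mean total — the simple stand-in for search-engine
    "autonormalization".  ``method='median_ratio'`` instead estimates each
    channel's loading factor as the median ratio of its intensities to the
    per-protein geometric mean across channels (size factors in the DESeq
    sense); it is robust to composition shifts, where equal-total scaling is
    biased when regulated proteins move a channel's true total.  Rows with
    missing values are excluded from scalar estimation but still scaled.
    """
    inten = plex.intensities
    empty = [c for c in plex.channel_labels if not inten[c].notna().any()]
    if empty:
        raise ValidationError(
            f"plex {plex.plex_id!r}: channels entirely missing: {empty}"
        )
    complete = inten.dropna(axis=0, how="any")
    if complete.empty:
        raise ValidationError(
            f"plex {plex.plex_id!r}: no protein present in every channel; "
            "cannot estimate channel scalars"
        )
    if method == "total":
        totals = complete.sum(axis=0)
        scalars = totals.mean() / totals
    elif method == "median_ratio":
        log_vals = np.log(complete)
        log_ratios = log_vals.sub(log_vals.mean(axis=1), axis=0)
        size_factors = np.exp(log_ratios.median(axis=0))
        scalars = np.exp(np.log(size_factors).mean()) / size_factors
    else:
        raise ConfigurationError(f"unknown scaling method {method!r}")
    logger.info("plex %s channel scalars: %s", plex.plex_id, scalars.round(4).to_dict())
    scaled = plex.with_intensities(inten * scalars)
    scaled.data.attrs["channel_scalars"] = scalars.to_dict()
    return scaled


# ---------------------------------------------------------------------------
# bridge normalization
# ---------------------------------------------------------------------------

def bridge_reference(
    plex: PlexTable, design: ChannelDesign, combiner: str = "mean"
) -> pd.Series:
    """Per-protein bridge reference: the combined bridge-channel intensity."""
    bridges = design.bridge_channels(plex.plex_id)
    if not bridges:
        raise ConfigurationError(
            f"no bridge channel defined for plex {plex.plex_id!r}"
        )
    bridge_int = plex.intensities[bridges]
    if combiner == "mean":
        return bridge_int.mean(axis=1)
    if combiner == "geomean":
        return np.exp(np.log(bridge_int).mean(axis=1))
    raise ConfigurationError(f"unknown bridge combiner {combiner!r}")


def bridge_normalize(
    plex: PlexTable,
    design: ChannelDesign,
    combiner: str = "mean",
    keep_bridge: bool = False,
) -> BridgeRelativeMatrix:
    """Express every sample channel as fold change relative to the bridge.

    The bridge reference is the arithmetic mean (or geometric mean) of the
    plex's bridge channels; proteins missing in every bridge channel are
    emitted missing and flagged in ``bridge_missing``.  With ``keep_bridge``
    the combined bridge itself is included as an extra column (identically 1
    where defined), which is occasionally useful for diagnostics.
    """
    design.validate_against(plex)
    ref = bridge_reference(plex, design, combiner)
    missing = ref.isna()
    entries = design.sample_entries(plex.plex_id)
    channels = entries["channel"].tolist()
    values = plex.intensities[channels].div(ref, axis=0)
    columns = pd.MultiIndex.from_frame(
        entries[list(SAMPLE_LEVELS)], names=SAMPLE_LEVELS
    )
    values.columns = columns
    if keep_bridge:
        values[("bridge", "pool", "pool", 0, 0)] = ref / ref
    return BridgeRelativeMatrix(
        values=values, bridge_missing=missing, plex_id=plex.plex_id
    )


def combine_plexes(matrices: Sequence[BridgeRelativeMatrix]) -> BridgeRelativeMatrix:
    """Assemble per-plex bridge-relative matrices into one cross-plex matrix.

    Takes the union of proteins; per-sample missingness is preserved.  The
    same sample must not occur in more than one plex.
    """
    frames = [m.values for m in matrices]
    combined = pd.concat(frames, axis=1, join="outer")
    if combined.columns.duplicated().any():
        dups = combined.columns[combined.columns.duplicated()].tolist()
        raise ConfigurationError(f"sample assigned to multiple plexes: {dups}")
    combined = combined.sort_index(axis=1)
    return BridgeRelativeMatrix(values=combined)


# ---------------------------------------------------------------------------
# technical-replicate averaging and biological summarization
# ---------------------------------------------------------------------------

def average_technical(
    matrix: BridgeRelativeMatrix, design: ChannelDesign | None = None
) -> BridgeRelativeMatrix:
    """Collapse technical replicates by arithmetic mean of present values.

    A value present in only one of several technical replicates is carried
    through and flagged in ``tech_coverage``.  A single-tech-rep design
    passes through unchanged (apart from the dropped index level).
    """
    vals = matrix.values
    levels = [l for l in vals.columns.names if l != "tech_replicate"]
    grouped = vals.T.groupby(level=levels, sort=True)
    mean = grouped.mean().T
    count = grouped.count().T
    total = grouped.size()
    partial = count.lt(total, axis=1) & count.ge(1)
    return BridgeRelativeMatrix(
        values=mean, tech_coverage=partial, bridge_missing=matrix.bridge_missing
    )


def summarize_replicates(
    matrix: BridgeRelativeMatrix, design: ChannelDesign | None = None
) -> ReplicateSummary:
    """Mean, sample SD (n−1), n and RSD over biological replicates.

    Expects technical replicates to have been averaged already; statistics
    are computed over the biological replicates with present values for each
    strain×condition×phase group.
    """
    vals = matrix.values
    if "tech_replicate" in (vals.columns.names or []):
        raise ConfigurationError(
            "summarize_replicates expects technical replicates to be averaged first"
        )
    grouped = vals.T.groupby(level=list(GROUP_LEVELS), sort=True)
    mean = grouped.mean().T
    sd = grouped.std(ddof=1).T
    n = grouped.count().T.astype(float)
    rsd = 100.0 * sd / mean
    pieces = {"mean": mean, "sd": sd, "n": n, "rsd": rsd}
    table = pd.concat(pieces, axis=1, names=["stat"] + list(GROUP_LEVELS))
    table = table.reorder_levels(list(GROUP_LEVELS) + ["stat"], axis=1)
    table = table.sort_index(axis=1)
    return ReplicateSummary(table=table)
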