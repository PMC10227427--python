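"""End-to-end orchestration of the multi-plex quantification pipeline.

One call takes raw per-plex tables plus the channel design through
identification filtering, (optional) channel scaling, bridge normalization,
cross-plex assembly, technical-replicate averaging and biological replicate
summarization.
"""

from __future__ import annotations

from typing import Sequence

from .io_formats import ChannelDesign, PlexTable, filter_identifications
from .normalize import (
    BridgeRelativeMatrix,
    ReplicateSummary,
    average_technical,
    bridge_normalize,
    combine_plexes,
    scale_channels,
    summarize_replicates,
)


def process_plexes(
    plexes: Sequence[PlexTable],
    design: ChannelDesign,
    min_unique: int = 2,
    scale: bool | str = False,
    combiner: str = "mean",
    average_tech: bool = True,
) -> tuple[BridgeRelativeMatrix, ReplicateSummary]:
    """Run the standard pipeline and return (sample matrix, replicate summary).

    ``scale`` selects an optional within-plex channel scaling method
    (``"total"``/True for channel-total equalization, ``"median_ratio"`` for
    composition-robust size factors, False to skip).  The default is off:
    search-engine exports are typically already channel-normalized
    (autonormalization), and rescaling data whose composition genuinely
    shifts between growth phases biases fold changes.  Bridge normalization
    always runs.  With ``average_tech=False`` the matrix keeps technical
    replicates and the returned summary is None.
    """
    if scale is True:
        scale = "total"
    matrices = []
    for plex in plexes:
        table = filter_identifications(plex, min_unique=min_unique, design=design)
        if scale:
            table = scale_channels(table, method=scale)
        matrices.append(bridge_normalize(table, design, combiner=combiner))
    combined = combine_plexes(matrices)
    if average_tech:
        combined = average_technical(combined, design)
        summary = summarize_replicates(combined, design)
    else:
        summary = None
    return combined, summary
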