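"""Descriptive outputs: replicate clustering, reference-phase heatmap
matrices, volcano exports and emPAI circle-graph tables.

Computation is separated from rendering: every figure is emitted as a data
table, so tests assert numbers, not pixels.  Distances are Euclidean on
log2-transformed bridge-relative values (log2 makes the metric symmetric in
fold direction); agglomeration uses average linkage (UPGMA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .exceptions import ConfigurationError, ValidationError
from .normalize import BridgeRelativeMatrix, ReplicateSummary


@dataclass
class DistanceMatrix:
    """Symmetric sample × sample Euclidean distance matrix."""

    frame: pd.DataFrame  # square, labels on both axes

    @property
    def labels(self) -> list:
        return list(self.frame.index)

    def nearest_neighbors(self) -> pd.Series:
        """Each sample's nearest other sample."""
        d = self.frame.copy()
        np.fill_diagonal(d.values, np.inf)
        return d.idxmin(axis=1)


@dataclass
class LinkageTree:
    """Agglomeration result: scipy-format merge list plus leaf labels.

    ``merges`` rows are (node a, node b, merge height, cluster size); leaves
    are numbered 0..n−1 in ``labels`` order, internal nodes n, n+1, ...
    """

    merges: np.ndarray
    labels: list


def distance_matrix(
    matrix: BridgeRelativeMatrix | pd.DataFrame,
    complete_only: bool = True,
    log_scale: bool = True,
) -> DistanceMatrix:
    """Pairwise Euclidean distances between sample profiles.

    With ``complete_only`` (the default) only proteins present in every
    sample enter the computation; otherwise each pair uses its pairwise
    complete proteins.  Values are log2-transformed unless ``log_scale`` is
    disabled.
    """
    values = matrix.values if isinstance(matrix, BridgeRelativeMatrix) else matrix
    if values.shape[1] < 2:
        raise ValidationError("need at least 2 samples")
    data = np.log2(values) if log_scale else values
    labels = list(data.columns)
    if complete_only:
        complete = data.dropna(axis=0, how="any")
        if len(complete) < 2:
            raise ValidationError(
                f"only {len(complete)} protein(s) complete across all samples"
            )
        dist = squareform(pdist(complete.T.to_numpy(float), metric="euclidean"))
    else:
        arr = data.to_numpy(float)
        k = len(labels)
        dist = np.zeros((k, k))
        for i in range(k):
            for j in range(i + 1, k):
                both = ~(np.isnan(arr[:, i]) | np.isnan(arr[:, j]))
                if both.sum() < 2:
                    raise ValidationError(
                        f"fewer than 2 shared proteins between samples "
                        f"{labels[i]} and {labels[j]}"
                    )
                diff = arr[both, i] - arr[both, j]
                dist[i, j] = dist[j, i] = float(np.sqrt(np.sum(diff * diff)))
    frame = pd.DataFrame(dist, index=labels, columns=labels)
    return DistanceMatrix(frame)


def average_linkage(dist: DistanceMatrix) -> LinkageTree:
    """UPGMA agglomeration of a distance matrix.

    Merges the closest pair first; a new cluster's distance to the others is
    the size-weighted mean of its members' distances.
    """
    condensed = squareform(dist.frame.to_numpy(float), checks=True)
    merges = hierarchy.linkage(condensed, method="average")
    return LinkageTree(merges=merges, labels=dist.labels)


def phase_reference_matrix(
    summary: ReplicateSummary,
    reference_phase: str = "ME",
) -> pd.DataFrame:
    """log2 fold-change matrix of phase means relative to a reference phase.

    Within each strain×condition, every phase column is
    log2(mean_phase / mean_reference); the reference column is identically 0
    where defined and cells with a missing reference mean are emitted
    missing.
    """
    groups = summary.groups
    combos = sorted({(s, c) for s, c, _ in groups})
    pieces = {}
    for strain, condition in combos:
        phases = [p for s, c, p in groups if (s, c) == (strain, condition)]
        if reference_phase not in phases:
            raise ConfigurationError(
                f"reference phase {reference_phase!r} absent for {strain}/{condition}"
            )
        ref = summary.get((strain, condition, reference_phase))["mean"]
        for phase in phases:
            mean = summary.get((strain, condition, phase))["mean"]
            with np.errstate(divide="ignore", invalid="ignore"):
                pieces[(strain, condition, phase)] = np.log2(mean / ref)
    out = pd.DataFrame(pieces)
    out.columns.names = ["strain", "condition", "phase"]
    return out


def export_volcano(diff) -> pd.DataFrame:
    """Volcano plot table: log2FC, −log10 p and the volcano class."""
    frame = diff.frame
    with np.errstate(divide="ignore"):
        neg_log10_p = -np.log10(frame["p"])
    return pd.DataFrame(
        {
            "log2fc": frame["log2fc"],
            "neg_log10_p": neg_log10_p,
            "volcano_class": frame["volcano_class"],
        }
    )


def export_circles(empai_table) -> pd.DataFrame:
    """Circle-graph table: circle area proportional to emPAI.

    Radius is sqrt(emPAI/π), i.e. area == emPAI up to the rendering scale
    constant.
    """
    em = empai_table.frame["empai"]
    return pd.DataFrame(
        {"empai": em, "area": em, "radius": np.sqrt(em / np.pi)}
    )


def go_category_counts(categories: pd.Series) -> pd.DataFrame:
    """Count-by-category table (e.g. cellular-component assignment)."""
    counts = categories.value_counts()
    return pd.DataFrame({"category": counts.index, "n_proteins": counts.to_numpy()})


def render_clustermap(matrix, path, **kwargs):  # pragma: no cover - thin optional layer
    """Optional rendering layer over :func:`distance_matrix` inputs."""
    import seaborn as sns  # deferred: plotting extras

    values = matrix.values if isinstance(matrix, BridgeRelativeMatrix) else matrix
    grid = sns.clustermap(
        np.log2(values.dropna(axis=0, how="any")),
        metric="euclidean",
        method="average",
        **kwargs,
    )
    grid.savefig(path)
    return path
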