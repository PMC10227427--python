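"""Two-sample t-tests, volcano classification and transition count tables.

Differential abundance between two groups (two growth phases, or two oxygen
conditions at one phase) is assessed per protein from the replicate summary
statistics with a two-sided two-sample t-test and the classic volcano rule:
a change is *significant* when p < 0.05 AND the linear fold change exceeds
1.25 (|log2 FC| > log2 1.25 ≈ 0.32), *statistical_only* when only the p
threshold is met, and *insignificant* otherwise.

Both t-test forms are provided: the pooled equal-variance form (the default
of the summary-statistics test in scipy, and the pipeline default — it is
correctly sized at triplicate scale) and the unequal-variance Welch form
with Welch–Satterthwaite degrees of freedom (:func:`welch_test`), which is
noticeably conservative at n = 3.  No multiple-testing correction is applied
to these per-protein tests (raw thresholds are the convention here);
BH-adjusted q-values are available as an opt-in column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    DegenerateVarianceError,
    InsufficientReplicationError,
    ValidationError,
)
from .normalize import ReplicateSummary

VOLCANO_CLASSES = ("insignificant", "statistical_only", "significant")


@dataclass
class DiffTable:
    """Per-protein contrast results.

    ``frame`` columns: fc, log2fc, t, df, p, volcano_class, direction, reason
    (and q when BH adjustment was requested).  Proteins lacking two
    biological replicates in either group are emitted unclassified with a
    reason code.
    """

    frame: pd.DataFrame
    contrast: str
    p_threshold: float
    fc_threshold: float

    @property
    def classified(self) -> pd.DataFrame:
        return self.frame[self.frame["volcano_class"] != "unclassified"]


def _welch_arrays(mean1, sd1, n1, mean2, sd2, n2):
    """Vectorized Welch statistic, Welch–Satterthwaite df and two-sided p."""
    v1 = np.square(sd1) / n1
    v2 = np.square(sd2) / n2
    denom = v1 + v2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean2) / np.sqrt(denom)
        df = np.square(denom) / (
            np.square(v1) / (n1 - 1) + np.square(v2) / (n2 - 1)
        )
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


def welch_test(mean1, sd1, n1, mean2, sd2, n2):
    """Welch's two-sided t-test from group summary statistics.

    Returns ``(t, df, p)`` with the unequal-variance statistic and the
    Welch–Satterthwaite degrees of freedom.  Raises
    :class:`InsufficientReplicationError` when either group has n < 2 and
    :class:`DegenerateVarianceError` when both SDs are zero.
    """
    mean1, sd1, n1 = np.asarray(mean1, float), np.asarray(sd1, float), np.asarray(n1)
    mean2, sd2, n2 = np.asarray(mean2, float), np.asarray(sd2, float), np.asarray(n2)
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise InsufficientReplicationError("both groups need n >= 2")
    if np.any(sd1 < 0) or np.any(sd2 < 0):
        raise ValidationError("standard deviations must be nonnegative")
    if np.any((sd1 == 0) & (sd2 == 0)):
        raise DegenerateVarianceError("both groups have zero variance")
    t, df, p = _welch_arrays(mean1, sd1, n1, mean2, sd2, n2)
    if t.ndim == 0:
        return float(t), float(df), float(p)
    return t, df, p


def _pooled_arrays(mean1, sd1, n1, mean2, sd2, n2):
    """Vectorized pooled (Student) two-sample statistic, df and two-sided p."""
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.square(sd1) + (n2 - 1) * np.square(sd2)) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, df, p


def contrast(
    summary: ReplicateSummary,
    group_a: tuple,
    group_b: tuple,
    p_threshold: float = 0.05,
    fc_threshold: float = 1.25,
    test: str = "pooled",
    adjust: bool = False,
    label: str | None = None,
) -> DiffTable:
    """Per-protein contrast of two strain×condition×phase groups.

    FC is the ratio of linear-scale replicate means (group A over group B);
    p comes from a two-sided two-sample t-test on the replicate summaries.
    ``test='pooled'`` (the default) uses the equal-variance form — the exact
    computation of ``scipy.stats.ttest_ind_from_stats`` at its defaults,
    which is correctly sized (rejects 5% under the null) at triplicate
    scale; ``test='welch'`` uses the unequal-variance Welch form, which is
    markedly conservative at n = 3 because the Welch–Satterthwaite degrees
    of freedom are themselves estimated from two variances.  Proteins with
    zero variance in both groups are classified by exact separation (equal
    means → p = 1, different means → p = 0).  Proteins failing n ≥ 2 in
    either group are unclassified with a reason code.
    """
    if test not in ("pooled", "welch"):
        raise ConfigurationError(f"unknown test {test!r}")
    if p_threshold <= 0 or fc_threshold <= 0:
        raise ValidationError("thresholds must be positive")
    a = summary.get(group_a)
    b = summary.get(group_b)
    log2_cut = np.log2(fc_threshold)

    fc = a["mean"] / b["mean"]
    with np.errstate(divide="ignore", invalid="ignore"):
        log2fc = np.log2(fc)
    out = pd.DataFrame(index=a.index)
    out["fc"] = fc
    out["log2fc"] = log2fc
    out["t"] = np.nan
    out["df"] = np.nan
    out["p"] = np.nan
    out["volcano_class"] = "unclassified"
    out["direction"] = "unchanged"
    out["reason"] = ""

    has_means = a["mean"].notna() & b["mean"].notna()
    replicated = (a["n"] >= 2) & (b["n"] >= 2)
    classifiable = has_means & replicated
    out.loc[~has_means, "reason"] = "missing"
    out.loc[has_means & ~replicated, "reason"] = "insufficient_replicates"

    idx = out.index[classifiable]
    if len(idx):
        m1, s1, n1 = (a.loc[idx, c].to_numpy(float) for c in ("mean", "sd", "n"))
        m2, s2, n2 = (b.loc[idx, c].to_numpy(float) for c in ("mean", "sd", "n"))
        degenerate = (s1 == 0) & (s2 == 0)
        stat_fn = _pooled_arrays if test == "pooled" else _welch_arrays
        t, df, p = stat_fn(m1, s1, n1, m2, s2, n2)
        # zero-variance groups: exact separation decides
        equal = degenerate & (m1 == m2)
        differ = degenerate & (m1 != m2)
        p = np.where(equal, 1.0, np.where(differ, 0.0, p))
        separated = np.where(m1 > m2, np.inf, -np.inf)
        t = np.where(equal, 0.0, np.where(differ, separated, t))
        df = np.where(degenerate, np.nan, df)
        out.loc[idx, "t"] = t
        out.loc[idx, "df"] = df
        out.loc[idx, "p"] = p

        lfc = out.loc[idx, "log2fc"].to_numpy(float)
        stat_sig = p < p_threshold
        bio_sig = np.abs(lfc) > log2_cut
        cls = np.where(
            stat_sig & bio_sig,
            "significant",
            np.where(stat_sig, "statistical_only", "insignificant"),
        )
        out.loc[idx, "volcano_class"] = cls
        direction = np.where(
            (cls == "significant") & (lfc > 0),
            "up",
            np.where((cls == "significant") & (lfc < 0), "down", "unchanged"),
        )
        out.loc[idx, "direction"] = direction
        if adjust:
            from .enrichment import bh_adjust

            out["q"] = np.nan
            out.loc[idx, "q"] = bh_adjust(np.clip(p, np.nextafter(0, 1), 1.0))

    name = label or f"{'/'.join(map(str, group_a))} vs {'/'.join(map(str, group_b))}"
    return DiffTable(
        frame=out, contrast=name, p_threshold=p_threshold, fc_threshold=fc_threshold
    )


def transition_counts(diffs: Sequence[DiffTable]) -> pd.DataFrame:
    """Per-contrast counts of quantified / more-abundant / less-abundant proteins.

    ``n_quantified`` counts proteins classified in the contrast, i.e. present
    in at least the replicate minimum (two biological replicates) in both
    groups; the abundance columns split the *significant* class by direction.
    """
    rows = []
    for diff in diffs:
        classified = diff.classified
        rows.append(
            {
                "contrast": diff.contrast,
                "n_quantified": int(len(classified)),
                "n_more_abundant": int((classified["direction"] == "up").sum()),
                "n_less_abundant": int((classified["direction"] == "down").sum()),
            }
        )
    frame = pd.DataFrame(rows).set_index("contrast")
    return frame
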