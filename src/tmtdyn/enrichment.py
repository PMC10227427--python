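"""Gene-set over-representation analysis against a custom background.

The universe ("background") is the set of genes actually detected across the
experiments — never the whole genome — and must be passed explicitly.  Each
gene set is first intersected with the background; the one-sided
hypergeometric upper tail P[X >= k] then asks whether the selected genes
overlap the set more than random draws from the background would, and
Benjamini–Hochberg adjustment across all tested sets controls the FDR.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .io_formats import GeneSetCollection

logger = logging.getLogger(__name__)

MIN_SET_SIZE = 2  # sets smaller than this after background intersection are skipped


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    selected: Iterable[str],
    background: Iterable[str],
    sets: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in ``selected``.

    Returns one row per tested set with K (set size in background), N
    (background size), n (selection size), k (overlap), p, BH q, the overlap
    gene list and an ``enriched`` flag (q < ``fdr_threshold``), sorted by
    (q, p).  ``selected`` must be a subset of ``background``.
    """
    background_list = list(dict.fromkeys(background))
    selected_set = set(dict.fromkeys(selected))
    if not selected_set:
        raise ValidationError("empty selected gene list")
    bg = set(background_list)
    offenders = sorted(selected_set - bg)
    if offenders:
        raise ValidationError(
            f"selected genes absent from background: {', '.join(offenders)}"
        )
    N = len(bg)
    n = len(selected_set)
    rows = []
    for gene_set in sets:
        members = [g for g in gene_set.genes if g in bg]
        K = len(members)
        if K < MIN_SET_SIZE:
            logger.info(
                "skipping set %r: %d member(s) in background", gene_set.name, K
            )
            continue
        overlap = sorted(selected_set.intersection(members))
        k = len(overlap)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append(
            {
                "set": gene_set.name,
                "description": gene_set.description,
                "K": K,
                "N": N,
                "n": n,
                "k": k,
                "p": min(p, 1.0),
                "overlap": ",".join(overlap),
            }
        )
    result = pd.DataFrame(
        rows, columns=["set", "description", "K", "N", "n", "k", "p", "overlap"]
    )
    if len(result):
        result["q"] = bh_adjust(np.clip(result["p"], np.nextafter(0, 1), 1.0))
        result["enriched"] = result["q"] < fdr_threshold
        result = result.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    else:
        result["q"] = pd.Series(dtype=float)
        result["enriched"] = pd.Series(dtype=bool)
    return result
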