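"""Replicate planning: required n and achieved power for two-group comparisons.

Effect sizes follow the convention d = (FC − 1) / (RSD/100): the reference
group mean is 1 (fold-change scale) and both groups share a standard
deviation of RSD/100.  A log-scale alternative d = ln(FC)/ln(1 + RSD/100) is
available.  Power is that of the two-sided two-sample t-test with equal group
sizes and equal variances (the standard planning model, computed from the
noncentral t distribution via statsmodels), even though the analysis-stage
test is Welch's.
"""

from __future__ import annotations

import math
import warnings
from typing import Sequence

import pandas as pd
from statsmodels.stats.power import TTestIndPower

from .exceptions import ValidationError

#: Fold-change and RSD grids used for the replicate-planning table.
DEFAULT_FOLDS = (1.25, 1.5, 2.0, 2.5, 3.0)
DEFAULT_RSDS = (5.0, 10.0, 15.0, 20.0, 30.0)

_power_engine = TTestIndPower()


def effect_size(fc: float, rsd_percent: float, scale: str = "linear") -> float:
    """Standardized effect size for a fold change at a given RSD (%)."""
    if rsd_percent <= 0:
        raise ValidationError("rsd must be > 0")
    if scale == "linear":
        return (fc - 1.0) / (rsd_percent / 100.0)
    if scale == "log":
        return math.log(fc) / math.log1p(rsd_percent / 100.0)
    raise ValidationError(f"unknown effect-size scale {scale!r}")


def achieved_power(
    fc: float,
    rsd_percent: float,
    n: int,
    alpha: float = 0.05,
    scale: str = "linear",
) -> float:
    """Power of the two-sided two-sample t-test at the given effect and n.

    At fc = 1 (zero effect) the power equals the test size alpha.
    """
    if n < 2:
        raise ValidationError("n must be >= 2")
    d = effect_size(fc, rsd_percent, scale)
    value = float(
        _power_engine.power(
            effect_size=d, nobs1=n, alpha=alpha, ratio=1.0, alternative="two-sided"
        )
    )
    if math.isnan(value):
        # statsmodels' noncentral-t evaluation overflows at large
        # noncentrality; fall back to the direct nct tail computation
        from scipy import stats

        df = 2 * n - 2
        ncp = d * math.sqrt(n / 2.0)
        crit = stats.t.ppf(1 - alpha / 2, df)
        value = float(stats.nct.sf(crit, df, ncp) + stats.nct.cdf(-crit, df, ncp))
        if math.isnan(value):
            value = 1.0 if abs(ncp) > crit else 0.0
    return value


def required_n(
    fc: float,
    rsd_percent: float,
    alpha: float = 0.05,
    power: float = 0.8,
    scale: str = "linear",
) -> int:
    """Smallest integer n per group attaining the target power.

    Guarantees ``achieved_power(n) >= power`` and, whenever n > 2,
    ``achieved_power(n - 1) < power``.  Raises on fc = 1 (zero effect:
    the target power is unreachable).
    """
    if not 0 < alpha < 1 or not 0 < power < 1:
        raise ValidationError("alpha and power must lie in (0, 1)")
    if fc == 1.0:
        raise ValidationError("zero effect (fc = 1): target power unreachable")
    if fc < 1.0:
        fc = 1.0 / fc  # symmetric two-sided planning
    # power is monotone in n: bracket by doubling, then bisect on integers
    # (an exact inverse of achieved_power, unlike a rounded float root)
    hi = 2
    while achieved_power(fc, rsd_percent, hi, alpha, scale) < power:
        hi *= 2
        if hi > 1_000_000:
            raise ValidationError("required n exceeds 1e6; check the inputs")
    lo = max(2, hi // 2)
    while lo < hi:
        mid = (lo + hi) // 2
        if achieved_power(fc, rsd_percent, mid, alpha, scale) >= power:
            hi = mid
        else:
            lo = mid + 1
    return hi


def power_grid(
    folds: Sequence[float] = DEFAULT_FOLDS,
    rsds: Sequence[float] = DEFAULT_RSDS,
    alpha: float = 0.05,
    power: float = 0.8,
    scale: str = "linear",
) -> pd.DataFrame:
    """Full cross table of required replicate numbers.

    One row per (fold change, RSD %) pair with the effect size, the required
    n per group and the power actually achieved at that n.  Duplicate grid
    entries are deduplicated with a warning.
    """
    if not len(folds) or not len(rsds):
        raise ValidationError("empty grid")
    uniq_folds = list(dict.fromkeys(folds))
    uniq_rsds = list(dict.fromkeys(rsds))
    if len(uniq_folds) != len(folds) or len(uniq_rsds) != len(rsds):
        warnings.warn("duplicate grid entries removed", stacklevel=2)
    rows = []
    for fc in uniq_folds:
        for rsd in uniq_rsds:
            n = required_n(fc, rsd, alpha, power, scale)
            rows.append(
                {
                    "fold_change": fc,
                    "rsd_percent": rsd,
                    "effect_size": effect_size(fc, rsd, scale),
                    "alpha": alpha,
                    "target_power": power,
                    "n_required": n,
                    "achieved_power": achieved_power(fc, rsd, n, alpha, scale),
                }
            )
    return pd.DataFrame(rows)
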