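"""Pore-size distribution statistics: beta Q-Q assessment and dispersion.

The quantile rule is shared bit-for-bit with the segmentation module
through :mod:`cryofront.quantiles`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta as beta_dist

from cryofront.quantiles import quartiles

logger = logging.getLogger(__name__)


@dataclass
class QQResult:
    """Q-Q comparison of diameters against a scaled Beta(a, b) law.

    ``r_squared`` is the coefficient of determination of the ordinary
    (intercept-free in neither sense: slope *and* intercept are free)
    linear fit of empirical vs theoretical quantiles.
    """

    empirical_q: np.ndarray
    theoretical_q: np.ndarray
    r_squared: float
    a: float
    b: float
    scale_um: float
    scale_fitted: bool

    def __post_init__(self):
        if self.empirical_q.shape != self.theoretical_q.shape:
            raise ValueError("quantile vectors must have equal length")
        if np.any(np.diff(self.empirical_q) < 0) or np.any(np.diff(self.theoretical_q) < 0):
            raise ValueError("quantile vectors must be non-decreasing")


def _fit_beta_scale(x: np.ndarray, a: float, b: float) -> float:
    """Maximum-likelihood scale for x ~ scale * Beta(a, b), shapes fixed."""
    xmax = float(x.max())

    def nll(log_s):
        s = np.exp(log_s)
        z = x / s
        if np.any(z >= 1.0):
            return np.inf
        return -(np.sum(beta_dist.logpdf(z, a, b)) - x.size * log_s)

    res = optimize.minimize_scalar(
        nll, bounds=(np.log(xmax * (1 + 1e-9)), np.log(xmax * 100.0)),
        method="bounded", options={"xatol": 1e-10})
    return float(np.exp(res.x))


def beta_qq(
    diameters_um,
    a: float = 1.2,
    b: float = 15.0,
    scale_um: float | None = None,
) -> QQResult:
    """Q-Q comparison of pore diameters against ``scale * Beta(a, b)``.

    Empirical order statistics are matched to theoretical quantiles at
    plotting positions ``(i - 0.5) / n``.  If ``scale_um`` is omitted it
    is fitted by maximum likelihood with the shapes held fixed (flagged in
    the result).  Requires n >= 20 and non-constant data.
    """
    x = np.sort(np.asarray(diameters_um, dtype=float))
    if x.size < 20:
        raise ValueError("need at least 20 diameters for a Q-Q assessment")
    if x[0] == x[-1]:
        raise ValueError("constant data: Q-Q quantiles degenerate")
    if np.any(x <= 0):
        raise ValueError("diameters must be positive")
    fitted = scale_um is None
    s = _fit_beta_scale(x, a, b) if fitted else float(scale_um)
    if s <= 0:
        raise ValueError("scale_um must be positive")
    p = (np.arange(1, x.size + 1) - 0.5) / x.size
    theo = s * beta_dist.ppf(p, a, b)
    slope, intercept = np.polyfit(theo, x, 1)
    resid = x - (slope * theo + intercept)
    ss_tot = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return QQResult(empirical_q=x, theoretical_q=theo, r_squared=r2,
                    a=a, b=b, scale_um=s, scale_fitted=fitted)


def dispersion_stats(
    table: pd.DataFrame,
    by: list[str] | str,
    value_col: str = "eq_diameter_um",
    min_group: int = 4,
) -> pd.DataFrame:
    """Per-group dispersion report: n, sample variance, Q1, Q3, IQR.

    Variance uses the n-1 denominator; Q1/Q3 follow the shared
    linear-interpolation quantile rule; IQR = Q3 - Q1.  Groups smaller
    than ``min_group`` are skipped with a warning.
    """
    if isinstance(by, str):
        by = [by]
    rows = []
    for key, grp in table.groupby(by, sort=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        vals = grp[value_col].to_numpy(dtype=float)
        if vals.size < min_group:
            logger.warning("group %s skipped: only %d pores", key, vals.size)
            continue
        q1, q3 = quartiles(vals)
        rows.append({
            **dict(zip(by, key)),
            "n_pores": int(vals.size),
            "variance": float(np.var(vals, ddof=1)),
            "Q1_um": q1,
            "Q3_um": q3,
            "IQR_um": q3 - q1,
        })
    return pd.DataFrame(rows, columns=[*by, "n_pores", "variance",
                                       "Q1_um", "Q3_um", "IQR_um"])


def compare_groups(
    reports: pd.DataFrame,
    pair_on: list[str] | str = "solution",
    arm_col: str = "loading",
    arms: tuple[str, str] = ("ON_SHELF", "OFF_SHELF"),
) -> tuple[pd.DataFrame, dict]:
    """Pairwise ON vs OFF dispersion comparison.

    For every combination of ``pair_on`` keys present in both arms the
    signed differences ``variance_ON - variance_OFF`` and
    ``IQR_ON - IQR_OFF`` are reported, plus a summary counting pairs where
    the OFF arm shows lower variability on both indicators.  Unpaired
    groups are listed in the summary as unmatched.
    """
    if isinstance(pair_on, str):
        pair_on = [pair_on]
    on_arm, off_arm = arms
    pivoted = {}
    unmatched = []
    for key, grp in reports.groupby(pair_on, sort=True, observed=True):
        if not isinstance(key, tuple):
            key = (key,)
        have = set(grp[arm_col])
        if not {on_arm, off_arm} <= have:
            unmatched.append(dict(zip(pair_on, key)))
            continue
        pivoted[key] = grp.set_index(arm_col)
    rows = []
    for key, grp in pivoted.items():
        var_diff = float(grp.loc[on_arm, "variance"] - grp.loc[off_arm, "variance"])
        iqr_diff = float(grp.loc[on_arm, "IQR_um"] - grp.loc[off_arm, "IQR_um"])
        rows.append({
            **dict(zip(pair_on, key)),
            "variance_diff": var_diff,
            "iqr_diff": iqr_diff,
            "off_lower_variance": var_diff > 0,
            "off_lower_iqr": iqr_diff > 0,
        })
    pairs = pd.DataFrame(rows, columns=[*pair_on, "variance_diff", "iqr_diff",
                                        "off_lower_variance", "off_lower_iqr"])
    summary = {
        "n_pairs": len(pairs),
        "off_lower_both": int((pairs["off_lower_variance"]
                               & pairs["off_lower_iqr"]).sum()) if len(pairs) else 0,
        "unmatched": unmatched,
    }
    return pairs, summary
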