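"""Expected-vs-observed abundance concordance.

Agreement between the abundances predicted by the even-mass mock model and
the abundances a sequencing strategy actually observes is summarized two
ways: the Pearson product-moment correlation with its two-sided p-value,
and an ordinary least-squares fit reporting slope, intercept and adjusted
R².  Abundances are compared as percentages; taxa expected but not
observed (or vice versa) enter as zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ConcordanceResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    adj_r2: float
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n": self.n, "pearson_r": self.r, "p_value": self.p_value,
            "coef": self.slope, "intercept": self.intercept,
            "adj_r2": self.adj_r2,
        }])


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided p-value (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def linfit(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope, intercept and adjusted R² for a simple linear model.

    adj R² = 1 - (1 - R²)(n - 1)/(n - 2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: zero variance")
    n = len(x)
    xc = x - x.mean()
    slope = float((xc * y).sum() / (xc ** 2).sum())
    intercept = float(y.mean() - slope * x.mean())
    ss_res = float(((y - slope * x - intercept) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0  # constant y: no variance explained
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return slope, intercept, adj_r2


def concordance(expected: Mapping[str, float],
                observed: Mapping[str, float],
                as_percent: bool = True) -> ConcordanceResult:
    """Concordance between expected and observed relative abundances.

    Inputs map taxon label -> relative abundance (fractions or percentages,
    consistently).  The union of taxa is used; absences count as zero.
    When ``as_percent`` and the inputs look like fractions (sum ≈ 1), both
    sides are rescaled to percentages, matching how such comparisons are
    plotted.
    """
    taxa = sorted(set(expected) | set(observed))
    x = np.array([expected.get(t, 0.0) for t in taxa], dtype=float)
    y = np.array([observed.get(t, 0.0) for t in taxa], dtype=float)
    if as_percent:
        if 0 < x.sum() <= 1.5:
            x = x * 100.0
        if 0 < y.sum() <= 1.5:
            y = y * 100.0
    r, p = pearson(x, y)
    slope, intercept, adj_r2 = linfit(x, y)
    return ConcordanceResult(r=r, p_value=p, slope=slope,
                             intercept=intercept, adj_r2=adj_r2, n=len(taxa))
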