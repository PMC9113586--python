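"""Correspondence between conservation priority and current protection.

If protected areas were ideally placed, catchments with high irreplaceability
(selection frequency across repeated solver runs, range 0..n_runs) would also
have high protected-area fractions (range 0..1).  Three complementary scores
of that correspondence, each using the full range of both variables:

1. **Quadrants** — split both variables at their medians into high/low and
   classify each catchment into one of four groups (ties go to "low").
2. **Regression residuals** — residuals from an ordinary least-squares
   regression of irreplaceability on protected fraction; a positive residual
   means more priority than its protection level would predict.
3. **Ideal-line deviation** — signed distance from the hypothetical perfect
   1:n_runs relationship, deviation = irreplaceability − n_runs × protection;
   positive means under-protected relative to priority.

The regression is deliberately a plain OLS of counts on fractions, matching
standard practice for this diagnostic; heteroscedasticity of the bounded
response is not corrected for (see the methods note).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

QUADRANTS = ("highP_highI", "highP_lowI", "lowP_highI", "lowP_lowI")


@dataclass(frozen=True)
class RegressionStats:
    """Global OLS summary: irreplaceability ~ protected fraction."""

    slope: float
    slope_se: float
    intercept: float
    correlation_r: float
    p_value: float
    n: int


@dataclass
class CorrespondenceResult:
    """Per-catchment scores plus the global regression summary."""

    table: pd.DataFrame  # columns: irreplaceability, protection, quadrant, residual, deviation
    stats: RegressionStats


def _as_arrays(irreplaceability, protection):
    irr = np.asarray(irreplaceability, dtype=float)
    prot = np.asarray(protection, dtype=float)
    if irr.shape != prot.shape or irr.ndim != 1:
        raise ValueError("inputs must be 1-d arrays of equal length")
    return irr, prot


def quadrant_classify(irreplaceability, protection) -> np.ndarray:
    """Median-split classification into the four priority/protection groups.

    A value strictly above the median is "high"; values at or below the
    median are "low".
    """
    irr, prot = _as_arrays(irreplaceability, protection)
    if irr.size < 2:
        raise ValueError("need at least 2 catchments to split at medians")
    hi_i = irr > np.median(irr)
    hi_p = prot > np.median(prot)
    labels = np.where(
        hi_p,
        np.where(hi_i, "highP_highI", "highP_lowI"),
        np.where(hi_i, "lowP_highI", "lowP_lowI"),
    )
    return labels


def ols_residuals(irreplaceability, protection):
    """OLS of irreplaceability on protected fraction.

    Returns ``(residuals, RegressionStats)``; residual = observed − fitted.
    The p-value is the two-sided t-test on the slope.
    """
    irr, prot = _as_arrays(irreplaceability, protection)
    if irr.size < 3:
        raise ValueError("need at least 3 catchments for the regression")
    if np.ptp(prot) == 0:
        raise ValueError("protected fraction is constant; regression is degenerate")
    fit = sm.OLS(irr, sm.add_constant(prot)).fit()
    resid = irr - fit.fittedvalues
    r = float(stats.pearsonr(prot, irr).statistic)
    reg = RegressionStats(
        slope=float(fit.params[1]),
        slope_se=float(fit.bse[1]),
        intercept=float(fit.params[0]),
        correlation_r=r,
        p_value=float(fit.pvalues[1]),
        n=int(irr.size),
    )
    return resid, reg


def ideal_line_deviation(irreplaceability, protection, n_runs: int = 1000) -> np.ndarray:
    """Signed deviation from the perfect 1:n_runs priority-protection line.

    deviation = irreplaceability − n_runs × protection.  Positive values flag
    catchments with higher priority than their protection level warrants.
    """
    irr, prot = _as_arrays(irreplaceability, protection)
    if ((irr < 0) | (irr > n_runs)).any():
        raise ValueError(f"irreplaceability must lie in [0, {n_runs}]")
    if ((prot < 0) | (prot > 1)).any():
        raise ValueError("protection must lie in [0, 1]")
    return irr - n_runs * prot


def group_summary(values, grouping) -> pd.DataFrame:
    """Mean ± SE of a per-catchment quantity by group, ranked by mean.

    SE is the sample standard deviation over √n; groups of one report SE as
    NaN.  Used for ecoregion- and country-level irreplaceability summaries.
    """
    vals = np.asarray(values, dtype=float)
    groups = np.asarray(grouping)
    if vals.shape != groups.shape or vals.ndim != 1:
        raise ValueError("values and grouping must be 1-d and equal length")
    if vals.size == 0:
        raise ValueError("empty input")
    df = pd.DataFrame({"group": groups, "value": vals})
    out = df.groupby("group")["value"].agg(
        mean="mean", sd=lambda v: v.std(ddof=1), n="count"
    )
    out["se"] = out["sd"] / np.sqrt(out["n"])
    out = out[["mean", "se", "n"]].sort_values("mean", ascending=False)
    return out


def analyze_correspondence(
    irreplaceability, protection, n_runs: int = 1000, index=None
) -> CorrespondenceResult:
    """Run all three correspondence methods on matched per-catchment inputs."""
    irr, prot = _as_arrays(irreplaceability, protection)
    resid, reg = ols_residuals(irr, prot)
    table = pd.DataFrame(
        {
            "irreplaceability": irr,
            "protection": prot,
            "quadrant": quadrant_classify(irr, prot),
            "residual": resid,
            "deviation": ideal_line_deviation(irr, prot, n_runs=n_runs),
        },
        index=index,
    )
    return CorrespondenceResult(table=table, stats=reg)
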