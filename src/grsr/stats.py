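"""GrSR statistics: OLS fits, correlations, OGT moving windows, BH correction,
and Poisson ML fit with goodness-of-fit for provirus counts.

The growth rate-specialization relationship (GrSR) is the linear regression of
host specialization d' on log10 growth rate (doublings/day). Moving windows
over optimal growth temperature (OGT) locate changes in GrSR strength along
the thermal gradient; p-values across the retained windows are adjusted by
Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import OLS, add_constant
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GrsrFit",
    "WindowResult",
    "StatsError",
    "ols_fit",
    "multiple_ols",
    "pearson",
    "moving_window_grsr",
    "grouped_grsr",
    "bh_adjust",
    "poisson_mle_gof",
]


class StatsError(ValueError):
    """Invalid input to a statistical operation."""


@dataclass(frozen=True)
class GrsrFit:
    """One linear GrSR fit: d' ~ log10(growth rate)."""

    n: int
    slope: float
    slope_se: float
    intercept: float
    r: float
    r2_adj: float
    p: float
    p_adj: float | None = None
    degenerate: bool = False    # constant response: slope 0, r undefined

    @property
    def abs_slope(self) -> float:
        """GrSR *strength*: magnitude of the slope."""
        return abs(self.slope)


@dataclass(frozen=True)
class WindowResult:
    """GrSR fit inside one OGT moving window [low, low + width)."""

    low: float
    high: float
    n: int
    fit: GrsrFit | None
    retained: bool              # False when n < min_n (excluded from BH)

    @property
    def width(self) -> float:
        return self.high - self.low


def ols_fit(x: Sequence[float], y: Sequence[float]) -> GrsrFit:
    """Simple least squares of y on x with Pearson r, adjusted R2 and t-test p.

    ``x`` is expected to already be log10 growth rate. A constant ``y`` is a
    degenerate (flat) relationship: slope 0, undefined r, flagged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("x and y lengths differ")
    n = x.size
    if n < 3:
        raise StatsError(f"need n >= 3 for a fit, got {n}")
    if np.ptp(x) == 0:
        raise StatsError("x is constant; slope undefined")
    if np.ptp(y) == 0:
        return GrsrFit(n=n, slope=0.0, slope_se=0.0, intercept=float(y[0]),
                       r=float("nan"), r2_adj=float("nan"), p=float("nan"),
                       degenerate=True)
    res = sps.linregress(x, y)
    r2 = res.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return GrsrFit(
        n=n,
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2_adj=float(r2_adj),
        p=float(res.pvalue),
    )


def multiple_ols(
    d_prime: Sequence[float],
    log_growth_rate: Sequence[float],
    ogt: Sequence[float],
    with_interaction: bool = False,
) -> pd.DataFrame:
    """Multiple regression d' ~ log10(growth rate) + OGT [+ interaction].

    Returns a coefficient table (coef, se, t, p) indexed by term. Used to ask
    whether growth rate and OGT have independent effects on specialization and
    whether their product term adds anything.
    """
    y = np.asarray(d_prime, dtype=float)
    x1 = np.asarray(log_growth_rate, dtype=float)
    x2 = np.asarray(ogt, dtype=float)
    X = pd.DataFrame({"log10_growth_rate": x1, "ogt": x2})
    if with_interaction:
        X["log10_growth_rate:ogt"] = x1 * x2
    if y.size <= X.shape[1] + 1:
        raise StatsError("too few observations for the number of coefficients")
    Xc = add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
        raise StatsError("design matrix is rank deficient (collinear predictors)")
    fit = OLS(y, Xc).fit()
    return pd.DataFrame({
        "coef": fit.params,
        "se": fit.bse,
        "t": fit.tvalues,
        "p": fit.pvalues,
    })


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided t-test p; (nan, nan) if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def moving_window_grsr(
    table: pd.DataFrame,
    width: float = 10.0,
    step: float = 1.0,
    range_: tuple[float, float] = (10.0, 80.0),
    min_n: int = 10,
    ogt_col: str = "ogt",
    x_col: str = "log10_growth_rate",
    y_col: str = "d_prime",
) -> list[WindowResult]:
    """GrSR fit inside overlapping OGT windows of fixed width.

    Windows start at ``range_[0]`` and advance by ``step`` until the last
    window's upper edge reaches ``range_[1]`` (e.g. width 10 over 10-80 °C
    gives 10-20, 11-21, ..., 70-80). Membership is the half-open interval
    [low, low + width). Windows with fewer than ``min_n`` hosts are flagged
    unretained and excluded from the BH family.
    """
    lo, hi = range_
    if width >= hi - lo:
        raise StatsError("window width must be smaller than the OGT range span")
    if step <= 0:
        raise StatsError("step must be positive")
    ogt = table[ogt_col].to_numpy(dtype=float)
    n_windows = int(np.floor((hi - lo - width) / step + 1e-9)) + 1
    results: list[WindowResult] = []
    for w in range(n_windows):
        low = lo + w * step
        high = low + width
        sel = (ogt >= low) & (ogt < high)
        n = int(sel.sum())
        fit = None
        retained = n >= min_n
        if retained:
            sub = table.loc[sel]
            try:
                fit = ols_fit(sub[x_col].to_numpy(), sub[y_col].to_numpy())
            except StatsError:
                fit, retained = None, False
        results.append(WindowResult(low=low, high=high, n=n, fit=fit,
                                    retained=retained))
    kept_idx = [i for i, w in enumerate(results)
                if w.retained and w.fit is not None and np.isfinite(w.fit.p)]
    if not kept_idx:
        raise StatsError(f"no window retains min_n = {min_n} hosts")
    adj = bh_adjust([results[i].fit.p for i in kept_idx])
    for i, a in zip(kept_idx, adj):
        w = results[i]
        results[i] = replace(w, fit=replace(w.fit, p_adj=float(a)))
    return results


def grouped_grsr(
    table: pd.DataFrame,
    by: str,
    x_col: str = "log10_growth_rate",
    y_col: str = "d_prime",
    min_n: int = 10,
) -> pd.DataFrame:
    """One GrSR fit per level of a grouping column, BH-adjusted across levels.

    ``by`` is a column name (e.g. ``ecosystem``) or ``trait:<name>``, which
    splits on presence/absence of the binary trait column ``<name>``.
    Levels with fewer than ``min_n`` hosts are reported unfitted.
    """
    if by.startswith("trait:"):
        col = by.split(":", 1)[1]
        if col not in table.columns:
            raise StatsError(f"trait column {col!r} not in table")
        groups = table.groupby(table[col].map({0: "absent", 1: "present"}))
    else:
        if by not in table.columns:
            raise StatsError(f"grouping column {by!r} not in table")
        groups = table.groupby(by)
    rows = []
    for level, sub in groups:
        row = {"group": level, "n": len(sub)}
        if len(sub) >= min_n:
            try:
                fit = ols_fit(sub[x_col].to_numpy(), sub[y_col].to_numpy())
                row.update(slope=fit.slope, slope_se=fit.slope_se, r=fit.r,
                           r2_adj=fit.r2_adj, p=fit.p)
            except StatsError:
                pass
        rows.append(row)
    out = pd.DataFrame(rows)
    if "p" in out.columns:
        ok = out["p"].notna()
        out.loc[ok, "p_adj"] = bh_adjust(out.loc[ok, "p"].to_numpy())
    return out


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def poisson_mle_gof(counts: Sequence[int]) -> dict:
    """Poisson fit of nonnegative counts plus a chi-square goodness-of-fit.

    The ML estimate of the Poisson rate is the sample mean. The GOF statistic
    compares observed count frequencies with Poisson(lambda_hat) expectations,
    merging adjacent bins from the upper tail (and, if needed, from 0 upward)
    until every expected count is >= 5; dof = bins - 2 (one for the total, one
    for the estimated rate). With dof < 1 or an all-zero sample, the test is
    skipped and flagged.
    """
    c = np.asarray(counts)
    if c.size < 5:
        raise StatsError(f"need at least 5 counts, got {c.size}")
    if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
        c = c.astype(float)
        if (c < 0).any() or (c != np.round(c)).any():
            raise StatsError("counts must be nonnegative integers")
        c = c.astype(np.int64)
    lam = float(c.mean())
    base = {"lambda_hat": lam, "n": int(c.size)}
    if lam == 0:
        return {**base, "chi2": float("nan"), "dof": 0, "p": float("nan"),
                "tested": False}
    kmax = int(c.max())
    observed = np.bincount(c, minlength=kmax + 2).astype(float)
    expected = sps.poisson.pmf(np.arange(kmax + 2), lam) * c.size
    expected[-1] = c.size - expected[:-1].sum()  # fold the tail into the top bin

    # merge from the right, then from the left, until all expected >= 5
    obs, exp = list(observed), list(expected)
    while len(exp) > 1 and exp[-1] < 5:
        e, o = exp.pop(), obs.pop()
        exp[-1] += e
        obs[-1] += o
    while len(exp) > 1 and exp[0] < 5:
        e, o = exp.pop(1), obs.pop(1)
        exp[0] += e
        obs[0] += o
    dof = len(exp) - 2
    if dof < 1:
        return {**base, "chi2": float("nan"), "dof": dof, "p": float("nan"),
                "tested": False}
    chi2 = float(np.sum((np.array(obs) - np.array(exp)) ** 2 / np.array(exp)))
    p = float(sps.chi2.sf(chi2, dof))
    return {**base, "chi2": chi2, "dof": dof, "p": p, "tested": True}
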