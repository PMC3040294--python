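"""Frequentist multiple-testing screen for areal counts.

Per-area exact Poisson tests of H0: RR = 1 (no normal approximation), and the
standard multiplicity procedures applied on top of them:

* Bonferroni at family-wise level alpha (each test at alpha/m);
* the Benjamini-Hochberg step-up, plain or adaptive (threshold scaled by an
  estimate of the proportion of true nulls, pi0);
* Storey's fixed-lambda pi0 estimator and q-values (minimum pFDR attainable
  when rejecting at the observed statistic or beyond);
* exact Poisson funnel-plot control limits: SMR plotted against precision
  (the expected count), with null limits that narrow as precision grows.

Thresholding q-values at level gamma rejects exactly the adaptive BH(gamma,
pi0) set; the suite asserts this equivalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .areal import AreaTable, compute_smr

__all__ = [
    "poisson_pvalue",
    "bonferroni",
    "bh_procedure",
    "estimate_pi0",
    "qvalues",
    "funnel_limits",
    "FrequentistResult",
    "FunnelLimits",
    "screen_table",
]


def poisson_pvalue(y, e, sided: str = "two"):
    """Exact Poisson p-value for H0: theta = 1, i.e. Y ~ Poisson(e).

    ``upper`` is P(Y >= y), ``lower`` is P(Y <= y), and ``two`` doubles the
    smaller tail (capped at 1).  Vectorized over ``y`` and ``e``.
    """
    y = np.asarray(y)
    e = np.asarray(e, dtype=float)
    if np.any(e <= 0):
        raise ValueError("expected count must be positive")
    if np.any(y < 0):
        raise ValueError("observed count must be non-negative")
    upper = stats.poisson.sf(y - 1, e)  # P(Y >= y)
    lower = stats.poisson.cdf(y, e)
    if sided == "upper":
        p = upper
    elif sided == "lower":
        p = lower
    elif sided == "two":
        p = np.minimum(1.0, 2.0 * np.minimum(upper, lower))
    else:
        raise ValueError(f"sided must be 'upper', 'lower' or 'two', got {sided!r}")
    return p if p.ndim else float(p)


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return p


def bonferroni(pvals, alpha: float = 0.05) -> np.ndarray:
    """FWER control: reject H0_i iff p_i <= alpha / m."""
    p = _check_pvals(pvals)
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return (p <= alpha / p.size).astype(int)


def bh_procedure(pvals, level: float = 0.05, pi0: float = 1.0) -> np.ndarray:
    """Benjamini-Hochberg step-up at FDR ``level``; ``pi0`` < 1 gives the
    adaptive variant (threshold (k/m) * level / pi0).

    Ties are handled by p-value, never by index: all hypotheses with
    p <= p_(k*) are rejected, where k* is the largest rank satisfying the
    step-up inequality.
    """
    p = _check_pvals(pvals)
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = (np.arange(1, m + 1) / m) * level / pi0
    ok = p[order] <= thresh
    if not ok.any():
        return np.zeros(m, dtype=int)
    k_star = int(np.flatnonzero(ok)[-1])
    return (p <= p[order][k_star]).astype(int)


def estimate_pi0(pvals, lam: float = 0.5) -> float:
    """Storey's fixed-lambda estimator of the proportion of true nulls:
    pi0_hat = #{p > lam} / ((1 - lam) m), capped at 1.

    The count is floored at 1 so the estimate stays positive (a zero estimate
    would make every q-value zero); the floor only binds when no p-value
    exceeds lam.
    """
    p = _check_pvals(pvals)
    if not 0 < lam < 1:
        raise ValueError("lambda must lie in (0, 1)")
    return min(1.0, max(float(np.sum(p > lam)), 1.0) / ((1.0 - lam) * p.size))


def qvalues(pvals, pi0_hat: float = 1.0) -> np.ndarray:
    """Storey q-values: q_(i) = min_{k >= i} pi0_hat * m * p_(k) / k,
    mapped back to input order.  Monotone in p by construction."""
    p = _check_pvals(pvals)
    if not 0 < pi0_hat <= 1:
        raise ValueError("pi0_hat must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = pi0_hat * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class FunnelLimits:
    """Exact-Poisson funnel control limits on the SMR scale.

    One row per grid point: expected count (precision), lower and upper SMR
    limits.  ``rule`` records whether the curve is a plain per-test band or a
    q-value-implied (multiplicity-adjusted) band, and at which level.
    """

    e_grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    rule: str
    per_test_alpha: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"expected": self.e_grid, "lower": self.lower, "upper": self.upper,
             "rule": self.rule}
        )


def _poisson_band(e_grid: np.ndarray, alpha: float) -> tuple[np.ndarray, np.ndarray]:
    # Conservative discrete quantiles: largest y_l with P(Y <= y_l) <= alpha/2
    # and smallest y_u with P(Y >= y_u) <= alpha/2.  Coverage >= nominal.
    half = alpha / 2.0
    lo = np.empty_like(e_grid)
    up = np.empty_like(e_grid)
    for i, e in enumerate(e_grid):
        y_l = int(stats.poisson.ppf(half, e))  # smallest y with cdf >= half
        while y_l >= 0 and stats.poisson.cdf(y_l, e) > half:
            y_l -= 1
        lo[i] = max(y_l, 0) / e if y_l >= 0 else 0.0
        y_u = int(stats.poisson.isf(half, e)) + 1
        while y_u > 1 and stats.poisson.sf(y_u - 2, e) <= half:
            y_u -= 1
        up[i] = y_u / e
    return lo, up


def funnel_limits(
    e_grid,
    alpha: float = 0.05,
    pvals=None,
    q_threshold: float | None = None,
    pi0_hat: float = 1.0,
) -> FunnelLimits:
    """Null control limits for a funnel plot of SMR against expected count.

    With ``q_threshold`` given, the band is multiplicity-adjusted: the
    per-test two-sided p cut-off becomes the largest observed p-value whose
    q-value is at or below the threshold (computed from ``pvals``), so the
    solid adjusted funnel line passes exactly between rejected and retained
    areas.  Without it the band is the plain per-test ``alpha`` percentile
    band of the null Poisson distribution.
    """
    e_grid = np.asarray(e_grid, dtype=float)
    if np.any(e_grid <= 0) or np.any(np.diff(e_grid) <= 0):
        raise ValueError("e_grid must be positive and strictly increasing")
    if q_threshold is not None:
        if pvals is None:
            raise ValueError("q-adjusted limits need the observed p-values")
        p = _check_pvals(pvals)
        q = qvalues(p, pi0_hat)
        hits = p[q <= q_threshold]
        cut = float(hits.max()) if hits.size else 0.0
        rule = f"q<={q_threshold:g}"
        per_test = cut
    else:
        rule = f"p<={alpha:g}"
        per_test = alpha
    if per_test <= 0:
        # nothing rejected at this threshold: band degenerates to (0, inf)
        lo = np.zeros_like(e_grid)
        up = np.full_like(e_grid, np.inf)
    else:
        lo, up = _poisson_band(e_grid, per_test)
    return FunnelLimits(e_grid, lo, up, rule, per_test)


@dataclass
class FrequentistResult:
    """Per-area screen output plus the rejection bookkeeping of each procedure."""

    ids: list[str]
    smr: np.ndarray
    p: np.ndarray
    q: np.ndarray
    pi0_hat: float
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_rejections(self) -> dict[str, int]:
        """R = sum of rejection indicators, per procedure."""
        return {k: int(v.sum()) for k, v in self.flags.items()}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"area_id": self.ids, "smr": self.smr,
                           "p_value": self.p, "q_value": self.q})
        for name, f in self.flags.items():
            df[f"reject_{name}"] = f
        return df


def screen_table(
    table: AreaTable,
    alpha: float = 0.05,
    fdr_level: float = 0.05,
    lam: float = 0.5,
    q_cutoffs: tuple[float, ...] = (0.05, 0.10, 0.20),
    sided: str = "two",
) -> FrequentistResult:
    """Run the full frequentist screen on an area table.

    Computes exact Poisson p-values, Storey's pi0 and q-values, then flags
    areas under Bonferroni(alpha), plain BH(fdr_level), adaptive
    BH(fdr_level, pi0_hat) and each q-value cut-off.
    """
    smr = compute_smr(table)
    p = poisson_pvalue(table.y, table.e, sided=sided)
    pi0_hat = estimate_pi0(p, lam=lam)
    q = qvalues(p, pi0_hat)
    flags = {
        "bonferroni": bonferroni(p, alpha),
        "bh": bh_procedure(p, fdr_level),
        "bh_adaptive": bh_procedure(p, fdr_level, pi0=pi0_hat),
    }
    for g in q_cutoffs:
        flags[f"q{g:g}"] = (q <= g).astype(int)
    return FrequentistResult(list(table.ids), smr.smr, p, q, pi0_hat, flags)
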