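"""Statistical tests shared by the interpretation and enrichment modules."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "dependent_correlation_test",
    "bh_fdr",
    "paired_signed_rank",
    "mann_whitney",
    "bootstrap_mean",
    "bootstrap_diff",
]


def dependent_correlation_test(rho12: float, rho13: float, rho23: float, n: int):
    """One-sided test of rho12 > rho13 when both share variable 1 (same cells).

    The two correlations are dependent because they are computed against the
    same observations; the statistic

        t = (r12 - r13) * sqrt( (n-1)(1+r23) /
              ( 2((n-1)/(n-3))|S| + ((r12+r13)^2 / 4)(1-r23)^3 ) )

    with |S| = 1 - (r12^2 + r13^2 + r23^2) + 2 r12 r13 r23 follows a Student
    t distribution with n-3 degrees of freedom. Returns (t, one-sided p).
    """
    if n <= 3:
        raise ValueError(f"need n > 3 cells, got {n}")
    for name, r in (("rho12", rho12), ("rho13", rho13), ("rho23", rho23)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} = {r} outside [-1, 1]")
    det = 1.0 - (rho12**2 + rho13**2 + rho23**2) + 2.0 * rho12 * rho13 * rho23
    denom = 2.0 * ((n - 1) / (n - 3)) * abs(det) + ((rho12 + rho13) ** 2 / 4.0) * (1.0 - rho23) ** 3
    if denom <= 0:  # rho23 -> 1 with identical predictions: statistic degenerates
        if rho12 == rho13:
            return 0.0, 0.5
        t = np.inf if rho12 > rho13 else -np.inf
        return float(t), float(sps.t.sf(t, df=n - 3))
    t = (rho12 - rho13) * np.sqrt((n - 1) * (1.0 + rho23) / denom)
    p = float(sps.t.sf(t, df=n - 3))
    return float(t), p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_signed_rank(a, b, alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; ties get average ranks; the exact null
    distribution is used for n <= 25 without ties, otherwise the normal
    approximation with continuity correction. All-zero differences return
    p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    has_ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, alternative=alternative, method=method, correction=(method == "approx"))
    return float(res.pvalue)


def mann_whitney(x, y, alternative: str = "greater") -> float:
    """Mann-Whitney U p-value (x vs y), average ranks for ties."""
    return float(sps.mannwhitneyu(x, y, alternative=alternative).pvalue)


def bootstrap_mean(values, n_iter: int = 1000, seed: int = 0):
    """Percentile bootstrap of the mean over units.

    Returns (mean, (ci_lo, ci_hi)) with a 95% percentile interval from
    ``n_iter`` resamples with replacement. A single unit gives a degenerate
    interval at its value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("need at least one unit to bootstrap")
    rng = np.random.default_rng(seed)
    if values.size == 1:
        v = float(values[0])
        return v, (v, v)
    idx = rng.integers(0, values.size, size=(n_iter, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(values.mean()), (float(lo), float(hi))


def bootstrap_diff(a, b, n_iter: int = 1000, seed: int = 0):
    """Two-sided bootstrap p for a difference in means over paired units.

    Resamples units with replacement; p = 2 * min(P(diff <= 0), P(diff >= 0)),
    floored at 1/n_iter. Constant zero difference returns p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 paired units")
    d = a - b
    if np.all(d == 0):
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, d.size, size=(n_iter, d.size))
    diffs = d[idx].mean(axis=1)
    p = 2.0 * min(np.mean(diffs <= 0), np.mean(diffs >= 0))
    return float(d.mean()), float(max(min(p, 1.0), 1.0 / n_iter))
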