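"""Rank and contingency tests used by the cohort analysis.

Both tests are written out explicitly (with documented exact/approximate
regimes) so the reported p-values are reproducible; the test suite checks
them against scipy as an independent oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm
from scipy.stats import rankdata

from .errors import InvalidParameterError

__all__ = ["TestResult", "mann_whitney_u", "chi_square_independence", "pairwise_mann_whitney"]

EXACT_LIMIT = 8  # exact enumeration when max(n_x, n_y) <= this and no ties


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    df: int | None = None
    warning: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidParameterError("p-value outside [0, 1]")


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney-Wilcoxon U test.

    Exact p by full enumeration of label assignments when both samples have
    at most ``EXACT_LIMIT`` observations and there are no ties; otherwise a
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise InvalidParameterError(f"unknown alternative {alternative!r}")

    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    rx = ranks[:nx].sum()
    u_x = rx - nx * (nx + 1) / 2.0  # number of (x > y) pairs (+ half-ties)

    has_ties = len(np.unique(pooled)) < len(pooled)
    if max(nx, ny) <= EXACT_LIMIT and not has_ties:
        p = _exact_p(pooled, nx, u_x, alternative)
        return TestResult(statistic=float(u_x), p_value=p, method="exact enumeration")

    mu = nx * ny / 2.0
    n = nx + ny
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1)) if n > 1 else 0.0
    sigma2 = nx * ny / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0.0:
        return TestResult(statistic=float(u_x), p_value=1.0, method="normal approximation (degenerate)")
    sigma = math.sqrt(sigma2)
    if alternative == "two-sided":
        z = max(abs(u_x - mu) - 0.5, 0.0) / sigma
        p = 2.0 * float(norm.sf(z))
    elif alternative == "greater":
        z = (u_x - mu - 0.5) / sigma
        p = float(norm.sf(z))
    else:
        z = (u_x - mu + 0.5) / sigma
        p = float(norm.cdf(z))
    return TestResult(statistic=float(u_x), p_value=min(p, 1.0), method="normal approximation")


def _exact_p(pooled: np.ndarray, nx: int, u_obs: float, alternative: str) -> float:
    n = len(pooled)
    ranks = rankdata(pooled)
    mu = nx * (n - nx) / 2.0
    us = []
    for combo in itertools.combinations(range(n), nx):
        rsum = ranks[list(combo)].sum()
        us.append(rsum - nx * (nx + 1) / 2.0)
    us = np.asarray(us)
    if alternative == "two-sided":
        p = float(np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12))
    elif alternative == "greater":
        p = float(np.mean(us >= u_obs - 1e-12))
    else:
        p = float(np.mean(us <= u_obs + 1e-12))
    return min(p, 1.0)


def chi_square_independence(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction; a warning flag is set when any expected count
    is below 5.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise InvalidParameterError("table must be at least 2x2")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise InvalidParameterError("table entries must be finite and >= 0")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows <= 0) or np.any(cols <= 0):
        raise InvalidParameterError("all row and column sums must be > 0")
    total = t.sum()
    expected = np.outer(rows, cols) / total
    stat = float(((t - expected) ** 2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(chi2_dist.sf(stat, df))
    warning = "expected count < 5" if np.any(expected < 5.0) else None
    return TestResult(statistic=stat, p_value=p, method="pearson chi-square", df=df, warning=warning)


def pairwise_mann_whitney(groups: dict[str, np.ndarray]) -> dict[tuple[str, str], TestResult]:
    """All pairwise two-sided tests between named groups (no multiplicity
    adjustment, mirroring per-pair box-plot annotations)."""
    names = sorted(groups)
    out: dict[tuple[str, str], TestResult] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if len(groups[a]) and len(groups[b]):
                out[(a, b)] = mann_whitney_u(groups[a], groups[b])
    return out
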