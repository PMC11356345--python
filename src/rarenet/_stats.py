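"""Shared rank-correlation machinery.

Every Spearman correlation in the package — all-pairs taxon correlations for
network construction and the environment screens — goes through this module,
so the rank/tie/p-value conventions are identical everywhere: average ranks
for ties, rho as the Pearson correlation of the ranks, and a two-sided
p-value from the t approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` with
``n - 2`` degrees of freedom (``|rho| = 1`` gives p = 0 exactly).
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _sps

__all__ = ["spearman_rho_p", "spearman_matrix", "pvalue_from_rho", "stars"]


def pvalue_from_rho(rho: np.ndarray | float, n: int) -> np.ndarray | float:
    """Two-sided p-value of a Spearman rho via the t approximation.

    Entries with ``|rho| = 1`` map to p = 0; NaN rho propagates to NaN p.
    Requires ``n >= 4`` so that the t statistic has positive df and the
    correlation is not trivially ±1.
    """
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got n={n}")
    rho_arr = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_arr * np.sqrt((n - 2) / (1.0 - rho_arr**2))
    p = 2.0 * _sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(rho_arr), 1.0), 0.0, p)
    p = np.where(np.isnan(rho_arr), np.nan, p)
    if np.isscalar(rho) or rho_arr.ndim == 0:
        return float(p)
    return p


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Average-rank each row of a 2-D array."""
    return _sps.rankdata(x, axis=-1, method="average")


def spearman_rho_p(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p for one pair of vectors.

    Returns ``(nan, nan)`` when either vector is constant (zero rank
    variance): the correlation is undefined and callers record no edge.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 paired observations, got n={n}")
    rx = _sps.rankdata(x, method="average")
    ry = _sps.rankdata(y, method="average")
    sx = rx.std()
    sy = ry.std()
    if sx == 0.0 or sy == 0.0:
        return float("nan"), float("nan")
    rho = float(np.clip(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy), -1.0, 1.0))
    return rho, float(pvalue_from_rho(rho, n))


def spearman_matrix(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho and p between the rows of ``x``.

    ``x`` is features x observations. Rows with zero rank variance
    (constant vectors) yield NaN rho/p against every other row; the
    diagonal is rho = 1, p = 0 for non-constant rows.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("x must be 2-D (features x observations)")
    m, n = x.shape
    if n < 4:
        raise ValueError(f"need at least 4 observations, got n={n}")
    ranks = _rank_rows(x)
    sd = ranks.std(axis=1)
    constant = sd == 0.0
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    safe_sd = np.where(constant, 1.0, sd)
    z = centered / safe_sd[:, None]
    rho = np.clip(z @ z.T / n, -1.0, 1.0)
    rho[constant, :] = np.nan
    rho[:, constant] = np.nan
    np.fill_diagonal(rho, np.where(constant, np.nan, 1.0))
    p = pvalue_from_rho(rho, n)
    # exact monotone agreement on the diagonal
    diag_p = np.where(constant, np.nan, 0.0)
    np.fill_diagonal(p, diag_p)
    return rho, p


def stars(p: float) -> str:
    """Significance stars: ``***`` p<0.001, ``**`` p<0.01, ``*`` p<0.05."""
    if p is None or np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""
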