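"""Alpha-diversity and coverage estimators for a single sample's counts.

Conventions: Shannon uses the natural log; "Simpson" is the Gini-Simpson
index 1 - sum(p^2); Chao1 uses the bias-corrected form when no doubletons
are observed; ACE is the Chao & Lee abundance-based coverage estimator with
the conventional rare/abundant cutoff of 10, falling back to Chao1 when its
sample-coverage term vanishes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "shannon",
    "simpson",
    "chao1",
    "ace",
    "goods_coverage",
    "alpha_diversity_table",
]


def _clean(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    if c.sum() == 0:
        raise ValueError("counts sum to zero; diversity undefined")
    return c[c > 0].astype(np.int64)


def shannon(counts) -> float:
    """Shannon entropy H = -sum(p ln p) in nats."""
    c = _clean(counts)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def simpson(counts) -> float:
    """Gini-Simpson diversity D = 1 - sum(p^2)."""
    c = _clean(counts)
    p = c / c.sum()
    return float(1.0 - (p**2).sum())


def chao1(counts) -> float:
    """Chao1 richness estimate.

    ``S_obs + F1^2 / (2 F2)`` with doubletons, otherwise the bias-corrected
    ``S_obs + F1 (F1 - 1) / 2``.
    """
    c = _clean(counts)
    s_obs = c.size
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    if f2 > 0:
        return float(s_obs + f1 * f1 / (2.0 * f2))
    return float(s_obs + f1 * (f1 - 1) / 2.0)


def ace(counts, rare_cutoff: int = 10) -> float:
    """Abundance-based coverage estimator (Chao & Lee).

    Taxa with counts <= ``rare_cutoff`` form the rare group. With sample
    coverage ``C = 1 - F1 / N_rare`` and squared coefficient of variation
    ``gamma^2`` (truncated at 0):

        ACE = S_abund + S_rare / C + (F1 / C) * gamma^2

    Degenerate rare groups (``C <= 0``, or too few rare reads to estimate
    the CV) fall back to Chao1; a sample with no rare taxa returns S_obs.
    """
    c = _clean(counts)
    rare = c[c <= rare_cutoff]
    s_abund = int((c > rare_cutoff).sum())
    s_rare = rare.size
    if s_rare == 0:
        return float(c.size)
    n_rare = int(rare.sum())
    f1 = int((rare == 1).sum())
    c_ace = 1.0 - f1 / n_rare
    if c_ace <= 0 or n_rare < 2:
        return chao1(counts)
    ssq = sum(i * (i - 1) * int((rare == i).sum()) for i in range(1, rare_cutoff + 1))
    gamma2 = max(s_rare / c_ace * ssq / (n_rare * (n_rare - 1.0)) - 1.0, 0.0)
    return float(s_abund + s_rare / c_ace + f1 / c_ace * gamma2)


def goods_coverage(counts) -> float:
    """Good's coverage G = 1 - F1 / N."""
    c = _clean(counts)
    return float(1.0 - (c == 1).sum() / c.sum())


def alpha_diversity_table(table) -> pd.DataFrame:
    """Per-sample diversity summary for an :class:`~rarenet.table.AsvTable`.

    Columns: S_obs, shannon, simpson, chao1, ace, goods_coverage, and the
    supporting statistics F1 (singletons), F2 (doubletons) and N (reads).
    """
    rows = {}
    for sample in table.sample_ids:
        c = table.counts[sample].to_numpy()
        nz = c[c > 0]
        rows[sample] = {
            "S_obs": int(nz.size),
            "shannon": shannon(c),
            "simpson": simpson(c),
            "chao1": chao1(c),
            "ace": ace(c),
            "goods_coverage": goods_coverage(c),
            "F1": int((nz == 1).sum()),
            "F2": int((nz == 2).sum()),
            "N": int(nz.sum()),
        }
    return pd.DataFrame.from_dict(rows, orient="index").loc[table.sample_ids]
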