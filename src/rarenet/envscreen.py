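"""Trophic state index and Spearman environment screens.

Two trophic state formulations are provided. The Carlson variant averages
the classic component indices

    TSI(SD)  = 60 - 14.41 ln SD          (Secchi depth, m)
    TSI(Chl) = 9.81 ln Chl + 30.6        (chlorophyll a, ug/L)
    TSI(TP)  = 14.42 ln(1000 TP) + 4.15  (total phosphorus, mg/L)

The Chinese comprehensive trophic level index (TLI) combines five component
indices with chlorophyll-correlation weights:

    TLI(Chl) = 10 (2.5   + 1.086 ln Chl)
    TLI(TP)  = 10 (9.436 + 1.624 ln TP)
    TLI(TN)  = 10 (5.453 + 1.694 ln TN)
    TLI(SD)  = 10 (5.118 - 1.94  ln SD)
    TLI(PI)  = 10 (0.109 + 2.661 ln PI)   (permanganate index, mg/L)

with weights proportional to the squared correlations with Chl-a
(r = 1, 0.84, 0.82, -0.83, 0.83). Components missing for a sample are
dropped and the remaining weights renormalised. Values of 0-30 indicate
oligotrophy, 30-50 mesotrophy, and above 50 eutrophy.

The screens correlate alpha-diversity indices, rank-aggregated taxa, or
keystone ASV abundances against environmental variables (with TSI appended)
using the package-wide Spearman routine, and star significance at p < 0.05
(*), p < 0.01 (**), p < 0.001 (***).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import spearman_rho_p, stars
from .table import SampleMetadata

__all__ = [
    "TsiResult",
    "trophic_state_index",
    "correlation_screen",
    "diversity_env_screen",
    "taxa_env_screen",
    "keystone_env_screen",
    "indicator_call",
]

# chlorophyll-correlation weights of the five TLI components
_TLI_R = {"Chl-a": 1.0, "TP": 0.84, "TN": 0.82, "SD": 0.83, "PI": 0.83}


@dataclass
class TsiResult:
    """Composite trophic state per sample with retained component indices."""

    composite: pd.Series  # sample -> TSI
    components: pd.DataFrame  # sample x component index
    method: str


def _safe_log(value: float, sample, variable: str) -> float:
    if value <= 0:
        raise ValueError(
            f"cannot take log of non-positive {variable!r}={value} for sample {sample!r}"
        )
    return float(np.log(value))


def trophic_state_index(meta: SampleMetadata, method: str = "tli_composite") -> TsiResult:
    """Compute the trophic state index per sample.

    ``method``: ``"carlson"`` (mean of the SD/Chl-a/TP component indices) or
    ``"tli_composite"`` (Chl-a-correlation-weighted Chinese TLI, default).
    Missing components are dropped per sample with weight renormalisation.
    """
    data = meta.data
    if method == "carlson":
        comps = {}
        for sample, row in data.iterrows():
            entry = {}
            if "SD" in row and not pd.isna(row.get("SD")):
                entry["TSI_SD"] = 60.0 - 14.41 * _safe_log(row["SD"], sample, "SD")
            if "Chl-a" in row and not pd.isna(row.get("Chl-a")):
                entry["TSI_Chl"] = 9.81 * _safe_log(row["Chl-a"], sample, "Chl-a") + 30.6
            if "TP" in row and not pd.isna(row.get("TP")):
                entry["TSI_TP"] = 14.42 * _safe_log(row["TP"] * 1000.0, sample, "TP") + 4.15
            if not entry:
                raise ValueError(f"no Carlson TSI components available for sample {sample!r}")
            comps[sample] = entry
        frame = pd.DataFrame.from_dict(comps, orient="index")
        composite = frame.mean(axis=1)
    elif method == "tli_composite":
        comps = {}
        for sample, row in data.iterrows():
            entry = {}
            if not pd.isna(row.get("Chl-a", np.nan)):
                entry["TLI_Chl"] = 10.0 * (2.5 + 1.086 * _safe_log(row["Chl-a"], sample, "Chl-a"))
            if not pd.isna(row.get("TP", np.nan)):
                entry["TLI_TP"] = 10.0 * (9.436 + 1.624 * _safe_log(row["TP"], sample, "TP"))
            if not pd.isna(row.get("TN", np.nan)):
                entry["TLI_TN"] = 10.0 * (5.453 + 1.694 * _safe_log(row["TN"], sample, "TN"))
            if not pd.isna(row.get("SD", np.nan)):
                entry["TLI_SD"] = 10.0 * (5.118 - 1.94 * _safe_log(row["SD"], sample, "SD"))
            if not pd.isna(row.get("PI", np.nan)):
                entry["TLI_PI"] = 10.0 * (0.109 + 2.661 * _safe_log(row["PI"], sample, "PI"))
            if not entry:
                raise ValueError(f"no TLI components available for sample {sample!r}")
            comps[sample] = entry
        frame = pd.DataFrame.from_dict(comps, orient="index")
        weight_of = {f"TLI_{k.split('-')[0] if k != 'Chl-a' else 'Chl'}": r**2
                     for k, r in _TLI_R.items()}
        composite = pd.Series(index=frame.index, dtype=float)
        for sample, row in frame.iterrows():
            avail = row.dropna()
            w = np.array([weight_of[c] for c in avail.index])
            composite[sample] = float((avail.to_numpy() * w / w.sum()).sum())
    else:
        raise ValueError(f"unknown TSI method {method!r}")
    composite.name = "TSI"
    return TsiResult(composite=composite.loc[data.index],
                     components=frame.loc[data.index], method=method)


def correlation_screen(
    features: pd.DataFrame,
    variables: pd.DataFrame,
    min_n: int = 5,
) -> pd.DataFrame:
    """Spearman rho/p/star for every (feature row, variable column) pair.

    ``features`` is feature x sample; ``variables`` is sample x variable.
    Pairs with fewer than ``min_n`` complete observations, or with a
    constant vector, are marked not-computed (NaN rho/p, empty star).
    Output is long-format with columns feature, variable, rho, p, star,
    direction, n.
    """
    shared = [s for s in features.columns if s in variables.index]
    rows = []
    for feat in features.index:
        x_full = features.loc[feat, shared].to_numpy(dtype=float)
        for var in variables.columns:
            y_full = variables.loc[shared, var].to_numpy(dtype=float)
            ok = ~(np.isnan(x_full) | np.isnan(y_full))
            n = int(ok.sum())
            if n < max(min_n, 4):
                rho, p = float("nan"), float("nan")
            else:
                rho, p = spearman_rho_p(x_full[ok], y_full[ok])
            star = stars(p)
            direction = ""
            if not np.isnan(rho) and rho != 0:
                direction = "positive" if rho > 0 else "negative"
            rows.append({
                "feature": feat, "variable": var, "rho": rho, "p": p,
                "star": star, "direction": direction, "n": n,
            })
    return pd.DataFrame(rows, columns=["feature", "variable", "rho", "p", "star",
                                       "direction", "n"])


def _variables_with_tsi(meta: SampleMetadata, tsi: TsiResult | None) -> pd.DataFrame:
    variables = meta.data.copy()
    if tsi is not None:
        variables["TSI"] = tsi.composite.reindex(variables.index)
    return variables


def diversity_env_screen(
    alpha: pd.DataFrame, meta: SampleMetadata, tsi: TsiResult | None = None
) -> pd.DataFrame:
    """Correlate alpha-diversity indices (rows: samples) with environment."""
    indices = alpha[[c for c in alpha.columns if c not in ("F1", "F2", "N")]]
    return correlation_screen(indices.T, _variables_with_tsi(meta, tsi))


def taxa_env_screen(
    rank_table: pd.DataFrame, meta: SampleMetadata, tsi: TsiResult | None = None
) -> pd.DataFrame:
    """Correlate rank-aggregated taxon proportions with environment + TSI."""
    return correlation_screen(rank_table, _variables_with_tsi(meta, tsi))


def keystone_env_screen(
    keystone_props: pd.DataFrame, meta: SampleMetadata, tsi: TsiResult | None = None
) -> pd.DataFrame:
    """Correlate keystone ASV proportions with environment + TSI."""
    return correlation_screen(keystone_props, _variables_with_tsi(meta, tsi))


def indicator_call(screen: pd.DataFrame, target: str = "TSI") -> list[tuple[str, str]]:
    """Taxa with a starred correlation against ``target``, with direction.

    Returns (feature, direction) pairs ordered by feature label; invariant
    to the row order of the screen.
    """
    if target not in set(screen["variable"]):
        raise ValueError(f"screen has no column for target {target!r}")
    hits = screen[(screen["variable"] == target) & (screen["star"] != "")]
    return sorted((str(r.feature), str(r.direction)) for r in hits.itertuples())
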