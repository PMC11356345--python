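"""Six-way abundance classification of ASVs and contribution accounting.

Each ASV is classified from its per-sample relative abundances using two
thresholds — rare below 0.01% (1e-4) and abundant at or above 1% (1e-2) —
into one of six categories:

* AAT  — always abundant: >= 1% in every sample
* ART  — always rare: < 0.01% in every sample
* CRAT — conditionally rare and abundant: spans < 0.01% up to >= 1%
* CAT  — conditionally abundant: reaches >= 1% without ever dropping below 0.01%
* CRT  — conditionally rare: drops below 0.01% somewhere, never reaches 1%
* MT   — moderate: always between 0.01% and 1%

The coarse grouping treats AAT/CAT/CRAT as the abundant sub-community,
ART/CRT as the rare sub-community (the "rare biosphere"), and MT as
moderate. Boundary conventions: >= 1% is inclusive, < 0.01% exclusive; an
ASV at exactly 0.01% in every sample is MT; a zero count is below the rare
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "GROUPS",
    "GROUP_OF_CATEGORY",
    "CategoryAssignment",
    "classify_asvs",
    "summarize_partition",
    "category_of_keystones",
]

CATEGORIES = ("AAT", "CAT", "CRAT", "ART", "CRT", "MT")
GROUPS = ("abundant", "rare", "moderate")
GROUP_OF_CATEGORY = {
    "AAT": "abundant",
    "CAT": "abundant",
    "CRAT": "abundant",
    "ART": "rare",
    "CRT": "rare",
    "MT": "moderate",
}


@dataclass
class CategoryAssignment:
    """Per-ASV category and coarse group, with the thresholds used."""

    category: pd.Series  # asv_id -> category code
    rare_cut: float = 1e-4
    abund_cut: float = 1e-2
    group: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        bad = set(self.category.unique()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown categories: {sorted(bad)}")
        self.group = self.category.map(GROUP_OF_CATEGORY)


def classify_asvs(
    props: pd.DataFrame,
    rare_cut: float = 1e-4,
    abund_cut: float = 1e-2,
) -> CategoryAssignment:
    """Classify every ASV from its per-sample proportions.

    ``props`` is ASV x sample with each column summing to 1. The decision
    uses only each ASV's minimum ``m`` and maximum ``M`` proportion across
    samples:

    ``m >= abund_cut`` -> AAT; else ``M < rare_cut`` -> ART; else
    ``M >= abund_cut and m < rare_cut`` -> CRAT; else ``M >= abund_cut`` ->
    CAT; else ``m < rare_cut`` -> CRT; else MT. The six branches partition
    all cases.
    """
    colsums = props.sum(axis=0).to_numpy()
    if not np.allclose(colsums, 1.0, atol=1e-8):
        raise ValueError("proportion columns must each sum to 1")
    x = props.to_numpy(dtype=float)
    m = x.min(axis=1)
    big = x.max(axis=1)

    cat = np.full(len(props), "MT", dtype=object)
    remaining = np.ones(len(props), dtype=bool)

    rule_aat = remaining & (m >= abund_cut)
    cat[rule_aat] = "AAT"
    remaining &= ~rule_aat
    rule_art = remaining & (big < rare_cut)
    cat[rule_art] = "ART"
    remaining &= ~rule_art
    rule_crat = remaining & (big >= abund_cut) & (m < rare_cut)
    cat[rule_crat] = "CRAT"
    remaining &= ~rule_crat
    rule_cat = remaining & (big >= abund_cut)
    cat[rule_cat] = "CAT"
    remaining &= ~rule_cat
    rule_crt = remaining & (m < rare_cut)
    cat[rule_crt] = "CRT"

    series = pd.Series(cat, index=props.index, name="category")
    return CategoryAssignment(series, rare_cut=rare_cut, abund_cut=abund_cut)


def summarize_partition(assignment: CategoryAssignment, props: pd.DataFrame) -> pd.DataFrame:
    """Contribution table: ASV count and average relative abundance (%) per
    category and per coarse group.

    The average relative abundance of a category is the mean over samples of
    the summed proportions of its member ASVs, expressed as a percentage;
    group rows aggregate their categories, so abundant + rare + moderate
    sums to 100%.
    """
    missing = props.index.difference(assignment.category.index)
    if len(missing):
        raise ValueError(f"ASVs missing from assignment: {list(missing[:5])}")
    cat = assignment.category.loc[props.index]
    rows = []
    for code in CATEGORIES:
        members = cat.index[cat == code]
        contrib = props.loc[members].sum(axis=0).mean() * 100.0 if len(members) else 0.0
        rows.append(
            {"label": code, "level": "category", "group": GROUP_OF_CATEGORY[code],
             "n_asvs": int(len(members)), "avg_relative_abundance_pct": float(contrib)}
        )
    frame = pd.DataFrame(rows)
    for grp in GROUPS:
        sub = frame[(frame["level"] == "category") & (frame["group"] == grp)]
        frame = pd.concat(
            [frame, pd.DataFrame([{
                "label": grp, "level": "group", "group": grp,
                "n_asvs": int(sub["n_asvs"].sum()),
                "avg_relative_abundance_pct": float(sub["avg_relative_abundance_pct"].sum()),
            }])],
            ignore_index=True,
        )
    return frame


def category_of_keystones(assignment: CategoryAssignment, keystones) -> dict[str, int]:
    """Count keystone ASVs per coarse group (abundant / rare / moderate)."""
    keystones = list(keystones)
    missing = [k for k in keystones if k not in assignment.group.index]
    if missing:
        raise ValueError(f"keystones not in assignment: {missing[:5]}")
    counts = {g: 0 for g in GROUPS}
    for k in keystones:
        counts[assignment.group[k]] += 1
    return counts
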