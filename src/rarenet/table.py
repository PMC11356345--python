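"""ASV count-table data model and core table operations.

The central container is :class:`AsvTable`, a validated integer count matrix
(ASVs x samples) backed by a pandas DataFrame. Operations cover the standard
amplicon preprocessing chain: organelle/unknown lineage exclusion,
without-replacement rarefaction to a common depth, relative-abundance
normalisation, taxonomic rank aggregation, and splitting the table into
abundant / rare / moderate sub-community tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "AsvTable",
    "TaxonomyMap",
    "SampleMetadata",
    "exclude_lineages",
    "rarefy",
    "relative_abundance",
    "aggregate_rank",
    "split_subcommunities",
]

#: The seven ranks of a QIIME-style lineage, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

# metadata variables that are physically non-negative (concentrations,
# densities, depths); pH and WT are validated only for finiteness
CONCENTRATION_VARS = frozenset(
    {"DO", "SD", "COD", "PI", "Chl-a", "TN", "TP", "TDN", "NH4-N", "PO4-P",
     "N/P", "phyto_density", "water_depth"}
)


@dataclass
class AsvTable:
    """Integer count matrix with unique ASV row ids and sample column ids."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV ids: {dups}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.isnan(values.astype(float)).any():
                raise ValueError("counts contain missing values")
            if (values < 0).any():
                i, j = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative count at ASV {self.counts.index[i]!r}, "
                    f"sample {self.counts.columns[j]!r}"
                )
            if not np.allclose(values, np.round(values)):
                i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
                raise ValueError(
                    f"non-integer count at ASV {self.counts.index[i]!r}, "
                    f"sample {self.counts.columns[j]!r}"
                )
        self.counts = self.counts.astype(np.int64)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def select(self, asv_ids) -> "AsvTable":
        """Row-subset preserving order of ``asv_ids``."""
        return AsvTable(self.counts.loc[list(asv_ids)].copy())

    def __eq__(self, other) -> bool:  # value equality, used by round-trip tests
        if not isinstance(other, AsvTable):
            return NotImplemented
        return self.counts.equals(other.counts)


class TaxonomyMap:
    """ASV id -> ordered lineage of up to 7 ranks; unassigned ranks are NaN."""

    def __init__(self, frame: pd.DataFrame):
        missing = [r for r in RANKS if r not in frame.columns]
        if missing:
            raise ValueError(f"taxonomy frame missing rank columns: {missing}")
        if frame.index.has_duplicates:
            raise ValueError("duplicate ASV ids in taxonomy")
        self.frame = frame.loc[:, list(RANKS)].copy()

    _PREFIXES = ("d__", "k__", "p__", "c__", "o__", "f__", "g__", "s__")
    _UNASSIGNED = {"", "unassigned", "unclassified", "unknown", "na", "n/a"}

    @classmethod
    def from_lineage_strings(cls, lineages: dict[str, str] | pd.Series) -> "TaxonomyMap":
        """Parse semicolon-delimited lineage strings (QIIME convention).

        Rank prefixes like ``p__`` are stripped; empty or
        unassigned/unclassified labels become NaN.
        """
        rows = {}
        for asv, lineage in dict(lineages).items():
            labels: list[object] = [np.nan] * len(RANKS)
            if isinstance(lineage, str):
                parts = [p.strip() for p in lineage.split(";")]
                for i, part in enumerate(parts[: len(RANKS)]):
                    for pref in cls._PREFIXES:
                        if part.startswith(pref):
                            part = part[len(pref):]
                            break
                    if part.lower() in cls._UNASSIGNED:
                        continue
                    labels[i] = part
            rows[asv] = labels
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
        return cls(frame)

    def lineage_string(self, asv_id: str) -> str:
        row = self.frame.loc[asv_id]
        return ";".join("" if pd.isna(v) else str(v) for v in row)

    def label(self, asv_id: str, rank: str):
        """Rank label for one ASV, or NaN if unassigned or unmapped."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        if asv_id not in self.frame.index:
            return np.nan
        return self.frame.at[asv_id, rank]

    def __contains__(self, asv_id: str) -> bool:
        return asv_id in self.frame.index

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class SampleMetadata:
    """Per-sample environmental measurements; missing values are NaN."""

    data: pd.DataFrame  # samples x variables
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        for var in self.data.columns:
            if var in CONCENTRATION_VARS:
                col = self.data[var]
                bad = col[col.notna() & (col < 0)]
                if len(bad):
                    raise ValueError(
                        f"negative {var!r} for sample {bad.index[0]!r}: {bad.iloc[0]}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def validate_against(self, table: AsvTable) -> None:
        """Check table samples are covered by the metadata (subset relation)."""
        missing = set(table.sample_ids) - set(self.data.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)}")


def exclude_lineages(
    table: AsvTable,
    tax: TaxonomyMap,
    terms: set[str] | None = None,
) -> AsvTable:
    """Drop ASVs whose lineage matches any exclusion term.

    Default terms remove chloroplast and mitochondrial reads and ASVs with no
    domain-level assignment (the sentinel term ``"unknown"``). Matching is a
    case-insensitive substring test against every assigned rank label; ASVs
    absent from the taxonomy are treated as unassigned. Row order of the
    survivors is preserved and the operation is idempotent.
    """
    if terms is None:
        terms = {"chloroplast", "mitochondria", "unknown"}
    if not terms:
        raise ValueError("terms must be non-empty")
    terms_lower = {t.lower() for t in terms}
    drop_unknown = "unknown" in terms_lower
    substr_terms = terms_lower - {"unknown"}

    keep = []
    for asv in table.asv_ids:
        if asv not in tax:
            if drop_unknown:
                continue
            keep.append(asv)
            continue
        row = tax.frame.loc[asv]
        if drop_unknown and pd.isna(row["domain"]):
            continue
        labels = " ".join(str(v).lower() for v in row if not pd.isna(v))
        if any(t in labels for t in substr_terms):
            continue
        keep.append(asv)
    return table.select(keep)


def rarefy(table: AsvTable, depth: int, seed: int) -> AsvTable:
    """Rarefy every sample to ``depth`` reads without replacement.

    Each sample is an independent multivariate hypergeometric draw: ``depth``
    reads are sampled without replacement from the sample's observed reads,
    so each rarefied count is bounded by the original and every column sums
    exactly to ``depth``. Deterministic for a given seed.
    """
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    sums = table.sample_sums()
    shallow = sums[sums < depth]
    if len(shallow):
        raise ValueError(
            f"sample {shallow.index[0]!r} has only {int(shallow.iloc[0])} reads, "
            f"fewer than rarefaction depth {depth}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts.to_numpy())
    for j, sample in enumerate(table.sample_ids):
        col = table.counts[sample].to_numpy()
        out[:, j] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    return AsvTable(pd.DataFrame(out, index=table.counts.index, columns=table.counts.columns))


def relative_abundance(table: AsvTable) -> pd.DataFrame:
    """Column-normalised proportions; every column sums to 1."""
    sums = table.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has zero total count")
    return table.counts.astype(float) / sums


def aggregate_rank(table: AsvTable, tax: TaxonomyMap, rank: str) -> pd.DataFrame:
    """Sum relative abundances of ASVs sharing a rank label.

    ASVs unassigned at ``rank`` (or absent from the taxonomy) pool into an
    ``"unassigned"`` row. Column sums stay at 1; rows are ordered by
    descending mean abundance with ``"unassigned"`` last.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    props = relative_abundance(table)
    labels = pd.Series(
        [tax.label(asv, rank) for asv in table.asv_ids], index=props.index, dtype=object
    )
    labels = labels.where(labels.notna(), "unassigned").astype(str)
    agg = props.groupby(labels, sort=False).sum()
    named = agg.drop(index="unassigned", errors="ignore")
    named = named.loc[named.mean(axis=1).sort_values(ascending=False, kind="stable").index]
    if "unassigned" in agg.index:
        named = pd.concat([named, agg.loc[["unassigned"]]])
    return named


def split_subcommunities(table: AsvTable, assignment) -> dict[str, AsvTable]:
    """Partition the table into abundant / rare / moderate count sub-tables.

    ``assignment`` is a :class:`~rarenet.partition.CategoryAssignment` (or any
    object with a ``group`` Series mapping ASV id to coarse group). Counts are
    unchanged; the three outputs partition the ASV set.
    """
    group = assignment.group
    missing = [a for a in table.asv_ids if a not in group.index]
    if missing:
        raise ValueError(f"ASVs missing from assignment: {missing[:5]}")
    out = {}
    for name in ("abundant", "rare", "moderate"):
        members = [a for a in table.asv_ids if group[a] == name]
        out[name] = table.select(members)
    return out
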