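"""Readers and writers for count tables, taxonomy and sample metadata.

Count tables round-trip through two dialects: a QIIME-style TSV (ASVs as
rows, first header ``#ASV_ID``) and BIOM v1.0 JSON (dense or sparse).
Taxonomy is a two-column TSV with semicolon-delimited lineages; metadata is a
TSV whose second line (prefixed ``#units``) carries the measurement units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .table import RANKS, AsvTable, SampleMetadata, TaxonomyMap

__all__ = [
    "read_asv_table",
    "write_asv_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
]

_TSV_HEADER = "#ASV_ID"
_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"


class ParseError(ValueError):
    """Raised when an input file does not conform to its dialect."""


def read_asv_table(path, dialect: str = "tsv") -> AsvTable:
    """Read a count table in the ``tsv`` or ``biom-json`` dialect."""
    path = Path(path)
    if dialect == "tsv":
        return _read_tsv(path)
    if dialect == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'biom-json'")


def write_asv_table(table: AsvTable, path, dialect: str = "tsv") -> None:
    path = Path(path)
    if dialect == "tsv":
        frame = table.counts.copy()
        frame.index.name = _TSV_HEADER
        frame.to_csv(path, sep="\t")
    elif dialect == "biom-json":
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'biom-json'")


def _read_tsv(path: Path) -> AsvTable:
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty count table")
    lines = text.splitlines()
    header = lines[0].split("\t")
    if header[0] != _TSV_HEADER:
        raise ParseError(
            f"{path}: malformed header; first column must be {_TSV_HEADER!r}, "
            f"got {header[0]!r}"
        )
    samples = header[1:]
    if len(set(samples)) != len(samples):
        raise ParseError(f"{path}: duplicate sample ids in header")
    asv_ids: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != len(samples) + 1:
            raise ParseError(
                f"{path}:{lineno}: expected {len(samples) + 1} fields, got {len(fields)}"
            )
        asv = fields[0]
        row = []
        for sample, cell in zip(samples, fields[1:]):
            try:
                value = float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric count {cell!r} "
                    f"(ASV {asv!r}, sample {sample!r})"
                ) from None
            if value < 0:
                raise ParseError(
                    f"{path}:{lineno}: negative count {cell!r} "
                    f"(ASV {asv!r}, sample {sample!r})"
                )
            if value != int(value):
                raise ParseError(
                    f"{path}:{lineno}: non-integer count {cell!r} "
                    f"(ASV {asv!r}, sample {sample!r})"
                )
            row.append(int(value))
        asv_ids.append(asv)
        rows.append(row)
    if len(set(asv_ids)) != len(asv_ids):
        dups = sorted({a for a in asv_ids if asv_ids.count(a) > 1})
        raise ParseError(f"{path}: duplicate ASV ids {dups}")
    counts = pd.DataFrame(
        np.asarray(rows, dtype=np.int64).reshape(len(asv_ids), len(samples)),
        index=pd.Index(asv_ids), columns=samples,
    )
    return AsvTable(counts)


def _read_biom_json(path: Path) -> AsvTable:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON: {exc}") from None
    for key in ("rows", "columns", "shape", "data", "matrix_type"):
        if key not in doc:
            raise ParseError(f"{path}: BIOM document missing {key!r}")
    n_rows, n_cols = doc["shape"]
    asv_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    if len(asv_ids) != n_rows or len(sample_ids) != n_cols:
        raise ParseError(f"{path}: shape does not match row/column lists")
    dense = np.zeros((n_rows, n_cols))
    if doc["matrix_type"] == "dense":
        for i, row in enumerate(doc["data"]):
            dense[i, :] = row
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            dense[int(i), int(j)] = v
    else:
        raise ParseError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    if (dense < 0).any() or not np.allclose(dense, np.round(dense)):
        i, j = np.argwhere((dense < 0) | ~np.isclose(dense, np.round(dense)))[0]
        raise ParseError(
            f"{path}: invalid count at ASV {asv_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    counts = pd.DataFrame(dense.astype(np.int64), index=asv_ids, columns=sample_ids)
    return AsvTable(counts)


def _write_biom_json(table: AsvTable, path: Path) -> None:
    values = table.counts.to_numpy()
    nz = np.argwhere(values != 0)
    doc = {
        "id": None,
        "format": _BIOM_FORMAT,
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "rarenet",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_asvs, table.n_samples],
        "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": [[int(i), int(j), int(values[i, j])] for i, j in nz],
    }
    path.write_text(json.dumps(doc, sort_keys=True))


def read_taxonomy(path) -> TaxonomyMap:
    """Two-column TSV: ASV id, semicolon-delimited lineage."""
    path = Path(path)
    lineages: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        asv, lineage = fields[0], fields[1]
        if asv in lineages:
            raise ParseError(f"{path}:{lineno}: duplicate ASV id {asv!r}")
        lineages[asv] = lineage
    return TaxonomyMap.from_lineage_strings(lineages)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    path = Path(path)
    lines = ["#ASV_ID\ttaxonomy"]
    for asv in tax.frame.index:
        lines.append(f"{asv}\t{tax.lineage_string(asv)}")
    path.write_text("\n".join(lines) + "\n")


def read_metadata(path) -> SampleMetadata:
    """Metadata TSV: header, optional ``#units`` line, then one row per sample."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: empty metadata file")
    header = lines[0].split("\t")
    variables = header[1:]
    units: dict[str, str] = {}
    body = lines[1:]
    if body and body[0].startswith("#units"):
        unit_fields = body[0].split("\t")[1:]
        units = dict(zip(variables, unit_fields))
        body = body[1:]
    records = {}
    for lineno, line in enumerate(body, start=1):
        fields = line.split("\t")
        sample = fields[0]
        values = []
        for cell in fields[1:]:
            cell = cell.strip()
            values.append(np.nan if cell in ("", "NA", "nan") else float(cell))
        records[sample] = values
    data = pd.DataFrame.from_dict(records, orient="index", columns=variables)
    return SampleMetadata(data, units)


def write_metadata(meta: SampleMetadata, path) -> None:
    path = Path(path)
    variables = list(meta.data.columns)
    lines = ["sample_id\t" + "\t".join(variables)]
    lines.append("#units\t" + "\t".join(meta.units.get(v, "") for v in variables))
    for sample, row in meta.data.iterrows():
        cells = ["" if pd.isna(v) else repr(float(v)) for v in row]
        lines.append(str(sample) + "\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def write_rank_table(frame: pd.DataFrame, path) -> None:
    """Write a taxon x sample proportion table as TSV."""
    frame = frame.copy()
    frame.index.name = "taxon"
    frame.to_csv(path, sep="\t")
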