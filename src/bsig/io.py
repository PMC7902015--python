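"""Readers and writers for the package's plain-text interchange formats.

One tabular dialect everywhere: tab-separated, UTF-8, '.' decimal, no
quoting. Expression matrices round-trip at full float precision; derived
result tables at 9 significant digits. Gene sets use standard GMT.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .datamodel import ExpressionMatrix, FlowEventTable, GeneSet, SampleSheet
from .errors import FormatError, ParseError


def _parse_float_block(df: pd.DataFrame, row_names, what: str) -> pd.DataFrame:
    """Convert a string-typed block to float, naming the offending cell on failure."""
    try:
        return df.astype(float)
    except ValueError:
        for col in df.columns:
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except ValueError:
                    raise ParseError(
                        f"non-numeric value {v!r} in {what} at row "
                        f"{row_names[i]!r}, column {col!r}"
                    ) from None
        raise  # pragma: no cover - astype failed but no cell did


def read_expression(path, metadata_path) -> tuple[ExpressionMatrix, SampleSheet]:
    """Read an expression matrix TSV plus its sample-metadata TSV.

    The matrix file has a 'gene_id' first column and one column per
    sample; the metadata file has columns sample_id, donor_id, group,
    subset. The returned sheet is aligned to matrix column order; metadata
    missing any matrix sample raises ConsistencyError naming it.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene_id column plus sample columns")
    if raw.columns[0] != "gene_id":
        raise FormatError(f"{path}: first column must be 'gene_id', got {raw.columns[0]!r}")
    gene_ids = raw.iloc[:, 0].tolist()
    block = _parse_float_block(raw.iloc[:, 1:], gene_ids, "expression matrix")
    block.index = pd.Index(gene_ids, name="gene_id")
    matrix = ExpressionMatrix(block)
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    sheet = SampleSheet(meta).aligned_to(matrix)
    return matrix, sheet


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def write_metadata(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, members...).

    Duplicate members within a line are collapsed with a warning; a line
    with fewer than three fields is a format error. Empty lines are
    ignored; an empty file yields an empty list.
    """
    sets: list[GeneSet] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
        name, description = fields[0], fields[1]
        members = [m for m in fields[2:] if m]
        deduped = list(dict.fromkeys(members))
        if len(deduped) != len(members):
            warnings.warn(
                f"{path}:{lineno}: gene set {name!r} has duplicate members; collapsed",
                stacklevel=2,
            )
        sets.append(GeneSet(name=name, description=description, members=tuple(deduped)))
    return sets


def write_gmt(sets, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *gs.members]) + "\n")


def write_table(records: pd.DataFrame, path) -> None:
    """Write a result table as unquoted TSV with >= 6 significant digits.

    String values containing a tab or newline are rejected rather than
    quoted, so files stay diff-able and round-trip bit-exactly.
    """
    for col in records.columns:
        if records[col].dtype == object:
            vals = records[col].astype(str)
            bad = vals.str.contains("\t") | vals.str.contains("\n")
            if bad.any():
                raise FormatError(
                    f"column {col!r} contains a tab or newline; no quoting is performed"
                )
    records.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_flow_events(path) -> FlowEventTable:
    """Read a per-cell flow event CSV (cell_id, dye_intensity, annexin,
    viability[, true_generation])."""
    return FlowEventTable(pd.read_csv(path))


def write_flow_events(events: FlowEventTable, path) -> None:
    events.table.to_csv(path, index=False, float_format="%.9g")
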