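"""Readers/writers for the tab-delimited matrix dialect and GEO-style series matrices.

The on-disk dialect is plain TSV: a header row of array (or sample) ids,
probe ids in the first column, one probe per row.  Sample annotations are a
separate TSV (``array_id``, ``group``, ``timepoint``, ``replicate``); atlas
annotations use (``sample_id``, ``cell_type``).  ``read_series_matrix``
additionally accepts the GEO series-matrix dialect, where ``!``-prefixed
key/value lines precede a table delimited by
``!series_matrix_table_begin``/``!series_matrix_table_end``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .matrix import CellTypeAtlas, ExpressionMatrix


class ParseError(ValueError):
    """Malformed input file; message carries the offending line number."""


def write_matrix(values: pd.DataFrame, path: str | Path, index_label: str = "probe_id") -> None:
    values.to_csv(path, sep="\t", index_label=index_label)


def write_annotations(annotations: pd.DataFrame, path: str | Path,
                      index_label: str = "array_id") -> None:
    annotations.to_csv(path, sep="\t", index_label=index_label)


def read_annotations(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    return ann.set_index(ann.columns[0])


def _parse_table(lines: list[tuple[int, str]]) -> pd.DataFrame:
    """Parse (lineno, text) rows into a DataFrame, checking shape and ids."""
    if not lines:
        raise ParseError("empty table")
    header_no, header = lines[0]
    cols = header.rstrip("\n").split("\t")
    width = len(cols)
    index = []
    rows = []
    for lineno, line in lines[1:]:
        fields = line.rstrip("\n").split("\t")
        if len(fields) != width:
            raise ParseError(
                f"line {lineno}: expected {width} fields, found {len(fields)} (ragged row)")
        index.append(fields[0].strip('"'))
        rows.append(fields[1:])
    seen: set[str] = set()
    for lineno, rid in zip((ln for ln, _ in lines[1:]), index):
        if rid in seen:
            raise ParseError(f"line {lineno}: duplicate row id {rid!r}")
        seen.add(rid)
    df = pd.DataFrame(rows, index=pd.Index(index, name=cols[0]),
                      columns=[c.strip('"') for c in cols[1:]])
    return df.astype(float)


def read_series_matrix(path: str | Path) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Read a GEO-style series matrix or a plain TSV matrix.

    Returns the numeric table (rows x samples) and a metadata dict built
    from any ``!``-prefixed key/value lines (empty for plain TSV input).
    """
    meta: dict[str, list[str]] = {}
    table_lines: list[tuple[int, str]] = []
    in_table = False
    saw_markers = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if line.startswith("!"):
                key, _, rest = line.rstrip("\n").partition("\t")
                key = key[1:]
                if key == "series_matrix_table_begin":
                    in_table, saw_markers = True, True
                elif key == "series_matrix_table_end":
                    in_table = False
                else:
                    meta.setdefault(key, []).extend(
                        f.strip('"') for f in rest.split("\t") if f != "")
                continue
            if in_table or not saw_markers:
                table_lines.append((lineno, line))
    return _parse_table(table_lines), meta


def read_matrix(path: str | Path, annotations_path: str | Path | None = None,
                scale: str = "raw") -> ExpressionMatrix | pd.DataFrame:
    """Read a matrix TSV; with an annotation path, build an ExpressionMatrix."""
    values, _ = read_series_matrix(path)
    if annotations_path is None:
        return values
    ann = read_annotations(annotations_path)
    return ExpressionMatrix(values, ann, scale)


def write_expression(m: ExpressionMatrix, matrix_path: str | Path,
                     annotations_path: str | Path) -> None:
    write_matrix(m.values, matrix_path)
    write_annotations(m.annotations, annotations_path)


def write_atlas(atlas: CellTypeAtlas, matrix_path: str | Path,
                annotations_path: str | Path) -> None:
    write_matrix(atlas.values, matrix_path, index_label="gene_id")
    ann = atlas.cell_type_of.to_frame("cell_type")
    write_annotations(ann, annotations_path, index_label="sample_id")


def read_atlas(matrix_path: str | Path, annotations_path: str | Path) -> CellTypeAtlas:
    values, _ = read_series_matrix(matrix_path)
    ann = read_annotations(annotations_path)
    return CellTypeAtlas(values, ann["cell_type"])


def read_probe_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip()]


def write_probe_list(probes: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(p + "\n" for p in probes))


def write_panels(panels, path: str | Path) -> None:
    """Two-column (cell_type, gene_id) serialization of a panel set."""
    with open(path, "w") as fh:
        fh.write("cell_type\tgene_id\n")
        for p in panels:
            for g in p.gene_ids:
                fh.write(f"{p.cell_type}\t{g}\n")


def read_panels(path: str | Path):
    from .matrix import MarkerPanel
    df = pd.read_csv(path, sep="\t", dtype=str)
    panels = []
    for ct, sub in df.groupby("cell_type", sort=False):
        panels.append(MarkerPanel(ct, list(sub["gene_id"])))
    return panels


def read_platform_map(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return list(df.itertuples(index=False, name=None))
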