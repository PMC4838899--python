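"""Readers and writers for the pipeline's tab-separated formats.

All matrices are TSV with a header row of sample ids and feature ids in the
first column (features in rows — transposed input is never guessed). The NA
token set on read is {"NA", ""}; NA is always written back as "NA".
Copy-number data is either SEG-like (sample, chrom, start, end, gnl; 1-based
inclusive coordinates) or a gene × sample integer table.
"""

from __future__ import annotations

import csv

import numpy as np
import pandas as pd

from .types import FormatError, GeneSet, GNLTable, OmicsMatrix, validate_sample_annot

NA_TOKENS = ["NA", ""]

_SEG_COLUMNS = ["sample", "chrom", "start", "end", "gnl"]


def _read_tsv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=NA_TOKENS, keep_default_na=False,
            dtype_backend="numpy_nullable",
        )
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    return df


def read_matrix(path, omic_kind: str, annot_path=None) -> OmicsMatrix:
    """Read a features × samples TSV (optionally with a sidecar annotation TSV).

    Raises :class:`FormatError` on duplicate ids or unparsable cells and
    :class:`ValidationError` if a methylation value falls outside [0, 1].
    """
    df = _read_tsv(path)
    if df.index.has_duplicates:
        raise FormatError(f"duplicate feature ids in {path}")
    if df.columns.has_duplicates:
        raise FormatError(f"duplicate sample ids in {path}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    values = pd.DataFrame(
        np.asarray(values, dtype=float), index=df.index.astype(str),
        columns=df.columns.astype(str),
    )
    annot = None
    if annot_path is not None:
        annot = pd.read_csv(
            annot_path, sep="\t", index_col=0, na_values=NA_TOKENS,
            keep_default_na=False, dtype={"chrom": str},
        )
        annot.index = annot.index.astype(str)
    return OmicsMatrix(values, omic_kind, annot)


def write_matrix(matrix: OmicsMatrix, path, float_format: str = "%.10g") -> None:
    matrix.values.to_csv(path, sep="\t", na_rep="NA", float_format=float_format)


def read_gnl(path) -> GNLTable:
    """Read copy-number calls: SEG-like segments or a gene × sample table.

    The mode is detected from the header: a header starting with the five
    SEG columns (sample, chrom, start, end, gnl) selects segment mode,
    anything else is parsed as a gene-level matrix.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if [h.lower() for h in header[:5]] == _SEG_COLUMNS:
        seg = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
        seg.columns = [c.lower() for c in seg.columns]
        return GNLTable("segment", segments=seg[_SEG_COLUMNS])
    df = _read_tsv(path)
    if df.index.has_duplicates:
        raise FormatError(f"duplicate gene ids in {path}")
    genes = df.astype("Int64").astype(object).where(lambda d: d.notna(), np.nan)
    genes = pd.DataFrame(
        genes.to_numpy(dtype=float), index=df.index.astype(str),
        columns=df.columns.astype(str),
    )
    return GNLTable("gene", genes=genes)


def write_gnl(gnl: GNLTable, path) -> None:
    if gnl.mode == "segment":
        gnl.segments.to_csv(path, sep="\t", index=False, na_rep="NA")
    else:
        gnl.genes.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_sample_annot(path) -> pd.DataFrame:
    annot = pd.read_csv(
        path, sep="\t", index_col=0, na_values=NA_TOKENS, keep_default_na=False
    )
    annot.index = annot.index.astype(str)
    for col in ("initial_radiotherapy", "is_normal_control"):
        if col in annot:
            annot[col] = annot[col].map(
                {"True": True, "False": False, True: True, False: False, 1: True, 0: False}
            )
    return validate_sample_annot(annot)


def write_sample_annot(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", na_rep="NA")


def read_partition(path) -> pd.Series:
    """Read a two-column TSV (sample, label) into a partition Series."""
    df = pd.read_csv(
        path, sep="\t", index_col=0, na_values=NA_TOKENS, keep_default_na=False
    )
    if df.shape[1] != 1:
        raise FormatError(f"partition file {path} must have exactly 2 columns")
    s = df.iloc[:, 0]
    s.index = s.index.astype(str)
    if s.index.has_duplicates:
        raise FormatError(f"duplicate sample ids in {path}")
    return s


def write_partition(labels: pd.Series, path, name: str = "label") -> None:
    labels.rename(name).to_frame().to_csv(path, sep="\t", na_rep="NA")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT (name <tab> source <tab> gene1 <tab> ...)."""
    sets = []
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or not row[0]:
                continue
            if len(row) < 3:
                raise FormatError(f"GMT line for {row[0]!r} has no genes")
            sets.append(GeneSet(row[0], tuple(g for g in row[2:] if g), source=row[1]))
    return sets


def write_gmt(sets: list[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.source, *gs.genes]) + "\n")
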