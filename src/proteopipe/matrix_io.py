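"""Read, write and validate the tabular formats shared by all stages.

An abundance matrix is a TSV whose first column holds unique protein
identifiers and whose header row names the samples; empty cells or
``NA`` denote missing values. A sample annotation is a TSV with columns
``sample_id``, ``genotype``, ``treatment`` and ``sex``. Writers emit a
sidecar JSON provenance record next to each file.
"""

from __future__ import annotations

import csv
import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import GENOTYPES, TREATMENTS

_NA_TOKENS = {"", "NA"}
ANNOTATION_COLUMNS = ("sample_id", "genotype", "treatment", "sex")


class MatrixFormatError(ValueError):
    """A matrix or annotation file violates the expected dialect."""


def validate_matrix(matrix: pd.DataFrame) -> None:
    """Check the in-memory invariants of an abundance matrix.

    Raises :class:`MatrixFormatError` on duplicate protein or sample
    ids, fewer than two samples, or negative values.
    """
    if matrix.index.duplicated().any():
        dupes = matrix.index[matrix.index.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate protein ids: {dupes}")
    if matrix.columns.duplicated().any():
        dupes = matrix.columns[matrix.columns.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate sample ids: {dupes}")
    if matrix.shape[1] < 2:
        raise MatrixFormatError("a matrix needs at least 2 samples")
    vals = matrix.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) < 0:
        rows, cols = np.where(vals < 0)
        pid, sid = matrix.index[rows[0]], matrix.columns[cols[0]]
        raise MatrixFormatError(f"negative abundance at ({pid}, {sid})")


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a wide proteins x samples abundance TSV.

    Missing cells may be empty or ``NA``. Errors (ragged rows,
    non-numeric cells, duplicate ids, negative values) are reported
    with one-based line numbers where applicable.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise MatrixFormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 3:
        raise MatrixFormatError(f"{path}: need a protein-id column and >=2 samples")
    width = len(header)
    sample_ids = header[1:]
    protein_ids: list[str] = []
    data = np.empty((len(rows) - 1, width - 1), dtype=float)
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise MatrixFormatError(
                f"{path}: line {lineno}: expected {width} fields, got {len(row)}"
            )
        protein_ids.append(row[0])
        for j, token in enumerate(row[1:]):
            if token in _NA_TOKENS:
                data[lineno - 2, j] = np.nan
            else:
                try:
                    data[lineno - 2, j] = float(token)
                except ValueError:
                    raise MatrixFormatError(
                        f"{path}: line {lineno}: non-numeric cell {token!r}"
                    ) from None
    matrix = pd.DataFrame(data, index=pd.Index(protein_ids, name="protein_id"),
                          columns=sample_ids)
    validate_matrix(matrix)
    return matrix


def write_matrix(matrix: pd.DataFrame, path: str | Path,
                 provenance: Mapping | None = None) -> None:
    """Write a matrix as TSV (missing -> empty string) plus a provenance sidecar."""
    path = Path(path)
    matrix.to_csv(path, sep="\t", na_rep="", index_label="protein_id")
    write_provenance(path, provenance)


def read_annotation(path: str | Path, matrix: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a sample-annotation TSV and cross-validate it against a matrix.

    Returns a DataFrame indexed by ``sample_id``. When a matrix is
    given, every matrix sample must be annotated exactly once; extra
    annotation rows are dropped with a warning.
    """
    path = Path(path)
    ann = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing_cols:
        raise MatrixFormatError(f"{path}: missing annotation columns {missing_cols}")
    if ann["sample_id"].duplicated().any():
        dupes = ann.loc[ann["sample_id"].duplicated(), "sample_id"].tolist()
        raise MatrixFormatError(f"{path}: duplicate sample ids {dupes}")
    ann = ann.set_index("sample_id")
    ann["sex"] = ann["sex"].replace("", "NA")
    bad_g = sorted(set(ann["genotype"]) - set(GENOTYPES))
    if bad_g:
        raise MatrixFormatError(f"{path}: unknown genotype level(s) {bad_g}")
    bad_t = sorted(set(ann["treatment"]) - set(TREATMENTS))
    if bad_t:
        raise MatrixFormatError(f"{path}: unknown treatment level(s) {bad_t}")
    bad_s = sorted(set(ann["sex"]) - {"M", "F", "NA"})
    if bad_s:
        raise MatrixFormatError(f"{path}: unknown sex level(s) {bad_s}")
    if matrix is not None:
        ann = align_annotation(ann, matrix)
    return ann


def align_annotation(ann: pd.DataFrame, matrix: pd.DataFrame) -> pd.DataFrame:
    """Reorder annotation to match matrix samples; error on unannotated samples."""
    unannotated = [s for s in matrix.columns if s not in ann.index]
    if unannotated:
        raise MatrixFormatError(f"samples without annotation: {unannotated}")
    extra = [s for s in ann.index if s not in matrix.columns]
    if extra:
        warnings.warn(f"dropping {len(extra)} annotation rows not in matrix: {extra}",
                      stacklevel=2)
    return ann.loc[list(matrix.columns)]


def write_annotation(ann: pd.DataFrame, path: str | Path,
                     provenance: Mapping | None = None) -> None:
    path = Path(path)
    ann.to_csv(path, sep="\t", index_label="sample_id")
    write_provenance(path, provenance)


def write_provenance(data_path: str | Path, record: Mapping | None) -> None:
    """Write ``<file>.provenance.json`` describing how a file was produced.

    The record is augmented with the tool version. Timestamps are
    deliberately omitted so re-runs are byte-identical.
    """
    from . import __version__

    data_path = Path(data_path)
    payload = dict(record or {})
    payload.setdefault("tool", "proteopipe")
    payload.setdefault("version", __version__)
    payload.setdefault("file", data_path.name)
    side = data_path.with_name(data_path.name + ".provenance.json")
    side.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")


def group_samples(ann: pd.DataFrame, by_sex: bool = True) -> dict[tuple, list[str]]:
    """Partition samples into genotype x treatment (x sex) cells.

    Sex enters the key only when ``by_sex`` is true and at least one
    sample carries a determined sex.
    """
    use_sex = by_sex and (ann["sex"] != "NA").any()
    keys = ["genotype", "treatment"] + (["sex"] if use_sex else [])
    groups: dict[tuple, list[str]] = {}
    for key, sub in ann.groupby(keys, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        groups[key] = list(sub.index)
    return groups


def require_nonempty_cells(ann: pd.DataFrame) -> None:
    """Ensure every genotype x treatment cell has at least one sample."""
    cells = {(g, t) for g, t in zip(ann["genotype"], ann["treatment"])}
    missing = [(g, t) for g in GENOTYPES for t in TREATMENTS if (g, t) not in cells]
    if missing:
        raise MatrixFormatError(f"empty design cells: {missing}")


def samples_for(ann: pd.DataFrame, **levels: str) -> list[str]:
    """Samples matching the given factor levels, e.g. genotype='TG', treatment='VEH'."""
    mask = pd.Series(True, index=ann.index)
    for col, val in levels.items():
        mask &= ann[col] == val
    return list(ann.index[mask])
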