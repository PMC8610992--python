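"""Text I/O for count matrices, run metadata, annotation sets, result tables.

All files are UTF-8, tab-separated; lines starting with ``#`` are comments.
The counts file has a header row of run ids and a first column of protein
ids; the metadata file has columns ``run_id, role, condition, replicate``.
Annotation sets use the GMT dialect (term id, term name, then member ids,
one term per line).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import AnnotationSet, RunMeta, SpectralCountMatrix, validate_unique_terms

_META_COLUMNS = ["run_id", "role", "condition", "replicate"]


def read_run_metadata(meta_path: str | Path) -> dict[str, RunMeta]:
    """Read a run-metadata TSV into a mapping run_id -> RunMeta."""
    meta = pd.read_csv(meta_path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValidationError(
            f"{meta_path}: metadata missing column(s) {missing}"
        )
    out: dict[str, RunMeta] = {}
    for _, row in meta.iterrows():
        rid = str(row["run_id"])
        if rid in out:
            raise ValidationError(f"{meta_path}: duplicate run id {rid!r}")
        try:
            rep = int(row["replicate"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"{meta_path}: run {rid!r}: replicate {row['replicate']!r} "
                "is not an integer"
            ) from None
        out[rid] = RunMeta(run_id=rid, role=str(row["role"]),
                           condition=str(row["condition"]), replicate=rep)
    return out


def read_count_matrix(count_path: str | Path,
                      meta_path: str | Path) -> SpectralCountMatrix:
    """Read a spectral-count matrix and its run metadata.

    Every run in the counts header must appear in the metadata; metadata
    rows for runs absent from the counts file are ignored (a study-wide
    metadata sheet may cover several count files).
    """
    raw = pd.read_csv(count_path, sep="\t", comment="#", index_col=0,
                      dtype=str)
    protein_ids = [str(p) for p in raw.index]
    if len(set(protein_ids)) != len(protein_ids):
        dup = next(p for p in protein_ids if protein_ids.count(p) > 1)
        raise ValidationError(f"{count_path}: duplicate protein id {dup!r}")
    run_ids = [str(c) for c in raw.columns]

    counts = np.zeros((len(protein_ids), len(run_ids)), dtype=np.int64)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            try:
                val = float(cell)
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{count_path}: non-numeric count {cell!r} for protein "
                    f"{protein_ids[i]!r}, run {run_ids[j]!r}"
                ) from None
            if math.isnan(val):
                val = 0.0  # missing cell = not detected
            if val != int(val):
                raise ValidationError(
                    f"{count_path}: non-integer count {cell!r} for protein "
                    f"{protein_ids[i]!r}, run {run_ids[j]!r}"
                )
            if val < 0:
                raise ValidationError(
                    f"{count_path}: negative count {cell!r} for protein "
                    f"{protein_ids[i]!r}, run {run_ids[j]!r}"
                )
            counts[i, j] = int(val)

    meta = read_run_metadata(meta_path)
    runs = []
    for rid in run_ids:
        if rid not in meta:
            raise ValidationError(
                f"run {rid!r} present in {count_path} but absent from "
                f"{meta_path}"
            )
        runs.append(meta[rid])
    return SpectralCountMatrix(protein_ids=protein_ids, runs=runs,
                               counts=counts)


def write_count_matrix(matrix: SpectralCountMatrix, count_path: str | Path,
                       meta_path: str | Path) -> None:
    """Write a matrix and its metadata in the dialect read_count_matrix expects."""
    matrix.to_frame().to_csv(count_path, sep="\t", index_label="protein_id",
                             encoding="utf-8")
    meta = pd.DataFrame(
        [(r.run_id, r.role, r.condition, r.replicate) for r in matrix.runs],
        columns=_META_COLUMNS,
    )
    meta.to_csv(meta_path, sep="\t", index=False, encoding="utf-8")


def read_annotations(gmt_path: str | Path) -> list[AnnotationSet]:
    """Read GMT-style annotation sets; blank and ``#`` lines are skipped."""
    out: list[AnnotationSet] = []
    with open(gmt_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{gmt_path}:{lineno}: expected term_id, term_name and "
                    f"at least one member, got {len(fields)} field(s)"
                )
            members = [f for f in fields[2:] if f.strip()]
            if not members:
                raise ValidationError(
                    f"{gmt_path}:{lineno}: term {fields[0]!r} has no members"
                )
            out.append(AnnotationSet(term_id=fields[0], term_name=fields[1],
                                     members=frozenset(members)))
    validate_unique_terms(out)
    return out


def write_annotations(annotations: Sequence[AnnotationSet],
                      gmt_path: str | Path) -> None:
    validate_unique_terms(annotations)
    with open(gmt_path, "w", encoding="utf-8") as fh:
        for a in annotations:
            fh.write("\t".join([a.term_id, a.term_name, *sorted(a.members)]))
            fh.write("\n")


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with stable float formatting."""
    frame.to_csv(path, sep="\t", index=False, encoding="utf-8",
                 float_format="%.6g")


def read_id_list(path: str | Path) -> set[str]:
    """Read a one-id-per-line text file into a set (``#`` lines skipped)."""
    out: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.add(line)
    return out
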