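"""Core containers for a proximity-labeling screen.

A screen is a proteins x runs grid of spectral counts together with run
metadata assigning each run a role (bait or control pulldown), a condition
label (e.g. "2D" / "3D" culture), and a replicate index. All downstream
stages — the replicate filter, SAINT-style scoring, the differential
comparison — operate on :class:`SpectralCountMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError

ROLES = ("bait", "control")


@dataclass(frozen=True)
class RunMeta:
    """Metadata for one MS run: identity, role, condition, replicate index."""

    run_id: str
    role: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if not self.run_id:
            raise ValidationError("run_id must be a non-empty string")
        if self.role not in ROLES:
            raise ValidationError(
                f"run {self.run_id!r}: unknown role {self.role!r} "
                f"(expected one of {ROLES})"
            )
        if not self.condition:
            raise ValidationError(f"run {self.run_id!r}: empty condition label")
        if int(self.replicate) != self.replicate or self.replicate < 1:
            raise ValidationError(
                f"run {self.run_id!r}: replicate must be a positive integer, "
                f"got {self.replicate!r}"
            )


@dataclass
class SpectralCountMatrix:
    """Proteins x runs spectral counts plus per-run metadata.

    Parameters
    ----------
    protein_ids
        Ordered, unique protein accessions (opaque strings).
    runs
        One :class:`RunMeta` per column, in column order.
    counts
        Non-negative integer array of shape ``(len(protein_ids), len(runs))``.
        A zero means the protein was not detected in that run.
    """

    protein_ids: list[str]
    runs: list[RunMeta]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.protein_ids = list(self.protein_ids)
        self.runs = list(self.runs)
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape != (len(self.protein_ids), len(self.runs)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.protein_ids)} proteins x {len(self.runs)} runs"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValidationError("spectral counts must be integers")
        counts = counts.astype(np.int64, copy=False)
        if counts.size and counts.min() < 0:
            raise ValidationError("spectral counts must be non-negative")
        self.counts = counts

        seen: set[str] = set()
        for pid in self.protein_ids:
            if pid in seen:
                raise ValidationError(f"duplicate protein id {pid!r}")
            seen.add(pid)
        run_ids = [r.run_id for r in self.runs]
        if len(set(run_ids)) != len(run_ids):
            dup = next(r for r in run_ids if run_ids.count(r) > 1)
            raise ValidationError(f"duplicate run id {dup!r}")
        groups: dict[tuple[str, str], set[int]] = {}
        for r in self.runs:
            reps = groups.setdefault((r.role, r.condition), set())
            if r.replicate in reps:
                raise ValidationError(
                    f"replicate index {r.replicate} duplicated within "
                    f"({r.role}, {r.condition})"
                )
            reps.add(r.replicate)

    # -- shape -------------------------------------------------------------
    @property
    def n_proteins(self) -> int:
        return len(self.protein_ids)

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def run_ids(self) -> list[str]:
        return [r.run_id for r in self.runs]

    # -- selection ---------------------------------------------------------
    def column_indices(self, role: str | None = None,
                       condition: str | None = None) -> list[int]:
        """Indices of runs matching the given role and/or condition."""
        return [
            j for j, r in enumerate(self.runs)
            if (role is None or r.role == role)
            and (condition is None or r.condition == condition)
        ]

    def group_counts(self, role: str, condition: str) -> np.ndarray:
        """Counts sub-array for one (role, condition) group, replicate order."""
        cols = self.column_indices(role=role, condition=condition)
        if not cols:
            raise ConfigurationError(
                f"no {role} runs for condition {condition!r}"
            )
        cols.sort(key=lambda j: self.runs[j].replicate)
        return self.counts[:, cols]

    def row(self, protein_id: str) -> np.ndarray:
        try:
            i = self.protein_ids.index(protein_id)
        except ValueError:
            raise ValidationError(f"unknown protein id {protein_id!r}") from None
        return self.counts[i]

    def conditions(self) -> list[str]:
        """Distinct condition labels in column order of first appearance."""
        out: list[str] = []
        for r in self.runs:
            if r.condition not in out:
                out.append(r.condition)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.protein_ids,
                            columns=self.run_ids)


def subset_runs(matrix: SpectralCountMatrix, role: str | None = None,
                condition: str | None = None) -> SpectralCountMatrix:
    """Column-subset of a matrix, preserving protein order.

    Raises :class:`ConfigurationError` if no run matches the selection.
    """
    cols = matrix.column_indices(role=role, condition=condition)
    if not cols:
        raise ConfigurationError(
            f"no runs match role={role!r}, condition={condition!r}"
        )
    return SpectralCountMatrix(
        protein_ids=list(matrix.protein_ids),
        runs=[matrix.runs[j] for j in cols],
        counts=matrix.counts[:, cols].copy(),
    )


def merge_runs(parts: Sequence[SpectralCountMatrix]) -> SpectralCountMatrix:
    """Concatenate column-subsets that share an identical protein index."""
    if not parts:
        raise ValidationError("nothing to merge")
    first = parts[0]
    for m in parts[1:]:
        if m.protein_ids != first.protein_ids:
            raise ValidationError("matrices to merge have different protein ids")
    return SpectralCountMatrix(
        protein_ids=list(first.protein_ids),
        runs=[r for m in parts for r in m.runs],
        counts=np.hstack([m.counts for m in parts]),
    )


@dataclass(frozen=True)
class AnnotationSet:
    """One annotation term (e.g. a GO biological process) and its members."""

    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.term_id:
            raise ValidationError("term_id must be non-empty")
        if not self.members:
            raise ValidationError(f"term {self.term_id!r} has no members")
        object.__setattr__(self, "members", frozenset(self.members))


def validate_unique_terms(annotations: Iterable[AnnotationSet]) -> None:
    seen: set[str] = set()
    for a in annotations:
        if a.term_id in seen:
            raise ValidationError(f"duplicate term id {a.term_id!r}")
        seen.add(a.term_id)
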