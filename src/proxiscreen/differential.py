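"""Differential comparison of two proximity screens (e.g. 3D vs 2D culture).

Candidate lists from two conditions are partitioned into common and
condition-specific proteins, and common proteins are additionally tested
for condition enrichment of their normalized bait abundance. Because two
screens rarely have comparable sequencing/identification depth, bait counts
are total-count normalized by default: each bait run's counts are divided
by that run's column total, averaged across the condition's bait
replicates, and rescaled by the mean bait column total of the whole study
so the values stay on a count-like scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .matrix import SpectralCountMatrix

NORMALIZATIONS = ("total_count", "none")

STATUS_COMMON = "common"
STATUS_SPECIFIC_A = "specific_A"
STATUS_SPECIFIC_B = "specific_B"


@dataclass(frozen=True)
class DifferentialParams:
    enrichment_threshold: float = 5.0
    normalization: str = "total_count"
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if self.enrichment_threshold <= 1:
            raise ValidationError("enrichment_threshold must be > 1")
        if self.normalization not in NORMALIZATIONS:
            raise ValidationError(
                f"normalization must be one of {NORMALIZATIONS}"
            )
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")


@dataclass(frozen=True)
class DifferentialCall:
    """Per-protein cross-condition status and normalized abundance ratio."""

    protein_id: str
    status: str
    ratio_A_over_B: float
    enriched_A: bool
    enriched_B: bool


def normalize_bait_means(matrix: SpectralCountMatrix, condition: str,
                         normalization: str = "total_count"
                         ) -> dict[str, float]:
    """Per-protein normalized mean bait abundance for one condition.

    With ``total_count`` each bait run is scaled to the mean bait-run depth
    of the whole matrix (all conditions); with ``none`` the plain mean of
    raw bait counts is returned.
    """
    if normalization not in NORMALIZATIONS:
        raise ValidationError(f"normalization must be one of {NORMALIZATIONS}")
    bait = matrix.group_counts("bait", condition)
    if normalization == "none":
        means = bait.mean(axis=1)
    else:
        cols = matrix.column_indices(role="bait", condition=condition)
        totals = bait.sum(axis=0).astype(float)
        for t, j in zip(totals, sorted(cols, key=lambda j: matrix.runs[j].replicate)):
            if t == 0:
                raise ValidationError(
                    f"bait run {matrix.runs[j].run_id!r} has zero total count"
                )
        all_bait_cols = matrix.column_indices(role="bait")
        scale = float(matrix.counts[:, all_bait_cols].sum(axis=0).mean())
        means = (bait / totals).mean(axis=1) * scale
    return {pid: float(m) for pid, m in zip(matrix.protein_ids, means)}


def classify_differential(
    passing_a: set[str],
    passing_b: set[str],
    means_a: Mapping[str, float],
    means_b: Mapping[str, float],
    params: DifferentialParams | None = None,
) -> list[DifferentialCall]:
    """Partition two candidate id sets and flag condition-enriched proteins.

    A protein in both sets is ``common``; its normalized-abundance ratio
    (A + pseudocount) / (B + pseudocount) is compared against the
    enrichment threshold (strict inequality, both directions). Proteins in
    only one set are ``specific_A`` / ``specific_B``; their ratio is still
    reported but enrichment flags stay False (specificity already captures
    the direction). Output is sorted by protein id.
    """
    params = params or DifferentialParams()
    union = passing_a | passing_b
    for pid in union:
        if pid not in means_a or pid not in means_b:
            raise ValidationError(f"no abundance record for protein {pid!r}")

    calls: list[DifferentialCall] = []
    for pid in sorted(union):
        num = means_a[pid] + params.pseudocount
        den = means_b[pid] + params.pseudocount
        if den == 0:
            ratio = math.inf if num > 0 else 0.0
        else:
            ratio = num / den
        if pid in passing_a and pid in passing_b:
            status = STATUS_COMMON
            enr_a = ratio > params.enrichment_threshold
            enr_b = ratio > 0 and (1.0 / ratio) > params.enrichment_threshold
        else:
            status = STATUS_SPECIFIC_A if pid in passing_a else STATUS_SPECIFIC_B
            enr_a = enr_b = False
        calls.append(DifferentialCall(protein_id=pid, status=status,
                                      ratio_A_over_B=ratio,
                                      enriched_A=enr_a, enriched_B=enr_b))
    return calls


def venn_counts(calls: Iterable[DifferentialCall]) -> tuple[int, int, int]:
    """(n_common, n_specific_A, n_specific_B); the three partition the union."""
    n_c = n_a = n_b = 0
    for c in calls:
        if c.status == STATUS_COMMON:
            n_c += 1
        elif c.status == STATUS_SPECIFIC_A:
            n_a += 1
        elif c.status == STATUS_SPECIFIC_B:
            n_b += 1
        else:  # pragma: no cover - dataclass is frozen, statuses fixed
            raise ValidationError(f"unknown status {c.status!r}")
    return n_c, n_a, n_b


def calls_to_frame(calls: Sequence[DifferentialCall]) -> pd.DataFrame:
    return pd.DataFrame({
        "protein_id": [c.protein_id for c in calls],
        "status": [c.status for c in calls],
        "ratio_A_over_B": [c.ratio_A_over_B for c in calls],
        "enriched_A": [c.enriched_A for c in calls],
        "enriched_B": [c.enriched_B for c in calls],
    })
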