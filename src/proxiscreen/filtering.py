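"""Replicate-based candidate filter for bait-vs-control spectral counts.

A protein is kept as a candidate proximity protein when it satisfies three
rules simultaneously:

1. it is detected (count >= ``detection_threshold``) in at least
   ``min_detected_replicates`` of the bait replicates;
2. its mean bait count is at least ``min_fold_over_control`` times the
   control reference (mean of control replicates by default);
3. every single control replicate count is strictly below
   ``max_control_count`` — a cap that removes abundant contaminants
   (endogenously biotinylated or bead-binding proteins present in bait and
   control alike).

This is the classic first-pass reduction of a BioID / AP-MS screen from the
full detected proteome to a candidate interactor list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .matrix import SpectralCountMatrix

CONTROL_AGGREGATES = ("mean", "max", "sum")


@dataclass(frozen=True)
class FilterCriteria:
    """Parameters of the three-rule candidate filter.

    ``pseudocount`` is added to the control reference before division, for
    reporting finite fold enrichments; with the default 0 a zero-background
    prey gets an infinite fold enrichment and passes rule 2.
    ``control_aggregate`` selects the control reference for rule 2: the
    mean over control replicates (default), their max, or their sum.
    """

    min_detected_replicates: int = 2
    total_bait_replicates: int = 3
    min_fold_over_control: float = 2.0
    max_control_count: int = 10
    detection_threshold: int = 1
    pseudocount: float = 0.0
    control_aggregate: str = "mean"

    def __post_init__(self) -> None:
        if not 1 <= self.min_detected_replicates <= self.total_bait_replicates:
            raise ValidationError(
                "need 1 <= min_detected_replicates <= total_bait_replicates, "
                f"got {self.min_detected_replicates} / {self.total_bait_replicates}"
            )
        if self.min_fold_over_control <= 0:
            raise ValidationError("min_fold_over_control must be > 0")
        if self.max_control_count <= 0:
            raise ValidationError("max_control_count must be > 0")
        if self.detection_threshold < 1:
            raise ValidationError("detection_threshold must be >= 1")
        if self.pseudocount < 0:
            raise ValidationError("pseudocount must be >= 0")
        if self.control_aggregate not in CONTROL_AGGREGATES:
            raise ValidationError(
                f"control_aggregate must be one of {CONTROL_AGGREGATES}"
            )


@dataclass(frozen=True)
class CandidateHit:
    """Per-protein filter diagnostics: statistics and per-rule pass flags."""

    protein_id: str
    n_bait_detected: int
    mean_bait: float
    mean_control: float
    fold_enrichment: float
    pass_detection: bool
    pass_fold: bool
    pass_control_cap: bool

    @property
    def pass_all(self) -> bool:
        return self.pass_detection and self.pass_fold and self.pass_control_cap


def _control_reference(control_counts: np.ndarray, aggregate: str) -> float:
    if aggregate == "mean":
        return float(np.mean(control_counts))
    if aggregate == "max":
        return float(np.max(control_counts))
    if aggregate == "sum":
        return float(np.sum(control_counts))
    raise ValidationError(f"unknown control aggregate {aggregate!r}")


def fold_enrichment(bait_counts: Sequence[int], control_counts: Sequence[int],
                    pseudocount: float = 0.0,
                    control_aggregate: str = "mean") -> float:
    """Mean bait count over the control reference (plus pseudocount).

    Returns ``math.inf`` when the denominator is zero but the bait mean is
    positive, and 0.0 when both are zero.
    """
    bait = np.asarray(bait_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    if bait.size == 0 or control.size == 0:
        raise ValidationError("bait and control count lists must be non-empty")
    if bait.min(initial=0) < 0 or control.min(initial=0) < 0:
        raise ValidationError("counts must be non-negative")
    if pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")
    mean_bait = float(bait.mean())
    denom = _control_reference(control, control_aggregate) + pseudocount
    if denom == 0:
        return math.inf if mean_bait > 0 else 0.0
    return mean_bait / denom


def apply_replicate_filter(
    matrix: SpectralCountMatrix,
    bait_condition: str,
    criteria: FilterCriteria | None = None,
) -> list[CandidateHit]:
    """Evaluate the three-rule filter for every protein in the matrix.

    Bait and control runs are taken from ``bait_condition``; output order
    matches the matrix protein order. Raises :class:`ConfigurationError`
    when the condition has no bait or no control runs.
    """
    criteria = criteria or FilterCriteria()
    bait = matrix.group_counts("bait", bait_condition)
    control = matrix.group_counts("control", bait_condition)
    if criteria.min_detected_replicates > bait.shape[1]:
        raise ConfigurationError(
            f"min_detected_replicates={criteria.min_detected_replicates} "
            f"exceeds the {bait.shape[1]} bait run(s) for {bait_condition!r}"
        )

    hits: list[CandidateHit] = []
    for i, pid in enumerate(matrix.protein_ids):
        b, c = bait[i], control[i]
        n_det = int(np.sum(b >= criteria.detection_threshold))
        fe = fold_enrichment(b, c, pseudocount=criteria.pseudocount,
                             control_aggregate=criteria.control_aggregate)
        hits.append(CandidateHit(
            protein_id=pid,
            n_bait_detected=n_det,
            mean_bait=float(np.mean(b)),
            mean_control=float(np.mean(c)),
            fold_enrichment=fe,
            pass_detection=n_det >= criteria.min_detected_replicates,
            pass_fold=fe >= criteria.min_fold_over_control,
            pass_control_cap=bool(np.all(c < criteria.max_control_count)),
        ))
    return hits


def passing_set(hits: Iterable[CandidateHit]) -> set[str]:
    """Protein ids passing all three rules."""
    return {h.protein_id for h in hits if h.pass_all}


def hits_to_frame(hits: Sequence[CandidateHit]) -> pd.DataFrame:
    return pd.DataFrame({
        "protein_id": [h.protein_id for h in hits],
        "n_bait_detected": [h.n_bait_detected for h in hits],
        "mean_bait": [h.mean_bait for h in hits],
        "mean_control": [h.mean_control for h in hits],
        "fold_enrichment": [h.fold_enrichment for h in hits],
        "pass_detection": [h.pass_detection for h in hits],
        "pass_fold": [h.pass_fold for h in hits],
        "pass_control_cap": [h.pass_control_cap for h in hits],
        "pass_all": [h.pass_all for h in hits],
    })
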