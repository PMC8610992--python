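"""SAINT-style interaction probability from bait vs control spectral counts.

Each prey's counts are modeled as a two-component Poisson mixture: a true
proximity interaction emits counts at rate lambda_true, background at rate
lambda_false. The per-replicate posterior probability of true interaction is

    p(x) = pi * f(x | l1) / (pi * f(x | l1) + (1 - pi) * f(x | l0))

with f the Poisson mass function, pi the prior probability of a true
interaction, l0 estimated from the control replicates (floored at
``lambda_floor``) and l1 from the bait replicates (floored at
``true_rate_factor`` times l0 so the "true" component always means more
signal than background). The reported score (AvgP) is the mean posterior
over bait replicates; preys with AvgP strictly above the high-confidence
cutoff (0.75 by convention) form the high-confidence interactor set.

This is a deliberately transparent plug-in version of the spectral-count
interaction-scoring idea: closed-form, deterministic, no EM refinement, no
prey-length or abundance normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import poisson

from .errors import ValidationError
from .matrix import SpectralCountMatrix


@dataclass(frozen=True)
class SaintParams:
    """Prior, rate floors and cutoff for the interaction score."""

    prior_true: float = 0.1
    lambda_floor: float = 0.1
    true_rate_factor: float = 2.0
    high_confidence_cutoff: float = 0.75

    def __post_init__(self) -> None:
        if not 0 < self.prior_true < 1:
            raise ValidationError("prior_true must be in (0, 1)")
        if self.lambda_floor <= 0:
            raise ValidationError("lambda_floor must be > 0")
        # factor 1 is allowed: it collapses the mixture (lambda_true may
        # equal lambda_false) and the posterior reduces to the prior.
        if self.true_rate_factor < 1:
            raise ValidationError("true_rate_factor must be >= 1")
        if not 0 <= self.high_confidence_cutoff <= 1:
            raise ValidationError("high_confidence_cutoff must be in [0, 1]")


@dataclass(frozen=True)
class SaintScore:
    """Per-protein score: AvgP, per-replicate posteriors, fitted rates."""

    protein_id: str
    avg_p: float
    per_replicate_p: tuple[float, ...]
    lambda_true: float
    lambda_false: float


def estimate_rates(bait_counts: Sequence[int], control_counts: Sequence[int],
                   params: SaintParams | None = None) -> tuple[float, float]:
    """Plug-in Poisson rates: control mean (floored) and bait mean (floored).

    Returns ``(lambda_true, lambda_false)`` with
    ``lambda_false = max(mean(control), lambda_floor)`` and
    ``lambda_true = max(mean(bait), true_rate_factor * lambda_false)``.
    """
    params = params or SaintParams()
    bait = np.asarray(bait_counts, dtype=float)
    control = np.asarray(control_counts, dtype=float)
    if bait.size == 0 or control.size == 0:
        raise ValidationError("bait and control count lists must be non-empty")
    lam_false = max(float(control.mean()), params.lambda_floor)
    lam_true = max(float(bait.mean()), params.true_rate_factor * lam_false)
    return lam_true, lam_false


def _posterior(x: np.ndarray, lam_true: float, lam_false: float,
               prior: float) -> np.ndarray:
    # log-space for numerical stability at large counts / tiny rates
    log_true = math.log(prior) + poisson.logpmf(x, lam_true)
    log_false = math.log1p(-prior) + poisson.logpmf(x, lam_false)
    return np.exp(log_true - np.logaddexp(log_true, log_false))


def saint_score(matrix: SpectralCountMatrix, bait_condition: str,
                params: SaintParams | None = None) -> list[SaintScore]:
    """Score every protein in the matrix for one bait condition."""
    params = params or SaintParams()
    bait = matrix.group_counts("bait", bait_condition)
    control = matrix.group_counts("control", bait_condition)

    scores: list[SaintScore] = []
    for i, pid in enumerate(matrix.protein_ids):
        lam_true, lam_false = estimate_rates(bait[i], control[i], params)
        p = _posterior(bait[i].astype(float), lam_true, lam_false,
                       params.prior_true)
        scores.append(SaintScore(
            protein_id=pid,
            avg_p=float(np.mean(p)),
            per_replicate_p=tuple(float(v) for v in p),
            lambda_true=lam_true,
            lambda_false=lam_false,
        ))
    return scores


def high_confidence(scores: Iterable[SaintScore],
                    params: SaintParams | None = None) -> set[str]:
    """Ids with AvgP strictly above the cutoff."""
    params = params or SaintParams()
    return {s.protein_id for s in scores
            if s.avg_p > params.high_confidence_cutoff}


def scores_to_frame(scores: Sequence[SaintScore],
                    params: SaintParams | None = None) -> pd.DataFrame:
    params = params or SaintParams()
    n_rep = max((len(s.per_replicate_p) for s in scores), default=0)
    data: dict[str, list] = {
        "protein_id": [s.protein_id for s in scores],
        "avg_p": [s.avg_p for s in scores],
    }
    for r in range(n_rep):
        data[f"p_rep{r + 1}"] = [
            s.per_replicate_p[r] if r < len(s.per_replicate_p) else float("nan")
            for s in scores
        ]
    data["lambda_false"] = [s.lambda_false for s in scores]
    data["lambda_true"] = [s.lambda_true for s in scores]
    data["high_confidence"] = [
        s.avg_p > params.high_confidence_cutoff for s in scores
    ]
    return pd.DataFrame(data)
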