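"""Synthetic proximity-labeling screens with known ground truth.

The generator emulates the design of a typical BioID study: for each
condition (two culture formats by default), triplicate bait and triplicate
control purifications of a ~550-protein detected proteome composed of

* *background* proteins with sparse low counts (Poisson, rate ``bg_rate``)
  in every run — nonspecific biotinylation and carry-over;
* *true interactors* with elevated, over-dispersed counts in bait runs
  only (negative binomial with mean ``true_mean`` x condition multiplier
  and size ``true_dispersion``, plus an independent per-replicate dropout),
  and background-level counts in controls;
* *contaminants* with high counts in bait AND control runs (Poisson, mean
  ``contaminant_mean``) — streptavidin-binding / endogenously biotinylated
  proteins that the control-count cap is designed to remove.

A small subset of true interactors carries a strong multiplier in one
condition, emulating condition-enriched interactions. The negative-binomial
bait counts deliberately violate the Poisson assumption of the scorer, so
recovery results measure robustness to over-dispersion, not best-case fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .matrix import AnnotationSet, RunMeta, SpectralCountMatrix


@dataclass(frozen=True)
class SyntheticScreenConfig:
    """Generative parameters for one synthetic screen."""

    n_background: int = 500
    n_true: int = 40
    n_contaminant: int = 15
    replicates: int = 3
    conditions: tuple[str, ...] = ("2D", "3D")
    bg_rate: float = 0.8
    true_mean: float = 12.0
    true_dispersion: float = 2.0
    contaminant_mean: float = 25.0
    n_condition_enriched: int = 5
    condition_multiplier: float = 25.0
    enriched_condition: str | None = None  # default: last condition label
    condition_effect: Mapping[str, Mapping[str, float]] | None = None
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_background", "n_true", "n_contaminant"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        if len(self.conditions) < 1 or len(set(self.conditions)) != len(self.conditions):
            raise ValidationError("conditions must be non-empty and unique")
        for name in ("bg_rate", "true_mean", "true_dispersion",
                     "contaminant_mean"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if not 0 <= self.dropout <= 1:
            raise ValidationError("dropout must be in [0, 1]")
        if not 0 <= self.n_condition_enriched <= self.n_true:
            raise ValidationError(
                "n_condition_enriched must be between 0 and n_true"
            )
        if self.condition_multiplier <= 0:
            raise ValidationError("condition_multiplier must be > 0")
        if (self.enriched_condition is not None
                and self.enriched_condition not in self.conditions):
            raise ValidationError(
                f"enriched_condition {self.enriched_condition!r} not among "
                f"conditions {self.conditions}"
            )

    def resolved_effects(self, true_ids: Sequence[str]
                         ) -> dict[str, dict[str, float]]:
        """Per-protein condition multipliers (explicit map wins)."""
        if self.condition_effect is not None:
            out = {}
            for pid, effects in self.condition_effect.items():
                if pid not in true_ids:
                    raise ValidationError(
                        f"condition_effect names unknown true interactor {pid!r}"
                    )
                out[pid] = dict(effects)
            return out
        cond = self.enriched_condition or self.conditions[-1]
        return {pid: {cond: self.condition_multiplier}
                for pid in true_ids[: self.n_condition_enriched]}


@dataclass(frozen=True)
class GroundTruth:
    """True-interactor and contaminant id sets, and condition enrichment."""

    true_interactors: frozenset[str]
    contaminants: frozenset[str]
    condition_enriched: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_interactors & self.contaminants:
            raise ValidationError(
                "true interactor and contaminant sets must be disjoint"
            )


@dataclass(frozen=True)
class RecoveryMetrics:
    """Sensitivity / observed FDR of a prediction against ground truth."""

    n_predicted: int
    n_true: int
    sensitivity: float
    fdr: float
    auc_sens_fdr: float | None = None  # only for ranked input


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size: float,
               shape: tuple[int, int]) -> np.ndarray:
    p = size / (size + mean)
    return rng.negative_binomial(size, p, shape)


def simulate_screen(config: SyntheticScreenConfig | None = None
                    ) -> tuple[SpectralCountMatrix, GroundTruth]:
    """Draw one screen; identical configs (incl. seed) give identical output."""
    config = config or SyntheticScreenConfig()
    rng = np.random.default_rng(config.seed)

    bg_ids = [f"BG{i + 1:04d}" for i in range(config.n_background)]
    true_ids = [f"INT{i + 1:03d}" for i in range(config.n_true)]
    cont_ids = [f"CTM{i + 1:02d}" for i in range(config.n_contaminant)]
    protein_ids = bg_ids + true_ids + cont_ids
    effects = config.resolved_effects(true_ids)

    runs: list[RunMeta] = []
    blocks: list[np.ndarray] = []
    reps = config.replicates
    for cond in config.conditions:
        mult = np.array([effects.get(pid, {}).get(cond, 1.0)
                         for pid in true_ids])
        for role in ("bait", "control"):
            runs.extend(
                RunMeta(run_id=f"{cond}_{role}_{r + 1}", role=role,
                        condition=cond, replicate=r + 1)
                for r in range(reps)
            )
            bg = rng.poisson(config.bg_rate, (config.n_background, reps))
            if role == "bait" and config.n_true:
                tr = _nb_counts(rng, (config.true_mean * mult)[:, None],
                                config.true_dispersion,
                                (config.n_true, reps))
                drop = rng.random((config.n_true, reps)) < config.dropout
                tr = np.where(drop, 0, tr)
            else:
                tr = rng.poisson(config.bg_rate, (config.n_true, reps))
            ct = rng.poisson(config.contaminant_mean,
                             (config.n_contaminant, reps))
            blocks.append(np.vstack([bg, tr, ct]))

    counts = np.hstack(blocks)
    matrix = SpectralCountMatrix(protein_ids=protein_ids, runs=runs,
                                 counts=counts.astype(np.int64))
    truth = GroundTruth(
        true_interactors=frozenset(true_ids),
        contaminants=frozenset(cont_ids),
        condition_enriched={pid: cond
                            for pid, eff in effects.items()
                            for cond, m in eff.items() if m > 1.0},
    )
    return matrix, truth


def synthetic_annotations(truth: GroundTruth, universe: Sequence[str],
                          seed: int = 0, n_random_terms: int = 10,
                          random_term_size: int = 30) -> list[AnnotationSet]:
    """Annotation terms for testing enrichment on a synthetic screen.

    One term collects the true interactors (it should come out enriched in
    any decent candidate list), one the contaminants, and the rest are
    random draws from the universe (null terms).
    """
    rng = np.random.default_rng(seed)
    terms: list[AnnotationSet] = []
    if truth.true_interactors:
        terms.append(AnnotationSet("SYN:TRUE", "synthetic true proximity interactome",
                                   frozenset(truth.true_interactors)))
    if truth.contaminants:
        terms.append(AnnotationSet("SYN:CONT", "synthetic contaminant background",
                                   frozenset(truth.contaminants)))
    universe = list(universe)
    size = min(random_term_size, len(universe))
    for t in range(n_random_terms):
        members = rng.choice(universe, size=size, replace=False)
        terms.append(AnnotationSet(f"SYN:RAND{t + 1:02d}",
                                   f"synthetic random term {t + 1}",
                                   frozenset(str(m) for m in members)))
    return terms


def _set_metrics(predicted: set[str], truth: GroundTruth
                 ) -> tuple[int, int, float, float]:
    true = truth.true_interactors
    tp = len(predicted & true)
    sens = tp / len(true) if true else 0.0
    fdr = (len(predicted) - tp) / len(predicted) if predicted else 0.0
    return len(predicted), len(true), sens, fdr


def evaluate_recovery(predicted, truth: GroundTruth,
                      universe: set[str] | None = None) -> RecoveryMetrics:
    """Sensitivity and observed FDR of a prediction against ground truth.

    ``predicted`` is either a set of ids, or a mapping id -> score for a
    ranked prediction; for ranked input the area under the sensitivity vs
    observed-FDR curve is also computed by an exhaustive sweep over all
    distinct score thresholds (trapezoidal rule over the swept path,
    anchored at (0, 0); higher is better).
    """
    if isinstance(predicted, Mapping):
        ids = set(predicted)
    else:
        ids = set(predicted)
    if universe is not None:
        unknown = ids - universe
        if unknown:
            raise ValidationError(f"unknown id(s): {sorted(unknown)[:5]}")

    if not isinstance(predicted, Mapping):
        n_pred, n_true, sens, fdr = _set_metrics(ids, truth)
        return RecoveryMetrics(n_pred, n_true, sens, fdr)

    n_pred, n_true, sens, fdr = _set_metrics(ids, truth)
    order = sorted(predicted, key=lambda pid: (-predicted[pid], pid))
    points = [(0.0, 0.0)]
    taken: set[str] = set()
    i = 0
    while i < len(order):
        # include whole tie groups so the sweep is threshold-exhaustive
        j = i
        while j < len(order) and predicted[order[j]] == predicted[order[i]]:
            taken.add(order[j])
            j += 1
        _, _, s, f = _set_metrics(taken, truth)
        points.append((f, s))
        i = j
    auc = sum((f1 - f0) * (s0 + s1) / 2.0
              for (f0, s0), (f1, s1) in zip(points, points[1:]))
    return RecoveryMetrics(n_pred, n_true, sens, fdr, auc_sens_fdr=auc)


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    rows = [(pid, "true_interactor", truth.condition_enriched.get(pid, ""))
            for pid in sorted(truth.true_interactors)]
    rows += [(pid, "contaminant", "") for pid in sorted(truth.contaminants)]
    return pd.DataFrame(rows, columns=["protein_id", "class",
                                       "enriched_condition"])
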