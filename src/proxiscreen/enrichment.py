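"""Term over-representation for a candidate list against a background.

For each annotation term the candidate list is tested with the
hypergeometric upper tail (one-sided over-representation), fold enrichment
is reported as (k/n)/(K/N), and p-values are adjusted across terms with the
Benjamini-Hochberg step-up (FDR). The background should be the set of
proteins detectable by the screen — typically everything identified in the
relevant purifications, not the whole proteome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .matrix import AnnotationSet, validate_unique_terms


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's 2x2 counts, fold enrichment, p and BH-adjusted q."""

    term_id: str
    term_name: str
    k: int  # candidates in term
    n: int  # candidate-list size
    K: int  # background members of term
    N: int  # background size
    fold_enrichment: float
    p_value: float
    q_value: float


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N objects, K of them marked, n drawn without replacement.
    """
    if not (0 <= k <= n <= N):
        raise ValidationError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (0 <= K <= N):
        raise ValidationError(f"need 0 <= K <= N, got K={K}, N={N}")
    if k > K:
        raise ValidationError(f"need k <= K, got k={k}, K={K}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted values, order-preserving with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    return [float(q) for q in multipletests(p, method="fdr_bh")[1]]


def enrich(candidates: set[str], background: set[str],
           annotations: Sequence[AnnotationSet],
           min_term_size: int = 2) -> list[EnrichmentRow]:
    """Over-representation of each term among candidates vs background.

    Terms are intersected with the background before counting; terms with
    fewer than ``min_term_size`` background members are dropped. Rows are
    sorted by q-value, then decreasing fold enrichment, then term id.
    """
    validate_unique_terms(annotations)
    stray = candidates - background
    if stray:
        raise ValidationError(
            f"candidate(s) not in background: {sorted(stray)[:5]}"
        )
    if min_term_size < 1:
        raise ValidationError("min_term_size must be >= 1")
    n, N = len(candidates), len(background)

    kept: list[tuple[AnnotationSet, int, int]] = []
    for term in annotations:
        members = term.members & background
        if len(members) < min_term_size:
            continue
        kept.append((term, len(candidates & members), len(members)))

    p_values = [hypergeom_upper_tail(k, n, K, N) for _, k, K in kept]
    q_values = benjamini_hochberg(p_values)

    rows = []
    for (term, k, K), p, q in zip(kept, p_values, q_values):
        fold = (k / n) / (K / N) if n > 0 and K > 0 else 0.0
        rows.append(EnrichmentRow(term_id=term.term_id,
                                  term_name=term.term_name,
                                  k=k, n=n, K=K, N=N,
                                  fold_enrichment=fold,
                                  p_value=p, q_value=q))
    rows.sort(key=lambda r: (r.q_value, -r.fold_enrichment, r.term_id))
    return rows


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame({
        "term_id": [r.term_id for r in rows],
        "term_name": [r.term_name for r in rows],
        "k": [r.k for r in rows],
        "n": [r.n for r in rows],
        "K": [r.K for r in rows],
        "N": [r.N for r in rows],
        "fold_enrichment": [r.fold_enrichment for r in rows],
        "p_value": [r.p_value for r in rows],
        "q_value": [r.q_value for r in rows],
    })
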