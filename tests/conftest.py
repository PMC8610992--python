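"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest

from proxiscreen import (SpectralCountMatrix, SyntheticScreenConfig,
                         simulate_screen)
from proxiscreen.matrix import RunMeta


def single_condition_matrix(bait_rows, control_rows, protein_ids=None,
                            condition="3D"):
    """Build a matrix with one condition from per-protein bait/control rows."""
    bait_rows = np.atleast_2d(np.asarray(bait_rows))
    control_rows = np.atleast_2d(np.asarray(control_rows))
    n = bait_rows.shape[0]
    if protein_ids is None:
        protein_ids = [f"P{i + 1}" for i in range(n)]
    runs = [RunMeta(f"{condition}_bait_{r + 1}", "bait", condition, r + 1)
            for r in range(bait_rows.shape[1])]
    runs += [RunMeta(f"{condition}_ctrl_{r + 1}", "control", condition, r + 1)
             for r in range(control_rows.shape[1])]
    return SpectralCountMatrix(
        protein_ids=list(protein_ids), runs=runs,
        counts=np.hstack([bait_rows, control_rows]))


def brute_force_filter(bait_row, control_row, min_reps=2, min_fold=2.0,
                       max_control=10, detection_threshold=1):
    """Independent rule evaluator in exact integer/Fraction arithmetic.

    Returns (pass_detection, pass_fold, pass_control_cap) for one protein.
    """
    bait = [int(x) for x in bait_row]
    control = [int(x) for x in control_row]
    detected = sum(1 for x in bait if x >= detection_threshold)
    pass_det = detected >= min_reps
    mean_b = Fraction(sum(bait), len(bait))
    mean_c = Fraction(sum(control), len(control))
    if mean_c == 0:
        pass_fold = mean_b > 0  # infinite enrichment passes; 0/0 does not
    else:
        pass_fold = mean_b / mean_c >= Fraction(min_fold).limit_denominator()
    pass_cap = all(x < max_control for x in control)
    return pass_det, pass_fold, pass_cap


def hypergeom_tail_by_enumeration(k, n, K, N):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws (exact)."""
    hits = total = 0
    marked = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for d in draw if d in marked) >= k:
            hits += 1
    return Fraction(hits, total) if total else Fraction(1)


def bh_step_up(p_values):
    """Independent Benjamini-Hochberg step-up, order-preserving."""
    n = len(p_values)
    order = sorted(range(n), key=lambda i: p_values[i])
    q = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * n / rank)
        q[i] = running
    return q


@pytest.fixture(scope="session")
def default_screen():
    """One synthetic screen drawn under the default study conditions."""
    config = SyntheticScreenConfig()
    matrix, truth = simulate_screen(config)
    return matrix, truth, config
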