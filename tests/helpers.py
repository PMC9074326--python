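"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the penalised L1
objective is minimised by exhaustive vertex enumeration instead of linear
programming, and AUC is computed by brute-force concordant-pair counting
instead of rank statistics.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def l1_objective(y: np.ndarray, X: np.ndarray, beta: np.ndarray,
                 penalties: np.ndarray) -> float:
    """(1/n)*sum|y - X beta| + sum_j penalties_j * |beta_j|."""
    resid = y - X @ beta
    return float(np.abs(resid).mean() + np.abs(beta) @ penalties)


def vertex_enumeration_minimum(y: np.ndarray, X: np.ndarray,
                               penalties: np.ndarray) -> float:
    """Global minimum of the penalised L1 objective by vertex enumeration.

    The objective is piecewise linear and (for positive penalties) coercive,
    so a minimiser lies at an intersection of k hyperplanes chosen from the
    n residual-zero planes ``X_i . beta = y_i`` and the k coordinate planes
    ``beta_j = 0``.  Every k-subset is solved and evaluated; feasible for
    the small instances the tests use (k <= 4, n <= 8).
    """
    n, k = X.shape
    rows = np.vstack([X, np.eye(k)])
    rhs = np.concatenate([y, np.zeros(k)])
    best = l1_objective(y, X, np.zeros(k), penalties)  # beta = 0 vertex
    for idx in combinations(range(n + k), k):
        A = rows[list(idx)]
        b = rhs[list(idx)]
        if abs(np.linalg.det(A)) < 1e-12:
            continue
        beta = np.linalg.solve(A, b)
        best = min(best, l1_objective(y, X, beta, penalties))
    return best


def brute_force_auc(scores: dict, positives: set, universe) -> float:
    """Concordant-pair fraction over every (positive, negative) pair,
    ties counted 1/2; unscored pairs score 0."""
    pos = [p for p in universe if p in positives]
    neg = [p for p in universe if p not in positives]
    total = 0.0
    for p in pos:
        sp = scores.get(p, 0.0)
        for q in neg:
            sq = scores.get(q, 0.0)
            total += 1.0 if sp > sq else (0.5 if sp == sq else 0.0)
    return total / (len(pos) * len(neg))
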