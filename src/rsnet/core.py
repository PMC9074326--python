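"""Constrained sparse regression and the recursive silencing loop.

For one target gene ``y`` with candidate-regulator matrix ``X`` the
regulatory strengths beta minimise

    (1/n) * ||y - X beta||_1  +  lambda * ||beta||_1  +  gamma * ||bhat o beta||_1

where ``o`` is the elementwise product and ``bhat`` is the enhancement mask:
1 for ordinary (mid-dependence) candidates, 0 for high-dependence
"enhancement" candidates.  Enhancement candidates therefore pay only the base
sparsity penalty lambda while everyone else pays lambda + gamma — a
differential penalty that gives the highly dependent regulators priority to
stay in the model.  The residual is measured in mean absolute error so that
the same lambda has comparable leverage at 5 and at 50 samples.

The objective is piecewise linear, so the exact global minimiser comes from a
linear program: split beta into nonnegative parts ``b+ - b-`` and the
residual into ``e+ - e-``, constrain ``X(b+ - b-) + e+ - e- = y`` and
minimise the corresponding nonnegative linear cost.

Redundancy silencing then iterates: solve, drop candidates whose |beta| falls
at or below ``silence_threshold``, rebuild the problem over the survivors
(recomputing the enhancement mask from the surviving high-dependence set) and
re-solve, until the surviving set no longer changes.  Weak and indirect
regulators, whose coefficients collapse once a mediator is available, are
removed step by step; the loop can only shrink, so it terminates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .mi import CandidatePartition, ScreenThresholds, mi_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SolverParams",
    "RegressionProblem",
    "StrengthVector",
    "WeightedNetwork",
    "solve_constrained_l1",
    "recursive_silencing",
    "combine_strengths",
    "infer_network",
]


@dataclass(frozen=True)
class SolverParams:
    """Tunable parameters of the silencing model.

    Attributes
    ----------
    lam : float
        Base L1 sparsity weight (lambda), paid by every candidate.
    gamma : float
        Extra redundancy-silencing weight, paid only by non-enhancement
        (mid-dependence) candidates.
    alpha : float in [0, 1]
        Balance between normalised |beta| (alpha) and normalised MI
        (1 - alpha) in the final edge strength.
    silence_threshold : float
        |beta| at or below this is treated as a silenced (weak) connection
        between iterations.  The default 0.05 assumes standardized
        expression, where beta is on the per-standard-deviation scale.
    enhance_fraction : float in [0, 1]
        A candidate keeps its enhancement protection only while its |beta|
        is at least this fraction of the target's largest |beta| (the
        high-dependence threshold reused on the normalized strength scale);
        once demoted it pays the full lam + gamma penalty for good.
    max_iterations : int
        Safety cap on silencing iterations; the loop normally stops at its
        fixed point long before.
    """

    lam: float = 0.1
    gamma: float = 0.1
    alpha: float = 0.5
    silence_threshold: float = 0.05
    enhance_fraction: float = 0.2
    max_iterations: int = 50

    def __post_init__(self):
        if self.lam < 0 or self.gamma < 0 or self.silence_threshold < 0:
            raise ValueError("lam, gamma and silence_threshold must be nonnegative")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if not (0.0 <= self.enhance_fraction <= 1.0):
            raise ValueError("enhance_fraction must be in [0, 1]")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class RegressionProblem:
    """One target's regression instance.

    ``enhancement_mask[j]`` is 0 exactly when candidate j is a protected
    high-dependence (enhancement) candidate, 1 otherwise.
    """

    y: np.ndarray
    X: np.ndarray
    candidate_ids: list
    enhancement_mask: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X must be (n_samples, k) matching y")
        if self.X.shape[1] != len(self.candidate_ids):
            raise ValueError("candidate_ids must match columns of X")
        self.enhancement_mask = np.asarray(self.enhancement_mask, dtype=float).ravel()
        if self.enhancement_mask.shape[0] != self.X.shape[1]:
            raise ValueError("enhancement_mask must have one entry per candidate")


@dataclass
class StrengthVector:
    """Estimated regulatory strengths for one target."""

    candidate_ids: list
    beta: np.ndarray
    objective: float = 0.0
    n_iterations: int = 0

    def support(self, threshold: float = 0.0) -> list:
        """Candidates with |beta| strictly above `threshold`, input order."""
        return [
            g for g, b in zip(self.candidate_ids, self.beta) if abs(b) > threshold
        ]


def solve_constrained_l1(
    problem: RegressionProblem, params: SolverParams
) -> StrengthVector:
    """Exact global minimiser of the penalised L1 objective, by LP.

    Returns an empty :class:`StrengthVector` when there are no candidates.
    LP infeasibility cannot occur for this formulation (e+/e- always absorb
    y) and is raised as an internal error if the solver reports it.
    """
    k = len(problem.candidate_ids)
    if k == 0:
        return StrengthVector([], np.zeros(0), 0.0)
    n = problem.y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")

    # variables: [b+ (k), b- (k), e+ (n), e- (n)], all >= 0
    coef_pen = params.lam + params.gamma * problem.enhancement_mask
    c = np.concatenate([coef_pen, coef_pen, np.full(n, 1.0 / n), np.full(n, 1.0 / n)])
    A_eq = np.hstack([problem.X, -problem.X, np.eye(n), -np.eye(n)])
    res = linprog(c, A_eq=A_eq, b_eq=problem.y, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - formulation is always feasible
        raise RuntimeError(f"internal LP failure: {res.message}")
    beta = res.x[:k] - res.x[k : 2 * k]
    return StrengthVector(list(problem.candidate_ids), beta, float(res.fun))


def _build_problem(
    expr: pd.DataFrame, target: str, candidates: list, high: frozenset
) -> RegressionProblem:
    y = expr.loc[target].to_numpy(dtype=float)
    X = expr.loc[candidates].to_numpy(dtype=float).T if candidates else np.zeros((len(y), 0))
    mask = np.array([0.0 if g in high else 1.0 for g in candidates])
    return RegressionProblem(y, X, list(candidates), mask)


def _silence_redundant(
    kept: list, beta_by_gene: dict, mi: pd.DataFrame, target: str
) -> list:
    """Drop the weaker member of every redundant surviving pair.

    Two surviving candidates are redundant when their mutual MI exceeds both
    of their MIs to the target: they carry more information about each other
    than about the target, so (by data-processing-inequality logic) at most
    one of them can be a direct regulator.  The one the optimization
    currently favours (larger |beta|; ties to the lexicographically earlier
    id) is kept.
    """
    kept = list(kept)
    pairs = [
        (gi, gj)
        for a, gi in enumerate(kept)
        for gj in kept[a + 1 :]
        if mi.loc[gi, gj] > max(mi.loc[gi, target], mi.loc[gj, target])
    ]
    alive = set(kept)
    for gi, gj in pairs:  # deterministic order; earlier drops shrink later pairs
        if gi in alive and gj in alive:
            bi, bj = abs(beta_by_gene[gi]), abs(beta_by_gene[gj])
            weaker = gj if (bi > bj or (bi == bj and gi < gj)) else gi
            alive.discard(weaker)
    return [g for g in kept if g in alive]


def recursive_silencing(
    expr: pd.DataFrame,
    target: str,
    partition: CandidatePartition,
    params: SolverParams | None = None,
    mi: pd.DataFrame | None = None,
) -> StrengthVector:
    """Iteratively silence weak and redundant candidates until stable.

    Starts from the partition's mid+high candidates, with the high class as
    the initial enhancement (protected) set.  Each round solves the LP, then
    silences (1) every candidate with ``|beta| <= silence_threshold`` (weak
    connections) and (2) the weaker member of every redundant candidate pair
    (two survivors more dependent on each other than on the target — the
    indirect-regulator signature; see :func:`_silence_redundant`).  The
    enhancement protection is updated from the optimization result: a
    protected candidate whose |beta| falls below ``enhance_fraction`` of the
    target's largest |beta| is demoted to the ordinary lam + gamma penalty
    (demotion is one-way, so the loop can only shrink and must terminate).
    Stops when neither the surviving set nor the protected set changes, or
    at `max_iterations` (last iterate returned with a warning).

    `mi` is the precomputed MI matrix; it is computed from `expr` when
    omitted.
    """
    if params is None:
        params = SolverParams()
    if mi is None:
        mi = mi_matrix(expr)
    survivors = sorted(partition.candidates)
    protected = set(partition.high)
    result = StrengthVector(list(survivors), np.zeros(len(survivors)), 0.0, 0)
    for it in range(1, params.max_iterations + 1):
        result = solve_constrained_l1(
            _build_problem(expr, target, survivors, frozenset(protected)), params
        )
        result.n_iterations = it
        kept = result.support(params.silence_threshold)
        beta_by_gene = dict(zip(result.candidate_ids, result.beta))
        kept = _silence_redundant(kept, beta_by_gene, mi, target)
        top = float(np.abs(result.beta).max()) if len(result.beta) else 0.0
        new_protected = {
            g
            for g, b in zip(result.candidate_ids, result.beta)
            if g in protected and g in kept and abs(b) >= params.enhance_fraction * top
        }
        if kept == survivors and new_protected == protected:
            # prune exact zeros from the report but keep the fixed point
            result = StrengthVector(
                kept,
                np.array([b for b in result.beta if abs(b) > params.silence_threshold]),
                result.objective,
                it,
            )
            return result
        survivors, protected = kept, new_protected
        if not survivors:
            return StrengthVector([], np.zeros(0), 0.0, it)
    logger.warning(
        "target %s: silencing did not stabilise in %d iterations", target,
        params.max_iterations,
    )
    return result


def combine_strengths(
    beta: StrengthVector,
    mi: pd.DataFrame,
    target: str,
    params: SolverParams | None = None,
) -> dict:
    """Blend regression and MI evidence into final edge strengths.

    Per surviving regulator j:
    ``strength = alpha * |beta_j| / max|beta| + (1 - alpha) * MI_j / max MI``,
    the max taken within the target's survivor set (an all-equal vector
    normalises to 1, so a lone survivor scores 1 regardless of alpha).

    Returns ``{regulator: (strength, beta, mi)}``.
    """
    if params is None:
        params = SolverParams()
    regs = beta.candidate_ids
    if not regs:
        return {}
    b = np.abs(np.asarray(beta.beta, dtype=float))
    m = mi.loc[regs, target].to_numpy(dtype=float)

    def _norm(v: np.ndarray) -> np.ndarray:
        top = v.max()
        return v / top if top > 0 else np.ones_like(v)

    strength = params.alpha * _norm(b) + (1.0 - params.alpha) * _norm(m)
    return {
        g: (float(s), float(bj), float(mj))
        for g, s, bj, mj in zip(regs, strength, beta.beta, m)
    }


@dataclass(frozen=True)
class EdgeRecord:
    regulator: str
    target: str
    strength: float
    beta: float
    mi: float


@dataclass
class WeightedNetwork:
    """Directed regulator->target edges with combined strengths.

    Edges are kept in the canonical output order: strength descending, then
    regulator id, then target id — bit-reproducible across runs.
    """

    edges: list = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for e in self.edges:
            if e.regulator == e.target:
                raise ValueError(f"self-edge {e.regulator}->{e.target}")
            if e.strength < 0:
                raise ValueError("combined strength must be nonnegative")
            pair = (e.regulator, e.target)
            if pair in seen:
                raise ValueError(f"duplicate edge {pair}")
            seen.add(pair)
        self.edges = sorted(
            self.edges, key=lambda e: (-e.strength, e.regulator, e.target)
        )

    def scores(self) -> dict:
        """``{(regulator, target): strength}`` for evaluation."""
        return {(e.regulator, e.target): e.strength for e in self.edges}

    def to_frame(self, extended: bool = False) -> pd.DataFrame:
        cols = ["regulator", "target", "strength"] + (
            ["beta", "mi"] if extended else []
        )
        return pd.DataFrame(
            [[getattr(e, c) for c in cols] for e in self.edges], columns=cols
        )

    def __len__(self) -> int:
        return len(self.edges)


def infer_network(
    expr: pd.DataFrame,
    regulators=None,
    thresholds: ScreenThresholds | None = None,
    params: SolverParams | None = None,
    *,
    standardize: bool = True,
) -> WeightedNetwork:
    """Infer a directed weighted network from a genes x samples matrix.

    Thin functional wrapper over :class:`rsnet.estimator.RSNet`; see that
    class for the algorithm.  `expr` follows the file convention (rows are
    genes); the estimator's sklearn-style samples x genes orientation is
    handled here.
    """
    from .estimator import RSNet  # local import: estimator builds on this module

    thresholds = thresholds or ScreenThresholds()
    params = params or SolverParams()
    model = RSNet(
        theta_low=thresholds.theta_low,
        theta_high=thresholds.theta_high,
        lam=params.lam,
        gamma=params.gamma,
        alpha=params.alpha,
        silence_threshold=params.silence_threshold,
        max_iterations=params.max_iterations,
        standardize=standardize,
    )
    model.fit(expr.T, regulators=regulators)
    return model.network_


def _zscore_rows(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene standardisation; constant genes are left at zero."""
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return pd.DataFrame(
        (values - mean) / sd, index=expr.index, columns=expr.columns
    )
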