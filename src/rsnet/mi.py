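"""Gaussian mutual information screening.

Under a bivariate-normal model the mutual information between two expression
profiles ``A`` and ``B`` is

    MI(A, B) = 1/2 * log( |M(A)| * |M(B)| / |M(A, B)| )

where ``M`` denotes a covariance matrix and ``|M|`` its determinant.  For the
scalar case this collapses to the closed form ``-1/2 * log(1 - r**2)`` with
``r`` the Pearson correlation, so the estimator captures linear dependence
only.  MI is reported in nats (natural log).

The screen partitions the candidate regulators of every target into three
dependence classes by two thresholds: *low* (``MI < theta_low``, discarded),
*mid* (``theta_low <= MI < theta_high``, enters the regression), and *high*
(``MI >= theta_high``, enters the regression as a protected "network
enhancement" candidate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Ceiling (nats) applied when |r| -> 1 makes the estimator diverge.
DEFAULT_MI_CAP = 50.0

# determinant floor guarding log(0) for perfectly collinear profiles
_DET_FLOOR = 1e-300


def gaussian_mi(x, y, *, mi_cap: float = DEFAULT_MI_CAP) -> float:
    """Gaussian mutual information between two expression profiles, in nats.

    Computed from the covariance determinants,
    ``0.5 * ln(var(x) * var(y) / det(cov([x, y])))``, clamped below at 0 and
    capped at `mi_cap` when the profiles are (near-)collinear.

    Parameters
    ----------
    x, y : array-like, shape (n_samples,)
        Expression profiles of equal length >= 3 with nonzero variance.
    mi_cap : float
        Upper bound in nats for near-singular pairs.

    Raises
    ------
    ValueError
        If the profiles differ in length, are shorter than 3 samples, or
        either has zero variance (MI undefined).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(
            f"profiles differ in length: {x.shape[0]} vs {y.shape[0]}"
        )
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate MI")
    cov = np.cov(x, y)  # unbiased (n-1) normalisation; cancels in the ratio
    vx, vy, cxy = cov[0, 0], cov[1, 1], cov[0, 1]
    if vx <= 0.0 or vy <= 0.0:
        raise ValueError("zero-variance profile: MI undefined")
    # explicit 2x2 determinant: avoids the LU round-off that 1/(1 - r^2)
    # would amplify for near-collinear profiles
    det = max(vx * vy - cxy * cxy, _DET_FLOOR)
    mi = 0.5 * np.log(vx * vy / det)
    return float(np.clip(mi, 0.0, mi_cap))


def mi_matrix(
    expr: pd.DataFrame,
    regulators=None,
    *,
    mi_cap: float = DEFAULT_MI_CAP,
) -> pd.DataFrame:
    """Pairwise Gaussian MI for all genes of an expression matrix.

    Parameters
    ----------
    expr : DataFrame, shape (n_genes, n_samples)
        Rows are genes, columns samples.
    regulators : iterable of gene ids, optional
        Unused for the computation itself (the matrix is symmetric and cheap
        to compute in full) but validated for membership so a typo in a
        regulator file fails early.
    mi_cap : float
        Ceiling in nats for near-collinear pairs.

    Returns
    -------
    DataFrame
        Symmetric gene x gene matrix; the (undefined) diagonal is NaN.
        Constant genes get MI 0 against everything, with a warning, so one
        dead probe cannot abort a whole run.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples to estimate MI")
    if regulators is not None:
        missing = sorted(set(regulators) - set(expr.index))
        if missing:
            raise ValueError(f"regulators absent from expression matrix: {missing}")

    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        dead = list(expr.index[constant])
        warnings.warn(f"constant gene(s) {dead}: MI set to 0", stacklevel=2)
        logger.warning("constant gene(s) %s: MI set to 0", dead)

    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 0.0)
    one_minus_r2 = np.clip(1.0 - r**2, _DET_FLOOR, None)
    mi = -0.5 * np.log(one_minus_r2)
    mi = np.clip(mi, 0.0, mi_cap)
    mi[constant, :] = 0.0
    mi[:, constant] = 0.0
    out = pd.DataFrame(mi, index=expr.index, columns=expr.index)
    np.fill_diagonal(out.values, np.nan)
    return out


@dataclass(frozen=True)
class ScreenThresholds:
    """MI thresholds separating low/mid/high dependence.

    Defaults are the values used on the small benchmark networks
    (0.05 for low-regulation, 0.2 for high-regulation).
    """

    theta_low: float = 0.05
    theta_high: float = 0.2

    def __post_init__(self):
        if self.theta_low < 0 or self.theta_high < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.theta_low > self.theta_high:
            raise ValueError(
                f"theta_low ({self.theta_low}) > theta_high ({self.theta_high})"
            )


@dataclass(frozen=True)
class CandidatePartition:
    """Three-way split of a target's candidate regulators by MI class.

    The classes are disjoint and exhaustive over the candidates:
    ``low`` = MI in [0, theta_low), ``mid`` = [theta_low, theta_high),
    ``high`` = [theta_high, inf).  ``mid | high`` is the regression candidate
    set; ``high`` is the enhancement set.
    """

    target: str
    low: frozenset = field(default_factory=frozenset)
    mid: frozenset = field(default_factory=frozenset)
    high: frozenset = field(default_factory=frozenset)

    @property
    def candidates(self) -> frozenset:
        """Regulators admitted to the regression (mid plus high)."""
        return self.mid | self.high


def classify_candidates(
    mi: pd.DataFrame,
    target: str,
    thresholds: ScreenThresholds | None = None,
    candidates=None,
) -> CandidatePartition:
    """Partition a target's candidate regulators into low/mid/high MI classes.

    Parameters
    ----------
    mi : DataFrame
        Symmetric MI matrix from :func:`mi_matrix`.
    target : gene id
        Must be present in `mi`.
    thresholds : ScreenThresholds
        Class boundaries; half-open intervals, boundary values round up
        (MI == theta_low is mid, MI == theta_high is high).
    candidates : iterable of gene ids, optional
        Restrict to this regulator set (the target itself is always
        excluded); defaults to every other gene in the matrix.
    """
    if thresholds is None:
        thresholds = ScreenThresholds()
    if target not in mi.index:
        raise KeyError(f"target {target!r} not in MI matrix")
    if candidates is None:
        candidates = [g for g in mi.index if g != target]
    else:
        candidates = [g for g in candidates if g != target]
        missing = sorted(set(candidates) - set(mi.index))
        if missing:
            raise KeyError(f"candidates absent from MI matrix: {missing}")

    low, mid, high = set(), set(), set()
    col = mi.loc[candidates, target] if candidates else pd.Series(dtype=float)
    for gene, value in col.items():
        if value >= thresholds.theta_high:
            high.add(gene)
        elif value >= thresholds.theta_low:
            mid.add(gene)
        else:
            low.add(gene)
    return CandidatePartition(
        target=target, low=frozenset(low), mid=frozenset(mid), high=frozenset(high)
    )
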