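"""Closed-form bounds on sufficient-cause interactions from profile risks.

Under the sufficient-component-cause model with two categorical exposures,
the completion risk of an interaction class (the probability that a causal
pie requiring both exposures is completed during follow-up) is not
identified by the observable profile risks.  Under the no-redundancy
assumption — at most one class of sufficient causes can be completed in any
infinitesimally short interval — it is sharply *bounded*:

* specific class ``(i, j)``::

      LB_ij = 1 - min over i' != i, j' != j of
              min{ (1 - R_ij) / ((1 - R_i'j)(1 - R_ij')), 1 }
      UB_ij = R_ij

  with relative prevalence ``RP_ij`` (completion risk over profile risk)
  bounded below by ``LB_ij / R_ij`` and above by 1;

* global (any interaction class)::

      LB = 1 - min over contrast pairs (u, v) of
           min{ prod_ij (1 - R_ij)^(u_i v_j), 1 }
      UB = 1 - prod_ij (1 - R_ij)

  with ``RP`` bounded below by ``LB / UB`` and above by 1.  Here the
  denominator of the global RP is the completion risk of *any* class, whose
  observable value is exactly ``UB``.

For 2x2 designs the global lower bound collapses to
``1 - min(PRISM, 1/PRISM)`` with PRISM the cross-ratio of survival
probabilities (the peril ratio index of synergy based on multiplicativity);
this equivalence is used as a consistency check, not as a separate code
path.

Boundary conventions (risks equal to 0 or 1) are the continuous limits of
the formulas: a zero denominator factor makes that comparison uninformative
(the capped term contributes 1); a zero numerator with positive denominator
drives the bound to 1.  Signed products are accumulated in log space so
that large grids cannot overflow.

All public functions take 1-based level indices or level labels; the
``*_arr`` helpers operate on bare arrays with arbitrary leading batch
dimensions and back both the public API and the bootstrap.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np

from .contrasts import contrast_pairs
from .types import BoundsResult, Level, RiskMatrix

__all__ = [
    "specific_risk_lb",
    "specific_risk_ub",
    "specific_rp_lb",
    "global_risk_lb",
    "global_risk_lb_detail",
    "global_risk_ub",
    "global_rp_lb",
    "prism",
    "sjolander_specific_lb",
    "all_bounds",
]


# ---------------------------------------------------------------------------
# array core (batched; leading dimensions broadcast)

def _excluded_extreme(x: np.ndarray, axis: int, exclude: int, mode: str) -> np.ndarray:
    """Max or min of ``x`` along ``axis`` with one index left out."""
    sl = [slice(None)] * x.ndim
    sl[axis] = [k for k in range(x.shape[axis]) if k != exclude]
    sub = x[tuple(sl)]
    return sub.max(axis=axis) if mode == "max" else sub.min(axis=axis)


def specific_risk_lb_arr(R: np.ndarray) -> np.ndarray:
    """Specific-class lower bounds for every ``(i, j)``; shape preserved.

    The minimum over comparison profiles separates: the smallest ratio uses
    the largest survival product, so for each target cell only the largest
    competing survival on its row and column is needed.
    """
    R = np.asarray(R, float)
    S = 1.0 - R
    out = np.zeros_like(R)
    L1, L2 = R.shape[-2:]
    for i in range(L1):
        for j in range(L2):
            num = S[..., i, j]
            den = (
                _excluded_extreme(S[..., :, j], -1, i, "max")
                * _excluded_extreme(S[..., i, :], -1, j, "max")
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = num / den
            # zero denominator: every comparison has a sure-risk profile on
            # the row or column -> uninformative, capped ratio is 1
            ratio = np.where(den > 0.0, ratio, 1.0)
            out[..., i, j] = 1.0 - np.minimum(ratio, 1.0)
    return out


def sjolander_specific_lb_arr(R: np.ndarray) -> np.ndarray:
    """Assumption-free specific lower bounds (additive-scale contrast)."""
    R = np.asarray(R, float)
    out = np.zeros_like(R)
    L1, L2 = R.shape[-2:]
    for i in range(L1):
        for j in range(L2):
            best = (
                R[..., i, j]
                - _excluded_extreme(R[..., :, j], -1, i, "min")
                - _excluded_extreme(R[..., i, :], -1, j, "min")
            )
            out[..., i, j] = np.maximum(best, 0.0)
    return out


def global_risk_lb_arr(
    R: np.ndarray, return_argmin: bool = False
) -> np.ndarray | tuple[np.ndarray, tuple[tuple[int, ...], tuple[int, ...]]]:
    """Global lower bound via the contrast minimisation, in log space.

    A survival probability of zero (risk exactly 1) with a positive
    exponent sends the signed product to 0; with a negative exponent the
    product diverges and the capped term is uninformative (1).  A pair
    containing both kinds is treated as uninformative.
    """
    R = np.asarray(R, float)
    S = 1.0 - R
    L1, L2 = R.shape[-2:]
    with np.errstate(divide="ignore"):
        logS = np.log(S)
    zero = S == 0.0
    safe_logS = np.where(zero, 0.0, logS)

    best = np.ones(R.shape[:-2])
    best_pair = None
    for u, v in contrast_pairs(L1, L2):
        E = np.outer(u, v).astype(float)
        ssum = np.einsum("...ij,ij->...", safe_logS, E)
        prod = np.minimum(np.exp(ssum), 1.0)
        if zero.any():
            pos0 = np.any(zero & (E > 0), axis=(-2, -1))
            neg0 = np.any(zero & (E < 0), axis=(-2, -1))
            prod = np.where(pos0 & ~neg0, 0.0, prod)
            prod = np.where(neg0, 1.0, prod)
        if return_argmin:
            if best_pair is None or prod < best:
                best_pair = (u, v)
        best = np.minimum(best, prod)
    lb = 1.0 - best
    if return_argmin:
        return lb, best_pair
    return lb


def global_risk_ub_arr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, float)
    return 1.0 - np.prod(1.0 - R, axis=(-2, -1))


def global_rp_lb_arr(R: np.ndarray) -> np.ndarray:
    lb = global_risk_lb_arr(R)
    ub = global_risk_ub_arr(R)
    with np.errstate(invalid="ignore", divide="ignore"):
        rp = lb / ub
    return np.where(ub > 0.0, rp, 0.0)


def specific_rp_lb_arr(R: np.ndarray) -> np.ndarray:
    R = np.asarray(R, float)
    lb = specific_risk_lb_arr(R)
    with np.errstate(invalid="ignore", divide="ignore"):
        rp = lb / R
    return np.where(R > 0.0, rp, 0.0)


# ---------------------------------------------------------------------------
# public API on RiskMatrix

def _warn_sure_risks(risks: RiskMatrix) -> None:
    if np.any(risks.values == 1.0):
        warnings.warn(
            "some profile risks equal 1 exactly; bounds use the continuous-"
            "limit conventions for zero survival probabilities",
            RuntimeWarning,
            stacklevel=3,
        )


def specific_risk_lb(risks: RiskMatrix, i: Level, j: Level) -> float:
    """Sharp lower bound on the completion risk of interaction class (i, j)."""
    a, b = risks.index(i, j)
    _warn_sure_risks(risks)
    return float(specific_risk_lb_arr(risks.values)[a, b])


def specific_risk_ub(risks: RiskMatrix, i: Level, j: Level) -> float:
    """Sharp upper bound: the profile risk itself."""
    return risks.risk(i, j)


def specific_rp_lb(risks: RiskMatrix, i: Level, j: Level) -> float:
    """Lower bound on the relative prevalence of class (i, j).

    Zero when the profile risk is zero (the numerator bound is then zero
    too); the upper bound on relative prevalence is identically 1.
    """
    a, b = risks.index(i, j)
    _warn_sure_risks(risks)
    return float(specific_rp_lb_arr(risks.values)[a, b])


def global_risk_lb(risks: RiskMatrix) -> float:
    """Sharp lower bound on the completion risk of any interaction class."""
    _warn_sure_risks(risks)
    return float(global_risk_lb_arr(risks.values))


def global_risk_lb_detail(
    risks: RiskMatrix,
) -> tuple[float, tuple[tuple[int, ...], tuple[int, ...]]]:
    """Global lower bound together with the minimising contrast pair.

    Ties are broken by the lexicographic enumeration order, so the reported
    pair is deterministic.
    """
    _warn_sure_risks(risks)
    lb, pair = global_risk_lb_arr(risks.values, return_argmin=True)
    return float(lb), pair


def global_risk_ub(risks: RiskMatrix) -> float:
    """Upper bound: one minus the product of all survival probabilities."""
    return float(global_risk_ub_arr(risks.values))


def global_rp_lb(risks: RiskMatrix) -> float:
    """Lower bound on the global relative prevalence (LB / UB; 0 if UB = 0)."""
    _warn_sure_risks(risks)
    return float(global_rp_lb_arr(risks.values))


def prism(risks: RiskMatrix) -> float:
    """Peril ratio index of synergy based on multiplicativity (2x2 only).

    ``PRISM = (1-R_21)(1-R_12) / ((1-R_22)(1-R_11))``; equals 1 under
    multiplicative survival (rank-1 peril) structure.  Returns ``inf`` when
    the denominator vanishes while the numerator does not.
    """
    if risks.L1 != 2 or risks.L2 != 2:
        raise ValueError(
            f"PRISM requires a 2x2 risk matrix, got {risks.L1}x{risks.L2}"
        )
    S = 1.0 - risks.values
    num = S[1, 0] * S[0, 1]
    den = S[1, 1] * S[0, 0]
    if den == 0.0:
        return float("inf") if num > 0.0 else float("nan")
    return float(num / den)


def sjolander_specific_lb(risks: RiskMatrix, i: Level, j: Level) -> float:
    """Assumption-free lower bound of Sjölander et al. for class (i, j).

    ``max over i' != i, j' != j of max{ R_ij - R_i'j - R_ij', 0 }`` — valid
    without the no-redundancy assumption but never sharper than
    :func:`specific_risk_lb`.  Provided for comparison and reporting.
    """
    a, b = risks.index(i, j)
    return float(sjolander_specific_lb_arr(risks.values)[a, b])


def all_bounds(risks: RiskMatrix) -> BoundsResult:
    """Every specific and global bound assembled into one result."""
    _warn_sure_risks(risks)
    R = risks.values
    return BoundsResult(
        scale="risk",
        level_labels_1=risks.level_labels_1,
        level_labels_2=risks.level_labels_2,
        specific_risk_lb=specific_risk_lb_arr(R),
        specific_risk_ub=R.copy(),
        specific_rp_lb=specific_rp_lb_arr(R),
        specific_rp_ub=np.ones_like(R),
        global_risk_lb=float(global_risk_lb_arr(R)),
        global_risk_ub=float(global_risk_ub_arr(R)),
        global_rp_lb=float(global_rp_lb_arr(R)),
        global_rp_ub=1.0,
    )
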