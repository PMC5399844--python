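"""Odds-ratio-scale bounds for case-control data under a rare disease.

When profile risks are uniformly small, survival probabilities are near 1
and the risk-scale bounds linearise: ratios of risks are approximated by
ratios of odds, which a case-control study estimates directly.  The
relative-prevalence lower bounds become

* specific class ``(i, j)``::

      RP_LB_ij ~= max over i' != i, j' != j of
                  max{ OR_ij - OR_i'j - OR_ij', 0 } / OR_ij

* global::

      RP_LB ~= max over contrast pairs (u, v) of
               max{ sum_ij u_i v_j OR_ij, 0 } / sum_ij OR_ij

where ``OR_ij`` is the odds ratio of profile ``(i, j)`` against the
reference profile ``(1, 1)``.  For 2x2 designs the global bound reduces to
``|RERI| / (OR_22 + OR_21 + OR_12 + 1)`` with
``RERI = OR_22 - OR_21 - OR_12 + 1`` the relative excess risk due to
interaction.  Completion risks themselves are not identified on this scale,
only relative prevalences; the relative-prevalence upper bound remains 1.

These are rare-disease approximations: no attempt is made to undo the
approximation with sampling fractions.
"""

from __future__ import annotations

import numpy as np

from .contrasts import contrast_pairs
from .risk_bounds import _excluded_extreme
from .types import BoundsResult, CaseControlTable, Level, ORMatrix

__all__ = [
    "odds_ratios",
    "specific_rp_lb_or",
    "global_rp_lb_or",
    "reri",
    "all_bounds_or",
]


def odds_ratios(
    table: CaseControlTable, continuity_correction: bool = False
) -> ORMatrix:
    """Per-profile odds ratios relative to the reference profile (1, 1).

    ``OR_ij = (cases_ij / controls_ij) / (cases_11 / controls_11)``.

    A zero count anywhere among the four numbers entering an odds ratio is
    an error unless ``continuity_correction`` is set, in which case 0.5 is
    added to all four counts of that cell's 2x2 comparison against the
    reference (Haldane–Anscombe).  The correction is applied per affected
    cell only, so cells with complete data reproduce their uncorrected odds
    ratios exactly.
    """
    a = table.case_counts.astype(float)
    b = table.control_counts.astype(float)
    ref = (a[0, 0], b[0, 0])
    vals = np.empty_like(a)
    for i in range(table.L1):
        for j in range(table.L2):
            four = np.array([a[i, j], b[i, j], ref[0], ref[1]], float)
            if np.any(four == 0.0):
                if not continuity_correction:
                    raise ValueError(
                        "zero count in profile "
                        f"({table.level_labels_1[i]}, {table.level_labels_2[j]}) "
                        "or the reference cell; enable the continuity "
                        "correction or amend the data"
                    )
                four = four + 0.5
            vals[i, j] = (four[0] / four[1]) / (four[2] / four[3])
    vals[0, 0] = 1.0  # exact by construction; guard against rounding
    return ORMatrix(vals, table.level_labels_1, table.level_labels_2)


# ---------------------------------------------------------------------------
# array core (batched), used by the bootstrap as well

def specific_rp_lb_or_arr(OR: np.ndarray) -> np.ndarray:
    """Specific RP lower bounds for every cell of an OR array (batched).

    The inner maximum separates: the best comparison uses the smallest
    competing odds ratio on the target's row and column.  Cells with a zero
    odds ratio (possible only in bootstrap resamples) get bound 0.
    """
    OR = np.asarray(OR, float)
    out = np.zeros_like(OR)
    L1, L2 = OR.shape[-2:]
    for i in range(L1):
        for j in range(L2):
            num = (
                OR[..., i, j]
                - _excluded_extreme(OR[..., :, j], -1, i, "min")
                - _excluded_extreme(OR[..., i, :], -1, j, "min")
            )
            num = np.maximum(num, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                rp = num / OR[..., i, j]
            out[..., i, j] = np.where(OR[..., i, j] > 0.0, rp, 0.0)
    return out


def global_rp_lb_or_arr(OR: np.ndarray) -> np.ndarray:
    OR = np.asarray(OR, float)
    L1, L2 = OR.shape[-2:]
    best = np.zeros(OR.shape[:-2])
    for u, v in contrast_pairs(L1, L2):
        E = np.outer(u, v).astype(float)
        best = np.maximum(best, np.einsum("...ij,ij->...", OR, E))
    return best / OR.sum(axis=(-2, -1))


# ---------------------------------------------------------------------------
# public API

def specific_rp_lb_or(ors: ORMatrix, i: Level, j: Level) -> float:
    """Rare-disease lower bound on the relative prevalence of class (i, j)."""
    a, b = ors.index(i, j)
    return float(specific_rp_lb_or_arr(ors.values)[a, b])


def global_rp_lb_or(ors: ORMatrix) -> float:
    """Rare-disease lower bound on the global relative prevalence."""
    return float(global_rp_lb_or_arr(ors.values))


def reri(ors: ORMatrix) -> float:
    """Relative excess risk due to interaction, ``OR_22 - OR_21 - OR_12 + 1``.

    Defined for 2x2 designs only; zero under odds-ratio additivity and
    equal to ``OR_21 * OR_12 - OR_21 - OR_12 + 1`` under multiplicativity.
    """
    if ors.L1 != 2 or ors.L2 != 2:
        raise ValueError(f"RERI requires a 2x2 OR matrix, got {ors.L1}x{ors.L2}")
    v = ors.values
    return float(v[1, 1] - v[1, 0] - v[0, 1] + 1.0)


def all_bounds_or(ors: ORMatrix) -> BoundsResult:
    """Every identified odds-ratio-scale bound in one result.

    Only relative-prevalence lower bounds are identified from case-control
    data; risk-scale fields are left unset.
    """
    OR = ors.values
    return BoundsResult(
        scale="odds-ratio",
        level_labels_1=ors.level_labels_1,
        level_labels_2=ors.level_labels_2,
        specific_rp_lb=specific_rp_lb_or_arr(OR),
        specific_rp_ub=np.ones_like(OR),
        global_rp_lb=float(global_rp_lb_or_arr(OR)),
        global_rp_ub=1.0,
    )
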