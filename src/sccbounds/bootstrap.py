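"""Nonparametric bootstrap confidence limits for the interaction bounds.

One limit is attached to each bounded quantity: a lower confidence limit
(LCL) for every lower bound and an upper confidence limit (UCL) for every
upper bound.  Limits are percentile-bootstrap quantiles and, by default,
one-sided: the 95% LCL is the 5th percentile of a bound's replicate
distribution and the 95% UCL the 95th percentile (``two_sided=True``
switches to the 2.5th / 97.5th).

Resampling respects each design's conditioning:

* cohort — exposure-profile totals are design constants, so case counts
  are redrawn per profile as ``Binomial(n_ij, cases_ij / n_ij)``;
* case-control — the case and control sample sizes are fixed by design,
  so profile counts are redrawn as two independent multinomials (one over
  cases, one over controls).

Case-control replicates in which a resampled cell makes some odds ratio
undefined (a zero control count, or an empty reference cell) are dropped
and counted; a warning is raised when more than 1% are lost, since the
quantiles then condition on a non-trivial selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import or_bounds, risk_bounds
from .types import BoundsResult, CaseControlTable, CohortTable

__all__ = ["BootstrapConfig", "bootstrap_cohort", "bootstrap_casecontrol"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the percentile bootstrap.

    ``replicates`` defaults to 10,000 and ``alpha`` to 0.05, giving 95%
    one-sided limits.  ``seed`` feeds a single NumPy generator; identical
    input and config give bit-identical limits.
    """

    replicates: int = 10_000
    alpha: float = 0.05
    seed: Optional[int] = None
    two_sided: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def lower_q(self) -> float:
        return self.alpha / 2 if self.two_sided else self.alpha

    @property
    def upper_q(self) -> float:
        return 1 - self.alpha / 2 if self.two_sided else 1 - self.alpha


def _meta(config: BootstrapConfig, design: str, dropped: int = 0) -> dict:
    return {
        "design": design,
        "replicates": config.replicates,
        "alpha": config.alpha,
        "seed": config.seed,
        "two_sided": config.two_sided,
        "dropped_replicates": dropped,
    }


def bootstrap_cohort(table: CohortTable, config: BootstrapConfig) -> BoundsResult:
    """Point bounds plus bootstrap confidence limits for a cohort table."""
    if np.any(table.totals == 0):
        raise ValueError("every profile must have a positive total")
    risks = table.risk_matrix()
    result = risk_bounds.all_bounds(risks)

    rng = np.random.default_rng(config.seed)
    B = config.replicates
    n = table.totals
    draws = rng.binomial(n, risks.values, size=(B,) + n.shape)
    Rb = draws / n  # (B, L1, L2) replicate risk matrices

    spec_lb = risk_bounds.specific_risk_lb_arr(Rb)
    spec_rp_lb = risk_bounds.specific_rp_lb_arr(Rb)
    glob_lb = risk_bounds.global_risk_lb_arr(Rb)
    glob_ub = risk_bounds.global_risk_ub_arr(Rb)
    with np.errstate(invalid="ignore", divide="ignore"):
        glob_rp = np.where(glob_ub > 0.0, glob_lb / glob_ub, 0.0)

    lq, uq = config.lower_q, config.upper_q
    result.specific_risk_lb_lcl = np.quantile(spec_lb, lq, axis=0)
    result.specific_risk_ub_ucl = np.quantile(Rb, uq, axis=0)
    result.specific_rp_lb_lcl = np.quantile(spec_rp_lb, lq, axis=0)
    result.global_risk_lb_lcl = float(np.quantile(glob_lb, lq))
    result.global_risk_ub_ucl = float(np.quantile(glob_ub, uq))
    result.global_rp_lb_lcl = float(np.quantile(glob_rp, lq))
    result.bootstrap = _meta(config, "cohort")
    return result


def bootstrap_casecontrol(
    table: CaseControlTable,
    config: BootstrapConfig,
    continuity_correction: bool = False,
) -> BoundsResult:
    """Point bounds plus bootstrap confidence limits for case-control data.

    The point estimates honour ``continuity_correction``; replicates never
    apply it — degenerate resamples are dropped instead, so corrections
    cannot contaminate the quantiles silently.
    """
    ors = or_bounds.odds_ratios(table, continuity_correction=continuity_correction)
    result = or_bounds.all_bounds_or(ors)

    rng = np.random.default_rng(config.seed)
    B = config.replicates
    shape = table.case_counts.shape
    p_case = table.case_counts.ravel() / table.n_cases
    p_ctrl = table.control_counts.ravel() / table.n_controls
    cases = rng.multinomial(table.n_cases, p_case, size=B).reshape((B,) + shape)
    ctrls = rng.multinomial(table.n_controls, p_ctrl, size=B).reshape((B,) + shape)

    # odds ratios need every control count and the reference cell non-zero
    ok = (
        np.all(ctrls > 0, axis=(1, 2))
        & (cases[:, 0, 0] > 0)
    )
    dropped = int(B - ok.sum())
    if dropped == B:
        raise ValueError("every bootstrap replicate was degenerate")
    if dropped > 0.01 * B:
        msg = (
            f"{dropped} of {B} bootstrap replicates dropped because an odds "
            "ratio was undefined; confidence limits condition on the rest"
        )
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
        result.warnings.append(msg)

    cases = cases[ok].astype(float)
    ctrls = ctrls[ok].astype(float)
    odds = cases / ctrls
    ORb = odds / odds[:, 0, 0][:, None, None]

    lq = config.lower_q
    result.specific_rp_lb_lcl = np.quantile(
        or_bounds.specific_rp_lb_or_arr(ORb), lq, axis=0
    )
    result.global_rp_lb_lcl = float(np.quantile(or_bounds.global_rp_lb_or_arr(ORb), lq))
    result.bootstrap = _meta(config, "case-control", dropped)
    return result
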