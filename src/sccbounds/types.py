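"""Domain containers for sufficient-cause interaction analysis.

Two categorical exposures ``X1`` (levels ``1..L1``) and ``X2`` (levels
``1..L2``) and a binary outcome observed over a fixed follow-up window define
an ``L1 x L2`` grid of exposure *profiles*.  Everything in this package is a
function of the per-profile summary data:

* a :class:`CohortTable` (cases and totals per profile) for cohort designs,
* a :class:`CaseControlTable` (cases and controls per profile) otherwise,

together with their derived :class:`RiskMatrix` / :class:`ORMatrix`.

Exposure levels are 1-based in every public signature, matching the usual
``profile = i, j`` notation of the sufficient-component-cause literature;
level labels (strings) are accepted everywhere an index is, and the first
level on each axis is the reference profile ``(1, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional, Sequence, Union

import numpy as np

__all__ = [
    "RiskMatrix",
    "CohortTable",
    "CaseControlTable",
    "ORMatrix",
    "BoundsResult",
    "Level",
]

#: A 1-based level index or a level label.
Level = Union[int, str]


def _as_labels(labels: Sequence[str] | None, L: int, axis: int) -> tuple[str, ...]:
    if labels is None:
        labels = tuple(str(k) for k in range(1, L + 1))
    labels = tuple(str(x) for x in labels)
    if len(labels) != L:
        raise ValueError(
            f"axis {axis}: expected {L} level labels, got {len(labels)}"
        )
    if len(set(labels)) != len(labels):
        raise ValueError(f"axis {axis}: duplicate level labels in {labels!r}")
    return labels


def _resolve_level(level: Level, labels: tuple[str, ...], axis: int) -> int:
    """Map a 1-based index or a label to a 0-based index."""
    if isinstance(level, str):
        try:
            return labels.index(level)
        except ValueError:
            raise ValueError(
                f"axis {axis}: unknown level {level!r}; known levels are {labels}"
            ) from None
    k = int(level)
    if not 1 <= k <= len(labels):
        raise ValueError(
            f"axis {axis}: level index {k} out of range 1..{len(labels)}"
        )
    return k - 1


class _Grid:
    """Mixin for L1 x L2 containers with labelled levels."""

    level_labels_1: tuple[str, ...]
    level_labels_2: tuple[str, ...]

    @property
    def L1(self) -> int:
        return len(self.level_labels_1)

    @property
    def L2(self) -> int:
        return len(self.level_labels_2)

    def index(self, i: Level, j: Level) -> tuple[int, int]:
        """0-based (row, col) for 1-based indices or labels ``(i, j)``."""
        return (
            _resolve_level(i, self.level_labels_1, axis=1),
            _resolve_level(j, self.level_labels_2, axis=2),
        )

    def profiles(self):
        """Iterate ``(label1, label2)`` pairs in row-major grid order."""
        for a in self.level_labels_1:
            for b in self.level_labels_2:
                yield a, b


@dataclass(frozen=True)
class RiskMatrix(_Grid):
    """Cumulative disease risks per exposure profile.

    ``values[i-1, j-1]`` is ``Pr(D = 1 | X1 = i, X2 = j)`` over the study
    window ``(0, T)`` — an ``L1 x L2`` matrix with every entry in ``[0, 1]``.
    """

    values: np.ndarray
    level_labels_1: tuple[str, ...] = None  # type: ignore[assignment]
    level_labels_2: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(
                f"risk matrix must be at least 2x2, got shape {v.shape}"
            )
        if not np.all(np.isfinite(v)) or v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("risks must all lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self, "level_labels_1", _as_labels(self.level_labels_1, v.shape[0], 1)
        )
        object.__setattr__(
            self, "level_labels_2", _as_labels(self.level_labels_2, v.shape[1], 2)
        )

    def risk(self, i: Level, j: Level) -> float:
        a, b = self.index(i, j)
        return float(self.values[a, b])

    def permute(self, order1: Sequence[int], order2: Sequence[int]) -> "RiskMatrix":
        """Reorder exposure levels (0-based permutations of each axis)."""
        o1, o2 = list(order1), list(order2)
        return RiskMatrix(
            self.values[np.ix_(o1, o2)],
            tuple(self.level_labels_1[k] for k in o1),
            tuple(self.level_labels_2[k] for k in o2),
        )


@dataclass(frozen=True)
class CohortTable(_Grid):
    """Aggregate cohort data: case counts and population totals per profile."""

    cases: np.ndarray
    totals: np.ndarray
    level_labels_1: tuple[str, ...] = None  # type: ignore[assignment]
    level_labels_2: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        c = np.asarray(self.cases)
        n = np.asarray(self.totals)
        if c.shape != n.shape or c.ndim != 2:
            raise ValueError(
                f"cases and totals must be equal-shape 2-D arrays, "
                f"got {c.shape} and {n.shape}"
            )
        for name, arr in (("cases", c), ("totals", n)):
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.all(np.asarray(arr, float) == np.round(np.asarray(arr, float))):
                    raise ValueError(f"{name} must be integers")
            if np.any(np.asarray(arr) < 0):
                raise ValueError(f"{name} must be non-negative")
        c = c.astype(np.int64)
        n = n.astype(np.int64)
        if np.any(c > n):
            raise ValueError("cases exceed totals in at least one profile")
        object.__setattr__(self, "cases", c)
        object.__setattr__(self, "totals", n)
        object.__setattr__(
            self, "level_labels_1", _as_labels(self.level_labels_1, c.shape[0], 1)
        )
        object.__setattr__(
            self, "level_labels_2", _as_labels(self.level_labels_2, c.shape[1], 2)
        )

    @property
    def cohort_size(self) -> int:
        return int(self.totals.sum())

    def risk_matrix(self) -> RiskMatrix:
        """Empirical risks ``cases / totals`` (requires every total > 0)."""
        if np.any(self.totals == 0):
            bad = np.argwhere(self.totals == 0)[0]
            raise ValueError(
                "profile "
                f"({self.level_labels_1[bad[0]]}, {self.level_labels_2[bad[1]]}) "
                "has zero total; risks are undefined"
            )
        return RiskMatrix(
            self.cases / self.totals, self.level_labels_1, self.level_labels_2
        )


@dataclass(frozen=True)
class CaseControlTable(_Grid):
    """Aggregate case-control data: case and control counts per profile.

    The reference profile ``(1, 1)`` (first level on each axis) must have at
    least one case and one control, otherwise no odds ratio is defined.
    Zeros elsewhere are tolerated at construction; the odds-ratio step
    rejects them unless a continuity correction is requested.
    """

    case_counts: np.ndarray
    control_counts: np.ndarray
    level_labels_1: tuple[str, ...] = None  # type: ignore[assignment]
    level_labels_2: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        a = np.asarray(self.case_counts)
        b = np.asarray(self.control_counts)
        if a.shape != b.shape or a.ndim != 2 or a.shape[0] < 2 or a.shape[1] < 2:
            raise ValueError(
                f"case and control counts must be equal-shape 2-D (>=2x2) arrays, "
                f"got {a.shape} and {b.shape}"
            )
        for name, arr in (("case_counts", a), ("control_counts", b)):
            arrf = np.asarray(arr, float)
            if not np.all(arrf == np.round(arrf)) or np.any(arrf < 0):
                raise ValueError(f"{name} must be non-negative integers")
        a = a.astype(np.int64)
        b = b.astype(np.int64)
        if a[0, 0] == 0 or b[0, 0] == 0:
            raise ValueError(
                "reference profile (1, 1) needs at least one case and one "
                "control for odds ratios to be defined"
            )
        object.__setattr__(self, "case_counts", a)
        object.__setattr__(self, "control_counts", b)
        object.__setattr__(
            self, "level_labels_1", _as_labels(self.level_labels_1, a.shape[0], 1)
        )
        object.__setattr__(
            self, "level_labels_2", _as_labels(self.level_labels_2, a.shape[1], 2)
        )

    @property
    def n_cases(self) -> int:
        return int(self.case_counts.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_counts.sum())


@dataclass(frozen=True)
class ORMatrix(_Grid):
    """Odds ratios relative to the reference profile ``(1, 1)``.

    All entries are positive and ``values[0, 0] == 1`` exactly.
    """

    values: np.ndarray
    level_labels_1: tuple[str, ...] = None  # type: ignore[assignment]
    level_labels_2: tuple[str, ...] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(f"OR matrix must be at least 2x2, got shape {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("odds ratios must be positive and finite")
        if v[0, 0] != 1.0:
            raise ValueError("reference entry (1, 1) must equal 1 exactly")
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self, "level_labels_1", _as_labels(self.level_labels_1, v.shape[0], 1)
        )
        object.__setattr__(
            self, "level_labels_2", _as_labels(self.level_labels_2, v.shape[1], 2)
        )


@dataclass
class BoundsResult:
    """Bounds on sufficient-cause interactions, with optional bootstrap limits.

    Specific (per-interaction-class) quantities are ``L1 x L2`` matrices
    indexed like the input grid; global quantities are scalars.  On the risk
    scale every field is populated; on the odds-ratio (case-control) scale
    only the relative-prevalence lower bounds are identified and the
    risk-scale fields are ``None``.

    Confidence limits, when present, are one per bounded quantity: a lower
    confidence limit for each lower bound and an upper confidence limit for
    each upper bound.
    """

    scale: str  # "risk" or "odds-ratio"
    level_labels_1: tuple[str, ...]
    level_labels_2: tuple[str, ...]

    specific_risk_lb: Optional[np.ndarray] = None
    specific_risk_ub: Optional[np.ndarray] = None
    specific_rp_lb: Optional[np.ndarray] = None
    specific_rp_ub: Optional[np.ndarray] = None  # identically 1, kept for symmetry
    global_risk_lb: Optional[float] = None
    global_risk_ub: Optional[float] = None
    global_rp_lb: Optional[float] = None
    global_rp_ub: Optional[float] = None  # identically 1

    # bootstrap confidence limits (None unless bootstrapped)
    specific_risk_lb_lcl: Optional[np.ndarray] = None
    specific_risk_ub_ucl: Optional[np.ndarray] = None
    specific_rp_lb_lcl: Optional[np.ndarray] = None
    global_risk_lb_lcl: Optional[float] = None
    global_risk_ub_ucl: Optional[float] = None
    global_rp_lb_lcl: Optional[float] = None

    bootstrap: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scale not in ("risk", "odds-ratio"):
            raise ValueError(f"scale must be 'risk' or 'odds-ratio', got {self.scale!r}")

    def to_dict(self) -> dict[str, Any]:
        """Plain-python representation (full precision, JSON-serialisable)."""

        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        out: dict[str, Any] = {
            "scale": self.scale,
            "levels_1": list(self.level_labels_1),
            "levels_2": list(self.level_labels_2),
        }
        for name in (
            "specific_risk_lb", "specific_risk_ub", "specific_rp_lb",
            "specific_rp_ub", "global_risk_lb", "global_risk_ub",
            "global_rp_lb", "global_rp_ub", "specific_risk_lb_lcl",
            "specific_risk_ub_ucl", "specific_rp_lb_lcl",
            "global_risk_lb_lcl", "global_risk_ub_ucl", "global_rp_lb_lcl",
        ):
            val = getattr(self, name)
            if val is not None:
                out[name] = conv(val)
        if self.bootstrap:
            out["bootstrap"] = dict(self.bootstrap)
        if self.warnings:
            out["warnings"] = list(self.warnings)
        return out
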