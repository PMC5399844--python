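"""CSV input, report assembly and rendering.

Input dialect: comma-separated UTF-8 with a header.  Cohort files carry
columns ``x1, x2, cases, total`` and case-control files
``x1, x2, cases, controls``, one row per exposure profile, every profile of
the L1 x L2 grid present exactly once.  Levels are arbitrary strings,
ordered by first appearance unless an explicit ordering is supplied; the
first level on each axis defines the reference profile ``(1, 1)``.

Reports round to 4 decimals in the human-readable table only; JSON and CSV
renderings carry full precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .types import BoundsResult, CaseControlTable, CohortTable

__all__ = [
    "read_cohort_csv",
    "read_casecontrol_csv",
    "write_cohort_csv",
    "write_casecontrol_csv",
    "AnalysisReport",
]


def _read_grid_csv(
    path,
    value_cols: list[str],
    levels_1: Optional[Sequence[str]],
    levels_2: Optional[Sequence[str]],
):
    df = pd.read_csv(path, dtype={"x1": str, "x2": str})
    missing = [c for c in ("x1", "x2", *value_cols) if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")

    counts = {}
    for col in value_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() | (vals != np.floor(vals)) | (vals < 0)]
        if len(bad):
            raise ValueError(
                f"{path} row {bad[0] + 2}: column {col!r} must be a "
                "non-negative integer"
            )
        counts[col] = vals.astype(np.int64)

    seen = {}
    for idx, (a, b) in enumerate(zip(df["x1"], df["x2"])):
        if (a, b) in seen:
            raise ValueError(
                f"{path} row {idx + 2}: duplicate profile ({a}, {b}) "
                f"(first at row {seen[(a, b)] + 2})"
            )
        seen[(a, b)] = idx

    lv1 = list(dict.fromkeys(df["x1"])) if levels_1 is None else list(levels_1)
    lv2 = list(dict.fromkeys(df["x2"])) if levels_2 is None else list(levels_2)
    unknown = (set(df["x1"]) - set(lv1)) | (set(df["x2"]) - set(lv2))
    if unknown:
        raise ValueError(f"{path}: levels {sorted(unknown)} not in the given ordering")

    grids = {c: np.zeros((len(lv1), len(lv2)), dtype=np.int64) for c in value_cols}
    for a_i, a in enumerate(lv1):
        for b_i, b in enumerate(lv2):
            if (a, b) not in seen:
                raise ValueError(f"{path}: profile ({a}, {b}) is missing")
            row = seen[(a, b)]
            for c in value_cols:
                grids[c][a_i, b_i] = counts[c].iloc[row]
    return grids, tuple(lv1), tuple(lv2), seen


def read_cohort_csv(
    path,
    levels_1: Optional[Sequence[str]] = None,
    levels_2: Optional[Sequence[str]] = None,
) -> CohortTable:
    """Parse a cohort contingency CSV (``x1, x2, cases, total``)."""
    grids, lv1, lv2, seen = _read_grid_csv(path, ["cases", "total"], levels_1, levels_2)
    over = np.argwhere(grids["cases"] > grids["total"])
    if len(over):
        a, b = over[0]
        raise ValueError(
            f"{path} row {seen[(lv1[a], lv2[b])] + 2}: cases exceed total "
            f"in profile ({lv1[a]}, {lv2[b]})"
        )
    return CohortTable(grids["cases"], grids["total"], lv1, lv2)


def read_casecontrol_csv(
    path,
    levels_1: Optional[Sequence[str]] = None,
    levels_2: Optional[Sequence[str]] = None,
) -> CaseControlTable:
    """Parse a case-control contingency CSV (``x1, x2, cases, controls``).

    Zero counts outside the reference cell parse fine; whether they are
    acceptable is decided by the odds-ratio step.
    """
    grids, lv1, lv2, _ = _read_grid_csv(path, ["cases", "controls"], levels_1, levels_2)
    return CaseControlTable(grids["cases"], grids["controls"], lv1, lv2)


def write_cohort_csv(table: CohortTable, path) -> None:
    _grid_frame(table, cases=table.cases, total=table.totals).to_csv(path, index=False)


def write_casecontrol_csv(table: CaseControlTable, path) -> None:
    _grid_frame(
        table, cases=table.case_counts, controls=table.control_counts
    ).to_csv(path, index=False)


def _grid_frame(table, **cols) -> pd.DataFrame:
    rows = []
    for a_i, a in enumerate(table.level_labels_1):
        for b_i, b in enumerate(table.level_labels_2):
            rows.append(
                {"x1": a, "x2": b, **{k: int(v[a_i, b_i]) for k, v in cols.items()}}
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report

def _r4(x: Optional[float]) -> str:
    return "" if x is None else f"{x:.4f}"


@dataclass
class AnalysisReport:
    """Input summary plus bounds, renderable as text table, JSON or CSV.

    The text table mirrors the conventional presentation: one row per
    exposure profile with its counts and point estimate, the bound columns
    (a lower confidence limit ahead of each lower bound, an upper limit
    after each upper bound), and a closing row for the global interaction.
    """

    design: str  # "cohort" or "case-control"
    table: Union[CohortTable, CaseControlTable]
    result: BoundsResult
    settings: dict = field(default_factory=dict)

    def rows(self) -> list[dict]:
        """Per-profile and global rows at full precision (None = not set)."""
        t, r = self.table, self.result
        rows = []
        spec = lambda m, a, b: None if m is None else float(m[a, b])
        for a_i, a in enumerate(t.level_labels_1):
            for b_i, b in enumerate(t.level_labels_2):
                row = {"x1": a, "x2": b}
                if self.design == "cohort":
                    row.update(
                        cases=int(t.cases[a_i, b_i]),
                        total=int(t.totals[a_i, b_i]),
                        risk=float(t.cases[a_i, b_i] / t.totals[a_i, b_i]),
                        risk_lb_lcl=spec(r.specific_risk_lb_lcl, a_i, b_i),
                        risk_lb=spec(r.specific_risk_lb, a_i, b_i),
                        risk_ub=spec(r.specific_risk_ub, a_i, b_i),
                        risk_ub_ucl=spec(r.specific_risk_ub_ucl, a_i, b_i),
                    )
                else:
                    cases = int(t.case_counts[a_i, b_i])
                    ctrls = int(t.control_counts[a_i, b_i])
                    row.update(
                        cases=cases,
                        controls=ctrls,
                        odds=cases / ctrls if ctrls else None,
                    )
                row.update(
                    rp_lb_lcl=spec(r.specific_rp_lb_lcl, a_i, b_i),
                    rp_lb=spec(r.specific_rp_lb, a_i, b_i),
                )
                rows.append(row)
        g = {"x1": "Global", "x2": ""}
        if self.design == "cohort":
            g.update(
                cases=int(t.cases.sum()),
                total=t.cohort_size,
                risk=float(t.cases.sum() / t.cohort_size),
                risk_lb_lcl=r.global_risk_lb_lcl,
                risk_lb=r.global_risk_lb,
                risk_ub=r.global_risk_ub,
                risk_ub_ucl=r.global_risk_ub_ucl,
            )
        else:
            g.update(
                cases=t.n_cases,
                controls=t.n_controls,
                odds=t.n_cases / t.n_controls,
            )
        g.update(rp_lb_lcl=r.global_rp_lb_lcl, rp_lb=r.global_rp_lb)
        rows.append(g)
        return rows

    def _columns(self) -> list[tuple[str, str]]:
        if self.design == "cohort":
            cols = [
                ("cases", "Cases"), ("total", "Total"), ("risk", "Risk"),
                ("risk_lb_lcl", "95% LCL"), ("risk_lb", "LB"),
                ("risk_ub", "UB"), ("risk_ub_ucl", "95% UCL"),
            ]
        else:
            cols = [
                ("cases", "Cases"), ("controls", "Controls"), ("odds", "Odds"),
            ]
        return cols + [("rp_lb_lcl", "RP 95% LCL"), ("rp_lb", "RP LB")]

    def to_text(self) -> str:
        cols = self._columns()
        rows = self.rows()
        head = ["Profile"] + [h for _, h in cols]
        body = []
        for row in rows:
            label = f"({row['x1']}, {row['x2']})" if row["x2"] else row["x1"]
            cells = [label]
            for key, _ in cols:
                v = row.get(key)
                if v is None:
                    cells.append("")
                elif isinstance(v, int):
                    cells.append(str(v))
                else:
                    cells.append(_r4(v))
            body.append(cells)
        widths = [max(len(r[k]) for r in [head] + body) for k in range(len(head))]
        fmt = "  ".join(f"{{:<{w}}}" if k == 0 else f"{{:>{w}}}" for k, w in enumerate(widths))
        lines = [fmt.format(*head), fmt.format(*["-" * w for w in widths])]
        lines += [fmt.format(*r) for r in body]
        if self.result.bootstrap:
            b = self.result.bootstrap
            lines.append(
                f"\nBootstrap: {b['replicates']} replicates, alpha={b['alpha']}"
                + (", two-sided" if b.get("two_sided") else ", one-sided")
                + (f", seed={b['seed']}" if b.get("seed") is not None else "")
                + (f", dropped={b['dropped_replicates']}" if b.get("dropped_replicates") else "")
            )
        for w in self.result.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def to_csv(self) -> str:
        return pd.DataFrame(self.rows()).to_csv(index=False)

    def to_dict(self) -> dict:
        out = {
            "design": self.design,
            "settings": dict(self.settings),
            "rows": self.rows(),
            "bounds": self.result.to_dict(),
        }
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)
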