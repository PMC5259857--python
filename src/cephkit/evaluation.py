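"""Method-comparison statistics for paired automatic vs manual measurements.

The reliability protocol for a computerised cephalometric system measured
against a human tracing of the same cases: per-parameter means and sample
standard deviations for each arm, a paired two-tailed t-test per parameter
(the same cases are measured by both methods, so a paired test is the
appropriate design), the maximum absolute disagreement split by linear and
angular parameters, and a study-level accuracy percentage.

Accuracy is defined as the mean relative absolute agreement,

    accuracy% = 100 * (1 - mean over cells of |auto - manual| / |manual|),

with zero-valued manual cells excluded (and reported).  This definition is
printed alongside the number in every report so it is never mistaken for a
differently-defined figure.

No multiple-testing correction is applied by default; a per-row Bonferroni
adjustment is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "PairedMeasurementTable",
    "ComparisonRow",
    "TTestResult",
    "paired_summary",
    "paired_t_test",
    "max_abs_error",
    "accuracy_percent",
    "compare_tables",
]

PAIRED_COLUMNS = ["parameter", "case", "kind", "unit", "auto", "manual"]


@dataclass
class PairedMeasurementTable:
    """A complete (parameter x case) grid of paired auto/manual values.

    Backed by a long-format DataFrame with columns
    ``parameter, case, kind, unit, auto, manual``.  Construction validates
    that the grid is complete (every parameter appears for every case) and
    free of missing cells.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing_cols = [c for c in PAIRED_COLUMNS if c not in df.columns]
        if missing_cols:
            raise InvalidInputError(f"paired table missing column(s): {missing_cols}")
        df = df[PAIRED_COLUMNS].copy()
        if df[["auto", "manual"]].isna().any().any():
            raise InvalidInputError("paired table contains missing cells")
        counts = df.groupby("parameter", sort=False)["case"].nunique()
        if counts.nunique() > 1:
            raise InvalidInputError(
                "auto and manual grids are ragged: case counts per parameter differ"
            )
        if df.duplicated(["parameter", "case"]).any():
            raise InvalidInputError("duplicate (parameter, case) cells")
        per_param = df.groupby("parameter", sort=False)[["kind", "unit"]].nunique()
        if (per_param > 1).any().any():
            raise InvalidInputError("a parameter carries inconsistent kind/unit labels")
        df["auto"] = df["auto"].astype(float)
        df["manual"] = df["manual"].astype(float)
        self.data = df.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, parameters: Sequence[str], cases: Sequence[str],
                    auto: np.ndarray, manual: np.ndarray,
                    kinds: Sequence[str], units: Sequence[str]) -> "PairedMeasurementTable":
        """Build from (n_parameters x n_cases) value matrices."""
        auto = np.asarray(auto, dtype=float)
        manual = np.asarray(manual, dtype=float)
        shape = (len(parameters), len(cases))
        if auto.shape != shape or manual.shape != shape:
            raise InvalidInputError(
                f"value matrices must have shape {shape}, got {auto.shape}/{manual.shape}"
            )
        rows = []
        for i, p in enumerate(parameters):
            for j, c in enumerate(cases):
                rows.append((p, c, kinds[i], units[i], auto[i, j], manual[i, j]))
        return cls(pd.DataFrame(rows, columns=PAIRED_COLUMNS))

    @property
    def parameters(self) -> List[str]:
        return list(dict.fromkeys(self.data["parameter"]))

    @property
    def cases(self) -> List[str]:
        return list(dict.fromkeys(self.data["case"]))

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def unit_of(self, parameter: str) -> str:
        return self._rows(parameter)["unit"].iloc[0]

    def kind_of(self, parameter: str) -> str:
        return self._rows(parameter)["kind"].iloc[0]

    def _rows(self, parameter: str) -> pd.DataFrame:
        rows = self.data[self.data["parameter"] == parameter]
        if rows.empty:
            raise InvalidInputError(f"unknown parameter {parameter!r}")
        return rows

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PairedMeasurementTable":
        return cls(pd.read_csv(path))


@dataclass
class TTestResult:
    """Paired t-test outcome; ``degenerate`` marks a zero-variance difference."""

    t_stat: float
    p_value: float
    df: int
    degenerate: bool = False


@dataclass
class ComparisonRow:
    """One parameter's agreement summary (one row of the comparison table)."""

    parameter: str
    kind: str
    unit: str
    n: int
    auto_mean: float
    auto_sd: float
    manual_mean: float
    manual_sd: float
    t_stat: Optional[float] = None
    p_value: Optional[float] = None
    max_abs_error: Optional[float] = None
    significant: Optional[bool] = None


def paired_summary(tbl: PairedMeasurementTable, parameter: str) -> ComparisonRow:
    """Per-arm mean and sample SD (n-1 denominator) for one parameter."""
    rows = tbl._rows(parameter)
    n = len(rows)
    if n < 2:
        raise InsufficientDataError(f"{parameter}: need >= 2 cases, have {n}")
    auto = rows["auto"].to_numpy()
    manual = rows["manual"].to_numpy()
    return ComparisonRow(
        parameter=parameter,
        kind=rows["kind"].iloc[0],
        unit=rows["unit"].iloc[0],
        n=n,
        auto_mean=float(auto.mean()),
        auto_sd=float(auto.std(ddof=1)),
        manual_mean=float(manual.mean()),
        manual_sd=float(manual.std(ddof=1)),
    )


def paired_t_test(tbl: PairedMeasurementTable, parameter: str) -> TTestResult:
    """Paired two-tailed t-test of zero mean auto-manual difference.

    t = mean(d) / (sd(d) / sqrt(n)) with df = n - 1; p is the two-sided
    tail of Student's t.  Degenerate inputs follow the conventions:
    identical arms (all differences zero) give t = 0, p = 1; a constant
    nonzero difference has zero variance, so the test is flagged
    degenerate with p = 0 (the difference is certain).
    """
    rows = tbl._rows(parameter)
    n = len(rows)
    if n < 2:
        raise InsufficientDataError(f"{parameter}: need >= 2 cases, have {n}")
    d = rows["auto"].to_numpy() - rows["manual"].to_numpy()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return TTestResult(t_stat=0.0, p_value=1.0, df=n - 1)
        return TTestResult(
            t_stat=np.inf if d.mean() > 0 else -np.inf,
            p_value=0.0, df=n - 1, degenerate=True,
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TTestResult(t_stat=float(t), p_value=float(min(p, 1.0)), df=n - 1)


def max_abs_error(tbl: PairedMeasurementTable, kind: Optional[str] = None) -> float:
    """Maximum |auto - manual| over all cells, optionally restricted by kind."""
    df = tbl.data
    if kind is not None:
        df = df[df["kind"] == kind]
        if df.empty:
            raise InsufficientDataError(f"no parameters of kind {kind!r}")
    return float((df["auto"] - df["manual"]).abs().max())


def accuracy_percent(tbl: PairedMeasurementTable) -> float:
    """Mean relative absolute agreement, as a percentage.

    100 * (1 - mean |auto - manual| / |manual|) over all cells; cells with
    a zero manual value cannot contribute a relative error and are skipped
    with a warning.
    """
    df = tbl.data
    nonzero = df["manual"] != 0.0
    skipped = int((~nonzero).sum())
    if skipped:
        warnings.warn(
            f"accuracy_percent: skipped {skipped} cell(s) with zero manual value",
            stacklevel=2,
        )
    df = df[nonzero]
    if df.empty:
        raise InsufficientDataError("no cells with nonzero manual value")
    rel = (df["auto"] - df["manual"]).abs() / df["manual"].abs()
    return float(100.0 * (1.0 - rel.mean()))


def compare_tables(tbl: PairedMeasurementTable, alpha: float = 0.05,
                   bonferroni: bool = False) -> Tuple[List[ComparisonRow], Dict]:
    """Full agreement analysis: one row per parameter plus a study summary.

    Each row carries the per-arm summary, the paired t-test, the
    per-parameter maximum absolute error, and a significance flag at the
    (optionally Bonferroni-adjusted) level ``alpha``.  The summary holds
    the study-wide maximum errors by kind and the accuracy percentage with
    its definition spelled out.
    """
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError(f"alpha must be in (0, 1), got {alpha!r}")
    params = tbl.parameters
    threshold = alpha / len(params) if bonferroni else alpha
    rows: List[ComparisonRow] = []
    for p in params:
        row = paired_summary(tbl, p)
        test = paired_t_test(tbl, p)
        row.t_stat = test.t_stat
        row.p_value = test.p_value
        sub = tbl._rows(p)
        row.max_abs_error = float((sub["auto"] - sub["manual"]).abs().max())
        row.significant = bool(test.p_value < threshold)
        rows.append(row)
    kinds = set(tbl.data["kind"])
    summary: Dict = {
        "n_parameters": len(params),
        "n_cases": tbl.n_cases,
        "alpha": alpha,
        "bonferroni": bonferroni,
        "significant_parameters": [r.parameter for r in rows if r.significant],
        "n_significant": sum(r.significant for r in rows),
        "max_abs_error_by_kind": {k: max_abs_error(tbl, k) for k in sorted(kinds)},
        "accuracy_percent": accuracy_percent(tbl),
        "accuracy_definition": (
            "100 * (1 - mean over cells of |auto - manual| / |manual|); "
            "cells with zero manual value excluded"
        ),
    }
    return rows, summary


def comparison_frame(rows: List[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a DataFrame in table order (for CSV export)."""
    return pd.DataFrame(
        {
            "parameter": [r.parameter for r in rows],
            "kind": [r.kind for r in rows],
            "unit": [r.unit for r in rows],
            "n": [r.n for r in rows],
            "auto_mean": [r.auto_mean for r in rows],
            "auto_sd": [r.auto_sd for r in rows],
            "manual_mean": [r.manual_mean for r in rows],
            "manual_sd": [r.manual_sd for r in rows],
            "t_stat": [r.t_stat for r in rows],
            "p_value": [r.p_value for r in rows],
            "max_abs_error": [r.max_abs_error for r in rows],
            "significant": [r.significant for r in rows],
        }
    )
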