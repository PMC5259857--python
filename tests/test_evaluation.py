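"""Paired automatic-vs-manual agreement statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import gammaln

from cephkit import (
    InsufficientDataError,
    PairedMeasurementTable,
    accuracy_percent,
    compare_tables,
    max_abs_error,
    paired_summary,
    paired_t_test,
)
from cephkit.errors import InvalidInputError


def _table(auto, manual, parameters=None, kinds=None, units=None):
    auto = np.atleast_2d(np.asarray(auto, dtype=float))
    manual = np.atleast_2d(np.asarray(manual, dtype=float))
    n_param, n_case = auto.shape
    parameters = parameters or [f"P{i}" for i in range(n_param)]
    kinds = kinds or ["linear"] * n_param
    units = units or ["mm" if k == "linear" else "deg" for k in kinds]
    return PairedMeasurementTable.from_arrays(
        parameters, [f"c{j}" for j in range(n_case)], auto, manual, kinds, units
    )


# ----------------------------------------------------------------- summary

def test_summary_equal_arms():
    tbl = _table([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
    row = paired_summary(tbl, "P0")
    assert row.auto_mean == row.manual_mean == 2.0
    assert row.auto_sd == row.manual_sd == pytest.approx(1.0)


def test_summary_closed_form_pair():
    row = paired_summary(_table([[1.0, 3.0]], [[0.0, 0.5]]), "P0")
    assert row.auto_mean == 2.0
    assert row.auto_sd == pytest.approx(math.sqrt(2.0))
    assert row.n == 2


def test_summary_matches_two_pass_oracle(rng):
    values = rng.normal(50, 4, size=(1, 1000))
    manual = values + rng.normal(0, 1, size=values.shape)
    row = paired_summary(_table(values, manual), "P0")
    for got_mean, got_sd, arr in (
        (row.auto_mean, row.auto_sd, values[0]),
        (row.manual_mean, row.manual_sd, manual[0]),
    ):
        mean = sum(arr) / len(arr)  # streaming two-pass oracle
        var = sum((v - mean) ** 2 for v in arr) / (len(arr) - 1)
        assert got_mean == pytest.approx(mean, abs=1e-12)
        assert got_sd == pytest.approx(math.sqrt(var), abs=1e-12)


def test_summary_requires_two_cases():
    with pytest.raises(InsufficientDataError):
        paired_summary(_table([[1.0]], [[1.0]]), "P0")


# ------------------------------------------------------------------ t-test

def test_symmetric_differences_give_null_result():
    tbl = _table([[1.0, 0.0]], [[0.0, 1.0]])  # differences +1, -1
    result = paired_t_test(tbl, "P0")
    assert result.t_stat == 0.0
    assert result.p_value == 1.0


def test_identical_arms_give_p_one():
    result = paired_t_test(_table([[3.0, 4.0, 5.0]], [[3.0, 4.0, 5.0]]), "P0")
    assert result.t_stat == 0.0 and result.p_value == 1.0 and not result.degenerate


def test_constant_nonzero_difference_is_degenerate():
    result = paired_t_test(_table([[2.0, 3.0]], [[1.0, 2.0]]), "P0")
    assert result.degenerate and result.p_value == 0.0


def _t_density(x, df):
    logc = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * math.log(df * math.pi)
    return math.exp(logc) * (1 + x * x / df) ** (-(df + 1) / 2)


def test_t_test_matches_tail_integration_oracle():
    """Differences 1..5: t from the closed form, p by numerically
    integrating the t density over both tails at df = 4."""
    auto = np.array([[2.0, 4.0, 6.0, 8.0, 10.0]])
    manual = auto - np.array([[1.0, 2.0, 3.0, 4.0, 5.0]])
    result = paired_t_test(_table(auto, manual), "P0")
    d = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    t_expected = d.mean() / (d.std(ddof=1) / math.sqrt(5))
    tail, _ = integrate.quad(_t_density, abs(t_expected), np.inf, args=(4,))
    assert result.t_stat == pytest.approx(t_expected, abs=1e-12)
    assert result.p_value == pytest.approx(2 * tail, abs=1e-8)
    assert result.df == 4


# ------------------------------------------------------------- max error

def test_max_error_zero_for_identical_arms():
    tbl = _table([[1.0, 2.0]], [[1.0, 2.0]])
    assert max_abs_error(tbl) == 0.0


def test_max_error_single_divergent_cell():
    tbl = _table([[1.0, 2.0], [5.0, 5.7]], [[1.0, 2.0], [5.0, 5.0]])
    assert max_abs_error(tbl) == pytest.approx(0.7)


def test_max_error_by_kind_matches_exhaustive_scan(rng):
    auto = rng.normal(50, 5, size=(6, 40))
    manual = auto + rng.normal(0, 1, size=auto.shape)
    kinds = ["linear"] * 3 + ["angular"] * 3
    tbl = _table(auto, manual, kinds=kinds)
    for kind, rows in (("linear", range(3)), ("angular", range(3, 6))):
        scan = max(abs(auto[i, j] - manual[i, j]) for i in rows for j in range(40))
        assert max_abs_error(tbl, kind) == scan
    with pytest.raises(InsufficientDataError):
        max_abs_error(_table([[1.0, 2.0]], [[1.0, 2.0]]), "angular")


# -------------------------------------------------------------- accuracy

def test_accuracy_identical_arms_is_100():
    assert accuracy_percent(_table([[1.0, 2.0]], [[1.0, 2.0]])) == 100.0


def test_accuracy_uniform_ten_percent_error():
    manual = np.array([[10.0, 20.0, 40.0]])
    assert accuracy_percent(_table(0.9 * manual, manual)) == pytest.approx(90.0)


def test_accuracy_matches_cell_loop_oracle(rng):
    manual = rng.uniform(5, 100, size=(4, 30))
    auto = manual + rng.normal(0, 2, size=manual.shape)
    rel = [
        abs(auto[i, j] - manual[i, j]) / abs(manual[i, j])
        for i in range(4) for j in range(30)
    ]
    expected = 100.0 * (1.0 - sum(rel) / len(rel))
    assert accuracy_percent(_table(auto, manual)) == pytest.approx(expected, abs=1e-12)


def test_accuracy_skips_zero_manual_cells():
    tbl = _table([[1.0, 5.0]], [[0.0, 5.0]])
    with pytest.warns(UserWarning, match="zero manual"):
        assert accuracy_percent(tbl) == 100.0


# --------------------------------------------------------- compare_tables

def _study_table(rng, n_param=18, n_case=30, bias=0.0):
    kinds = ["linear"] * 12 + ["angular"] * 6
    kinds = kinds[:n_param]
    auto = rng.normal(60, 5, size=(n_param, n_case))
    manual = auto + rng.normal(0, 1, size=auto.shape) + bias
    return _table(auto, manual, kinds=kinds)


def test_compare_tables_full_study_shape(rng):
    tbl = _study_table(rng)
    rows, summary = compare_tables(tbl, alpha=0.05)
    assert len(rows) == 18
    assert summary["n_parameters"] == 18 and summary["n_cases"] == 30
    assert set(summary["max_abs_error_by_kind"]) == {"linear", "angular"}
    assert "accuracy_definition" in summary


def test_significance_flag_respects_alpha(rng):
    tbl = _study_table(rng, n_param=2, n_case=10)
    rows, _ = compare_tables(tbl, alpha=0.05)
    for row in rows:
        assert row.significant == (row.p_value < 0.05)


def test_bonferroni_tightens_threshold(rng):
    tbl = _study_table(rng, bias=0.3)
    plain_rows, _ = compare_tables(tbl, alpha=0.05)
    bonf_rows, _ = compare_tables(tbl, alpha=0.05, bonferroni=True)
    for plain, bonf in zip(plain_rows, bonf_rows):
        assert bonf.significant == (bonf.p_value < 0.05 / 18)
        if bonf.significant:
            assert plain.significant


def test_compare_tables_case_order_invariant(rng):
    tbl = _study_table(rng, n_param=4, n_case=12)
    shuffled = tbl.data.sample(frac=1.0, random_state=3).reset_index(drop=True)
    rows_a, sum_a = compare_tables(tbl)
    rows_b, sum_b = compare_tables(PairedMeasurementTable(shuffled))
    by_param = {r.parameter: r for r in rows_b}
    for row in rows_a:
        other = by_param[row.parameter]
        assert other.t_stat == pytest.approx(row.t_stat, abs=1e-12)
        assert other.max_abs_error == pytest.approx(row.max_abs_error, abs=1e-12)
    assert sum_a["accuracy_percent"] == pytest.approx(sum_b["accuracy_percent"])


# -------------------------------------------------------------- validation

def test_ragged_grid_rejected():
    df = pd.DataFrame(
        [
            ("P0", "c0", "linear", "mm", 1.0, 1.0),
            ("P0", "c1", "linear", "mm", 2.0, 2.0),
            ("P1", "c0", "linear", "mm", 3.0, 3.0),
        ],
        columns=["parameter", "case", "kind", "unit", "auto", "manual"],
    )
    with pytest.raises(InvalidInputError, match="ragged"):
        PairedMeasurementTable(df)


def test_missing_cells_rejected():
    df = pd.DataFrame(
        [("P0", "c0", "linear", "mm", 1.0, np.nan)],
        columns=["parameter", "case", "kind", "unit", "auto", "manual"],
    )
    with pytest.raises(InvalidInputError, match="missing"):
        PairedMeasurementTable(df)


def test_paired_csv_round_trip(tmp_path, rng):
    tbl = _study_table(rng, n_param=3, n_case=5)
    path = tmp_path / "paired.csv"
    tbl.to_csv(path)
    back = PairedMeasurementTable.from_csv(path)
    pd.testing.assert_frame_equal(back.data, tbl.data)
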