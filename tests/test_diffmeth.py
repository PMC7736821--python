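"""Differential methylation: centering, replicate summaries, Welch, deltas."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nmquant.diffmeth import (
    ConditionDesign,
    DesignError,
    delta_vs_control,
    row_center,
    summarize_replicates,
    welch_test,
)


def table(rows, samples):
    index = pd.MultiIndex.from_tuples(
        [(f"t{i}", 30) for i in range(len(rows))], names=["ref_id", "position"]
    )
    return pd.DataFrame(rows, index=index, columns=samples)


def design_2x3():
    assignments = {}
    for cond in ("control", "stress"):
        for r in (1, 2, 3):
            assignments[f"{cond}_r{r}"] = (cond, r)
    return ConditionDesign(assignments, control="control")


SAMPLES = [f"{c}_r{r}" for c in ("control", "stress") for r in (1, 2, 3)]


def welch_oracle(x, y):
    """Textbook Welch formulas, independent of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / math.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    from scipy.special import stdtr

    p = 2 * stdtr(df, -abs(t))
    return t, df, p


class TestRowCenter:
    def test_arithmetic(self):
        t = table([[0.2, 0.4, 0.6]], ["a", "b", "c"])
        out = row_center(t)
        assert np.allclose(out.iloc[0], [-0.2, 0.0, 0.2])

    def test_constant_row_zeroed_and_na_preserved(self):
        t = table([[0.3, 0.3, np.nan]], ["a", "b", "c"])
        out = row_center(t)
        assert out.iloc[0, 0] == 0.0
        assert np.isnan(out.iloc[0, 2])

    def test_all_na_row_dropped_with_warning(self):
        t = table([[np.nan, np.nan], [0.1, 0.5]], ["a", "b"])
        with pytest.warns(UserWarning, match="all-NA"):
            out = row_center(t)
        assert len(out) == 1

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.lists(st.floats(0, 1, allow_nan=False), min_size=3, max_size=3),
            min_size=1,
            max_size=6,
        )
    )
    def test_rows_sum_to_zero_and_idempotent(self, rows):
        t = table(rows, ["a", "b", "c"])
        out = row_center(t)
        assert np.allclose(out.sum(axis=1), 0, atol=1e-12)
        assert np.allclose(row_center(out), out, atol=1e-12)


class TestSummarizeReplicates:
    def test_single_replicate_degenerate_box(self):
        t = table([[0.4] + [np.nan] * 5], SAMPLES)
        out = summarize_replicates(t, design_2x3())
        row = out[out["condition"] == "control"].iloc[0]
        assert row["mean"] == row["min"] == row["max"] == row["q1"] == row["q3"] == 0.4
        assert row["n"] == 1

    def test_three_values(self):
        t = table([[0.1, 0.2, 0.3, np.nan, np.nan, np.nan]], SAMPLES)
        row = summarize_replicates(t, design_2x3()).iloc[0]
        assert row["mean"] == pytest.approx(0.2)
        assert row["min"] == 0.1
        assert row["max"] == 0.3

    def test_four_replicate_quartiles_match_order_statistic_oracle(self):
        vals = [0.1, 0.7, 0.3, 0.2]
        assignments = {f"s{i}": ("c", i + 1) for i in range(4)}
        design = ConditionDesign(assignments, control="c")
        t = table([vals], [f"s{i}" for i in range(4)])
        row = summarize_replicates(t, design).iloc[0]
        # brute force: sort, linear interpolation between order statistics
        v = sorted(vals)
        def interp(p):
            h = p * (len(v) - 1)
            lo = math.floor(h)
            return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])
        assert row["q1"] == pytest.approx(interp(0.25))
        assert row["q3"] == pytest.approx(interp(0.75))

    def test_uncovered_sample_rejected(self):
        t = table([[0.1]], ["orphan"])
        with pytest.raises(DesignError, match="does not cover"):
            summarize_replicates(t, design_2x3())


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_against_textbook_oracle(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]
        got = welch_test(x, y)
        exp = welch_oracle(x, y)
        for g, e in zip(got, exp):
            assert g == pytest.approx(e, abs=1e-10)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        x=st.lists(st.floats(-5, 5), min_size=2, max_size=8),
        y=st.lists(st.floats(-5, 5), min_size=2, max_size=8),
    )
    def test_swap_negates_t_preserves_p(self, x, y):
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            return
        t1, df1, p1 = welch_test(x, y)
        t2, df2, p2 = welch_test(y, x)
        assert t1 == pytest.approx(-t2)
        assert df1 == pytest.approx(df2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_samples_rejected(self):
        with pytest.raises(DesignError, match="degenerate"):
            welch_test([1.0, 1.0], [1.0, 1.0])

    def test_too_few_observations_rejected(self):
        with pytest.raises(DesignError, match="at least 2"):
            welch_test([1.0], [1.0, 2.0])


class TestDelta:
    def test_identical_conditions_zero(self):
        t = table([[0.3, 0.4, 0.5, 0.3, 0.4, 0.5]], SAMPLES)
        out = delta_vs_control(t, design_2x3())
        assert out["delta"].iloc[0] == pytest.approx(0.0)

    def test_arithmetic(self):
        t = table([[0.1, 0.1, 0.1, 0.7, 0.7, 0.7]], SAMPLES)
        out = delta_vs_control(t, design_2x3())
        assert out["delta"].iloc[0] == pytest.approx(0.6)

    def test_control_na_gives_na(self):
        t = table([[np.nan, np.nan, np.nan, 0.7, 0.7, 0.7]], SAMPLES)
        out = delta_vs_control(t, design_2x3())
        assert np.isnan(out["delta"].iloc[0])

    def test_ratio_mode(self):
        t = table([[0.2, 0.2, 0.2, 0.6, 0.6, 0.6]], SAMPLES)
        out = delta_vs_control(t, design_2x3(), as_ratio=True)
        assert out["delta"].iloc[0] == pytest.approx(3.0)

    def test_welch_column(self):
        t = table([[0.10, 0.12, 0.11, 0.70, 0.72, 0.69]], SAMPLES)
        out = delta_vs_control(t, design_2x3(), with_tests=True)
        assert out["p_welch"].iloc[0] < 0.01


class TestDesign:
    def test_exactly_one_control_enforced(self, tmp_path):
        tsv = tmp_path / "design.tsv"
        tsv.write_text(
            "sample_id\tcondition\treplicate\tis_control\n"
            "a\tc1\t1\tTrue\nb\tc2\t1\tTrue\n"
        )
        with pytest.raises(DesignError, match="exactly one"):
            ConditionDesign.from_table(tsv)

    def test_round_trip(self, tmp_path):
        tsv = tmp_path / "design.tsv"
        tsv.write_text(
            "sample_id\tcondition\treplicate\tis_control\n"
            "a\tctl\t1\tTrue\nb\tstress\t1\tFalse\n"
        )
        d = ConditionDesign.from_table(tsv)
        assert d.control == "ctl"
        assert d.samples_of("stress") == ["b"]
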