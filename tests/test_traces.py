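"""Trace parsing and per-line difference classification."""

import pytest
from hypothesis import given, settings, strategies as st

from reprotrace.traces import (
    CallRecord,
    DiffClass,
    TraceParseError,
    classify_pair,
    diff_traces,
    diff_traces_per_pid,
    parse_trace,
    split_by_pid,
    summarize_functions,
)
from reprotrace.synthetic import InjectionSpec, gen_trace_pair


def rec(func, args, ret, index=0, pid=None):
    return CallRecord(index=index, func=func, args=tuple(args), ret=ret, pid=pid)


class TestParsing:
    def test_plain_call_line(self):
        (r,) = parse_trace("expf(1.540630) = 4.667011")
        assert r.func == "expf"
        assert r.args == ("1.540630",)
        assert r.ret == "4.667011"
        assert r.pid is None and r.index == 0

    def test_pid_prefix(self):
        (r,) = parse_trace("[pid 1234] floorf(2.700000) = 2.000000")
        assert r.pid == 1234
        assert r.func == "floorf"
        assert r.args == ("2.700000",)

    def test_multiple_args_and_no_args(self):
        r1, r2 = parse_trace("atan2f(1.0, 2.0) = 0.463648\nrand() = 42")
        assert r1.args == ("1.0", "2.0")
        assert r2.args == ()

    def test_comments_and_blanks_do_not_consume_indices(self):
        text = "# header\n\nexpf(1.0) = 2.718282\n# mid\nlogf(1.0) = 0.000000\n"
        records = list(parse_trace(text))
        assert [r.index for r in records] == [0, 1]

    def test_strict_mode_names_the_offending_line(self):
        with pytest.raises(TraceParseError, match="line 2.*garbage"):
            list(parse_trace("expf(1.0) = 2.7\ngarbage line\n", strict=True))

    def test_lenient_mode_skips_without_consuming_index(self, caplog):
        records = list(parse_trace("expf(1.0) = 2.7\ngarbage\nlogf(1.0) = 0.0\n"))
        assert [r.index for r in records] == [0, 1]

    def test_crlf_lines(self):
        (r,) = parse_trace("expf(1.0) = 2.7\r\n")
        assert r.ret == "2.7"


class TestClassifyPair:
    CASES = [
        # different args, same result: the floor() signature case
        (rec("floorf", ["2.300000"], "2.000000"),
         rec("floorf", ["2.600000"], "2.000000"), DiffClass.TYPE1),
        # different args, different result
        (rec("expf", ["1.0"], "2.718282"),
         rec("expf", ["1.1"], "3.004166"), DiffClass.TYPE2),
        # same args, different result: implementation difference
        (rec("expf", ["1.540630"], "4.667010"),
         rec("expf", ["1.540630"], "4.667011"), DiffClass.TYPE3),
        # different functions: control flow diverged (decided before args)
        (rec("cosf", ["0.866"], "0.5"),
         rec("sinf", ["0.866"], "0.5"), DiffClass.MISMATCH),
        (rec("expf", ["1.0"], "2.718282"),
         rec("expf", ["1.0"], "2.718282"), DiffClass.IDENTICAL),
    ]

    @pytest.mark.parametrize("a, b, expected", CASES)
    def test_taxonomy(self, a, b, expected):
        assert classify_pair(a, b) is expected

    @pytest.mark.parametrize("a, b, expected", CASES)
    def test_swapping_sides_never_changes_the_class(self, a, b, expected):
        assert classify_pair(b, a) is expected

    def test_mismatch_takes_precedence_over_token_comparison(self):
        a = rec("cosf", ["1.0"], "0.540302")
        b = rec("sinf", ["2.0"], "0.909297")
        assert classify_pair(a, b) is DiffClass.MISMATCH

    def test_whitespace_trimmed_before_comparison(self):
        a = rec("expf", [" 1.0"], "2.7")
        b = rec("expf", ["1.0 "], "2.7")
        assert classify_pair(a, b) is DiffClass.IDENTICAL

    def test_numeric_mode_equates_formatting_variants(self):
        a = rec("expf", ["1.50"], "4.4817")
        b = rec("expf", ["1.5"], "4.4817")
        assert classify_pair(a, b) is DiffClass.TYPE1  # string mode: args differ
        assert classify_pair(a, b, numeric=True) is DiffClass.IDENTICAL


class TestDiffTraces:
    def _identical_traces(self, n=1000):
        text = "".join(f"expf({i}.000000) = {i}.500000\n" for i in range(n))
        return list(parse_trace(text)), list(parse_trace(text))

    def test_identical_traces(self):
        a, b = self._identical_traces()
        res = diff_traces(a, b)
        assert res.first_difference is None
        assert res.n_identical == res.n_lines == 1000
        assert not res.records

    def test_single_injected_type3_located_exactly(self):
        spec = InjectionSpec(type3=[500])
        ta, tb, _ = gen_trace_pair(1000, spec, seed=1)
        res = diff_traces(parse_trace(ta), parse_trace(tb))
        assert res.first_difference == (500, DiffClass.TYPE3)
        assert res.class_totals[DiffClass.TYPE3] == 1
        assert res.n_identical == 999

    def test_trailing_lines_count_as_mismatch(self):
        a, _ = self._identical_traces(10)
        b, _ = self._identical_traces(12)
        res = diff_traces(a, b)
        assert res.class_totals[DiffClass.MISMATCH] == 2
        assert res.n_lines == 12
        assert res.first_difference == (10, DiffClass.MISMATCH)

    def test_empty_traces_rejected(self):
        with pytest.raises(ValueError):
            diff_traces([], [])

    def test_class_totals_partition_all_lines(self):
        spec = InjectionSpec(type1=0.02, type2=0.01, type3=0.01, mismatch=0.01)
        ta, tb, _ = gen_trace_pair(2000, spec, seed=2)
        res = diff_traces(parse_trace(ta), parse_trace(tb))
        assert sum(res.class_totals.values()) + res.n_identical == res.n_lines

    def test_cumulative_series_monotone_and_end_at_totals(self):
        spec = InjectionSpec(type3=0.05)
        ta, tb, _ = gen_trace_pair(3000, spec, seed=3)
        res = diff_traces(parse_trace(ta), parse_trace(tb), checkpoint=100)
        for key, series in res.cumulative.items():
            counts = [c for _, c in series]
            assert counts == sorted(counts)
            assert counts[-1] == res.totals[key]

    def test_totals_equal_final_cumulative_values(self):
        spec = InjectionSpec(type1=0.01, mismatch=0.01)
        ta, tb, _ = gen_trace_pair(5000, spec, seed=4)
        res = diff_traces(parse_trace(ta), parse_trace(tb), checkpoint=1000)
        final = {k: s[-1][1] for k, s in res.cumulative.items()}
        assert final == dict(res.totals)


class TestPerPid:
    def test_split_renumbers_within_streams(self):
        text = ("[pid 1] expf(1.0) = 2.7\n"
                "[pid 2] logf(1.0) = 0.0\n"
                "[pid 1] expf(2.0) = 7.4\n")
        streams = split_by_pid(parse_trace(text))
        assert [r.index for r in streams[1]] == [0, 1]
        assert [r.index for r in streams[2]] == [0]

    def test_interleaved_children_compare_clean_per_pid(self):
        # file order differs between runs, per-pid content does not
        a = ("[pid 1] expf(1.0) = 2.7\n[pid 2] logf(1.0) = 0.0\n"
             "[pid 1] expf(2.0) = 7.4\n")
        b = ("[pid 2] logf(1.0) = 0.0\n[pid 1] expf(1.0) = 2.7\n"
             "[pid 1] expf(2.0) = 7.4\n")
        file_order = diff_traces(parse_trace(a), parse_trace(b))
        assert file_order.class_totals[DiffClass.MISMATCH] > 0
        per_pid = diff_traces_per_pid(parse_trace(a), parse_trace(b))
        assert all(r.n_identical == r.n_lines for r in per_pid.values())


class TestSummarizeFunctions:
    def test_all_identical_gives_empty_table(self):
        text = "expf(1.0) = 2.7\n" * 5
        res = diff_traces(parse_trace(text), parse_trace(text))
        assert summarize_functions(res).empty

    def test_injected_counts_recovered_per_function(self):
        # direct construction: 3 type-3 in cosf, 2 type-1 in ceilf
        a_lines, b_lines = [], []
        for i in range(10):
            a_lines.append(f"expf({i}.000000) = 1.000000")
            b_lines.append(f"expf({i}.000000) = 1.000000")
        for i in range(3):
            a_lines.append("cosf(1.000000) = 0.540302")
            b_lines.append("cosf(1.000000) = 0.540303")
        for i in range(2):
            a_lines.append("ceilf(1.200000) = 2.000000")
            b_lines.append("ceilf(1.500000) = 2.000000")
        res = diff_traces(parse_trace("\n".join(a_lines)),
                          parse_trace("\n".join(b_lines)))
        table = summarize_functions(res)
        got = {(r.function, r.diff_class): r.count for r in table.itertuples()}
        assert got == {("cosf", "type3"): 3, ("ceilf", "type1"): 2}

    def test_table_counts_sum_to_result_totals(self):
        spec = InjectionSpec(type1=0.02, type3=0.02)
        ta, tb, _ = gen_trace_pair(2000, spec, seed=5)
        res = diff_traces(parse_trace(ta), parse_trace(tb))
        table = summarize_functions(res)
        assert table["count"].sum() == sum(res.class_totals.values())


@settings(derandomize=True, max_examples=50)
@given(
    func=st.sampled_from(["expf", "cosf"]),
    args_a=st.text("0123456789.", min_size=1, max_size=8),
    args_b=st.text("0123456789.", min_size=1, max_size=8),
    ret_a=st.text("0123456789.", min_size=1, max_size=8),
    ret_b=st.text("0123456789.", min_size=1, max_size=8),
)
def test_classification_exhaustive_and_symmetric(func, args_a, args_b, ret_a, ret_b):
    """Every pair gets exactly one class and the class ignores side order."""
    a = rec(func, [args_a], ret_a)
    b = rec(func, [args_b], ret_b)
    cls = classify_pair(a, b)
    assert cls in DiffClass
    assert classify_pair(b, a) is cls
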