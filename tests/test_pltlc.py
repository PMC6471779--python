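import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qsbiofilm.fixtures import TraceRecipe, make_category_trace
from qsbiofilm.pltlc import (
    CATEGORIES,
    CATEGORY_ORDER,
    PLTLcError,
    classify,
    evaluate,
    evaluate_free,
    parse,
    probability,
)
from qsbiofilm.simulate import Trace


def mk_trace(values, names=None, dt=1.0):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    names = names or ["A"]
    times = np.arange(len(values)) * dt
    return Trace(times, values, names)


# ---------------------------------------------------------------------------
# an independent brute-force evaluator used as the oracle
# ---------------------------------------------------------------------------

def trunc(v):
    return math.trunc(v * 100) / 100


def naive_eval(f, trace, i, subst=None):
    names = list(trace.names)

    def series(name):
        name = subst if name == "$x" else name
        return [trunc(v) for v in trace.values[:, names.index(name)]]

    def deriv(name, j):
        x = series(name)
        t = trace.times
        if j == len(x) - 1:
            j = len(x) - 2
        return (x[j + 1] - x[j]) / (t[j + 1] - t[j])

    def num(node, j):
        if node.op == "lit":
            return node.value
        if node.op == "var":
            return series(node.value)[j]
        if node.op == "deriv":
            return deriv(node.value, j)
        if node.op == "maxv":
            return max(series(node.value))
        a, b = (num(x, j) for x in node.args)
        return {"add": a + b, "sub": a - b, "mul": a * b, "div": a / b}[node.op]

    n = len(trace.times)
    op = f.op
    if op == "cmp":
        a, b = num(f.args[0], i), num(f.args[1], i)
        return {"<": a < b, "<=": a <= b, ">": a > b, ">=": a >= b,
                "=": a == b, "!=": a != b}[f.value]
    if op == "not":
        return not naive_eval(f.args[0], trace, i, subst)
    if op == "and":
        return naive_eval(f.args[0], trace, i, subst) and naive_eval(
            f.args[1], trace, i, subst)
    if op == "or":
        return naive_eval(f.args[0], trace, i, subst) or naive_eval(
            f.args[1], trace, i, subst)
    if op == "implies":
        return (not naive_eval(f.args[0], trace, i, subst)) or naive_eval(
            f.args[1], trace, i, subst)
    if op == "G":
        return all(naive_eval(f.args[0], trace, j, subst) for j in range(i, n))
    if op == "F":
        return any(naive_eval(f.args[0], trace, j, subst) for j in range(i, n))
    if op == "U":
        # first-witness reading: phi1 before the first phi2 point
        for j in range(i, n):
            if naive_eval(f.args[1], trace, j, subst):
                return True
            if not naive_eval(f.args[0], trace, j, subst):
                return False
        return False
    raise AssertionError(op)


class TestParser:
    def test_probability_bound_formula(self):
        f = parse("P>=1[ G([A]<100 & d[A]<0) ]")
        assert f.op == "prob" and f.value == (">=", 1.0)
        assert f.args[0].op == "G"

    def test_free_variable_formula(self):
        f = parse("P>=1[ G([$x]=0) ]")
        assert f.free_variable

    def test_syntax_error_reports_position(self):
        with pytest.raises(PLTLcError, match="position"):
            parse("G(")

    def test_trailing_input_rejected(self):
        with pytest.raises(PLTLcError):
            parse("[A]>0 )")

    def test_arithmetic_and_max(self):
        f = parse("max[A] - [A] >= 0.5*[B]")
        assert f.op == "cmp"

    def test_until_and_parentheses(self):
        f = parse("([A]>0) U (G(d[A]=0))")
        assert f.op == "U"


class TestEvaluate:
    def test_constant_zero_satisfies_G_zero(self):
        assert evaluate("G([A]=0)", mk_trace(np.zeros(10)))

    def test_truncation_tolerates_sub_quantum_values(self):
        assert evaluate("G([A]=0)", mk_trace(np.full(10, 0.009)))
        assert not evaluate("G([A]=0)", mk_trace(np.full(10, 0.011)))

    def test_max_function(self):
        tr = mk_trace([0, 2, 5, 3, 1])
        assert evaluate("F([A]=max[A])", tr)
        assert evaluate("max[A]=5", tr)

    def test_derivative_from_truncated_series(self):
        # a drift below the truncation quantum is an exact steady state
        tr = mk_trace(1.001 + np.arange(20) * 1e-4)
        assert evaluate("G(d[A]=0)", tr)

    def test_unknown_variable_raises(self):
        with pytest.raises(PLTLcError):
            evaluate("G([Z]=0)", mk_trace(np.zeros(5)))

    def test_free_variable_in_closed_evaluation_raises(self):
        with pytest.raises(PLTLcError):
            evaluate("G([$x]=0)", mk_trace(np.zeros(5)))

    @settings(max_examples=80, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=12), st.data())
    def test_against_bruteforce_oracle(self, vals, data):
        formula = data.draw(st.sampled_from([
            "G([A]<=2)", "F([A]=3)", "([A]<2) U ([A]>=2)",
            "G(d[A]>=0) | F([A]=0)", "(d[A]>0 U G(d[A]<=0))",
            "!G([A]>0) -> F([A]=0)", "G(([A]>0) -> F([A]=0))",
        ]))
        tr = mk_trace(vals)
        f = parse(formula)
        assert evaluate(f, tr) == naive_eval(f, tr, 0)

    def test_G_is_not_F_not(self):
        tr = mk_trace([0, 1, 2, 1, 0, 0])
        for phi in ("[A]>0", "d[A]>=0", "[A]=0"):
            assert evaluate(f"G({phi})", tr) == (not evaluate(f"F(!({phi}))", tr))


class TestFreeVariable:
    def test_set_of_satisfying_species(self):
        tr = mk_trace(np.column_stack([np.zeros(6), np.ones(6)]), ["Z", "O"])
        assert evaluate_free("P>=1[ G([$x]=0) ]", tr) == {"Z"}
        assert evaluate_free("P>=1[ G([$x]>0) ]", tr) == {"O"}
        assert evaluate_free("P>=1[ F([$x]<0) ]", tr) == set()


class TestProbability:
    def test_fraction_of_satisfying_runs(self):
        runs = [mk_trace(np.zeros(5)), mk_trace(np.ones(5)),
                mk_trace(np.zeros(5)), mk_trace(np.ones(5))]
        assert probability("G([A]=0)", runs) == 0.5
        assert probability("F([A]>=0)", runs) == 1.0

    def test_needs_at_least_one_run(self):
        with pytest.raises(PLTLcError):
            probability("G([A]=0)", [])


class TestClassify:
    def test_all_zero_trace_is_category_one(self):
        cats = classify(mk_trace(np.zeros((30, 2)), ["A", "B"]))
        assert set(cats.values()) == {CATEGORY_ORDER[0]}

    @pytest.mark.parametrize("cat", range(1, 7))
    def test_fixture_lands_in_generating_category(self, cat):
        tr = make_category_trace(TraceRecipe(category=cat))
        assert classify(tr)["X"] == CATEGORY_ORDER[cat - 1]

    @pytest.mark.parametrize("cat", [3, 4, 5, 6])
    def test_rising_plateau_satisfies_only_category_four(self, cat):
        tr = make_category_trace(TraceRecipe(category=4))
        want = cat == 4
        assert evaluate_free(CATEGORIES[CATEGORY_ORDER[cat - 1]], tr) == (
            {"X"} if want else set())

    def test_invariant_under_time_rescaling(self):
        for cat in range(1, 7):
            tr = make_category_trace(TraceRecipe(category=cat))
            for factor in (0.5, 2.0):
                scaled = Trace(tr.times * factor, tr.values, list(tr.names))
                assert classify(scaled)["X"] == classify(tr)["X"]
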