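"""PLTLc: probabilistic linear-time temporal logic over simulation traces.

The checker evaluates formulas over finite recorded traces.  Numeric atoms
compare arithmetic expressions built from

* ``[X]``     -- the value of species ``X`` at the current time point,
* ``d[X]``    -- its forward finite-difference derivative,
* ``max[X]``  -- its maximum over the whole trace,
* numeric literals,

with the comparators ``< <= > >= = !=``.  Boolean connectives are ``&``,
``|``, ``->`` and ``!``; temporal operators ``G`` (globally), ``F``
(finally) and binary ``U`` (until).  An outer probability bound
``P>=theta[ ... ]`` turns a path formula into a property; on a single or
averaged trace the result degenerates to {0, 1}.  ``$x`` is a meta
variable ranging over all species: :func:`evaluate_free` returns the set
of species satisfying the formula.

Species values and maxima are truncated towards zero to 2 decimal places
before comparison, and derivatives are finite differences of the
*truncated* series (not truncated again), so equality atoms act as
steady-state detectors tolerant of sub-0.01 drift: a flat-to-quantisation
segment gives ``d[X] = 0`` exactly, while any residual relaxation shows up
as sparse one-quantum steps.  The digit count is configurable.

Finite-trace semantics: ``G`` requires its operand at every remaining
point, ``F`` at some remaining point, and ``f U g`` requires a remaining
point satisfying ``g`` with ``f`` holding everywhere before the first such
point (equivalent to the classical any-witness semantics).  The derivative
at point ``i`` is ``(x[i+1]-x[i])/(t[i+1]-t[i])``; the last point inherits
the previous derivative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Formula",
    "parse",
    "evaluate",
    "evaluate_free",
    "probability",
    "classify",
    "CATEGORIES",
    "CATEGORY_ORDER",
    "PLTLcError",
]


class PLTLcError(ValueError):
    pass


# ---------------------------------------------------------------------------
# abstract syntax
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Formula:
    op: str  # prob, G, F, U, and, or, not, implies, cmp, plus arithmetic
    args: tuple = ()
    value: object = None  # comparator / literal / variable / bound

    def __str__(self):  # pragma: no cover - debugging aid
        return f"{self.op}{self.value if self.value is not None else ''}{self.args}"

    @property
    def free_variable(self) -> bool:
        if self.op in ("var", "deriv", "maxv") and self.value == "$x":
            return True
        return any(a.free_variable for a in self.args)


# ---------------------------------------------------------------------------
# parser (recursive descent)
# ---------------------------------------------------------------------------

_TOKEN = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?)"
    r"|(?P<fun>d\[|max\[)"
    r"|(?P<lvar>\[)"
    r"|(?P<name>\$?[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op><=|>=|!=|->|[]()<>=&|!~+*/-])"
    r")"
)


def _tokenize(text: str):
    pos, out = 0, []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.end() == pos:
            if text[pos:].strip():
                raise PLTLcError(f"syntax error at position {pos}: {text[pos:pos+10]!r}")
            break
        for kind in ("num", "fun", "lvar", "name", "op"):
            if m.group(kind) is not None:
                out.append((kind, m.group(kind), pos))
                break
        pos = m.end()
    out.append(("eof", "", len(text)))
    return out


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.toks = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.toks[self.i]

    def next(self):
        tok = self.toks[self.i]
        self.i += 1
        return tok

    def expect(self, value):
        kind, val, pos = self.next()
        if val != value:
            raise PLTLcError(
                f"parse error at position {pos}: expected {value!r}, got {val!r}"
            )

    # formula := P cmp num [ path ] | path
    def formula(self) -> Formula:
        kind, val, _ = self.peek()
        if kind == "name" and val == "P":
            self.next()
            _, cmp_op, pos = self.next()
            if cmp_op not in (">=", ">", "=", "<=", "<"):
                raise PLTLcError(f"parse error at position {pos}: bad probability bound")
            k, num, pos = self.next()
            if k != "num":
                raise PLTLcError(f"parse error at position {pos}: expected number")
            self.expect("[")
            body = self.path()
            self.expect("]")
            f = Formula("prob", (body,), (cmp_op, float(num)))
        else:
            f = self.path()
        kind, val, pos = self.peek()
        if kind != "eof":
            raise PLTLcError(f"parse error at position {pos}: trailing input {val!r}")
        return f

    # precedence: -> < | < & < U < unary
    def path(self) -> Formula:
        f = self.or_expr()
        if self.peek()[1] == "->":
            self.next()
            return Formula("implies", (f, self.path()))
        return f

    def or_expr(self) -> Formula:
        f = self.and_expr()
        while self.peek()[1] == "|":
            self.next()
            f = Formula("or", (f, self.and_expr()))
        return f

    def and_expr(self) -> Formula:
        f = self.until_expr()
        while self.peek()[1] == "&":
            self.next()
            f = Formula("and", (f, self.until_expr()))
        return f

    def until_expr(self) -> Formula:
        f = self.unary()
        while self.peek()[:2] == ("name", "U"):
            self.next()
            f = Formula("U", (f, self.unary()))
        return f

    def unary(self) -> Formula:
        kind, val, pos = self.peek()
        if val in ("!", "~"):
            self.next()
            return Formula("not", (self.unary(),))
        if kind == "name" and val in ("G", "F"):
            self.next()
            self.expect("(")
            body = self.path()
            self.expect(")")
            return Formula(val, (body,))
        if val == "(":
            # parentheses group either a path formula or an arithmetic
            # sub-expression; try the former, backtrack to the latter
            mark = self.i
            try:
                self.next()
                f = self.path()
                self.expect(")")
                return f
            except PLTLcError:
                self.i = mark
        return self.comparison()

    def comparison(self) -> Formula:
        left = self.arith()
        kind, val, pos = self.next()
        if val not in ("<", "<=", ">", ">=", "=", "!="):
            raise PLTLcError(f"parse error at position {pos}: expected comparator")
        right = self.arith()
        return Formula("cmp", (left, right), val)

    def arith(self) -> Formula:
        f = self.term()
        while self.peek()[1] in ("+", "-"):
            _, op, _ = self.next()
            f = Formula("add" if op == "+" else "sub", (f, self.term()))
        return f

    def term(self) -> Formula:
        f = self.atom()
        while self.peek()[1] in ("*", "/"):
            _, op, _ = self.next()
            f = Formula("mul" if op == "*" else "div", (f, self.atom()))
        return f

    def atom(self) -> Formula:
        kind, val, pos = self.next()
        if kind == "num":
            return Formula("lit", (), float(val))
        if val == "-":
            inner = self.atom()
            return Formula("sub", (Formula("lit", (), 0.0), inner))
        if kind == "lvar":  # [Name]
            k, name, p2 = self.next()
            if k != "name":
                raise PLTLcError(f"parse error at position {p2}: expected species name")
            self.expect("]")
            return Formula("var", (), name)
        if kind == "fun":  # d[Name] or max[Name]
            k, name, p2 = self.next()
            if k != "name":
                raise PLTLcError(f"parse error at position {p2}: expected species name")
            self.expect("]")
            return Formula("deriv" if val == "d[" else "maxv", (), name)
        if val == "(":
            f = self.arith()
            self.expect(")")
            return f
        raise PLTLcError(f"parse error at position {pos}: unexpected {val!r}")


def parse(text: str) -> Formula:
    """Parse a PLTLc formula string into its abstract syntax."""
    return _Parser(text).formula()


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _truncate(a: np.ndarray, digits: int) -> np.ndarray:
    scale = 10.0**digits
    return np.trunc(np.asarray(a, dtype=float) * scale) / scale


def _series(trace, name: str) -> np.ndarray:
    names = list(trace.names)
    if name not in names:
        raise PLTLcError(f"unknown variable {name!r}")
    return np.asarray(trace.values)[:, names.index(name)]


def _derivative(trace, name: str, digits: int) -> np.ndarray:
    # the derivative of the *truncated* series: flat-to-quantisation
    # segments give an exact zero, every residual drift shows up as a
    # +/- one-quantum step -- this is what makes the steady-state
    # detectors of the category library work on slowly relaxing traces
    x = _truncate(_series(trace, name), digits)
    t = np.asarray(trace.times, dtype=float)
    d = np.empty_like(x, dtype=float)
    if len(x) < 2:
        return np.zeros_like(d)
    d[:-1] = np.diff(x) / np.diff(t)
    d[-1] = d[-2]
    return d


def _eval_numeric(f: Formula, trace, subst: str | None, digits: int) -> np.ndarray:
    n = len(trace.times)

    def resolve(name):
        if name == "$x":
            if subst is None:
                raise PLTLcError("free variable $x in a closed evaluation")
            return subst
        return name

    if f.op == "lit":
        return np.full(n, f.value)
    if f.op == "var":
        return _truncate(_series(trace, resolve(f.value)), digits)
    if f.op == "deriv":
        return _derivative(trace, resolve(f.value), digits)
    if f.op == "maxv":
        return np.full(n, _truncate(_series(trace, resolve(f.value)).max(), digits))
    a = _eval_numeric(f.args[0], trace, subst, digits)
    b = _eval_numeric(f.args[1], trace, subst, digits)
    if f.op == "add":
        return a + b
    if f.op == "sub":
        return a - b
    if f.op == "mul":
        return a * b
    if f.op == "div":
        return a / b
    raise PLTLcError(f"bad numeric node {f.op}")


_CMP = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
    "=": np.equal,
    "!=": np.not_equal,
}


def _eval_bool(f: Formula, trace, subst: str | None, digits: int) -> np.ndarray:
    """Satisfaction vector: sat[i] == formula holds at time point i."""
    if f.op == "cmp":
        a = _eval_numeric(f.args[0], trace, subst, digits)
        b = _eval_numeric(f.args[1], trace, subst, digits)
        return _CMP[f.value](a, b)
    if f.op == "not":
        return ~_eval_bool(f.args[0], trace, subst, digits)
    if f.op == "and":
        return _eval_bool(f.args[0], trace, subst, digits) & _eval_bool(
            f.args[1], trace, subst, digits
        )
    if f.op == "or":
        return _eval_bool(f.args[0], trace, subst, digits) | _eval_bool(
            f.args[1], trace, subst, digits
        )
    if f.op == "implies":
        return ~_eval_bool(f.args[0], trace, subst, digits) | _eval_bool(
            f.args[1], trace, subst, digits
        )
    if f.op == "G":
        sat = _eval_bool(f.args[0], trace, subst, digits)
        return np.flip(np.logical_and.accumulate(np.flip(sat)))
    if f.op == "F":
        sat = _eval_bool(f.args[0], trace, subst, digits)
        return np.flip(np.logical_or.accumulate(np.flip(sat)))
    if f.op == "U":
        f1 = _eval_bool(f.args[0], trace, subst, digits)
        f2 = _eval_bool(f.args[1], trace, subst, digits)
        out = np.empty_like(f1)
        nxt = False
        for i in range(len(f1) - 1, -1, -1):
            out[i] = f2[i] or (f1[i] and nxt)
            nxt = out[i]
        return out
    raise PLTLcError(f"bad boolean node {f.op}")


def _strip_prob(f: Formula):
    if f.op == "prob":
        return f.args[0], f.value
    return f, (">=", 1.0)


def evaluate(f: Formula | str, trace, digits: int = 2) -> bool:
    """Evaluate a closed formula on one trace (satisfaction at time 0)."""
    if isinstance(f, str):
        f = parse(f)
    body, (op, theta) = _strip_prob(f)
    if body.free_variable:
        raise PLTLcError("formula has a free variable; use evaluate_free")
    p = 1.0 if bool(_eval_bool(body, trace, None, digits)[0]) else 0.0
    return bool(_CMP[op](p, theta))


def evaluate_free(f: Formula | str, trace, digits: int = 2) -> set[str]:
    """Set of species names satisfying a formula with free variable $x."""
    if isinstance(f, str):
        f = parse(f)
    body, (op, theta) = _strip_prob(f)
    out = set()
    for name in trace.names:
        p = 1.0 if bool(_eval_bool(body, trace, name, digits)[0]) else 0.0
        if _CMP[op](p, theta):
            out.add(name)
    return out


def probability(f: Formula | str, runs, digits: int = 2) -> float:
    """Fraction of runs whose trace satisfies the (closed) path formula."""
    if isinstance(f, str):
        f = parse(f)
    body, _ = _strip_prob(f)
    if not runs:
        raise PLTLcError("probability needs at least one run")
    hits = sum(bool(_eval_bool(body, tr, None, digits)[0]) for tr in runs)
    return hits / len(runs)


# ---------------------------------------------------------------------------
# behaviour-category library
# ---------------------------------------------------------------------------

#: The six-category behaviour library used to validate the AI-2 production
#: component, ordered; a species is assigned the first matching category.
CATEGORIES: dict[str, str] = {
    "always steady state zero": "P>=1[ G([$x]=0) ]",
    "always steady state above zero": "P>=1[ G(d[$x]=0 & [$x]>0) ]",
    "decreasing weakly until steady state zero": (
        "P>=1[ G(d[$x]<=0) & !G(d[$x]=0) & "
        "((G(d[$x]<=0) & !G(d[$x]=0)) U (G(d[$x]=0 & [$x]=0))) ]"
    ),
    "increasing weakly until steady state": (
        "P>=1[ G(d[$x]>=0) & !G(d[$x]=0) & "
        "((G(d[$x]>=0) & !G(d[$x]=0)) U (G(d[$x]=0))) ]"
    ),
    "peaks once and falls weakly until steady state zero": (
        "P>=1[ d[$x]>0 & (d[$x]>0 U (G(d[$x]<=0) U (G(d[$x]=0 & [$x]=0)))) ]"
    ),
    "falls and rises to peak before falling weakly until steady state zero": (
        "P>=1[ (d[$x]<0) & (d[$x]<0 U F((d[$x]>0) & (d[$x]>0 U "
        "F((d[$x]<0) & (d[$x]<0 U (G(d[$x]=0) & [$x]=0)))))) ]"
    ),
}

CATEGORY_ORDER = list(CATEGORIES)


def classify(trace, digits: int = 2) -> dict[str, str]:
    """Assign every trace variable its first matching behaviour category
    (or ``"unclassified"``)."""
    parsed = {name: parse(text) for name, text in CATEGORIES.items()}
    result: dict[str, str] = {}
    for species in trace.names:
        result[species] = "unclassified"
        for cat in CATEGORY_ORDER:
            body, (op, theta) = _strip_prob(parsed[cat])
            p = 1.0 if bool(_eval_bool(body, trace, species, digits)[0]) else 0.0
            if _CMP[op](p, theta):
                result[species] = cat
                break
    return result
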