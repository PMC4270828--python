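"""The 25 integer combination functions.

Every slot of the model hierarchy combines two integer operands with one of
25 total (never-failing) functions, organised into the groups Basic,
Logical, Bitwise, Unary, Large and Miscellaneous. All functions map a pair
of integers to an integer; undefined cases (division by zero, negative
factorials, ...) return 0, and results saturate at the 32-bit two's
complement range so that chained factorials/powers cannot blow up and
liability supports stay finite.

Unary functions (ABS, NOT, FAC, plus LOG) act on the left operand and
ignore the right, consistent with LEFT/RIGHT being operand selectors.
XOR is arithmetic parity, (a + b) mod 2: on genotype inputs this makes a
single operand carry no information about the output while both operands
determine it completely — the pure-epistasis mechanism. It coincides with
MOD2; both names are kept because both appear in model specifications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .distributions import DiscreteDistribution

__all__ = [
    "MathFunction",
    "FUNCTIONS",
    "FUNCTION_NAMES",
    "function_by_index",
    "normalize_function_name",
    "apply_function",
    "function_output_distribution",
    "INT_MIN",
    "INT_MAX",
]

INT_MIN = -(2**31)
INT_MAX = 2**31 - 1


def _clamp(v: int) -> int:
    if v > INT_MAX:
        return INT_MAX
    if v < INT_MIN:
        return INT_MIN
    return v


def _div(a: int, b: int) -> int:
    # truncated (toward-zero) integer division; x/0 -> 0
    if b == 0:
        return 0
    q = abs(a) // abs(b)
    return -q if (a < 0) != (b < 0) else q


def _mod(a: int, b: int) -> int:
    # remainder with the sign of b (Python semantics); x mod 0 -> 0
    return a % b if b != 0 else 0


def _fac(a: int, b: int) -> int:
    if a < 0:
        return 0
    if a > 12:  # 13! exceeds the saturation range
        return INT_MAX
    return math.factorial(a)


def _pow(a: int, b: int) -> int:
    if b < 0:
        return 0
    if a == 0:
        return 1 if b == 0 else 0
    if a == 1:
        return 1
    if a == -1:
        return -1 if b % 2 else 1
    # |a| >= 2: saturate without computing huge intermediates
    if (abs(a).bit_length() - 1) * b > 40:
        negative = a < 0 and b % 2 == 1
        return INT_MIN if negative else INT_MAX
    return _clamp(a**b)


def _log(a: int, b: int) -> int:
    # floor(log2 |a|) for |a| >= 1, else 0; unary in the left operand
    a = abs(a)
    return a.bit_length() - 1 if a >= 1 else 0


def _per(a: int, b: int) -> int:
    # falling factorial a!/(a-b)! for 0 <= b <= a, else 0
    if b < 0 or b > a:
        return 0
    result = 1
    for i in range(b):
        result *= a - i
        if result > INT_MAX:
            return INT_MAX
    return result


def _chs(a: int, b: int) -> int:
    # binomial coefficient C(a, b) for 0 <= b <= a, else 0
    if b < 0 or b > a:
        return 0
    k = min(b, a - b)
    result = 1
    for i in range(k):
        result = result * (a - i) // (i + 1)
        if result > INT_MAX:
            return INT_MAX
    return result


@dataclass(frozen=True)
class MathFunction:
    """One of the 25 combination functions.

    ``index`` is the canonical position (0-24) used by the search encoding;
    ``symbol`` is the operator glyph accepted as an alias in configs.
    """

    name: str
    group: str
    index: int
    symbol: str
    func: callable

    def __call__(self, a: int, b: int) -> int:
        return _clamp(self.func(int(a), int(b)))


_TABLE = [
    # name, group, symbol, implementation
    ("ADD", "Basic", "+", lambda a, b: a + b),
    ("SUB", "Basic", "-", lambda a, b: a - b),
    ("MULT", "Basic", "*", lambda a, b: a * b),
    ("DIV", "Basic", "/", _div),
    ("MOD", "Basic", "%", _mod),
    ("MOD2", "Basic", "MOD2", lambda a, b: (a + b) & 1),
    ("GT", "Logical", ">", lambda a, b: 1 if a > b else 0),
    ("LT", "Logical", "<", lambda a, b: 1 if a < b else 0),
    ("AND", "Logical", "&&", lambda a, b: 1 if (a != 0 and b != 0) else 0),
    ("OR", "Logical", "||", lambda a, b: 1 if (a != 0 or b != 0) else 0),
    ("XOR", "Logical", "^^", lambda a, b: (a + b) & 1),
    ("BITA", "Bitwise", "&", lambda a, b: a & b),
    ("BITO", "Bitwise", "|", lambda a, b: a | b),
    ("BITX", "Bitwise", "^", lambda a, b: a ^ b),
    ("ABS", "Unary", "ABS", lambda a, b: abs(a)),
    ("NOT", "Unary", "~", lambda a, b: ~a),
    ("FAC", "Unary", "!", _fac),
    ("LEFT", "Unary", "LEFT", lambda a, b: a),
    ("RIGHT", "Unary", "RIGHT", lambda a, b: b),
    ("POW", "Large", "POW", _pow),
    ("LOG", "Large", "LOG", _log),
    ("PER", "Large", "P", _per),
    ("CHS", "Large", "C", _chs),
    ("MIN", "Miscellaneous", "MIN", min),
    ("MAX", "Miscellaneous", "MAX", max),
]

FUNCTIONS: dict[str, MathFunction] = {
    name: MathFunction(name, group, i, symbol, impl)
    for i, (name, group, symbol, impl) in enumerate(_TABLE)
}

FUNCTION_NAMES: tuple[str, ...] = tuple(FUNCTIONS)

_ALIASES: dict[str, str] = {f.symbol: name for name, f in FUNCTIONS.items()}
_ALIASES.update({"x": "MULT", "×": "MULT", "÷": "DIV", "−": "SUB", "⊕": "BITX", "∥": "OR", "∼": "NOT"})


def normalize_function_name(name: str) -> str:
    """Resolve a function name or operator symbol (case-insensitively) to
    its canonical upper-case name, raising ``KeyError`` for unknown names."""
    key = str(name).strip()
    if key.upper() in FUNCTIONS:
        return key.upper()
    if key in _ALIASES:
        return _ALIASES[key]
    raise KeyError(f"unknown function name or symbol: {name!r}")


def function_by_index(index: int) -> MathFunction:
    """Canonical function at position ``index`` (0-24)."""
    return FUNCTIONS[FUNCTION_NAMES[index]]


def apply_function(name: str, a: int, b: int) -> int:
    """Apply one of the 25 functions to a pair of integers.

    Total: never raises for integer operands; undefined cases return 0 and
    results saturate at the 32-bit range.
    """
    return FUNCTIONS[normalize_function_name(name)](a, b)


def function_output_distribution(
    name: str,
    dist_a: DiscreteDistribution,
    dist_b: DiscreteDistribution,
) -> DiscreteDistribution:
    """Exact pushforward distribution of ``f(A, B)`` for independent ``A, B``.

    P(out = x) = sum over (u, v) with f(u, v) = x of P_A(u) * P_B(v).
    """
    fn = FUNCTIONS[normalize_function_name(name)]
    out: dict[int, float] = {}
    for u, pu in dist_a.items():
        for v, pv in dist_b.items():
            x = fn(u, v)
            out[x] = out.get(x, 0.0) + pu * pv
    return DiscreteDistribution(out)
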