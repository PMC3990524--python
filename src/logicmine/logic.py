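"""Entropies, Boolean logic functions and uncertainty coefficients.

The central quantity is the uncertainty coefficient

    U(c | x) = [H(x) + H(c) - H(x, c)] / H(c) = I(x; c) / H(c),

the fraction of the entropy of a target vector ``c`` explained by a
predictor ``x``.  ``U = 0`` for empirically independent vectors and
``U = 1`` when ``c`` is a deterministic function of ``x``.  A *lower*
relationship scores a single feature against a phenotype (the value is
invariant under negation of the feature, so one number covers both the
identity and the negation reading); a *higher* relationship scores the
Boolean combination ``f(a, b)`` of two features, where ``f`` ranges over the
ten two-input logic functions.  Output-complement partners (e.g. AND/NAND)
produce bitwise-complementary vectors and hence identical coefficients, so
the ten functions collapse into five scoring classes; within the winning
class the reported type is chosen by rule confidence.

All entropies are in bits (base 2); only ratios of entropies are used
downstream, so the base cancels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import xlogy

from logicmine.errors import InapplicableRule, ValidationError

_LN2 = np.log(2.0)


# ---------------------------------------------------------------------------
# logic-function registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogicFunction:
    """A Boolean function of one or two binary inputs.

    ``truth_table`` lists the output for each input combination in
    lexicographic order of the inputs: ``(f(0), f(1))`` for arity 1 and
    ``(f(0,0), f(0,1), f(1,0), f(1,1))`` for arity 2.
    ``complement_partner`` is the ``type_index`` of the function whose
    output is the bitwise complement of this one; partnering is an
    involution.
    """

    arity: int
    type_index: int
    name: str
    truth_table: tuple[int, ...]
    complement_partner: int

    def __call__(self, a: np.ndarray, b: np.ndarray | None = None) -> np.ndarray:
        return apply_logic(self, a, b)


def _mk(arity: int, idx: int, name: str, table: tuple[int, ...], partner: int) -> LogicFunction:
    return LogicFunction(arity, idx, name, table, partner)


#: Lower (arity-1) functions: Type 1 reads "feature present iff phenotype
#: present", Type 2 the negated reading.
LOWER_FUNCTIONS: Mapping[int, LogicFunction] = {
    1: _mk(1, 1, "IDENTITY", (0, 1), 2),
    2: _mk(1, 2, "NOT", (1, 0), 1),
}

#: Higher (arity-2) functions.  Type 1 = AND and Type 8 = XOR are fixed;
#: the remaining canonical functions fill the other indices in registry
#: order.  Every output also carries its unambiguous symbolic name.
HIGHER_FUNCTIONS: Mapping[int, LogicFunction] = {
    1: _mk(2, 1, "AND", (0, 0, 0, 1), 5),
    2: _mk(2, 2, "OR", (0, 1, 1, 1), 6),
    3: _mk(2, 3, "A_ANDN_B", (0, 0, 1, 0), 9),
    4: _mk(2, 4, "NOTA_AND_B", (0, 1, 0, 0), 7),
    5: _mk(2, 5, "NAND", (1, 1, 1, 0), 1),
    6: _mk(2, 6, "NOR", (1, 0, 0, 0), 2),
    7: _mk(2, 7, "A_ORN_B", (1, 0, 1, 1), 4),
    8: _mk(2, 8, "XOR", (0, 1, 1, 0), 10),
    9: _mk(2, 9, "NOTA_OR_B", (1, 1, 0, 1), 3),
    10: _mk(2, 10, "XNOR", (1, 0, 0, 1), 8),
}

#: One representative per output-complement class, in scoring order.
HIGHER_CLASS_REPRESENTATIVES: tuple[LogicFunction, ...] = (
    HIGHER_FUNCTIONS[1],   # AND / NAND
    HIGHER_FUNCTIONS[2],   # OR / NOR
    HIGHER_FUNCTIONS[3],   # a AND NOT b / NOT a OR b
    HIGHER_FUNCTIONS[4],   # NOT a AND b / a OR NOT b
    HIGHER_FUNCTIONS[8],   # XOR / XNOR
)

_BY_NAME = {f.name: f for f in (*LOWER_FUNCTIONS.values(), *HIGHER_FUNCTIONS.values())}


def function_by_name(name: str) -> LogicFunction:
    try:
        return _BY_NAME[name]
    except KeyError:
        raise ValidationError(f"unknown logic function name: {name!r}") from None


def partner_of(f: LogicFunction) -> LogicFunction:
    registry = LOWER_FUNCTIONS if f.arity == 1 else HIGHER_FUNCTIONS
    return registry[f.complement_partner]


def registry_table() -> list[dict]:
    """Machine-readable export of the logic-type registry."""
    rows = []
    for f in (*LOWER_FUNCTIONS.values(), *HIGHER_FUNCTIONS.values()):
        rows.append(
            {
                "arity": f.arity,
                "type_index": f.type_index,
                "name": f.name,
                "truth_table": list(f.truth_table),
                "complement_partner": f.complement_partner,
            }
        )
    return rows


# ---------------------------------------------------------------------------
# vector validation and entropies
# ---------------------------------------------------------------------------

def as_binary_vector(v: Sequence[int] | np.ndarray, what: str = "vector") -> np.ndarray:
    arr = np.asarray(v)
    if arr.ndim != 1:
        raise ValidationError(f"{what} must be one-dimensional")
    if arr.size == 0:
        raise ValidationError(f"{what} is empty")
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{what} contains values outside {{0, 1}}")
    return arr.astype(np.uint8)


def _check_same_length(a: np.ndarray, b: np.ndarray) -> None:
    if a.size != b.size:
        raise ValidationError(f"length mismatch: {a.size} vs {b.size}")


def binary_entropy_from_counts(ones, n):
    """Entropy in bits of a 0/1 vector with ``ones`` ones out of ``n`` (vectorised)."""
    ones = np.asarray(ones, dtype=np.float64)
    p = ones / n
    return -(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / _LN2


def joint_entropy_from_counts(n11, na, nc, n):
    """Joint entropy in bits of two 0/1 vectors from their 2x2 contingency counts."""
    n11 = np.asarray(n11, dtype=np.float64)
    na = np.asarray(na, dtype=np.float64)
    nc = np.asarray(nc, dtype=np.float64)
    n10 = na - n11
    n01 = nc - n11
    n00 = n - na - nc + n11
    h = np.zeros(np.broadcast(n11, na, nc).shape, dtype=np.float64)
    for k in (n11, n10, n01, n00):
        p = k / n
        h = h - xlogy(p, p)
    return h / _LN2


def mutual_information_from_counts(n11, na, nc, n):
    """I(a; c) in bits from contingency counts; tiny negative rounding is clipped."""
    mi = (
        binary_entropy_from_counts(na, n)
        + binary_entropy_from_counts(nc, n)
        - joint_entropy_from_counts(n11, na, nc, n)
    )
    return np.maximum(mi, 0.0)


def entropy(v: Sequence[int] | np.ndarray) -> float:
    """Shannon entropy H(v) in bits of a binary vector (0*log 0 == 0)."""
    arr = as_binary_vector(v)
    return float(binary_entropy_from_counts(int(arr.sum()), arr.size))


def joint_entropy(a: Sequence[int] | np.ndarray, b: Sequence[int] | np.ndarray) -> float:
    """Joint entropy H(a, b) in bits over the four joint states."""
    av = as_binary_vector(a, "a")
    bv = as_binary_vector(b, "b")
    _check_same_length(av, bv)
    n11 = int((av & bv).sum())
    return float(joint_entropy_from_counts(n11, int(av.sum()), int(bv.sum()), av.size))


# ---------------------------------------------------------------------------
# logic application
# ---------------------------------------------------------------------------

def apply_logic(
    f: LogicFunction,
    a: Sequence[int] | np.ndarray,
    b: Sequence[int] | np.ndarray | None = None,
) -> np.ndarray:
    """Elementwise truth-table application of ``f`` to its argument vector(s)."""
    av = as_binary_vector(a, "a")
    table = np.asarray(f.truth_table, dtype=np.uint8)
    if f.arity == 1:
        if b is not None:
            raise ValidationError(f"{f.name} has arity 1 but got two arguments")
        return table[av]
    if b is None:
        raise ValidationError(f"{f.name} has arity 2 but got one argument")
    bv = as_binary_vector(b, "b")
    _check_same_length(av, bv)
    return table[(av.astype(np.intp) << 1) | bv]


# ---------------------------------------------------------------------------
# uncertainty coefficients
# ---------------------------------------------------------------------------

def _u(n11: int, nx: int, nc: int, n: int, denom_ones: int) -> float:
    h_denom = binary_entropy_from_counts(denom_ones, n)
    mi = mutual_information_from_counts(n11, nx, nc, n)
    u = float(mi / h_denom)
    return min(max(u, 0.0), 1.0)


def u_lower_forward(a, c) -> float:
    """U(c | a): phenotype ``c`` predicted by a single feature ``a``.

    Identical for the identity and negated reading of ``a`` (mutual
    information is invariant under input negation), so one value covers
    both lower logic types.
    """
    av = as_binary_vector(a, "a")
    cv = as_binary_vector(c, "c")
    _check_same_length(av, cv)
    if cv.min() == cv.max():
        raise ValidationError("undefined uncertainty (zero-entropy target)")
    n = av.size
    na = int(av.sum())
    nc = int(cv.sum())
    n11 = int((av & cv).sum())
    # canonicalize (a vs NOT a) so the invariance holds bit-exactly, not
    # merely to rounding: both readings share one count representation
    if 2 * na > n or (2 * na == n and n11 > nc - n11):
        na, n11 = n - na, nc - n11
    return _u(n11, na, nc, n, nc)


def u_higher_forward(a, b, c) -> tuple[dict[str, float], float]:
    """Five class coefficients U(c | f(a, b)) and their maximum.

    One value per output-complement class, keyed by the class
    representative's name; the overall pair score is the maximum.
    """
    av = as_binary_vector(a, "a")
    bv = as_binary_vector(b, "b")
    cv = as_binary_vector(c, "c")
    _check_same_length(av, bv)
    _check_same_length(av, cv)
    if cv.min() == cv.max():
        raise ValidationError("undefined uncertainty (zero-entropy target)")
    nc = int(cv.sum())
    values: dict[str, float] = {}
    for f in HIGHER_CLASS_REPRESENTATIVES:
        v = apply_logic(f, av, bv)
        n11 = int((v & cv).sum())
        values[f.name] = _u(n11, int(v.sum()), nc, av.size, nc)
    return values, max(values.values())


def u_reverse(x, c) -> float:
    """U(x | c): feature (or composed logic output) ``x`` predicted by ``c``."""
    xv = as_binary_vector(x, "x")
    cv = as_binary_vector(c, "c")
    _check_same_length(xv, cv)
    if xv.min() == xv.max():
        raise ValidationError("undefined uncertainty (zero-entropy target)")
    n11 = int((xv & cv).sum())
    return _u(n11, int(xv.sum()), int(cv.sum()), xv.size, int(xv.sum()))


def confidence(f: LogicFunction, args, c) -> float:
    """Confidence of the rule "f(args) = 1 implies c = 1".

    P(f(args) = 1 and c = 1) / P(f(args) = 1).  Raises
    :class:`InapplicableRule` when the antecedent is never true.
    """
    if f.arity == 1:
        v = apply_logic(f, args)
    else:
        v = apply_logic(f, args[0], args[1])
    cv = as_binary_vector(c, "c")
    _check_same_length(v, cv)
    ones = int(v.sum())
    if ones == 0:
        raise InapplicableRule(f"antecedent {f.name}(args) = 1 never holds")
    return float((v & cv).sum()) / ones


def select_logic_type(candidates: tuple[LogicFunction, LogicFunction], args, c) -> LogicFunction:
    """Pick the member of an output-complement pair with the greater confidence.

    Both candidates share the same uncertainty coefficient by construction;
    confidence breaks the tie.  An inapplicable rule (antecedent never true)
    loses to an applicable one; on an exact tie the lower ``type_index``
    wins (documented tie-break).
    """
    scored = []
    for f in candidates:
        try:
            conf = confidence(f, args, c)
        except InapplicableRule:
            conf = -np.inf
        scored.append((f, conf))
    scored.sort(key=lambda fc: (-fc[1], fc[0].type_index))
    return scored[0][0]
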