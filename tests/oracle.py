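"""Independent brute-force oracles built on explicit joint-probability tables.

Everything here uses Counter dictionaries and math.log2 only, sharing no
code path with the package implementation it checks.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations


def joint_probs(*vectors) -> dict[tuple, float]:
    n = len(vectors[0])
    counts = Counter(zip(*vectors))
    return {state: k / n for state, k in counts.items()}


def entropy_oracle(*vectors) -> float:
    return -sum(p * math.log2(p) for p in joint_probs(*vectors).values() if p > 0)


def mi_oracle(a, c) -> float:
    return entropy_oracle(a) + entropy_oracle(c) - entropy_oracle(a, c)


def u_forward_oracle(x, c) -> float:
    """U(c | x) = I(x; c) / H(c)."""
    return mi_oracle(x, c) / entropy_oracle(c)


def u_reverse_oracle(x, c) -> float:
    """U(x | c) = I(x; c) / H(x)."""
    return mi_oracle(x, c) / entropy_oracle(x)


def confidence_oracle(v, c) -> float:
    """P(c = 1 | v = 1) from explicit joint counts."""
    both = sum(1 for vi, ci in zip(v, c) if vi == 1 and ci == 1)
    ones = sum(1 for vi in v if vi == 1)
    return both / ones


def apply_table(table, a, b=None):
    if b is None:
        return [table[ai] for ai in a]
    return [table[2 * ai + bi] for ai, bi in zip(a, b)]


def hypergeom_upper_oracle(N: int, B: int, n: int, b: int) -> float:
    """P[X >= b] by exhaustive enumeration of all C(N, n) draws.

    The first B items of the universe are the annotated ones.
    """
    total = 0
    hits = 0
    for draw in combinations(range(N), n):
        total += 1
        if sum(1 for item in draw if item < B) >= b:
            hits += 1
    return hits / total if total else 1.0
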