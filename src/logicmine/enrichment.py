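"""Hypergeometric over-representation and enrichment scores for term sets.

For a universe of N items of which B are annotated to a term, and a
selection of n items of which b are annotated, the p-value is the
hypergeometric upper tail P[X >= b] and the enrichment score is
(b/n)/(B/N).  Items may be genes or unordered gene pairs; a gene pair is
annotated to the unordered pairs of terms formed from its two members'
annotations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from logicmine.errors import ValidationError


@dataclass
class EnrichmentResult:
    term: Hashable
    N: int
    B: int
    n: int
    b: int
    p_value: float
    enrichment: float


def _check_counts(N: int, B: int, n: int, b: int) -> None:
    if min(N, B, n, b) < 0:
        raise ValidationError("counts must be non-negative")
    if B > N or n > N:
        raise ValidationError(f"B ({B}) and n ({n}) must not exceed N ({N})")
    if b > min(n, B):
        raise ValidationError(f"b ({b}) exceeds min(n, B) = {min(n, B)}")


def hypergeom_p(N: int, B: int, n: int, b: int) -> float:
    """Upper-tail P[X >= b] of the hypergeometric distribution."""
    _check_counts(N, B, n, b)
    if b == 0:
        return 1.0
    return float(hypergeom.sf(b - 1, N, B, n))


def enrichment_score(N: int, B: int, n: int, b: int) -> float:
    """(b/n) / (B/N)."""
    _check_counts(N, B, n, b)
    if n == 0 or B == 0:
        raise ValidationError("enrichment undefined for n = 0 or B = 0")
    return (b / n) / (B / N)


def enrich_terms(
    selected: Iterable[Hashable],
    annotation: Mapping[Hashable, Iterable[Hashable]],
    universe: Iterable[Hashable],
    p_max: float = 1.0,
    e_min: float = 0.0,
) -> list[EnrichmentResult]:
    """Score every term annotating the universe; filter and sort by p.

    ``annotation`` maps an item (gene or gene pair) to its terms (or term
    pairs).  Counts use the stated universe; results with p <= p_max and
    enrichment >= e_min are returned sorted by (p, term).
    """
    universe_set = set(universe)
    selected_set = set(selected)
    outside = selected_set - universe_set
    if outside:
        raise ValidationError(f"selected items outside the universe: {sorted(outside)[:5]}")
    term_items: dict[Hashable, set] = {}
    for item in universe_set:
        for term in annotation.get(item, ()):
            term_items.setdefault(term, set()).add(item)
    N = len(universe_set)
    n = len(selected_set)
    results = []
    for term, items in term_items.items():
        B = len(items)
        b = len(items & selected_set)
        p = hypergeom_p(N, B, n, b)
        e = enrichment_score(N, B, n, b) if n > 0 else 0.0
        if p <= p_max and e >= e_min:
            results.append(EnrichmentResult(term, N, B, n, b, p, e))
    results.sort(key=lambda r: (r.p_value, str(r.term)))
    return results


def pair_annotation(
    gene_annotation: Mapping[str, Iterable[Hashable]],
    gene_pairs: Iterable[tuple[str, str]],
) -> dict[frozenset, set[frozenset]]:
    """Annotation of unordered gene pairs by unordered term pairs.

    The pair (g1, g2) is annotated to every {t1, t2} with t1 from g1's
    terms and t2 from g2's.
    """
    out: dict[frozenset, set[frozenset]] = {}
    for g1, g2 in gene_pairs:
        terms = set()
        for t1 in gene_annotation.get(g1, ()):
            for t2 in gene_annotation.get(g2, ()):
                terms.add(frozenset((t1, t2)))
        out[frozenset((g1, g2))] = terms
    return out
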