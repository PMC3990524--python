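"""Discovery scans for lower (single-feature) and higher (feature-pair) relationships.

A feature and a phenotype form a *lower* relationship when the uncertainty
coefficients in both directions exceed the lower threshold: the feature's
state is then both a sufficient and a necessary condition for the
phenotype.  A feature pair forms a *higher* relationship with a phenotype
when the best of the five output-complement class coefficients and the
reverse coefficient of the composed vector both exceed the higher
threshold AND neither member on its own holds a lower relationship with
that phenotype (the exclusion rule: pairs are only reported where the
combination carries information that no single member already carries).

With exactly two complementary phenotypes every relationship with one
phenotype implies the partner relationship with the other, obtained by
negating the logic function's output; ``propagate_complement`` performs
that lift.

The scans are vectorised over contingency-table counts: for binary
vectors every entropy in U is a function of the 2x2 table, and the tables
for all feature pairs and all ten logic functions derive from the Gram
matrices ``M @ M.T`` and ``(M * c) @ M.T`` plus row marginals.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from logicmine.errors import ValidationError
from logicmine.logic import (
    HIGHER_CLASS_REPRESENTATIVES,
    HIGHER_FUNCTIONS,
    LOWER_FUNCTIONS,
    LogicFunction,
    binary_entropy_from_counts,
    function_by_name,
    mutual_information_from_counts,
    partner_of,
)
from logicmine.matrices import check_phenotype_profiles

#: Symmetric higher classes report their two features in lexicographic
#: order; asymmetric ones (a AND NOT b etc.) keep explicit argument order.
_SYMMETRIC = {"AND", "OR", "XOR", "NAND", "NOR", "XNOR"}


@dataclass
class LogicRelationship:
    """A discovered feature(s)-phenotype logic relationship."""

    feature_ids: tuple[str, ...]
    phenotype: str
    logic_type: LogicFunction
    u_forward: float
    u_reverse: float
    confidence: float | None = None
    p_value: float | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        if len(self.feature_ids) != self.logic_type.arity:
            raise ValidationError(
                f"{self.logic_type.name} has arity {self.logic_type.arity} "
                f"but relationship names {len(self.feature_ids)} feature(s)"
            )

    @property
    def coefficient(self) -> float:
        """Mean of the forward and reverse uncertainty coefficients."""
        return 0.5 * (self.u_forward + self.u_reverse)

    @property
    def key(self) -> tuple[tuple[str, ...], str, int]:
        """Identity of the relationship: features, phenotype and logic type."""
        return (self.feature_ids, self.phenotype, self.logic_type.type_index)


def _threshold_value(t, which: str) -> float:
    if hasattr(t, which):
        return float(getattr(t, which))
    return float(t)


def _matrix_arrays(m: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    arr = m.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError("binary matrix contains values outside {0, 1}")
    return arr.astype(np.uint8), [str(i) for i in m.index]


def _phenotype_rows(p: pd.DataFrame, phenotypes: Sequence[str] | None) -> list[str]:
    names = [str(i) for i in p.index] if phenotypes is None else list(phenotypes)
    for name in names:
        if name not in p.index:
            raise ValidationError(f"unknown phenotype {name!r}")
    return names


def lower_u_arrays(M: np.ndarray, c: np.ndarray):
    """Forward/reverse U of every matrix row against ``c`` (NaN for constant rows)."""
    n = M.shape[1]
    nc = int(c.sum())
    if nc == 0 or nc == n:
        raise ValidationError("undefined uncertainty (zero-entropy phenotype)")
    na = M.sum(axis=1, dtype=np.int64)
    n11 = M @ c.astype(np.int64)
    mi = mutual_information_from_counts(n11, na, nc, n)
    h_c = binary_entropy_from_counts(nc, n)
    h_a = binary_entropy_from_counts(na, n)
    nonconst = (na > 0) & (na < n)
    with np.errstate(divide="ignore", invalid="ignore"):
        u_fwd = np.where(nonconst, mi / h_c, np.nan)
        u_rev = np.where(nonconst, mi / h_a, np.nan)
    return np.clip(u_fwd, 0, 1), np.clip(u_rev, 0, 1), na, n11


def scan_lower(
    m: pd.DataFrame,
    p: pd.DataFrame,
    t,
    phenotypes: Sequence[str] | None = None,
    features: Iterable[str] | None = None,
) -> list[LogicRelationship]:
    """Emit a lower relationship wherever both U directions strictly exceed ``t``.

    Constant feature rows are skipped (their U is inapplicable); a constant
    phenotype row is a hard error.  The logic type (identity vs. negation)
    is chosen by rule confidence, ties going to the lower type index.
    """
    t_l = _threshold_value(t, "t_lower")
    if features is not None:
        keep = [f for f in m.index if str(f) in set(map(str, features))]
        m = m.loc[keep]
    M, feature_ids = _matrix_arrays(m)
    n = M.shape[1]
    out: list[LogicRelationship] = []
    for ph in _phenotype_rows(p, phenotypes):
        c = p.loc[ph].to_numpy().astype(np.uint8)
        u_fwd, u_rev, na, n11 = lower_u_arrays(M, c)
        nc = int(c.sum())
        with np.errstate(invalid="ignore"):
            hits = np.where((u_fwd > t_l) & (u_rev > t_l))[0]
        for i in hits:
            conf_id = n11[i] / na[i]
            conf_not = (nc - n11[i]) / (n - na[i])
            if conf_id >= conf_not:
                func, conf = LOWER_FUNCTIONS[1], conf_id
            else:
                func, conf = LOWER_FUNCTIONS[2], conf_not
            out.append(
                LogicRelationship(
                    feature_ids=(feature_ids[i],),
                    phenotype=ph,
                    logic_type=func,
                    u_forward=float(u_fwd[i]),
                    u_reverse=float(u_rev[i]),
                    confidence=float(conf),
                )
            )
    return out


def pair_class_counts(
    na_i: np.ndarray, na_j: np.ndarray, s_and: np.ndarray,
    na11_i: np.ndarray, na11_j: np.ndarray, x_and: np.ndarray,
    class_name: str,
):
    """Ones-count and joint 1-1 count of ``f(a_i, a_j)`` vs. the phenotype.

    All five class representatives reduce to linear combinations of the
    AND counts and the row marginals.
    """
    if class_name == "AND":
        return s_and, x_and
    if class_name == "OR":
        return na_i + na_j - s_and, na11_i + na11_j - x_and
    if class_name == "A_ANDN_B":
        return na_i - s_and, na11_i - x_and
    if class_name == "NOTA_AND_B":
        return na_j - s_and, na11_j - x_and
    if class_name == "XOR":
        return na_i + na_j - 2 * s_and, na11_i + na11_j - 2 * x_and
    raise ValidationError(f"not a class representative: {class_name}")


def _select_higher_type(rep: LogicFunction, ones: float, n11: float, nc: int, n: int):
    """Confidence tie-break between a class representative and its partner."""
    conf_rep = n11 / ones if ones > 0 else -np.inf
    ones_p = n - ones
    conf_par = (nc - n11) / ones_p if ones_p > 0 else -np.inf
    partner = HIGHER_FUNCTIONS[rep.complement_partner]
    if conf_rep >= conf_par:
        if conf_rep == conf_par and partner.type_index < rep.type_index:
            return partner, float(conf_par)
        return rep, float(conf_rep)
    return partner, float(conf_par)


def scan_higher(
    m: pd.DataFrame,
    p: pd.DataFrame,
    t,
    lower_rels: Sequence[LogicRelationship] = (),
    candidate_features: Iterable[str] | None = None,
    phenotypes: Sequence[str] | None = None,
    chunk_rows: int = 512,
) -> list[LogicRelationship]:
    """Scan all unordered feature pairs for higher logic relationships.

    Pairs in which either member already holds a lower relationship with
    the phenotype are excluded.  ``candidate_features`` restricts the scan
    to an explicit feature subset (for very large matrices); the default
    scans everything.  ``chunk_rows`` bounds memory by processing the pair
    matrix in row blocks.
    """
    t_h = _threshold_value(t, "t_higher")
    M_all, ids_all = _matrix_arrays(m)
    n = M_all.shape[1]
    lower_by_ph: dict[str, set[str]] = {}
    for rel in lower_rels:
        lower_by_ph.setdefault(rel.phenotype, set()).update(rel.feature_ids)
    cand = None if candidate_features is None else set(map(str, candidate_features))
    out: list[LogicRelationship] = []
    for ph in _phenotype_rows(p, phenotypes):
        c = p.loc[ph].to_numpy().astype(np.uint8)
        nc = int(c.sum())
        if nc == 0 or nc == n:
            raise ValidationError("undefined uncertainty (zero-entropy phenotype)")
        h_c = binary_entropy_from_counts(nc, n)
        excluded = lower_by_ph.get(ph, set())
        row_sums = M_all.sum(axis=1)
        eligible = [
            k
            for k, fid in enumerate(ids_all)
            if fid not in excluded
            and 0 < row_sums[k] < n
            and (cand is None or fid in cand)
        ]
        if len(eligible) < 2:
            continue
        E = M_all[eligible]
        ids = [ids_all[k] for k in eligible]
        A = E.astype(np.float64)
        Ac = (E * c).astype(np.float64)
        na = E.sum(axis=1, dtype=np.int64).astype(np.float64)
        na11 = (E @ c.astype(np.int64)).astype(np.float64)
        F = len(eligible)
        for start in range(0, F, chunk_rows):
            stop = min(start + chunk_rows, F)
            s_and = A[start:stop] @ A.T
            x_and = Ac[start:stop] @ A.T
            na_i = na[start:stop, None]
            na11_i = na11[start:stop, None]
            best_u = np.full(s_and.shape, -1.0)
            best_cls = np.zeros(s_and.shape, dtype=np.int8)
            best_ones = np.zeros(s_and.shape)
            best_n11 = np.zeros(s_and.shape)
            for ci, rep in enumerate(HIGHER_CLASS_REPRESENTATIVES):
                ones, n11 = pair_class_counts(
                    na_i, na[None, :], s_and, na11_i, na11[None, :], x_and, rep.name
                )
                valid = (ones > 0) & (ones < n)
                mi = mutual_information_from_counts(n11, ones, nc, n)
                u_fwd = np.where(valid, np.clip(mi / h_c, 0, 1), -1.0)
                better = u_fwd > best_u
                best_u = np.where(better, u_fwd, best_u)
                best_cls = np.where(better, ci, best_cls)
                best_ones = np.where(better, ones, best_ones)
                best_n11 = np.where(better, n11, best_n11)
            h_v = binary_entropy_from_counts(best_ones, n)
            mi_best = mutual_information_from_counts(best_n11, best_ones, nc, n)
            with np.errstate(divide="ignore", invalid="ignore"):
                u_rev = np.clip(mi_best / h_v, 0, 1)
            # only unordered pairs i < j
            jj = np.arange(F)[None, :]
            ii = np.arange(start, stop)[:, None]
            mask = (best_u > t_h) & (u_rev > t_h) & (ii < jj)
            for r, cix in zip(*np.nonzero(mask)):
                i = start + r
                j = int(cix)
                rep = HIGHER_CLASS_REPRESENTATIVES[int(best_cls[r, j])]
                func, conf = _select_higher_type(
                    rep, float(best_ones[r, j]), float(best_n11[r, j]), nc, n
                )
                fi, fj = ids[i], ids[j]
                if func.name in _SYMMETRIC and fj < fi:
                    fi, fj = fj, fi
                out.append(
                    LogicRelationship(
                        feature_ids=(fi, fj),
                        phenotype=ph,
                        logic_type=func,
                        u_forward=float(best_u[r, j]),
                        u_reverse=float(u_rev[r, j]),
                        confidence=conf,
                    )
                )
    return out


def propagate_complement(
    rels: Sequence[LogicRelationship],
    p: pd.DataFrame,
    m: pd.DataFrame | None = None,
) -> list[LogicRelationship]:
    """Lift each relationship to the complementary phenotype.

    Requires exactly two bitwise-complementary phenotype rows.  The partner
    relationship uses the output-complement logic type and identical U
    values (negating the target leaves mutual information and both
    marginal entropies unchanged).  Confidence of the partnered rule is
    recomputed when the binary matrix is supplied, otherwise left unset.
    Applying the operation twice returns the original relationships.
    """
    check_phenotype_profiles(p)
    if p.shape[0] != 2:
        raise ValidationError("complement propagation requires exactly two phenotypes")
    rows = p.to_numpy().astype(np.uint8)
    if not ((rows[0] ^ rows[1]) == 1).all():
        raise ValidationError("phenotype rows are not bitwise complementary")
    other = {str(p.index[0]): str(p.index[1]), str(p.index[1]): str(p.index[0])}
    out: list[LogicRelationship] = []
    for rel in rels:
        partner = partner_of(rel.logic_type)
        conf = None
        if m is not None:
            from logicmine.logic import confidence as _confidence

            c2 = p.loc[other[rel.phenotype]].to_numpy().astype(np.uint8)
            args = [m.loc[f].to_numpy().astype(np.uint8) for f in rel.feature_ids]
            conf = _confidence(partner, args[0] if partner.arity == 1 else args, c2)
        out.append(
            dataclasses.replace(
                rel,
                phenotype=other[rel.phenotype],
                logic_type=partner,
                confidence=conf,
            )
        )
    return out


def filter_by_types(
    rels: Sequence[LogicRelationship], wanted: Iterable[str]
) -> list[LogicRelationship]:
    """Keep only relationships whose logic type name is in ``wanted``."""
    wanted_names = {function_by_name(name).name for name in wanted}
    return [r for r in rels if r.logic_type.name in wanted_names]


def relationships_to_frame(rels: Sequence[LogicRelationship]) -> pd.DataFrame:
    """Tabular report: one row per relationship."""
    rows = []
    for r in rels:
        rows.append(
            {
                "features": ";".join(r.feature_ids),
                "phenotype": r.phenotype,
                "type_index": r.logic_type.type_index,
                "type_name": r.logic_type.name,
                "arity": r.logic_type.arity,
                "u_forward": r.u_forward,
                "u_reverse": r.u_reverse,
                "coefficient": r.coefficient,
                "confidence": r.confidence,
                "p_value": r.p_value,
                "q": r.q,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "features", "phenotype", "type_index", "type_name", "arity",
            "u_forward", "u_reverse", "coefficient", "confidence", "p_value", "q",
        ],
    )
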