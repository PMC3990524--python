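"""Permutation null model: thresholds, p-values, positive FDR and recurrence.

The null model randomizes vectors while preserving their 0/1 histograms
(a uniformly random permutation); feature pairs are permuted jointly so
the pairwise distribution is preserved as well.  Discovery thresholds are
the maximum uncertainty coefficient observed anywhere in the randomized
data, taken over all combinations, all trials and both directions, so a
relationship is accepted only if it beats everything the null ever
produced.  (A trial-averaged variant is available via
``threshold_stat="trial-mean"``.)

For a binary vector permuted against a fixed partner, the joint 1-1 count
is exactly hypergeometric and the marginal entropies are permutation
invariant, so randomized U values are sampled directly from hypergeometric
counts where only per-combination values are needed; wherever the
correlation between the five class coefficients of one triplet matters
(p-values, FDR counting) an explicit shared permutation is used instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from logicmine.errors import ValidationError
from logicmine.logic import (
    HIGHER_CLASS_REPRESENTATIVES,
    binary_entropy_from_counts,
    mutual_information_from_counts,
)
from logicmine.discovery import (
    LogicRelationship,
    lower_u_arrays,
    pair_class_counts,
)


@dataclass
class NullConfig:
    """Trial counts and sampling sizes for the permutation null.

    Every count the method needs is configurable; the defaults are desk
    scale.  ``n_trials`` drives p-values, ``n_threshold_trials`` the
    threshold randomization, ``triplet_sample_fraction`` the share of all
    feature pairs sampled when randomizing triplets, ``n_fdr_datasets``
    the number of independent random datasets (and repeats) for the
    positive FDR, and ``n_cv_trials``/``cv_counts`` the specimen
    subsampling for recurrence rates.
    """

    n_trials: int = 1000
    n_threshold_trials: int = 100
    seed: int | None = None
    triplet_sample_fraction: float = 0.01
    n_fdr_datasets: int = 20
    n_cv_trials: int = 100
    cv_counts: Mapping[str, int] | int | None = None
    threshold_stat: str = "max"
    q_min: float = 0.5

    def __post_init__(self) -> None:
        for name in ("n_trials", "n_threshold_trials", "n_fdr_datasets", "n_cv_trials"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be a positive integer")
        if not (0.0 < self.triplet_sample_fraction <= 1.0):
            raise ValidationError("triplet_sample_fraction must be in (0, 1]")
        if self.threshold_stat not in ("max", "trial-mean"):
            raise ValidationError("threshold_stat must be 'max' or 'trial-mean'")

    def rng(self, rng: np.random.Generator | int | None = None) -> np.random.Generator:
        if isinstance(rng, np.random.Generator):
            return rng
        if rng is None:
            rng = self.seed
        return np.random.default_rng(rng)


@dataclass
class Thresholds:
    """Lower/higher discovery thresholds plus the configuration that made them."""

    t_lower: float
    t_higher: float
    provenance: NullConfig | None = field(default=None, repr=False)


@dataclass
class RecurrenceResult:
    key: tuple
    n_recur: int
    n_trials: int

    @property
    def q(self) -> float:
        return self.n_recur / self.n_trials


# ---------------------------------------------------------------------------
# randomization primitives
# ---------------------------------------------------------------------------

def permute_preserving_histogram(v, rng: np.random.Generator) -> np.ndarray:
    """Uniformly random permutation of ``v`` (0/1 counts unchanged)."""
    arr = np.asarray(v)
    return arr[rng.permutation(arr.size)]


def permute_pair_preserving_joint(a, b, rng: np.random.Generator):
    """Jointly permute the columns of a stacked pair.

    The joint 2-bit histogram of the output equals that of the input, so
    individual and pairwise distributions are both preserved; the target
    vector is left untouched by the caller.
    """
    av = np.asarray(a)
    bv = np.asarray(b)
    if av.size != bv.size:
        raise ValidationError(f"length mismatch: {av.size} vs {bv.size}")
    perm = rng.permutation(av.size)
    return av[perm], bv[perm]


# ---------------------------------------------------------------------------
# randomized U sampling (internal)
# ---------------------------------------------------------------------------

def _null_u_draws(na: np.ndarray, nc: int, n: int, trials: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Randomized (forward, reverse) U draws for vectors with ``na`` ones vs.
    a target with ``nc`` ones: the permuted joint count is hypergeometric and
    the marginal entropies are fixed."""
    na = np.asarray(na, dtype=np.int64)
    n11 = rng.hypergeometric(na[:, None], n - na[:, None], nc, size=(na.size, trials))
    mi = mutual_information_from_counts(n11, na[:, None], nc, n)
    h_c = binary_entropy_from_counts(nc, n)
    h_x = binary_entropy_from_counts(na, n)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        u_fwd = np.clip(mi / h_c, 0, 1)
        u_rev = np.clip(mi / h_x, 0, 1)
    return u_fwd, u_rev


def _sample_pairs(n_features: int, fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``fraction`` of all unordered index pairs without replacement."""
    n_pairs = n_features * (n_features - 1) // 2
    n_take = max(1, int(np.ceil(fraction * n_pairs)))
    ks = rng.choice(n_pairs, size=n_take, replace=False)
    # decode linear index k into (i, j), i < j, row-major upper triangle
    i = (
        n_features
        - 2
        - np.floor(np.sqrt(-8.0 * ks + 4.0 * n_features * (n_features - 1) - 7) / 2.0 - 0.5)
    ).astype(np.int64)
    j = ks - (i * (2 * n_features - i - 1) // 2) + i + 1
    return i, j.astype(np.int64)


def _composed_class_stats(E: np.ndarray, c: np.ndarray, i: np.ndarray, j: np.ndarray):
    """Ones counts and actual joint counts of the five composed vectors for
    the sampled pairs (i, j)."""
    n = E.shape[1]
    na = E.sum(axis=1, dtype=np.int64)
    na11 = E @ c.astype(np.int64)
    s = (E[i] & E[j]).sum(axis=1, dtype=np.int64)
    x = (E[i] & E[j] & c).sum(axis=1, dtype=np.int64)
    ones, n11 = [], []
    for rep in HIGHER_CLASS_REPRESENTATIVES:
        o, m11 = pair_class_counts(na[i], na[j], s, na11[i], na11[j], x, rep.name)
        ones.append(o)
        n11.append(m11)
    return np.stack(ones), np.stack(n11)  # (5, n_pairs)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def compute_thresholds(
    m: pd.DataFrame,
    p: pd.DataFrame,
    cfg: NullConfig,
    rng: np.random.Generator | int | None = None,
    phenotypes: Sequence[str] | None = None,
) -> Thresholds:
    """Randomize every pairwise and (sampled) triplet combination and take the
    extreme randomized U as the discovery thresholds.

    ``t_lower`` ranges over all feature-phenotype pairs, ``t_higher`` over a
    ``triplet_sample_fraction`` sample of all feature-pair-phenotype
    triplets; both directions enter the statistic.
    """
    rng = cfg.rng(rng)
    M = m.to_numpy().astype(np.uint8)
    n = M.shape[1]
    na = M.sum(axis=1, dtype=np.int64)
    nonconst = (na > 0) & (na < n)
    if not nonconst.any():
        raise ValidationError("all feature rows are constant")
    names = [str(i) for i in p.index] if phenotypes is None else list(phenotypes)
    T = cfg.n_threshold_trials
    t_lower = 0.0
    t_higher = 0.0
    any_pheno = False
    for ph in names:
        c = p.loc[ph].to_numpy().astype(np.uint8)
        nc = int(c.sum())
        if nc == 0 or nc == n:
            continue
        any_pheno = True
        u_fwd, u_rev = _null_u_draws(na[nonconst], nc, n, T, rng)
        if cfg.threshold_stat == "max":
            t_lower = max(t_lower, float(u_fwd.max()), float(u_rev.max()))
        else:
            t_lower = max(
                t_lower, float(u_fwd.mean(axis=1).max()), float(u_rev.mean(axis=1).max())
            )
        # triplets: the composed vector of a jointly permuted pair is the
        # permuted composed vector, so each class is randomized by
        # histogram-preserving permutation of f(a, b)
        E = M[nonconst]
        i, j = _sample_pairs(E.shape[0], cfg.triplet_sample_fraction, rng)
        ones, _ = _composed_class_stats(E, c, i, j)
        for k in range(ones.shape[0]):
            ok = (ones[k] > 0) & (ones[k] < n)
            if not ok.any():
                continue
            u_fwd, u_rev = _null_u_draws(ones[k][ok], nc, n, T, rng)
            if cfg.threshold_stat == "max":
                t_higher = max(t_higher, float(u_fwd.max()), float(u_rev.max()))
            else:
                t_higher = max(
                    t_higher,
                    float(u_fwd.mean(axis=1).max()),
                    float(u_rev.mean(axis=1).max()),
                )
    if not any_pheno:
        raise ValidationError("no nonconstant phenotype row")
    return Thresholds(t_lower=t_lower, t_higher=t_higher, provenance=cfg)


# ---------------------------------------------------------------------------
# p-values
# ---------------------------------------------------------------------------

def _permuted_targets(c: np.ndarray, trials: int, rng) -> np.ndarray:
    """(trials, n) matrix of independent permutations of ``c``."""
    order = np.argsort(rng.random((trials, c.size)), axis=1)
    return c[order]


def p_values(
    rels: Sequence[LogicRelationship],
    m: pd.DataFrame,
    p: pd.DataFrame,
    cfg: NullConfig,
    rng: np.random.Generator | int | None = None,
) -> list[float]:
    """Permutation p-value per relationship (also stored on ``rel.p_value``).

    Fraction of trials in which the randomized forward OR the randomized
    reverse coefficient exceeds the corresponding actual value; trials
    that tie the actual value exactly count one half (mid-p correction —
    the permutation null of U is discrete with sizeable atoms, and
    counting ties fully in or fully out would bias null p-values away
    from uniformity).  Triplets are randomized with one shared permutation
    per trial so the five class coefficients keep their mutual
    correlation; the per-trial forward value is the class maximum and the
    reverse value follows that trial's winning class, mirroring the
    actual computation.
    """
    rng = cfg.rng(rng)
    T = cfg.n_trials
    n = m.shape[1]
    out: list[float] = []
    for rel in rels:
        c = p.loc[rel.phenotype].to_numpy().astype(np.uint8)
        nc = int(c.sum())
        h_c = binary_entropy_from_counts(nc, n)
        if rel.logic_type.arity == 1:
            a = m.loc[rel.feature_ids[0]].to_numpy().astype(np.uint8)
            u_fwd, u_rev = _null_u_draws(
                np.array([a.sum()]), nc, n, T, rng
            )
            greater = (u_fwd[0] > rel.u_forward) | (u_rev[0] > rel.u_reverse)
            tied = ~greater & (
                (u_fwd[0] == rel.u_forward) | (u_rev[0] == rel.u_reverse)
            )
        else:
            a = m.loc[rel.feature_ids[0]].to_numpy().astype(np.uint8)
            b = m.loc[rel.feature_ids[1]].to_numpy().astype(np.uint8)
            V = np.stack(
                [rep(a, b) for rep in HIGHER_CLASS_REPRESENTATIVES]
            ).astype(np.int64)  # (5, n)
            ones = V.sum(axis=1)
            h_v = binary_entropy_from_counts(ones, n)
            C = _permuted_targets(c, T, rng).astype(np.int64)  # (T, n)
            n11 = C @ V.T  # (T, 5)
            mi = mutual_information_from_counts(n11, ones[None, :], nc, n)
            with np.errstate(divide="ignore", invalid="ignore"):
                u_fwd_cls = np.where(
                    (ones > 0) & (ones < n), np.clip(mi / h_c, 0, 1), -1.0
                )
            best = np.argmax(u_fwd_cls, axis=1)
            rows = np.arange(T)
            u_fwd_trial = u_fwd_cls[rows, best]
            with np.errstate(divide="ignore", invalid="ignore"):
                u_rev_trial = np.clip(mi[rows, best] / h_v[best], 0, 1)
            greater = (u_fwd_trial > rel.u_forward) | (u_rev_trial > rel.u_reverse)
            tied = ~greater & (
                (u_fwd_trial == rel.u_forward) | (u_rev_trial == rel.u_reverse)
            )
        pv = (float(greater.sum()) + 0.5 * float(tied.sum())) / T
        rel.p_value = pv
        out.append(pv)
    return out


# ---------------------------------------------------------------------------
# positive FDR
# ---------------------------------------------------------------------------

def count_lower_discoveries(M: np.ndarray, c: np.ndarray, t_lower: float) -> int:
    """Number of rows whose bidirectional U both strictly exceed ``t_lower``."""
    u_fwd, u_rev, _, _ = lower_u_arrays(M, c)
    with np.errstate(invalid="ignore"):
        return int(((u_fwd > t_lower) & (u_rev > t_lower)).sum())


def fdr_lower(
    m: pd.DataFrame,
    p: pd.DataFrame,
    t: Thresholds,
    cfg: NullConfig,
    rng: np.random.Generator | int | None = None,
    actual_count: int | None = None,
    phenotypes: Sequence[str] | None = None,
) -> float | None:
    """Estimated positive FDR for lower relationships.

    Mean discovery count over ``n_fdr_datasets`` independently randomized
    datasets (every feature row permuted independently, phenotypes fixed),
    divided by the actual discovery count.  ``None`` when there are no
    actual discoveries (FDR not applicable).
    """
    rng = cfg.rng(rng)
    names = [str(i) for i in p.index] if phenotypes is None else list(phenotypes)
    M = m.to_numpy().astype(np.uint8)
    cs = [p.loc[ph].to_numpy().astype(np.uint8) for ph in names]
    if actual_count is None:
        actual_count = sum(count_lower_discoveries(M, c, t.t_lower) for c in cs)
    if actual_count == 0:
        warnings.warn("no actual lower discoveries: FDR not applicable")
        return None
    counts = []
    for _ in range(cfg.n_fdr_datasets):
        Mr = rng.permuted(M, axis=1)
        counts.append(sum(count_lower_discoveries(Mr, c, t.t_lower) for c in cs))
    return float(np.mean(counts)) / actual_count


def _count_higher_in_sample(
    E: np.ndarray,
    c: np.ndarray,
    i: np.ndarray,
    j: np.ndarray,
    t: Thresholds,
    randomize: bool,
    rng,
    chunk: int = 65536,
) -> int:
    """Count sampled pairs discovered as higher relationships.

    Applies the full rule: best class forward and its reverse above
    ``t_higher`` and neither member a lower relationship (both member
    directions above ``t_lower``).  With ``randomize=True`` each pair is
    jointly permuted against the fixed phenotype (implemented as one
    shared permuted phenotype per pair, identical in law).
    """
    n = E.shape[1]
    nc = int(c.sum())
    h_c = binary_entropy_from_counts(nc, n)
    total = 0
    for s0 in range(0, i.size, chunk):
        ii = i[s0 : s0 + chunk]
        jj = j[s0 : s0 + chunk]
        if randomize:
            C = _permuted_targets(c, ii.size, rng).astype(np.uint8)  # (B, n)
        else:
            C = np.broadcast_to(c, (ii.size, n))
        Ai, Aj = E[ii], E[jj]
        na_i = Ai.sum(axis=1, dtype=np.int64)
        na_j = Aj.sum(axis=1, dtype=np.int64)
        na11_i = (Ai & C).sum(axis=1, dtype=np.int64)
        na11_j = (Aj & C).sum(axis=1, dtype=np.int64)
        s = (Ai & Aj).sum(axis=1, dtype=np.int64)
        x = (Ai & Aj & C).sum(axis=1, dtype=np.int64)
        # member lower-relationship status under the same randomization
        def _bidir(n11, na):
            mi = mutual_information_from_counts(n11, na, nc, n)
            h_a = binary_entropy_from_counts(na, n)
            with np.errstate(divide="ignore", invalid="ignore"):
                ok = (na > 0) & (na < n)
                return ok & (mi / h_c > t.t_lower) & (
                    np.where(ok, mi / np.where(h_a > 0, h_a, 1.0), 0.0) > t.t_lower
                )
        member_lower = _bidir(na11_i, na_i) | _bidir(na11_j, na_j)
        found = np.zeros(ii.size, dtype=bool)
        for rep in HIGHER_CLASS_REPRESENTATIVES:
            ones, n11 = pair_class_counts(na_i, na_j, s, na11_i, na11_j, x, rep.name)
            ok = (ones > 0) & (ones < n)
            mi = mutual_information_from_counts(n11, ones, nc, n)
            h_v = binary_entropy_from_counts(ones, n)
            with np.errstate(divide="ignore", invalid="ignore"):
                u_fwd = np.where(ok, mi / h_c, 0.0)
                u_rev = np.where(ok, mi / np.where(h_v > 0, h_v, 1.0), 0.0)
            found |= (u_fwd > t.t_higher) & (u_rev > t.t_higher)
        total += int((found & ~member_lower).sum())
    return total


def fdr_higher(
    m: pd.DataFrame,
    p: pd.DataFrame,
    t: Thresholds,
    cfg: NullConfig,
    rng: np.random.Generator | int | None = None,
    phenotypes: Sequence[str] | None = None,
    fraction: float | None = None,
) -> float | None:
    """Estimated positive FDR for higher (triplet) relationships.

    Each repeat samples the same triplet subset in the actual and the
    randomized data and counts discoveries in both; the FDR is the mean of
    the per-repeat random/actual ratios.  Repeats with zero actual
    discoveries are skipped with a warning; ``None`` if every repeat was
    skipped.
    """
    rng = cfg.rng(rng)
    frac = cfg.triplet_sample_fraction if fraction is None else fraction
    names = [str(i) for i in p.index] if phenotypes is None else list(phenotypes)
    M = m.to_numpy().astype(np.uint8)
    n = M.shape[1]
    na = M.sum(axis=1, dtype=np.int64)
    E = M[(na > 0) & (na < n)]
    ratios = []
    skipped = 0
    for _ in range(cfg.n_fdr_datasets):
        r_act = 0
        r_rand = 0
        for ph in names:
            c = p.loc[ph].to_numpy().astype(np.uint8)
            i, j = _sample_pairs(E.shape[0], frac, rng)
            r_act += _count_higher_in_sample(E, c, i, j, t, False, rng)
            r_rand += _count_higher_in_sample(E, c, i, j, t, True, rng)
        if r_act == 0:
            skipped += 1
            continue
        ratios.append(r_rand / r_act)
    if not ratios:
        warnings.warn(
            f"all {cfg.n_fdr_datasets} FDR repeats had zero actual triplet "
            "discoveries in the sample: FDR not applicable"
        )
        return None
    if skipped:
        warnings.warn(f"{skipped} FDR repeat(s) skipped (no actual discoveries in sample)")
    return float(np.mean(ratios))


# ---------------------------------------------------------------------------
# recurrence (cross validation by specimen subsampling)
# ---------------------------------------------------------------------------

def recurrence(
    rels: Sequence[LogicRelationship],
    m: pd.DataFrame,
    p: pd.DataFrame,
    cfg: NullConfig,
    rng: np.random.Generator | int | None = None,
) -> list[RecurrenceResult]:
    """Recurrence rate Q = n_recur / n_trials per relationship.

    Each trial subsamples a fixed number of specimens per phenotype
    (preserving column order), recomputes thresholds on the subsample and
    re-discovers; a relationship recurs when the same features, phenotype
    and logic type are found again.  Results are stored on ``rel.q`` as
    well.
    """
    from logicmine.discovery import scan_higher, scan_lower

    rng = cfg.rng(rng)
    counts_cfg = cfg.cv_counts
    rows = p.to_numpy().astype(np.uint8)
    class_sizes = {str(p.index[k]): int(rows[k].sum()) for k in range(p.shape[0])}
    if counts_cfg is None:
        counts_cfg = min(class_sizes.values())
    if isinstance(counts_cfg, int):
        counts = {ph: counts_cfg for ph in class_sizes}
    else:
        counts = dict(counts_cfg)
    for ph, want in counts.items():
        if want > class_sizes.get(ph, 0):
            raise ValidationError(
                f"cv count {want} exceeds the {class_sizes.get(ph, 0)} specimens "
                f"of phenotype {ph!r}"
            )
    cand_single = sorted({f for r in rels if r.logic_type.arity == 1 for f in r.feature_ids})
    cand_pairf = sorted({f for r in rels if r.logic_type.arity == 2 for f in r.feature_ids})
    phenos = sorted({r.phenotype for r in rels})
    n_recur = {r.key: 0 for r in rels}
    for _ in range(cfg.n_cv_trials):
        keep = np.zeros(m.shape[1], dtype=bool)
        for k, ph in enumerate([str(i) for i in p.index]):
            members = np.where(rows[k] == 1)[0]
            take = counts.get(ph, members.size)
            keep[rng.choice(members, size=take, replace=False)] = True
        cols = m.columns[keep]
        m_sub = m.loc[:, cols]
        p_sub = p.loc[:, cols]
        t_sub = compute_thresholds(m_sub, p_sub, cfg, rng, phenotypes=phenos)
        found_low = scan_lower(m_sub, p_sub, t_sub, phenotypes=phenos,
                               features=cand_single + cand_pairf)
        found = {r.key for r in found_low}
        if cand_pairf:
            found |= {
                r.key
                for r in scan_higher(
                    m_sub, p_sub, t_sub, found_low,
                    candidate_features=cand_pairf, phenotypes=phenos,
                )
            }
        for key in n_recur:
            if key in found:
                n_recur[key] += 1
    results = []
    for r in rels:
        res = RecurrenceResult(key=r.key, n_recur=n_recur[r.key], n_trials=cfg.n_cv_trials)
        r.q = res.q
        results.append(res)
    return results
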