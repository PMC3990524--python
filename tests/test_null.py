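"""Randomization primitives, thresholds, p-values, FDR and recurrence."""

import numpy as np
import pandas as pd
import pytest

from logicmine import (
    NullConfig,
    ValidationError,
    compute_thresholds,
    fdr_higher,
    fdr_lower,
    generate,
    p_values,
    permute_pair_preserving_joint,
    permute_preserving_histogram,
    recurrence,
    scan_higher,
    scan_lower,
    SyntheticConfig,
)
from logicmine.nullmodel import Thresholds, _null_u_draws, _sample_pairs

from conftest import random_nonconstant
from oracle import u_forward_oracle, u_reverse_oracle


class TestPermutations:
    def test_histogram_preserved_every_trial(self, rng):
        v = random_nonconstant(rng, 37)
        for _ in range(50):
            w = permute_preserving_histogram(v, rng)
            assert w.sum() == v.sum() and w.size == v.size

    def test_constant_vector_is_fixed_point(self, rng):
        v = np.ones(9, dtype=np.uint8)
        assert (permute_preserving_histogram(v, rng) == v).all()

    def test_fixed_seed_reproducible(self):
        v = np.arange(20) % 2
        a = permute_preserving_histogram(v, np.random.default_rng(5))
        b = permute_preserving_histogram(v, np.random.default_rng(5))
        assert (a == b).all()

    def test_joint_histogram_preserved(self, rng):
        a = random_nonconstant(rng, 40)
        b = random_nonconstant(rng, 40)
        a2, b2 = permute_pair_preserving_joint(a, b, rng)
        from collections import Counter

        assert Counter(zip(a, b)) == Counter(zip(a2, b2))
        assert a2.sum() == a.sum() and b2.sum() == b.sum()

    def test_identical_pair_stays_identical(self, rng):
        a = random_nonconstant(rng, 15)
        a2, b2 = permute_pair_preserving_joint(a, a.copy(), rng)
        assert (a2 == b2).all()

    def test_length_mismatch(self, rng):
        with pytest.raises(ValidationError):
            permute_pair_preserving_joint([1, 0], [1, 0, 1], rng)


class TestNullDraws:
    def test_hypergeometric_draws_match_explicit_permutation_null(self):
        """The vectorised null sampler must agree in distribution with
        literally permuting the vector (two-sample KS on 4000 draws)."""
        from scipy.stats import ks_2samp

        rng = np.random.default_rng(7)
        n, T = 48, 4000
        a = random_nonconstant(rng, n)
        c = random_nonconstant(rng, n)
        u_fast, _ = _null_u_draws(np.array([a.sum()]), int(c.sum()), n, T, rng)
        u_slow = np.array(
            [
                u_forward_oracle(permute_preserving_histogram(a, rng), c)
                for _ in range(T)
            ]
        )
        # round away 1e-16 jitter so identical atoms coincide
        assert ks_2samp(np.round(u_fast[0], 10), np.round(u_slow, 10)).statistic < 0.05

    def test_sample_pairs_decodes_upper_triangle(self):
        rng = np.random.default_rng(3)
        i, j = _sample_pairs(30, 1.0, rng)
        assert i.size == 30 * 29 // 2
        assert (i < j).all() and i.min() >= 0 and j.max() < 30
        assert len({(x, y) for x, y in zip(i, j)}) == i.size


class TestThresholds:
    def test_deterministic_under_fixed_seed(self, small_dataset):
        m, p, _, _ = small_dataset
        cfg = NullConfig(n_threshold_trials=30, triplet_sample_fraction=0.1)
        t1 = compute_thresholds(m, p, cfg, rng=9)
        t2 = compute_thresholds(m, p, cfg, rng=9)
        assert (t1.t_lower, t1.t_higher) == (t2.t_lower, t2.t_higher)

    def test_thresholds_positive_but_small_on_null_data(self, rng):
        m = pd.DataFrame(
            (rng.random((60, 40)) < 0.4).astype(np.int8),
            index=[f"f{i}" for i in range(60)],
            columns=[f"s{j}" for j in range(40)],
        )
        p = pd.DataFrame(
            [np.r_[np.ones(20), np.zeros(20)].astype(np.int8),
             np.r_[np.zeros(20), np.ones(20)].astype(np.int8)],
            index=["A", "B"],
            columns=m.columns,
        )
        t = compute_thresholds(m, p, NullConfig(n_threshold_trials=50), rng=1)
        assert 0.0 < t.t_lower < 1.0
        assert 0.0 < t.t_higher < 1.0

    def test_all_constant_features_error(self):
        m = pd.DataFrame(np.ones((3, 4), dtype=np.int8), index=list("abc"),
                         columns=list("wxyz"))
        p = pd.DataFrame([[1, 1, 0, 0], [0, 0, 1, 1]], index=["A", "B"], columns=m.columns)
        with pytest.raises(ValidationError, match="constant"):
            compute_thresholds(m, p, NullConfig(n_threshold_trials=5), rng=0)

    def test_trial_mean_variant_is_below_max_variant(self, small_dataset):
        m, p, _, _ = small_dataset
        t_max = compute_thresholds(
            m, p, NullConfig(n_threshold_trials=40, threshold_stat="max"), rng=2
        )
        t_mean = compute_thresholds(
            m, p, NullConfig(n_threshold_trials=40, threshold_stat="trial-mean"), rng=2
        )
        assert t_mean.t_lower < t_max.t_lower


class TestPValues:
    def test_noise_free_plants_get_zero(self, small_dataset):
        m, p, _, truth = small_dataset
        t = compute_thresholds(m, p, NullConfig(n_threshold_trials=50), rng=0,
                               phenotypes=["AC"])
        lower = scan_lower(m, p, t, phenotypes=["AC"])
        higher = scan_higher(m, p, t, lower, phenotypes=["AC"])
        rels = lower + higher
        assert rels, "plants must be discovered"
        pv = p_values(rels, m, p, NullConfig(n_trials=200), rng=1)
        planted = {k for r in truth.planted for k in r.feature_ids}
        for rel, value in zip(rels, pv):
            if set(rel.feature_ids) <= planted and rel.u_forward == 1.0:
                assert value == 0.0
            assert rel.p_value == value

    def test_single_trial_exceed_gives_one(self, toy_matrix):
        from logicmine.discovery import LogicRelationship
        from logicmine.logic import LOWER_FUNCTIONS

        m, p = toy_matrix
        rel = LogicRelationship(("f1",), "A", LOWER_FUNCTIONS[1], -0.1, -0.1)
        (pv,) = p_values([rel], m, p, NullConfig(n_trials=1), rng=0)
        assert pv == 1.0  # any random draw beats a negative "actual"

    def test_null_features_have_dispersed_p_values(self, rng):
        """p-values of pure-noise features spread over (0, 1) with a
        median near one half (null calibration at small scale)."""
        from logicmine.discovery import LogicRelationship, lower_u_arrays
        from logicmine.logic import LOWER_FUNCTIONS

        n = 60
        m = pd.DataFrame(
            (rng.random((80, n)) < 0.5).astype(np.int8),
            index=[f"f{i}" for i in range(80)],
            columns=[f"s{j}" for j in range(n)],
        )
        c = np.r_[np.ones(30), np.zeros(30)].astype(np.uint8)
        p = pd.DataFrame([c, 1 - c], index=["A", "B"], columns=m.columns)
        u_fwd, u_rev, _, _ = lower_u_arrays(m.to_numpy().astype(np.uint8), c)
        rels = [
            LogicRelationship((f"f{i}",), "A", LOWER_FUNCTIONS[1], u_fwd[i], u_rev[i])
            for i in range(80)
        ]
        pv = np.array(p_values(rels, m, p, NullConfig(n_trials=200), rng=3))
        assert 0.25 < np.median(pv) < 0.75


class TestFDR:
    def _planted(self):
        cfg = SyntheticConfig(
            n_per_phenotype=(20, 20), n_background=150, lower_plants={1: 3, 2: 3},
            lower_noise=0.0, higher_plants={"XOR": 2}, higher_noise=0.0, seed=21,
        )
        return generate(cfg)

    def test_clean_plants_have_zero_fdr(self):
        m, p, _, _ = self._planted()
        cfg = NullConfig(n_threshold_trials=60, n_fdr_datasets=10,
                         triplet_sample_fraction=0.2)
        t = compute_thresholds(m, p, cfg, rng=0, phenotypes=["AC"])
        lower = scan_lower(m, p, t, phenotypes=["AC"])
        assert len(lower) >= 6
        assert fdr_lower(m, p, t, cfg, rng=1, actual_count=len(lower),
                         phenotypes=["AC"]) == 0.0

    def test_no_actual_discoveries_is_not_applicable(self):
        m, p, _, _ = self._planted()
        cfg = NullConfig(n_fdr_datasets=3)
        sky_high = Thresholds(t_lower=2.0, t_higher=2.0)
        with pytest.warns(UserWarning, match="not applicable"):
            assert fdr_lower(m, p, sky_high, cfg, rng=0, phenotypes=["AC"]) is None

    def test_permissive_threshold_on_noise_gives_fdr_one(self, rng):
        # with a threshold below every U, all features are "discovered" in
        # actual and random data alike, so the estimated FDR is exactly 1
        m = pd.DataFrame(
            (rng.random((40, 30)) < 0.5).astype(np.int8),
            index=[f"f{i}" for i in range(40)],
            columns=[f"s{j}" for j in range(30)],
        )
        p = pd.DataFrame(
            [np.r_[np.ones(15), np.zeros(15)].astype(np.int8),
             np.r_[np.zeros(15), np.ones(15)].astype(np.int8)],
            index=["A", "B"], columns=m.columns,
        )
        loose = Thresholds(t_lower=-1.0, t_higher=-1.0)
        cfg = NullConfig(n_fdr_datasets=4)
        assert fdr_lower(m, p, loose, cfg, rng=2, phenotypes=["A"]) == 1.0

    def test_fdr_higher_zero_on_clean_plants(self):
        m, p, _, _ = self._planted()
        cfg = NullConfig(n_threshold_trials=60, n_fdr_datasets=6,
                         triplet_sample_fraction=0.2)
        t = compute_thresholds(m, p, cfg, rng=0, phenotypes=["AC"])
        value = fdr_higher(m, p, t, cfg, rng=3, phenotypes=["AC"], fraction=0.9)
        assert value == 0.0


class TestRecurrence:
    def test_noise_free_plants_always_recur(self, small_dataset):
        m, p, _, _ = small_dataset
        cfg = NullConfig(
            n_threshold_trials=30, n_cv_trials=6, cv_counts=12,
            triplet_sample_fraction=0.2,
        )
        t = compute_thresholds(m, p, cfg, rng=0, phenotypes=["AC"])
        lower = scan_lower(m, p, t, phenotypes=["AC"])
        higher = scan_higher(m, p, t, lower, phenotypes=["AC"])
        rels = lower + higher
        results = recurrence(rels, m, p, cfg, rng=5)
        for rel, res in zip(rels, results):
            if rel.u_forward == 1.0:
                assert res.q == 1.0
            assert res.n_trials == 6
            assert rel.q == res.q

    def test_infeasible_counts_error(self, small_dataset):
        m, p, _, _ = small_dataset
        cfg = NullConfig(n_cv_trials=2, cv_counts=999)
        with pytest.raises(ValidationError, match="exceeds"):
            recurrence([], m, p, cfg, rng=0)
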