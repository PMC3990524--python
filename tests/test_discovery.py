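"""Discovery scans, the exclusion rule, complement propagation and filters."""

import numpy as np
import pandas as pd
import pytest

from logicmine import (
    ValidationError,
    filter_by_types,
    propagate_complement,
    scan_higher,
    scan_lower,
)
from logicmine.discovery import LogicRelationship, relationships_to_frame
from logicmine.logic import HIGHER_FUNCTIONS, LOWER_FUNCTIONS
from logicmine.nullmodel import Thresholds

from conftest import random_nonconstant
from oracle import u_forward_oracle, u_reverse_oracle

T = Thresholds(t_lower=0.3, t_higher=0.3)


def _pheno(n1, n2, names=("A", "B")):
    c = np.r_[np.ones(n1), np.zeros(n2)].astype(np.int8)
    cols = [f"s{j}" for j in range(n1 + n2)]
    return pd.DataFrame([c, 1 - c], index=list(names), columns=cols)


def _frame(rows, columns):
    return pd.DataFrame(
        np.asarray(rows, dtype=np.int8),
        index=[f"f{i}" for i in range(len(rows))],
        columns=columns,
    )


class TestScanLower:
    def test_identity_and_not_types(self, rng):
        p = _pheno(8, 8)
        c = p.loc["A"].to_numpy()
        noise = [random_nonconstant(rng, 16) for _ in range(5)]
        m = _frame([c, 1 - c, *noise], p.columns)
        rels = scan_lower(m, p, T, phenotypes=["A"])
        by_feature = {r.feature_ids[0]: r for r in rels}
        assert by_feature["f0"].logic_type.name == "IDENTITY"
        assert by_feature["f0"].u_forward == 1.0 == by_feature["f0"].u_reverse
        assert by_feature["f1"].logic_type.name == "NOT"
        assert by_feature["f1"].coefficient == 1.0

    def test_independent_feature_not_reported(self):
        p = _pheno(2, 2)
        m = _frame([[1, 0, 1, 0]], p.columns)  # independent of [1,1,0,0]
        assert scan_lower(m, p, T, phenotypes=["A"]) == []

    def test_constant_features_skipped_not_fatal(self):
        p = _pheno(2, 2)
        m = _frame([[1, 1, 1, 1], [1, 1, 0, 0]], p.columns)
        rels = scan_lower(m, p, T, phenotypes=["A"])
        assert [r.feature_ids[0] for r in rels] == ["f1"]

    def test_constant_phenotype_is_hard_error(self):
        p = pd.DataFrame([[1, 1, 1, 1]], index=["A"], columns=list("wxyz"))
        m = _frame([[1, 0, 1, 0]], p.columns)
        with pytest.raises(ValidationError, match="zero-entropy"):
            scan_lower(m, p, T, phenotypes=["A"])

    def test_stored_u_matches_oracle(self, rng):
        p = _pheno(10, 10)
        c = p.loc["A"].to_numpy()
        rows = [(c ^ (rng.random(20) < 0.15)).astype(np.int8) for _ in range(6)]
        m = _frame(rows, p.columns)
        for rel in scan_lower(m, p, Thresholds(0.05, 0.05), phenotypes=["A"]):
            a = m.loc[rel.feature_ids[0]].to_numpy()
            assert rel.u_forward == pytest.approx(u_forward_oracle(a, c), abs=1e-12)
            assert rel.u_reverse == pytest.approx(u_reverse_oracle(a, c), abs=1e-12)


class TestScanHigher:
    def test_xor_pair_found_without_lower_relationships(self):
        p = _pheno(8, 8)
        c = p.loc["A"].to_numpy().astype(np.uint8)
        a = np.r_[np.ones(4), np.zeros(4), np.ones(4), np.zeros(4)].astype(np.uint8)
        b = a ^ c
        m = _frame([a, b], p.columns)
        lower = scan_lower(m, p, T, phenotypes=["A"])
        assert lower == []  # members balanced within each class
        rels = scan_higher(m, p, T, lower, phenotypes=["A"])
        assert len(rels) == 1
        rel = rels[0]
        assert rel.logic_type.name == "XOR"
        assert rel.logic_type.type_index == 8
        assert rel.u_forward == 1.0 == rel.u_reverse

    def test_and_pair_found_when_members_below_threshold(self, rng):
        # an approximate conjunction: strong pair signal, weak members;
        # with a permissive lower threshold the members are excluded first
        p = _pheno(12, 12)
        c = p.loc["A"].to_numpy().astype(np.uint8)
        a = np.r_[np.ones(12), (rng.random(12) < 0.5)].astype(np.uint8)
        b = np.r_[np.ones(12), 1 - a[12:]].astype(np.uint8)
        m = _frame([a, b], p.columns)
        rels = scan_higher(m, p, Thresholds(t_lower=0.9, t_higher=0.3), [],
                           phenotypes=["A"])
        names = {r.logic_type.name for r in rels}
        assert names  # the pair is reported
        assert names <= {"AND", "XNOR", "NAND", "XOR"}

    def test_exclusion_rule_removes_pairs_with_lower_members(self):
        p = _pheno(8, 8)
        c = p.loc["A"].to_numpy().astype(np.uint8)
        a = c.copy()          # perfect lower relationship
        b = np.r_[np.ones(4), np.zeros(4), np.ones(4), np.zeros(4)].astype(np.uint8)
        m = _frame([a, b], p.columns)
        lower = scan_lower(m, p, T, phenotypes=["A"])
        assert len(lower) == 1
        rels = scan_higher(m, p, T, lower, phenotypes=["A"])
        assert rels == []  # AND(a,b)-like combos excluded via member f0
        # no feature of a higher relationship may hold a lower one
        rels_all = scan_higher(m, p, T, [], phenotypes=["A"])
        lower_feats = {f for r in lower for f in r.feature_ids}
        assert any(lower_feats & set(r.feature_ids) for r in rels_all)

    def test_candidate_restriction(self, small_dataset):
        m, p, _, truth = small_dataset
        pair = next(t for t in truth.planted if len(t.feature_ids) == 2)
        rels = scan_higher(
            m, p, Thresholds(0.5, 0.5), [], candidate_features=pair.feature_ids,
            phenotypes=["AC"],
        )
        assert any(set(r.feature_ids) == set(pair.feature_ids) for r in rels)

    def test_asymmetric_type_records_argument_order(self):
        p = _pheno(9, 9)
        c = p.loc["A"].to_numpy().astype(np.uint8)
        rng = np.random.default_rng(4)
        # f(a, b) = a AND NOT b == c, members shuffled enough to be weak
        a = np.where(c == 1, 1, (rng.random(18) < 0.66)).astype(np.uint8)
        b = np.where((c == 0) & (a == 1), 1, 0).astype(np.uint8)
        m = _frame([a, b], p.columns)
        rels = scan_higher(m, p, Thresholds(2.0, 0.5), [], phenotypes=["A"])
        rel = next(r for r in rels if r.logic_type.name in ("A_ANDN_B", "NOTA_OR_B"))
        assert rel.u_forward == 1.0
        # argument order must reproduce the planted orientation
        va = m.loc[rel.feature_ids[0]].to_numpy()
        vb = m.loc[rel.feature_ids[1]].to_numpy()
        from logicmine.logic import apply_logic

        composed = apply_logic(rel.logic_type, va, vb)
        target = c if rel.logic_type.name == "A_ANDN_B" else None
        if target is not None:
            assert (composed == target).all()

    def test_stored_pair_u_matches_oracle(self, small_dataset):
        from logicmine.logic import apply_logic

        m, p, _, _ = small_dataset
        c = p.loc["AC"].to_numpy().astype(np.uint8)
        rels = scan_higher(m, p, Thresholds(0.4, 0.4), [], phenotypes=["AC"])
        assert rels
        for rel in rels[:10]:
            va = m.loc[rel.feature_ids[0]].to_numpy().astype(np.uint8)
            vb = m.loc[rel.feature_ids[1]].to_numpy().astype(np.uint8)
            v = apply_logic(rel.logic_type, va, vb)
            assert rel.u_forward == pytest.approx(u_forward_oracle(v, c), abs=1e-12)
            assert rel.u_reverse == pytest.approx(u_reverse_oracle(v, c), abs=1e-12)


class TestComplementPropagation:
    def test_lower_and_higher_partners(self, small_dataset):
        m, p, _, _ = small_dataset
        rels = [
            LogicRelationship(("P000001_at",), "AC", LOWER_FUNCTIONS[2], 0.8, 0.7),
            LogicRelationship(
                ("P000005_at", "P000006_at"), "SCC", HIGHER_FUNCTIONS[1], 0.9, 0.6
            ),
        ]
        out = propagate_complement(rels, p)
        assert out[0].phenotype == "SCC"
        assert out[0].logic_type.name == "IDENTITY"
        assert (out[0].u_forward, out[0].u_reverse) == (0.8, 0.7)
        assert out[1].phenotype == "AC"
        assert out[1].logic_type.name == "NAND"

    def test_involution(self, small_dataset):
        m, p, _, _ = small_dataset
        rels = scan_lower(m, p, Thresholds(0.4, 0.4), phenotypes=["AC"])
        assert rels
        twice = propagate_complement(propagate_complement(rels, p), p)
        assert [r.key for r in twice] == [r.key for r in rels]

    def test_empty_input(self, small_dataset):
        _, p, _, _ = small_dataset
        assert propagate_complement([], p) == []

    def test_non_complementary_profiles_error(self):
        p = pd.DataFrame(
            [[1, 1, 0], [0, 1, 1]], index=["A", "B"], columns=["s0", "s1", "s2"]
        )
        with pytest.raises(ValidationError):
            propagate_complement([], p)


class TestFilters:
    def _rels(self):
        return [
            LogicRelationship(("x",), "A", LOWER_FUNCTIONS[1], 0.9, 0.9),
            LogicRelationship(("y", "z"), "A", HIGHER_FUNCTIONS[1], 0.9, 0.9),
            LogicRelationship(("u", "v"), "A", HIGHER_FUNCTIONS[8], 0.9, 0.9),
        ]

    def test_keep_and_xor(self):
        kept = filter_by_types(self._rels(), {"AND", "XOR"})
        assert [r.logic_type.name for r in kept] == ["AND", "XOR"]

    def test_all_and_empty(self):
        rels = self._rels()
        everything = {"IDENTITY", "NOT", "AND", "XOR"}
        assert filter_by_types(rels, everything) == rels
        assert filter_by_types(rels, set()) == []

    def test_unknown_type_errors(self):
        with pytest.raises(ValidationError, match="unknown"):
            filter_by_types(self._rels(), {"NANDOR"})

    def test_report_frame_columns(self):
        frame = relationships_to_frame(self._rels())
        assert list(frame["type_name"]) == ["IDENTITY", "AND", "XOR"]
        assert (frame["coefficient"] == 0.9).all()
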