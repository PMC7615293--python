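import itertools
import math

import numpy as np
import pytest

from pylortho import (
    EntityMetadata,
    OrthogonalityCriteria,
    activity_matrix,
    classify_interclass,
    count_summary,
    enumerate_orthogonal_sets,
    group_into_families,
    is_orthogonal,
    orthogonality_coefficient,
    planted_quintuplet_fixture,
)
from pylortho.errors import IncompleteDataError, ParameterError, SetOrderError
from pylortho.orthomine import OrthogonalSet, write_sets_tsv

from _oracles import brute_force_orthogonal_sets, random_activity_values
from conftest import block_matrix

DIAG2 = [("s1", "t1"), ("s2", "t2")]


class TestOrthogonalityCoefficient:
    def test_hand_quotient(self, doublet_matrix):
        assert orthogonality_coefficient(doublet_matrix, DIAG2) == 6.0

    def test_zero_cross_gives_infinity(self):
        m = block_matrix(2, cognate=80.0, cross=0.0)
        assert math.isinf(
            orthogonality_coefficient(m, [("s0", "t0"), ("s1", "t1")])
        )

    def test_missing_entry_rejected(self):
        m = activity_matrix(
            np.array([[80.0, np.nan], [5.0, 60.0]]), ["t1", "t2"], ["s1", "s2"]
        )
        with pytest.raises(IncompleteDataError, match="t1"):
            orthogonality_coefficient(m, DIAG2)
        # explicit policy flag allows exploratory use
        assert orthogonality_coefficient(m, DIAG2, treat_missing_as_zero=True) == (
            60.0 / 5.0
        )

    def test_order_below_two_rejected(self, doublet_matrix):
        with pytest.raises(SetOrderError):
            orthogonality_coefficient(doublet_matrix, [("s1", "t1")])

    def test_duplicate_entity_rejected(self, doublet_matrix):
        with pytest.raises(SetOrderError):
            orthogonality_coefficient(doublet_matrix, [("s1", "t1"), ("s1", "t2")])

    def test_scale_invariance(self, rng):
        vals = random_activity_values(rng, 4, 4)
        m1 = activity_matrix(vals, list("abcd"), list("wxyz"))
        m2 = activity_matrix(vals * 3.7, list("abcd"), list("wxyz"))
        pairs = [("w", "a"), ("x", "b"), ("y", "c")]
        assert orthogonality_coefficient(m1, pairs) == pytest.approx(
            orthogonality_coefficient(m2, pairs)
        )


class TestIsOrthogonal:
    def test_passing_doublet(self, doublet_matrix):
        res = is_orthogonal(doublet_matrix, DIAG2)
        assert res.passed and res.oc == 6.0

    def test_cross_violation_diagnosed(self):
        m = activity_matrix(
            np.array([[80.0, 25.0], [5.0, 60.0]]), ["t1", "t2"], ["s1", "s2"]
        )
        res = is_orthogonal(m, DIAG2)
        assert not res.passed
        assert res.failed_criterion == "cross"
        assert res.offending_cell == ("t1", "s2")

    def test_oc_violation_diagnosed(self):
        m = activity_matrix(
            np.array([[41.0, 19.0], [19.0, 41.0]]), ["t1", "t2"], ["s1", "s2"]
        )
        res = is_orthogonal(m, DIAG2)
        assert not res.passed
        assert res.failed_criterion == "oc"
        assert res.oc == pytest.approx(41 / 19)

    def test_cognate_violation_diagnosed(self):
        m = activity_matrix(
            np.array([[35.0, 5.0], [5.0, 60.0]]), ["t1", "t2"], ["s1", "s2"]
        )
        res = is_orthogonal(m, DIAG2)
        assert res.failed_criterion == "cognate"
        assert res.offending_cell == ("t1", "s1")

    def test_thresholds_are_strict(self):
        m = activity_matrix(
            np.array([[40.0, 5.0], [5.0, 60.0]]), ["t1", "t2"], ["s1", "s2"]
        )
        assert not is_orthogonal(m, DIAG2).passed  # cognate exactly 40 fails
        m2 = activity_matrix(
            np.array([[80.0, 20.0], [5.0, 60.0]]), ["t1", "t2"], ["s1", "s2"]
        )
        assert not is_orthogonal(m2, DIAG2).passed  # cross exactly 20 fails

    def test_criteria_invariants(self):
        with pytest.raises(ParameterError):
            OrthogonalityCriteria(min_cognate=10, max_cross=20)
        with pytest.raises(ParameterError):
            OrthogonalityCriteria(min_oc=1.0)


class TestEnumeration:
    def test_matches_brute_force(self, rng):
        """Pruned search is output-equivalent to exhaustive enumeration."""
        for _ in range(40):
            T = int(rng.integers(4, 8))
            S = int(rng.integers(4, 7))
            vals = random_activity_values(rng, T, S, p_missing=0.05)
            trnas = [f"t{i}" for i in range(T)]
            synths = [f"s{j}" for j in range(S)]
            m = activity_matrix(vals, trnas, synths)
            for order in (2, 3):
                got = enumerate_orthogonal_sets(m, order)
                oracle = brute_force_orthogonal_sets(
                    vals, trnas, synths, order
                )
                assert {frozenset(s.pairs) for s in got} == set(oracle)
                for s in got:
                    assert s.oc == pytest.approx(oracle[frozenset(s.pairs)])

    def test_block_diagonal_counts(self):
        m = block_matrix(4, cognate=90.0, cross=0.0)
        doublets = enumerate_orthogonal_sets(m, 2)
        assert len(doublets) == 6  # k(k-1)/2
        assert all(math.isinf(s.oc) for s in doublets)
        assert enumerate_orthogonal_sets(m, 5, OrthogonalityCriteria()) == []

    def test_sorted_by_descending_oc(self, rng):
        vals = random_activity_values(rng, 7, 7)
        m = activity_matrix(
            vals, [f"t{i}" for i in range(7)], [f"s{j}" for j in range(7)]
        )
        sets = enumerate_orthogonal_sets(m, 2)
        ocs = [s.oc for s in sets]
        assert all(a >= b for a, b in zip(ocs, ocs[1:]))

    def test_heterologous_pairings_found(self):
        # only the off-diagonal "cognate" assignment passes
        vals = np.array([[5.0, 90.0], [85.0, 5.0]])
        m = activity_matrix(vals, ["t1", "t2"], ["s1", "s2"])
        sets = enumerate_orthogonal_sets(m, 2)
        assert len(sets) == 1
        assert set(sets[0].pairs) == {("s1", "t2"), ("s2", "t1")}
        # and can be switched off given a cognate map
        none = enumerate_orthogonal_sets(
            m, 2, allow_heterologous=False,
            cognate_map={"t1": "s1", "t2": "s2"},
        )
        assert none == []

    def test_hereditary_property(self, rng):
        """Every sub-tuple of a passing set passes, with oc at least as high."""
        for _ in range(15):
            vals = random_activity_values(rng, 6, 6)
            m = activity_matrix(
                vals, [f"t{i}" for i in range(6)], [f"s{j}" for j in range(6)]
            )
            for s in enumerate_orthogonal_sets(m, 3):
                for sub in itertools.combinations(s.pairs, 2):
                    check = is_orthogonal(m, sub)
                    assert check.passed
                    assert check.oc >= s.oc - 1e-12

    def test_monotone_in_criteria(self, rng):
        vals = random_activity_values(rng, 7, 7)
        m = activity_matrix(
            vals, [f"t{i}" for i in range(7)], [f"s{j}" for j in range(7)]
        )
        lax = OrthogonalityCriteria(min_oc=2.5)
        strict = OrthogonalityCriteria(min_oc=5.0)
        for order in (2, 3):
            assert len(enumerate_orthogonal_sets(m, order, strict)) <= len(
                enumerate_orthogonal_sets(m, order, lax)
            )

    def test_missing_cross_excludes_tuple(self):
        vals = np.array([[80.0, np.nan], [5.0, 60.0]])
        m = activity_matrix(vals, ["t1", "t2"], ["s1", "s2"])
        assert enumerate_orthogonal_sets(m, 2) == []
        found = enumerate_orthogonal_sets(m, 2, treat_missing_as_zero=True)
        assert len(found) == 1 and math.isinf(found[0].oc) is False


class TestFamilies:
    def mk(self, pairs, oc=5.0):
        return OrthogonalSet(tuple(sorted(pairs)), oc, 80.0, 10.0)

    def test_same_synthetases_one_family(self):
        a = self.mk([("s1", "tA"), ("s2", "tB")], oc=3.0)
        b = self.mk([("s1", "tC"), ("s2", "tD")], oc=7.0)
        fams = group_into_families([a, b])
        assert len(fams) == 1
        assert fams[0].best is fams[0].members[0]
        assert fams[0].best.oc == 7.0

    def test_different_synthetases_two_families(self):
        a = self.mk([("s1", "tA"), ("s2", "tB")])
        b = self.mk([("s1", "tA"), ("s3", "tB")])
        assert len(group_into_families([a, b])) == 2

    def test_mixed_orders_rejected(self):
        a = self.mk([("s1", "tA"), ("s2", "tB")])
        b = self.mk([("s1", "tA"), ("s2", "tB"), ("s3", "tC")])
        with pytest.raises(SetOrderError):
            group_into_families([a, b])

    def test_partition(self, rng):
        vals = random_activity_values(rng, 7, 7)
        m = activity_matrix(
            vals, [f"t{i}" for i in range(7)], [f"s{j}" for j in range(7)]
        )
        sets = enumerate_orthogonal_sets(m, 2)
        fams = group_into_families(sets)
        assert sum(len(f.members) for f in fams) == len(sets)
        seen = [frozenset(s.pairs) for f in fams for s in f.members]
        assert len(seen) == len(set(seen))


class TestInterClass:
    def meta(self, classes):
        return {
            s: EntityMetadata(s, "synthetase", "dN", c) for s, c in classes.items()
        }

    def test_passing_doublet_mutually_orthogonal(self):
        m = activity_matrix(
            np.array([[80.0, 5.0], [5.0, 80.0]]), ["t1", "t2"], ["sA", "sB"]
        )
        rels = classify_interclass(m, self.meta({"sA": "A", "sB": "B"}))
        assert rels[0].status == "mutually-orthogonal"
        assert rels[0].witnesses

    def test_two_sided_cross_reactivity(self):
        m = activity_matrix(
            np.array([[80.0, 50.0], [50.0, 80.0]]), ["t1", "t2"], ["sA", "sB"]
        )
        rels = classify_interclass(m, self.meta({"sA": "A", "sB": "B"}))
        assert rels[0].status == "two-sided"

    def test_one_sided_cross_reactivity(self):
        m = activity_matrix(
            np.array([[80.0, 50.0], [5.0, 80.0]]), ["t1", "t2"], ["sA", "sB"]
        )
        rels = classify_interclass(m, self.meta({"sA": "A", "sB": "B"}))
        assert rels[0].status == "one-sided"

    def test_unlabelled_synthetase_rejected(self):
        m = activity_matrix(
            np.array([[80.0, 5.0], [5.0, 80.0]]), ["t1", "t2"], ["sA", "sB"]
        )
        from pylortho.errors import MetadataError

        with pytest.raises(MetadataError):
            classify_interclass(m, self.meta({"sA": "A"}))


class TestCountSummaryAndFixture:
    def test_block_fixture_counts(self):
        m = block_matrix(4)
        summary = count_summary(m)
        assert summary[2]["count"] == 6
        assert summary[3]["count"] == 4
        assert summary[4]["count"] == 1
        assert summary[5]["count"] == 0

    def test_planted_quintuplet_unique(self):
        m, truth = planted_quintuplet_fixture(seed=11)
        found = enumerate_orthogonal_sets(m, 5)
        assert len(found) == 1
        assert frozenset(found[0].pairs) == frozenset(truth.planted_sets[0].pairs)

    def test_decoys_fail_with_intended_criterion(self):
        m, truth = planted_quintuplet_fixture(seed=11)
        planted = dict(truth.planted_sets[0].pairs)
        base = list(truth.planted_sets[0].pairs)[:4]
        for decoy, expected in (("s6", "cognate"), ("s7", "cross"), ("s8", "oc")):
            tup = base + [(decoy, decoy.replace("s", "t"))]
            res = is_orthogonal(m, tup)
            assert not res.passed
            assert res.failed_criterion == expected

    def test_planted_subsets_pass(self):
        m, truth = planted_quintuplet_fixture(seed=11)
        pairs = truth.planted_sets[0].pairs
        for sub in itertools.combinations(pairs, 4):
            assert is_orthogonal(m, sub).passed

    def test_sets_tsv(self, tmp_path, rng):
        import pandas as pd

        m = block_matrix(3)
        sets = enumerate_orthogonal_sets(m, 2)
        fams = group_into_families(sets)
        p = tmp_path / "sets.tsv"
        write_sets_tsv(sets, p, fams)
        df = pd.read_csv(p, sep="\t")
        assert len(df) == 3
        assert np.isinf(df["oc"].astype(float)).all()
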