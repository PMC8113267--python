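import itertools
import math

import numpy as np
import pandas as pd
import pytest

from clseq.identity import (
    AssignmentResult,
    assign_consensus,
    assign_identities,
    assignments_to_frame,
    compare_composition,
    correlate_to_reference,
    frame_to_assignments,
    group_queries,
    permutation_test,
    score_cells,
)
from clseq.model import InputError


def pearson(x, y):
    """Independent scalar Pearson implementation for oracles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


class TestCorrelateToReference:
    def test_query_identical_to_reference_cell(self, rng):
        ref = rng.normal(size=(6, 4)) + 1
        query = ref[:, [2]].copy()
        res = correlate_to_reference(
            query, ["q"], ref, ["a", "a", "b", "b"],
            [f"g{i}" for i in range(6)], [f"g{i}" for i in range(6)],
        )
        j = 2
        assert res.r_matrix[0, j] == pytest.approx(1.0, abs=1e-12)

    def test_two_cell_reference_negation(self, rng):
        # with exactly two reference cells, gene standardization maps them to
        # mirror images; a query equal to cell B anti-correlates with cell A
        ref = rng.normal(size=(5, 2))
        query = ref[:, [1]].copy()
        res = correlate_to_reference(
            query, ["q"], ref, ["a", "b"],
            [f"g{i}" for i in range(5)], [f"g{i}" for i in range(5)],
        )
        assert res.r_matrix[0, 0] == pytest.approx(-1.0, abs=1e-12)
        assert res.r_matrix[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_oracle_4_genes_2_cells(self):
        genes = ["g0", "g1", "g2", "g3"]
        ref = np.array(
            [
                [1.0, 3.0],
                [2.0, 0.0],
                [0.0, 1.0],
                [4.0, 2.0],
            ]
        )
        query = np.array([[2.5], [1.0], [0.25], [3.5]])
        res = correlate_to_reference(query, ["q"], ref, ["a", "b"], genes, genes)
        mu = ref.mean(axis=1, keepdims=True)
        sd = ref.std(axis=1, ddof=1, keepdims=True)
        qz = ((query - mu) / sd)[:, 0]
        rz = (ref - mu) / sd
        for j in range(2):
            assert res.r_matrix[0, j] == pytest.approx(pearson(qz, rz[:, j]), abs=1e-12)
        assert res.state_means.loc["q", "a"] == pytest.approx(
            res.r_matrix[0, 0], abs=1e-12
        )

    def test_per_state_mean_over_cells(self, rng):
        ref = rng.normal(size=(8, 5)) + 2
        query = rng.normal(size=(8, 2)) + 2
        states = ["a", "a", "a", "b", "b"]
        res = correlate_to_reference(
            query, ["q1", "q2"], ref, states,
            [f"g{i}" for i in range(8)], [f"g{i}" for i in range(8)],
        )
        np.testing.assert_allclose(
            res.state_means["a"].to_numpy(), res.r_matrix[:, :3].mean(axis=1), atol=1e-12
        )

    def test_too_few_genes_rejected(self, rng):
        ref = rng.normal(size=(5, 3))
        with pytest.raises(InputError, match=">= 3 genes"):
            correlate_to_reference(
                ref[:, :1], ["q"], ref, ["a", "a", "b"],
                [f"g{i}" for i in range(5)], ["g0", "g1"],
            )

    def test_constant_profile_warns_and_zeroes(self, rng):
        ref = rng.normal(size=(4, 3))
        query = ref.mean(axis=1, keepdims=True)  # standardizes to all zeros
        genes = [f"g{i}" for i in range(4)]
        with pytest.warns(UserWarning, match="constant"):
            res = correlate_to_reference(query, ["q"], ref, ["a", "a", "b"], genes, genes)
        np.testing.assert_allclose(res.r_matrix[0], 0.0, atol=1e-12)


class TestGroupQueries:
    def test_identical_vectors_one_group(self):
        vecs = pd.DataFrame(np.tile([0.5, -0.1, 0.2, 0.0], (6, 1)))
        labels = group_queries(vecs, height=0.5)
        assert len(set(labels)) == 1

    def test_singletons_when_n_groups_equals_n(self, rng):
        vecs = pd.DataFrame(rng.normal(size=(5, 4)))
        labels = group_queries(vecs, n_groups=5)
        assert sorted(labels) == [0, 1, 2, 3, 4]

    def test_two_blob_recovery(self, rng):
        c1 = np.array([1.0, 0.0, -1.0, 0.0])
        c2 = np.array([-1.0, 0.5, 1.0, -0.5])
        vecs = np.vstack(
            [c1 + rng.normal(0, 0.01, 4) for _ in range(8)]
            + [c2 + rng.normal(0, 0.01, 4) for _ in range(8)]
        )
        labels = group_queries(pd.DataFrame(vecs), n_groups=2)
        assert len(set(labels[:8])) == 1
        assert len(set(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_too_many_groups_rejected(self, rng):
        vecs = pd.DataFrame(rng.normal(size=(3, 4)))
        with pytest.raises(InputError, match="exceeds"):
            group_queries(vecs, n_groups=4)

    def test_exactly_one_criterion(self, rng):
        vecs = pd.DataFrame(rng.normal(size=(4, 4)))
        with pytest.raises(InputError, match="exactly one"):
            group_queries(vecs, n_groups=2, height=0.5)


class TestPermutationTest:
    def test_constant_r_gives_p_one(self):
        r = np.full((6, 4), 0.3)
        p = permutation_test(r, [0, 0, 0, 1, 1, 1], ["a", "a", "b", "b"], n_perm=200, seed=0)
        assert (p.to_numpy() == 1.0).all()

    def test_matches_exhaustive_enumeration_4_queries(self):
        rng = np.random.default_rng(3)
        r = rng.normal(size=(4, 6))
        ref_states = ["a", "a", "a", "b", "b", "b"]
        groups = np.array([0, 0, 1, 1])
        p = permutation_test(r, groups, ref_states, n_perm=100_000, seed=1)

        # exhaustive oracle over all 4! query orderings
        state_cols = np.column_stack(
            [r[:, :3].mean(axis=1), r[:, 3:].mean(axis=1)]
        )
        obs = {
            (g, s): state_cols[groups == g, s].mean()
            for g in (0, 1)
            for s in (0, 1)
        }
        for g in (0, 1):
            for s, sname in ((0, "a"), (1, "b")):
                count = total = 0
                for perm in itertools.permutations(range(4)):
                    permuted = state_cols[list(perm)]
                    t = permuted[groups == g, s].mean()
                    total += 1
                    count += t >= obs[(g, s)] - 1e-12
                exact = count / total
                # sampled p converges to the add-one-smoothed exact rate
                assert p.loc[g, sname] == pytest.approx(exact, abs=0.01)

    def test_single_group_rejected(self, rng):
        r = rng.normal(size=(4, 4))
        with pytest.raises(InputError, match="single group"):
            permutation_test(r, [0, 0, 0, 0], ["a", "a", "b", "b"])

    def test_p_floor(self, rng):
        r = rng.normal(size=(10, 4))
        p = permutation_test(r, [0] * 5 + [1] * 5, ["a", "a", "b", "b"], n_perm=99, seed=0)
        assert (p.to_numpy() >= 1 / 100).all()

    def test_deterministic_given_seed(self, rng):
        r = rng.normal(size=(8, 5))
        args = (r, [0, 1] * 4, ["a", "a", "b", "b", "b"])
        p1 = permutation_test(*args, n_perm=200, seed=5)
        p2 = permutation_test(*args, n_perm=200, seed=5)
        assert p1.equals(p2)


class TestAssignIdentities:
    states = ["1", "2", "3", "4"]

    def call(self, r, p, **kw):
        rdf = pd.DataFrame([r], index=["q"], columns=self.states)
        pdf = pd.DataFrame([p], index=["q"], columns=self.states)
        return assign_identities(rdf, pdf, **kw)[0]

    def test_pure_call(self):
        a = self.call([0.8, 0.2, 0.1, 0.0], [0.001, 0.5, 0.9, 0.9])
        assert a.call == "pure"
        assert a.call_states == ("1",)

    def test_mixed_call(self):
        a = self.call([0.7, 0.65, 0.1, 0.0], [0.002, 0.004, 0.6, 0.8])
        assert a.call == "mixed"
        assert set(a.call_states) == {"1", "2"}

    def test_unassigned_when_r_low(self):
        a = self.call([0.5, 0.4, 0.1, 0.0], [0.001, 0.001, 0.001, 0.001])
        assert a.call == "unassigned"

    def test_threshold_monotonicity(self, rng):
        rdf = pd.DataFrame(rng.uniform(-1, 1, size=(20, 4)), columns=self.states)
        pdf = pd.DataFrame(rng.uniform(0, 1, size=(20, 4)), columns=self.states)
        loose = assign_identities(rdf, pdf, r_min=0.2, p_max=0.2)
        strict_r = assign_identities(rdf, pdf, r_min=0.5, p_max=0.2)
        strict_p = assign_identities(rdf, pdf, r_min=0.2, p_max=0.05)
        for a, b, c in zip(loose, strict_r, strict_p):
            assert set(b.call_states) <= set(a.call_states)
            assert set(c.call_states) <= set(a.call_states)

    def test_misaligned_tables_rejected(self):
        rdf = pd.DataFrame([[0.1]], index=["q"], columns=["1"])
        pdf = pd.DataFrame([[0.1]], index=["other"], columns=["1"])
        with pytest.raises(InputError, match="axis"):
            assign_identities(rdf, pdf)


class TestScoreCells:
    def population(self, rng, n_extra=0):
        # 20 a-cells, 20 b-cells (plus optional extras appended by callers)
        x = rng.normal(0, 0.05, size=(6, 40 + n_extra))
        x[0:2, :20] += 2.0   # a markers high in a-cells
        x[2:4, 20:40] += 2.0  # b markers high in b-cells
        return x

    def test_pure_cell_by_construction(self, rng):
        x = self.population(rng)
        table = score_cells(x, [f"g{i}" for i in range(6)], {"a": ["g0", "g1"], "b": ["g2", "g3"]})
        assert table.loc[0, "call"] == "pure"
        assert table.loc[0, "primary"] == "a"
        assert table.loc[25, "call"] == "pure"
        assert table.loc[25, "primary"] == "b"

    def test_hybrid_cell_both_sets_elevated(self, rng):
        x = self.population(rng, n_extra=1)
        x[0:4, 40] += 2.0  # last cell co-expresses both programs
        table = score_cells(x, [f"g{i}" for i in range(6)], {"a": ["g0", "g1"], "b": ["g2", "g3"]})
        assert table.loc[40, "call"] == "hybrid"
        assert table.loc[40, "hybrid_pair"] == "a+b"

    def test_all_zero_cell_unassigned(self, rng):
        x = rng.normal(2, 1.0, size=(4, 30))
        x[:, 0] = 0.0
        x[0, 1:] += 5  # markers clearly up elsewhere
        table = score_cells(x, ["g0", "g1", "g2", "g3"], {"a": ["g0"], "b": ["g1"]})
        assert table.loc[0, "call"] == "unassigned"

    def test_missing_marker_rejected(self, rng):
        with pytest.raises(InputError, match="marker gene"):
            score_cells(rng.normal(size=(2, 5)), ["g0", "g1"], {"a": ["nope"]})


class TestCompareComposition:
    def make_assignment(self, lib, call_states):
        call = "unassigned" if not call_states else ("pure" if len(call_states) == 1 else "mixed")
        return AssignmentResult(
            library_id=lib, states=("1", "2", "3", "4"),
            r=np.zeros(4), p_perm=np.ones(4), call=call,
            call_states=tuple(call_states), n_perm=100,
        )

    def test_absent_state_flagged_with_zero_odds(self):
        assignments = [self.make_assignment(f"A{i}", ["4"]) for i in range(3)]
        assignments += [self.make_assignment(f"A{i+3}", ["1"]) for i in range(3)]
        assignments += [self.make_assignment(f"B{i}", ["1"]) for i in range(4)]
        cond = {a.library_id: a.library_id[0] for a in assignments}
        table = compare_composition(assignments, cond)
        assert table.loc["4", "odds_ratio"] == 0.0
        assert table.loc["4", "note"] == "absent in B"

    def test_fisher_matches_hypergeometric_enumeration(self):
        # 2x2 table (3,7;9,1): two-sided p by enumerating the hypergeometric
        import scipy.stats

        a = [self.make_assignment(f"A{i}", ["1"]) for i in range(3)]
        a += [self.make_assignment(f"A{i+3}", ["2"]) for i in range(7)]
        b = [self.make_assignment(f"B{i}", ["1"]) for i in range(9)]
        b += [self.make_assignment(f"B{i+9}", ["2"]) for i in range(1)]
        cond = {x.library_id: x.library_id[0] for x in a + b}
        table = compare_composition(a + b, cond)

        rv = scipy.stats.hypergeom(20, 12, 10)  # N, K (state-1 total), n (A draws)
        p_obs = rv.pmf(3)
        p_exact = sum(rv.pmf(k) for k in range(13) if rv.pmf(k) <= p_obs + 1e-12)
        assert table.loc["1", "p_value"] == pytest.approx(p_exact, rel=1e-9)

    def test_identical_compositions_p_one(self):
        a = [self.make_assignment(f"A{i}", ["1" if i % 2 else "2"]) for i in range(8)]
        b = [self.make_assignment(f"B{i}", ["1" if i % 2 else "2"]) for i in range(8)]
        cond = {x.library_id: x.library_id[0] for x in a + b}
        table = compare_composition(a + b, cond)
        assert (table["p_adjusted"] == 1.0).all()

    def test_mixed_calls_count_each_state(self):
        a = [self.make_assignment("A0", ["1", "2"])]
        b = [self.make_assignment("B0", ["1"])]
        cond = {"A0": "A", "B0": "B"}
        table = compare_composition(a + b, cond)
        assert table.loc["1", "A"] == 1
        assert table.loc["2", "A"] == 1
        assert table.loc["1", "B"] == 1

    def test_missing_condition_rejected(self):
        a = [self.make_assignment("A0", ["1"])]
        with pytest.raises(InputError, match="condition"):
            compare_composition(a, {})


class TestAssignmentFrameRoundTrip:
    def test_round_trip(self):
        rows = [
            AssignmentResult(
                library_id="C1", states=("1", "2"), r=np.array([0.5, -0.2]),
                p_perm=np.array([0.01, 0.8]), call="pure", call_states=("1",),
                n_perm=999, members=("C1",),
            ),
            AssignmentResult(
                library_id="C2", states=("1", "2"), r=np.array([0.7, 0.6]),
                p_perm=np.array([0.001, 0.004]), call="mixed",
                call_states=("1", "2"), n_perm=999,
            ),
        ]
        frame = assignments_to_frame(rows)
        back = frame_to_assignments(frame)
        for orig, got in zip(rows, back):
            assert got.library_id == orig.library_id
            assert got.states == orig.states
            assert got.call == orig.call
            assert got.call_states == orig.call_states
            np.testing.assert_allclose(got.r, orig.r)
            np.testing.assert_allclose(got.p_perm, orig.p_perm)
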