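"""Divergent-group selection: standardisation, relationships, greedy index."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pooldiver import cohort, simulate
from pooldiver.errors import (ArgumentError, DegenerateInputError,
                              PedigreeError)


class TestStandardize:
    def test_symmetric_pair_is_fixed_point(self):
        assert cohort.standardize([1.0, -1.0]) == pytest.approx([1.0, -1.0])

    def test_hand_zscores(self):
        out = cohort.standardize([2.0, 4.0, 6.0])
        assert out == pytest.approx([-1.2247, 0.0, 1.2247], abs=1e-4)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=2, max_size=50)
           .filter(lambda v: len(set(v)) > 1))
    def test_mean_zero_unit_variance(self, values):
        z = cohort.standardize(values)
        assert abs(z.mean()) < 1e-9
        assert z.std() == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateInputError):
            cohort.standardize([3.0, 3.0, 3.0])


def _ped(rows):
    return pd.DataFrame(rows, columns=["id", "sire", "dam"])


class TestRelationshipMatrix:
    def test_founders_identity(self):
        A = cohort.numerator_relationship_matrix(
            _ped([("a", None, None), ("b", None, None)]))
        assert np.allclose(A.to_numpy(), np.eye(2))

    def test_parent_offspring_half(self):
        A = cohort.numerator_relationship_matrix(
            _ped([("s", None, None), ("o", "s", None)]))
        assert A.loc["s", "o"] == pytest.approx(0.5)

    def test_half_sibs_quarter(self):
        A = cohort.numerator_relationship_matrix(
            _ped([("s", None, None), ("x", "s", None), ("y", "s", None)]))
        assert A.loc["x", "y"] == pytest.approx(0.25)

    def test_full_sibs_half_and_inbreeding(self):
        ped = _ped([("s", None, None), ("d", None, None),
                    ("x", "s", "d"), ("y", "s", "d"), ("z", "s", "x")])
        A = cohort.numerator_relationship_matrix(ped)
        assert A.loc["x", "y"] == pytest.approx(0.5)
        # z is the offspring of a sire-daughter mating: a_zz = 1 + 0.25
        assert A.loc["z", "z"] == pytest.approx(1.25)

    def test_cycle_detected(self):
        with pytest.raises(PedigreeError, match="cycle"):
            cohort.numerator_relationship_matrix(
                _ped([("a", "b", None), ("b", "a", None)]))

    def test_symmetric_and_bounded(self):
        ped = simulate.simulate_pedigree(80, 8, seed=2)
        A = cohort.numerator_relationship_matrix(ped).to_numpy()
        assert np.allclose(A, A.T)
        assert (np.diag(A) >= 1).all()
        assert (A >= 0).all()


class TestSelection:
    def test_unrelated_animals_pure_ebv_split(self, unrelated_pedigree):
        ped = unrelated_pedigree.iloc[:4]
        A = cohort.numerator_relationship_matrix(ped)
        res = cohort.select_divergent_groups(ped, A, size=2)
        assert set(res.low_group) == {"F0", "F1"}   # EBVs -5, -1
        assert set(res.high_group) == {"F3", "F2"}  # EBVs 5, 1

    def test_weight_one_zero_is_ebv_ranking(self):
        ped = simulate.simulate_pedigree(40, 5, seed=3)
        A = cohort.numerator_relationship_matrix(ped)
        res = cohort.select_divergent_groups(
            ped, A, size=10, weights=cohort.IndexWeights(1.0, 0.0))
        ranked = ped.sort_values("ebv")
        assert set(res.low_group) == set(ranked["id"].head(10))
        assert set(res.high_group) == set(ranked["id"].tail(10))

    def test_relatedness_penalty_beats_ebv(self):
        # the 2nd-lowest-EBV animal is a half-sib of the seed; with a
        # heavy relatedness weight the greedy must prefer a slightly
        # worse but unrelated animal, matching exhaustive enumeration
        ped = _ped([("s", None, None), ("u1", None, None),
                    ("u2", None, None), ("u3", None, None),
                    ("a", "s", None), ("b", "s", None)])
        ped["ebv"] = [9.0, -4.4, 5.0, 6.0, -5.0, -4.5]  # a is the seed
        A = cohort.numerator_relationship_matrix(ped)
        weights = cohort.IndexWeights(0.2, 0.8)
        res = cohort.select_divergent_groups(ped, A, 2, weights)
        assert res.low_group[0] == "a"
        # enumeration oracle over all possible second members
        z_ebv = cohort.standardize(ped["ebv"].to_numpy())
        a = A.loc[ped["id"], ped["id"]].to_numpy()
        off = a[np.triu_indices_from(a, k=1)]
        z_rel = (a - off.mean()) / off.std()
        seed = list(ped["id"]).index("a")
        scores = {
            ped["id"][i]: weights.w_ebv * z_ebv[i]
            + weights.w_rel * z_rel[i, seed]
            for i in range(len(ped)) if i != seed}
        best = min(scores, key=lambda k: (scores[k], k))
        assert res.low_group[1] == best == "u1"

    def test_disjoint_exact_sizes(self):
        ped = simulate.simulate_pedigree(60, 6, seed=4)
        A = cohort.numerator_relationship_matrix(ped)
        res = cohort.select_divergent_groups(ped, A, size=15)
        assert len(res.low_group) == len(res.high_group) == 15
        assert not set(res.low_group) & set(res.high_group)

    def test_greedy_score_trace_replayable(self):
        # at every step the chosen candidate's score is the minimum over
        # the remaining candidates, recomputed from scratch
        ped = simulate.simulate_pedigree(50, 5, seed=9)
        A = cohort.numerator_relationship_matrix(ped)
        weights = cohort.IndexWeights()
        res = cohort.select_divergent_groups(ped, A, 12, weights)
        ids = list(ped["id"])
        z_ebv = dict(zip(ids, cohort.standardize(ped["ebv"].to_numpy())))
        a = A.loc[ids, ids].to_numpy()
        off = a[np.triu_indices_from(a, k=1)]
        zmat = pd.DataFrame((a - off.mean()) / off.std(),
                            index=ids, columns=ids)
        used: set = set()
        for group, sign in (("low", 1.0), ("high", -1.0)):
            steps = res.trace[res.trace["group"] == group]
            selected: list = []
            for step in steps.itertuples():
                if step.step == 0:
                    selected.append(step.id)
                    used.add(step.id)
                    continue
                scores = {}
                for c in ids:
                    if c in used:
                        continue
                    rel = np.mean([zmat.loc[c, j] for j in selected])
                    scores[c] = (weights.w_ebv * sign * z_ebv[c]
                                 + weights.w_rel * rel)
                expect = min(scores.values())
                assert step.score == pytest.approx(expect, abs=1e-9)
                assert scores[step.id] == pytest.approx(expect, abs=1e-9)
                selected.append(step.id)
                used.add(step.id)

    def test_insufficient_candidates(self, unrelated_pedigree):
        A = cohort.numerator_relationship_matrix(unrelated_pedigree)
        with pytest.raises(ArgumentError):
            cohort.select_divergent_groups(unrelated_pedigree, A, size=4)


class TestGroupSummary:
    def test_unrelated_group_zero_coancestry(self, unrelated_pedigree):
        A = cohort.numerator_relationship_matrix(unrelated_pedigree)
        res = cohort.select_divergent_groups(unrelated_pedigree, A, 3)
        summary = cohort.group_summary(res, A, unrelated_pedigree)
        within = summary[summary["group"].isin(["low", "high"])]
        assert (within["mean_coancestry_pct"] == 0).all()

    def test_half_sib_pair_coancestry(self):
        ped = _ped([("s", None, None), ("x", "s", None), ("y", "s", None),
                    ("u1", None, None), ("u2", None, None)])
        ped["ebv"] = [0.0, -3.0, -2.0, 4.0, 5.0]
        A = cohort.numerator_relationship_matrix(ped)
        res = cohort.SelectionResult(low_group=["x", "y"],
                                     high_group=["u1", "u2"],
                                     trace=pd.DataFrame())
        summary = cohort.group_summary(res, A, ped).set_index("group")
        # half-sib co-ancestry = 0.25 / 2 = 12.5%
        assert summary.loc["low", "mean_coancestry_pct"] == \
            pytest.approx(12.5)
        assert summary.loc["low", "mean_ebv"] == pytest.approx(-2.5)

    def test_mean_ebv_arithmetic(self):
        ped = _ped([("p", None, None), ("q", None, None),
                    ("r", None, None), ("t", None, None)])
        ped["ebv"] = [-5.0, -6.6, 5.0, 6.0]
        A = cohort.numerator_relationship_matrix(ped)
        res = cohort.SelectionResult(low_group=["p", "q"],
                                     high_group=["r", "t"],
                                     trace=pd.DataFrame())
        summary = cohort.group_summary(res, A, ped).set_index("group")
        assert summary.loc["low", "mean_ebv"] == pytest.approx(-5.8)
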