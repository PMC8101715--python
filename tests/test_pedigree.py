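import math

import numpy as np
import pytest

from herdgen import (
    Pedigree,
    complete_generation_equivalent,
    completeness_index,
    effective_number_of_ancestors,
    effective_number_of_founders,
    generation_intervals,
    inbreeding_meuwissen_luo,
    ne_from_regression,
)

from .conftest import random_pedigree
from .oracles import cge_by_walk, montecarlo_founder_contributions, wright_inbreeding


class TestInbreeding:
    def test_founders_zero(self, full_sib_pedigree):
        F = inbreeding_meuwissen_luo(full_sib_pedigree)
        assert F["A"] == 0.0 and F["B"] == 0.0

    def test_full_sib_offspring(self, full_sib_pedigree):
        assert inbreeding_meuwissen_luo(full_sib_pedigree)["E"] == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_wright_path_counting(self, seed):
        ped, parents = random_pedigree(seed)
        F = inbreeding_meuwissen_luo(ped)
        oracle = wright_inbreeding(parents)
        for iid in parents:
            assert F[iid] == pytest.approx(oracle[iid], abs=1e-12)

    def test_order_invariant_under_relabeling(self):
        ped, parents = random_pedigree(7)
        relabel = {i: f"Z{k}" for k, i in enumerate(reversed(ped.ids))}
        rows = []
        for i in ped.ids:
            r = ped.record(i)
            rows.append((relabel[i],
                         relabel.get(r.sire_id), relabel.get(r.dam_id), r.sex, r.birth_year))
        ped2 = Pedigree.from_tuples(rows)
        F1 = inbreeding_meuwissen_luo(ped)
        F2 = inbreeding_meuwissen_luo(ped2)
        for i in ped.ids:
            assert F1[i] == pytest.approx(F2[relabel[i]], abs=1e-14)


class TestCGE:
    def test_one_complete_generation(self):
        ped = Pedigree.from_tuples(
            [("s", None, None, "male"), ("d", None, None, "female"), ("x", "s", "d")]
        )
        assert complete_generation_equivalent(ped)["x"] == pytest.approx(1.0)

    def test_two_complete_generations(self, full_sib_pedigree):
        assert complete_generation_equivalent(full_sib_pedigree)["E"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", [1, 5, 9, 13])
    def test_matches_ancestor_walk(self, seed):
        ped, parents = random_pedigree(seed)
        cge = complete_generation_equivalent(ped)
        for iid in parents:
            assert cge[iid] == pytest.approx(cge_by_walk(parents, iid), abs=1e-12)


class TestCompleteness:
    def test_founder_all_zero(self):
        ped = Pedigree.from_tuples([("f", None, None)])
        tab = completeness_index(ped, depth=3)
        assert tab.loc["f", "index"] == 0.0
        assert (tab.loc["f", ["gen1", "gen2", "gen3"]] == 0).all()

    def test_fully_known_depth2(self, full_sib_pedigree):
        tab = completeness_index(full_sib_pedigree, depth=2)
        assert tab.loc["E", "gen1"] == 1.0
        assert tab.loc["E", "gen2"] == 1.0
        assert tab.loc["E", "index"] == pytest.approx(1.0)

    def test_unknown_dam_zeroes_index(self):
        # sire line complete to depth 2, dam unknown -> harmonic mean 0
        ped = Pedigree.from_tuples(
            [("gs", None, None, "male"), ("gd", None, None, "female"),
             ("s", "gs", "gd", "male"), ("x", "s", None)]
        )
        tab = completeness_index(ped, depth=2)
        assert tab.loc["x", "index"] == 0.0
        assert tab.loc["x", "gen1"] == 0.5

    def test_depth_validation(self, full_sib_pedigree):
        with pytest.raises(ValueError):
            completeness_index(full_sib_pedigree, depth=0)


class TestGenerationIntervals:
    def make(self):
        return Pedigree.from_tuples(
            [
                ("sire", None, None, "male", 2000),
                ("dam", None, None, "female", 2001),
                ("son", "sire", "dam", "male", 2003),
                ("dtr", "sire", "dam", "female", 2005),
                ("kid1", "son", "dtr", "male", 2008),
                ("kid2", "son", "dtr", "female", 2009),
            ]
        )

    def test_pathways_hand_computed(self):
        gi = generation_intervals(self.make())
        # son (2003) and dtr (2005) are the only parents-with-progeny
        assert gi.pathways.loc["L_ss", "mean"] == pytest.approx(3.0)   # sire->son
        assert gi.pathways.loc["L_sd", "mean"] == pytest.approx(5.0)   # sire->dtr
        assert gi.pathways.loc["L_ds", "mean"] == pytest.approx(2.0)   # dam->son
        assert gi.pathways.loc["L_dd", "mean"] == pytest.approx(4.0)   # dam->dtr
        assert gi.overall_mean == pytest.approx((3 + 5 + 2 + 4) / 4)

    def test_childless_offspring_excluded(self):
        gi = generation_intervals(self.make())
        # kid1/kid2 have no progeny: they contribute to no pathway
        assert gi.overall_n == 4

    def test_no_pairs_flagged(self):
        ped = Pedigree.from_tuples([("a", None, None, "male", 2000)])
        with pytest.warns(UserWarning, match="no qualifying"):
            gi = generation_intervals(ped)
        assert gi.overall_mean is None


class TestNeRegression:
    def test_closed_form(self):
        # slope 0.005 exactly: F = 0.005 * CGE
        cge = np.array([1.0, 2.0, 3.0, 4.0])
        F = 0.005 * cge
        dF, ne = ne_from_regression(F, cge, mode="whole")
        assert dF == pytest.approx(0.005)
        assert ne == pytest.approx(100.0)

    def test_subpopulation_formula(self):
        # b = 0.004, F_t = 0.035 -> dF = 0.004/0.969, Ne ~ 121.12
        cge = np.array([5.0, 6.0, 7.0, 8.0])
        F = 0.035 + 0.004 * (cge - cge.mean())
        dF, ne = ne_from_regression(F, cge, mode="subpopulation")
        assert dF == pytest.approx(0.004 / 0.969, rel=1e-9)
        assert ne == pytest.approx(121.125, abs=0.01)

    def test_subpopulation_reduces_to_whole_when_ft_equals_b(self):
        cge = np.array([0.0, 1.0, 2.0, 3.0])
        b = 0.02
        # construct F with mean exactly b
        F = b * (cge - cge.mean()) + b
        dF_sub, _ = ne_from_regression(F, cge, mode="subpopulation")
        dF_whole, _ = ne_from_regression(F, cge, mode="whole")
        assert dF_sub == pytest.approx(dF_whole, rel=1e-12)

    def test_negative_slope_infinite_ne(self):
        cge = np.array([1.0, 2.0, 3.0])
        F = np.array([0.03, 0.02, 0.01])
        with pytest.warns(UserWarning, match="infinite"):
            dF, ne = ne_from_regression(F, cge)
        assert math.isinf(ne)

    def test_absolute_slope(self):
        cge = np.array([1.0, 2.0, 3.0])
        F = np.array([0.03, 0.02, 0.01])
        dF, ne = ne_from_regression(F, cge, absolute_slope=True)
        assert dF == pytest.approx(0.01)
        assert ne == pytest.approx(50.0)


class TestGeneOrigin:
    def equal_founder_pedigree(self, k=4):
        # k unrelated founders in k/2 couples, each with 4 offspring, so
        # founder contributions are equal and exceed any single kid's
        rows = []
        for i in range(k):
            rows.append((f"F{i}", None, None, "male" if i % 2 == 0 else "female"))
        kids = []
        for i in range(0, k, 2):
            for j in range(4):
                kid = f"K{i}_{j}"
                rows.append((kid, f"F{i}", f"F{i + 1}", "male"))
                kids.append(kid)
        return Pedigree.from_tuples(rows), kids

    def test_fe_equals_founder_count(self):
        ped, kids = self.equal_founder_pedigree(6)
        fe, q = effective_number_of_founders(ped, kids)
        assert fe == pytest.approx(6.0)
        assert sum(q.values()) == pytest.approx(1.0)

    def test_fe_single_founder_line(self):
        ped = Pedigree.from_tuples([("F", None, None, "male"), ("x", "F", None)])
        fe, q = effective_number_of_founders(ped, ["x"])
        # half of x's genes stop at x (unknown dam side), half at F
        assert fe == pytest.approx(2.0)
        assert q["F"] == pytest.approx(0.5)

    def test_missing_reference_errors(self, full_sib_pedigree):
        with pytest.raises(KeyError):
            effective_number_of_founders(full_sib_pedigree, ["nope"])

    def test_contributions_match_montecarlo(self):
        # 12-individual fixture: two founder couples, a shared sire, grandkids
        rows = [
            ("f1", None, None, "male"), ("f2", None, None, "female"),
            ("f3", None, None, "male"), ("f4", None, None, "female"),
            ("s1", "f1", "f2", "male"), ("d1", "f3", "f4", "female"),
            ("d2", "f3", "f4", "female"),
            ("k1", "s1", "d1", "male"), ("k2", "s1", "d1", "female"),
            ("k3", "s1", "d2", "male"), ("k4", "s1", "d2", "female"),
            ("k5", "s1", "d2", "male"),
        ]
        ped = Pedigree.from_tuples(rows)
        parents = {r[0]: (r[1], r[2]) for r in rows}
        ref = ["k1", "k2", "k3", "k4", "k5"]
        _, q = effective_number_of_founders(ped, ref)
        mc, n = montecarlo_founder_contributions(parents, ref, n_drops=100_000, seed=5)
        for f, qv in q.items():
            se = math.sqrt(qv * (1 - qv) / n)
            assert abs(mc.get(f, 0.0) - qv) <= 3 * se + 1e-9

    def test_fa_equals_fe_without_bottleneck(self):
        ped, kids = self.equal_founder_pedigree(6)
        fe, _ = effective_number_of_founders(ped, kids)
        fa, _, _ = effective_number_of_ancestors(ped, kids)
        assert fa == pytest.approx(fe)

    def test_bottleneck_sire_first_contribution(self):
        # one non-founder sire fathers every reference animal, dams unknown:
        # his marginal contribution is 0.5 and funnelling makes f_a < f_e
        rows = [("gf", None, None, "male"), ("gm", None, None, "female"),
                ("sire", "gf", "gm", "male")]
        refs = []
        for i in range(6):
            rows.append((f"r{i}", "sire", None, "female"))
            refs.append(f"r{i}")
        ped = Pedigree.from_tuples(rows)
        fa, qj, chosen = effective_number_of_ancestors(ped, refs)
        fe, _ = effective_number_of_founders(ped, refs)
        assert chosen[0] == "sire"
        assert qj["sire"] == pytest.approx(0.5)
        assert fa < fe

    @pytest.mark.parametrize("seed", range(0, 50, 1))
    def test_fa_never_exceeds_fe(self, seed):
        ped, _ = random_pedigree(seed, n_max=25)
        ref = ped.ids[-5:]
        fe, _ = effective_number_of_founders(ped, ref)
        fa, _, _ = effective_number_of_ancestors(ped, ref)
        assert fa <= fe + 1e-9
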