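import numpy as np
import pandas as pd
import pytest

from floradyn.data_model import SurveyTable, TraitSchema, TraitTable
from floradyn.diversity_metrics import (CommunityVector, cwm, fdis,
                                        functional_redundancy, rao_q,
                                        simpson_diversity, simpson_evenness,
                                        strategy_proportions)
from floradyn.trait_space import DissimilarityMatrix, embed, gower_distance


def _cv(*abund):
    return CommunityVector([f"s{i}" for i in range(len(abund))], np.array(abund))


def _dmat(n, value=1.0):
    m = np.full((n, n), value)
    np.fill_diagonal(m, 0.0)
    return DissimilarityMatrix([f"s{i}" for i in range(n)], m)


class TestSimpson:
    def test_single_species_zero(self):
        assert simpson_diversity(_cv(5.0)) == 0.0

    def test_four_equal(self):
        assert simpson_diversity(_cv(1, 1, 1, 1)) == pytest.approx(0.75)

    def test_uneven_pair(self):
        assert simpson_diversity(_cv(0.9, 0.1)) == pytest.approx(0.18)

    def test_empty_community_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            simpson_diversity(_cv(0.0, 0.0))


class TestEvenness:
    @pytest.mark.parametrize("s", [1, 2, 5, 12])
    def test_equal_abundances_give_one(self, s):
        assert simpson_evenness(_cv(*([3.0] * s))) == pytest.approx(1.0)

    def test_uneven_pair(self):
        assert simpson_evenness(_cv(0.9, 0.1)) == pytest.approx((1 / 0.82) / 2)


class TestRao:
    def test_single_species_zero(self):
        d = _dmat(1)
        assert rao_q(CommunityVector(["s0"], np.array([2.0])), d) == 0.0

    @pytest.mark.parametrize("s", [2, 4, 7])
    def test_unit_distances_equal_gini_simpson(self, s):
        q = rao_q(_cv(*([1.0] * s)), _dmat(s))
        assert q == pytest.approx(1 - 1 / s)

    def test_two_species_hand_value(self):
        assert rao_q(_cv(1, 1), _dmat(2, 0.4)) == pytest.approx(0.2)

    def test_divc_convention_uses_half_squared_distances(self):
        q = rao_q(_cv(1, 1), _dmat(2, 0.4), convention="divc")
        assert q == pytest.approx(0.4 ** 2 / 2 * 0.5)

    def test_species_missing_from_matrix_is_error(self):
        with pytest.raises(KeyError, match="s2"):
            rao_q(_cv(1, 1, 1), _dmat(2))


class TestRedundancy:
    def test_no_redundancy_when_all_distances_one(self):
        assert functional_redundancy(_cv(1, 1, 1), _dmat(3)) == pytest.approx(0.0)

    def test_complete_redundancy_when_distances_zero(self):
        com = _cv(2, 1, 1)
        fr = functional_redundancy(com, _dmat(3, 0.0))
        assert fr == pytest.approx(simpson_diversity(com))


class TestFDis:
    def test_single_species_zero(self):
        d = DissimilarityMatrix(["s0", "s1"], np.array([[0, 0.4], [0.4, 0]]))
        emb = embed(d)
        assert fdis(CommunityVector(["s0"], np.array([1.0])), emb) == 0.0

    def test_two_point_equal_weights(self):
        d = _dmat(2, 0.4)
        assert fdis(_cv(1, 1), embed(d)) == pytest.approx(0.2)

    def test_species_absent_from_embedding_is_error(self):
        emb = embed(_dmat(2, 0.4))
        with pytest.raises(KeyError, match="s2"):
            fdis(_cv(1, 1, 1), emb)

    def test_one_numeric_trait_matches_direct_computation(self, rng):
        # Gower on a single numeric trait is Euclidean: FDis from the
        # embedding must equal the direct weighted mean |x - centroid|/range
        x = rng.uniform(size=6)
        t = TraitTable(pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(6)]),
                       TraitSchema({"x": "numeric"}))
        emb = embed(gower_distance(t))
        a = rng.uniform(0.5, 2.0, size=6)
        com = CommunityVector([f"s{i}" for i in range(6)], a)
        p = a / a.sum()
        xn = (x - x.min()) / (x.max() - x.min())
        expect = float(p @ np.abs(xn - p @ xn))
        assert fdis(com, emb) == pytest.approx(expect, abs=1e-10)


class TestCWM:
    def _traits(self):
        df = pd.DataFrame({"ldmc": [100.0, 200.0, np.nan]},
                          index=["s0", "s1", "s2"])
        return TraitTable(df, TraitSchema({"ldmc": "numeric"}))

    def test_single_species_returns_its_value(self):
        t = self._traits()
        assert cwm(CommunityVector(["s0"], np.array([3.0])), t, "ldmc") == 100.0

    def test_weighted_mean(self):
        t = self._traits()
        com = CommunityVector(["s0", "s1"], np.array([0.25, 0.75]))
        assert cwm(com, t, "ldmc") == pytest.approx(175.0)

    def test_missing_species_excluded_with_renormalisation(self):
        t = self._traits()
        com = CommunityVector(["s0", "s1", "s2"], np.array([1.0, 1.0, 10.0]))
        assert cwm(com, t, "ldmc") == pytest.approx(150.0)

    def test_all_missing_is_error(self):
        t = self._traits()
        with pytest.raises(ValueError, match="missing"):
            cwm(CommunityVector(["s2"], np.array([1.0])), t, "ldmc")


class TestInvariants:
    """Randomised property checks for the metric inequalities."""

    def test_metric_inequalities_on_random_communities(self, rng):
        n_pool = 15
        m = rng.uniform(0, 1, (n_pool, n_pool))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0.0)
        d = DissimilarityMatrix([f"s{i}" for i in range(n_pool)], m)
        for _ in range(300):
            s = int(rng.integers(1, n_pool + 1))
            idx = rng.choice(n_pool, size=s, replace=False)
            com = CommunityVector([f"s{i}" for i in idx],
                                  rng.uniform(0.1, 5.0, size=s))
            D = simpson_diversity(com)
            Q = rao_q(com, d)
            fr = functional_redundancy(com, d)
            assert 0.0 <= Q <= D + 1e-12 <= 1 - 1 / s + 1e-12
            assert -1e-12 <= fr <= D + 1e-12

    def test_duplicating_a_species_leaves_q_unchanged(self, rng):
        x = rng.uniform(size=(5, 2))
        names = [f"s{i}" for i in range(5)]
        df = pd.DataFrame(x, columns=["a", "b"], index=names)
        # duplicate species s0 as s0bis with identical traits
        df2 = pd.concat([df, df.iloc[[0]].rename(index={"s0": "s0bis"})])
        schema = TraitSchema({"a": "numeric", "b": "numeric"})
        d1, d2 = gower_distance(TraitTable(df, schema)), gower_distance(
            TraitTable(df2, schema))
        a = rng.uniform(1.0, 3.0, size=5)
        com1 = CommunityVector(names, a)
        split = np.concatenate([[a[0] / 2], a[1:], [a[0] / 2]])
        com2 = CommunityVector(names + ["s0bis"], split)
        assert rao_q(com2, d2) == pytest.approx(rao_q(com1, d1), abs=1e-10)

    def test_duplicating_a_species_leaves_fdis_unchanged_euclidean(self, rng):
        # FDis subset-consistency is exact only when the Gower matrix is
        # Euclidean (corrections depend on the full species set otherwise),
        # so the invariance is checked on a single numeric trait
        x = rng.uniform(size=5)
        names = [f"s{i}" for i in range(5)]
        schema = TraitSchema({"a": "numeric"})
        df = pd.DataFrame({"a": x}, index=names)
        df2 = pd.concat([df, df.iloc[[0]].rename(index={"s0": "s0bis"})])
        e1 = embed(gower_distance(TraitTable(df, schema)))
        e2 = embed(gower_distance(TraitTable(df2, schema)))
        a = rng.uniform(1.0, 3.0, size=5)
        com1 = CommunityVector(names, a)
        split = np.concatenate([[a[0] / 2], a[1:], [a[0] / 2]])
        com2 = CommunityVector(names + ["s0bis"], split)
        assert fdis(com2, e2) == pytest.approx(fdis(com1, e1), abs=1e-10)

    def test_cwm_bounded_by_present_trait_values(self, rng):
        vals = rng.uniform(50, 400, size=8)
        t = TraitTable(pd.DataFrame({"ldmc": vals},
                                    index=[f"s{i}" for i in range(8)]),
                       TraitSchema({"ldmc": "numeric"}))
        for _ in range(100):
            s = int(rng.integers(1, 9))
            idx = rng.choice(8, size=s, replace=False)
            com = CommunityVector([f"s{i}" for i in idx],
                                  rng.uniform(0.1, 1.0, size=s))
            v = cwm(com, t, "ldmc")
            assert vals[idx].min() - 1e-9 <= v <= vals[idx].max() + 1e-9


class TestStrategyProportions:
    def _traits(self, strategies):
        df = pd.DataFrame({"regeneration_strategy": strategies},
                          index=[f"s{i}" for i in range(len(strategies))])
        return TraitTable(df, TraitSchema({"regeneration_strategy": "categorical"}))

    def _survey(self, covers):
        rows = [{"plot": 1, "transect": 1, "block": 1, "assemblage": "A",
                 "year": 1, "species": f"s{i}", "cover": c, "sown": True}
                for i, c in enumerate(covers)]
        return SurveyTable(pd.DataFrame(rows))

    def test_all_annual_community(self):
        t = self._traits(["annual", "annual"])
        out = strategy_proportions(self._survey([30.0, 20.0]), t)
        assert out["fraction"].tolist() == [1.0]
        assert out["category"].tolist() == ["annual"]

    def test_two_equal_categories_split_half(self):
        t = self._traits(["annual", "biennial"])
        out = strategy_proportions(self._survey([25.0, 25.0]), t)
        assert sorted(out["fraction"]) == [0.5, 0.5]

    def test_unknown_strategy_excluded_and_reported(self):
        t = self._traits(["annual", None])
        with pytest.warns(UserWarning, match="excluded"):
            out = strategy_proportions(self._survey([30.0, 10.0]), t)
        assert out["fraction"].tolist() == [1.0]
        assert out["excluded_cover_share"].iloc[0] == pytest.approx(0.25)

    def test_fractions_sum_to_one_per_year(self, benchmark):
        out = strategy_proportions(benchmark.survey, benchmark.pool)
        sums = out.groupby("year")["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_benchmark_annual_share_near_sixty_percent_in_year_one(self, benchmark):
        out = strategy_proportions(benchmark.survey, benchmark.pool)
        y1 = out[(out["year"] == 1) & (out["category"] == "annual")]
        assert 0.45 <= float(y1["fraction"].iloc[0]) <= 0.75
        y4 = out[(out["year"] == 4) & (out["category"] == "annual")]
        assert float(y4["fraction"].iloc[0]) < float(y1["fraction"].iloc[0])
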