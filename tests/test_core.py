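import numpy as np
import pandas as pd
import pytest

from phylofactor import (
    RegressionSpec,
    choose_factor,
    fit_candidate,
    ks_stop_check,
    phylofactorize,
    total_variance,
    close_to_composition,
    clr_transform,
    rooted_ilr_transform,
)
from phylofactor.core import CandidateFit, _contrast_row, _gaussian_fit_stats
from phylofactor.phylo_tree import (
    Phylogeny,
    TaxonBin,
    candidate_partitions,
    rooted_sbp,
)

from conftest import make_composition
from _oracle import balance_value, explained_ss


def _spec():
    return RegressionSpec(("site",))


class TestTotalVariance:
    def test_identical_samples_zero(self):
        comp = close_to_composition(pd.DataFrame(np.tile([[1.0], [2.0], [3.0]], 4)))
        assert total_variance(comp) == pytest.approx(0.0, abs=1e-12)

    def test_equals_any_full_sbp_balance_variance(self, rng):
        tree = Phylogeny.from_newick("(((A,B),C),(D,(E,F)));")
        comp = make_composition(rng, "ABCDEF", 9)
        balances = rooted_ilr_transform(comp, rooted_sbp(tree))
        assert total_variance(comp) == pytest.approx(
            float(balances.to_numpy().var(axis=1, ddof=1).sum()), abs=1e-10
        )

    def test_needs_two_samples(self):
        comp = close_to_composition(pd.DataFrame([[1.0], [2.0]]))
        with pytest.raises(ValueError):
            total_variance(comp)


class TestFitCandidate:
    def test_perfect_linear_fit(self):
        X = pd.DataFrame({"site": [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]})
        y = 2.0 + 3.0 * X["site"].to_numpy()
        fit = fit_candidate(y, _spec(), X)
        tss = float(((y - y.mean()) ** 2).sum())
        assert fit.objective == pytest.approx(tss, rel=1e-10)
        assert fit.p_value < 1e-10

    def test_constant_balance_is_degenerate(self):
        X = pd.DataFrame({"site": ["a", "a", "b", "b", "a", "b"]})
        fit = fit_candidate(np.full(6, 3.7), _spec(), X)
        assert fit.objective == 0.0 and fit.p_value == 1.0

    def test_matches_normal_equations_by_hand(self):
        # OLS of y = (1,2,3,5) on x = (0,1,2,3): slope 1.3, ESS = 1.3^2 * 5
        X = pd.DataFrame({"site": [0.0, 1.0, 2.0, 3.0]})
        fit = fit_candidate(np.array([1.0, 2.0, 3.0, 5.0]), _spec(), X)
        assert fit.objective == pytest.approx(8.45, abs=1e-10)
        assert fit.coefficients["site"] == pytest.approx(1.3, abs=1e-10)

    def test_rank_deficient_design_rejected(self):
        X = pd.DataFrame({"site": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="rank"):
            fit_candidate(np.arange(4.0), _spec(), X)


class TestChooseFactor:
    def _cand(self, edge, obj):
        return CandidateFit((edge,), frozenset("A"), frozenset("B"), 0, obj, 0.5)

    def test_maximum_wins(self):
        cands = [self._cand(1, 3.0), self._cand(2, 7.0), self._cand(3, 2.0)]
        assert choose_factor(cands).edge_id == 2

    def test_tie_broken_by_smallest_edge_id(self):
        cands = [self._cand(9, 5.0), self._cand(4, 5.0)]
        assert choose_factor(cands).edge_id == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            choose_factor([])


class TestKsStop:
    def test_extreme_small_p_values_continue(self):
        assert ks_stop_check([1e-8] * 50) < 1e-6

    def test_uniform_grid_stops(self):
        n = 50
        grid = [(i + 1) / (n + 1) for i in range(n)]
        assert ks_stop_check(grid) > 0.5

    def test_all_degenerate_p_one_stops(self):
        # pools of p=1 (constant balances) carry no signal
        assert ks_stop_check([1.0] * 30) > 0.9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ks_stop_check([])
        with pytest.raises(ValueError):
            ks_stop_check([0.5, 1.5])


class TestPhylofactorize:
    def test_no_signal_stops_at_zero_factors(self, toy_tree):
        values = np.tile(np.array([[0.1, 0.2, 0.3, 0.25, 0.15]]).T, 12)
        comp = close_to_composition(
            pd.DataFrame(values, index=list("ABCDE"), columns=[f"s{j}" for j in range(12)])
        )
        X = pd.DataFrame({"site": ["a"] * 6 + ["b"] * 6}, index=comp.samples)
        res = phylofactorize(comp, toy_tree, _spec(), X, stop="ks")
        assert res.n_factors == 0
        assert len(res.bins) == 1

    def test_noiseless_doubling_recovers_clade_by_exhaustive_check(self, toy_tree, binary_env):
        # {A,B} doubled in condition 2; no noise: the {A,B} edge must win
        base = np.tile([[1.0], [1.5], [0.8], [1.2], [2.0]], 12)
        base[:2, 6:] *= 2.0
        df = pd.DataFrame(base, index=list("ABCDE"), columns=binary_env.index)
        comp = close_to_composition(df)
        res = phylofactorize(comp, toy_tree, _spec(), binary_env, stop=1)
        f = res.factors[0]
        assert {f.side_R, f.side_S} == {frozenset("AB"), frozenset("CDE")}
        # independent exhaustive check over all 7 edges
        x = (binary_env["site"] == "tongue").to_numpy(dtype=float)
        objs = {}
        for bp in toy_tree.bipartitions():
            objs[bp.side_R] = explained_ss(
                balance_value(comp.relabund, bp.side_R, bp.side_S), x
            )
        best = max(objs, key=objs.get)
        assert best in (frozenset("AB"), frozenset("CDE"))
        assert f.candidate.objective == pytest.approx(objs[best], rel=1e-9)

    def test_bins_partition_and_count(self, effect_comp, toy_tree, binary_env):
        res = phylofactorize(effect_comp, toy_tree, _spec(), binary_env, stop=3)
        assert len(res.bins) == res.n_factors + 1
        union = frozenset().union(*(b.members for b in res.bins))
        assert union == frozenset("ABCDE")
        assert sum(len(b.members) for b in res.bins) == 5

    def test_full_factorization_gives_orthonormal_basis_and_roundtrip(self, rng):
        from phylofactor import inverse_ilr, project
        from phylofactor.simulate import random_tree

        tree = random_tree(8, 3)
        comp = make_composition(rng, tree.tips, 10)
        X = pd.DataFrame({"site": ["a", "b"] * 5}, index=comp.samples)
        res = phylofactorize(comp, tree, _spec(), X, stop=7)
        assert res.n_factors == 7
        V = res.basis.matrix
        assert np.allclose(V.T @ V, np.eye(7), atol=1e-10)
        back = inverse_ilr(res.balances, res.basis, sample_ids=comp.samples)
        assert np.allclose(back.values, comp.values, atol=1e-10)
        # cumulative objective bounded by total SS; objectives came out sorted-ish
        objs = [f.candidate.objective for f in res.factors]
        assert sum(objs) <= res.total_ss * (1 + 1e-10)

    def test_vectorized_and_scalar_fits_agree(self, effect_comp, toy_tree, binary_env):
        spec = _spec()
        bins = [TaxonBin(frozenset("ABCDE"), True, ())]
        cands = candidate_partitions(bins, toy_tree, set())
        index = {t: i for i, t in enumerate(effect_comp.taxa)}
        C = np.array([_contrast_row(c, index, 5) for c in cands])
        A, _ = spec.build_design(binary_env)
        Q, _ = np.linalg.qr(A)
        ess, pvals = _gaussian_fit_stats(C @ np.log(effect_comp.values), Q, 2)
        for i, c in enumerate(cands):
            bal = balance_value(effect_comp.relabund, c.side_R, c.side_S)
            fit = fit_candidate(bal, spec, binary_env, c)
            assert fit.objective == pytest.approx(float(ess[i]), rel=1e-8, abs=1e-12)
            assert fit.p_value == pytest.approx(float(pvals[i]), rel=1e-6, abs=1e-12)

    def test_taxa_missing_from_tree_is_hard_error(self, effect_comp, binary_env):
        tree = Phylogeny.from_newick("((A,B),(C,D));")  # no E
        with pytest.raises(ValueError, match="absent from the tree"):
            phylofactorize(effect_comp, tree, _spec(), binary_env)

    def test_extra_tree_tips_pruned_with_warning(self, effect_comp, binary_env):
        tree = Phylogeny.from_newick("(((A,B),(C,D)),(E,(F,G)));")
        with pytest.warns(UserWarning, match="pruning"):
            res = phylofactorize(effect_comp, tree, _spec(), binary_env, stop=1)
        assert res.n_factors == 1
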