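import numpy as np
import pandas as pd
import pytest

from phylofactor import (
    RegressionSpec,
    balance_to_fold_ratio,
    balancing_element,
    bins_after,
    clr_significance,
    close_to_composition,
    explained_variance_fraction,
    inverse_ilr,
    lmg_dominance,
    phylofactorize,
    predicted_bpu,
    shortest_unique_prefix,
)
from phylofactor.ilr import IlrBasis
from phylofactor.phylo_tree import Phylogeny, TaxonBin
from phylofactor.summaries import amalgamate_bpu, ordination_coordinates

from conftest import make_composition


@pytest.fixture
def fitted(effect_comp, toy_tree, binary_env):
    return phylofactorize(effect_comp, toy_tree, RegressionSpec(("site",)), binary_env, stop=4)


class TestBins:
    def test_counts_across_k(self, fitted):
        assert len(bins_after(fitted, 0)) == 1
        for k in range(fitted.n_factors + 1):
            bins = bins_after(fitted, k)
            assert len(bins) == k + 1
            assert frozenset().union(*(b.members for b in bins)) == frozenset("ABCDE")
        assert all(len(b.members) == 1 for b in bins_after(fitted, 4))

    def test_out_of_range(self, fitted):
        with pytest.raises(ValueError):
            bins_after(fitted, fitted.n_factors + 1)


class TestAmalgamation:
    def test_hand_example(self):
        comp = close_to_composition(
            pd.DataFrame([[0.1], [0.2], [0.3], [0.4]], index=list("ABCD"))
        )
        bins = [TaxonBin(frozenset("AB"), True, ()), TaxonBin(frozenset("CD"), True, ())]
        bpu = amalgamate_bpu(comp, bins)
        assert np.allclose(bpu.composition.to_numpy().flatten(), [0.3, 0.7])

    def test_singletons_are_identity_and_mass_conserved(self, toy_comp):
        bins = [TaxonBin(frozenset(t), True, ()) for t in toy_comp.taxa]
        bpu = amalgamate_bpu(toy_comp, bins)
        assert np.allclose(bpu.composition.to_numpy(), toy_comp.values)
        one = amalgamate_bpu(toy_comp, [TaxonBin(frozenset(toy_comp.taxa), True, ())])
        assert np.allclose(one.composition.to_numpy(), 1.0)

    def test_non_partition_rejected(self, toy_comp):
        with pytest.raises(ValueError, match="partition"):
            amalgamate_bpu(toy_comp, [TaxonBin(frozenset("AB"), True, ())])


class TestFoldRatio:
    def test_zero_balance_is_ratio_one(self):
        assert balance_to_fold_ratio(0.0, 3, 7) == 1.0

    def test_exact_inverse(self):
        x = np.sqrt(0.5) * np.log(4.0)
        assert balance_to_fold_ratio(x, 1, 1) == pytest.approx(4.0, rel=1e-12)


class TestExplainedVariance:
    def test_zero_and_monotone(self, fitted):
        assert explained_variance_fraction(fitted, 0) == 0.0
        fracs = [explained_variance_fraction(fitted, k) for k in range(fitted.n_factors + 1)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        assert fracs[-1] <= 1.0 + 1e-10

    def test_noiseless_model_data_fully_explained(self, toy_tree, binary_env):
        # data generated exactly from the covariate model: full basis R^2 = 1
        base = np.tile([[1.0], [1.5], [0.8], [1.2], [2.0]], 12)
        base[:2, 6:] *= 3.0
        base[4:, 6:] *= 0.5
        comp = close_to_composition(
            pd.DataFrame(base, index=list("ABCDE"), columns=binary_env.index)
        )
        res = phylofactorize(comp, toy_tree, RegressionSpec(("site",)), binary_env, stop=4)
        assert explained_variance_fraction(res, 4) == pytest.approx(1.0, abs=1e-8)


class TestPredictedBpu:
    def test_noiseless_round_trip(self, toy_tree, binary_env):
        # model-generated data: between-bin fold only, flat within bins (the
        # k-factor model constrains between-bin structure alone)
        base = np.ones((5, 12))
        base[:2, 6:] *= 3.0
        comp = close_to_composition(
            pd.DataFrame(base, index=list("ABCDE"), columns=binary_env.index)
        )
        res = phylofactorize(comp, toy_tree, RegressionSpec(("site",)), binary_env, stop=1)
        observed = amalgamate_bpu(comp, bins_after(res, 1)).composition.to_numpy()
        predicted = predicted_bpu(res, 1, binary_env).composition.to_numpy()
        assert np.allclose(predicted, observed, atol=1e-8)

    def test_k_zero_single_bin(self, fitted, binary_env):
        bpu = predicted_bpu(fitted, 0, binary_env)
        assert np.allclose(bpu.composition.to_numpy(), 1.0)

    def test_predictions_constant_in_covariate_free_direction(self, fitted, binary_env):
        # two samples with identical covariates get identical predictions
        newX = pd.DataFrame({"site": ["gut", "gut"]}, index=["n1", "n2"])
        bpu = predicted_bpu(fitted, 2, newX)
        assert np.allclose(bpu.composition["n1"], bpu.composition["n2"])


class TestTaxonomyLabels:
    TAX = {
        "A": "k__B;p__Firmicutes;g__Staph",
        "B": "k__B;p__Firmicutes;g__Strep",
        "C": "k__B;p__Bacteroidetes;g__Prevotella",
        "D": "k__B;p__Bacteroidetes;g__Bacteroides",
        "E": "k__B;p__Proteobacteria;g__Campylobacter",
    }

    def test_phylum_prefix_covers_clean_bin(self):
        bins = [TaxonBin(frozenset("AB"), True, ()), TaxonBin(frozenset("CDE"), False, ())]
        labels = shortest_unique_prefix(self.TAX, bins)
        assert labels[0] == ["k__B;p__Firmicutes"]
        assert set(labels[1]) == {"k__B;p__Bacteroidetes", "k__B;p__Proteobacteria"}

    def test_singleton_gets_genus_level(self):
        bins = [TaxonBin(frozenset("C"), True, ()), TaxonBin(frozenset("ABDE"), False, ())]
        labels = shortest_unique_prefix(self.TAX, bins)
        assert labels[0] == ["k__B;p__Bacteroidetes;g__Prevotella"]

    def test_identical_lineages_fall_back_to_ids(self):
        tax = {"A": "k__B;p__X", "B": "k__B;p__X"}
        bins = [TaxonBin(frozenset("A"), True, ()), TaxonBin(frozenset("B"), True, ())]
        labels = shortest_unique_prefix(tax, bins)
        assert labels == [["A"], ["B"]]


class TestClrSignificance:
    def test_affected_taxa_discovered_and_bh_superset_of_bonferroni(self, rng):
        taxa = [f"t{i}" for i in range(30)]
        N = np.exp(rng.normal(8, 0.5, size=(30, 40)))
        df = pd.DataFrame(N, index=taxa, columns=[f"s{j}" for j in range(40)])
        df.iloc[:3, 20:] *= 8.0  # strong effect on 3 taxa
        comp = close_to_composition(df)
        X = pd.DataFrame({"site": ["a"] * 20 + ["b"] * 20}, index=comp.samples)
        out = clr_significance(comp, RegressionSpec(("site",)), X, fdr=0.01)
        assert out.loc[["t0", "t1", "t2"], "significant"].all()
        assert set(out.index[out.bonferroni]) <= set(out.index[out.significant])

    def test_fdr_validation(self, toy_comp, binary_env):
        with pytest.raises(ValueError):
            clr_significance(toy_comp, RegressionSpec(("site",)), binary_env, fdr=1.5)


class TestLmgDominance:
    def test_single_regressor_share_is_model_ess(self, rng):
        X = pd.DataFrame({"ph": rng.normal(size=30)}, index=range(30))
        y = 2.0 * X["ph"].to_numpy() + rng.normal(0, 0.1, 30)
        spec = RegressionSpec(("ph",))
        dom = lmg_dominance(y, spec, X)
        assert dom.shares["ph"] == pytest.approx(dom.explained_ss, rel=1e-12)

    def test_orthogonal_equal_regressors_share_equally(self):
        n = 8
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = x1 + x2
        X = pd.DataFrame({"a": x1, "b": x2}, index=range(n))
        dom = lmg_dominance(y, RegressionSpec(("a", "b")), X)
        assert dom.shares["a"] == pytest.approx(dom.shares["b"], rel=1e-10)
        assert dom.pct_of_explained.sum() == pytest.approx(100.0, rel=1e-10)

    def test_two_regressor_closed_form(self, rng):
        import statsmodels.api as sm

        X = pd.DataFrame(
            {"ph": rng.normal(size=40), "c": rng.normal(size=40)}, index=range(40)
        )
        X["c"] += 0.5 * X["ph"]  # correlated regressors
        y = 1.5 * X["ph"].to_numpy() - 0.7 * X["c"].to_numpy() + rng.normal(0, 0.3, 40)
        dom = lmg_dominance(y, RegressionSpec(("ph", "c")), X)

        def ess(cols):
            A = sm.add_constant(X[list(cols)].to_numpy()) if cols else np.ones((40, 1))
            fit = sm.OLS(y, A).fit()
            return float(fit.ess) if cols else 0.0

        share_ph = 0.5 * (ess(["ph"]) + (ess(["ph", "c"]) - ess(["c"])))
        assert dom.shares["ph"] == pytest.approx(share_ph, rel=1e-8)
        assert dom.shares.sum() == pytest.approx(ess(["ph", "c"]), rel=1e-10)

    def test_too_many_regressors_rejected(self, rng):
        X = pd.DataFrame({f"v{i}": rng.normal(size=20) for i in range(9)}, index=range(20))
        with pytest.raises(ValueError, match="m!"):
            lmg_dominance(rng.normal(size=20), RegressionSpec(tuple(f"v{i}" for i in range(9))), X)


def test_ordination_coordinates_shape(fitted):
    coords = ordination_coordinates(fitted, 2)
    assert coords.shape == (12, 2)
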