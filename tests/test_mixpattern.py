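"""Density estimation, mixture fitting, Bayes boundaries and tissue tree."""

import numpy as np
import pytest
from scipy import stats

from methaccord import mixpattern
from methaccord.mixpattern import (
    MixtureModel,
    association_chi2,
    bayes_boundaries,
    component_assignment,
    fit_gmm,
    pde,
    tissue_tree,
)


class TestPDE:
    def test_matches_standard_normal_density(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        grid = pde(x)
        assert np.max(np.abs(grid.density - stats.norm.pdf(grid.x))) < 0.03

    def test_matches_uniform_density_in_bulk(self):
        x = np.random.default_rng(2).uniform(0, 1, 10_000)
        grid = pde(x)
        bulk = (grid.x > 0.1) & (grid.x < 0.9)
        assert np.max(np.abs(grid.density[bulk] - 1.0)) < 0.1

    def test_normalized_to_unit_integral(self, rng):
        grid = pde(rng.normal(5, 3, 500))
        assert np.trapezoid(grid.density, grid.x) == pytest.approx(1.0, abs=1e-3)
        assert (grid.density >= 0).all()

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError, match="constant"):
            pde(np.full(100, 3.0))
        with pytest.raises(ValueError, match="n >= 10"):
            pde(np.arange(5.0))


class TestFitGMM:
    def test_single_gaussian_parameter_recovery(self):
        x = np.random.default_rng(7).normal(5, 2, 2000)
        model = fit_gmm(x, seed=1)
        assert model.M == 1
        assert model.means[0] == pytest.approx(5.0, abs=0.15)
        assert model.sds[0] == pytest.approx(2.0, abs=0.15)

    def test_two_separated_components_recovered(self):
        r = np.random.default_rng(7)
        x = np.concatenate([r.normal(-10, 1, 1000), r.normal(10, 1, 1000)])
        model = fit_gmm(x, seed=1)
        assert model.M == 2
        assert model.means == pytest.approx([-10.0, 10.0], abs=0.2)
        assert model.w == pytest.approx([0.5, 0.5], abs=0.05)

    def test_three_component_recovery_at_10x_study_size(self):
        """A separated 3-lump pattern is recovered to within 1 % methylation."""
        r = np.random.default_rng(0)
        w_true = np.array([0.20, 0.25, 0.55])
        means_true = np.array([-12.0, 0.0, 20.1])
        sds_true = np.array([4.0, 5.0, 3.42])
        comp = r.choice(3, size=2380, p=w_true)
        x = r.normal(means_true[comp], sds_true[comp])
        model = fit_gmm(x, M_range=[3], seed=0)
        assert np.max(np.abs(model.means - means_true)) < 1.0

    def test_weights_sum_to_one_and_means_sorted(self, default_sheet):
        d = (default_sheet["line1_pct"] - default_sheet["luma_pct"]).to_numpy()
        model = fit_gmm(d, M_range=[3], seed=3)
        assert model.w.sum() == pytest.approx(1.0, abs=1e-9)
        assert (np.diff(model.means) > 0).all()
        assert (model.sds > 0).all()

    def test_deterministic_under_seed(self, default_sheet):
        d = (default_sheet["line1_pct"] - default_sheet["luma_pct"]).to_numpy()
        a = fit_gmm(d, M_range=[2], seed=9)
        b = fit_gmm(d, M_range=[2], seed=9)
        assert np.array_equal(a.means, b.means) and np.array_equal(a.w, b.w)

    def test_too_small_sample_raises(self):
        with pytest.raises(ValueError, match="n >="):
            fit_gmm(np.arange(20.0), M_range=range(1, 6))


class TestBayesBoundaries:
    def test_symmetric_pair_splits_at_midpoint(self):
        model = MixtureModel(2, np.array([0.5, 0.5]), np.array([-1.0, 1.0]),
                             np.array([1.0, 1.0]), 0.0)
        assert bayes_boundaries(model) == pytest.approx([0.0], abs=1e-9)

    def test_weight_imbalance_closed_form(self):
        """With w = (0.9, 0.1), sd 1, means 0/2 the changeover sits at
        1 + ln(9)/2, beyond the second mean (grid fallback)."""
        model = MixtureModel(2, np.array([0.9, 0.1]), np.array([0.0, 2.0]),
                             np.array([1.0, 1.0]), 0.0)
        b = bayes_boundaries(model)
        assert b[0] == pytest.approx(1 + np.log(9) / 2, abs=1e-3)

    def test_posteriors_equal_at_boundary(self, default_sheet):
        d = (default_sheet["line1_pct"] - default_sheet["luma_pct"]).to_numpy()
        model = fit_gmm(d, M_range=[2], seed=1)
        b = model.boundaries
        _, post = component_assignment(b, model)
        assert abs(post[0, 0] - post[0, 1]) < 1e-6

    def test_single_component_has_no_boundary(self):
        model = MixtureModel(1, np.array([1.0]), np.array([0.0]), np.array([1.0]), 0.0)
        with pytest.raises(ValueError, match="M >= 2"):
            bayes_boundaries(model)


class TestComponentAssignment:
    def make_model(self):
        return MixtureModel(3, np.array([0.3, 0.2, 0.5]),
                            np.array([-10.0, 0.0, 15.0]),
                            np.array([2.0, 1.5, 3.0]), 0.0)

    def test_matches_brute_force_posterior(self, rng):
        model = self.make_model()
        x = rng.normal(0, 10, 500)
        _, post = component_assignment(x, model)
        dens = model.w * stats.norm.pdf(x[:, None], model.means, model.sds)
        brute = dens / dens.sum(axis=1, keepdims=True)
        assert np.max(np.abs(post - brute)) < 1e-12

    def test_posteriors_normalized(self, rng):
        _, post = component_assignment(rng.normal(0, 20, 300), self.make_model())
        assert np.max(np.abs(post.sum(axis=1) - 1.0)) < 1e-12

    def test_point_at_mean_of_separated_component(self):
        labels, post = component_assignment(np.array([-10.0]), self.make_model())
        assert labels[0] == 0
        assert post[0, 0] > 0.99


class TestAssociationChi2:
    def test_perfect_association_3x3(self):
        tissue = np.repeat(["a", "b", "c"], 30)
        res = association_chi2(tissue, tissue)
        assert res["chi2"] == pytest.approx(180.0)  # 2n for a perfect 3x3
        assert res["df"] == 4

    def test_perfect_association_2x2(self):
        labels = np.repeat(["a", "b"], 10)
        res = association_chi2(labels, labels)
        assert res["chi2"] == pytest.approx(20.0)
        assert res["df"] == 1

    def test_type_one_error_rate_under_independence(self):
        r = np.random.default_rng(3)
        reps, rejections = 1000, 0
        for _ in range(reps):
            tissue = r.choice(3, size=200)
            comp = r.choice(3, size=200)
            rejections += association_chi2(tissue, comp)["p"] < 0.05
        assert abs(rejections / reps - 0.05) < 0.02

    def test_degenerate_table_raises(self):
        with pytest.raises(ValueError, match="2 rows"):
            association_chi2(np.repeat("a", 10), np.repeat([0, 1], 5))


class TestTissueTree:
    def test_injective_tissue_component_map(self):
        tissue = np.repeat(["a", "b", "c"], 20)
        comp = np.repeat([0, 1, 2], 20)
        tree = tissue_tree(tissue, comp, seed=0)
        assert tree.cv_accuracy == 1.0
        assert (tree.predict(["a", "b", "c"]) == [0, 1, 2]).all()

    def test_uninformative_tissue_scores_at_class_prior(self):
        r = np.random.default_rng(8)
        tissue = r.choice(["a", "b", "c"], size=600)
        comp = r.choice(3, size=600, p=[0.5, 0.3, 0.2])
        tree = tissue_tree(tissue, comp, seed=1)
        assert tree.cv_accuracy == pytest.approx(0.5, abs=0.08)

    def test_accuracy_at_least_majority_prior(self, rng):
        for trial in range(5):
            tissue = rng.choice(["a", "b", "c", "d"], size=200)
            comp = rng.choice(3, size=200)
            tree = tissue_tree(tissue, comp, seed=trial)
            prior = np.max(np.bincount(comp)) / len(comp)
            assert tree.cv_accuracy >= prior - 0.1

    def test_matches_reference_tree_classifier(self, default_sheet):
        """Resubstitution predictions equal sklearn's entropy tree on
        one-hot tissue labels (independent route to the same splits)."""
        from sklearn.tree import DecisionTreeClassifier
        from sklearn.preprocessing import OneHotEncoder

        d = (default_sheet["line1_pct"] - default_sheet["luma_pct"]).to_numpy()
        model = fit_gmm(d, M_range=[3], seed=1)
        labels, _ = component_assignment(d, model)
        tissue = default_sheet["subset"].to_numpy()
        tree = tissue_tree(tissue, labels, seed=0)
        enc = OneHotEncoder(sparse_output=False).fit(tissue[:, None])
        ref = DecisionTreeClassifier(criterion="entropy", random_state=0)
        ref.fit(enc.transform(tissue[:, None]), labels)
        ours = tree.predict(tissue)
        theirs = ref.predict(enc.transform(tissue[:, None]))
        assert (ours == theirs).all()

    def test_leaf_proportions_sum_to_one(self, default_sheet):
        d = (default_sheet["line1_pct"] - default_sheet["luma_pct"]).to_numpy()
        model = fit_gmm(d, M_range=[3], seed=1)
        labels, _ = component_assignment(d, model)
        tree = tissue_tree(default_sheet["subset"].to_numpy(), labels, seed=0)
        for props in tree.leaf_class_props:
            assert sum(props) == pytest.approx(1.0)

    def test_needs_two_tissues_and_components(self):
        with pytest.raises(ValueError, match="2 tissues"):
            tissue_tree(np.repeat("a", 20), np.repeat([0, 1], 10), seed=0)
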