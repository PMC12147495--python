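import numpy as np
import pytest

from bonevar import (
    MaterialDataset,
    MaterialSample,
    assemble_feature_matrix,
    default_zoo,
    double_cross_validate,
    fast_zoo,
    generate_subdatasets,
    predict_ensemble,
    select_and_fit,
)
from bonevar.ensemble import DegenerateTargetError, FoldError, ModelZoo, zoo_from_names


def _linear_dataset(n=38, noise=0.0, seed=0, n_meas=1):
    """Materials with y = 3*x1 + 1 (+ optional noise), x2 a distractor."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        x1, x2 = rng.uniform(0, 10), rng.uniform(0, 10)
        y = 3 * x1 + 1
        meas = [float(y + rng.normal(0, noise)) for _ in range(n_meas)]
        samples.append(MaterialSample(f"s{i}", {"x1": x1, "x2": x2}, meas))
    return MaterialDataset(samples=samples, feature_names=["x1", "x2"])


class TestGenerateSubdatasets:
    def test_responses_are_drawn_from_own_measurements(self, tiny_dataset):
        table = assemble_feature_matrix(tiny_dataset, "A")
        for sub in generate_subdatasets(tiny_dataset, table, 25, seed=3):
            for i, s in enumerate(tiny_dataset.samples):
                assert sub.responses[i] == s.measurements[sub.chosen_index[i]]

    def test_single_measurement_material_is_constant_across_subdatasets(self, tiny_dataset):
        table = assemble_feature_matrix(tiny_dataset, "A")
        subs = generate_subdatasets(tiny_dataset, table, 50, seed=0)
        assert all(sub.responses[0] == 50.0 for sub in subs)  # m1 has one measurement

    def test_uniform_draw_frequencies(self):
        ds = MaterialDataset(
            samples=[MaterialSample("m", {"x": 1.0}, [10.0, 20.0])], feature_names=["x"]
        )
        table = assemble_feature_matrix(ds, "A")
        subs = generate_subdatasets(ds, table, 10_000, seed=7)
        n_first = sum(sub.responses[0] == 10.0 for sub in subs)
        # binomial(10000, 0.5): 4-sigma band is 5000 +/- 200
        assert abs(n_first - 5000) <= 200

    def test_deterministic_given_seed(self, tiny_dataset):
        table = assemble_feature_matrix(tiny_dataset, "A")
        a = generate_subdatasets(tiny_dataset, table, 10, seed=9)
        b = generate_subdatasets(tiny_dataset, table, 10, seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.chosen_index, sb.chosen_index)

    def test_empty_dataset_rejected(self):
        ds = MaterialDataset(samples=[], feature_names=[])
        with pytest.raises(ValueError):
            generate_subdatasets(ds, None, 5, seed=0)


class TestSelectAndFit:
    def test_single_candidate_is_always_chosen(self, rng):
        X = rng.normal(size=(20, 3))
        y = X @ [1.0, 2.0, 0.5] + rng.normal(0, 0.1, 20)
        model = select_and_fit(X, y, fast_zoo(["ridge"]), inner_folds=4, seed=0)
        assert model.method == "ridge"

    def test_linear_truth_prefers_linear_model_over_tree(self, rng):
        X = rng.uniform(0, 10, size=(30, 2))
        y = 3 * X[:, 0] + 1
        model = select_and_fit(X, y, fast_zoo(["ols", "decision-tree"]), inner_folds=5, seed=0)
        assert model.method == "ols"
        assert model.inner_cv_r2 > 0.99

    def test_too_few_rows_rejected(self, rng):
        X = rng.normal(size=(4, 2))
        with pytest.raises(FoldError):
            select_and_fit(X, rng.normal(size=4), fast_zoo(["ridge"]), inner_folds=5)

    def test_degenerate_target_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(DegenerateTargetError):
            select_and_fit(X, np.full(10, 3.0), fast_zoo(["ridge"]), inner_folds=5)


class TestDoubleCrossValidate:
    def test_every_material_predicted_exactly_once(self):
        ds = _linear_dataset(n=20, noise=0.5)
        table = assemble_feature_matrix(ds, "A")
        sub = generate_subdatasets(ds, table, 1, seed=0)[0]
        est, chosen = double_cross_validate(sub, fast_zoo(["ridge"]), outer_folds=5, seed=0)
        assert est.shape == (20,)
        assert np.isfinite(est).all()
        assert len(chosen) == 5

    def test_deterministic_given_seed(self):
        ds = _linear_dataset(n=15, noise=1.0)
        table = assemble_feature_matrix(ds, "A")
        sub = generate_subdatasets(ds, table, 1, seed=0)[0]
        kw = dict(zoo=fast_zoo(["ridge"]), inner_folds=3, outer_folds=5, seed=11)
        a, _ = double_cross_validate(sub, **kw)
        b, _ = double_cross_validate(sub, **kw)
        np.testing.assert_array_equal(a, b)

    def test_noiseless_linear_data_recovered_out_of_fold(self):
        ds = _linear_dataset(n=38, noise=0.0)
        table = assemble_feature_matrix(ds, "A")
        sub = generate_subdatasets(ds, table, 1, seed=0)[0]
        est, _ = double_cross_validate(sub, fast_zoo(["ridge"]), outer_folds=10, seed=0)
        ss_res = np.sum((est - sub.responses) ** 2)
        ss_tot = np.sum((sub.responses - sub.responses.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.99

    def test_too_few_materials_rejected(self, tiny_dataset):
        table = assemble_feature_matrix(tiny_dataset, "A")
        sub = generate_subdatasets(tiny_dataset, table, 1, seed=0)[0]
        with pytest.raises(FoldError):
            double_cross_validate(sub, fast_zoo(["ridge"]), outer_folds=10, seed=0)


class TestPredictEnsemble:
    def test_cardinality_of_models_and_estimates(self):
        ds = _linear_dataset(n=12, noise=1.0, n_meas=2)
        pred = predict_ensemble(
            ds, "A", fast_zoo(["ridge"]), n_subdatasets=3, inner_folds=3, outer_folds=4, seed=0
        )
        assert pred.n_models_fitted == 3 * 4
        assert pred.matrix.shape == (12, 3)
        assert all(len(v) == 3 for v in pred.estimates.values())

    def test_reproducible_from_root_seed(self):
        ds = _linear_dataset(n=12, noise=1.0, n_meas=3)
        kw = dict(zoo=fast_zoo(["ridge"]), n_subdatasets=2, inner_folds=3, outer_folds=3, seed=5)
        a = predict_ensemble(ds, "A", **kw)
        b = predict_ensemble(ds, "A", **kw)
        np.testing.assert_array_equal(a.matrix, b.matrix)


class TestZoos:
    def test_default_zoo_has_all_13_methods(self):
        assert len(default_zoo().names) == 13

    def test_zoo_subsetting_by_name(self):
        zoo = zoo_from_names(["ridge", "random-forest"])
        assert zoo.names == ["ridge", "random-forest"]
        with pytest.raises(ValueError):
            zoo_from_names(["not-a-method"])

    def test_empty_zoo_rejected(self):
        with pytest.raises(ValueError):
            ModelZoo({})
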