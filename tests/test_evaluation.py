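import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonevar import (
    GaussianSummary,
    IntegrationGrid,
    compute_fallback_sd,
    evaluate_method,
    fit_gaussian_measured,
    fit_gaussian_predicted,
    js_divergence,
    kl_divergence,
    r_squared_of_means,
    rectangle_summary,
)
from bonevar.ensemble import EnsemblePrediction
from bonevar.evaluation import (
    DegenerateDistributionError,
    FallbackUndefinedError,
    gaussian_kl_closed_form,
)

LN2 = np.log(2.0)

gaussians = st.builds(
    GaussianSummary,
    mean=st.floats(-3, 3),
    sd=st.floats(0.1, 10.0),
    n=st.just(10),
)


class TestFitGaussianMeasured:
    def test_three_or_more_measurements_use_sample_sd(self):
        g = fit_gaussian_measured([10, 20, 30])
        assert (g.mean, g.sd, g.sd_substituted) == (20.0, pytest.approx(10.0), False)

    @pytest.mark.parametrize("vals,mean", [([15.0], 15.0), ([7.0, 9.0], 8.0)])
    def test_one_or_two_measurements_substitute_fallback_sd(self, vals, mean):
        g = fit_gaussian_measured(vals, fallback_sd=4.0)
        assert (g.mean, g.sd, g.sd_substituted) == (mean, 4.0, True)

    def test_empty_and_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_measured([])
        with pytest.raises(ValueError):
            fit_gaussian_measured([5.0])  # no fallback given
        with pytest.raises(DegenerateDistributionError):
            fit_gaussian_measured([5.0, 5.0, 5.0])


class TestComputeFallbackSd:
    def test_mean_of_qualifying_sample_sds(self, tiny_dataset):
        # m3 sd=5, m4 sd ~2.582, m5 sd ~7.906; m1, m2 excluded (n<=2)
        expected = np.mean(
            [np.std(s.measurements, ddof=1) for s in tiny_dataset.samples if len(s.measurements) >= 3]
        )
        assert compute_fallback_sd(tiny_dataset) == pytest.approx(expected)

    def test_no_qualifying_material_rejected(self, tiny_dataset):
        tiny_dataset.samples = tiny_dataset.samples[:2]  # only n=1 and n=2 remain
        with pytest.raises(FallbackUndefinedError):
            compute_fallback_sd(tiny_dataset)


class TestFitGaussianPredicted:
    def test_consecutive_integers_closed_form(self):
        g = fit_gaussian_predicted(np.arange(1, 101))
        assert g.mean == pytest.approx(50.5)
        assert g.sd == pytest.approx(np.sqrt(100 * 101 / 12), rel=1e-12)  # ~29.0115

    def test_zero_variance_vector_floored_and_flagged(self):
        g = fit_gaussian_predicted(np.full(100, 42.0))
        assert g.sd_floored and g.sd > 0

    def test_single_estimate_rejected(self):
        with pytest.raises(ValueError):
            fit_gaussian_predicted([1.0])


class TestKlDivergence:
    def test_identical_gaussians_give_zero(self):
        g = GaussianSummary(0.0, 1.0, 5)
        assert kl_divergence(g, g) == pytest.approx(0.0, abs=1e-8)

    def test_unit_mean_shift_equals_half(self):
        assert kl_divergence(GaussianSummary(0, 1, 5), GaussianSummary(1, 1, 5)) == pytest.approx(
            0.5, abs=1e-6
        )

    def test_variance_mismatch_matches_closed_form(self):
        # ln(1/2) + (4+0)/2 - 1/2 = 0.80685...
        val = kl_divergence(GaussianSummary(0, 2, 5), GaussianSummary(0, 1, 5))
        assert val == pytest.approx(np.log(0.5) + 2.0 - 0.5, abs=1e-6)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(p=gaussians, q=gaussians)
    def test_matches_closed_form_gaussian_kl(self, p, q):
        assert kl_divergence(p, q) == pytest.approx(gaussian_kl_closed_form(p, q), abs=1e-6)


class TestJsDivergence:
    def test_identical_distributions_give_zero(self):
        g = GaussianSummary(3.0, 2.0, 5)
        assert js_divergence(g, g) == pytest.approx(0.0, abs=1e-8)

    def test_disjoint_support_approaches_ln2(self):
        val = js_divergence(GaussianSummary(0, 1, 5), GaussianSummary(100, 1, 5))
        assert val == pytest.approx(LN2, abs=1e-4)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(p=gaussians, q=gaussians)
    def test_symmetric_and_bounded(self, p, q):
        ab, ba = js_divergence(p, q), js_divergence(q, p)
        assert abs(ab - ba) < 1e-10
        assert -1e-12 <= ab <= LN2 + 1e-6

    def test_strictly_increasing_in_mean_separation(self):
        vals = [
            js_divergence(GaussianSummary(0, 1, 5), GaussianSummary(d, 1, 5))
            for d in (0, 0.5, 1, 2, 4)
        ]
        assert all(a < b for a, b in zip(vals, vals[1:]))

    def test_stable_under_grid_refinement(self):
        p, q = GaussianSummary(0, 1, 5), GaussianSummary(2, 3, 5)
        coarse = js_divergence(p, q, grid=IntegrationGrid(n_points=20001))
        fine = js_divergence(p, q, grid=IntegrationGrid(n_points=40001))
        assert abs(coarse - fine) < 1e-7

    def test_bits_scale_bounded_by_one(self):
        val = js_divergence(GaussianSummary(0, 1, 5), GaussianSummary(100, 1, 5), base="2")
        assert val == pytest.approx(1.0, abs=1e-3)


class TestRSquaredOfMeans:
    def test_perfect_prediction_gives_one(self):
        assert r_squared_of_means([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_constant_mean_baseline_gives_zero(self):
        assert r_squared_of_means([1, 2, 3], [2, 2, 2]) == pytest.approx(0.0)

    def test_anticorrelated_prediction_goes_negative(self):
        assert r_squared_of_means([0, 10], [10, 0]) == pytest.approx(-3.0)

    def test_invariant_under_common_shift(self, rng):
        m, p = rng.normal(size=20), rng.normal(size=20)
        assert r_squared_of_means(m + 7.5, p + 7.5) == pytest.approx(
            r_squared_of_means(m, p), rel=1e-9
        )

    def test_equal_measured_means_rejected(self):
        with pytest.raises(ValueError):
            r_squared_of_means([3, 3, 3], [1, 2, 3])


def _prediction_for(dataset, rows):
    return EnsemblePrediction(
        material_ids=list(dataset.material_ids),
        matrix=np.asarray(rows, dtype=float),
        chosen_methods=[],
        n_models_fitted=0,
    )


class TestEvaluateMethod:
    def test_aggregate_is_mean_of_per_material_d_js(self, tiny_dataset, rng):
        pred = _prediction_for(tiny_dataset, rng.normal(40, 5, size=(5, 20)))
        ev = evaluate_method(tiny_dataset, pred, combo_label="A")
        assert ev.aggregate_d_js == pytest.approx(np.mean([m.d_js for m in ev.per_material]))
        assert len(ev.per_material) == 5

    def test_constant_predictor_has_nonpositive_r_squared(self, tiny_dataset, rng):
        pred = _prediction_for(tiny_dataset, np.full((5, 20), 45.0) + rng.normal(0, 1e-6, (5, 20)))
        ev = evaluate_method(tiny_dataset, pred, combo_label="A")
        assert ev.r_squared <= 0


class TestRectangleSummary:
    def test_aspect_ratio_tracks_sd_ratio(self, tiny_dataset, rng):
        fallback_rows = rng.normal(40, 5, size=(5, 50))
        pred = _prediction_for(tiny_dataset, fallback_rows)
        rows = rectangle_summary(tiny_dataset, pred)
        for r in rows:
            assert r["aspect_ratio"] == pytest.approx(r["height"] / r["width"])
            assert r["width"] > 0 and r["height"] > 0

    def test_equal_sds_give_square(self, tiny_dataset):
        # predicted vectors drawn so their sample SD matches the measured sd exactly
        rows = []
        fallback = compute_fallback_sd(tiny_dataset)
        for s in tiny_dataset.samples:
            g = fit_gaussian_measured(s.measurements, fallback_sd=fallback)
            base = np.array([-1.0, 1.0] * 25)
            rows.append(g.mean + g.sd * base / base.std(ddof=1))
        pred = _prediction_for(tiny_dataset, rows)
        for r in rectangle_summary(tiny_dataset, pred):
            assert r["aspect_ratio"] == pytest.approx(1.0, rel=1e-9)
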