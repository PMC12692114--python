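"""Band fusion, Shapley attribution and multi-stage screening."""

import numpy as np
import pytest

import nirfuse as nf
from nirfuse import reference_bands as rb
from nirfuse.fusion_shap import BandSet, FusionError
from nirfuse.model import PLSRModel


def _affine_model(coefficients, x_means=None, y_mean=0.0):
    """A hand-built PLSR model carrier for attribution tests."""
    coefficients = np.asarray(coefficients, float)
    p = coefficients.size
    x_means = np.zeros(p) if x_means is None else np.asarray(x_means, float)
    return PLSRModel(x_means=x_means, y_mean=y_mean,
                     weights=np.zeros((p, 1)), x_loadings=np.zeros((p, 1)),
                     y_loadings=np.zeros(1), coefficients=coefficients,
                     n_components=1, wavelength_ids=list(range(p)))


class TestFuseBands:
    def test_published_band_lists_fuse_to_38(self):
        fused = nf.fuse_bands(
            [rb.SSC_BANDS_NM, rb.MC_BANDS_NM, rb.FF_BANDS_NM],
            ["SSC", "MC", "FF"])
        assert len(fused) == 38
        assert len(rb.SSC_BANDS_NM) == 20
        assert len(rb.MC_BANDS_NM) == 9
        assert len(rb.FF_BANDS_NM) == 20

    def test_shared_band_carries_multiple_provenance_tags(self):
        fused = nf.fuse_bands(
            [rb.SSC_BANDS_NM, rb.MC_BANDS_NM, rb.FF_BANDS_NM],
            ["SSC", "MC", "FF"])
        tags = dict(zip(fused.wavelengths, fused.provenance))
        assert tags[1425.75] == ["SSC", "MC", "FF"]
        assert tags[1224.131] == ["FF"]   # the canonicalized entry

    def test_single_list_returned_sorted(self):
        fused = nf.fuse_bands([[1300.0, 1100.0, 1200.0]])
        assert fused.wavelengths == [1100.0, 1200.0, 1300.0]

    def test_disjoint_lists_concatenate(self):
        fused = nf.fuse_bands([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0]],
                              ["a", "b"])
        assert len(fused) == 7
        assert all(len(tags) == 1 for tags in fused.provenance)

    def test_idempotent(self):
        once = nf.fuse_bands([rb.SSC_BANDS_NM, rb.FF_BANDS_NM])
        twice = nf.fuse_bands([once.wavelengths])
        assert twice.wavelengths == once.wavelengths

    def test_empty_list_rejected(self):
        with pytest.raises(FusionError):
            nf.fuse_bands([[1.0], []])


def test_percent_reduction_matches_screening_outcome():
    assert nf.percent_reduction(38, 17) == pytest.approx(55.26, abs=0.005)


class TestValueFunction:
    def test_empty_subset_is_base_value(self, rng):
        m = _affine_model(rng.standard_normal(5), rng.standard_normal(5), 2.0)
        bg = rng.standard_normal(5)
        x = rng.standard_normal(5)
        base = nf.predict(m, bg[None, :])[0]
        assert nf.value_function(m, x, [], bg) == pytest.approx(base)

    def test_full_subset_is_prediction(self, rng):
        m = _affine_model(rng.standard_normal(5), rng.standard_normal(5))
        x, bg = rng.standard_normal(5), rng.standard_normal(5)
        assert nf.value_function(m, x, range(5), bg) == \
            pytest.approx(nf.predict(m, x[None, :])[0])

    def test_singleton_expands_affinely(self, rng):
        m = _affine_model(rng.standard_normal(4), rng.standard_normal(4), 1.5)
        x, bg = rng.standard_normal(4), rng.standard_normal(4)
        base = nf.predict(m, bg[None, :])[0]
        got = nf.value_function(m, x, [2], bg)
        assert got == pytest.approx(base + m.coefficients[2] * (x[2] - bg[2]))

    def test_unknown_index_rejected(self, rng):
        m = _affine_model(rng.standard_normal(3))
        with pytest.raises(FusionError):
            nf.value_function(m, np.zeros(3), [5], np.zeros(3))


class TestShapley:
    def test_one_band_marginal(self, rng):
        m = _affine_model([2.0], [0.5])
        X = rng.standard_normal((4, 1))
        bg = np.array([0.1])
        shap = nf.shap_exact(m, X, bg)
        f1 = np.array([nf.value_function(m, x, [0], bg) for x in X])
        f0 = nf.value_function(m, X[0], [], bg)
        np.testing.assert_allclose(shap.values[:, 0], f1 - f0, atol=1e-12)

    def test_symmetry_for_identical_bands(self, rng):
        m = _affine_model([1.3, 1.3, -0.4])
        col = rng.standard_normal(5)
        X = np.column_stack([col, col, rng.standard_normal(5)])
        shap = nf.shap_exact(m, X, np.zeros(3))
        np.testing.assert_allclose(shap.values[:, 0], shap.values[:, 1],
                                   atol=1e-10)

    def test_dummy_band_gets_zero(self, rng):
        m = _affine_model([0.7, 0.0, -1.1])
        shap = nf.shap_linear(m, rng.standard_normal((6, 3)),
                              rng.standard_normal(3))
        np.testing.assert_allclose(shap.values[:, 1], 0.0, atol=1e-15)

    def test_background_row_has_zero_attribution(self, rng):
        bg = rng.standard_normal(4)
        m = _affine_model(rng.standard_normal(4))
        shap = nf.shap_linear(m, bg[None, :], bg)
        np.testing.assert_allclose(shap.values, 0.0, atol=1e-15)

    @pytest.mark.parametrize("p", [2, 5, 10])
    def test_exact_enumeration_matches_closed_form(self, p, rng):
        m = _affine_model(rng.standard_normal(p), rng.standard_normal(p),
                          float(rng.standard_normal()))
        X = rng.standard_normal((3, p))
        bg = rng.standard_normal(p)
        exact = nf.shap_exact(m, X, bg)
        linear = nf.shap_linear(m, X, bg)
        np.testing.assert_allclose(exact.values, linear.values, atol=1e-8)
        assert exact.base_value == pytest.approx(linear.base_value)

    def test_additivity_per_sample(self, rng):
        for fn in (nf.shap_exact, nf.shap_linear):
            m = _affine_model(rng.standard_normal(6), rng.standard_normal(6))
            X = rng.standard_normal((4, 6))
            bg = rng.standard_normal(6)
            shap = fn(m, X, bg)
            recon = shap.base_value + shap.values.sum(axis=1)
            np.testing.assert_allclose(recon, nf.predict(m, X), atol=1e-8)

    def test_enumeration_guard(self, rng):
        m = _affine_model(rng.standard_normal(21))
        with pytest.raises(FusionError, match="shap_linear"):
            nf.shap_exact(m, rng.standard_normal((1, 21)), np.zeros(21))


class TestBandImportance:
    def test_constant_column(self):
        shap = nf.ShapMatrix(np.full((5, 2), 3.0), 0.0, [0, 1])
        np.testing.assert_allclose(nf.band_importance(shap), [3.0, 3.0])

    def test_alternating_signs_use_absolute_value(self):
        col = np.array([[2.0], [-2.0], [2.0], [-2.0]])
        shap = nf.ShapMatrix(col, 0.0, [0])
        assert nf.band_importance(shap)[0] == pytest.approx(2.0)

    def test_matches_direct_reaggregation(self, rng):
        vals = rng.standard_normal((10, 6))
        shap = nf.ShapMatrix(vals, 0.0, list(range(6)))
        np.testing.assert_allclose(nf.band_importance(shap),
                                   np.abs(vals).mean(axis=0), atol=1e-15)


class TestScreening:
    @staticmethod
    def _setup(seed=1, n_bands=38, planted=(3, 10, 20, 30, 36)):
        X, y, planted = nf.planted_band_data(n_bands=n_bands, planted=planted,
                                             seed=seed)
        split = nf.kennard_stone(X, 80)
        initial = BandSet([1000.0 + j for j in range(n_bands)])
        return X, y, split, initial, planted

    def test_zero_threshold_retains_everything(self):
        X, y, split, initial, _ = self._setup()
        stages = nf.screen_stages(X, y, split, initial, [0.0])
        assert len(stages[1].retained) == len(initial)

    def test_retained_counts_non_increasing_and_nested(self):
        X, y, split, initial, _ = self._setup()
        stages = nf.screen_stages(X, y, split, initial, [0.01, 0.05, 0.2])
        counts = [len(st.retained) for st in stages]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
        for prev, cur in zip(stages, stages[1:]):
            assert set(cur.retained_indices) <= set(prev.retained_indices)

    def test_threshold_between_noise_and_signal_keeps_planted_bands(self):
        X, y, split, initial, planted = self._setup()
        stages = nf.screen_stages(X, y, split, initial, [0.05])
        assert stages[1].retained_indices == sorted(planted)
        drop = stages[0].val_metrics.r2 - stages[1].val_metrics.r2
        assert drop <= 0.05

    def test_overshoot_threshold_marks_degenerate(self):
        X, y, split, initial, _ = self._setup()
        stages = nf.screen_stages(X, y, split, initial, [0.05, 1e6])
        assert stages[2].degenerate and len(stages[2].retained) == 0
        assert not stages[1].degenerate

    def test_non_increasing_thresholds_rejected(self):
        X, y, split, initial, _ = self._setup()
        with pytest.raises(FusionError):
            nf.screen_stages(X, y, split, initial, [0.4, 0.2])

    def test_one_shot_reuses_stage_zero_importances(self):
        X, y, split, initial, _ = self._setup()
        iterative = nf.screen_stages(X, y, split, initial, [0.01, 0.05])
        one_shot = nf.screen_stages(X, y, split, initial, [0.01, 0.05],
                                    one_shot=True)
        imp0 = one_shot[0].importances
        expected = [one_shot[0].retained_indices[j]
                    for j in np.nonzero(imp0 >= 0.05)[0]]
        assert one_shot[2].retained_indices == expected
        assert [len(s.retained) for s in iterative][0] == len(initial)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        M = np.column_stack([x, 2 * x + 1, x])
        C = nf.pearson_matrix(M)
        assert C[0, 1] == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        C = nf.pearson_matrix(np.column_stack([x, -x, x ** 2]))
        assert C[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        z = np.array([2.0, 1.0, 4.0, 3.0])
        C = nf.pearson_matrix(np.column_stack([x, z, x + z]))
        assert C[0, 1] == pytest.approx(0.6)

    def test_constant_column_rejected(self):
        M = np.column_stack([np.arange(5.0), np.ones(5), np.arange(5.0)])
        with pytest.raises(FusionError, match="constant"):
            nf.pearson_matrix(M)

    def test_symmetric_unit_diagonal(self, default_dataset):
        _, traits = default_dataset
        C = nf.pearson_matrix(traits)
        np.testing.assert_allclose(C, C.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(C), 1.0, atol=1e-12)
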