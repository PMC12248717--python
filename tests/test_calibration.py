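import numpy as np
import pytest
from sklearn.decomposition import PCA as SKPCA

from savelight.calibration import (
    CalibrationBundle,
    CameraPatchCapture,
    VariableMatrix,
    apply_correction,
    calibrate,
    calibration_report,
    expand_variables,
    expand_xyz,
    fit_correction_matrix,
    fit_spectral_transform,
    pca_reflectance,
    similarity_index,
    subtract_dark,
)
from savelight.colorimetry import MASTER_GRID, Spectrum
from savelight.reconstruction import reconstruct_spectra
from savelight.synthetic_data import (
    make_camera_model,
    make_reference_chart,
    simulate_capture,
)


class TestSubtractDark:
    def test_zero_offset_is_identity(self):
        rgb = np.array([[10.0, 20.0, 30.0]])
        assert np.array_equal(subtract_dark(rgb, np.zeros(3)), rgb)

    def test_floors_at_zero(self):
        assert subtract_dark(np.array([10.0]), np.array([25.0]))[0] == 0.0

    def test_plain_subtraction(self):
        assert subtract_dark(np.array([100.0]), np.array([20.0]))[0] == 80.0

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError):
            subtract_dark(np.array([10.0]), np.array([-1.0]))


class TestExpandVariables:
    def test_degree_one_columns(self):
        vm = expand_variables(np.array([[0.2, 0.4, 0.6]]), degree=1)
        assert vm.term_labels == ("1", "r", "g", "b")
        assert np.allclose(vm.values, [[1, 0.2, 0.4, 0.6]])

    @pytest.mark.parametrize("degree,expected", [(1, 4), (2, 10), (3, 20)])
    def test_column_counts_match_enumeration(self, degree, expected):
        # brute-force count of trivariate monomials of total degree <= d
        brute = sum(
            1
            for i in range(degree + 1)
            for j in range(degree + 1)
            for k in range(degree + 1)
            if 0 < i + j + k <= degree
        ) + 1
        vm = expand_variables(np.zeros((2, 3)), degree=degree)
        assert len(vm.term_labels) == expected == brute

    def test_zero_row_keeps_constant_only(self):
        vm = expand_variables(np.zeros((1, 3)), degree=3)
        expected = np.zeros(20)
        expected[0] = 1.0
        assert np.array_equal(vm.values[0], expected)

    def test_monomial_values(self):
        vm = expand_variables(np.array([[2.0, 3.0, 5.0]]), degree=2)
        by_label = dict(zip(vm.term_labels, vm.values[0]))
        assert by_label["r*g"] == 6.0
        assert by_label["g*b"] == 15.0
        assert by_label["r^2"] == 4.0

    def test_invalid_degree_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            expand_variables(np.zeros((1, 3)), degree=4)


class TestFitCorrectionMatrix:
    def test_construct_and_recover(self, rng):
        true_c = rng.normal(size=(3, 20))
        V = expand_variables(rng.uniform(0.05, 0.95, (24, 3)), degree=3)
        xyz = V.values @ true_c.T
        fitted = fit_correction_matrix(xyz, V)
        assert np.allclose(fitted.entries, true_c, atol=1e-8)

    def test_consistent_square_subsystem_interpolates(self, rng):
        V = VariableMatrix(rng.normal(size=(4, 4)), ("1", "r", "g", "b"))
        xyz = rng.normal(size=(4, 3))
        fitted = fit_correction_matrix(xyz, V)
        assert np.allclose(apply_correction(fitted, V), xyz, atol=1e-9)

    def test_full_rank_matches_ridge_normal_equations(self, rng):
        # explicit first-kind normal equations with ridge epsilon as the
        # independent oracle on a full-rank 24x20 instance
        labels = expand_variables(np.zeros((1, 3)), degree=3).term_labels
        A = rng.normal(size=(24, 20))
        xyz = rng.normal(size=(24, 3))
        fitted = fit_correction_matrix(xyz, VariableMatrix(A, labels))
        eps = 1e-10
        ridge = np.linalg.solve(A.T @ A + eps * np.eye(20), A.T @ xyz).T
        assert np.allclose(fitted.entries, ridge, atol=1e-8)

    def test_rank_deficient_matches_minimum_norm_oracle(self, rng):
        # duplicated patches -> rank-deficient V.  The minimum-norm solution
        # of the duplicated system equals that of the deduplicated system
        # with averaged targets, computed here through the explicit
        # second-kind normal equations x = A' (A A' + eps I)^-1 y, which are
        # well conditioned because the deduplicated A has full row rank.
        labels = expand_variables(np.zeros((1, 3)), degree=3).term_labels
        base = rng.normal(size=(6, 20))
        V = VariableMatrix(np.vstack([base, base]), labels)
        xyz = rng.normal(size=(12, 3))
        fitted = fit_correction_matrix(xyz, V)
        ybar = 0.5 * (xyz[:6] + xyz[6:])
        eps = 1e-10
        oracle = base.T @ np.linalg.solve(base @ base.T + eps * np.eye(6), ybar)
        assert np.allclose(fitted.entries, oracle.T, atol=1e-8)
        # the fit ignores the null space: rows lie in the row space of V
        _, _, Vt = np.linalg.svd(base)
        null_basis = Vt[6:]
        assert np.max(np.abs(fitted.entries @ null_basis.T)) < 1e-10

    def test_all_zero_rejected(self):
        V = VariableMatrix(np.zeros((4, 4)), ("1", "r", "g", "b"))
        with pytest.raises(ValueError):
            fit_correction_matrix(np.zeros((4, 3)), V)


class TestApplyCorrection:
    def test_selector_returns_channels(self, rng):
        rgb = rng.uniform(0, 1, (5, 3))
        V = expand_variables(rgb, degree=3)
        C = np.zeros((3, 20))
        for row, label in zip(range(3), ("r", "g", "b")):
            C[row, V.term_labels.index(label)] = 1.0
        from savelight.calibration import CorrectionMatrix

        out = apply_correction(CorrectionMatrix(C, V.term_labels), V)
        assert np.allclose(out, rgb)

    def test_label_mismatch_names_offender(self, rng):
        from savelight.calibration import CorrectionMatrix

        V = expand_variables(rng.uniform(0, 1, (5, 3)), degree=1)
        wrong = list(V.term_labels)
        wrong[2] = "h"
        C = CorrectionMatrix(np.zeros((3, 4)), tuple(wrong))
        with pytest.raises(ValueError, match="'h' != 'g'"):
            apply_correction(C, V)

    def test_label_count_mismatch_rejected(self, rng):
        from savelight.calibration import CorrectionMatrix

        V2 = expand_variables(rng.uniform(0, 1, (5, 3)), degree=2)
        C3 = CorrectionMatrix(
            np.zeros((3, 20)), expand_variables(np.zeros((1, 3)), 3).term_labels
        )
        with pytest.raises(ValueError, match="mismatch"):
            apply_correction(C3, V2)


class TestPCAReflectance:
    def test_full_basis_reconstructs(self, chart):
        basis, scores = pca_reflectance(chart.spectra)
        recon = basis.synthesize(scores)
        assert np.max(np.abs(recon - chart.spectra_matrix())) < 1e-10

    def test_two_dimensional_family_fully_explained(self, rng):
        grid = MASTER_GRID
        b1 = np.sin(np.linspace(0, np.pi, grid.n_samples))
        b2 = np.linspace(0, 1, grid.n_samples)
        coeffs = rng.uniform(0, 0.5, (10, 2))
        specs = [Spectrum(grid, 0.2 + c1 * b1 + c2 * b2) for c1, c2 in coeffs]
        basis, _ = pca_reflectance(specs, n_components=2)
        assert basis.explained_variance_fraction.sum() == pytest.approx(1.0, abs=1e-9)

    def test_variance_fractions_non_increasing(self, chart):
        basis, _ = pca_reflectance(chart.spectra, n_components=6)
        evf = basis.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-15)

    def test_components_orthonormal(self, chart):
        basis, _ = pca_reflectance(chart.spectra, n_components=6)
        gram = basis.components @ basis.components.T
        assert np.allclose(gram, np.eye(6), atol=1e-8)

    def test_sign_convention(self, chart):
        basis, _ = pca_reflectance(chart.spectra, n_components=6)
        for comp in basis.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_matches_sklearn_oracle(self, rng):
        data = rng.uniform(0, 1, (15, 40))
        basis, scores = pca_reflectance(data, n_components=4)
        sk = SKPCA(n_components=4).fit(data)
        # compare subspaces (sign conventions differ): |cos| of matched axes
        cos = np.abs(np.sum(basis.components * sk.components_, axis=1))
        assert np.allclose(cos, 1.0, atol=1e-8)
        assert np.allclose(
            basis.explained_variance_fraction, sk.explained_variance_ratio_, atol=1e-10
        )

    def test_too_few_spectra_rejected(self, chart):
        with pytest.raises(ValueError):
            pca_reflectance(chart.spectra[:1])


class TestSpectralTransform:
    def test_zero_scores_give_zero_transform(self, rng):
        v = expand_xyz(rng.uniform(0, 100, (10, 3)))
        M = fit_spectral_transform(np.zeros((10, 6)), v)
        assert np.allclose(M.entries, 0.0)

    def test_duplicated_rows_same_fit(self, rng):
        xyz = rng.uniform(0, 100, (24, 3))
        scores = rng.normal(size=(24, 6))
        v1 = expand_xyz(xyz)
        v2 = expand_xyz(np.vstack([xyz, xyz]))
        m1 = fit_spectral_transform(scores, v1)
        m2 = fit_spectral_transform(np.vstack([scores, scores]), v2)
        assert np.allclose(m1.entries, m2.entries, atol=1e-8)

    def test_row_mismatch_rejected(self, rng):
        v = expand_xyz(rng.uniform(0, 100, (10, 3)))
        with pytest.raises(ValueError):
            fit_spectral_transform(np.zeros((9, 6)), v)


class TestEndToEndRecovery:
    def test_noiseless_loop_recovers_chart_spectra(self, chart, ideal_bundle,
                                                   ideal_capture):
        V = expand_variables(ideal_capture.linear_rgb(), 3)
        corrected = apply_correction(ideal_bundle.correction, V)
        recon, n_clipped = reconstruct_spectra(corrected, ideal_bundle)
        rmse = np.sqrt(np.mean((recon - chart.spectra_matrix()) ** 2, axis=1))
        assert rmse.max() < 1e-6
        assert n_clipped == 0

    def test_noisy_capture_stays_accurate(self, chart):
        cam = make_camera_model("realistic", noise_sd=0.01, seed=7)
        cap = simulate_capture(chart, cam)
        bundle = calibrate(chart, cap)
        V = expand_variables(cap.linear_rgb(), 3)
        corrected = apply_correction(bundle.correction, V)
        recon, _ = reconstruct_spectra(corrected, bundle)
        rmse = np.sqrt(np.mean((recon - chart.spectra_matrix()) ** 2))
        assert rmse < 0.05


class TestSimilarityIndex:
    def test_identical_sets(self, rng):
        xyz = rng.uniform(0, 100, (5, 3))
        assert similarity_index(xyz, xyz) == 1.0

    def test_hand_built_example(self):
        measured = np.array([[3.0, 0.0, 0.0], [0.0, 4.0, 0.0], [0.0, 0.0, 12.0]])
        predicted = measured + 1.0
        rmse = np.sqrt(np.mean((predicted - measured) ** 2))  # = 1
        rms_ref = np.sqrt(np.mean(measured**2))
        assert similarity_index(predicted, measured) == pytest.approx(1 - rmse / rms_ref)

    def test_total_disagreement_clips_to_zero(self):
        measured = np.array([[1.0, 0.0, 0.0]])
        predicted = np.array([[-5.0, 0.0, 0.0]])
        assert similarity_index(predicted, measured) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            similarity_index(np.empty((0, 3)), np.empty((0, 3)))


class TestCalibrationReport:
    def test_perfect_loop_reports_zero_errors(self, chart, ideal_bundle,
                                              ideal_capture):
        rep = calibration_report(ideal_bundle, chart, ideal_capture)
        assert rep.mean_spectral_rmse < 1e-8
        assert rep.mean_delta_e_post < 1e-8
        assert rep.similarity > 0.999999

    def test_lists_exactly_24_patches(self, chart, ideal_bundle, ideal_capture):
        rep = calibration_report(ideal_bundle, chart, ideal_capture)
        assert len(rep.table) == 24

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5])
    def test_correction_improves_colour(self, chart, seed):
        cam = make_camera_model("realistic", seed=seed)
        cap = simulate_capture(chart, cam)
        bundle = calibrate(chart, cap)
        rep = calibration_report(bundle, chart, cap)
        assert rep.mean_delta_e_post < rep.mean_delta_e_pre


class TestBundleSerialisation:
    def test_json_round_trip_bit_exact(self, ideal_bundle, tmp_path):
        path = tmp_path / "bundle.json"
        ideal_bundle.to_json(path)
        loaded = CalibrationBundle.from_json(path)
        assert np.array_equal(loaded.correction.entries,
                              ideal_bundle.correction.entries)
        assert np.array_equal(loaded.transform.entries,
                              ideal_bundle.transform.entries)
        assert np.array_equal(loaded.basis.components, ideal_bundle.basis.components)
        assert np.array_equal(loaded.basis.mean_spectrum.values,
                              ideal_bundle.basis.mean_spectrum.values)
        assert loaded.correction.term_labels == ideal_bundle.correction.term_labels
        assert loaded.white == ideal_bundle.white
        assert loaded.grid == ideal_bundle.grid

    def test_rejects_foreign_documents(self, tmp_path):
        path = tmp_path / "other.json"
        path.write_text('{"format": "something-else"}')
        with pytest.raises(ValueError):
            CalibrationBundle.from_json(path)


class TestCaptureValidation:
    def test_out_of_range_rgb_rejected(self):
        with pytest.raises(ValueError):
            CameraPatchCapture(("a",), np.array([[0.0, 0.0, 300.0]]), np.zeros(3))

    def test_mismatched_patch_order_rejected(self, chart, ideal_capture):
        cap = CameraPatchCapture(
            tuple(reversed(ideal_capture.patch_ids)),
            ideal_capture.rgb,
            ideal_capture.dark_offset,
            encoding=ideal_capture.encoding,
        )
        with pytest.raises(ValueError, match="match"):
            calibrate(chart, cap)
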