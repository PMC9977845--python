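"""Spectral decomposition, species counting, fractions and the full chain."""

import numpy as np
import pytest

from dnabind.chemometrics import (
    AnalysisConfig,
    TitrationSeries,
    analyze_titration,
    center_series,
    decompose,
    double_pca,
    estimate_species_count,
    scores_to_fractions,
)
from dnabind.errors import (
    DegenerateAnchorError,
    InsufficientDataError,
    NoBindingSignalError,
    ValidationError,
)
from dnabind.synthetic import (
    SimulationConfig,
    default_free_spectrum,
    simulate_titration,
)
from tests.conftest import KD_GRID, SPARSE_KD


@pytest.fixture()
def noiseless_series():
    series, x_bound = simulate_titration(SimulationConfig(Kd=0.26))
    return series, x_bound


class TestTitrationSeries:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            TitrationSeries(
                wavelengths=np.arange(5.0),
                absorbance=np.zeros((4, 3)),
                ligand_total=10.0,
                dna_ratios=np.array([0.0, 1.0, 2.0]),
            )

    def test_non_increasing_ratios_rejected(self):
        with pytest.raises(ValidationError):
            TitrationSeries(
                wavelengths=np.arange(4.0),
                absorbance=np.zeros((4, 2)),
                ligand_total=10.0,
                dna_ratios=np.array([1.0, 1.0]),
            )

    def test_windowing(self, noiseless_series):
        series, _ = noiseless_series
        sub = series.windowed(400.0, 460.0)
        assert sub.wavelengths.min() >= 400.0
        assert sub.wavelengths.max() <= 460.0
        assert sub.absorbance.shape[0] == sub.wavelengths.size


class TestCentering:
    def test_row_means_vanish_and_reconstruct(self, noiseless_series):
        series, _ = noiseless_series
        centered, mean = center_series(series)
        assert np.all(np.abs(centered.mean(axis=1)) < 1e-12)
        np.testing.assert_allclose(
            centered + mean[:, None], series.absorbance, atol=1e-12
        )

    def test_identical_columns_center_to_zero(self):
        col = np.linspace(0.0, 1.0, 11)
        series = TitrationSeries(
            wavelengths=np.arange(11.0),
            absorbance=np.column_stack([col, col]),
            ligand_total=10.0,
            dna_ratios=np.array([0.0, 1.0]),
        )
        centered, _ = center_series(series)
        assert np.all(centered == 0.0)

    def test_single_column_insufficient(self):
        series = TitrationSeries(
            wavelengths=np.arange(3.0),
            absorbance=np.zeros((3, 1)),
            ligand_total=10.0,
            dna_ratios=np.array([1.0]),
        )
        with pytest.raises(InsufficientDataError):
            center_series(series)


class TestDecompose:
    def test_two_species_closed_system_has_rank_one(self, noiseless_series):
        series, _ = noiseless_series
        centered, _ = center_series(series)
        result = decompose(centered)
        assert result.eigenvalues[1] < 1e-10 * result.eigenvalues[0]

    def test_zero_matrix(self):
        result = decompose(np.zeros((5, 3)))
        assert np.all(result.eigenvalues == 0.0)

    def test_full_reconstruction(self, noiseless_series):
        series, _ = noiseless_series
        centered, mean = center_series(series)
        result = decompose(centered, mean)
        np.testing.assert_allclose(
            result.reconstruct(), series.absorbance,
            atol=1e-10 * np.abs(series.absorbance).max(),
        )

    def test_loadings_orthonormal(self, noiseless_series):
        series, _ = noiseless_series
        centered, _ = center_series(series)
        U = decompose(centered).loadings
        np.testing.assert_allclose(U.T @ U, np.eye(U.shape[1]), atol=1e-10)

    def test_matches_covariance_eigendecomposition(self):
        """Independent oracle: eigenvalues of X X^T on a small instance."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 6))
        X -= X.mean(axis=1, keepdims=True)
        expected = np.sort(np.linalg.eigvalsh(X @ X.T))[::-1][:6]
        np.testing.assert_allclose(
            decompose(X).eigenvalues, np.clip(expected, 0.0, None), atol=1e-8
        )

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 5))
        a, b = decompose(X), decompose(X.copy())
        np.testing.assert_array_equal(a.loadings, b.loadings)
        for j in range(a.loadings.shape[1]):
            assert a.loadings[np.argmax(np.abs(a.loadings[:, j])), j] > 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            decompose(np.array([[np.nan, 0.0], [0.0, 0.0]]))


class TestDoublePca:
    def test_no_outliers_equals_single_pass(self, noiseless_series):
        series, _ = noiseless_series
        centered, mean = center_series(series)
        result, outliers = double_pca(centered, mean)
        assert outliers == []
        np.testing.assert_array_equal(
            result.scores, decompose(centered, mean).scores
        )

    def test_corrupted_column_flagged(self, noiseless_series):
        series, _ = noiseless_series
        centered, mean = center_series(series)
        rng = np.random.default_rng(0)
        centered = centered + 0.002 * rng.normal(size=centered.shape)
        centered[:, 4] += 0.05 * rng.normal(size=centered.shape[0])
        _, outliers = double_pca(centered, mean)
        assert outliers == [4]


class TestSpeciesCount:
    def test_two_species(self, noiseless_series):
        series, _ = noiseless_series
        centered, _ = center_series(series)
        ev = decompose(centered).eigenvalues
        assert estimate_species_count(ev) == 2

    def test_three_species(self):
        """A third independently varying spectrum raises the count to 3."""
        wl = np.arange(350.0, 551.0)
        bands = [
            np.exp(-0.5 * ((wl - c) / 20.0) ** 2) for c in (400.0, 440.0, 500.0)
        ]
        t = np.linspace(0.0, 1.0, 9)
        fracs = np.column_stack([(1 - t) ** 2, 2 * t * (1 - t), t ** 2])
        X = np.stack(bands, axis=1) @ fracs.T
        X -= X.mean(axis=1, keepdims=True)
        assert estimate_species_count(decompose(X).eigenvalues) == 3

    def test_zero_matrix_single_species(self):
        ev = decompose(np.zeros((4, 3))).eigenvalues
        assert estimate_species_count(ev) == 1


class TestScoresToFractions:
    def test_ratio_zero_anchors_free(self, noiseless_series):
        series, x_bound = noiseless_series
        centered, _ = center_series(series)
        scores = decompose(centered).scores[:, 0]
        fr = scores_to_fractions(scores, series.dna_ratios)
        assert fr.x_bound[0] == 0.0
        assert fr.x_free[0] == 1.0

    def test_closure_exact(self, noiseless_series):
        series, _ = noiseless_series
        centered, _ = center_series(series)
        scores = decompose(centered).scores[:, 0]
        fr = scores_to_fractions(scores, series.dna_ratios)
        np.testing.assert_array_equal(fr.x_free + fr.x_bound, np.ones(9))

    @pytest.mark.parametrize("anchor", ["fit", "saturation"])
    def test_recovers_ground_truth_fractions(self, anchor):
        series, x_bound = simulate_titration(SimulationConfig(Kd=0.26))
        centered, _ = center_series(series)
        scores = decompose(centered).scores[:, 0]
        fr = scores_to_fractions(scores, series.dna_ratios, anchor_mode=anchor)
        tol = 0.02 if anchor == "fit" else 0.05
        np.testing.assert_allclose(fr.x_bound, x_bound, atol=tol)

    def test_monotone_in_ratio_noiseless(self):
        for Kd in (0.034, 0.26, 0.608):
            series, _ = simulate_titration(SimulationConfig(Kd=Kd))
            centered, _ = center_series(series)
            scores = decompose(centered).scores[:, 0]
            fr = scores_to_fractions(scores, series.dna_ratios)
            assert np.all(np.diff(fr.x_bound) >= -1e-9)

    def test_constant_scores_degenerate(self):
        with pytest.raises(DegenerateAnchorError):
            scores_to_fractions(
                np.zeros(5), np.array([0.0, 1.0, 2.0, 3.0, 4.0])
            )


class TestAnalyzeTitration:
    def test_noiseless_recovery_within_five_percent(self):
        series, _ = simulate_titration(SimulationConfig(Kd=0.156))
        result = analyze_titration(series)
        assert result.Kd == pytest.approx(0.156, rel=0.05)
        assert result.n == pytest.approx(1.0, rel=0.05)
        assert result.provenance["n_species"] == 2

    def test_sparse_data_case_flagged(self):
        series, _ = simulate_titration(SimulationConfig(Kd=SPARSE_KD))
        result = analyze_titration(series)
        assert result.estimate_flag

    def test_preclip_fractions_well_posed(self):
        """Pre-clip anchored fractions stay within [-0.05, 1.05] on
        well-posed synthetic data."""
        for Kd in KD_GRID:
            series, _ = simulate_titration(
                SimulationConfig(Kd=Kd, noise_sd=0.005, seed=1)
            )
            result = analyze_titration(series)
            lo, hi = result.provenance["preclip_range"]
            assert -0.05 <= lo and hi <= 1.05

    def test_zero_dna_everywhere_is_no_signal(self):
        wl = np.arange(350.0, 551.0)
        free = default_free_spectrum()(wl)
        series = TitrationSeries(
            wavelengths=wl,
            absorbance=np.column_stack([free] * 5),
            ligand_total=10.0,
            dna_ratios=np.arange(5.0),
        )
        with pytest.raises(NoBindingSignalError):
            analyze_titration(series)

    def test_saturation_anchor_pipeline_runs(self):
        series, _ = simulate_titration(SimulationConfig(Kd=0.26))
        result = analyze_titration(
            series, AnalysisConfig(anchor_mode="saturation")
        )
        # anchor bias is bounded for a strong binder at ratio 7
        assert result.Kd == pytest.approx(0.26, rel=0.10)
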