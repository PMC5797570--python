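"""Principal factor analysis: extraction, rotation, orientation, scores."""

import numpy as np
import pytest

from soilrisk.compositional import clr_transform, standardised_log_transform
from soilrisk.exceptions import FitError, ValidationError
from soilrisk.factor import (
    PrincipalFactorAnalysis,
    biplot_data,
    correlation_matrix,
    factor_scores,
    label_factors,
    orient_factors,
    principal_factor_analysis,
    select_n_factors,
    varimax_criterion,
    varimax_rotate,
)
from soilrisk.tables import TransformedTable


def _ttable(values, transform="log"):
    values = np.asarray(values, dtype=float)
    return TransformedTable(
        sample_id=np.arange(values.shape[0]),
        coords=np.zeros((values.shape[0], 2)),
        values=values,
        elements=[f"e{i}" for i in range(values.shape[1])],
        transform=transform,
    )


def _two_block_data(n=5000, seed=0):
    """Two disjoint correlated triplets driven by independent latents."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal((n, 2))
    loadings = np.zeros((6, 2))
    loadings[:3, 0] = [0.9, 0.8, 0.7]
    loadings[3:, 1] = [0.85, 0.8, 0.75]
    noise = rng.standard_normal((n, 6)) * np.sqrt(
        1 - np.sum(loadings**2, axis=1)
    )
    return f, loadings, f @ loadings.T + noise


class TestCorrelationMatrix:
    def test_identical_and_negated_columns(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal(50)
        r = correlation_matrix(_ttable(np.column_stack([a, a, -a])))
        assert r[0, 1] == pytest.approx(1.0)
        assert r[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(r), 1.0)

    def test_clr_matrix_is_singular(self, random_soil_table):
        r = correlation_matrix(clr_transform(random_soil_table))
        assert np.linalg.eigvalsh(r)[0] < 1e-8


class TestSelectNFactors:
    @pytest.mark.parametrize(
        "fractions, threshold, expected",
        [
            ((0.5, 0.2, 0.1, 0.1, 0.05, 0.05), 0.75, 3),
            ((0.8, 0.2), 0.75, 1),
        ],
    )
    def test_threshold_rule(self, fractions, threshold, expected):
        assert select_n_factors(fractions, threshold) == expected

    def test_unreachable_threshold_errors(self):
        with pytest.raises(FitError):
            select_n_factors((0.4, 0.3), 0.75)


class TestPrincipalFactorAnalysis:
    def test_identity_correlation_gives_zero_loadings(self):
        loadings, h2, _, _, _ = principal_factor_analysis(np.eye(4), 1)
        assert np.allclose(loadings, 0.0)
        assert np.allclose(h2, 0.0)

    def test_recovers_rank_one_structure(self):
        ell = np.array([0.9, 0.8, 0.7])
        corr = np.outer(ell, ell)
        np.fill_diagonal(corr, 1.0)
        loadings, _, _, _, heywood = principal_factor_analysis(corr, 1)
        sign = np.sign(loadings[0, 0])
        assert np.allclose(sign * loadings.ravel(), ell, atol=1e-3)
        assert not heywood

    def test_two_block_structure_separates(self):
        _, _, y = _two_block_data()
        corr = correlation_matrix(_ttable(y))
        loadings, *_ = principal_factor_analysis(corr, 2)
        rotated, _ = varimax_rotate(loadings)
        oriented, _ = orient_factors(rotated)
        # each factor loads > 0.4 on exactly one block
        strong = np.abs(oriented) > 0.4
        blocks = [set(np.where(strong[:, j])[0]) for j in range(2)]
        assert {frozenset(b) for b in blocks} == {
            frozenset({0, 1, 2}), frozenset({3, 4, 5})
        }

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            principal_factor_analysis(np.eye(3), 3)
        bad = np.eye(3)
        bad[0, 0] = 2.0
        with pytest.raises(ValidationError):
            principal_factor_analysis(bad, 1)


class TestVarimax:
    def test_simple_structure_is_fixed_point(self):
        loadings = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.7], [0.0, 0.6]])
        rotated, rot = varimax_rotate(loadings)
        assert varimax_criterion(rotated) >= varimax_criterion(loadings) - 1e-10
        # unchanged up to column sign/permutation
        match = np.abs(rotated.T @ loadings)
        assert np.allclose(np.sort(match.max(axis=0)),
                           np.sort((loadings**2).sum(axis=0)), atol=1e-6)

    def test_k1_identity(self):
        loadings = np.array([[0.5], [0.4]])
        rotated, rot = varimax_rotate(loadings)
        assert np.allclose(rot, [[1.0]])
        assert np.allclose(rotated, loadings)

    def test_rotation_is_orthonormal_and_preserves_communality(self):
        rng = np.random.default_rng(3)
        loadings = rng.uniform(-1, 1, size=(8, 3)) * 0.7
        rotated, rot = varimax_rotate(loadings)
        assert np.linalg.norm(rot.T @ rot - np.eye(3)) < 1e-8
        assert np.allclose((rotated**2).sum(axis=1),
                           (loadings**2).sum(axis=1), atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_single_angle(self, seed):
        loadings = np.random.default_rng(seed).uniform(-0.8, 0.8, size=(6, 2))
        rotated, _ = varimax_rotate(loadings)
        w = np.sqrt((loadings**2).sum(axis=1))
        w[w < 1e-12] = 1.0
        normed = loadings / w[:, None]
        best = -np.inf
        for theta in np.arange(0, np.pi / 2, 1e-4):
            c, s = np.cos(theta), np.sin(theta)
            cand = (normed @ np.array([[c, -s], [s, c]])) * w[:, None]
            best = max(best, varimax_criterion(cand))
        assert varimax_criterion(rotated) >= best - 1e-6


class TestOrientation:
    @pytest.mark.parametrize(
        "col, flipped",
        [([-0.9, 0.2], True), ([0.9, -0.2], False)],
    )
    def test_dominant_negative_flips(self, col, flipped):
        loadings = np.array(col)[:, None]
        oriented, signs = orient_factors(loadings)
        assert (signs[0] == -1.0) == flipped
        assert oriented[np.argmax(np.abs(oriented[:, 0])), 0] > 0

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        loadings = rng.uniform(-1, 1, size=(6, 3))
        once, _ = orient_factors(loadings)
        twice, signs = orient_factors(once)
        assert np.allclose(once, twice)
        assert np.all(signs == 1.0)


class TestLabels:
    def test_threshold_rule(self):
        loadings = np.array([[0.68], [0.55], [-0.45], [0.1]])
        labels = label_factors(loadings, ["Pb", "Zn", "Ni", "Cu"])
        assert labels == ["Pb, Zn, -Ni"]

    def test_empty_and_zero_threshold(self):
        loadings = np.array([[0.3], [-0.2]])
        assert label_factors(loadings, ["a", "b"]) == [""]
        assert label_factors(loadings, ["a", "b"], threshold=0.0) == ["a, -b"]


class TestScores:
    def test_centred_row_of_zeros_scores_zero(self):
        a = np.array([1.0, -0.5, 2.0, 0.3, -1.2, 0.7])
        values = np.vstack([a, -a, np.zeros(6)])  # columns have mean zero
        table = _ttable(values)
        results = PrincipalFactorAnalysis(table, n_factors=1).fit()
        scores = factor_scores(table, results)
        assert np.allclose(scores.scores[2], 0.0, atol=1e-10)

    def test_score_means_are_zero(self):
        _, _, y = _two_block_data(n=800, seed=5)
        table = _ttable(y)
        results = PrincipalFactorAnalysis(table, n_factors=2).fit()
        scores = results.scores(table)
        assert np.max(np.abs(scores.scores.mean(axis=0))) < 1e-6

    def test_scores_track_planted_latents(self):
        f, _, y = _two_block_data(n=5000, seed=6)
        table = _ttable(y)
        results = PrincipalFactorAnalysis(table, n_factors=2).fit()
        scores = results.scores(table).scores
        # match each factor to its best-correlated latent
        corr = np.abs(np.corrcoef(scores.T, f.T)[:2, 2:])
        assert np.max(corr[:, 0]) > 0.9
        assert np.max(corr[:, 1]) > 0.9

    def test_element_mismatch_errors(self):
        _, _, y = _two_block_data(n=200, seed=7)
        table = _ttable(y)
        results = PrincipalFactorAnalysis(table, n_factors=1).fit()
        other = _ttable(y[:, ::-1])
        other.elements = [f"x{i}" for i in range(6)]
        with pytest.raises(ValidationError):
            factor_scores(other, results)

    def test_clr_singular_path_runs_end_to_end(self, random_soil_table):
        table = clr_transform(random_soil_table)
        results = PrincipalFactorAnalysis(table, n_factors=2).fit()
        scores = results.scores(table)
        assert scores.scores.shape == (random_soil_table.n_samples, 2)
        assert np.all(np.isfinite(scores.scores))


class TestBiplot:
    def test_schema_row_count(self, random_soil_table):
        table = standardised_log_transform(random_soil_table)
        df = biplot_data(table)
        assert len(df) == table.n_samples + len(table.elements)
        assert set(df["kind"]) == {"score", "loading"}

    def test_rank_one_data_concentrates_on_pc1(self):
        rng = np.random.default_rng(8)
        f = rng.standard_normal(300)
        y = np.outer(f, [1.0, 0.8, -0.6]) + 1e-6 * rng.standard_normal((300, 3))
        df = biplot_data(_ttable(y))
        assert df["explained_PC1"].iloc[0] > 0.999

    def test_isotropic_data_shares_balance(self):
        rng = np.random.default_rng(9)
        df = biplot_data(_ttable(rng.standard_normal((4000, 4))))
        assert abs(df["explained_PC1"].iloc[0] - df["explained_PC2"].iloc[0]) < 0.05


class TestModelClass:
    def test_automatic_factor_count_and_summary(self):
        _, _, y = _two_block_data(n=3000, seed=10)
        table = _ttable(y)
        fa = PrincipalFactorAnalysis(table, variance_threshold=0.5)
        results = fa.fit()
        assert results.n_factors == 2
        assert 0 <= results.communalities.max() <= 1 + 1e-8
        # rotation orthonormal; squared-loading row sums equal communalities
        assert np.linalg.norm(
            results.rotation.T @ results.rotation - np.eye(2)) < 1e-8
        assert np.allclose((results.loadings**2).sum(axis=1),
                           results.communalities, atol=1e-6)
        assert np.all(np.diff(results.cumulative_explained) >= -1e-12)
        text = results.summary()
        assert "F1" in text and "explained variance" in text
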