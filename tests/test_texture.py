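import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptocad.errors import DegenerateInputError, ParameterError
from cryptocad.texture import GLCM, compute_glcm, glcm_stats


def brute_force_stats(P: np.ndarray) -> dict:
    """Independent oracle: explicit double loop over all (i, j)."""
    L = P.shape[0]
    mu_i = sum(i * P[i, j] for i in range(L) for j in range(L))
    mu_j = sum(j * P[i, j] for i in range(L) for j in range(L))
    var_i = sum((i - mu_i) ** 2 * P[i, j] for i in range(L) for j in range(L))
    var_j = sum((j - mu_j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    return {
        "contrast": sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L)),
        "correlation": sum(
            (i - mu_i) * (j - mu_j) * P[i, j] for i in range(L) for j in range(L)
        )
        / np.sqrt(var_i * var_j),
        "energy": sum(P[i, j] ** 2 for i in range(L) for j in range(L)),
        "homogeneity": sum(
            P[i, j] / (1 + abs(i - j)) for i in range(L) for j in range(L)
        ),
    }


def random_glcm(rng, L=8) -> GLCM:
    """A normalized random co-occurrence matrix with nondegenerate marginals."""
    while True:
        P = rng.random((L, L)) ** 3
        P /= P.sum()
        i = np.arange(L)
        if (P.sum(axis=1) * i).std() > 0 and (P.sum(axis=0) * i).std() > 0:
            return GLCM(P=P, levels=L, offset=(0, 1))


class TestComputeGlcm:
    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_glcm(np.full((2, 2), 0.5), levels=8)

    def test_two_row_image_hand_enumeration(self):
        img = np.array([[0.1, 0.1], [0.9, 0.9]])
        g = compute_glcm(img, levels=8, offset=(0, 1))
        expected = np.zeros((8, 8))
        expected[0, 0] = expected[7, 7] = 0.5
        assert np.array_equal(g.P, expected)

    def test_normalization_and_pair_weight(self, rng):
        img = rng.random((17, 23))
        for offset in [(0, 1), (1, 0), (1, 1), (-2, 3)]:
            g = compute_glcm(img, levels=8, offset=offset)
            assert g.P.sum() == pytest.approx(1.0, abs=1e-12)
            # reconstruct the raw pair count from the normalization
            n_pairs = (17 - abs(offset[0])) * (23 - abs(offset[1]))
            counts = g.P * n_pairs
            assert np.allclose(counts, np.round(counts), atol=1e-9)

    def test_offset_and_level_validation(self, rng):
        img = rng.random((16, 16))
        with pytest.raises(ParameterError):
            compute_glcm(img, levels=1)
        with pytest.raises(ParameterError):
            compute_glcm(img, offset=(0, 0))
        with pytest.raises(ParameterError):
            compute_glcm(img, offset=(0, 16))

    def test_matches_skimage(self, rng):
        """Cross-check counting against the reference toolbox routine."""
        from skimage.feature import graycomatrix

        q = rng.integers(0, 8, size=(32, 32)).astype(np.float64)
        ours = compute_glcm(q / 7.0, levels=8, offset=(0, 1))
        ref = graycomatrix(q.astype(np.uint8), [1], [0], levels=8, normed=True)
        assert np.allclose(ours.P, ref[:, :, 0, 0], atol=1e-12)


class TestGlcmStats:
    def test_pure_diagonal(self):
        P = np.zeros((8, 8))
        P[0, 0] = P[7, 7] = 0.5
        s = glcm_stats(GLCM(P=P, levels=8, offset=(0, 1)))
        assert s.contrast == 0.0
        assert s.homogeneity == pytest.approx(1.0, abs=1e-15)
        assert s.energy == pytest.approx(0.5, abs=1e-15)
        assert s.correlation == pytest.approx(1.0, abs=1e-12)

    def test_uniform_matrix_closed_forms(self):
        L = 8
        P = np.full((L, L), 1.0 / L**2)
        s = glcm_stats(GLCM(P=P, levels=L, offset=(0, 1)))
        expected_contrast = sum(
            (i - j) ** 2 for i in range(L) for j in range(L)
        ) / L**2
        assert s.energy == pytest.approx(1.0 / L**2, abs=1e-15)
        assert s.contrast == pytest.approx(expected_contrast, abs=1e-12)
        assert s.correlation == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            g = random_glcm(rng)
            s = glcm_stats(g)
            ref = brute_force_stats(g.P)
            assert s.contrast == pytest.approx(ref["contrast"], abs=1e-12)
            assert s.correlation == pytest.approx(ref["correlation"], abs=1e-12)
            assert s.energy == pytest.approx(ref["energy"], abs=1e-12)
            assert s.homogeneity == pytest.approx(ref["homogeneity"], abs=1e-12)

    def test_matches_skimage_props(self, rng):
        from skimage.feature import graycomatrix, graycoprops

        q = rng.integers(0, 8, size=(32, 32)).astype(np.uint8)
        ref = graycomatrix(q, [1], [0], levels=8, normed=True)
        s = glcm_stats(compute_glcm(q.astype(float) / 7.0, levels=8, offset=(0, 1)))
        assert s.contrast == pytest.approx(graycoprops(ref, "contrast")[0, 0], abs=1e-10)
        assert s.correlation == pytest.approx(graycoprops(ref, "correlation")[0, 0], abs=1e-10)
        assert s.energy == pytest.approx(graycoprops(ref, "ASM")[0, 0], abs=1e-10)
        # homogeneity is not compared: the library uses the squared-difference
        # variant 1/(1+(i-j)^2); ours is the classic 1/(1+|i-j|) form

    def test_energy_bound_and_single_cell_equality(self, rng):
        g = random_glcm(rng)
        assert glcm_stats(g).energy < 1.0
        P = np.zeros((8, 8))
        P[2, 5] = 1.0
        # single-cell GLCM has energy exactly 1 (correlation degenerate)
        assert float(np.sum(P**2)) == 1.0

    def test_contrast_transpose_invariant(self, rng):
        g = random_glcm(rng)
        gt = GLCM(P=g.P.T.copy(), levels=g.levels, offset=g.offset)
        assert glcm_stats(g).contrast == pytest.approx(glcm_stats(gt).contrast, abs=1e-12)

    def test_correlation_invariant_under_index_reversal(self, rng):
        g = random_glcm(rng)
        rev = GLCM(P=g.P[::-1, ::-1].copy(), levels=g.levels, offset=g.offset)
        assert glcm_stats(g).correlation == pytest.approx(
            glcm_stats(rev).correlation, abs=1e-12
        )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_ranges(self, seed):
        g = random_glcm(np.random.default_rng(seed))
        s = glcm_stats(g)
        assert s.contrast >= 0
        assert -1 <= s.correlation <= 1
        assert 0 < s.energy <= 1
        assert 0 < s.homogeneity <= 1
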