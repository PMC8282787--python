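"""GPA, object-symmetry decomposition, species averaging and tangent PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from columnmorph import average_by_species, gpa, symmetric_component, tangent_pca
from columnmorph.column_data import LandmarkPairing
from columnmorph.errors import DegenerateShapeError, DimensionError
from columnmorph.procrustes import AlignedShapes, mirror_relabel, optimal_rotation
from columnmorph.synthetic import build_template

from conftest import random_rotation


def _labels(n, species=None):
    import pandas as pd

    species = species or [f"sp{i}" for i in range(n)]
    return pd.DataFrame(
        {
            "specimen_id": [f"v{i}" for i in range(n)],
            "species": species,
            "region": ["cervical"] * n,
            "position": [3] * n,
        }
    )


class TestGPA:
    def test_rotated_translated_copy_has_zero_distance(self, rng):
        tri = rng.standard_normal((5, 3))
        R = random_rotation(rng)
        pair = [tri, tri @ R.T + np.array([3.0, -1.0, 2.0])]
        aligned = gpa(pair)
        d = np.linalg.norm(aligned.coords[0] - aligned.coords[1])
        assert d < 1e-9

    def test_invariance_under_similarity_transform_of_inputs(self, rng):
        """Similarity-transforming the inputs changes the aligned set only by
        a common rotation (orientation of shape space is arbitrary)."""
        shapes = rng.standard_normal((6, 10, 3))
        base = gpa(shapes)
        moved = shapes.copy()
        for i in range(6):
            moved[i] = 1.7 * shapes[i] @ random_rotation(rng).T + rng.uniform(-4, 4, 3)
        again = gpa(moved)
        R = optimal_rotation(
            again.coords.reshape(-1, 3), base.coords.reshape(-1, 3)
        )
        np.testing.assert_allclose(again.coords @ R, base.coords, atol=1e-7)

    def test_two_shape_size_difference_closed_form(self, rng):
        """With scaling off, shapes differing only in scale end at distance
        |s - 1| * size(X) after centring (rotation is identity)."""
        X = rng.standard_normal((8, 3))
        X -= X.mean(axis=0)
        s = 1.37
        aligned = gpa([X, s * X], scale=False)
        d = np.linalg.norm(aligned.coords[0] - aligned.coords[1])
        # distance to the consensus is half of the inter-shape distance
        expected = abs(s - 1) * np.linalg.norm(X)
        assert d == pytest.approx(expected, rel=1e-8)

    def test_rotation_is_optimal_against_grid_search(self, rng):
        """RMS residual of a planar two-shape fit beats every tested rotation
        angle about the normal axis."""
        a = rng.standard_normal((3, 2))
        A = np.column_stack([a, np.zeros(3)])
        B = np.column_stack([rng.standard_normal((3, 2)), np.zeros(3)])
        aligned = gpa([A, B], scale=True)
        rss = ((aligned.coords[0] - aligned.coords[1]) ** 2).sum()

        def unit(X):
            X = X - X.mean(axis=0)
            return X / np.linalg.norm(X)

        A0, B0 = unit(A), unit(B)
        for theta in np.linspace(0, 2 * np.pi, 720):
            c, s = np.cos(theta), np.sin(theta)
            R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
            grid_rss = ((A0 @ R.T - B0) ** 2).sum()
            assert rss <= grid_rss + 1e-9

    def test_residuals_nonincreasing_over_iterations(self, rng):
        shapes = rng.standard_normal((7, 12, 3))
        _, history = gpa(shapes, return_history=True)
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_degenerate_configuration_raises(self):
        flat = np.ones((4, 3))
        with pytest.raises(DegenerateShapeError):
            gpa([flat, np.eye(4, 3)])

    def test_unit_centroid_size_and_centred_output(self, rng):
        aligned = gpa(rng.standard_normal((5, 9, 3)))
        for X in aligned.coords:
            assert np.abs(X.mean(axis=0)).max() < 1e-8
            assert np.linalg.norm(X) == pytest.approx(1.0, abs=1e-8)
        np.testing.assert_allclose(
            aligned.consensus, aligned.coords.mean(axis=0), atol=1e-12
        )

    def test_fewer_than_two_configs_rejected(self, rng):
        with pytest.raises(DimensionError):
            gpa([rng.standard_normal((5, 3))])


class TestOptimalRotation:
    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1))
    def test_recovers_applied_rotation(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((6, 3))
        R_true = random_rotation(rng)
        R = optimal_rotation(A @ R_true.T, A)
        np.testing.assert_allclose((A @ R_true.T) @ R, A, atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


@pytest.fixture(scope="module")
def cervical_template():
    return build_template("cervical")


class TestSymmetricComponent:
    def test_symmetric_shape_is_fixed_point(self, cervical_template, rng):
        template, pairing = cervical_template
        shapes = [template @ random_rotation(rng).T + rng.uniform(-2, 2, 3)
                  for _ in range(4)]
        sym = symmetric_component(shapes, pairing)
        aligned = gpa(shapes)
        for i in range(4):
            d = np.linalg.norm(sym.coords[i] - aligned.coords[i])
            assert d < 1e-8

    def test_idempotence(self, cervical_template, rng):
        template, pairing = cervical_template
        shapes = np.stack([template + 0.02 * rng.standard_normal(template.shape)
                           for _ in range(5)])
        once = symmetric_component(shapes, pairing)
        twice = symmetric_component(once.coords, pairing)
        R = optimal_rotation(
            twice.coords.reshape(-1, 3), once.coords.reshape(-1, 3)
        )
        np.testing.assert_allclose(twice.coords @ R, once.coords, atol=1e-6)

    def test_symmetric_component_lies_in_invariant_subspace(self, cervical_template, rng):
        template, pairing = cervical_template
        shapes = np.stack([template + 0.05 * rng.standard_normal(template.shape)
                           for _ in range(5)])
        sym = symmetric_component(shapes, pairing)
        for X in sym.coords:
            M = mirror_relabel(X[None], pairing)[0]
            # mirroring+relabelling a symmetric shape returns it up to rotation
            R = optimal_rotation(M, X, allow_reflection=True)
            assert np.linalg.norm(M @ R - X) < 1e-8

    def test_single_landmark_asymmetry_averages_with_mirrored_partner(self):
        """Perturbing one paired landmark: its symmetric position is the mean
        of the landmark and the mirror of its partner (hand-computable case,
        checked through the Procrustes distance of the result)."""
        template, pairing = build_template("thoracic")
        left, right = pairing.paired[0]
        bumped = template.copy()
        delta = np.array([0.0, 0.004, 0.002])
        bumped[left] += delta
        expected = template.copy()
        # partner mirror carries half of the (mirror-symmetrised) bump
        expected[left] += delta / 2
        expected[right] += np.array([-1, 1, 1]) * delta / 2
        sym = symmetric_component([bumped, template], pairing)
        ref = gpa([expected, template])
        d_sym = np.linalg.norm(sym.coords[0] - sym.coords[1])
        d_ref = np.linalg.norm(ref.coords[0] - ref.coords[1])
        assert d_sym == pytest.approx(d_ref, rel=1e-3)

    def test_pairing_out_of_range_rejected(self, rng):
        bad = LandmarkPairing(paired=[(0, 99)], midline=[1, 2])
        with pytest.raises(Exception):
            symmetric_component(rng.standard_normal((3, 4, 3)), bad)


class TestAverageBySpecies:
    def test_single_specimen_identity(self, rng):
        aligned = gpa(rng.standard_normal((4, 6, 3)), labels=_labels(4))
        avg = average_by_species(aligned)
        np.testing.assert_allclose(avg.coords, aligned.coords, atol=1e-12)

    def test_two_specimens_average_landmarkwise(self, rng):
        shapes = rng.standard_normal((4, 6, 3))
        aligned = gpa(shapes, labels=_labels(4, species=["A", "A", "B", "B"]))
        avg = average_by_species(aligned)
        assert avg.n == 2
        np.testing.assert_allclose(
            avg.coords[0], aligned.coords[:2].mean(axis=0), atol=1e-12
        )
        np.testing.assert_allclose(
            avg.centroid_size[1], aligned.centroid_size[2:].mean(), atol=1e-12
        )

    def test_species_mean_shrinks_error_like_sqrt_n(self, cervical_template, rng):
        """Triplicate specimens with isotropic noise: the species mean is
        closer to truth, with error shrinking roughly as 1/sqrt(3)."""
        template, pairing = cervical_template
        reps, sigma = 200, 0.01
        ratio = []
        for _ in range(reps):
            specs = template + sigma * rng.standard_normal((3, *template.shape))
            aligned = gpa(
                np.vstack([specs, template[None]]),
                labels=_labels(4, species=["A", "A", "A", "truth"]),
            )
            mean_err = np.linalg.norm(
                aligned.coords[:3].mean(axis=0) - aligned.coords[3]
            )
            spec_err = np.mean(
                [np.linalg.norm(aligned.coords[i] - aligned.coords[3]) for i in range(3)]
            )
            ratio.append(mean_err / spec_err)
        assert np.mean(ratio) == pytest.approx(1 / np.sqrt(3), rel=0.12)


class TestTangentPCA:
    def test_single_direction_variation_concentrates_on_pc1(self, rng):
        base = rng.standard_normal((7, 3))
        shapes = np.stack([base] * 10)
        t = np.linspace(-1, 1, 10)
        shapes[:, 2, 1] = base[2, 1] + 0.2 * t
        aligned = AlignedShapes(shapes, np.ones(10), shapes.mean(0), _labels(10))
        pca = tangent_pca(aligned)
        assert pca.variance_explained[0] > 0.999

    def test_scores_preserve_pairwise_distances(self, rng):
        shapes = rng.standard_normal((8, 5, 3))
        aligned = AlignedShapes(shapes, np.ones(8), shapes.mean(0), _labels(8))
        pca = tangent_pca(aligned)
        flat = shapes.reshape(8, -1)
        for i in range(8):
            for j in range(i + 1, 8):
                d_raw = np.linalg.norm(flat[i] - flat[j])
                d_pc = np.linalg.norm(pca.scores[i] - pca.scores[j])
                assert d_pc == pytest.approx(d_raw, rel=1e-9)

    def test_variance_explained_is_trace_ratio_and_nonincreasing(self, rng):
        shapes = rng.standard_normal((9, 6, 3))
        aligned = AlignedShapes(shapes, np.ones(9), shapes.mean(0), _labels(9))
        pca = tangent_pca(aligned)
        assert pca.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(pca.variance_explained) <= 1e-12)
        # scores are column-centred; reconstruction reproduces the data
        assert np.abs(pca.scores.mean(axis=0)).max() < 1e-9
        np.testing.assert_allclose(pca.reconstruct(pca.scores), shapes, atol=1e-9)
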