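"""Centroid size, pairwise and generalized Procrustes, form space, TPS."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_similarity
from toothmark import (
    LandmarkConfiguration,
    ValidationError,
    centroid_size,
    gpa,
    procrustes_superimpose_pair,
    to_form_space,
    tps_warp,
)
from toothmark.io import dataset_from_arrays
from toothmark.procrustes import TPSWarp


class TestCentroidSize:
    def test_unit_square_analytic(self):
        square = LandmarkConfiguration(
            np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        )
        assert centroid_size(square) == pytest.approx(np.sqrt(2), abs=1e-12)

    @given(scale=st.floats(0.01, 100), seed=st.integers(0, 100))
    def test_homogeneous_degree_one(self, scale, seed):
        coords = np.random.default_rng(seed).normal(size=(17, 3))
        assert centroid_size(scale * coords) == pytest.approx(
            scale * centroid_size(coords), rel=1e-10
        )

    def test_matches_double_loop_formula(self, rng):
        coords = rng.normal(size=(17, 3))
        centroid = coords.mean(axis=0)
        brute = 0.0
        for i in range(17):
            for j in range(3):
                brute += (coords[i, j] - centroid[j]) ** 2
        assert centroid_size(coords) == pytest.approx(np.sqrt(brute), abs=1e-12)

    def test_coincident_landmarks_error(self):
        with pytest.raises(ValidationError, match="coincident"):
            centroid_size(np.ones((4, 2)))


def _rotation2(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


class TestPairwiseProcrustes:
    def test_similarity_transformed_copy_has_zero_distance(self, rng):
        coords = rng.normal(size=(7, 2))
        src = LandmarkConfiguration(coords)
        tgt = LandmarkConfiguration(2.5 * coords @ _rotation2(np.radians(37)) + [3, -1])
        aligned, dist = procrustes_superimpose_pair(src, tgt)
        assert dist < 1e-9
        assert np.allclose(aligned.coords, tgt.coords, atol=1e-9)

    def test_self_alignment_is_identity(self, rng):
        config = LandmarkConfiguration(rng.normal(size=(5, 3)), "pit")
        aligned, dist = procrustes_superimpose_pair(config, config)
        assert dist < 1e-12
        assert np.allclose(aligned.coords, config.coords, atol=1e-9)

    def test_distance_matches_rotation_grid_oracle(self, rng):
        """Brute-force minimization over a 0.01-degree rotation grid."""
        for _ in range(3):
            a = rng.normal(size=(4, 2))
            b = rng.normal(size=(4, 2))
            _, dist = procrustes_superimpose_pair(
                LandmarkConfiguration(a), LandmarkConfiguration(b)
            )
            au = (a - a.mean(0)) / centroid_size(a)
            bu = (b - b.mean(0)) / centroid_size(b)
            thetas = np.radians(np.arange(0, 360, 0.01))
            best = min(
                np.sqrt(np.sum((au @ _rotation2(t) - bu) ** 2)) for t in thetas
            )
            assert dist == pytest.approx(best, abs=1e-4)

    def test_pseudometric_properties(self, rng):
        configs = [LandmarkConfiguration(rng.normal(size=(6, 2))) for _ in range(3)]

        def d(x, y):
            return procrustes_superimpose_pair(x, y)[1]

        d01, d10 = d(configs[0], configs[1]), d(configs[1], configs[0])
        assert d01 == pytest.approx(d10, abs=1e-8)
        assert d(configs[0], configs[2]) <= d01 + d(configs[1], configs[2]) + 1e-10

    def test_shape_mismatch_error(self, rng):
        with pytest.raises(ValidationError, match="mismatch"):
            procrustes_superimpose_pair(
                LandmarkConfiguration(rng.normal(size=(4, 2))),
                LandmarkConfiguration(rng.normal(size=(5, 2))),
            )


class TestGPA:
    def test_similarity_copies_collapse_to_consensus(self, rng):
        base = rng.normal(size=(7, 2))
        coords = np.stack([random_similarity(base, rng) for _ in range(8)])
        result = gpa(dataset_from_arrays(coords, ["x"] * 8, "score"))
        assert np.max(np.abs(result.aligned - result.aligned[0])) < 1e-8
        _, dist = procrustes_superimpose_pair(
            result.consensus_configuration(), LandmarkConfiguration(base)
        )
        assert dist < 1e-8

    def test_single_configuration(self, rng):
        coords = rng.normal(size=(1, 5, 2))
        result = gpa(dataset_from_arrays(coords, ["x"], "score"))
        assert result.iterations == 1
        centered = coords[0] - coords[0].mean(axis=0)
        _, dist = procrustes_superimpose_pair(
            LandmarkConfiguration(result.aligned[0]), LandmarkConfiguration(centered)
        )
        assert dist < 1e-10

    def test_idempotence_fixed_point(self, fixture_datasets):
        _, scores, _ = fixture_datasets
        first = gpa(scores)
        second = gpa(first.to_dataset())
        assert np.max(np.abs(second.aligned - first.aligned)) < 1e-8

    def test_invariance_under_input_similarity_transforms(self, fixture_datasets, rng):
        _, scores, _ = fixture_datasets
        reference = gpa(scores)
        transformed = dataset_from_arrays(
            np.stack([random_similarity(c.coords, rng) for c in scores]),
            list(scores.labels),
            "score",
        )
        result = gpa(transformed)
        assert np.max(np.abs(result.aligned - reference.aligned)) < 1e-8
        assert np.allclose(result.consensus, reference.consensus, atol=1e-8)

    def test_monotone_residual_trace(self, fixture_datasets):
        _, scores, _ = fixture_datasets
        trace = gpa(scores).trace
        assert all(a >= b - 1e-12 for a, b in zip(trace, trace[1:]))

    def test_aligned_structure(self, fixture_datasets):
        pits, _, _ = fixture_datasets
        result = gpa(pits)
        # centred at the origin
        assert np.max(np.abs(result.aligned.mean(axis=1))) < 1e-9
        # consensus is the mean of the aligned configurations
        assert np.allclose(result.consensus, result.aligned.mean(axis=0), atol=1e-12)
        # unit centroid size up to the second-order effect of tangent projection
        cs = [centroid_size(a) for a in result.aligned]
        assert max(abs(c - 1) for c in cs) < 0.1
        assert result.final_change < 1e-10

    def test_covariance_rank_bound(self, fixture_datasets):
        """Rank <= kd - d - d(d-1)/2 - 1: 10 for 7x2, 44 for 17x3."""
        pits, scores, _ = fixture_datasets
        for dataset, bound in ((scores, 10), (pits, 44)):
            flat = gpa(dataset).flattened()
            eigs = np.linalg.eigvalsh(np.cov(flat, rowvar=False))[::-1]
            assert np.sum(eigs > 1e-10 * eigs[0]) == bound


class TestFormSpace:
    def test_ln_e_identity(self, rng):
        """Centroid size e in working units leaves coordinates unchanged."""
        coords = np.e * np.stack([rng.normal(size=(6, 2)) for _ in range(4)])
        ds = dataset_from_arrays(coords, ["x"] * 4, "score")
        result = gpa(ds)
        result.centroid_sizes = np.full(4, np.e)
        form = to_form_space(result)
        assert np.allclose(form.values, result.flattened(), atol=1e-12)

    def test_column_count_and_unit_guard(self, fixture_datasets):
        _, scores, _ = fixture_datasets
        result = gpa(scores)
        form = to_form_space(result, unit_scale=1000.0)
        assert form.n_columns == 14
        small = gpa(scores)
        small.centroid_sizes = small.centroid_sizes * 0 + 0.9
        with pytest.raises(ValidationError, match="rescale"):
            to_form_space(small)


class TestThinPlateSpline:
    def test_identity_warp(self, rng):
        ref = rng.normal(size=(7, 2))
        grid = rng.uniform(-2, 2, size=(40, 2))
        warp = TPSWarp(ref, ref)
        assert np.max(np.abs(warp(grid) - grid)) < 1e-9
        assert warp.bending_energy < 1e-9

    @pytest.mark.parametrize("d", [2, 3])
    def test_maps_landmarks_exactly(self, d, rng):
        ref = rng.normal(size=(8, d))
        tgt = ref + rng.normal(0, 0.3, size=(8, d))
        warp = TPSWarp(ref, tgt)
        assert np.max(np.abs(warp(ref) - tgt)) < 1e-9

    @pytest.mark.parametrize("d", [2, 3])
    def test_affine_target_zero_bending(self, d, rng):
        ref = rng.normal(size=(9, d))
        affine = np.eye(d) + rng.normal(0, 0.2, size=(d, d))  # shear + scale
        tgt = ref @ affine + rng.normal(size=d)
        warp = TPSWarp(ref, tgt)
        assert warp.bending_energy < 1e-9
        # direct evaluation of the quadratic form w^T K w
        direct = abs(
            float(np.trace(warp.weights.T @ warp._kernel @ warp.weights))
        )
        assert direct < 1e-9

    def test_tps_warp_helper(self, rng):
        ref = LandmarkConfiguration(rng.normal(size=(7, 2)))
        tgt = LandmarkConfiguration(ref.coords + rng.normal(0, 0.1, size=(7, 2)))
        out = tps_warp(ref, tgt, ref.coords)
        assert np.allclose(out, tgt.coords, atol=1e-9)
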