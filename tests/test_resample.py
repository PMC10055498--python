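"""Barycentric resampling exactness and the two surface augmentations."""

import numpy as np
import pytest

from mssit.icosphere import build_icosphere
from mssit.resample import (
    AugmentationConfig,
    augment,
    barycentric_resample,
    choose_transform,
    elastic_warp,
    random_rotation,
    sample_coarse_displacements,
    warp_vertices,
    _warp_cache,
)
from mssit.surface_io import SurfaceSignal


@pytest.fixture(scope="module")
def smooth_signal():
    mesh = build_icosphere(4)
    vals = np.stack([mesh.vertices[:, 2], mesh.vertices[:, 0] * mesh.vertices[:, 1]], axis=1)
    return SurfaceSignal(vals, mesh_order=4)


class TestBarycentricResample:
    def test_constant_preserved(self):
        src = build_icosphere(2)
        sig = SurfaceSignal(np.full((src.n_vertices, 3), 2.5), mesh_order=2)
        out = barycentric_resample(sig, src, build_icosphere(4).vertices)
        assert np.abs(out.values - 2.5).max() < 1e-12

    def test_identity_at_source_vertices(self, rng):
        src = build_icosphere(3)
        sig = SurfaceSignal(rng.standard_normal((src.n_vertices, 2)), mesh_order=3)
        out = barycentric_resample(sig, src, src.vertices)
        assert np.abs(out.values - sig.values).max() < 1e-9

    def test_refinement_improves_accuracy(self):
        # resampling f(x,y,z)=z from a finer source must beat a coarser one
        target = build_icosphere(5).vertices
        errs = {}
        for order in (2, 3):
            src = build_icosphere(order)
            sig = SurfaceSignal(src.vertices[:, 2:3], mesh_order=order)
            out = barycentric_resample(sig, src, target)
            errs[order] = np.abs(out.values[:, 0] - target[:, 2]).max()
        assert errs[3] < errs[2]

    def test_output_within_input_range(self, rng):
        src = build_icosphere(3)
        sig = SurfaceSignal(rng.standard_normal((src.n_vertices, 2)), mesh_order=3)
        out = barycentric_resample(sig, src, build_icosphere(4).vertices)
        assert out.values.min() >= sig.values.min() - 1e-12
        assert out.values.max() <= sig.values.max() + 1e-12

    def test_vertex_count_mismatch(self):
        sig = SurfaceSignal(np.ones((42, 1)), mesh_order=1)
        with pytest.raises(ValueError):
            barycentric_resample(sig, build_icosphere(3), build_icosphere(2).vertices)


class TestRotation:
    def test_zero_rotation_is_identity(self, smooth_signal, rng):
        out = random_rotation(smooth_signal, build_icosphere(4), 0.0, rng)
        assert np.array_equal(out.values, smooth_signal.values)

    def test_constant_field_unchanged(self, rng):
        mesh = build_icosphere(3)
        sig = SurfaceSignal(np.full((mesh.n_vertices, 1), 1.5), mesh_order=3)
        out = random_rotation(sig, mesh, 30.0, rng)
        assert np.abs(out.values - 1.5).max() < 1e-12

    def test_rotation_pair_roundtrip_error_bounded(self, smooth_signal):
        # rotating by R then by R^-1 should deviate from the input by no more
        # than twice the one-step interpolation error of the same field
        mesh = build_icosphere(4)
        from scipy.spatial.transform import Rotation

        angles = np.array([17.0, -11.0, 23.0])
        R = Rotation.from_euler("xyz", angles, degrees=True)

        def resample_at(sig, rot):
            pts = rot.inv().apply(np.array(mesh.vertices))
            pts /= np.linalg.norm(pts, axis=1, keepdims=True)
            return barycentric_resample(sig, mesh, pts)

        once = resample_at(smooth_signal, R)
        back = resample_at(once, R.inv())
        roundtrip_err = np.abs(back.values - smooth_signal.values).max()
        # one-step error: interpolate the analytic field at rotated points
        pts = R.inv().apply(np.array(mesh.vertices))
        exact = np.stack([pts[:, 2], pts[:, 0] * pts[:, 1]], axis=1)
        one_step_err = np.abs(once.values - exact).max()
        assert roundtrip_err <= 2 * one_step_err + 1e-12

    def test_label_transform_nearest_corner(self, rng):
        mesh = build_icosphere(3)
        labels = (mesh.vertices[:, 2] > 0).astype(np.int64)
        sig = SurfaceSignal(labels[:, None].astype(float), mesh_order=3)
        out, out_labels = random_rotation(sig, mesh, 20.0, rng, labels=labels)
        assert out_labels.shape == labels.shape
        assert set(np.unique(out_labels)) <= {0, 1}
        # identity transform leaves labels untouched
        _, same = random_rotation(sig, mesh, 0.0, np.random.default_rng(0), labels=labels)
        assert np.array_equal(same, labels)


class TestElasticWarp:
    def test_zero_magnitude_is_identity(self, smooth_signal, rng):
        cfg = AugmentationConfig(warp_max_fraction=0.0)
        out = elastic_warp(smooth_signal, build_icosphere(4), cfg, rng)
        assert np.array_equal(out.values, smooth_signal.values)

    def test_displacement_bound_over_1000_draws(self):
        # every ico2 vertex displacement <= 1/8 of its mean neighbour distance
        rng = np.random.default_rng(11)
        _, nbr_scale, _ = _warp_cache(2, 2)
        bound = nbr_scale / 8.0
        for _ in range(1000):
            d = sample_coarse_displacements(2, 1.0 / 8.0, rng)
            assert (np.linalg.norm(d, axis=1) <= bound + 1e-12).all()

    def test_no_inverted_faces_after_warp(self):
        mesh = build_icosphere(4)
        cfg = AugmentationConfig()
        for seed in range(20):
            warped = warp_vertices(mesh, cfg, np.random.default_rng(seed))
            tri = warped[mesh.faces]
            signed = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
            assert (signed > 0).all()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig(warp_max_fraction=1.0)

    def test_warp_needs_finer_mesh(self, rng):
        sig = SurfaceSignal(np.ones((42, 1)), mesh_order=1)
        with pytest.raises(ValueError):
            elastic_warp(sig, build_icosphere(1), AugmentationConfig(warp_grid_order=2), rng)


class TestAugment:
    def test_zero_probability_is_identity(self, smooth_signal, rng):
        cfg = AugmentationConfig(apply_probability=0.0)
        out = augment(smooth_signal, cfg, rng)
        assert np.array_equal(out.values, smooth_signal.values)

    def test_seeded_determinism(self, smooth_signal):
        cfg = AugmentationConfig()
        a = augment(smooth_signal, cfg, np.random.default_rng(5))
        b = augment(smooth_signal, cfg, np.random.default_rng(5))
        assert np.array_equal(a.values, b.values)

    def test_application_frequencies(self):
        # 80% application, 50/50 rotation-vs-warp split, within 3 binomial SEs
        cfg = AugmentationConfig()
        rng = np.random.default_rng(99)
        n = 10_000
        choices = [choose_transform(cfg, rng) for _ in range(n)]
        applied = sum(c != "none" for c in choices)
        se_apply = np.sqrt(0.8 * 0.2 / n)
        assert abs(applied / n - 0.8) < 3 * se_apply
        rotations = sum(c == "rotate" for c in choices)
        se_split = np.sqrt(0.5 * 0.5 / applied)
        assert abs(rotations / applied - 0.5) < 3 * se_split

    def test_each_branch_transforms(self, smooth_signal):
        # force each branch and confirm the expected behaviour on the signal
        mesh = build_icosphere(4)
        rot_cfg = AugmentationConfig(apply_probability=1.0, rotation_share=1.0)
        out = augment(smooth_signal, rot_cfg, np.random.default_rng(3), mesh=mesh)
        assert not np.array_equal(out.values, smooth_signal.values)
        warp_cfg = AugmentationConfig(apply_probability=1.0, rotation_share=0.0)
        out = augment(smooth_signal, warp_cfg, np.random.default_rng(3), mesh=mesh)
        assert not np.array_equal(out.values, smooth_signal.values)

    def test_labels_follow_signal(self, rng):
        mesh = build_icosphere(3)
        labels = (mesh.vertices[:, 0] > 0).astype(np.int64)
        sig = SurfaceSignal(labels[:, None].astype(float), mesh_order=3)
        cfg = AugmentationConfig(apply_probability=1.0, rotation_share=1.0, max_rotation_deg=15)
        out, out_labels = augment(sig, cfg, np.random.default_rng(8), mesh=mesh, labels=labels)
        # the rotated binary channel and the rotated labels agree wherever the
        # channel is unambiguous (not on the decision boundary)
        confident = (out.values[:, 0] < 0.25) | (out.values[:, 0] > 0.75)
        assert (np.round(out.values[confident, 0]) == out_labels[confident]).all()
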