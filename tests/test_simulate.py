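"""Synthetic scene/pair generator: determinism, ground-truth consistency."""

import numpy as np
import pytest

from penreg.evaluate import evaluate_method
from penreg.losses import diffusion_regularizer
from penreg.simulate import (
    SceneConfig,
    generate_dataset,
    generate_pairs,
    generate_scene,
    generate_smooth_field,
    generate_view_pair,
)
from penreg.warp import sample_field, warp_points_dense


class TestGenerateScene:
    def test_empty_scene_is_floor_texture(self):
        cfg = SceneConfig(n_animals=0, seed=3)
        img, blobs = generate_scene(cfg)
        assert blobs == []
        # floor model: mean ~0.22, std ~0.06 (moment check, 10% band is generous)
        assert abs(img.mean() - 0.22) < 0.022
        assert abs(img.std() - 0.06) < 0.012

    def test_same_seed_identical(self):
        cfg = SceneConfig(seed=11)
        a, _ = generate_scene(cfg)
        b, _ = generate_scene(cfg)
        assert np.array_equal(a, b)

    def test_blob_count_as_connected_components(self):
        from scipy import ndimage

        cfg = SceneConfig(size=(256, 256), n_animals=11, seed=5)
        img, blobs = generate_scene(cfg)
        assert len(blobs) == 11
        lab, n = ndimage.label(img > 0.45)
        sizes = ndimage.sum_labels(np.ones_like(img), lab, index=range(1, n + 1))
        # components of blob size; floor-texture speckle above threshold is tiny
        assert int((sizes >= 30).sum()) == 11


class TestGenerateSmoothField:
    def test_zero_magnitude_zero_field(self):
        field = generate_smooth_field((32, 32), 0.0, seed=1)
        assert np.array_equal(field, np.zeros((32, 32, 2)))

    def test_bound_respected_over_draws(self):
        for seed in range(100):
            field = generate_smooth_field((32, 32), 4.0, seed=seed)
            assert np.abs(field).max() <= 4.0 + 1e-12

    def test_wider_spacing_is_smoother(self):
        vals = [
            diffusion_regularizer(generate_smooth_field((64, 64), 6.0, s, seed=17))
            for s in (8.0, 16.0, 32.0)
        ]
        assert vals[0] > vals[1] > vals[2]


class TestGenerateViewPair:
    def test_zero_magnitudes_bitwise_equal_views(self):
        cfg = SceneConfig(seed=2, illumination_delta=0.0, noise_sigma=0.0)
        pair = generate_view_pair(cfg, homography_magnitude=0, residual_magnitude=0)
        assert np.array_equal(pair.moving_prereg, pair.fixed)
        assert pair.prereg_tre == 0.0

    def test_prereg_tre_in_expected_band(self):
        tres = [
            generate_view_pair(SceneConfig(seed=s), residual_magnitude=6.0).prereg_tre
            for s in range(8)
        ]
        assert 1.0 <= np.mean(tres) <= 6.0

    def test_ground_truth_self_consistency(self):
        """Moving landmarks map back onto fixed landmarks within 0.5 px
        through true homography + residual-field inversion."""
        from penreg.homography import map_points_projective

        for seed in range(50):
            pair = generate_view_pair(SceneConfig(seed=seed))
            prereg_pts = map_points_projective(pair.raw_moving_points, pair.true_homography)
            mapped = warp_points_dense(
                prereg_pts, pair.true_residual_field, tol=1e-4, max_iter=100
            )
            err = np.linalg.norm(mapped - pair.landmarks.fixed_points, axis=1)
            assert err.max() < 0.5

    def test_true_field_oracle_beats_identity_everywhere(self):
        pairs = generate_pairs(5, SceneConfig(), seed=33)

        def oracle(fixed, moving, pts, _pairs=iter(pairs)):
            raise NotImplementedError

        for pair in pairs:
            mapped = warp_points_dense(
                pair.landmarks.moving_points, pair.true_residual_field,
                tol=1e-4, max_iter=100,
            )
            tre_oracle = np.linalg.norm(
                mapped - pair.landmarks.fixed_points, axis=1
            ).mean()
            assert tre_oracle < 1.0
            assert tre_oracle < max(pair.prereg_tre, 1e-9) or pair.prereg_tre == 0

    def test_difficulty_ordering_with_residual_magnitude(self):
        means = []
        for mag in (2.0, 6.0, 12.0):
            tres = [
                generate_view_pair(
                    SceneConfig(seed=s), residual_magnitude=mag, residual_smoothness=24.0
                ).prereg_tre
                for s in range(6)
            ]
            means.append(np.mean(tres))
        assert means[0] < means[1] < means[2]

    def test_landmark_labels_follow_protocol(self, small_pair):
        labels = small_pair.landmarks.labels
        assert labels.count("foreground") == 3
        assert labels.count("background") == 3


class TestGenerateDataset:
    def test_single_test_record(self, tmp_path):
        manifest = generate_dataset(0, 0, 1, tmp_path, seed=9)
        assert len(manifest["splits"]["test"]) == 1
        rec = manifest["splits"]["test"][0]
        assert rec["landmarks"] is not None
        assert (tmp_path / rec["landmarks"]).exists()

    def test_deterministic_manifest_and_files(self, tmp_path):
        import hashlib, json

        def checksum(d):
            m = generate_dataset(3, 2, 2, d, seed=21)
            h = hashlib.sha256(json.dumps(m, sort_keys=True).encode())
            for p in sorted(x.name for x in d.iterdir()):
                h.update((d / p).read_bytes())
            return h.hexdigest()

        a = checksum(tmp_path / "a")
        b = checksum(tmp_path / "b")
        assert a == b

    def test_train_records_carry_no_landmarks(self, tmp_path):
        manifest = generate_dataset(2, 1, 1, tmp_path, seed=4)
        assert all(r["landmarks"] is None for r in manifest["splits"]["train"])
        assert all(r["landmarks"] for r in manifest["splits"]["finetune"])

    def test_roundtrip_via_manifest(self, tmp_path):
        from penreg.io import load_manifest_records

        generate_dataset(1, 1, 1, tmp_path, seed=6)
        recs = load_manifest_records(tmp_path / "manifest.json", "test")
        fixed, moving, lms = recs[0]
        assert fixed.shape == (64, 64) and moving.shape == (64, 64)
        assert len(lms) == 6
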