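"""Warp-texture PCA face space: alignment, warps, PCA, synthesis, stimuli."""

import numpy as np
import pytest

from facespace import faces, space
from facespace.faces import FaceParams
from facespace.space import WarpTextureVector


@pytest.fixture(scope="module")
def one_face():
    return faces.render_face(FaceParams())


CANON = ((35.0, 46.0), (65.0, 46.0))


class TestAlignByEyes:
    def test_identity_when_already_canonical(self, one_face):
        img, lm = one_face
        eyes = (lm["left_eye"], lm["right_eye"])
        aligned, new_lm, tform = space.align_by_eyes(img, lm, eyes)
        assert np.allclose(aligned, img, atol=1e-6)
        assert np.allclose(new_lm.as_array(), lm.as_array(), atol=1e-9)

    def test_translation_recovered(self, one_face):
        img, lm = one_face
        shifted = {n: (x + 5, y - 3) for n, (x, y) in lm.points.items()}
        shifted_lm = faces.LandmarkSet(shifted)
        _, new_lm, tform = space.align_by_eyes(
            img, shifted_lm, (lm["left_eye"], lm["right_eye"])
        )
        assert tform.translation == pytest.approx((-5, 3), abs=1e-9)
        assert np.allclose(new_lm.as_array(), lm.as_array(), atol=1e-9)

    def test_rotation_recovered(self, one_face):
        img, lm = one_face
        theta = np.deg2rad(10)
        mid = np.mean([lm["left_eye"], lm["right_eye"]], axis=0)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        rot = {
            n: tuple(R @ (np.array(p) - mid) + mid) for n, p in lm.points.items()
        }
        _, _, tform = space.align_by_eyes(
            img, faces.LandmarkSet(rot), (lm["left_eye"], lm["right_eye"])
        )
        assert np.rad2deg(tform.rotation) == pytest.approx(-10, abs=0.1)

    def test_coincident_eyes_rejected(self, one_face):
        img, lm = one_face
        lmx = faces.LandmarkSet(dict(lm.points))
        lmx.points["right_eye"] = lmx.points["left_eye"]  # bypass the ctor invariant
        with pytest.raises(ValueError, match="coincident"):
            space.align_by_eyes(img, lmx, CANON)


class TestEstimateWarp:
    def test_identical_landmarks_zero_field(self, one_face):
        _, lm = one_face
        wx, wy = space.estimate_warp(lm, lm, (120, 100))
        assert np.allclose(wx, 0) and np.allclose(wy, 0)

    def test_uniform_displacement_interpolated_everywhere(self, one_face):
        _, lm = one_face
        moved = faces.LandmarkSet({n: (x + 2, y) for n, (x, y) in lm.points.items()})
        wx, wy = space.estimate_warp(moved, lm, (120, 100))
        for x, y in lm.points.values():
            assert wx[int(round(y)), int(round(x))] == pytest.approx(2.0, abs=1e-6)
            assert wy[int(round(y)), int(round(x))] == pytest.approx(0.0, abs=1e-6)

    def test_too_few_landmarks_rejected(self):
        lm = faces.LandmarkSet(
            {
                "left_eye": (30, 40),
                "right_eye": (60, 40),
                "nose_tip": (45, 60),
                "mouth_left": (35, 75),
                "mouth_right": (55, 75),
                "chin": (45, 95),
            }
        )
        small_src = faces.LandmarkSet(dict(lm.points))
        # drop to two names by constructing directly
        with pytest.raises(ValueError, match="at least 3"):
            two = {"left_eye": (30, 40), "right_eye": (60, 40)}

            class Two:
                names = list(two)
                points = two

                def as_array(self, names=None):
                    return np.array([two[n] for n in (names or self.names)])

            space.estimate_warp(Two(), Two(), (10, 10))

    def test_warping_toward_target_reduces_ssd(self):
        src_img, src_lm = faces.render_face(FaceParams())
        tgt_img, tgt_lm = faces.render_face(
            FaceParams(eye_separation=36, nose_length=22, mouth_width=30, head_width=70)
        )
        wx, wy = space.estimate_warp(src_lm, tgt_lm, src_img.shape)
        warped = space.extract_shape_free_texture(src_img, wx, wy)
        before = ((src_img - tgt_img) ** 2).sum()
        after = ((warped - tgt_img) ** 2).sum()
        assert after <= 0.10 * before


class TestShapeFreeTexture:
    def test_zero_warp_is_identity(self, one_face):
        img, _ = one_face
        z = np.zeros_like(img)
        assert np.allclose(space.extract_shape_free_texture(img, z, z), img)

    def test_integer_translation(self, one_face):
        img, _ = one_face
        wx = np.full(img.shape, 3.0)
        wy = np.zeros(img.shape)
        tex = space.extract_shape_free_texture(img, wx, wy)
        assert np.allclose(tex[:, :-3], img[:, 3:], atol=1e-12)

    def test_round_trip_within_interpolation_tolerance(self, one_face):
        img, lm = one_face
        moved = faces.LandmarkSet(
            {n: (x + 0.08 * (x - 50), y + 0.05 * (y - 60)) for n, (x, y) in lm.points.items()}
        )
        wx, wy = space.estimate_warp(moved, lm, img.shape)
        fwd = space.extract_shape_free_texture(img, wx, wy)
        bx, by = space.estimate_warp(lm, moved, img.shape)
        back = space.extract_shape_free_texture(fwd, bx, by)
        interior = (slice(20, 100), slice(15, 85))
        err = np.abs(back[interior] - img[interior]).mean()
        assert err < 0.02  # < 2% of the unit intensity range

    def test_shape_mismatch_rejected(self, one_face):
        img, _ = one_face
        with pytest.raises(ValueError):
            space.extract_shape_free_texture(img, np.zeros((10, 10)), np.zeros((10, 10)))


class TestFaceSpaceModel:
    def test_orthonormal_components(self, small_space):
        _, model = small_space
        gram = model.components @ model.components.T
        assert np.abs(gram - np.eye(model.k)).max() < 1e-8

    def test_loadings_zero_mean_and_sd_matches_brute_force(self, small_space):
        vectors, model = small_space
        X = np.stack([v.to_vector() for v in vectors])
        proj = (X - model.mean) @ model.components.T  # independent projection oracle
        assert np.abs(proj.mean(axis=0)).max() < 1e-8 * np.abs(proj).max()
        assert np.allclose(proj.std(axis=0, ddof=1), model.loading_sd, rtol=1e-10)

    def test_variance_explained_non_increasing(self, small_space):
        _, model = small_space
        assert np.all(np.diff(model.explained_variance) <= 1e-12)

    def test_rank_bound_and_k_validation(self, small_space):
        vectors, model = small_space
        assert model.k <= len(vectors) - 1
        with pytest.raises(ValueError, match="exceeds"):
            space.build_face_space(vectors, k=len(vectors))
        with pytest.raises(ValueError, match="at least 2"):
            space.build_face_space(vectors[:1])

    def test_save_load_round_trip(self, small_space, tmp_path):
        _, model = small_space
        model.save(tmp_path / "model.npz")
        back = space.FaceSpaceModel.load(tmp_path / "model.npz")
        assert np.allclose(back.mean, model.mean)
        assert np.allclose(back.components, model.components)
        assert back.layout == model.layout


class TestProjectSynthesize:
    def test_mean_projects_to_origin(self, small_space):
        _, model = small_space
        assert np.allclose(space.project(model.mean, model), 0.0)

    def test_unit_coordinate_round_trip(self, small_space):
        _, model = small_space
        e1 = np.zeros(model.k)
        e1[0] = 1.0
        assert np.allclose(space.project(space.synthesize(e1, model), model), e1, atol=1e-8)

    def test_training_faces_reconstruct_losslessly(self, small_space):
        vectors, model = small_space
        for v in vectors:
            rec = space.synthesize(space.project(v, model), model)
            num = np.linalg.norm(rec.to_vector() - v.to_vector())
            den = np.linalg.norm(v.to_vector())
            assert num / den < 1e-8

    def test_positive_negative_coordinates_mirror_about_mean(self, small_space):
        _, model = small_space
        c = np.zeros(model.k)
        c[1] = 2.5
        plus = space.synthesize(c, model).to_vector() - model.mean
        minus = space.synthesize(-c, model).to_vector() - model.mean
        assert np.allclose(plus, -minus)

    def test_synthesis_linearity(self, small_space):
        _, model = small_space
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, model.k))
        lhs = space.synthesize(a + b, model).to_vector()
        rhs = (
            space.synthesize(a, model).to_vector()
            + space.synthesize(b, model).to_vector()
            - model.mean
        )
        assert np.allclose(lhs, rhs, atol=1e-8)

    def test_caricature_distance_exactly_linear_in_sd(self, small_space):
        _, model = small_space
        for i in (0, 2):
            for s in (0.5, 1.0, 3.0, 6.0):
                c = np.zeros(model.k)
                c[i] = s
                d = np.linalg.norm(space.synthesize(c, model).to_vector() - model.mean)
                assert d == pytest.approx(s * model.loading_sd[i], rel=1e-10)

    def test_dimension_mismatch_rejected(self, small_space):
        _, model = small_space
        with pytest.raises(ValueError):
            space.project(np.zeros(17), model)
        with pytest.raises(ValueError):
            space.synthesize(np.zeros(model.k + 1), model)


class TestGenerativeDimensionRecovery:
    def test_three_generative_axes_dominate_variance(self):
        # vary exactly three independent parameters; the space should put
        # >= 90% of its variance in the first three components
        rng = np.random.default_rng(8)
        imgs, lsets = [], []
        for _ in range(30):
            p = FaceParams(
                eye_separation=30 + rng.normal(0, 2.5),
                nose_length=18 + rng.normal(0, 2.0),
                texture_tone=0.62 + rng.normal(0, 0.05),
            )
            img, lm = faces.render_face(p)
            imgs.append(img)
            lsets.append(lm)
        vectors, _ = space.vectorize_faces(imgs, lsets)
        model = space.build_face_space(vectors)
        frac = model.explained_variance[:3].sum() / model.explained_variance.sum()
        assert frac >= 0.90


class TestRenderAndStimuli:
    def test_zero_warp_render_returns_texture(self, small_space):
        _, model = small_space
        vec = space.synthesize(np.zeros(model.k), model)
        vec.warp_x[:] = 0
        vec.warp_y[:] = 0
        assert np.allclose(space.render_face(vec), np.clip(vec.texture, 0, 1))

    def test_render_dimensions_match_canvas(self, small_space):
        _, model = small_space
        img = space.render_face(space.synthesize(np.zeros(2), model))
        assert img.shape == (120, 100)

    def test_mean_render_close_to_pixel_average_of_aligned_faces(self, face_population):
        imgs, lsets = face_population
        vectors, avg_lms = space.vectorize_faces(imgs, lsets)
        model = space.build_face_space(vectors)
        rendered_mean = space.render_face(
            space.synthesize(np.zeros(model.k), model)
        )
        aligned = [
            space.align_by_eyes(i, l, (avg_lms["left_eye"], avg_lms["right_eye"]))[0]
            for i, l in zip(imgs, lsets)
        ]
        explicit_avg = np.mean(aligned, axis=0)
        interior = (slice(15, 105), slice(10, 90))
        err = np.abs(rendered_mean[interior] - explicit_avg[interior]).mean()
        assert err < 0.05

    def test_double_inversion_is_identity(self, one_face):
        img, _ = one_face
        once = space.prepare_stimulus(img, orientation="inverted", feather_px=4)
        twice = once[::-1]
        assert np.allclose(twice, space.prepare_stimulus(img, orientation="upright", feather_px=4))

    def test_zero_feather_preserves_face_region(self, one_face):
        img, _ = one_face
        out = space.prepare_stimulus(img, feather_px=0)
        assert np.allclose(out, img)

    def test_border_blends_to_background(self, one_face):
        img, _ = one_face
        bg = 0.5
        out = space.prepare_stimulus(img, background=bg, feather_px=5)
        assert np.abs(out[0] - bg).max() < 1 / 255
        assert np.abs(out[:, -1] - bg).max() < 1 / 255

    def test_feather_margin_validation(self, one_face):
        img, _ = one_face
        with pytest.raises(ValueError):
            space.prepare_stimulus(img, feather_px=60)


class TestNoiseMask:
    def test_zero_sd_gives_constant_mask(self):
        stim = [np.full((8, 8), 0.4)]
        mask = space.make_noise_mask(stim, (16, 16), seed=0)
        assert np.allclose(mask, 0.4)

    def test_moments_match_stimuli(self):
        rng = np.random.default_rng(0)
        stim = [np.clip(rng.normal(0.5, 0.1, (64, 64)), 0, 1) for _ in range(4)]
        mask = space.make_noise_mask(stim, (256, 256), seed=1)
        ref = np.concatenate([s.ravel() for s in stim])
        assert mask.mean() == pytest.approx(ref.mean(), rel=0.05)
        assert mask.std() == pytest.approx(ref.std(), rel=0.05)

    def test_seeded_and_rejects_empty(self):
        stim = [np.full((4, 4), 0.3)]
        a = space.make_noise_mask(stim, (8, 8), seed=3)
        b = space.make_noise_mask(stim, (8, 8), seed=3)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError, match="empty"):
            space.make_noise_mask([], (8, 8))


class TestWarpTextureVector:
    def test_vector_layout_round_trip(self):
        rng = np.random.default_rng(0)
        v = WarpTextureVector(
            rng.random((6, 5)), rng.random((6, 5)), rng.random((6, 5))
        )
        back = WarpTextureVector.from_vector(v.to_vector(), v.layout)
        assert np.allclose(back.texture, v.texture)
        assert np.allclose(back.warp_x, v.warp_x)

    def test_rejects_nonfinite_and_mismatch(self):
        with pytest.raises(ValueError, match="finite"):
            WarpTextureVector(np.full((3, 3), np.nan), np.zeros((3, 3)), np.zeros((3, 3)))
        with pytest.raises(ValueError, match="share"):
            WarpTextureVector(np.zeros((3, 3)), np.zeros((4, 3)), np.zeros((4, 3)))
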