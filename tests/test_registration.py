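"""Registration: grayscale conversion, dihedral search, fine rigid recovery."""

import dataclasses

import numpy as np
import pytest

from ihcmap.geometry import DihedralOp, apply_dihedral_to_image
from ihcmap.registration import (
    RegistrationConfig,
    coarse_align,
    fine_register,
    register_all,
    to_grayscale,
)
from ihcmap.slide_io import SlideImage
from ihcmap.synthetic import generate_case

from conftest import small_spec

FAST = RegistrationConfig(max_side=512)


class TestGrayscale:
    def test_white_maps_to_255(self):
        img = SlideImage(np.full((2, 2, 3), 255, np.uint8), 1.0)
        assert np.allclose(to_grayscale(img), 255.0)

    def test_pure_red_luminance(self):
        img = SlideImage(np.tile(np.array([255, 0, 0], np.uint8), (2, 2, 1)), 1.0)
        assert np.allclose(to_grayscale(img), 0.299 * 255)

    def test_gray_fixed_points(self):
        g = np.arange(256, dtype=np.uint8)
        img = SlideImage(np.stack([np.tile(g, (4, 1))] * 3, axis=-1), 1.0)
        assert np.allclose(to_grayscale(img), np.tile(g, (4, 1)).astype(float))


@pytest.fixture(scope="module")
def textured_ref():
    """Reference slide of a small noise-free synthetic case (chiral tissue)."""
    case = generate_case(small_spec(seed=9, size=384, noise=0.0))
    return case.reference


class TestCoarseAlign:
    def test_identical_image_gives_identity(self, textured_ref):
        assert coarse_align(textured_ref, textured_ref, config=FAST) is DihedralOp.IDENTITY

    @pytest.mark.parametrize("op", [DihedralOp.FLIP_H, DihedralOp.ROT180], ids=lambda o: o.value)
    def test_recovers_planted_op(self, textured_ref, op, rng):
        moved = apply_dihedral_to_image(
            {DihedralOp.FLIP_H: DihedralOp.FLIP_H, DihedralOp.ROT180: DihedralOp.ROT180}[op],
            textured_ref.pixels,
        )
        noisy = np.clip(moved.astype(float) + rng.normal(0, 2, moved.shape), 0, 255).astype(np.uint8)
        ihc = SlideImage(noisy, textured_ref.microns_per_pixel, "moved")
        # planted array op D means the aligning op is D^-1; both here are involutions
        assert coarse_align(textured_ref, ihc, config=FAST) is op

    def test_manual_mode_returns_given_op(self, textured_ref):
        got = coarse_align(textured_ref, textured_ref, mode="manual", manual_op=DihedralOp.ROT270)
        assert got is DihedralOp.ROT270

    def test_constant_image_warns_identity(self, flat_slide):
        with pytest.warns(UserWarning, match="constant"):
            assert coarse_align(flat_slide, flat_slide) is DihedralOp.IDENTITY


class TestFineRegister:
    def test_self_registration_is_identity(self, textured_ref):
        res = fine_register(textured_ref, textured_ref, config=FAST)
        assert abs(res.transform.theta) < 0.1
        assert abs(res.transform.tx) < 0.5 and abs(res.transform.ty) < 0.5
        assert res.final_cost < 1.0
        assert not res.failed
        assert res.overlap_fraction > 0.99

    def test_known_transform_recovered(self):
        """theta*=7 deg, t*=(31,-12) px on a 1024 px slide within 0.5 deg / 2 px."""
        spec = small_spec(seed=21, size=1024)
        spec.stains = [dataclasses.replace(spec.stains[0], theta=7.0, translation=(31.0, -12.0))]
        case = generate_case(spec)
        res = fine_register(case.reference, case.ihc_images[0], init=DihedralOp.IDENTITY)
        assert res.transform.theta == pytest.approx(7.0, abs=0.5)
        assert res.transform.tx == pytest.approx(31.0, abs=2.0)
        assert res.transform.ty == pytest.approx(-12.0, abs=2.0)

    def test_noise_floor_cost_matches_theory(self, rng):
        """Two independently noised copies: E[MSE] at identity = 2 sigma^2.

        The registered optimum can dip below that (a sub-pixel shift lets the
        bilinear interpolation average noise) but never exceed it.
        """
        sigma = 5.0
        base = np.full((256, 256), 128.0)
        base[64:192, 64:192] = 90.0  # structure so the optimum is well defined
        a = np.clip(base + rng.normal(0, sigma, base.shape), 0, 255).astype(np.uint8)
        b = np.clip(base + rng.normal(0, sigma, base.shape), 0, 255).astype(np.uint8)
        ref = SlideImage(np.stack([a] * 3, -1), 1.0)
        ihc = SlideImage(np.stack([b] * 3, -1), 1.0)

        from ihcmap.registration import _warp_cost

        g_ref, g_ihc = to_grayscale(ref).astype(np.float32), to_grayscale(ihc).astype(np.float32)
        c = np.array([127.5, 127.5])
        cost_at_identity, _ = _warp_cost(g_ref, g_ihc, 0, 0, 0, c, 0.0)
        assert cost_at_identity == pytest.approx(2 * sigma**2, rel=0.2)

        res = fine_register(ref, ihc, config=FAST)
        assert abs(res.transform.theta) < 0.5
        assert abs(res.transform.tx) < 1.0 and abs(res.transform.ty) < 1.0
        assert sigma**2 * 0.5 < res.final_cost <= cost_at_identity + 1e-6

    def test_cost_not_worse_than_init(self, textured_ref, rng):
        noisy = np.clip(textured_ref.pixels.astype(float) + rng.normal(0, 3, textured_ref.pixels.shape), 0, 255)
        ihc = SlideImage(noisy.astype(np.uint8), textured_ref.microns_per_pixel)
        res = fine_register(textured_ref, ihc, config=FAST)
        from ihcmap.registration import _warp_cost, to_grayscale as gs

        g_ref = gs(textured_ref).astype(np.float32)
        g_ihc = gs(ihc).astype(np.float32)
        c = np.array([(g_ihc.shape[1] - 1) / 2.0, (g_ihc.shape[0] - 1) / 2.0])
        init_cost, _ = _warp_cost(g_ref, g_ihc, 0, 0, 0, c, 0.0)
        assert res.final_cost <= init_cost + 1e-6

    def test_symmetry_forward_backward_compose_to_identity(self):
        spec = small_spec(seed=31, size=384)
        spec.stains = [dataclasses.replace(spec.stains[0], theta=5.0, translation=(10.0, -6.0))]
        case = generate_case(spec)
        a, b = case.reference, case.ihc_images[0]
        t_ab = fine_register(a, b, config=FAST).transform
        t_ba = fine_register(b, a, config=FAST).transform
        pts = np.random.default_rng(0).uniform(100, 280, (100, 2))
        back = t_ab.apply_points(t_ba.apply_points(pts))
        assert np.abs(back - pts).max() < 3.0


class TestRegisterAll:
    def test_empty_list(self, textured_ref):
        assert register_all(textured_ref, []) == []

    def test_single_identical_ihc(self, textured_ref):
        (res,) = register_all(textured_ref, [textured_ref], config=FAST)
        assert not res.failed
        assert abs(res.transform.theta) < 0.1

    def test_three_planted_moves_recovered(self, moved_case):
        results = register_all(moved_case.reference, moved_case.ihc_images)
        assert [not r.failed for r in results] == [True] * 3
        for img, res in zip(moved_case.ihc_images, results):
            truth = moved_case.transforms[img.name]
            assert res.transform.pre is truth.pre
            pts = np.random.default_rng(1).uniform(100, 400, (50, 2))
            err = np.abs(res.transform.apply_points(pts) - truth.apply_points(pts)).max()
            assert err < 2.0
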