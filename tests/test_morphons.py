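"""The multi-scale phase-based registration driver."""

import numpy as np
import pytest

from sctmorph.fields import DisplacementField, compose, jacobian_determinant, warp
from sctmorph.metrics import mutual_information, slpd
from sctmorph.morphons import RegistrationConfig, accumulate, field_update, register
from sctmorph.phantom import PhantomSpec, generate_phantom, head_mask, random_smooth_field
from sctmorph.quadrature import build_filter_bank

RHO0 = np.pi / 3


def _band_limited(n=64, seed=0):
    """Smooth random texture whose spectrum sits near the filter band."""
    from scipy import ndimage

    rng = np.random.default_rng(seed)
    img = ndimage.gaussian_filter(rng.standard_normal((n, n)), 1.5)
    return img / np.abs(img).max()


class TestFieldUpdate:
    def test_identical_images_give_zero_update(self, clean_phantom):
        bank = build_filter_bank(2)
        du, cu = field_update(clean_phantom.ct, clean_phantom.ct, bank)
        assert np.abs(du.vectors).max() < 1e-8
        assert cu.min() >= 0

    def test_subvoxel_shift_recovered_within_twenty_percent(self):
        # band-limited content at the filter center frequency, displaced by
        # a sub-voxel amount along axis 0: one update reads the shift back
        delta = 0.5
        x = np.arange(64, dtype=float)
        f = np.tile(np.cos(RHO0 * x)[:, None], (1, 64))
        m = np.tile(np.cos(RHO0 * (x - delta))[:, None], (1, 64))
        bank = build_filter_bank(2)
        du, cu = field_update(f, m, bank, sigma_system=2.0)
        interior = du.vectors[0][16:48, 16:48]
        assert np.median(interior) == pytest.approx(delta, rel=0.2)
        assert np.abs(np.median(du.vectors[1][16:48, 16:48])) < 0.1

    def test_structureless_pair_guarded_to_zero(self):
        bank = build_filter_bank(2)
        du, cu = field_update(np.ones((32, 32)), np.ones((32, 32)), bank)
        assert np.all(du.vectors == 0)
        assert cu.max() < 1e-12


class TestAccumulate:
    def test_zero_update_certainty_leaves_field_unchanged(self):
        d = random_smooth_field((24, 24), 1.0, 4.0, 1)
        c = np.ones((24, 24))
        du = random_smooth_field((24, 24), 2.0, 4.0, 2)
        new_d, new_c, inc = accumulate(d, c, du, np.zeros((24, 24)))
        assert np.allclose(new_d.vectors, d.vectors)
        assert np.all(inc.vectors == 0)

    def test_first_iteration_takes_update_wholesale(self):
        shape = (16, 16)
        du = DisplacementField(np.stack([np.full(shape, 1.2), np.full(shape, -0.4)]))
        cu = np.full(shape, 3.0)
        new_d, new_c, _ = accumulate(DisplacementField.zero(shape), np.zeros(shape), du, cu)
        assert np.allclose(new_d.vectors, du.vectors, atol=1e-9)
        assert np.allclose(new_c, cu, rtol=1e-9)

    def test_equal_certainties_halve_the_increment(self):
        shape = (16, 16)
        du = DisplacementField(np.stack([np.full(shape, 2.0), np.zeros(shape)]))
        c = np.full(shape, 5.0)
        _, _, inc = accumulate(DisplacementField.zero(shape), c, du, c)
        assert np.allclose(inc.vectors[0], 1.0, rtol=1e-9)

    def test_negative_certainty_rejected(self):
        d = DisplacementField.zero((8, 8))
        with pytest.raises(ValueError):
            accumulate(d, -np.ones((8, 8)), d, np.ones((8, 8)))


class TestRegister:
    def test_self_registration_yields_negligible_field(self, clean_phantom):
        res = register(clean_phantom.ct, clean_phantom.ct)
        assert res.field.magnitude().max() < 0.1

    def test_moved_is_exactly_the_warped_moving_image(self, clean_phantom, test_case):
        res = register(clean_phantom.ct, test_case.ct)
        assert np.array_equal(res.moved.data, warp(test_case.ct, res.field).data)

    def test_intensity_affine_change_leaves_field_unchanged(self, clean_phantom):
        fixed = clean_phantom.ct
        t = DisplacementField(np.stack([np.full((64, 64), 2.0), np.full((64, 64), -1.0)]))
        moving = warp(fixed, t)
        res_a = register(fixed, moving)
        res_b = register(fixed.like(3.0 * fixed.data + 10.0), moving)
        mask = head_mask(clean_phantom.labels)
        diff = np.sqrt(((res_a.field.vectors - res_b.field.vectors) ** 2).sum(axis=0))
        assert diff[mask].mean() < 0.1

    @pytest.mark.parametrize("seed", range(5))
    def test_update_magnitude_trends_downward_at_finest_scale(self, seed):
        case = generate_phantom(PhantomSpec(shape=(64, 64), seed=seed, deform_amplitude=0, sp_noise_fraction=0))
        tf = random_smooth_field((64, 64), 3.0, 8.0, seed + 1000)
        res = register(case.ct, warp(case.ct, tf))
        finest = [u for s, i, u, c in res.log if s == 0]
        assert len(finest) >= 6
        assert np.mean(finest[-3:]) <= np.mean(finest[:3])

    def test_registration_improves_mi_and_slpd(self, clean_phantom):
        fixed = clean_phantom.ct
        tf = random_smooth_field((64, 64), 3.0, 8.0, 77)
        moving = warp(fixed, tf)
        res = register(fixed, moving)
        assert mutual_information(fixed, res.moved) > mutual_information(fixed, moving)
        assert slpd(fixed, res.moved) < slpd(fixed, moving)
        assert jacobian_determinant(res.field).min() > 0

    def test_too_small_image_for_pyramid_rejected(self):
        with pytest.raises(ValueError):
            register(np.zeros((16, 16)), np.zeros((16, 16)), RegistrationConfig(n_scales=3))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            register(np.zeros((64, 64)), np.zeros((64, 32)))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RegistrationConfig(n_scales=0)
        with pytest.raises(ValueError):
            RegistrationConfig(iterations_per_scale=0)
        with pytest.raises(ValueError):
            RegistrationConfig(sigma_regularize=0.0)

    def test_log_records_scales_coarse_to_fine(self, clean_phantom):
        res = register(clean_phantom.ct, clean_phantom.ct, RegistrationConfig(iterations_per_scale=2, stop_tol=0.0))
        scales = [s for s, *_ in res.log]
        assert scales == sorted(scales, reverse=True)
        assert set(scales) == {0, 1, 2}
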