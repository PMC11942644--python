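"""Phantom construction, forward model, noise, AEC and dose accounting."""

import dataclasses

import numpy as np
import pytest

import dexray
from dexray.phantom import (LUNG, RIB, SIGNAL_FLOOR, AcquisitionSettings,
                            AttenuationTable, MaterialPhantom, PhantomConfig,
                            add_noise, apply_motion, auto_exposure,
                            build_chest_phantom, estimate_esd, simulate_pair,
                            simulate_transmission)


class TestBuildChestPhantom:
    def test_empty_config_gives_zero_maps(self):
        cfg = PhantomConfig(torso_soft_thickness=0, lung_soft_thickness=0,
                            mediastinum_extra=0, rib_thickness=0,
                            spine_thickness=0, clavicle_thickness=0,
                            scapula_thickness=0, nodule_extra_soft=0)
        ph = build_chest_phantom(96, 96, cfg)
        assert np.all(ph.soft_thickness == 0)
        # bone labels keep a hair of thickness by invariant; everything else 0
        assert ph.bone_thickness[~np.isin(ph.anatomy_labels, (3, 4, 5, 6))].max() == 0

    def test_rib_thickness_read_back(self):
        cfg = PhantomConfig(rib_thickness=0.8)
        ph = build_chest_phantom(256, 256, cfg)
        rib = ph.mask(RIB)
        assert rib.any()
        assert (ph.bone_thickness[rib] > 0).all()
        # band centres reach the configured thickness
        assert ph.bone_thickness[rib].max() == pytest.approx(0.8, rel=0.02)
        # thickness scales linearly with the config value
        ph2 = build_chest_phantom(256, 256, PhantomConfig(rib_thickness=1.6))
        np.testing.assert_allclose(ph2.bone_thickness[ph2.mask(RIB)],
                                   2 * ph.bone_thickness[rib], rtol=1e-9)

    def test_mirror_symmetry(self):
        ph = build_chest_phantom(128, 128)
        phm = build_chest_phantom(128, 128, PhantomConfig(mirror=True))
        np.testing.assert_array_equal(phm.soft_thickness,
                                      ph.soft_thickness[:, ::-1])
        np.testing.assert_array_equal(phm.bone_thickness,
                                      ph.bone_thickness[:, ::-1])

    def test_rejects_small_dimensions(self):
        with pytest.raises(ValueError):
            build_chest_phantom(32, 128)

    def test_bone_labels_carry_bone(self, phantom):
        bone_lbl = phantom.mask(3, 4, 5, 6)
        assert (phantom.bone_thickness[bone_lbl] > 0).all()


class TestTransmission:
    def test_zero_thickness_gives_unity(self, atten):
        cfg = PhantomConfig(torso_soft_thickness=0, lung_soft_thickness=0,
                            mediastinum_extra=0, rib_thickness=0,
                            spine_thickness=0, clavicle_thickness=0,
                            scapula_thickness=0, nodule_extra_soft=0)
        ph = build_chest_phantom(96, 96, cfg)
        t = simulate_transmission(ph, atten, "high")
        # bone-labelled pixels keep a hair of thickness; elsewhere exactly 1
        assert t.max() == 1.0
        assert t.min() > 0.999

    def test_hand_value_beer_lambert(self):
        ph = MaterialPhantom(np.full((64, 64), 5.0), np.zeros((64, 64)),
                             0.14, np.full((64, 64), LUNG, np.int8))
        at = AttenuationTable(mu_soft_low=0.25, mu_soft_high=0.2,
                              mu_bone_low=0.9, mu_bone_high=0.4)
        t = simulate_transmission(ph, at, "high")
        assert t[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_monotone_in_thickness(self, phantom, atten):
        t1 = simulate_transmission(phantom, atten, "low")
        thicker = MaterialPhantom(phantom.soft_thickness + 1.0,
                                  phantom.bone_thickness, phantom.pixel_pitch,
                                  phantom.anatomy_labels)
        t2 = simulate_transmission(thicker, atten, "low")
        assert (t2 < t1).all()

    def test_log_linear_model_exact(self, phantom, atten, clean_pair):
        """Noiseless log-transmission is affine in the thickness maps."""
        for img, beam in ((clean_pair.image_low, "low"),
                          (clean_pair.image_high, "high")):
            pred = -(atten.mu("soft", beam) * phantom.soft_thickness
                     + atten.mu("bone", beam) * phantom.bone_thickness)
            np.testing.assert_allclose(np.log(img), pred, atol=1e-10)

    def test_attenuation_table_invariants(self):
        with pytest.raises(ValueError):
            AttenuationTable(mu_bone_low=0.4, mu_bone_high=0.9)
        with pytest.raises(ValueError):  # bone must harden faster
            AttenuationTable(mu_soft_low=0.25, mu_soft_high=0.10,
                             mu_bone_low=0.90, mu_bone_high=0.85)


class TestMotion:
    def test_zero_field_is_identity(self, clean_pair):
        field = np.zeros((2, *clean_pair.shape))
        np.testing.assert_array_equal(
            apply_motion(clean_pair.image_high, field), clean_pair.image_high)

    def test_integer_translation_moves_delta(self):
        img = np.zeros((32, 32))
        img[10, 20] = 1.0
        field = np.zeros((2, 32, 32))
        field[0] = 3.0  # out(p) = in(p + 3) pulls content up by 3 rows
        out = apply_motion(img, field)
        assert out[7, 20] == 1.0
        assert out.sum() == pytest.approx(1.0)

    def test_warp_inverse_round_trip(self, phantom, atten):
        from scipy.ndimage import gaussian_filter
        # band-limit the image: sub-pixel bilinear resampling cannot
        # round-trip structure at the single-pixel scale
        img = gaussian_filter(
            simulate_transmission(phantom, atten, "high"), 1.5)
        field = dexray.phantom.random_smooth_motion(img.shape, 2.0, seed=4,
                                                     sigma=30.0)
        back = apply_motion(apply_motion(img, field), -field)
        rng = img.max() - img.min()
        # edge-replicated borders cannot round-trip; compare the interior
        m = 4
        err = np.abs(back - img)[m:-m, m:-m].max()
        assert err < 0.02 * rng

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_motion(np.ones((16, 16)), np.zeros((2, 8, 8)))


class TestNoise:
    def test_same_seed_reproducible(self):
        img = np.full((64, 64), 0.5)
        a = add_noise(img, 1e4, seed=7)
        b = add_noise(img, 1e4, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_poisson_moment_identity(self):
        """Sample variance of counts ~ mean of counts on a flat region."""
        img = np.full((128, 128), 0.3)
        noisy = add_noise(img, 1e4, seed=1)
        counts = noisy * 1e4
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_vanishing_noise_limit(self):
        img = np.full((64, 64), 0.5)
        noisy = add_noise(img, 1e8, seed=2)
        assert np.abs(noisy / img - 1).max() < 1e-3

    def test_simulation_reproducible(self, phantom, atten):
        s = AcquisitionSettings(seed=11)
        a = simulate_pair(phantom, atten, s)
        b = simulate_pair(phantom, atten, s)
        np.testing.assert_array_equal(a.image_low, b.image_low)
        np.testing.assert_array_equal(a.image_high, b.image_high)
        assert a.noise_budget == s.photon_budget

    def test_floor_keeps_positivity(self):
        img = np.full((32, 32), 1e-9)
        noisy = add_noise(img, 1e3, seed=0)
        assert noisy.min() >= SIGNAL_FLOOR


class TestAutoExposure:
    def test_flat_field_closed_form(self, atten):
        ph = MaterialPhantom(np.full((64, 64), 10.0), np.zeros((64, 64)),
                             0.14, np.full((64, 64), LUNG, np.int8))
        s = AcquisitionSettings()
        target = 0.5
        out = auto_exposure(ph, atten, s, target)
        t = np.exp(-atten.mu_soft_low * 10.0)
        scale = out.exposure_time_low / s.exposure_time_low
        assert scale == pytest.approx(target / t, rel=0.01)

    def test_thicker_patient_needs_longer_exposure(self, atten):
        base = build_chest_phantom(128, 128)
        thick = build_chest_phantom(
            128, 128, PhantomConfig(torso_soft_thickness=40,
                                    lung_soft_thickness=14))
        s = AcquisitionSettings()
        t1 = auto_exposure(base, atten, s, 0.5).exposure_time_low
        t2 = auto_exposure(thick, atten, s, 0.5).exposure_time_low
        assert t2 > t1

    def test_target_already_met_is_fixed_point(self, atten):
        ph = MaterialPhantom(np.full((64, 64), 10.0), np.zeros((64, 64)),
                             0.14, np.full((64, 64), LUNG, np.int8))
        s = AcquisitionSettings()
        adjusted = auto_exposure(ph, atten, s, 0.4)
        assert auto_exposure(ph, atten, adjusted, 0.4) is adjusted

    def test_no_lung_rejected(self, atten):
        ph = MaterialPhantom(np.ones((64, 64)), np.zeros((64, 64)),
                             0.14, np.zeros((64, 64), np.int8))
        with pytest.raises(ValueError):
            auto_exposure(ph, atten, AcquisitionSettings(), 0.5)


class TestEsd:
    CAL = {60.0: 80.0, 120.0: 160.0}  # uGy per mAs at 1 m

    def test_esd_vanishes_with_mas(self):
        tiny = dataclasses.replace(AcquisitionSettings(),
                                   exposure_time_low=1e-12,
                                   exposure_time_high=1e-12)
        assert estimate_esd(tiny, self.CAL).total == pytest.approx(0, abs=1e-9)

    def test_doubling_mas_doubles_esd(self):
        s = AcquisitionSettings()
        r = estimate_esd(s, self.CAL)
        s2 = dataclasses.replace(s, exposure_time_low=2 * s.exposure_time_low,
                                 exposure_time_high=2 * s.exposure_time_high)
        r2 = estimate_esd(s2, self.CAL)
        assert r2.esd_low == pytest.approx(2 * r.esd_low)
        assert r2.esd_high == pytest.approx(2 * r.esd_high)

    def test_reported_means_sum_to_total(self):
        """Per-exposure doses of 0.141 and 0.134 mGy sum to 0.275 mGy."""
        s = AcquisitionSettings()
        fsd = s.sid - 20.0
        cal = {
            s.kvp_low: 0.141e3 / (s.mas_low * (100 / fsd) ** 2 * 1.35),
            s.kvp_high: 0.134e3 / (s.mas_high * (100 / fsd) ** 2 * 1.35),
        }
        r = estimate_esd(s, cal)
        assert r.esd_low == pytest.approx(0.141, abs=1e-12)
        assert r.esd_high == pytest.approx(0.134, abs=1e-12)
        assert r.total == pytest.approx(0.275, abs=1e-12)

    def test_invalid_distance_rejected(self):
        with pytest.raises(ValueError):
            estimate_esd(AcquisitionSettings(), self.CAL,
                         focus_skin_distance=-1.0)
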