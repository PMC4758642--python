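"""Synthetic-data generators: determinism, ground truth, physical layout."""

import numpy as np
import pytest

from cordflux.core import Image
from cordflux.simdata import (
    SimImageSpec,
    SimMovieSpec,
    VesicleSpec,
    make_lambda_stack,
    make_movie,
    make_puncta_image,
    make_rab6_family,
    make_two_channel_image,
)
from cordflux.unmix import (default_autofluorescence_profile,
                            default_gfp_profile)


class TestPunctaImage:
    def test_empty_image_is_flat_background(self):
        spec = SimImageSpec(n_puncta=0, noise_sd=0.0, background_level=5.0)
        img, truth = make_puncta_image(spec)
        assert np.all(img.data == 5.0)
        assert len(truth.puncta) == 0

    def test_ground_truth_count_and_cord_density(self):
        # 12 puncta over a 60 µm cord -> 20 per 100 µm downstream
        spec = SimImageSpec(width_px=375, pixel_size_um=0.16, n_puncta=12,
                            noise_sd=0.0)
        assert spec.cord_length_um == pytest.approx(60.0)
        _, truth = make_puncta_image(spec)
        assert len(truth.puncta) == 12
        assert 12 * 100 / spec.cord_length_um == pytest.approx(20.0)

    def test_default_spot_width_in_diffraction_limited_range(self):
        assert 0.5 <= SimImageSpec().punctum_fwhm_um <= 0.7

    def test_same_seed_bit_identical(self, noisy_spec):
        img1, t1 = make_puncta_image(noisy_spec)
        img2, t2 = make_puncta_image(noisy_spec)
        np.testing.assert_array_equal(img1.data, img2.data)
        assert t1.puncta.equals(t2.puncta)

    def test_intensities_non_negative_under_heavy_noise(self):
        spec = SimImageSpec(background_level=1.0, noise_sd=50.0, seed=1)
        img, _ = make_puncta_image(spec)
        assert img.data.min() >= 0

    @pytest.mark.parametrize("kw", [
        {"width_px": 0}, {"height_px": -1}, {"pixel_size_um": 0.0},
        {"n_puncta": -2}, {"punctum_sigma_um": 0.0}, {"noise_sd": -1.0},
    ])
    def test_invalid_spec_rejected(self, kw):
        with pytest.raises(ValueError):
            SimImageSpec(**kw)


class TestTwoChannel:
    def test_coloc_fraction_bounds_enforced(self, clean_spec):
        with pytest.raises(ValueError):
            make_two_channel_image(clean_spec, 1.2)
        with pytest.raises(ValueError):
            make_two_channel_image(clean_spec, -0.1)

    def test_full_colocalization_gives_identical_channels(self, clean_spec):
        (c1, c2), truth = make_two_channel_image(clean_spec, 1.0)
        np.testing.assert_array_equal(c1.data, c2.data)
        assert (truth.puncta["kind"] == "shared").all()

    def test_zero_colocalization_disjoint_positions(self, clean_spec):
        (c1, c2), truth = make_two_channel_image(clean_spec, 0.0)
        kinds = truth.puncta["kind"].value_counts()
        assert kinds.get("shared", 0) == 0
        assert kinds["ch1"] == clean_spec.n_puncta
        assert kinds["ch2"] == clean_spec.n_puncta
        # no punctum position is reused across channels
        x1 = truth.puncta["x1_um"].dropna().to_numpy()
        x2 = truth.puncta["x2_um"].dropna().to_numpy()
        assert np.abs(x1[:, None] - x2[None, :]).min() > 1.0

    def test_offset_pairs_lie_at_requested_offset(self, clean_spec):
        (_, _), truth = make_two_channel_image(clean_spec, 0.5, offset_um=0.8)
        pairs = truth.puncta[truth.puncta["kind"] == "offset_pair"]
        assert len(pairs) == clean_spec.n_puncta - 6
        np.testing.assert_allclose(pairs["offset_um"], 0.8)

    def test_channel1_punctum_count_is_constant(self, clean_spec):
        for f in [0.0, 0.25, 0.5, 1.0]:
            _, truth = make_two_channel_image(clean_spec, f)
            n_ch1 = truth.puncta["x1_um"].notna().sum()
            assert n_ch1 == clean_spec.n_puncta


class TestLambdaStack:
    def test_single_component_spectra_proportional_to_profile(self):
        g = default_gfp_profile()
        a = default_autofluorescence_profile()
        gmap = Image(np.random.default_rng(0).uniform(0, 1, (8, 8)))
        zero = Image(np.zeros((8, 8)))
        stack, _ = make_lambda_stack(gmap, zero, g, a, noise_sd=0.0)
        # every pixel spectrum = abundance * profile
        expected = gmap.data[None] * g.array[:, None, None]
        np.testing.assert_allclose(stack.data, expected)

    def test_band_mismatch_rejected(self):
        from cordflux.unmix import SpectralProfile
        with pytest.raises(ValueError):
            SpectralProfile(tuple([1 / 8] * 8))

    def test_noisy_stack_reproducible(self):
        g = default_gfp_profile()
        a = default_autofluorescence_profile()
        m = Image(np.ones((6, 6)))
        s1, _ = make_lambda_stack(m, m, g, a, noise_sd=0.3, seed=9)
        s2, _ = make_lambda_stack(m, m, g, a, noise_sd=0.3, seed=9)
        np.testing.assert_array_equal(s1.data, s2.data)


class TestMovie:
    def test_zero_velocity_vesicle_is_stationary(self, single_vesicle_spec):
        _, truth = make_movie(single_vesicle_spec(0.0, frames=50))
        assert truth.track_classes.loc[0, "true_class"] == "stationary"

    def test_leftward_motion_is_retrograde(self, single_vesicle_spec):
        # anterior is to the left: negative velocity moves retrograde
        _, truth = make_movie(single_vesicle_spec(-1.5))
        assert truth.track_classes.loc[0, "true_direction"] == "retrograde"

    def test_per_frame_displacement_matches_velocity(self, single_vesicle_spec):
        # 1.0 µm/s at 0.16 µm/px and 3.1 fps -> ~2.02 px/frame
        spec = single_vesicle_spec(1.0, start=10.0)
        _, truth = make_movie(spec)
        xs = truth.tracks["x_um"].to_numpy() / spec.pixel_size_um
        steps = np.diff(xs)
        np.testing.assert_allclose(steps, 1.0 / (0.16 * 3.1), rtol=1e-9)
        assert steps[0] == pytest.approx(2.0161, abs=1e-3)

    def test_start_outside_cord_rejected(self):
        with pytest.raises(ValueError, match="outside cord"):
            SimMovieSpec(vesicles=(VesicleSpec(95.0, 1.0),),
                         cord_length_um=80.0)

    def test_bleached_region_has_lower_background(self):
        spec = SimMovieSpec(frames=10, vesicles=(), stationary_n=0,
                            noise_sd=0.0, bleached_interval_um=(20.0, 60.0),
                            background_level=10.0)
        movie, _ = make_movie(spec)
        col_in = int(40.0 / spec.pixel_size_um)
        col_out = int(5.0 / spec.pixel_size_um)
        assert movie.data[0, 0, col_in] < movie.data[0, 0, col_out]

    def test_same_seed_bit_identical(self):
        spec = SimMovieSpec(frames=20, vesicles=(VesicleSpec(10.0, 1.0, 0.1, 3, 0.05),),
                            stationary_n=2, noise_sd=1.0, seed=5)
        m1, t1 = make_movie(spec)
        m2, t2 = make_movie(spec)
        np.testing.assert_array_equal(m1.data, m2.data)
        assert t1.tracks.equals(t2.tracks)

    def test_vesicle_leaving_cord_disappears(self, single_vesicle_spec):
        spec = single_vesicle_spec(2.0, frames=200, start=70.0)
        _, truth = make_movie(spec)
        # 10 µm of headroom at 2 µm/s = ~5 s = ~16 frames
        assert truth.tracks["frame"].max() < 30


class TestRab6Family:
    def test_family_structure(self):
        fam = make_rab6_family(seed=0)
        a = fam["Rab6A_synthetic"]
        ap = fam["Rab6Aprime_synthetic"]
        assert len(a) == len(ap) == 210
        assert sum(x != y for x, y in zip(a, ap)) == 3
        # diagnostic residues (1-based positions 63/106/139)
        assert (a[62], a[105], a[138]) == ("V", "T", "S")
        assert (ap[62], ap[105], ap[138]) == ("I", "T", "S")
        assert (fam["Rab6B_synthetic"][105], fam["Rab6B_synthetic"][138]) == ("S", "T")
        r61, r62 = fam["RAB-6.1_synthetic"], fam["RAB-6.2_synthetic"]
        assert (r61[62], r61[105], r61[138]) == ("V", "T", "S")
        assert (r62[62], r62[105], r62[138]) == ("I", "S", "T")

    def test_deterministic(self):
        assert make_rab6_family(seed=3) == make_rab6_family(seed=3)
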