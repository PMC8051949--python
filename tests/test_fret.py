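"""FRET indexing: band geometry, bleed-through calibration, NFRET, normalization."""

import numpy as np
import pytest
from scipy import ndimage

from nuctension import fret
from nuctension import synthetic as syn
from nuctension.errors import BandError, CalibrationError


def brute_force_band(mask: np.ndarray, width: int) -> np.ndarray:
    """Independent set-arithmetic oracle for the NE band.

    dilate(mask, 1) minus erode(mask, width-1), both via explicit 3x3
    neighborhood shifts.
    """
    def shift_or(m):
        out = np.zeros_like(m)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                out |= np.roll(np.roll(m, dy, axis=0), dx, axis=1)
        return out

    def shift_and(m):
        out = np.ones_like(m)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                out &= np.roll(np.roll(m, dy, axis=0), dx, axis=1)
        return out

    dil = shift_or(mask)
    ero = mask.copy()
    for _ in range(width - 1):
        ero = shift_and(ero)
    return dil & ~ero


def random_blob(rng, shape=(64, 64)) -> np.ndarray:
    """A random connected blob away from the image border."""
    img = rng.random(shape)
    img = ndimage.gaussian_filter(img, 6)
    mask = img > np.quantile(img, 0.8)
    labels, n = ndimage.label(mask)
    if n == 0:
        return random_blob(rng, shape)
    sizes = ndimage.sum(mask, labels, range(1, n + 1))
    blob = labels == (1 + int(np.argmax(sizes)))
    blob[:2, :] = blob[-2:, :] = False
    blob[:, :2] = blob[:, -2:] = False
    return blob


class TestMakeNeBand:
    def test_square_matches_oracle(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[10:30, 10:30] = True
        band = fret.make_ne_band(mask, width=3)
        np.testing.assert_array_equal(band, brute_force_band(mask, 3))

    def test_width_one_is_outer_contour(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        band = fret.make_ne_band(mask, width=1)
        dil = ndimage.binary_dilation(mask, structure=np.ones((3, 3), bool))
        np.testing.assert_array_equal(band, dil & ~mask)

    def test_band_set_identities(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[8:22, 8:22] = True
        width = 3
        band = fret.make_ne_band(mask, width)
        ero = ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool), iterations=width - 1)
        assert not np.any(band & ero)
        boundary = mask & ~ndimage.binary_erosion(mask, structure=np.ones((3, 3), bool))
        assert np.all(band[boundary])

    def test_thin_object_raises(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[10, 5:15] = True  # 1 px thick line
        with pytest.raises(BandError):
            fret.make_ne_band(mask, width=3)

    def test_oracle_equivalence_random_blobs(self, rng):
        for _ in range(50):
            mask = random_blob(rng)
            for width in (1, 2, 3, 5):
                try:
                    band = fret.make_ne_band(mask, width)
                except BandError:
                    continue
                np.testing.assert_array_equal(band, brute_force_band(mask, width))


class TestSegmentNuclei:
    def test_blank_image_no_nuclei(self):
        with pytest.warns(UserWarning):
            labels = fret.segment_nuclei(np.full((64, 64), 7.0))
        assert labels.max() == 0

    def test_synthetic_field_centroids(self):
        cfg = syn.FretSimConfig(n_nuclei=30, image_shape=(512, 512), seed=21)
        s, truth = syn.simulate_fret_image_set(cfg)
        labels = fret.segment_nuclei(s.acceptor)
        assert labels.max() == 30
        from skimage.measure import regionprops

        found = np.array([r.centroid for r in regionprops(labels)])
        for t in truth:
            d = np.hypot(found[:, 0] - t.centroid[0], found[:, 1] - t.centroid[1])
            assert d.min() < 2.0

    def test_min_area_filter(self):
        img = np.zeros((80, 80))
        img[10:40, 10:40] = 100.0  # 900 px
        img[60:65, 60:68] = 100.0  # 40 px
        labels = fret.segment_nuclei(img, min_area=100)
        assert labels.max() == 1


class TestBleedthrough:
    def test_exact_constant_ratio(self):
        # noiseless donor-only field with I_F - bg = 0.30 (I_D - bg)
        cfg = syn.FretSimConfig(
            n_nuclei=5, image_shape=(300, 300), mode="donor_only", bt_donor=0.30,
            shot_noise=False, read_noise_sd=0.0, seed=5,
        )
        d, _ = syn.simulate_fret_image_set(cfg)
        acfg = syn.FretSimConfig(
            n_nuclei=5, image_shape=(300, 300), mode="acceptor_only", bt_acceptor=0.12,
            shot_noise=False, read_noise_sd=0.0, seed=6,
        )
        a, _ = syn.simulate_fret_image_set(acfg)
        model = fret.estimate_bleedthrough([d], [a])
        assert model.bt_donor_intercept == pytest.approx(0.30, abs=1e-9)
        assert model.bt_acceptor_intercept == pytest.approx(0.12, abs=1e-9)

    @pytest.mark.parametrize("seed", [31, 32, 33])
    def test_noisy_recovery_within_tolerance(self, seed):
        dcfg = syn.FretSimConfig(
            n_nuclei=10, image_shape=(400, 400), mode="donor_only", bt_donor=0.25, seed=seed
        )
        acfg = syn.FretSimConfig(
            n_nuclei=10, image_shape=(400, 400), mode="acceptor_only", bt_acceptor=0.10,
            seed=seed + 100,
        )
        d, _ = syn.simulate_fret_image_set(dcfg)
        a, _ = syn.simulate_fret_image_set(acfg)
        model = fret.estimate_bleedthrough([d], [a])
        assert model.bt_donor_intercept == pytest.approx(0.25, abs=0.01)
        assert model.bt_acceptor_intercept == pytest.approx(0.10, abs=0.01)

    def test_wrong_channel_raises(self):
        # acceptor-only field passed as donor-only: donor channel is flat bg
        acfg = syn.FretSimConfig(n_nuclei=5, image_shape=(300, 300), mode="acceptor_only", seed=7)
        a, _ = syn.simulate_fret_image_set(acfg)
        with pytest.raises(CalibrationError):
            fret.estimate_bleedthrough([a], [a])

    def test_linear_model_runs(self):
        dcfg = syn.FretSimConfig(n_nuclei=10, image_shape=(400, 400), mode="donor_only", seed=8)
        acfg = syn.FretSimConfig(n_nuclei=10, image_shape=(400, 400), mode="acceptor_only", seed=9)
        d, _ = syn.simulate_fret_image_set(dcfg)
        a, _ = syn.simulate_fret_image_set(acfg)
        model = fret.estimate_bleedthrough([d], [a], model_kind="linear")
        assert model.model_kind == "linear"
        assert model.bt_donor(2000.0) == pytest.approx(0.25, abs=0.02)


class TestComputeFretMap:
    def test_hand_computed_pixel(self):
        bt = fret.BleedthroughModel(bt_donor_intercept=0.2, bt_acceptor_intercept=0.1)
        nfret, valid = fret.compute_nfret_image(
            fret.FretImageSet(
                donor=np.full((4, 4), 100.0),
                acceptor=np.full((4, 4), 100.0),
                fret=np.full((4, 4), 50.0),
            ),
            bt,
            background=(0.0, 0.0, 0.0),
            validity_threshold=1.0,
        )
        assert valid.all()
        np.testing.assert_allclose(nfret, (50 - 20 - 10) / 100.0)

    def test_donor_only_nuclei_dropped(self, default_bt_model):
        cfg = syn.FretSimConfig(n_nuclei=5, image_shape=(300, 300), mode="donor_only", seed=41)
        s, truth = syn.simulate_fret_image_set(cfg)
        labels = fret.segment_nuclei(s.donor)
        with pytest.warns(UserWarning):
            nuclei, _ = fret.compute_fret_map(s, default_bt_model, labels)
        assert nuclei == []

    def test_median_increases_with_efficiency(self, default_bt_model):
        medians = []
        for e in (0.1, 0.3, 0.5):
            cfg = syn.FretSimConfig(
                n_nuclei=30, image_shape=(512, 512), efficiency=e, seed=50
            )
            s, truth = syn.simulate_fret_image_set(cfg)
            labels = fret.segment_nuclei(s.acceptor)
            nuclei, _ = fret.compute_fret_map(s, default_bt_model, labels)
            assert len(nuclei) >= 25
            medians.append(np.median([n.nfret_mean for n in nuclei]))
        assert medians[0] < medians[1] < medians[2]

    def test_scale_invariance(self, default_bt_model):
        cfg = syn.FretSimConfig(n_nuclei=6, image_shape=(300, 300), efficiency=0.3, seed=60)
        s, _ = syn.simulate_fret_image_set(cfg)
        labels = fret.segment_nuclei(s.acceptor)
        outside = ~ndimage.binary_dilation(labels > 0, np.ones((3, 3), bool), iterations=3)
        bg = tuple(float(np.median(ch[outside])) for ch in (s.donor, s.acceptor, s.fret))
        n1, _ = fret.compute_nfret_image(s, default_bt_model, bg, 10.0)
        k = 2.0
        scaled = fret.FretImageSet(
            donor=bg[0] + k * (s.donor - bg[0]),
            acceptor=bg[1] + k * (s.acceptor - bg[1]),
            fret=bg[2] + k * (s.fret - bg[2]),
        )
        # constant-model coefficients do not depend on intensity, so scaling
        # all background-subtracted channels by k leaves NFRET unchanged
        n2, _ = fret.compute_nfret_image(scaled, default_bt_model, bg, 10.0 * k)
        both = np.isfinite(n1) & np.isfinite(n2)
        assert both.sum() > 1000
        np.testing.assert_allclose(n1[both], n2[both], atol=1e-9)

    def test_zero_efficiency_population_mean_near_zero(self, default_bt_model):
        cfg = syn.FretSimConfig(n_nuclei=30, image_shape=(512, 512), efficiency=0.0, seed=70)
        s, _ = syn.simulate_fret_image_set(cfg)
        labels = fret.segment_nuclei(s.acceptor)
        nuclei, _ = fret.compute_fret_map(s, default_bt_model, labels)
        assert len(nuclei) >= 25
        assert abs(np.mean([n.nfret_mean for n in nuclei])) <= 0.02


class TestNormalizeToControl:
    def test_definition(self):
        values, control = fret.normalize_to_control([1.0, 2.0], [2.0, 4.0, 6.0])
        np.testing.assert_allclose(control, [0.5, 1.0, 1.5])
        assert np.median(control) == 1.0
        np.testing.assert_allclose(values, [0.25, 0.5])

    def test_identical_groups_map_identically(self):
        vals = [3.0, 5.0, 9.0]
        out_v, out_c = fret.normalize_to_control(vals, vals)
        np.testing.assert_array_equal(out_v, out_c)

    def test_large_random_control_median_one(self, rng):
        control = rng.lognormal(0.0, 0.7, size=1000)
        _, out_c = fret.normalize_to_control(control, control)
        assert np.median(out_c) == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self, rng):
        control = rng.uniform(0.5, 2.0, size=101)
        _, once = fret.normalize_to_control(control, control)
        _, twice = fret.normalize_to_control(once, once)
        np.testing.assert_allclose(once, twice)

    def test_nonpositive_median_rejected(self):
        with pytest.raises(ValueError):
            fret.normalize_to_control([1.0], [-1.0, -2.0])
        with pytest.raises(ValueError):
            fret.normalize_to_control([1.0], [])
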