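"""Phantom generator: moment matching, determinism, geometry, fixtures."""

import numpy as np
import pytest

import spinefuse as sf
from spinefuse.phantom import (DEFAULT_PROFILES, canal_template, draw_volumes,
                               lognormal_params, volume_to_area_cm2)


class TestSizeDistribution:
    @pytest.mark.parametrize("mean,sd", [
        (8.1, 5.3), (6.8, 7.1), (32.8, 30.4),
        (7.6, 3.1), (5.2, 4.6), (20.3, 19.7),
        (2.3, 4.9), (16.5, 14.2), (47.6, 36.7),
    ])
    def test_analytic_moments_match_exactly(self, mean, sd):
        """The moment-matched log-normal has exactly the requested mean/sd,
        including cells where sd exceeds the mean."""
        mu, sigma = lognormal_params(mean, sd)
        m = np.exp(mu + sigma**2 / 2)
        v = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert m == pytest.approx(mean, rel=1e-12)
        assert np.sqrt(v) == pytest.approx(sd, rel=1e-12)

    def test_sample_mean_within_two_standard_errors(self):
        rng = np.random.default_rng(7)
        draws = draw_volumes(8.1, 5.3, 10_000, rng)
        assert abs(draws.mean() - 8.1) <= 2 * 5.3 / np.sqrt(10_000)
        assert (draws > 0).all()

    def test_class_ordering_of_mean_tumor_area(self):
        """Mean simulated tumor area orders hemangioblastoma < ependymoma <
        astrocytoma, mirroring the class-conditional size statistics."""
        rng = np.random.default_rng(0)
        means = {}
        for name in ("hemangioblastoma", "ependymoma", "astrocytoma"):
            p = DEFAULT_PROFILES[name]
            v = draw_volumes(p.tumor_vol_mean, p.tumor_vol_sd, 500, rng)
            means[name] = volume_to_area_cm2(v).mean()
        assert (means["hemangioblastoma"] < means["ependymoma"]
                < means["astrocytoma"])


class TestGeneratePhantom:
    def test_same_seed_is_bit_identical(self):
        p = DEFAULT_PROFILES["astrocytoma"]
        a = sf.generate_phantom(p, rng_seed=42)
        b = sf.generate_phantom(p, rng_seed=42)
        for ch in a.channels:
            np.testing.assert_array_equal(a.channels[ch], b.channels[ch])

    def test_zero_offsets_noise_off_is_canal_template(self):
        p = sf.ClassProfile(name="flat", tumor_vol_mean=8, tumor_vol_sd=1,
                            edema_vol_mean=5, edema_vol_sd=1,
                            cavity_vol_mean=10, cavity_vol_sd=1,
                            intensity_offsets={"tumor": 0, "edema": 0,
                                               "cavity": 0})
        s = sf.generate_phantom(p, rng_seed=5, noise_sigma=0.0)
        tmpl = canal_template(256, s.meta["canal_col"])
        for ch in s.channels.values():
            np.testing.assert_allclose(ch, tmpl)

    def test_canal_column_in_central_half(self):
        for seed in range(20):
            s = sf.generate_phantom(DEFAULT_PROFILES["ependymoma"],
                                    rng_seed=seed)
            assert 64 <= s.meta["canal_col"] < 192

    def test_intensities_bounded_and_channels_coregistered(self):
        s = sf.generate_phantom(DEFAULT_PROFILES["hemangioblastoma"],
                                rng_seed=1)
        shapes = {c.shape for c in s.channels.values()}
        assert shapes == {(256, 256)}
        for c in s.channels.values():
            assert c.min() >= 0 and c.max() <= 1

    def test_invalid_arguments(self):
        p = DEFAULT_PROFILES["astrocytoma"]
        with pytest.raises(ValueError):
            sf.generate_phantom(p, size=32)
        with pytest.raises(ValueError):
            sf.generate_phantom(p, modalities=["flair"])
        with pytest.raises(ValueError):
            sf.generate_phantom(p, modalities=[])


class TestGenerateCohort:
    def test_requested_counts_and_labels(self):
        counts = {"astrocytoma": 2, "ependymoma": 3}
        c = sf.generate_cohort(counts=counts, base_seed=0, size=64)
        assert len(c) == 5
        assert c.class_counts == counts
        assert sorted(set(c.labels)) == sorted(counts)

    def test_single_case_cohort(self):
        c = sf.generate_cohort(counts={"astrocytoma": 1}, base_seed=3, size=64)
        assert len(c) == 1

    def test_distinct_base_seeds_give_distinct_images(self):
        a = sf.generate_cohort(counts={"ependymoma": 10}, base_seed=0, size=64)
        b = sf.generate_cohort(counts={"ependymoma": 10}, base_seed=1, size=64)
        for ca, cb in zip(a.cases, b.cases):
            assert not np.array_equal(ca.channels["t2"], cb.channels["t2"])

    def test_missing_profile_rejected(self):
        with pytest.raises(ValueError, match="no matching profile"):
            sf.generate_cohort(counts={"lipoma": 2})


class TestAugment:
    @pytest.fixture()
    def stack(self, rng):
        return sf.SliceStack(channels={"t2": rng.random((64, 64))},
                             label="x", case_id="x")

    def test_horizontal_flip_is_involution(self, stack):
        cfg = sf.AugmentConfig(p_flip_h=1.0, p_flip_v=0.0, max_rotation_deg=0,
                               intensity_scale_range=(1, 1),
                               noise_sigma_range=(0, 0))
        twice = sf.augment(sf.augment(stack, cfg, 0), cfg, 0)
        np.testing.assert_allclose(twice.channels["t2"], stack.channels["t2"])

    def test_disabled_config_is_identity(self, stack):
        cfg = sf.AugmentConfig(p_flip_h=0, p_flip_v=0, max_rotation_deg=0,
                               intensity_scale_range=(1, 1),
                               noise_sigma_range=(0, 0))
        out = sf.augment(stack, cfg, 7)
        np.testing.assert_allclose(out.channels["t2"], stack.channels["t2"])
        assert out.label == stack.label

    def test_noise_sigma_moment(self, rng):
        base = sf.SliceStack(
            channels={"t2": rng.random((256, 256)) * 0.8 + 0.1},
            label="x", case_id="x")
        cfg = sf.AugmentConfig(p_flip_h=0, p_flip_v=0, max_rotation_deg=0,
                               intensity_scale_range=(1, 1),
                               noise_sigma_range=(0.05, 0.05))
        out = sf.augment(base, cfg, 1)
        diff = (out.channels["t2"] - base.channels["t2"])[10:-10, 10:-10]
        assert diff.std() == pytest.approx(0.05, rel=0.10)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sf.AugmentConfig(p_flip_h=1.5)
        with pytest.raises(ValueError):
            sf.AugmentConfig(noise_sigma_range=(0.1, 0.05))
        with pytest.raises(ValueError):
            sf.AugmentConfig(max_rotation_deg=-1)


class TestFeatureFixture:
    def test_chance_level_at_zero_effect(self):
        """With no signal, a nearest-centroid rule fitted on half the cases
        scores the other half at chance over 20 repeats (within 3 sd)."""
        accs = []
        for rep in range(20):
            fx = sf.make_feature_fixture(40, 3, 4, 4, effect_size=0.0,
                                         seed=rep)
            tr = np.concatenate([np.flatnonzero(fx.y == c)[:20]
                                 for c in range(3)])
            te = np.setdiff1d(np.arange(120), tr)
            centroids = np.stack([fx.X[tr][fx.y[tr] == c, :4].mean(axis=0)
                                  for c in range(3)])
            d = ((fx.X[te][:, None, :4] - centroids[None]) ** 2).sum(axis=2)
            accs.append(np.mean(d.argmin(axis=1) == fx.y[te]))
        se = np.sqrt((1 / 3) * (2 / 3) / 60) / np.sqrt(20)
        assert abs(np.mean(accs) - 1 / 3) < 3 * se

    def test_informative_index_bookkeeping(self):
        fx = sf.make_feature_fixture(2, 2, 1, 0, effect_size=1.0, seed=0)
        assert fx.informative_idx == {0}
        assert fx.X.shape == (4, 1)

    def test_strong_effect_is_centroid_separable(self):
        fx = sf.make_feature_fixture(30, 3, 3, 0, effect_size=6.0, seed=1)
        centroids = np.stack([fx.X[fx.y == c].mean(axis=0) for c in range(3)])
        d = ((fx.X[:, None, :] - centroids[None]) ** 2).sum(axis=2)
        assert np.mean(d.argmin(axis=1) == fx.y) == 1.0

    def test_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            sf.make_feature_fixture(5, 2, 1, 1, effect_size=-0.5)
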