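"""Object pipeline: detection, cargo sampling, offset null, classification."""

import numpy as np
import pytest
from scipy import ndimage

from vesiflux import scenes, vesicles
from vesiflux.scenes import ImageStack
from tests.conftest import clean_spec


def _stack(defining, cargo=None, voxel=(150.0, 25.0, 25.0)):
    channels = {"streptavidin": np.asarray(defining, dtype=float)}
    channels["transferrin"] = (
        np.asarray(cargo, dtype=float) if cargo is not None
        else np.zeros_like(channels["streptavidin"])
    )
    return ImageStack(channels=channels, voxel_size=voxel)


def _random_blob_stack(rng, amplitude, n_blobs=8, shape=(10, 64, 64)):
    """Constant-amplitude random blobs: foreground = amplitude, background 0."""
    img = np.zeros(shape)
    for _ in range(n_blobs):
        c = (rng.integers(2, shape[0] - 2), rng.integers(5, shape[1] - 5),
             rng.integers(5, shape[2] - 5))
        dz, dy, dx = rng.integers(-1, 2, 20), rng.integers(-3, 4, 20), rng.integers(-3, 4, 20)
        img[np.clip(c[0] + dz, 0, shape[0] - 1),
            np.clip(c[1] + dy, 0, shape[1] - 1),
            np.clip(c[2] + dx, 0, shape[2] - 1)] = amplitude
    return img


class TestDetectVesicles:
    def test_blank_stack_empty_list(self):
        stack = _stack(np.zeros((8, 64, 64)))
        assert vesicles.detect_vesicles(
            stack, "streptavidin", vesicles.DetectionSpec(seed_threshold=10.0)
        ) == []

    def test_single_noise_free_vesicle_recovered(self):
        spec = clean_spec(n_vesicles=1)
        stack, truth = scenes.generate_scene(spec)
        det = vesicles.DetectionSpec(seed_threshold=1.0, min_voxels=1)
        objs = vesicles.detect_vesicles(stack, spec.defining_channel, det)
        assert len(objs) == 1
        true_c = truth.records[["z", "y", "x"]].iloc[0].to_numpy()
        assert np.all(np.abs(np.array(objs[0].centroid) - true_c) <= 1.0)
        st = objs[0].stats[spec.defining_channel]
        assert st.max >= st.mean
        assert st.sd >= 0

    def test_well_separated_vesicles_give_disjoint_objects(self):
        img = np.zeros((10, 60, 60))
        img[5, 15, 15] = 100.0
        img[5, 45, 45] = 80.0
        det = vesicles.DetectionSpec(seed_threshold=10.0, min_voxels=1,
                                     growing_tolerance=0.5)
        objs = vesicles.detect_vesicles(_stack(img), "streptavidin", det)
        assert len(objs) == 2
        sets = [set(map(tuple, o.voxels)) for o in objs]
        assert not sets[0] & sets[1]

    def test_oracle_equivalence_with_connected_components(self, rng):
        """On constant-amplitude noise-free blobs, region growing with the
        tolerance matched to the threshold equals thresholded connected
        components (the stated independent oracle)."""
        for _ in range(100):
            amplitude = float(rng.uniform(50, 500))
            threshold = float(rng.uniform(0.2, 0.9)) * amplitude
            img = _random_blob_stack(rng, amplitude,
                                     n_blobs=int(rng.integers(2, 10)))
            det = vesicles.DetectionSpec(
                seed_threshold=threshold, min_voxels=1, max_voxels=10_000,
                growing_tolerance=threshold / amplitude, connectivity=26,
                seed_footprint=(3, 3, 3),
            )
            objs = vesicles.detect_vesicles(_stack(img), "streptavidin", det)
            labels, n_cc = ndimage.label(img > threshold,
                                         structure=np.ones((3, 3, 3)))
            assert len(objs) == n_cc
            got = {frozenset(map(tuple, o.voxels)) for o in objs}
            expected = {
                frozenset(map(tuple, np.argwhere(labels == k)))
                for k in range(1, n_cc + 1)
            }
            assert got == expected

    def test_2d_image_treated_as_single_slice(self):
        img = np.zeros((40, 40))
        img[20, 20] = 100.0
        det = vesicles.DetectionSpec(seed_threshold=10.0, min_voxels=1)
        objs = vesicles.detect_vesicles(_stack(img), "streptavidin", det)
        assert len(objs) == 1
        assert objs[0].voxels[0][0] == 0  # z index of the single slice

    def test_size_bounds_discard(self):
        img = np.zeros((8, 40, 40))
        img[4, 10:30, 10:30] = 100.0  # 400-voxel slab
        det = vesicles.DetectionSpec(seed_threshold=10.0, min_voxels=1, max_voxels=100)
        assert vesicles.detect_vesicles(_stack(img), "streptavidin", det) == []


class TestSampleCargo:
    def test_zero_cargo_gives_zero_means(self, small_scene):
        spec, stack, _ = small_scene
        objs = vesicles.detect_vesicles(stack, spec.defining_channel)
        zero = ImageStack(
            channels={spec.defining_channel: stack.channel(spec.defining_channel),
                      "t": np.zeros(stack.shape)},
            voxel_size=stack.voxel_size,
        )
        assert np.all(vesicles.sample_cargo(objs, zero, "t") == 0)

    def test_identity_channel_matches_defining_mean(self, small_scene):
        spec, stack, _ = small_scene
        objs = vesicles.detect_vesicles(stack, spec.defining_channel)
        means = vesicles.sample_cargo(objs, stack, spec.defining_channel)
        expected = np.array([o.stats[spec.defining_channel].mean for o in objs])
        assert np.allclose(means, expected)

    def test_handcrafted_object_mean(self):
        img = np.zeros((4, 8, 8))
        vox = np.array([[1, 2, 2], [1, 2, 3], [1, 3, 2], [2, 2, 2], [2, 2, 3]])
        vals = [10.0, 20.0, 30.0, 40.0, 50.0]
        for (z, y, x), v in zip(vox, vals):
            img[z, y, x] = v
        obj = vesicles.VesicleObject(0, vox, (1.4, 2.2, 2.4), {})
        means = vesicles.sample_cargo([obj], _stack(np.zeros((4, 8, 8)), img),
                                      "transferrin")
        assert means[0] == pytest.approx(30.0)


class TestOffsetNull:
    def _objects_from_values(self, values):
        """One single-voxel object per value, spaced in y, cargo at x+20."""
        n = len(values)
        cargo = np.zeros((3, n + 2, 40))
        objs = []
        for i, v in enumerate(values):
            cargo[1, i + 1, 25] = v  # x=5+20
            objs.append(vesicles.VesicleObject(i, np.array([[1, i + 1, 5]]),
                                               (1.0, i + 1.0, 5.0), {}))
        return objs, _stack(np.zeros_like(cargo), cargo)

    def test_rank_interpolation_oracle(self):
        objs, stack = self._objects_from_values(np.arange(1.0, 101.0))
        null = vesicles.build_offset_null(objs, stack, "transferrin")
        assert null.cutoff == pytest.approx(95.05)

    def test_matches_sort_and_interpolate_oracle_random(self, rng):
        vals = rng.gamma(2.0, 10.0, 1000)
        objs, stack = self._objects_from_values(vals)
        null = vesicles.build_offset_null(objs, stack, "transferrin")
        # independent oracle: sort and linearly interpolate between ranks
        s = np.sort(vals)
        h = 0.95 * (len(s) - 1)
        lo, hi = int(np.floor(h)), int(np.ceil(h))
        expected = s[lo] + (h - lo) * (s[hi] - s[lo])
        assert null.cutoff == pytest.approx(expected, rel=1e-12)

    def test_all_zero_cargo_gives_zero_cutoff(self):
        objs, stack = self._objects_from_values(np.zeros(30))
        null = vesicles.build_offset_null(objs, stack, "transferrin")
        assert null.cutoff == 0.0
        assert np.all(null.background_intensities == 0)

    def test_constant_background_cutoff_is_that_constant(self):
        objs, stack = self._objects_from_values(np.full(25, 3.5))
        assert vesicles.build_offset_null(objs, stack, "transferrin").cutoff == 3.5

    def test_objects_leaving_image_excluded(self):
        cargo = np.zeros((3, 10, 30))
        objs = [
            vesicles.VesicleObject(0, np.array([[1, 5, 5]]), (1, 5, 5), {}),
            vesicles.VesicleObject(1, np.array([[1, 5, 15]]), (1, 5, 15), {}),
        ]
        stack = _stack(np.zeros_like(cargo), cargo)
        with pytest.raises(ValueError, match="retained"):
            vesicles.build_offset_null(objs, stack, "transferrin", min_retained=2)
        null = vesicles.build_offset_null(objs, stack, "transferrin", min_retained=1)
        assert null.retained_ids == (0,)  # x=15+20 leaves the 30-wide image

    def test_exclusion_monotone_in_offset(self, rng):
        vals = rng.random(200)
        objs, stack = self._objects_from_values(vals)
        prev = None
        for off in (1, 5, 10, 19):
            n = vesicles.build_offset_null(
                objs, stack, "transferrin", offset_voxels=off, min_retained=1
            ).n_retained
            if prev is not None:
                assert n <= prev
            prev = n


class TestClassifyCargo:
    def test_all_above_cutoff(self):
        null = vesicles.NullDistribution(20, np.zeros(30), cutoff=1.0)
        cls = vesicles.classify_cargo(np.full(10, 5.0), null)
        assert cls.fraction_positive == 1.0

    def test_tie_is_negative(self):
        null = vesicles.NullDistribution(20, np.zeros(30), cutoff=2.0)
        cls = vesicles.classify_cargo(np.array([2.0, 2.0001]), null)
        assert cls.calls.tolist() == [False, True]

    def test_null_draws_classified_at_five_percent(self, rng):
        bg = rng.normal(0, 1, 10_000)
        null = vesicles.NullDistribution(
            20, bg, cutoff=float(np.percentile(bg, 95))
        )
        fresh = rng.normal(0, 1, 10_000)
        frac = vesicles.classify_cargo(fresh, null).fraction_positive
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 10_000)


class TestGaussianFit:
    def test_recovers_normal_parameters(self, rng):
        loads = rng.normal(500.0, 50.0, 5000)
        fit = vesicles.fit_gaussian_loads(loads)
        assert fit.converged
        assert fit.mu == pytest.approx(500.0, abs=5.0)
        assert fit.sigma == pytest.approx(50.0, abs=5.0)

    def test_symmetric_loads_mu_near_sample_mean(self, rng):
        loads = rng.laplace(50.0, 10.0, 2000)
        fit = vesicles.fit_gaussian_loads(loads, n_bins=20)
        bin_width = np.ptp(loads) / 20
        assert abs(fit.mu - loads.mean()) < bin_width

    def test_degenerate_identical_loads_flagged(self):
        fit = vesicles.fit_gaussian_loads(np.full(100, 7.0))
        assert not fit.converged
        assert fit.mu == 7.0

    def test_too_few_loads_rejected(self):
        with pytest.raises(ValueError):
            vesicles.fit_gaussian_loads(np.arange(10.0))


class TestRankDiagnostic:
    def _objects_with_defining(self, values):
        return [
            vesicles.VesicleObject(
                i, np.array([[0, 0, i]]), (0, 0, i),
                {"streptavidin": vesicles.ChannelStats(v, v, v, 0.0)},
            )
            for i, v in enumerate(values)
        ]

    def test_independent_calls_no_association(self, rng):
        n = 2000
        defining = rng.normal(100, 10, n)
        objs = self._objects_with_defining(defining)
        calls = rng.random(n) > 0.05
        cls = vesicles.CargoClassification(calls=calls, cutoff=0.0)
        table, rho, _ = vesicles.intensity_rank_diagnostic(
            objs, rng.normal(50, 5, n), cls, "streptavidin"
        )
        assert abs(rho) < 3 / np.sqrt(n)
        assert table["defining_mean"].is_monotonic_decreasing

    def test_dim_negative_calls_give_strong_association(self, rng):
        n = 500
        defining = np.sort(rng.normal(100, 10, n))
        objs = self._objects_with_defining(defining)
        calls = np.ones(n, bool)
        calls[:50] = False  # the 50 dimmest are negative
        cls = vesicles.CargoClassification(calls=calls, cutoff=0.0)
        _, rho, p = vesicles.intensity_rank_diagnostic(
            objs, defining, cls, "streptavidin"
        )
        assert rho < -0.3  # dim <-> negative
        assert p < 1e-6

    def test_constant_defining_intensity_flagged(self):
        objs = self._objects_with_defining(np.full(30, 5.0))
        cls = vesicles.CargoClassification(
            calls=np.arange(30) % 2 == 0, cutoff=0.0
        )
        with pytest.warns(UserWarning, match="constant"):
            _, rho, _ = vesicles.intensity_rank_diagnostic(
                objs, np.ones(30), cls, "streptavidin"
            )
        assert np.isnan(rho)


class TestCompareConditions:
    def _cls(self, n, n_neg):
        calls = np.ones(n, bool)
        calls[:n_neg] = False
        return vesicles.CargoClassification(calls=calls, cutoff=0.0)

    def test_identical_inputs_zero_difference(self):
        a = self._cls(1000, 50)
        rep = vesicles.compare_conditions(a, a)
        assert rep["difference"] == 0.0
        assert rep["ci_low"] <= 0.0 <= rep["ci_high"]

    def test_matches_closed_form_wald_interval(self):
        a = self._cls(2000, 80)   # 4% negative
        b = self._cls(2000, 100)  # 5% negative
        rep = vesicles.compare_conditions(a, b)
        pa, pb = 0.04, 0.05
        se = np.sqrt(pa * (1 - pa) / 2000 + pb * (1 - pb) / 2000)
        from scipy import stats

        z = stats.norm.ppf(0.975)
        assert rep["difference"] == pytest.approx(pa - pb)
        assert rep["ci_low"] == pytest.approx(pa - pb - z * se, abs=1e-9)
        assert rep["ci_high"] == pytest.approx(pa - pb + z * se, abs=1e-9)

    def test_empty_classification_rejected(self):
        a = self._cls(100, 5)
        with pytest.raises(ValueError):
            vesicles.compare_conditions(
                a, vesicles.CargoClassification(calls=np.array([], bool), cutoff=0.0)
            )
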