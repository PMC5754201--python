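import numpy as np
import pytest

from nichechart.morphometrics import (
    ThresholdPolicy,
    count_nuclei,
    marker_positive_fraction,
    membrane_intensity,
    membrane_to_nsc_ratio,
    neuronal_volume,
    normalize_volumes,
    read_manual_counts,
)
from nichechart.stack_io import ImageStack, RegionOfInterest
from nichechart.synthetic import SceneConfig, generate_scene

ROLES = {"glia": 0, "nsc": 1, "neuron": 2}


def uniform_stack(value, shape=(5, 4, 4, 3)):
    return ImageStack(np.full(shape, float(value)), dict(ROLES))


class TestThresholdPolicy:
    def test_absolute(self):
        assert ThresholdPolicy("glia", "absolute", 3.5).resolve(uniform_stack(1)) == 3.5

    def test_quantile_matches_numpy(self, random_stack):
        stack = random_stack()
        policy = ThresholdPolicy("glia", "quantile", 0.9)
        assert policy.resolve(stack) == pytest.approx(
            np.quantile(stack.voxels[..., 0], 0.9)
        )

    def test_otsu_separates_bimodal_channel(self):
        voxels = np.zeros((6, 8, 8, 3))
        voxels[:3, :, :, 0] = 100.0
        stack = ImageStack(voxels, dict(ROLES))
        thr = ThresholdPolicy("glia", "otsu").resolve(stack)
        assert 0.0 < thr < 100.0

    @pytest.mark.parametrize("mode,value", [("quantile", 1.5), ("nearest", 0.5)])
    def test_invalid_policy_rejected(self, mode, value):
        with pytest.raises(ValueError):
            ThresholdPolicy("glia", mode, value)


class TestMembraneIntensity:
    def test_all_below_threshold_gives_zero(self):
        policy = ThresholdPolicy("glia", "absolute", 99.0)
        assert membrane_intensity(uniform_stack(1.0), policy=policy) == 0.0

    def test_uniform_stack_definition(self):
        stack = uniform_stack(10.0, shape=(5, 4, 4, 3))
        policy = ThresholdPolicy("glia", "absolute", 5.0)
        assert membrane_intensity(stack, policy=policy) == 10.0 * 5 * 4 * 4

    def test_matches_brute_force_masked_sum(self, random_stack):
        stack = random_stack(shape=(8, 10, 10, 3))
        roi = RegionOfInterest(1, 9, 2, 10)
        policy = ThresholdPolicy("glia", "absolute", 40.0)
        got = membrane_intensity(stack, roi, policy)
        expected = 0.0
        for z in range(8):
            for y in range(1, 9):
                for x in range(2, 10):
                    v = stack.voxels[z, y, x, 0]
                    if v >= 40.0:
                        expected += v
        assert got == pytest.approx(expected, rel=1e-12)

    def test_count_statistic_variant(self):
        stack = uniform_stack(10.0)
        policy = ThresholdPolicy("glia", "absolute", 5.0)
        assert membrane_intensity(stack, policy=policy, statistic="count") == 5 * 4 * 4

    def test_threshold_monotonicity(self, random_stack):
        """Raising the threshold never increases intensity or volume."""
        stack = random_stack(shape=(6, 8, 8, 3))
        thresholds = np.linspace(0, 110, 12)
        intensities = [
            membrane_intensity(stack, policy=ThresholdPolicy("glia", "absolute", t))
            for t in thresholds
        ]
        volumes = [
            neuronal_volume(stack, policy=ThresholdPolicy("neuron", "absolute", t))
            for t in thresholds
        ]
        assert all(a >= b for a, b in zip(intensities, intensities[1:]))
        assert all(a >= b for a, b in zip(volumes, volumes[1:]))

    def test_homogeneity_with_scaled_threshold(self, random_stack):
        """Scaling intensities and threshold together scales the total by k."""
        stack = random_stack(shape=(6, 8, 8, 3))
        k = 3.7
        scaled = stack.with_voxels(stack.voxels * k)
        base = membrane_intensity(stack, policy=ThresholdPolicy("glia", "absolute", 40.0))
        up = membrane_intensity(scaled, policy=ThresholdPolicy("glia", "absolute", 40.0 * k))
        assert up == pytest.approx(k * base, rel=1e-12)


class TestRatio:
    def test_arithmetic(self):
        assert membrane_to_nsc_ratio(1000.0, 10) == 100.0

    def test_doubling_count_halves_ratio(self):
        assert membrane_to_nsc_ratio(900.0, 6) == 2 * membrane_to_nsc_ratio(900.0, 12)

    def test_zero_count_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            membrane_to_nsc_ratio(100.0, 0)

    def test_generator_known_intensity_over_count(self, fed_scene):
        """Ratio from the clean render equals generator intensity / true count."""
        _, truth, config = fed_scene
        from dataclasses import replace

        clean, _ = generate_scene(replace(config, noise_sd=0.0, blur_sigma=0.0))
        policy = ThresholdPolicy("glia", "absolute", truth.glia_threshold)
        intensity = membrane_intensity(clean, policy=policy)
        ratio = membrane_to_nsc_ratio(intensity, truth.nsc_count)
        assert ratio == pytest.approx(
            truth.glia_suprathreshold_intensity / truth.nsc_count, rel=1e-12
        )


class TestCountNuclei:
    POLICY = ThresholdPolicy("nsc", "absolute", 0.5)

    def test_empty_channel_counts_zero(self):
        voxels = np.zeros((6, 8, 8, 3))
        voxels[..., 0] = 1.0
        stack = ImageStack(voxels, dict(ROLES))
        assert count_nuclei(stack, "nsc", self.POLICY) == 0

    def test_non_touching_spheres_counted_exactly(self, fed_scene):
        """Clean renders yield one component per placed nucleus."""
        _, truth, config = fed_scene
        from dataclasses import replace

        clean, _ = generate_scene(replace(config, noise_sd=0.0, blur_sigma=0.0))
        assert count_nuclei(clean, "nsc", self.POLICY, min_volume=10) == truth.nsc_count
        assert (
            count_nuclei(clean, "neuron", ThresholdPolicy("neuron", "absolute", 0.5), 10)
            == truth.neuron_count
        )

    def test_touching_spheres_merge_into_one(self):
        """Overlapping nuclei merge — the documented connected-components limit."""
        config = SceneConfig(
            shape=(24, 64, 64),
            nsc_centers=[(12.0, 30.0, 30.0), (12.0, 30.0, 35.0)],
            nsc_radius=4.0,
            neuron_depth_band=(15.0, 20.0),
            neuron_count=0,
            noise_sd=0.0,
            blur_sigma=0.0,
        )
        stack, truth = generate_scene(config)
        assert truth.nsc_count == 2
        assert count_nuclei(stack, "nsc", self.POLICY) == 1

    def test_min_volume_rejects_speckle(self):
        voxels = np.zeros((6, 8, 8, 3))
        voxels[2, 2, 2, 1] = 1.0  # single-voxel speckle
        voxels[3:5, 4:7, 4:7, 1] = 1.0  # 18-voxel blob
        stack = ImageStack(voxels, dict(ROLES))
        assert count_nuclei(stack, "nsc", self.POLICY, min_volume=1) == 2
        assert count_nuclei(stack, "nsc", self.POLICY, min_volume=5) == 1

    def test_diagonal_voxels_are_26_connected(self):
        voxels = np.zeros((6, 8, 8, 3))
        voxels[2, 2, 2, 1] = 1.0
        voxels[3, 3, 3, 1] = 1.0  # touches only at a corner
        stack = ImageStack(voxels, dict(ROLES))
        assert count_nuclei(stack, "nsc", self.POLICY) == 1


class TestVolumes:
    def test_solid_block_volume(self):
        voxels = np.zeros((12, 12, 12, 3))
        voxels[1:11, 1:11, 1:11, 2] = 8.0
        stack = ImageStack(voxels, dict(ROLES))
        policy = ThresholdPolicy("neuron", "absolute", 1.0)
        assert neuronal_volume(stack, policy=policy) == 1000
        assert neuronal_volume(stack, policy=policy, voxel_volume=0.5) == 500.0

    def test_matches_brute_force_masked_count(self, random_stack):
        stack = random_stack(shape=(6, 7, 7, 3))
        policy = ThresholdPolicy("neuron", "absolute", 60.0)
        expected = int((stack.voxels[..., 2] >= 60.0).sum())
        assert neuronal_volume(stack, policy=policy) == expected

    def test_normalize_volumes_centres_control_at_one(self):
        out = normalize_volumes([2.0, 4.0, 3.0], control_values=[2.0, 4.0])
        np.testing.assert_allclose(out, [2 / 3, 4 / 3, 1.0])
        assert np.mean(normalize_volumes([2.0, 4.0], [2.0, 4.0])) == pytest.approx(1.0)

    def test_normalize_volumes_preserves_order_and_ratios(self, rng):
        values = rng.uniform(1, 50, size=10)
        out = normalize_volumes(values, control_values=values[:4])
        np.testing.assert_allclose(out[1] / out[0], values[1] / values[0])
        assert list(np.argsort(out)) == list(np.argsort(values))

    def test_degenerate_control_rejected(self):
        with pytest.raises(ValueError):
            normalize_volumes([1.0], control_values=[])
        with pytest.raises(ValueError):
            normalize_volumes([1.0], control_values=[0.0, 0.0])


class TestMarkerFraction:
    @pytest.mark.parametrize("pos,total,expected", [(0, 50, 0.0), (50, 50, 1.0), (7, 28, 0.25)])
    def test_fraction(self, pos, total, expected):
        assert marker_positive_fraction(pos, total) == expected

    @pytest.mark.parametrize("pos,total", [(1, 0), (5, 4), (-1, 10)])
    def test_invalid_inputs(self, pos, total):
        with pytest.raises(ValueError):
            marker_positive_fraction(pos, total)


def test_manual_counts_round_trip(tmp_path):
    path = tmp_path / "counts.csv"
    path.write_text("specimen_id,marker,count\ns1,nsc,42\ns1,ph3,5\n")
    df = read_manual_counts(path)
    assert df.loc[df["marker"] == "nsc", "count"].iloc[0] == 42
    bad = tmp_path / "bad.csv"
    bad.write_text("specimen_id,n\ns1,2\n")
    with pytest.raises(ValueError):
        read_manual_counts(bad)
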