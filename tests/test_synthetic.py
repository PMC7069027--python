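"""Synthetic canopy scenes: color contracts, geometry, determinism."""

import numpy as np
import pytest

from spikecount.features import LEAF, SOIL, SPIKE, image_features
from spikecount.synthetic import (
    ColorModel,
    PlacementError,
    SceneConfig,
    default_color_models,
    generate_dataset,
    generate_scene,
    sample_pixels,
)

N_SAMPLE = 100_000


def _index_stats(model, rng, n=N_SAMPLE):
    """Empirical mean/SD of each color index over sampled pixels."""
    pixels = sample_pixels(model, n, rng).reshape(-1, 1, 3)
    fm = image_features(pixels)
    return {
        name: (float(fm.plane(name).mean()), float(fm.plane(name).std()))
        for name in ("Eg", "Dgr", "Dgb")
    }


def _dgr_separation(models, rng):
    leaf = _index_stats(models["leaf"], rng)["Dgr"]
    spike = _index_stats(models["spike"], rng)["Dgr"]
    pooled = np.sqrt((leaf[1] ** 2 + spike[1] ** 2) / 2.0)
    return abs(leaf[0] - spike[0]) / pooled


class TestColorModels:
    def test_unknown_treatment_rejected(self):
        with pytest.raises(ValueError, match="treatment"):
            default_color_models("N5")

    @pytest.mark.parametrize("treatment", ["N1", "N2", "N3", "N4"])
    def test_soil_excess_green_negative(self, treatment, rng):
        models = default_color_models(treatment)
        eg_mean, _ = _index_stats(models["soil"], rng)["Eg"]
        assert eg_mean < 0.0

    @pytest.mark.parametrize("treatment", ["N1", "N2", "N3", "N4"])
    def test_spike_excess_green_positive(self, treatment, rng):
        models = default_color_models(treatment)
        eg_mean, _ = _index_stats(models["spike"], rng)["Eg"]
        assert eg_mean > 0.0

    def test_high_nitrogen_dgr_contract(self, rng):
        """Well-fertilized canopy: leaf and spike Dgr far apart and tight."""
        models = default_color_models("N4")
        leaf = _index_stats(models["leaf"], rng)["Dgr"]
        spike = _index_stats(models["spike"], rng)["Dgr"]
        assert spike[0] == pytest.approx(0.05, abs=0.02)
        assert leaf[0] == pytest.approx(0.25, abs=0.02)
        pooled = np.sqrt((leaf[1] ** 2 + spike[1] ** 2) / 2.0)
        assert pooled <= 0.05
        assert abs(leaf[0] - spike[0]) / pooled >= 2.0

    def test_separation_grades_with_nitrogen(self, rng):
        """Leaf-vs-spike contrast decays monotonically toward no fertilizer."""
        seps = {
            t: _dgr_separation(default_color_models(t), rng)
            for t in ("N1", "N2", "N3", "N4")
        }
        assert seps["N4"] >= seps["N3"] >= seps["N2"] >= seps["N1"]
        assert seps["N4"] >= 2.0 and seps["N3"] >= 2.0
        assert seps["N2"] >= 1.0
        assert seps["N1"] < 1.0

    def test_color_model_validation(self):
        with pytest.raises(ValueError, match="mean_rgb"):
            ColorModel("soil", (300, 0, 0), (1, 1, 1))
        with pytest.raises(ValueError, match="sd_rgb"):
            ColorModel("soil", (10, 10, 10), (-1, 1, 1))

    def test_sampling_stays_in_range(self, rng):
        model = ColorModel("spike", (250, 4, 128), (30, 30, 30))
        pixels = sample_pixels(model, 50_000, rng)
        assert pixels.min() >= 0 and pixels.max() <= 255


class TestGenerateScene:
    def test_empty_scene_is_all_soil(self):
        config = SceneConfig(
            image_height=200, image_width=260, n_spikes=0, n_leaves=0, seed=0
        )
        image, truth = generate_scene(config)
        assert image.shape == (200, 260, 3)
        assert truth.true_count == 0
        assert np.all(truth.class_map == SOIL)

    def test_bit_exact_reproducibility(self, small_scene):
        config, image, truth = small_scene
        image2, truth2 = generate_scene(config)
        assert image.tobytes() == image2.tobytes()
        assert np.array_equal(truth.class_map, truth2.class_map)

    def test_disjoint_masks_without_overlap(self, small_scene):
        config, _, truth = small_scene
        assert config.overlap_probability == 0.0
        assert truth.overlap_groups == []
        total = np.zeros(truth.class_map.shape, dtype=int)
        for mask in truth.instance_masks:
            total += mask
        assert total.max() <= 1  # pairwise disjoint

    def test_class_map_partition(self, small_scene):
        _, _, truth = small_scene
        assert set(np.unique(truth.class_map)) <= {SOIL, LEAF, SPIKE}
        union = np.zeros(truth.class_map.shape, dtype=bool)
        for mask in truth.instance_masks:
            union |= mask
        assert np.array_equal(union, truth.class_map == SPIKE)
        assert truth.true_count == len(truth.instance_masks)

    def test_overlap_groups_found_by_intersection_oracle(self):
        config = SceneConfig(
            image_height=972,
            image_width=1296,
            n_spikes=30,
            overlap_probability=0.3,
            n_leaves=0,
            seed=1,
        )
        _, truth = generate_scene(config)
        assert truth.true_count == 30
        assert len(truth.overlap_groups) > 0
        # oracle: recompute touching pairs by pairwise mask intersection
        masks = truth.instance_masks
        touching = {
            frozenset((i, j))
            for i in range(len(masks))
            for j in range(i + 1, len(masks))
            if (masks[i] & masks[j]).any()
        }
        grouped = set()
        for group in truth.overlap_groups:
            members = sorted(group)
            assert len(members) >= 2
            assert any(
                frozenset((a, b)) in touching for a in members for b in members if a < b
            )
            grouped |= set(members)
        assert {i for pair in touching for i in pair} == grouped

    def test_crowded_scene_fails_explicitly(self):
        config = SceneConfig(
            image_height=250,
            image_width=250,
            n_spikes=40,
            n_leaves=0,
            overlap_probability=0.0,
            max_retries=30,
            seed=0,
        )
        with pytest.raises(PlacementError, match="spike"):
            generate_scene(config)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="range"):
            SceneConfig(spike_length_range=(50.0, 20.0))
        with pytest.raises(ValueError, match="overlap_probability"):
            SceneConfig(overlap_probability=1.5)
        with pytest.raises(ValueError, match="treatment"):
            SceneConfig(nitrogen_like="N9")


class TestGenerateDataset:
    def _config(self, **kw):
        base = dict(
            image_height=300,
            image_width=400,
            n_spikes=4,
            n_leaves=4,
            spike_length_range=(60.0, 90.0),
            spike_width_range=(14.0, 20.0),
            leaf_length_range=(60.0, 120.0),
            leaf_width_range=(6.0, 10.0),
            overlap_probability=0.0,
            seed=0,
        )
        base.update(kw)
        return SceneConfig(**base)

    def test_deterministic_and_counts(self):
        a = generate_dataset(3, self._config(), base_seed=5)
        b = generate_dataset(3, self._config(), base_seed=5)
        for (img1, t1), (img2, t2) in zip(a, b):
            assert img1.tobytes() == img2.tobytes()
            assert t1.true_count == t2.true_count == 4

    def test_distinct_seeds_give_distinct_scenes(self):
        scenes = generate_dataset(2, self._config(), base_seed=9)
        assert scenes[0][0].tobytes() != scenes[1][0].tobytes()

    def test_spike_pixel_fraction_within_bounds(self):
        scenes = generate_dataset(4, self._config(), base_seed=3)
        area = 300 * 400
        # 4 spikes of at most 90 x 20 px (plus awns), at least ~60 x 14 px
        for _, truth in scenes:
            frac = (truth.class_map == SPIKE).sum() / area
            assert 4 * 0.5 * 60 * 14 / area < frac < 4 * 2.5 * 90 * 20 / area

    def test_requires_at_least_one_scene(self):
        with pytest.raises(ValueError, match="n_scenes"):
            generate_dataset(0, self._config(), base_seed=0)
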