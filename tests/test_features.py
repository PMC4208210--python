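import numpy as np
import pytest

import copalign as ca
from copalign import features
from copalign.errors import DataError
from copalign.signal_io import InsoleRecording


def _recording(pressures, mass=76.1):
    pressures = np.atleast_2d(np.asarray(pressures, dtype=float))
    return InsoleRecording(time_s=np.arange(len(pressures)) / 60.0,
                          pressure_kpa=pressures, body_mass_kg=mass)


class TestNormalizedForces:
    def test_pressure_times_area_gives_newtons(self, geometry):
        # 100 kPa on this layout's 175 mm^2 sensor = 17.5 N
        p = np.zeros((1, 99))
        p[0, 0] = 100.0
        out = features.pressures_to_normalized_forces(_recording(p, mass=80.0),
                                                      geometry)
        half_bw = 0.5 * 80.0 * 9.81
        assert np.isclose(out[0, 0], 17.5 / half_bw)

    def test_half_body_weight_normalizer(self, geometry):
        # a sensor carrying 392.4 N on an 80 kg participant normalizes to 1.0
        area = geometry.areas_mm2[0]
        p = np.zeros((1, 99))
        p[0, 0] = 392.4 * 1000.0 / area
        out = features.pressures_to_normalized_forces(_recording(p, mass=80.0),
                                                      geometry)
        assert np.isclose(out[0, 0], 1.0)

    def test_zero_pressures_zero_features(self, geometry):
        out = features.pressures_to_normalized_forces(_recording(np.zeros((3, 99))),
                                                      geometry)
        assert np.all(out == 0)

    def test_nonpositive_mass_rejected(self, geometry):
        with pytest.raises(DataError):
            features.pressures_to_normalized_forces(_recording(np.zeros((1, 99)),
                                                               mass=0.0), geometry)


class TestActiveRatio:
    @pytest.mark.parametrize("n_active,expected", [(33, 1 / 3), (0, 0.0), (99, 1.0)])
    def test_global_ratio(self, n_active, expected):
        p = np.zeros(99)
        p[:n_active] = 5.0
        assert np.isclose(features.active_ratio(p)[0], expected)

    def test_regional_denominator_is_region_size(self):
        p = np.zeros(99)
        subset = np.arange(12)
        p[:3] = 1.0
        assert np.isclose(features.active_ratio(p, subset)[0], 0.25)

    def test_strictly_positive_activity(self):
        p = np.zeros(99)
        p[0] = 1e-12     # any positive value counts ...
        assert features.active_ratio(p)[0] > 0
        assert features.active_ratio(np.zeros(99))[0] == 0   # ... zero does not


class TestPCA:
    def test_rank_one_data_keeps_one_component(self):
        rng = np.random.default_rng(0)
        pattern = rng.normal(size=99)
        x = np.outer(rng.normal(size=200), pattern)
        x += rng.normal(scale=1e-6, size=x.shape)
        model = features.fit_pca(x)
        assert model.k == 1

    def test_even_two_way_variance_split_keeps_both(self):
        rng = np.random.default_rng(1)
        a = np.zeros(99); a[0] = 1.0
        b = np.zeros(99); b[1] = 1.0
        coeff = rng.normal(size=(400, 2))
        x = coeff @ np.vstack([a, b])
        model = features.fit_pca(x)
        assert model.k == 2          # 0.5 < 0.9 < 1.0

    def test_projecting_training_mean_gives_zero_scores(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 99))
        model = features.fit_pca(x)
        scores = features.project_pca(model, x.mean(axis=0, keepdims=True))
        np.testing.assert_allclose(scores, 0, atol=1e-9)

    def test_zero_variance_training_rejected(self):
        with pytest.raises(DataError):
            features.fit_pca(np.ones((50, 99)))


class TestPartition:
    def test_every_sensor_assigned_all_regions_nonempty(self, partition):
        assert len(partition.labels) == 99
        for region in features.REGIONS:
            assert len(partition.indices(region)) > 0

    def test_file_round_trip(self, tmp_path, partition):
        path = tmp_path / "partition.csv"
        features.write_partition(path, partition)
        back = features.read_partition(path)
        assert list(back.labels) == list(partition.labels)

    def test_empty_region_rejected(self, partition):
        labels = partition.labels.copy()
        labels[labels == "toes"] = "forefoot_2"
        with pytest.raises(DataError, match="toes"):
            features.RegionPartition(labels=labels)


@pytest.fixture(scope="module")
def loaded_recording(geometry):
    cfg = ca.SyntheticConfig(seed=21)
    return ca.generate_trial(cfg, geometry).insole


class TestBuildFeatures:
    @pytest.mark.parametrize("variant,width", [(2, 4), (3, 11), (4, 18)])
    def test_fixed_variant_widths(self, loaded_recording, geometry, partition,
                                  variant, width):
        fm = features.build_features(loaded_recording, geometry, partition, variant)
        assert fm.width == width
        assert len(fm.names) == width

    def test_variant1_width_tracks_retained_components(self, loaded_recording,
                                                       geometry, partition):
        forces = features.pressures_to_normalized_forces(loaded_recording, geometry)
        model = features.fit_pca(forces[loaded_recording.pressure_kpa.sum(1) > 0])
        fm = features.build_features(loaded_recording, geometry, partition, 1, model)
        assert fm.width == model.k + 2

    def test_unknown_variant_rejected(self, loaded_recording, geometry, partition):
        with pytest.raises(DataError):
            features.build_features(loaded_recording, geometry, partition, 5)

    def test_variant1_requires_pca(self, loaded_recording, geometry, partition):
        with pytest.raises(DataError, match="PCA"):
            features.build_features(loaded_recording, geometry, partition, 1)

    def test_regional_forces_conserve_total(self, loaded_recording, geometry,
                                            partition):
        fm = features.build_features(loaded_recording, geometry, partition, 4)
        regional = fm.values[:, :8].sum(axis=1)
        total = features.pressures_to_normalized_forces(
            loaded_recording, geometry).sum(axis=1)
        np.testing.assert_allclose(regional, total, atol=1e-9)

    def test_region_weighted_ratios_reproduce_global(self, loaded_recording,
                                                     geometry, partition):
        fm = features.build_features(loaded_recording, geometry, partition, 3)
        weights = np.array([len(partition.indices(r)) for r in features.REGIONS])
        weighted = fm.values[:, 1:9] @ weights / 99.0
        global_ratio = features.active_ratio(loaded_recording.pressure_kpa)
        np.testing.assert_allclose(weighted, global_ratio, atol=1e-9)

    def test_ratio_bounds_and_force_signs(self, loaded_recording, geometry,
                                          partition):
        fm = features.build_features(loaded_recording, geometry, partition, 4)
        forces, ratios = fm.values[:, :8], fm.values[:, 8:16]
        assert np.all(forces >= 0)
        assert np.all((ratios >= 0) & (ratios <= 1))

    def test_extraction_deterministic(self, loaded_recording, geometry, partition):
        a = features.build_features(loaded_recording, geometry, partition, 3)
        b = features.build_features(loaded_recording, geometry, partition, 3)
        np.testing.assert_array_equal(a.values, b.values)
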