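import numpy as np
import pytest

from ecaleaf.augment import (
    ENVIRONMENT_NAMES,
    Environment,
    ImageRecord,
    apply_environment,
    default_environments,
    expand_dataset,
    read_image_tree,
    split_per_class,
)


@pytest.fixture
def leaf_image(rng):
    return rng.integers(0, 256, (24, 24, 3), dtype=np.uint8)


def _dummy_records(per_class: dict[str, int]):
    return [ImageRecord(f"{cls}/{cls}_{i}", cls)
            for cls, n in per_class.items() for i in range(n)]


class TestEnvironments:
    def test_fourteen_environments(self):
        assert len(ENVIRONMENT_NAMES) == 14
        assert ENVIRONMENT_NAMES[0] == "original"
        assert len(default_environments()) == 14

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown environment"):
            Environment("posterize")

    @pytest.mark.parametrize("name", ENVIRONMENT_NAMES)
    def test_shape_and_dtype_preserved(self, name, leaf_image):
        out = apply_environment(leaf_image, name)
        assert out.shape == leaf_image.shape
        assert out.dtype == np.uint8

    @pytest.mark.parametrize("name", ["horizontal_flip", "vertical_flip"])
    def test_flip_involution(self, name, leaf_image):
        twice = apply_environment(apply_environment(leaf_image, name), name)
        np.testing.assert_array_equal(twice, leaf_image)

    @pytest.mark.parametrize("name", ["horizontal_flip", "vertical_flip"])
    def test_flip_preserves_pixel_multiset(self, name, leaf_image):
        out = apply_environment(leaf_image, name)
        assert sorted(out.reshape(-1, 3).tolist()) == sorted(
            leaf_image.reshape(-1, 3).tolist()
        )

    def test_brightness_factor_algebra(self):
        # reciprocal factors on an unclipped gradient invert within quantisation
        grad = np.tile(np.linspace(60, 160, 32).astype(np.uint8)[None, :, None],
                       (32, 1, 3))
        up = apply_environment(grad, Environment("brightness_increase", {"factor": 1.5}))
        back = apply_environment(
            up, Environment("brightness_reduction", {"factor": 1 / 1.5})
        )
        assert np.abs(back.astype(int) - grad.astype(int)).max() <= 1

    def test_identity_limits(self):
        flat = np.full((16, 16, 3), 128, np.uint8)
        np.testing.assert_array_equal(
            apply_environment(flat, Environment("gamma", {"gamma": 1.0})), flat
        )
        np.testing.assert_array_equal(
            apply_environment(flat, Environment("clahe", {"clip_limit": 1.0})), flat
        )

    def test_determinism(self, leaf_image):
        for name in ("laplace", "clahe", "gamma"):
            a = apply_environment(leaf_image, name, seed=3)
            b = apply_environment(leaf_image, name, seed=3)
            np.testing.assert_array_equal(a, b)

    def test_zero_extent_rejected(self):
        with pytest.raises(ValueError):
            apply_environment(np.zeros((0, 4, 3), np.uint8), "original")


class TestExpansion:
    @pytest.mark.parametrize("n_sources,expected", [
        (6001, 84_014), (4802, 67_228), (775, 10_850), (1, 14),
    ])
    def test_fourteen_fold_multiplicity(self, n_sources, expected):
        records = [ImageRecord(f"c/{i}", "c") for i in range(n_sources)]
        assert len(expand_dataset(records)) == expected

    def test_per_class_counts_scale_by_fourteen(self):
        per_class = {"powdery_mildew": 968, "late_blight": 2335,
                     "leaf_mould": 1441, "healthy": 1257}
        dataset = expand_dataset(_dummy_records(per_class))
        assert dataset.per_class_counts() == {
            "powdery_mildew": 13_552, "late_blight": 32_690,
            "leaf_mould": 20_174, "healthy": 17_598,
        }
        assert len(dataset) == 84_014

    def test_single_source_covers_every_environment(self):
        dataset = expand_dataset([ImageRecord("c/0", "c")])
        assert sorted(r.environment for r in dataset.records) == sorted(ENVIRONMENT_NAMES)

    def test_each_source_appears_once_per_environment(self):
        dataset = expand_dataset([ImageRecord(f"c/{i}", "c") for i in range(5)])
        seen = {(r.source_id, r.environment) for r in dataset.records}
        assert len(seen) == len(dataset.records) == 70

    def test_record_ids_reproducible(self):
        records = [ImageRecord(f"c/{i}", "c") for i in range(3)]
        ids1 = [r.record_id for r in expand_dataset(records, seed=4).records]
        ids2 = [r.record_id for r in expand_dataset(records, seed=4).records]
        assert ids1 == ids2

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            dataset = expand_dataset([])
        assert len(dataset) == 0

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            expand_dataset([ImageRecord("a", "c"), ImageRecord("a", "c")])


class TestSplit:
    @pytest.mark.parametrize("n,train_n,test_n", [
        (968, 775, 193), (2335, 1868, 467), (1441, 1153, 288),
        (1257, 1006, 251), (10, 8, 2),
    ])
    def test_ceil_eighty_twenty(self, n, train_n, test_n):
        train, test = split_per_class(_dummy_records({"c": n}), 0.8, seed=0)
        assert (len(train), len(test)) == (train_n, test_n)

    def test_disjoint_and_exhaustive(self):
        records = _dummy_records({"a": 13, "b": 7})
        train, test = split_per_class(records, 0.8, seed=2)
        ids = {r.image_id for r in train} | {r.image_id for r in test}
        assert not ({r.image_id for r in train} & {r.image_id for r in test})
        assert ids == {r.image_id for r in records}

    def test_stratified_per_class(self):
        train, _ = split_per_class(_dummy_records({"a": 10, "b": 10}), 0.8, seed=0)
        assert sum(r.label == "a" for r in train) == 8
        assert sum(r.label == "b" for r in train) == 8

    def test_seed_reproducible_and_effective(self):
        records = _dummy_records({"a": 20})
        t1, _ = split_per_class(records, 0.8, seed=5)
        t2, _ = split_per_class(records, 0.8, seed=5)
        t3, _ = split_per_class(records, 0.8, seed=6)
        assert [r.image_id for r in t1] == [r.image_id for r in t2]
        assert {r.image_id for r in t1} != {r.image_id for r in t3}

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_per_class(_dummy_records({"a": 4}), 1.0, seed=0)


class TestMaterialisation:
    def test_tree_round_trip(self, tmp_path, rng):
        src = tmp_path / "src"
        for cls in ("healthy", "late_blight"):
            (src / cls).mkdir(parents=True)
            from PIL import Image

            Image.fromarray(
                rng.integers(0, 256, (16, 16, 3), dtype=np.uint8), "RGB"
            ).save(src / cls / "img0.png")
        records = read_image_tree(src)
        assert len(records) == 2
        dataset = expand_dataset(records)
        manifest = dataset.materialize(tmp_path / "out")
        assert len(manifest) == 28
        assert (tmp_path / "out" / "manifest.csv").exists()
        written = sorted((tmp_path / "out").rglob("*.png"))
        assert len(written) == 28
        # file naming: <source-id>__<environment>.png inside the class directory
        assert any(p.name.endswith("__clahe.png") for p in written)
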