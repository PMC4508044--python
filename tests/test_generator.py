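import numpy as np
import pytest
import tifffile
from scipy.ndimage import label as ndi_label

import illumibench as ib
from illumibench.benchmark_generator import SHAPES, to_uint8


def _simple_spec(n_objects=5, n_classes=3):
    objects = tuple(
        ib.ObjectSpec(
            class_id=1 + i % n_classes,
            shape="disc",
            size=16,
            intensity=180,
            position=(30 + 40 * (i // 3), 30 + 50 * (i % 3)),
        )
        for i in range(n_objects)
    )
    return ib.SceneSpec(scene_id=1, rows=120, cols=180, objects=objects)


class TestRenderScene:
    def test_label_range_and_instance_count(self):
        clean = ib.render_scene(_simple_spec(5, 3))
        assert set(np.unique(clean.truth_classes)) <= {0, 1, 2, 3}
        assert clean.n_objects == 5
        assert set(np.unique(clean.truth_instances)) == set(range(6))

    def test_deterministic(self):
        a = ib.render_scene(_simple_spec())
        b = ib.render_scene(_simple_spec())
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.truth_instances, b.truth_instances)

    def test_empty_scene_is_background(self):
        clean = ib.render_scene(ib.SceneSpec(scene_id=1, rows=50, cols=60))
        assert np.all(clean.image == 110.0)
        assert not clean.truth_classes.any()
        assert clean.n_objects == 0

    def test_class_instance_consistency(self, clean_scene):
        assert np.array_equal(clean_scene.truth_classes > 0, clean_scene.truth_instances > 0)
        for row in clean_scene.object_table.itertuples():
            cls = np.unique(
                clean_scene.truth_classes[clean_scene.truth_instances == row.instance_id]
            )
            assert cls.tolist() == [row.class_id]

    @pytest.mark.parametrize("shape", SHAPES)
    def test_each_shape_renders_one_connected_instance(self, shape):
        spec = ib.SceneSpec(
            scene_id=1,
            rows=80,
            cols=80,
            objects=(
                ib.ObjectSpec(
                    class_id=1, shape=shape, size=24, intensity=200,
                    position=(40, 40), orientation=25.0,
                ),
            ),
        )
        clean = ib.render_scene(spec)
        mask = clean.truth_instances == 1
        assert mask.any()
        _, n_components = ndi_label(mask, structure=np.ones((3, 3)))
        assert n_components == 1

    def test_overlapping_objects_rejected(self):
        objects = tuple(
            ib.ObjectSpec(class_id=1, shape="disc", size=20, intensity=200, position=(40, c))
            for c in (40, 50)
        )
        with pytest.raises(ValueError, match="overlap"):
            ib.render_scene(ib.SceneSpec(scene_id=1, rows=80, cols=120, objects=objects))

    def test_out_of_bounds_object_rejected(self):
        obj = ib.ObjectSpec(class_id=1, shape="square", size=30, intensity=200, position=(5, 40))
        with pytest.raises(ValueError, match="fit"):
            ib.render_scene(ib.SceneSpec(scene_id=1, rows=80, cols=80, objects=(obj,)))


class TestShading:
    def test_level_one_is_identity(self, clean_scene, shading_model):
        out = ib.apply_shading(clean_scene.image, 1, shading_model)
        assert np.array_equal(out, clean_scene.image)

    def test_mean_decreases_with_grade(self, clean_scene, shading_model):
        means = [
            ib.apply_shading(clean_scene.image, b, shading_model).mean()
            for b in range(1, 14)
        ]
        assert all(m1 >= m2 for m1, m2 in zip(means, means[1:]))
        assert means[-1] < means[1]

    def test_black_image_stays_black(self, shading_model):
        out = ib.apply_shading(np.zeros((20, 30)), 13, shading_model)
        assert not out.any()

    def test_out_of_range_grade(self, shading_model):
        with pytest.raises(ValueError):
            ib.apply_shading(np.zeros((5, 5)), 14, shading_model)

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            ib.ShadingModel(gains=(0.9, 0.8), slopes=(0.0, 0.1))  # g_1 != 1
        with pytest.raises(ValueError):
            ib.ShadingModel(gains=(1.0, 1.0), slopes=(0.0, -0.1))


class TestClipAndNoise:
    @pytest.mark.parametrize("x,expected", [(-10, 0), (300, 255), (128, 128)])
    def test_clip_branches(self, x, expected):
        assert ib.clip_intensity(x) == expected

    def test_grade_one_adds_nothing(self, clean_scene):
        out = ib.add_noise(clean_scene.image, 1, seed=42, r=1, b=1)
        assert np.array_equal(out, clean_scene.image)

    def test_output_stays_in_gray_range(self, clean_scene):
        out = ib.add_noise(clean_scene.image, 14, seed=42, r=1, b=1)
        assert out.min() >= 0 and out.max() <= 255

    def test_reproducible_and_cell_independent(self):
        img = np.full((50, 50), 128.0)
        a = ib.add_noise(img, 5, seed=7, r=1, b=2)
        b = ib.add_noise(img, 5, seed=7, r=1, b=2)
        c = ib.add_noise(img, 5, seed=7, r=2, b=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_sigma_schedule(self):
        assert ib.noise_sigma(1) == 0.0
        assert ib.noise_sigma(2) == pytest.approx(np.sqrt(125.0))
        with pytest.raises(ValueError):
            ib.noise_sigma(0)


class TestFilenames:
    def test_worked_example(self):
        assert ib.make_filename(2, 1, 3) == "benchdata_02_01_03.tif"

    def test_top_of_grid(self):
        assert ib.make_filename(1, 13, 14) == "benchdata_01_13_14.tif"

    @pytest.mark.parametrize("triple", [(0, 1, 1), (1, 0, 1), (1, 1, 100)])
    def test_out_of_range(self, triple):
        with pytest.raises(ValueError):
            ib.make_filename(*triple)


class TestGenerateBenchmark:
    def test_grid_arithmetic_and_files(self, tiny_benchmark):
        outdir, manifest = tiny_benchmark
        assert len(manifest) == 4  # R=1, B=2, N=2
        for fname in manifest["filename"]:
            assert (outdir / fname).exists()
        assert (outdir / "benchdata_01_truth.tif").exists()
        assert (outdir / "benchdata_01_instances.tif").exists()
        assert (outdir / "benchdata_01_objects.csv").exists()
        assert (outdir / "manifest.csv").exists()

    def test_images_are_8bit_with_valid_range(self, tiny_benchmark):
        outdir, manifest = tiny_benchmark
        img = tifffile.imread(outdir / manifest["filename"].iloc[0])
        assert img.dtype == np.uint8
        assert img.ndim == 2

    def test_regeneration_is_byte_identical(self, tmp_path, scene_specs):
        grid = ib.DistortionGrid(B=2, N=2, R_count=1)
        model = ib.ShadingModel.linear(grid.B)
        for sub in ("a", "b"):
            ib.generate_benchmark(scene_specs[:1], grid, model, tmp_path / sub, seed=42)
        name = ib.make_filename(1, 2, 2)
        assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_noise_grade_one_matches_shaded_image(self, tiny_benchmark, clean_scene):
        outdir, _ = tiny_benchmark
        model = ib.ShadingModel.linear(2)
        for b in (1, 2):
            stored = tifffile.imread(outdir / ib.make_filename(1, b, 1))
            expected = to_uint8(ib.apply_shading(clean_scene.image, b, model))
            assert np.array_equal(stored, expected)
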