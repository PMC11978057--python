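import numpy as np
import pytest

from macaqueid import imaging, synth
from macaqueid.features import eigenfaces as ef
from macaqueid.features.lbp import LBPSpec, lbp_histogram


class TestMakePopulation:
    def test_same_seed_identical_population(self):
        a = synth.make_population(3, seed=9)
        b = synth.make_population(3, seed=9)
        for ta, tb in zip(a, b):
            assert ta.id == tb.id
            assert np.array_equal(ta.shape_params, tb.shape_params)
            assert ta.base_texture_seed == tb.base_texture_seed

    def test_pairwise_separation_enforced(self):
        pop = synth.make_population(8, seed=2, separation=0.8)
        for i in range(len(pop)):
            for j in range(i + 1, len(pop)):
                d = np.linalg.norm(pop[i].shape_params - pop[j].shape_params)
                assert d >= 0.8

    def test_impossible_separation_raises(self):
        with pytest.raises(synth.SeparationError):
            synth.make_population(8, seed=0, separation=10.0, max_attempts=50)

    def test_needs_two_identities(self):
        with pytest.raises(ValueError):
            synth.make_population(1)


class TestRender:
    def test_fully_deterministic_without_noise(self, small_population):
        cfg = synth.RenderConfig(noise_sd=0, max_shift=0, max_rotation=0)
        a = synth.render(small_population[0], cfg, seed=1)
        b = synth.render(small_population[0], cfg, seed=99)  # seed unused here
        assert np.array_equal(a, b)

    def test_same_seed_same_image_with_noise(self, small_population):
        a = synth.render(small_population[0], seed=4)
        b = synth.render(small_population[0], seed=4)
        assert np.array_equal(a, b)

    def test_output_is_rgb_uint8_at_render_shape(self, small_population):
        img = synth.render(small_population[0], seed=0)
        assert img.shape == (*synth.RENDER_SHAPE, 3)
        assert img.dtype == np.uint8

    def test_channel_mean_recovers_gray(self, small_population):
        img = synth.render(small_population[0], seed=0)
        gray = imaging.to_grayscale(img)
        assert np.array_equal(gray, img[:, :, 1])

    def test_pure_gain_change_leaves_lbp_invariant(self, small_population):
        """A multiplicative lighting change is a strictly monotone intensity
        map, so LBP histograms are bit-identical (on unquantized renders)."""
        base = dict(noise_sd=0, max_shift=0, max_rotation=0,
                    lighting_gradient=(0.0, 0.0), blur_sigma=0.6)
        g1 = synth.render(small_population[1],
                          synth.RenderConfig(lighting_gain=1.0, **base),
                          seed=3, float_gray=True)
        g2 = synth.render(small_population[1],
                          synth.RenderConfig(lighting_gain=1.2, **base),
                          seed=3, float_gray=True)
        spec = LBPSpec(grid_rows=4, grid_cols=4)
        assert np.array_equal(lbp_histogram(g1, spec), lbp_histogram(g2, spec))

    def test_inter_identity_distance_exceeds_intra(self, small_population):
        """Eigen-distances between identities dominate within-identity spread."""
        t1, t2 = small_population[0], small_population[1]
        renders = {t.id: [imaging.preprocess(synth.render(t, seed=s))
                          for s in range(20)] for t in (t1, t2)}
        model = ef.fit_eigenfaces(renders[t1.id] + renders[t2.id], 0.90)
        proj = {k: np.stack([ef.project_eigenface(im, model) for im in v])
                for k, v in renders.items()}
        intra = [np.linalg.norm(p[i] - p[j])
                 for p in proj.values()
                 for i in range(20) for j in range(i + 1, 20)]
        inter = [np.linalg.norm(a - b)
                 for a in proj[t1.id] for b in proj[t2.id]]
        assert np.mean(inter) > np.mean(intra)


class TestMakeDataset:
    def test_manifest_row_count(self, small_population):
        ds = synth.make_dataset(small_population, images_per_id=6, seed=3)
        assert len(ds.manifest) == 24
        assert len(ds.images) == 24

    def test_same_seed_identical_manifest_and_images(self, small_population):
        a = synth.make_dataset(small_population, images_per_id=5, seed=8)
        b = synth.make_dataset(small_population, images_per_id=5, seed=8)
        assert a.manifest.equals(b.manifest)
        assert all(np.array_equal(x, y) for x, y in zip(a.images, b.images))

    def test_unbalanced_class_counts(self, small_population):
        counts = {"id01": 21, "id02": 5, "id03": 7, "id04": 12}
        ds = synth.make_dataset(small_population, images_per_id=5, seed=1,
                                class_counts=counts)
        got = ds.manifest["identity_id"].value_counts().to_dict()
        assert got == counts

    def test_write_produces_loadable_tree(self, small_population, tmp_path):
        ds = synth.make_dataset(small_population, images_per_id=2, seed=2)
        manifest_path = ds.write(tmp_path)
        images, labels = imaging.load_labeled_images(manifest_path)
        assert len(images) == 8
        assert sorted(set(labels)) == [t.id for t in small_population]
        assert (tmp_path / "boxes.json").exists()


class TestSessionStream:
    def test_stream_shape_and_sidecar(self, small_population):
        stream, sidecar = synth.make_session_stream(
            small_population[:3], duration=3.0, fps=10.0, segment=1.0, seed=5)
        assert len(stream) == 30
        assert len(sidecar) == 30
        for rec in sidecar:
            assert rec["identity_id"] in {t.id for t in small_population[:3]}
        # one identity per segment, cycling
        assert sidecar[0]["identity_id"] == small_population[0].id
        assert sidecar[15]["identity_id"] == small_population[1].id

    def test_boxes_contain_the_rendered_face(self, small_population):
        stream, sidecar = synth.make_session_stream(
            small_population[:2], duration=1.0, fps=5.0, seed=1)
        fh, fw = synth.RENDER_SHAPE
        for rec in sidecar:
            assert rec["x1"] - rec["x0"] == fw
            assert rec["y1"] - rec["y0"] == fh
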