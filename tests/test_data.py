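"""Data IO: fixtures, folder loading, splits, preprocessing."""

import numpy as np
import pytest

from fruitnet.data import (FixtureSpec, LabeledImageSet, SplitSpec,
                           generate_fixture, load_image_folder, preprocess,
                           stratified_split)


class TestFixtureGeneration:
    def test_size_and_seeded_determinism(self):
        spec = FixtureSpec(num_classes=5, images_per_class=20, image_size=48, seed=7)
        a = generate_fixture(spec)
        b = generate_fixture(spec)
        assert len(a) == 100
        assert a.class_names == b.class_names
        for ia, ib in zip(a.images, b.images):
            assert ia.tobytes() == ib.tobytes()  # byte-identical across runs

    def test_distinct_seeds_differ(self):
        a = generate_fixture(FixtureSpec(3, 2, 48, seed=1))
        b = generate_fixture(FixtureSpec(3, 2, 48, seed=2))
        assert any(x.tobytes() != y.tobytes() for x, y in zip(a.images, b.images))

    def test_zero_noise_images_are_clean_shapes(self):
        ds = generate_fixture(FixtureSpec(2, 3, 48, seed=0, noise_level=0.0))
        # white background stays exactly white without noise
        for img in ds.images:
            corners = img[[0, 0, -1, -1], [0, -1, 0, -1]]
            assert np.all(corners == 255)

    def test_white_background_dominates(self):
        ds = generate_fixture(FixtureSpec(2, 2, 64, seed=3))
        frac_white = np.mean([np.mean(im > 220) for im in ds.images])
        assert frac_white > 0.5

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FixtureSpec(num_classes=1, images_per_class=5)
        with pytest.raises(ValueError):
            FixtureSpec(num_classes=3, images_per_class=5, image_size=16)


class TestFolderRoundTrip:
    def test_disk_round_trip_preserves_everything(self, tmp_path):
        ds = generate_fixture(FixtureSpec(3, 4, 48, seed=5), out_dir=tmp_path / "tree")
        back = load_image_folder(tmp_path / "tree")
        assert back.class_names == ds.class_names
        assert len(back) == len(ds)
        np.testing.assert_array_equal(back.labels, np.sort(ds.labels))
        # PNG is lossless: pixel-exact recovery
        for k in range(3):
            orig = [im for im, l in zip(ds.images, ds.labels) if l == k]
            got = [im for im, l in zip(back.images, back.labels) if l == k]
            assert sorted(i.tobytes() for i in orig) == sorted(i.tobytes() for i in got)

    @staticmethod
    def _write_png(path):
        from PIL import Image

        path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray(np.full((40, 40, 3), 128, np.uint8)).save(path)

    def test_class_names_sorted_bytewise(self, tmp_path):
        for name in ("pear", "Apple", "banana"):
            self._write_png(tmp_path / "flat" / name / "a.png")
        ds = load_image_folder(tmp_path / "flat")
        assert ds.class_names == ("Apple", "banana", "pear")  # bytewise order

    def test_single_class_rejected(self, tmp_path):
        self._write_png(tmp_path / "t" / "only" / "a.png")
        with pytest.raises(ValueError, match="at least 2"):
            load_image_folder(tmp_path / "t")

    def test_non_image_files_skipped(self, tmp_path):
        ds = generate_fixture(FixtureSpec(2, 2, 48, seed=0), out_dir=tmp_path / "t")
        (tmp_path / "t" / ds.class_names[0] / "notes.txt").write_text("not an image")
        back = load_image_folder(tmp_path / "t")
        assert len(back) == 4


class TestStratifiedSplit:
    @staticmethod
    def _tiny(labels):
        labels = np.asarray(labels)
        return LabeledImageSet(
            images=[np.zeros((1, 1, 3), np.uint8)] * len(labels),
            labels=labels,
            class_names=tuple(f"c{i}" for i in range(labels.max() + 1)),
        )

    def test_exact_80_20_arithmetic(self):
        ds = self._tiny(np.repeat(np.arange(5), 20))
        tr, va = stratified_split(ds, SplitSpec((0.8, 0.2), seed=3))
        assert len(tr) == 80 and len(va) == 20
        for k in range(5):
            assert np.sum(tr.labels == k) == 16
            assert np.sum(va.labels == k) == 4

    def test_same_seed_reproduces_partitions(self):
        ds = self._tiny(np.repeat(np.arange(4), 9))
        s = SplitSpec((0.5, 0.25, 0.25), seed=11)
        a = stratified_split(ds, s)
        b = stratified_split(ds, s)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.labels, pb.labels)

    def test_disjoint_and_exhaustive_over_many_seeded_sets(self):
        rng = np.random.default_rng(31)
        for trial in range(200):
            n_cls = int(rng.integers(2, 5))
            labels = np.concatenate(
                [np.full(int(rng.integers(4, 12)), k) for k in range(n_cls)])
            ds = self._tiny(labels)
            ds.paths = [str(i) for i in range(len(ds))]  # unique ids
            parts = stratified_split(ds, SplitSpec((0.6, 0.4), seed=trial))
            ids = [set(p.paths) for p in parts]
            assert ids[0].isdisjoint(ids[1])
            assert ids[0] | ids[1] == set(ds.paths)

    def test_too_small_class_rejected_by_name(self):
        ds = self._tiny([0, 0, 0, 0, 1])
        with pytest.raises(ValueError, match="c1"):
            stratified_split(ds, SplitSpec((0.5, 0.25, 0.25), seed=0))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec((0.5, 0.4))
        with pytest.raises(ValueError):
            SplitSpec((0.5, -0.1, 0.6))


class TestPreprocess:
    def test_already_sized_input_keeps_dims_and_range(self):
        img = np.random.default_rng(0).integers(0, 256, (100, 100, 3)).astype(np.uint8)
        out = preprocess(img, 100)
        assert out.shape == (100, 100, 3)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_white_image_maps_to_plus_one(self):
        out = preprocess(np.full((100, 100, 3), 255, np.uint8), 100)
        np.testing.assert_array_equal(out, np.ones((100, 100, 3), np.float32))

    def test_downscale_matches_separable_bilinear_oracle(self):
        rng = np.random.default_rng(12)
        img = (rng.integers(0, 2, (200, 200, 1)) * 255).astype(np.uint8)
        img = np.repeat(img, 3, axis=2)  # checkerboard-like binary pattern
        out = preprocess(img, 100)
        scaled = img.astype(np.float64) / 127.5 - 1.0
        want = _bilinear_resize_oracle(scaled, 100)
        np.testing.assert_allclose(out, want, atol=1e-4)

    def test_idempotent_on_scaled_sized_input(self):
        img = np.random.default_rng(1).integers(0, 256, (100, 100, 3)).astype(np.uint8)
        once = preprocess(img, 100)
        twice = preprocess(once, 100)
        np.testing.assert_array_equal(once, twice)

    def test_non_rgb_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            preprocess(np.zeros((10, 10), np.uint8), 10)


def _bilinear_resize_oracle(img: np.ndarray, size: int) -> np.ndarray:
    """Naive 4-neighbour bilinear sampling, pixel centers aligned."""
    h, w, c = img.shape
    out = np.zeros((size, size, c))
    sy, sx = h / size, w / size
    for oi in range(size):
        for oj in range(size):
            y = (oi + 0.5) * sy - 0.5
            x = (oj + 0.5) * sx - 0.5
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            dy, dx = y - y0, x - x0
            y0c, y1c = np.clip([y0, y0 + 1], 0, h - 1)
            x0c, x1c = np.clip([x0, x0 + 1], 0, w - 1)
            out[oi, oj] = ((1 - dy) * (1 - dx) * img[y0c, x0c]
                           + (1 - dy) * dx * img[y0c, x1c]
                           + dy * (1 - dx) * img[y1c, x0c]
                           + dy * dx * img[y1c, x1c])
    return out
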