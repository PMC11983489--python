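"""Phantom generator, PCA band reduction, fold splitting and I/O."""

import numpy as np
import pytest

from benet.data import (FoldSplit, HyperCube, Mask, PhantomParams,
                        boundary_blur_phantom_params, easy_phantom_params,
                        generate_phantom, generate_phantom_set, kfold_split,
                        nearest_centroid_mask, pca_reduce, read_cube,
                        read_manifest, read_mask, write_cube, write_manifest,
                        write_mask)


class TestPhantom:
    def test_same_seed_reproduces_cube_and_mask(self):
        p = PhantomParams(height=32, width=32, bands=5, seed=9)
        c1, m1 = generate_phantom(p)
        c2, m2 = generate_phantom(p)
        assert np.array_equal(c1.values, c2.values)
        assert np.array_equal(m1.labels, m2.labels)

    def test_noise_free_separable_phantom_matches_nearest_centroid(self):
        p = PhantomParams(height=48, width=48, bands=8, noise_sigma=0.0,
                          within_class_jitter=0.0, boundary_blur_sigma=0.0,
                          distractor_density=0.0, signature_separation=2.0,
                          seed=3)
        cube, mask = generate_phantom(p)
        pred = nearest_centroid_mask(cube, p)
        assert np.array_equal(pred, mask.labels)

    def test_lesion_area_fraction_within_configured_window(self):
        for seed in range(30):
            p = PhantomParams(height=48, width=48, bands=4, seed=seed)
            _, mask = generate_phantom(p)
            frac = mask.labels.mean()
            assert p.area_fraction[0] <= frac <= p.area_fraction[1]

    def test_blur_softens_spectra_but_not_labels(self):
        base = dict(height=48, width=48, bands=6, noise_sigma=0.0,
                    within_class_jitter=0.0, distractor_density=0.0, seed=5)
        crisp_cube, crisp_mask = generate_phantom(
            PhantomParams(boundary_blur_sigma=0.0, **base))
        soft_cube, soft_mask = generate_phantom(
            PhantomParams(boundary_blur_sigma=2.0, **base))
        assert np.array_equal(crisp_mask.labels, soft_mask.labels)
        assert not np.allclose(crisp_cube.values, soft_cube.values)
        # blurring shrinks the spatial gradient magnitude at the boundary
        g_crisp = np.abs(np.diff(crisp_cube.values[:, :, 0], axis=1)).max()
        g_soft = np.abs(np.diff(soft_cube.values[:, :, 0], axis=1)).max()
        assert g_soft < g_crisp

    def test_difficulty_monotone_in_noise(self):
        # nearest-centroid accuracy should not improve as noise grows
        sigmas = [0.0, 0.3, 0.9]
        accs = []
        for sigma in sigmas:
            vals = []
            for seed in range(10):
                p = PhantomParams(height=32, width=32, bands=6,
                                  noise_sigma=sigma, within_class_jitter=0.0,
                                  distractor_density=0.0,
                                  signature_separation=1.0, seed=100 + seed)
                cube, mask = generate_phantom(p)
                pred = nearest_centroid_mask(cube, p)
                vals.append((pred == mask.labels).mean())
            accs.append(np.mean(vals))
        assert accs[0] >= accs[1] - 0.02 >= accs[2] - 0.04

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            PhantomParams(height=16, width=16, blob_radius=(4, 20))

    def test_phantom_set_items_differ(self):
        cubes, masks = generate_phantom_set(
            easy_phantom_params(32, 4), 3, seed=1)
        assert len(cubes) == 3
        assert not np.array_equal(masks[0].labels, masks[1].labels)

    def test_preset_profiles_produce_valid_phantoms(self):
        for params in (easy_phantom_params(32, 4, seed=2),
                       boundary_blur_phantom_params(32, 4, seed=2)):
            cube, mask = generate_phantom(params)
            assert cube.shape == (32, 32, 4)
            assert mask.labels.max() == 1


class TestPCA:
    def test_rank_one_cube_first_component_explains_everything(self, rng):
        spectrum = rng.uniform(0.5, 1.5, 6)
        weights = rng.uniform(0.1, 2.0, (8, 8))
        cube = HyperCube((weights[:, :, None] * spectrum).astype(np.float64))
        reduced = pca_reduce([cube], 2)[0]
        var = reduced.values.reshape(-1, 2).var(axis=0)
        assert var[1] <= 1e-12 * max(var[0], 1.0)

    def test_full_rank_projection_preserves_centered_data(self, rng):
        cube = HyperCube(rng.standard_normal((6, 6, 4)))
        reduced = pca_reduce([cube], 4)[0]
        flat = cube.values.reshape(-1, 4)
        centered = flat - flat.mean(axis=0)
        # an orthogonal change of basis preserves pairwise distances
        d0 = np.linalg.norm(centered[:, None] - centered[None], axis=2)
        flat_r = reduced.values.reshape(-1, 4)
        d1 = np.linalg.norm(flat_r[:, None] - flat_r[None], axis=2)
        assert np.allclose(d0, d1, atol=1e-8)

    def test_retained_variance_matches_eigendecomposition(self, rng):
        cube = HyperCube(rng.standard_normal((8, 8, 5)))
        reduced = pca_reduce([cube], 2)[0]
        flat = cube.values.reshape(-1, 5)
        cov = np.cov(flat.T, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        retained = reduced.values.reshape(-1, 2).var(axis=0).sum()
        assert retained == pytest.approx(eig[:2].sum(), rel=1e-6)

    def test_fit_restricted_to_training_cubes(self, rng):
        train = [HyperCube(rng.standard_normal((6, 6, 4))) for _ in range(3)]
        test = [HyperCube(rng.standard_normal((6, 6, 4)) * 5 + 3)]
        with_test = pca_reduce(train + test, 2, fit_indices=[0, 1, 2])
        alone = pca_reduce(train, 2, fit_indices=[0, 1, 2])
        for a, b in zip(with_test[:3], alone):
            assert np.allclose(a.values, b.values, atol=1e-6)

    def test_too_many_components_rejected(self, rng):
        cube = HyperCube(rng.standard_normal((4, 4, 3)))
        with pytest.raises(ValueError):
            pca_reduce([cube], 5)


class TestKFold:
    def test_ten_into_five_gives_pairs(self):
        split = kfold_split(10, 5, seed=1)
        assert [len(f) for f in split.folds] == [2] * 5

    def test_partition_properties(self):
        split = kfold_split(13, 5, seed=2)
        all_idx = sorted(i for f in split.folds for i in f)
        assert all_idx == list(range(13))
        sizes = [len(f) for f in split.folds]
        assert max(sizes) - min(sizes) <= 1

    def test_same_seed_same_split(self):
        a = kfold_split(20, 5, seed=3)
        b = kfold_split(20, 5, seed=3)
        assert a.folds == b.folds
        c = kfold_split(20, 5, seed=4)
        assert a.folds != c.folds

    def test_train_val_complementary(self):
        split = kfold_split(11, 4, seed=0)
        tr, va = split.train_val(2)
        assert sorted(list(tr) + list(va)) == list(range(11))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            kfold_split(3, 5)
        with pytest.raises(ValueError):
            kfold_split(10, 1)


class TestIO:
    def test_cube_roundtrip_bitwise(self, tmp_path, rng):
        cube = HyperCube(rng.standard_normal((9, 7, 5)).astype(np.float32))
        for name in ("cube.tif", "cube.npy"):
            path = tmp_path / name
            write_cube(path, cube)
            back = read_cube(path)
            assert np.array_equal(back.values, cube.values)

    def test_mask_roundtrip(self, tmp_path, rng):
        mask = Mask((rng.random((9, 7)) < 0.4).astype(np.uint8))
        path = tmp_path / "mask.png"
        write_mask(path, mask)
        assert np.array_equal(read_mask(path).labels, mask.labels)

    def test_rgb_png_read_as_three_band_cube(self, tmp_path, rng):
        import imageio.v3 as iio
        arr = rng.integers(0, 255, (8, 8, 3), dtype=np.uint8)
        path = tmp_path / "rgb.png"
        iio.imwrite(path, arr)
        cube = read_cube(path)
        assert cube.band_count == 3

    def test_band_count_mismatch_raises(self, tmp_path, rng):
        cube = HyperCube(rng.standard_normal((6, 6, 4)).astype(np.float32))
        path = tmp_path / "cube.tif"
        write_cube(path, cube)
        with pytest.raises(ValueError):
            read_cube(path, expected_bands=7)

    def test_manifest_roundtrip(self, tmp_path, rng):
        pairs = []
        for i in range(2):
            cube = HyperCube(rng.standard_normal((8, 8, 3)).astype(np.float32))
            mask = Mask((rng.random((8, 8)) < 0.3).astype(np.uint8))
            cp, mp = tmp_path / f"c{i}.tif", tmp_path / f"m{i}.png"
            write_cube(cp, cube)
            write_mask(mp, mask)
            pairs.append((cp.name, mp.name))
        manifest = tmp_path / "manifest.yaml"
        write_manifest(manifest, pairs)
        loaded = read_manifest(manifest)
        assert len(loaded) == 2
        assert loaded[0][0].band_count == 3

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError):
            Mask(np.array([[0, 2], [1, 0]]))
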