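"""Simulator: spine shapes, nanodomain placement, rendering, bleaching."""

import numpy as np
import pytest
from scipy import ndimage

from tagan import simulate as sim


class TestSpineShape:
    def test_area_window_and_geometry_sweep(self):
        """Masks stay connected, inside the grid and in the area window."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            mask = sim.generate_spine_shape(rng)
            area = int(mask.sum())
            assert 300 <= area <= 1200  # 0.12-0.48 um^2 at 20 nm/px
            assert not (mask[0].any() or mask[-1].any()
                        or mask[:, 0].any() or mask[:, -1].any())
            assert ndimage.label(mask)[1] == 1

    def test_degenerate_area_window(self, rng):
        mask = sim.generate_spine_shape(rng, 0.12, 0.12)
        assert abs(int(mask.sum()) - 300) <= 0.02 * 300

    def test_unreachable_grid_errors(self, rng):
        with pytest.raises(sim.ConstraintError):
            sim.generate_spine_shape(rng, grid_size=16)


class TestPlacement:
    def test_single_domain(self, rng):
        mask = sim.generate_spine_shape(rng)
        centers = sim.place_nanodomains(mask, 1, rng)
        assert len(centers) == 1
        r, c = centers[0]
        assert mask[r, c]

    def test_bruteforce_constraint_recheck(self):
        """Distance-transform-free recheck of separation and edge rules."""
        rng = np.random.default_rng(1)
        for _ in range(100):
            mask = sim.generate_spine_shape(rng)
            n = int(rng.integers(1, 7))
            centers = sim.place_nanodomains(mask, n, rng)
            bg = np.argwhere(~mask)
            for i, (r, c) in enumerate(centers):
                d_edge = np.sqrt(((bg - (r, c)) ** 2).sum(1)).min() * 20.0
                assert d_edge < 140.0
                for j in range(i + 1, n):
                    r2, c2 = centers[j]
                    assert np.hypot(r - r2, c - c2) >= 2.0

    def test_infeasible_placement_errors(self, rng):
        tiny = np.zeros((64, 64), dtype=bool)
        tiny[30:32, 30:32] = True
        with pytest.raises(sim.ConstraintError):
            sim.place_nanodomains(tiny, 6, rng, max_retries=200)


class TestDatamap:
    def test_count_levels_and_conservation(self, rng):
        mask = sim.generate_spine_shape(rng)
        centers = sim.place_nanodomains(mask, 3, rng)
        dm = sim.build_datamap(mask, centers, base_density=5, domain_amplitude=50)
        assert set(np.unique(dm.counts)) <= {0.0, 5.0, 55.0}
        assert dm.counts.sum() == 5 * mask.sum() + 50 * 3
        assert sim.validate_datamap(dm) == []

    def test_empty_centers(self, rng):
        mask = sim.generate_spine_shape(rng)
        dm = sim.build_datamap(mask, [], 5, 50)
        assert np.array_equal(dm.counts, 5.0 * mask)

    def test_center_outside_mask_rejected(self, rng):
        mask = sim.generate_spine_shape(rng)
        outside = tuple(np.argwhere(~mask)[0])
        with pytest.raises(ValueError):
            sim.build_datamap(mask, [outside], 5, 50)


class TestRender:
    def test_noise_free_linearity(self, bundle):
        dm = bundle["datamaps"][2]
        a = sim.render_image(dm, sim.STED, noise_free=True).pixels
        import dataclasses

        dm3 = dataclasses.replace(dm, counts=3.0 * dm.counts)
        b = sim.render_image(
            dm3,
            dataclasses.replace(sim.STED, background_rate=0.0),
            noise_free=True,
        ).pixels
        a0 = sim.render_image(
            dm, dataclasses.replace(sim.STED, background_rate=0.0), noise_free=True
        ).pixels
        assert np.allclose(b, 3.0 * a0, atol=1e-9)
        assert (a >= sim.STED.background_rate - 1e-12).all()

    def test_poisson_mean_matches_noise_free(self, bundle):
        """Sample mean over 1,000 draws within 3 standard errors."""
        dm = bundle["datamaps"][0]
        mean = sim.render_image(dm, sim.CONFOCAL, noise_free=True).pixels
        rng = np.random.default_rng(3)
        draws = np.stack(
            [sim.render_image(dm, sim.CONFOCAL, rng).pixels for _ in range(1000)]
        ).astype(float)
        se = np.sqrt(np.maximum(mean, 1e-9) / 1000)
        frac_ok = np.mean(np.abs(draws.mean(0) - mean) <= 3 * se + 1e-9)
        assert frac_ok > 0.99

    def test_sted_resolves_60nm_pair_confocal_does_not(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[20:45, 20:45] = True
        dm = sim.build_datamap(mask, [(32, 30), (32, 33)], 5, 50)
        from skimage.feature import peak_local_max

        sted = sim.render_image(dm, sim.STED, noise_free=True).pixels
        conf = sim.render_image(dm, sim.CONFOCAL, noise_free=True).pixels
        assert len(peak_local_max(sted, min_distance=1, threshold_rel=0.5)) == 2
        assert len(peak_local_max(conf, min_distance=1, threshold_rel=0.5)) == 1

    def test_empty_datamap_zero_background(self, rng):
        dm = sim.Datamap(
            counts=np.zeros((32, 32)), spine_mask=np.zeros((32, 32), bool), centers=()
        )
        import dataclasses

        cfg = dataclasses.replace(sim.CONFOCAL, background_rate=0.0)
        assert sim.render_image(dm, cfg, rng).pixels.sum() == 0

    def test_invalid_fwhm_rejected(self):
        with pytest.raises(ValueError):
            sim.ImagingConfig(modality="confocal", psf_fwhm_nm=0.0)


class TestBleaching:
    def test_zero_fraction_is_identity(self, bundle, rng):
        dm = bundle["datamaps"][1]
        import dataclasses

        cfg = dataclasses.replace(sim.STED, bleach_fraction=0.0)
        assert sim.apply_bleaching(dm, cfg, rng) is dm

    def test_binomial_thinning_mean(self):
        mask = np.zeros((8, 8), dtype=bool)
        mask[4, 4] = True
        dm = sim.Datamap(counts=1000.0 * mask, spine_mask=mask, centers=())
        import dataclasses

        cfg = dataclasses.replace(sim.STED, bleach_fraction=0.5)
        rng = np.random.default_rng(0)
        survived = [sim.apply_bleaching(dm, cfg, rng).counts[4, 4] for _ in range(300)]
        assert abs(np.mean(survived) - 500.0) < 3 * np.sqrt(1000 * 0.25 / 300)

    def test_repeated_sted_monotone_decline(self, bundle):
        """Expected total signal never increases over 15 STED acquisitions."""
        dm0 = bundle["datamaps"][3]
        totals = np.zeros(16)
        for seed in range(50):
            rng = np.random.default_rng(seed)
            dm = dm0
            totals[0] += dm.counts.sum()
            for k in range(1, 16):
                dm = sim.apply_bleaching(dm, sim.STED, rng)
                totals[k] += dm.counts.sum()
        assert (np.diff(totals) < 0).all()


class TestDataset:
    def test_counts_and_split(self):
        cfg = sim.DatasetConfig(per_n_train=10, test1_per_n=2, test2_count=4)
        m = sim.generate_dataset(cfg, 11)
        by = m.groupby("split").size().to_dict()
        assert by == {"train": 54, "validation": 6, "test1": 10, "test2": 4}
        pool = m[m.split.isin(["train", "validation"])]
        assert pool.groupby("n_domains").size().eq(10).all()

    def test_reproducible(self):
        cfg = sim.DatasetConfig(per_n_train=4, test1_per_n=1, test2_count=2)
        assert sim.generate_dataset(cfg, 5).equals(sim.generate_dataset(cfg, 5))

    def test_two_domain_distances_in_range(self):
        cfg = sim.DatasetConfig(per_n_train=1, test1_per_n=0, test2_count=25)
        m = sim.generate_dataset(cfg, 2)
        d = m[m.split == "test2"].pair_distance_nm
        assert d.min() >= 40.0 and d.max() <= 450.0

    def test_refuses_nonempty_outdir(self, tmp_path):
        (tmp_path / "occupied").mkdir()
        (tmp_path / "occupied" / "x.txt").write_text("x")
        cfg = sim.DatasetConfig(per_n_train=1, test1_per_n=0, test2_count=0,
                                out_dir=str(tmp_path / "occupied"))
        with pytest.raises(FileExistsError):
            sim.generate_dataset(cfg, 0)
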