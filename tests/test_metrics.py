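"""Evaluation metrics against closed forms and independent oracles."""

import numpy as np
import pytest

from tagan import metrics as M


class TestImageSimilarity:
    def test_identical_images(self, rng):
        a = rng.random((32, 32))
        r = M.image_similarity(a, a.copy())
        assert r["mse"] == 0.0 and r["ssim"] == pytest.approx(1.0)
        assert r["psnr"] == float("inf")

    def test_constant_offset_closed_form(self, rng):
        a = rng.random((32, 32))
        r = M.image_similarity(a, a + 0.25, data_range=1.0)
        assert r["mse"] == pytest.approx(0.0625)
        assert r["psnr"] == pytest.approx(10 * np.log10(1 / 0.0625))

    def test_mse_psnr_independent_formula(self, rng):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        r = M.image_similarity(a, b, data_range=1.0)
        mse = float(sum((x - y) ** 2 for x, y in zip(a.ravel(), b.ravel())) / a.size)
        assert r["mse"] == pytest.approx(mse, abs=1e-12)
        assert r["psnr"] == pytest.approx(-10 * np.log10(mse), abs=1e-9)
        assert -1.0 <= r["ssim"] <= 1.0

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            M.image_similarity(rng.random((8, 8)), rng.random((9, 8)))


class TestOverlap:
    def test_identical_and_arithmetic(self):
        a = np.zeros((8, 8), bool)
        a[0, 0:4] = True          # |A| = 4
        b = np.zeros((8, 8), bool)
        b[0, 0:2] = True          # |B| = 2, inter = 2
        r = M.overlap_metrics(a, b)
        assert r["dice"] == pytest.approx(2 * 2 / 6)
        assert r["iou"] == pytest.approx(0.5)
        same = M.overlap_metrics(a, a)
        assert same["dice"] == 1.0 and same["iou"] == 1.0

    def test_both_empty_defined_one(self):
        z = np.zeros((4, 4), bool)
        assert M.overlap_metrics(z, z) == {"dice": 1.0, "iou": 1.0}

    def test_dice_iou_identity_sweep(self, rng):
        for _ in range(50):
            a = rng.random((16, 16)) > 0.5
            b = rng.random((16, 16)) > 0.5
            r = M.overlap_metrics(a, b)
            assert r["dice"] == pytest.approx(2 * r["iou"] / (1 + r["iou"]))
            assert r["dice"] == M.overlap_metrics(b, a)["dice"]  # symmetric


class TestLocalizationF1:
    def test_perfect_predictions(self):
        pts = [(3, 4), (10, 10), (20, 5)]
        r = M.localization_f1(pts, pts)
        assert r["f1"] == 1.0

    def test_four_pixel_miss(self):
        r = M.localization_f1([(0, 4)], [(0, 0)], tol_px=3)
        assert r["f1"] == 0.0

    def test_empty_vs_empty(self):
        assert M.localization_f1([], [])["f1"] == 1.0

    def test_matches_hungarian_for_separated_truths(self, rng):
        """Greedy matching equals optimal assignment when truths are far apart."""
        from scipy.optimize import linear_sum_assignment

        for _ in range(20):
            truths = [(10 * i + rng.uniform(-1, 1), 10 * i) for i in range(5)]
            preds = [(t[0] + rng.uniform(-2, 2), t[1] + rng.uniform(-2, 2))
                     for t in truths if rng.random() > 0.3]
            preds += [(100 + rng.uniform(0, 5), 100)]  # one false positive
            r = M.localization_f1(preds, truths, tol_px=3)
            cost = np.full((len(preds), len(truths)), 1e6)
            for i, p in enumerate(preds):
                for j, t in enumerate(truths):
                    d = np.hypot(p[0] - t[0], p[1] - t[1])
                    if d <= 3:
                        cost[i, j] = d
            ri, ci = linear_sum_assignment(cost)
            tp = int(sum(cost[a, b] < 1e5 for a, b in zip(ri, ci)))
            assert len(r["matches"]) == tp

    def test_order_invariance(self, rng):
        preds = [tuple(p) for p in rng.uniform(0, 50, size=(6, 2))]
        truths = [tuple(t) for t in rng.uniform(0, 50, size=(4, 2))]
        r1 = M.localization_f1(preds, truths)
        r2 = M.localization_f1(list(reversed(preds)), truths)
        assert r1["f1"] == r2["f1"]


class TestCounting:
    def test_well_separated_pair_on_sted(self):
        from tagan import simulate as sim

        mask = np.zeros((64, 64), bool)
        mask[10:55, 10:55] = True
        dm = sim.build_datamap(mask, [(20, 20), (45, 45)], 5, 50)  # 500 nm apart
        img = sim.render_image(dm, sim.STED, noise_free=True).pixels
        centers, n = M.detect_and_count_nanodomains(img)
        assert n == 2
        assert M.localization_f1(centers, dm.centers, tol_px=3)["f1"] == 1.0

    def test_flat_image_no_detection(self):
        assert M.detect_and_count_nanodomains(np.ones((32, 32)))[1] == 0


class TestDividingCellRule:
    @pytest.mark.parametrize(
        "n_pixels,expected",
        [(0, "non_dividing"), (1, "ambiguous"), (10, "ambiguous"),
         (19, "ambiguous"), (20, "dividing"), (400, "dividing")],
    )
    def test_rule(self, n_pixels, expected):
        mask = np.zeros((32, 32), dtype=np.uint8)
        mask.flat[:n_pixels] = 1
        assert M.classify_dividing_cell(mask) == expected

    def test_partition_has_no_gaps(self):
        seen = {M.classify_dividing_cell(np.ones(n, dtype=int)) for n in range(0, 50)}
        assert seen == {"non_dividing", "ambiguous", "dividing"}


class TestMorphology:
    def test_square_cluster_geometry(self):
        img = np.ones((32, 32))
        lab = np.zeros((32, 32), dtype=int)
        lab[4:7, 4:7] = 1       # 3x3 square
        lab[4:7, 20:23] = 2     # second cluster, centroid 16 px away
        other = np.zeros((32, 32), dtype=int)
        other[20:23, 4:7] = 1
        df = M.cluster_morphology([img, img], [lab, other],
                                  channel_names=("psd95", "bassoon"))
        sq = df[(df.channel == "psd95") & (df.label == 1)].iloc[0]
        assert sq.area == 9.0
        assert sq.eccentricity == 0.0
        assert sq.nn_same_channel == pytest.approx(16.0)

    def test_single_cluster_missing_neighbour(self):
        img = np.ones((32, 32))
        lab = np.zeros((32, 32), dtype=int)
        lab[4:8, 4:8] = 1
        df = M.cluster_morphology([img, img], [lab, np.zeros_like(lab)])
        assert np.isnan(df.iloc[0].nn_same_channel)
        assert np.isnan(df.iloc[0].nn_other_channel)

    def test_weighted_centroids_against_hand_computation(self, bundle):
        ph = bundle["cluster_phantom"]
        from tagan.annotate import wavelet_segment_clusters

        labs = [wavelet_segment_clusters(c, apply_filters=False) for c in ph["channels"]]
        df = M.cluster_morphology(ph["channels"], labs)
        for _, row in df.iterrows():
            ch = 0 if row.channel == "ch0" else 1
            lab_img = labs[ch]
            rr, cc = np.nonzero(lab_img == row.label)
            w = ph["channels"][ch][rr, cc]
            assert row.centroid_row == pytest.approx((rr * w).sum() / w.sum(), abs=1e-6)
            assert row.area == float(len(rr))


class TestAuroc:
    def test_perfect_and_uninformative(self):
        assert M.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
        assert M.auroc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_matches_threshold_sweep_oracle(self, rng):
        scores = rng.random(20)
        labels = rng.integers(0, 2, size=20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        # brute-force: P(score_pos > score_neg) + 0.5 P(tie)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        assert M.auroc(scores, labels) == pytest.approx(
            wins / (len(pos) * len(neg)), abs=1e-9
        )

    def test_single_class_undefined(self):
        with pytest.raises(ValueError):
            M.auroc([0.1, 0.9], [1, 1])
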