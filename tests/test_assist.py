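"""Optical flow, trigger policies, the closed loop and dose accounting."""

import numpy as np
import pytest

from tagan import assist as eng
from tagan import simulate as sim


class TestHornSchunck:
    def test_identical_frames_zero_flow(self, rng):
        img = rng.random((32, 32))
        ff = eng.horn_schunck_flow(img, img, n_iter=50)
        assert np.abs(ff.u).max() < 1e-12 and np.abs(ff.v).max() < 1e-12

    def test_recovers_one_pixel_shift(self):
        """A (0, 1) px translation yields mean v ~ 1 within 25%."""
        rr, cc = np.mgrid[0:64, 0:64]
        blob = np.exp(-((rr - 32) ** 2 + (cc - 30) ** 2) / 50.0)
        blob2 = np.exp(-((rr - 32) ** 2 + (cc - 31) ** 2) / 50.0)
        ff = eng.horn_schunck_flow(blob, blob2, alpha=0.25, n_iter=800)
        support = blob > 0.2
        assert abs(ff.u[support].mean()) < 0.25
        assert ff.v[support].mean() == pytest.approx(1.0, rel=0.25)

    def test_energy_non_increasing(self):
        rr, cc = np.mgrid[0:48, 0:48]
        a = np.exp(-((rr - 24) ** 2 + (cc - 22) ** 2) / 40.0)
        b = np.exp(-((rr - 23) ** 2 + (cc - 23) ** 2) / 40.0)
        ff = eng.horn_schunck_flow(a, b, alpha=0.5, n_iter=150, track_energy=True)
        e = np.asarray(ff.energies)
        assert (np.diff(e) <= 1e-12).all()

    def test_bad_iteration_count(self, rng):
        with pytest.raises(ValueError):
            eng.horn_schunck_flow(rng.random((8, 8)), rng.random((8, 8)), n_iter=0)


class TestBlockPooling:
    def test_500_to_5x5_exact_vs_bruteforce(self, rng):
        img = rng.random((500, 500))
        bm = eng.block_mean(img, 100)
        assert bm.shape == (5, 5)
        for i in range(5):
            for j in range(5):
                assert bm[i, j] == pytest.approx(
                    img[100 * i : 100 * (i + 1), 100 * j : 100 * (j + 1)].mean(),
                    abs=1e-12,
                )

    def test_indivisible_shape_errors(self, rng):
        with pytest.raises(ValueError):
            eng.block_mean(rng.random((510, 500)), 100)

    def test_identical_ensemble_zero_map(self, rng):
        s = rng.random((200, 200))
        bm = eng.ensemble_flow_map([s, s.copy(), s.copy()], block=100)
        assert bm.shape == (2, 2) and bm.sum() == 0.0


class TestSubregionSelection:
    def test_hot_block_outside_roi(self):
        bm = np.zeros((5, 5))
        bm[0, 3] = 2.0
        roi = np.zeros((5, 5), bool)
        roi[1:4, 1:4] = True
        assert eng.select_subregion(bm, roi) == (0, 300, 100, 100)

    def test_uniform_map_row_major_tiebreak(self):
        roi = np.zeros((5, 5), bool)
        roi[1:4, 1:4] = True
        assert eng.select_subregion(np.ones((5, 5)), roi) == (0, 0, 100, 100)

    def test_roi_maximum_masked_out(self):
        bm = np.zeros((5, 5))
        bm[2, 2] = 9.0   # hottest, but inside ROI
        bm[4, 1] = 5.0
        roi = np.zeros((5, 5), bool)
        roi[1:4, 1:4] = True
        assert eng.select_subregion(bm, roi) == (400, 100, 100, 100)

    def test_all_blocks_in_roi_errors(self):
        with pytest.raises(ValueError):
            eng.select_subregion(np.ones((3, 3)), np.ones((3, 3), bool))


class TestTriggers:
    def test_dice_identical_and_disjoint(self):
        ref = np.zeros((10, 10), bool)
        ref[2:5, 2:5] = True
        same = np.stack([ref] * 4)
        dc, trig = eng.dice_trigger(same, ref)
        assert dc == 1.0 and not trig
        disjoint = np.zeros((4, 10, 10), bool)
        disjoint[:, 7:9, 7:9] = True
        dc, trig = eng.dice_trigger(disjoint, ref)
        assert dc == 0.0 and trig

    def test_dice_boundary_is_strict(self):
        """Mean DC exactly at theta does not trigger (strict <)."""
        ref = np.zeros((6, 6), bool)
        ref[0:3, :] = True
        segs = np.stack([ref] * 5 + [np.zeros((6, 6), bool)] * 5)
        dc, trig = eng.dice_trigger(segs, ref, theta=0.5)
        assert dc == 0.5 and not trig

    def test_vs_printed_examples(self):
        cm = np.zeros((10, 10), dtype=int)
        cm.flat[:60] = 5    # high variability
        cm.flat[60:100] = 10  # low variability
        vs, vmap, trig = eng.variability_score(cm)
        assert vs == pytest.approx(0.6) and trig
        assert (vmap == 2).sum() == 60 and (vmap == 1).sum() == 40

    def test_vs_tipping_point_no_trigger(self):
        cm = np.zeros((20, 20), dtype=int)
        cm.flat[:50] = 4
        cm.flat[50:100] = 9
        vs, _, trig = eng.variability_score(cm)
        assert vs == 0.5 and not trig

    def test_vs_unanimous_ensemble(self):
        cm = np.zeros((8, 8), dtype=int)
        cm[0:4] = 10
        vs, _, trig = eng.variability_score(cm)
        assert vs == 0.0 and not trig

    def test_vs_empty_foreground_defined_zero(self):
        vs, _, trig = eng.variability_score(np.zeros((5, 5), dtype=int))
        assert vs == 0.0 and not trig

    def test_triggers_match_bruteforce_oracle(self):
        """1,000 random count maps vs an explicit pixel-count recomputation."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            cm = rng.integers(0, 11, size=(12, 12))
            vs, _, trig = eng.variability_score(cm)
            n_low = n_high = 0
            for val in cm.ravel():
                if val == 0:
                    continue
                if val in (1, 2, 9, 10):
                    n_low += 1
                else:
                    n_high += 1
            expect = n_high / (n_high + n_low) if n_high + n_low else 0.0
            assert vs == pytest.approx(expect, abs=1e-12)
            assert trig == (expect > 0.5)

    def test_vs_monotone_in_high_pixels(self, rng):
        """Converting a low-variability pixel to high never decreases VS."""
        cm = rng.integers(0, 11, size=(10, 10))
        vs0 = eng.variability_score(cm)[0]
        low_pos = np.argwhere((cm > 0) & ((cm <= 2) | (cm >= 9)))
        if len(low_pos):
            r, c = low_pos[0]
            cm2 = cm.copy()
            cm2[r, c] = 5
            assert eng.variability_score(cm2)[0] >= vs0


def _run(policy, seed, mix, n_frames=15, change_frame=8):
    geom = eng.LoopGeometry()
    provider = eng.scripted_change_provider(seed, geom, change_frame)
    scope = eng.SimulatedMicroscope(provider, seed=seed, geometry=geom)
    gen = eng.GroundTruthGenerator(scope, mix_prob=mix)
    return eng.run_assisted_sequence(
        scope, policy, gen, eng.ThresholdSegmenter(), n_frames=n_frames, seed=seed
    )


class TestClosedLoop:
    def test_static_sample_never_triggers_dc(self):
        """A perfect generator on an unchanging sample keeps DC near 1."""
        geom = eng.LoopGeometry()
        dm = eng.scripted_change_provider(5, geom, change_frame=99)(0)
        scope = eng.SimulatedMicroscope(lambda f: dm, seed=5, geometry=geom)
        gen = eng.GroundTruthGenerator(scope, mix_prob=0.0)
        records, steds = eng.run_assisted_sequence(
            scope, "dc", gen, eng.ThresholdSegmenter(), n_frames=6, seed=5
        )
        assert not any(r.triggered for r in records)
        assert all(r.value > 0.9 for r in records)
        assert set(steds) == {0, 7}  # only the two reference frames

    def test_scripted_change_triggers_both_policies(self):
        for policy, mix in (("dc", 0.0), ("vs", 0.5)):
            records, _ = _run(policy, seed=11, mix=mix)
            fired = [r.frame_index for r in records if r.triggered]
            assert fired and abs(fired[0] - 8) <= 1
            for r in records:
                r.check()  # trigger invariant audit

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError):
            _run("both", seed=1, mix=0.0)


class TestDose:
    def _records(self, trigger_frames, n_frames=15, geom=eng.LoopGeometry()):
        roi = geom.roi_rect
        sub = (0, 0, geom.block_px, geom.block_px)
        recs = []
        for f in range(1, n_frames + 1):
            acqs = [
                {"modality": "confocal", "rect": (0, 0, geom.fov_px, geom.fov_px),
                 "dose": 0.0},
                {"modality": "sted", "rect": sub, "dose": 0.0},
            ]
            trig = f in trigger_frames
            if trig:
                acqs.append({"modality": "sted", "rect": roi, "dose": 0.0})
            recs.append(eng.DecisionRecord(
                frame_index=f, policy="dc", value=0.4 if trig else 0.9,
                threshold=0.5, triggered=trig, reference_frame=0,
                subregion_rect=sub, cumulative_dose={}, acquisitions=acqs,
            ))
        return recs

    def test_printed_89_percent_reduction(self):
        """1.6 STED per 15-frame sequence reduces the ROI dose by 89%."""
        counts = [2, 1, 2, 1, 2]  # mean 1.6 triggers across five sequences
        reductions = []
        for k in counts:
            recs = self._records(set(range(1, k + 1)))
            rep = eng.light_dose_summary(recs)
            reductions.append(rep["reduction_excluding_references"])
        assert round(100 * np.mean(reductions)) == 89

    def test_zero_triggers_full_reduction(self):
        rep = eng.light_dose_summary(self._records(set()))
        # only the negligible confocal overhead remains
        assert rep["reduction_excluding_references"] == pytest.approx(1.0, abs=1e-3)

    def test_all_triggers_no_reduction(self):
        rep = eng.light_dose_summary(self._records(set(range(1, 16))))
        assert rep["reduction_excluding_references"] == pytest.approx(0.0, abs=1e-3)

    def test_ledger_additive_and_permutation_invariant(self):
        recs = self._records({3, 7})
        rep1 = eng.light_dose_summary(recs)
        rep2 = eng.light_dose_summary(list(reversed(recs)))
        assert rep1["roi_dose_assisted"] == rep2["roi_dose_assisted"]
        total = sum(rep1["roi_dose_assisted"].values())
        parts = [
            sum(eng.light_dose_summary([r])["roi_dose_assisted"].values())
            for r in recs
        ]
        assert total == pytest.approx(sum(parts))
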