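"""Reference limits (UL = mu + 2 sigma, LL = fat-mode) and the FFG/MEG
pixel-fraction predictors."""
from __future__ import annotations

import numpy as np
import pytest

import stirqmri as sq
from stirqmri import wf3
from stirqmri.phantoms import RoiMaskSet, SliceImage, Subject


def subject_from_pixels(muscle_pixels: dict[str, np.ndarray],
                        subcut: np.ndarray | None = None,
                        cohort="HC") -> Subject:
    """Assemble a one-slice subject whose named ROIs hold given values."""
    blocks = []
    labels = {}
    col = 0
    rows = max(len(v) for v in muscle_pixels.values())
    if subcut is not None:
        rows = max(rows, len(subcut))
    width = len(muscle_pixels) + (1 if subcut is not None else 0)
    img = np.zeros((rows, width))
    for name, vals in muscle_pixels.items():
        img[:len(vals), col] = vals
        m = np.zeros_like(img, dtype=bool)
        m[:len(vals), col] = True
        labels[name] = m
        col += 1
    if subcut is not None:
        img[:len(subcut), col] = subcut
        m = np.zeros_like(img, dtype=bool)
        m[:len(subcut), col] = True
        labels["SUBCUT_FAT"] = m
    sl = SliceImage(img, 1.0, 5.0)
    return Subject("T000", cohort, [sl], [RoiMaskSet(labels=labels)])


class TestReferenceLimits:
    def test_ul_is_mean_plus_two_sd(self):
        # pixels [90, 110]: mean 100, population SD 10 -> UL 120
        pixels = {f"{m}_{s}": np.array([90.0, 110.0])
                  for m in sq.MUSCLES for s in sq.SIDES}
        subj = subject_from_pixels(pixels, subcut=np.array([30.0] * 5))
        limits = wf3.compute_reference_limits([subj])
        for m in sq.MUSCLES:
            assert limits.UL[m] == pytest.approx(120.0)

    def test_ll_is_histogram_mode_with_low_tie_break(self):
        pixels = {f"{m}_{s}": np.array([100.0, 100.0])
                  for m in sq.MUSCLES for s in sq.SIDES}
        fat = np.concatenate([np.full(500, 30.0), np.full(20, 60.0)])
        subj = subject_from_pixels(pixels, subcut=fat)
        limits = wf3.compute_reference_limits([subj])
        assert limits.LL == 30.0

    def test_mode_robust_to_vessel_admixture(self):
        rng = np.random.default_rng(0)
        fat = rng.normal(30.0, 8.0, 20_000)
        vessels = rng.normal(220.0, 15.0, 1_000)     # 5% admixture
        assert (wf3._histogram_mode(fat, 1.0)
                == wf3._histogram_mode(np.concatenate([fat, vessels]), 1.0))

    def test_limits_on_default_hc_cohort(self, wf3_default_tables):
        limits, _ = wf3_default_tables
        assert abs(limits.LL - 30.0) <= 1.0
        for m in sq.MUSCLES:
            assert abs(limits.UL[m] - 120.0) < 1.0
        assert limits.LL < min(limits.UL.values())

    def test_missing_subcut_fat_errors(self):
        pixels = {f"{m}_{s}": np.array([90.0, 110.0])
                  for m in sq.MUSCLES for s in sq.SIDES}
        subj = subject_from_pixels(pixels, subcut=None)
        with pytest.raises(ValueError):
            wf3.compute_reference_limits([subj])

    def test_per_subject_pooling_switch(self, hc_small):
        pooled = wf3.compute_reference_limits(hc_small, pooling="pooled")
        per = wf3.compute_reference_limits(hc_small, pooling="per_subject")
        for m in sq.MUSCLES:                 # same law -> close, not equal
            assert abs(pooled.UL[m] - per.UL[m]) < 1.0


class TestFfgMeg:
    def test_ffg_counting_example(self):
        pixels = {f"{m}_{s}": np.array([10.0, 20.0, 40.0, 50.0])
                  for m in sq.MUSCLES for s in sq.SIDES}
        subj = subject_from_pixels(pixels, cohort="FSHD")
        limits = wf3.ReferenceLimits(UL={m: 120.0 for m in sq.MUSCLES},
                                     LL=30.0)
        w = wf3.compute_ffg_meg(subj, "S", limits)
        assert w.FFG == pytest.approx(0.50)

    def test_meg_counting_example(self):
        pixels = {f"{m}_{s}": np.array([100.0, 130.0, 90.0, 125.0])
                  for m in sq.MUSCLES for s in sq.SIDES}
        subj = subject_from_pixels(pixels, cohort="FSHD")
        limits = wf3.ReferenceLimits(UL={m: 120.0 for m in sq.MUSCLES},
                                     LL=30.0)
        w = wf3.compute_ffg_meg(subj, "MG", limits)
        assert w.MEG == pytest.approx(0.50)

    def test_pixels_inside_limits_give_zero(self):
        pixels = {f"{m}_{s}": np.array([50.0, 60.0, 80.0])
                  for m in sq.MUSCLES for s in sq.SIDES}
        subj = subject_from_pixels(pixels, cohort="FSHD")
        limits = wf3.ReferenceLimits(UL={m: 120.0 for m in sq.MUSCLES},
                                     LL=30.0)
        w = wf3.compute_ffg_meg(subj, "LG", limits)
        assert w.FFG == 0.0 and w.MEG == 0.0

    def test_strict_inequalities_at_boundaries(self):
        pixels = {f"{m}_{s}": np.array([30.0, 120.0])
                  for m in sq.MUSCLES for s in sq.SIDES}
        subj = subject_from_pixels(pixels, cohort="FSHD")
        limits = wf3.ReferenceLimits(UL={m: 120.0 for m in sq.MUSCLES},
                                     LL=30.0)
        w = wf3.compute_ffg_meg(subj, "S", limits)
        assert w.FFG == 0.0 and w.MEG == 0.0     # boundary pixels excluded

    def test_invariant_under_joint_intensity_shift(self, hc_small,
                                                   fshd_small):
        """Applying a strictly increasing (bin-respecting) intensity map
        to every image and recomputing the limits leaves FFG/MEG
        unchanged: the predictors depend on ranks relative to the
        cohort-derived thresholds, not on the absolute scale."""
        def warp(subjects):
            import copy
            out = copy.deepcopy(subjects)
            for s in out:
                for sl in s.slices:
                    sl.pixels = sl.pixels + 7.0
            return out

        limits = wf3.compute_reference_limits(hc_small, bin_width=1.0)
        limits_w = wf3.compute_reference_limits(warp(hc_small), bin_width=1.0)
        assert limits_w.LL == pytest.approx(limits.LL + 7.0)
        subj = fshd_small[0]
        subj_w = warp([subj])[0]
        for muscle in sq.MUSCLES:
            a = wf3.compute_ffg_meg(subj, muscle, limits)
            b = wf3.compute_ffg_meg(subj_w, muscle, limits_w)
            assert a.FFG == pytest.approx(b.FFG, abs=1e-12)
            assert a.MEG == pytest.approx(b.MEG, abs=1e-12)


class TestWf3Tables:
    def test_table_structure(self, wf3_default_tables, fshd_default):
        _, tables = wf3_default_tables
        assert set(tables) == set(sq.MUSCLES)
        for muscle in sq.MUSCLES:
            assert list(tables[muscle]["FF"].columns) == ["FFG", "FF_pp"]
            assert list(tables[muscle]["wT2"].columns) == ["MEG", "wT2_ms"]
            assert len(tables[muscle]["FF"]) == len(fshd_default)

    def test_zero_fat_override_gives_tiny_ffg(self, hc_small):
        cohort = sq.generate_fshd_cohort(
            sq.PhantomParams(n_subjects=3, seed=2, image_size=(96, 96)),
            latent_override=(0.0, 0.0))
        limits = wf3.compute_reference_limits(hc_small)
        tables = wf3.build_wf3_tables(cohort, limits)
        for muscle in sq.MUSCLES:
            assert (tables[muscle]["FF"]["FFG"] <= 0.02).all()

    def test_deterministic_given_cohort_and_limits(self, hc_small,
                                                   fshd_small):
        limits = wf3.compute_reference_limits(hc_small)
        t1 = wf3.build_wf3_tables(fshd_small, limits)
        t2 = wf3.build_wf3_tables(fshd_small, limits)
        for muscle in sq.MUSCLES:
            assert t1[muscle]["FF"].equals(t2[muscle]["FF"])

    def test_latent_monotonicity_construct_validity(self, fshd_default,
                                                    wf3_default_tables):
        """Spearman correlation between the latent fat fraction and FFG
        (and edema fraction vs MEG) exceeds 0.9 across >= 50 ROIs: the
        bespoke features actually track the tissue state they name."""
        from scipy.stats import spearmanr
        limits, _ = wf3_default_tables
        f_lat, ffg, e_lat, meg = [], [], [], []
        for subj in fshd_default:
            for muscle in sq.MUSCLES:
                w = wf3.compute_ffg_meg(subj, muscle, limits)
                f_lat.append(np.mean([subj.latent[(muscle, s)]["f"]
                                      for s in sq.SIDES]))
                e_lat.append(np.mean([subj.latent[(muscle, s)]["e"]
                                      for s in sq.SIDES]))
                ffg.append(w.FFG)
                meg.append(w.MEG)
        assert len(ffg) >= 50
        assert spearmanr(f_lat, ffg).statistic > 0.9
        assert spearmanr(e_lat, meg).statistic > 0.9
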