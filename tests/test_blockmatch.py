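"""Tests for RF up-sampling, pyramids, NCC surfaces and multi-level tracking."""

import numpy as np
import pytest

import echostrain as es
from echostrain._interp import (FLAG_BOUNDARY, FLAG_DEGENERATE, subsample_peak)
from echostrain.blockmatch import (BMConfig, DisplacementField, RFFrame,
                                   _LevelConfig, build_pyramid, compand_rf,
                                   compute_smi, compute_smi_stack,
                                   estimate_displacement_multilevel,
                                   resolve_level, upsample_rf)

from _oracles import ncc_direct


def frame_of(arr, fs=40.0, pitch=0.2, f0=8.0):
    return RFFrame(arr, fs, pitch, f0)


class TestUpsample:
    def test_identity_factors(self, rng):
        f = frame_of(rng.normal(0, 1, (50, 20)))
        g = upsample_rf(f, 1, 1)
        np.testing.assert_array_equal(g.samples, f.samples)

    def test_non_integer_factor_rejected(self, rng):
        f = frame_of(rng.normal(0, 1, (10, 10)))
        with pytest.raises(ValueError):
            upsample_rf(f, 1.5, 1)

    def test_nodes_preserved(self, rng):
        f = frame_of(rng.normal(0, 1, (40, 16)))
        g = upsample_rf(f, 2, 2)
        np.testing.assert_array_equal(g.samples[::2, ::2], f.samples)
        assert g.axial_fs == 2 * f.axial_fs
        assert g.pitch == f.pitch / 2

    def test_sinusoid_analytic_oracle(self):
        # band-limited tone well below Nyquist: interpolation error < 1e-3
        n = np.arange(120)
        tone = np.sin(2 * np.pi * 0.12 * n)
        f = frame_of(np.tile(tone[:, None], (1, 8)))
        g = upsample_rf(f, 2, 1)
        m = np.arange(g.shape[0]) / 2.0
        expect = np.sin(2 * np.pi * 0.12 * m)
        interior = slice(40, -40)
        err = np.abs(g.samples[interior, 4] - expect[interior])
        assert err.max() < 1e-3

    def test_impulse_gives_windowed_sinc_kernel(self):
        from echostrain._interp import hann_sinc_kernel
        a = np.zeros((9, 41))
        a[4, 20] = 1.0
        g = upsample_rf(frame_of(a), 1, 2)
        kern = hann_sinc_kernel(2)
        prof = g.samples[4, 40 - 16:40 + 17]
        np.testing.assert_allclose(prof, kern, atol=1e-12)


class TestPyramid:
    def test_unity_level_equals_input(self, rng):
        f = frame_of(rng.normal(0, 1, (60, 30)))
        cfg = BMConfig(n_levels=1, axial_decimation=(1,), lateral_decimation=(1,),
                       axial_kernel_wavelengths=(3.0,), lateral_kernel_lines=(9,),
                       search_axial=(2,), search_lateral=(2,))
        lv = build_pyramid(f, cfg)
        np.testing.assert_array_equal(lv[0].samples, f.samples)

    def test_shape_arithmetic(self, rng):
        f = frame_of(rng.normal(0, 1, (300, 100)))
        lv = build_pyramid(f, BMConfig())
        assert lv[0].shape == (100, 50)
        assert lv[1].shape == (150, 100)
        assert lv[2].shape == (300, 100)

    def test_dc_preserved_at_every_level(self):
        f = frame_of(np.full((300, 100), 3.7))
        for lv in build_pyramid(f, BMConfig()):
            np.testing.assert_allclose(lv.samples, 3.7, atol=1e-9)


def level_cfg(kernel, search, rows, cols):
    return _LevelConfig(kernel=kernel, search=search, step=(1, 1),
                        rows=np.asarray(rows), cols=np.asarray(cols))


class TestComputeSMI:
    def test_no_motion_peak_one_at_zero(self, rng):
        a = rng.normal(0, 1, (80, 40))
        pre = post = frame_of(a)
        smi = compute_smi(pre, post, (40, 20), level_cfg((15, 9), (5, 3), [40], [20]))
        assert smi.values[5, 3] == pytest.approx(1.0, abs=1e-12)
        assert smi.values.max() == smi.values[5, 3]
        assert smi.values.min() >= -1.0 - 1e-12

    def test_pure_translation_peak(self, rng):
        a = rng.normal(0, 1, (80, 40))
        b = np.roll(a, (3, 0), axis=(0, 1))
        smi = compute_smi(frame_of(a), frame_of(b), (40, 20),
                          level_cfg((15, 9), (5, 3), [40], [20]))
        assert smi.values[5 + 3, 3] == pytest.approx(1.0, abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(50):
            pre = rng.normal(0, 1, (70, 45))
            post = rng.normal(0, 1, (70, 45))
            smi = compute_smi(frame_of(pre), frame_of(post), (35, 22),
                              level_cfg((31, 15), (10, 5), [35], [22]))
            direct = ncc_direct(pre, post, (35, 22), (31, 15), (10, 5))
            np.testing.assert_allclose(smi.values, direct, atol=1e-12)

    def test_stack_consistent_with_single_blocks(self, rng):
        pre = rng.normal(0, 1, (90, 50))
        post = rng.normal(0, 1, (90, 50))
        lc = level_cfg((15, 9), (4, 3), [30, 45, 60], [15, 25, 35])
        stack = compute_smi_stack(frame_of(pre), frame_of(post), lc)
        for i, r in enumerate(lc.rows):
            for j, c in enumerate(lc.cols):
                one = compute_smi(frame_of(pre), frame_of(post), (r, c),
                                  level_cfg((15, 9), (4, 3), [r], [c]))
                np.testing.assert_allclose(stack.values[i, j], one.values,
                                           atol=1e-14)

    def test_matches_skimage_match_template(self, rng):
        # independent library oracle for the ZNCC definition
        skimage = pytest.importorskip("skimage.feature")
        pre = rng.normal(0, 1, (60, 40))
        post = rng.normal(0, 1, (60, 40))
        r, c, ka, kl, sa, sl = 30, 20, 15, 9, 6, 4
        smi = compute_smi(frame_of(pre), frame_of(post), (r, c),
                          level_cfg((ka, kl), (sa, sl), [r], [c]))
        template = pre[r - 7:r + 8, c - 4:c + 5]
        image = post[r - 7 - sa:r + 8 + sa, c - 4 - sl:c + 5 + sl]
        ref = skimage.match_template(image, template)
        np.testing.assert_allclose(smi.values, ref, atol=1e-7)

    def test_zero_variance_window_flagged_zero(self):
        pre = np.zeros((60, 30))
        pre[28:33, 14:17] = 1.0
        post = np.zeros((60, 30))
        smi = compute_smi(frame_of(pre), frame_of(post), (30, 15),
                          level_cfg((11, 7), (3, 2), [30], [15]))
        np.testing.assert_array_equal(smi.values, 0.0)


class TestSubsamplePeak:
    def test_grid_aligned_delta(self):
        s = np.zeros((7, 5))
        s[4, 3] = 1.0
        a, l, fl = subsample_peak(s, (-3, -2))
        assert (a, l) == (1.0, 1.0) and fl == 0

    def test_raised_cosine_oracle(self):
        a = np.arange(-7, 8)
        A, L = np.meshgrid(a, a, indexing="ij")
        r = np.sqrt((A - 1.37) ** 2 + (L + 0.52) ** 2)
        surf = np.where(r < 6, 0.5 * (1 + np.cos(np.pi * r / 6)), 0.0)
        pa, pl, fl = subsample_peak(surf, (-7, -7))
        assert abs(pa - 1.37) <= 0.02 and abs(pl + 0.52) <= 0.02

    def test_symmetric_tie_breaks_to_lower_magnitude(self):
        s = np.zeros((7, 7))
        s[1, 3] = s[5, 3] = 0.9   # lags -2 and +2 axially
        s[3, 3] = 0.9             # and 0: all tied
        a, l, fl = subsample_peak(s, (-3, -3), exact_peak_tol=0.0)
        assert (a, l) == (0.0, 0.0)
        s2 = np.zeros((7, 7))
        s2[1, 3] = s2[5, 3] = 1.0  # only -2 / +2 tie: negative (smaller axial) wins
        a2, _, _ = subsample_peak(s2, (-3, -3))
        assert a2 == -2.0

    def test_flat_surface_degenerate(self):
        a, l, fl = subsample_peak(np.full((5, 5), 0.4), (-2, -2))
        assert (a, l) == (0.0, 0.0)
        assert fl & FLAG_DEGENERATE

    def test_boundary_peak_flagged(self):
        s = np.zeros((5, 5))
        s[0, 2] = 0.9
        a, l, fl = subsample_peak(s, (-2, -2))
        assert fl & FLAG_BOUNDARY and a == -2.0


class TestCompand:
    def _field(self, ax, lat, rows, cols):
        return DisplacementField(np.asarray(ax, float), np.asarray(lat, float),
                                 np.asarray(rows, float), np.asarray(cols, float),
                                 dz_mm=0.01, pitch_mm=0.2)

    def test_zero_field_identity(self, rng):
        post = frame_of(rng.normal(0, 1, (50, 30)))
        f = self._field(np.zeros((3, 3)), np.zeros((3, 3)),
                        [10, 25, 40], [5, 15, 25])
        out = compand_rf(post, f)
        np.testing.assert_array_equal(out.samples, post.samples)

    def test_uniform_integer_shift_exact(self, rng):
        a = rng.normal(0, 1, (50, 30))
        post = frame_of(a)
        f = self._field(np.full((3, 3), 4.0), np.full((3, 3), -2.0),
                        [10, 25, 40], [5, 15, 25])
        out = compand_rf(post, f)
        np.testing.assert_array_equal(out.samples[:-4, 2:], a[4:, :-2])

    def test_linear_strain_field_residual_centered(self, rng):
        # after companding by a 1% axial ramp, interior NCC peaks at lag 0
        depth, lines = 200, 40
        a = rng.normal(0, 1, (depth + 20, lines))
        rowpos = np.arange(depth)
        disp = 0.01 * (rowpos - depth / 2)
        src = np.clip(np.rint(rowpos + disp).astype(int), 0, depth + 19)
        b = a[src]  # post frame: pre warped by the ramp (integer gather)
        rows = np.arange(20, 180, 20)
        f = self._field(np.tile(disp[rows][:, None], (1, 3)),
                        np.zeros((len(rows), 3)), rows, [10, 20, 30])
        out = compand_rf(frame_of(b), f)
        lc = level_cfg((15, 9), (3, 2), [100], [20])
        smi = compute_smi(frame_of(a[:depth]), out, (100, 20), lc)
        ia = np.unravel_index(smi.values.argmax(), smi.values.shape)
        assert ia == (3, 2)  # lag (0, 0)


class TestMultilevel:
    def test_wrong_frame_count_rejected(self, speckle_pair):
        seq, _ = speckle_pair
        with pytest.raises(ValueError, match="exactly 2"):
            estimate_displacement_multilevel(seq.frames[:3], BMConfig(), "none")
        with pytest.raises(ValueError, match="exactly 4"):
            estimate_displacement_multilevel(seq.frames[:2], BMConfig(), "stbr2")

    def test_translation_recovered_exactly(self, speckle_pair):
        seq, _ = speckle_pair
        f = estimate_displacement_multilevel(seq.frames[:2], BMConfig(), "none")
        interior = (slice(3, -3), slice(5, -5))
        assert np.abs(f.axial[interior] - 4.0).max() < 1e-6
        assert np.abs(f.lateral[interior] - 1.0).max() < 1e-6

    def test_shift_equivariance_zero_relative_motion(self, speckle_pair):
        seq, _ = speckle_pair
        pre = seq.frames[0]
        f1 = estimate_displacement_multilevel([pre, pre], BMConfig(), "none")
        shifted = RFFrame(np.roll(pre.samples, (7, 2), axis=(0, 1)),
                          pre.axial_fs, pre.pitch, pre.center_frequency)
        f2 = estimate_displacement_multilevel([shifted, shifted], BMConfig(),
                                              "none")
        interior = (slice(2, -2), slice(3, -3))
        np.testing.assert_allclose(f1.axial[interior], 0.0, atol=1e-9)
        np.testing.assert_allclose(f2.axial[interior], f1.axial[interior],
                                   atol=1e-9)
        np.testing.assert_allclose(f2.lateral[interior], f1.lateral[interior],
                                   atol=1e-9)

    def test_zero_motion_noisy_median_small(self, imaging):
        scene = es.SceneConfig(imaging=imaging, n_frames=4, snr_db=40.0, seed=21)
        seq, _ = es.generate_sequence(scene)
        f = estimate_displacement_multilevel(seq.frames[:2], BMConfig(), "none")
        good = f.flags == 0
        assert np.median(np.abs(f.axial[good])) < 0.05
        assert np.median(np.abs(f.lateral[good])) < 0.05

    def test_uniform_strain_recovered(self, imaging):
        center = (4.0, (imaging.lines - 1) * imaging.pitch / 2)
        motion = es.MotionModel.uniform_strain((0.01, 0.0), center)
        scene = es.SceneConfig(imaging=imaging, motion=motion, n_frames=4,
                               snr_db=None, seed=7)
        seq, _ = es.generate_sequence(scene)
        f = estimate_displacement_multilevel(seq.frames[:2], BMConfig(), "none")
        # LS slope of axial displacement vs depth = strain
        interior = (slice(3, -3), slice(5, -5))
        rows_mm = f.rows_mm[interior[0]]
        prof = f.axial_mm[interior].mean(axis=1)
        slope = np.polyfit(rows_mm, prof, 1)[0]
        assert slope == pytest.approx(0.01, rel=0.1)

    def test_ncc_bound_and_autocorr_peak(self, speckle_pair, rng):
        seq, _ = speckle_pair
        pre = seq.frames[0]
        up = upsample_rf(pre, 1, 2)
        lv = build_pyramid(up, BMConfig())[2]
        lc = resolve_level(lv.shape, BMConfig(), 2, up.wavelength_samples)
        stack = compute_smi_stack(lv, lv, lc)
        assert stack.values.max() <= 1.0 + 1e-12
        assert stack.values.min() >= -1.0 - 1e-12
        sa, sl = lc.search
        center_peak = stack.values[:, :, sa, sl]
        np.testing.assert_allclose(center_peak, 1.0, atol=1e-12)
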