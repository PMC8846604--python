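"""Unit and oracle tests for the Bayesian SMI regularizers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import echostrain as es
from echostrain.bayes import (NeighborhoodSpec, RegularizationParams,
                              _likelihood, couple_sigma, map_displacement,
                              neighbor_likelihood, sbr_posterior, smi_to_pdf,
                              stbr1_posterior, stbr2_posterior)

from _oracles import likelihood_direct, sbr_direct, stbr1_direct, stbr2_direct
from conftest import random_pdf_grid


def assert_valid_pdf(p):
    assert p.min() >= 0
    np.testing.assert_allclose(p.sum(axis=(-2, -1)), 1.0, atol=1e-12)


class TestSmiToPdf:
    def test_stated_transform_arithmetic(self):
        smi = np.array([[1.0, -1.0], [0.0, 0.5]])
        expect = np.array([[2.0, 0.0], [1.0, 1.5]]) / 4.5
        np.testing.assert_allclose(smi_to_pdf(smi), expect, atol=1e-12)

    def test_constant_smi_gives_uniform(self):
        p = smi_to_pdf(np.full((5, 7), 0.3))
        np.testing.assert_allclose(p, 1.0 / 35, atol=1e-12)

    def test_all_minus_one_gives_uniform(self):
        p = smi_to_pdf(np.full((3, 3), -1.0))
        np.testing.assert_allclose(p, 1.0 / 9, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            smi_to_pdf(np.array([[2.0, 0.0], [0.0, 0.0]]))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_any_valid_smi_yields_valid_pdf(self, seed):
        r = np.random.default_rng(seed)
        smi = r.uniform(-1, 1, (7, 5))
        assert_valid_pdf(smi_to_pdf(smi))


class TestCoupleSigma:
    def test_stated_coupling_rule(self):
        np.testing.assert_allclose(couple_sigma((0.01, 0.01), (50, 50)),
                                   (0.5, 0.5))

    def test_degenerate_spacing_rejected(self):
        with pytest.raises(ValueError):
            couple_sigma((0.01, 0.01), (0, 5))

    def test_homogeneity(self):
        one = couple_sigma((0.02, 0.03), (10, 7))
        two = couple_sigma((0.04, 0.06), (10, 7))
        np.testing.assert_allclose(two, 2 * one)


class TestNeighborLikelihood:
    def test_delta_pdf_gives_truncated_gaussian(self):
        pdf = np.zeros((9, 9))
        pdf[4, 4] = 1.0  # lag (0, 0) at grid center
        L = neighbor_likelihood(pdf, (1.0, 1.0))
        ua, ul = np.meshgrid(np.arange(9) - 4, np.arange(9) - 4, indexing="ij")
        expect = np.where((np.abs(ua) <= 3) & (np.abs(ul) <= 3),
                          np.exp(-(ua ** 2 + ul ** 2) / 2.0), 1e-12)
        expect = np.maximum(expect, 1e-12)
        np.testing.assert_allclose(L, expect, atol=1e-14)

    def test_uniform_pdf_constant_interior(self):
        L = neighbor_likelihood(np.full((9, 9), 1.0 / 81), (1.5, 1.5))
        assert np.allclose(L, L[4, 4])

    def test_matches_double_max_brute_force(self, rng):
        pdf = rng.random((7, 7))
        pdf /= pdf.sum()
        L = neighbor_likelihood(pdf, (1.2, 0.8))
        np.testing.assert_allclose(L, likelihood_direct(pdf, (1.2, 0.8)),
                                   atol=1e-14)

    def test_infinite_sigma_gives_flat_max(self, rng):
        pdf = rng.random((5, 5))
        pdf /= pdf.sum()
        L = _likelihood(pdf, np.array([np.inf, np.inf]), 1e-12)
        np.testing.assert_allclose(L, pdf.max(), atol=1e-15)


# lag-unit sigmas passed straight through the strain coupling: spacing of 1
UNIT_SPACING = (1, 1)


def params_with(sigma_s, sigma_t=(1.0, 1.0), **kw):
    return RegularizationParams(sigma_eps=sigma_s, sigma_t=sigma_t,
                                coupling_mode="lag", **kw)


class TestSBR:
    def test_consensus_fixed_point_keeps_argmax(self, rng):
        base = np.zeros((9, 9))
        base[4, 4] = 1.0
        base = smi_to_pdf(base * 2 - 1)  # symmetric single-peak pdf
        grid = np.tile(base, (3, 3, 1, 1))
        post = sbr_posterior(grid, params_with((1.0, 1.0)), UNIT_SPACING)
        for i in range(3):
            for j in range(3):
                assert np.unravel_index(post[i, j].argmax(), (9, 9)) == (4, 4)
        assert_valid_pdf(post)

    def test_outlier_block_pulled_to_consensus(self, rng):
        grid = np.zeros((3, 3, 7, 7))
        peaked = np.zeros((7, 7))
        peaked[3, 3] = 5.0
        peaked += 0.1
        for i in range(3):
            for j in range(3):
                grid[i, j] = peaked / peaked.sum()
        outlier = np.zeros((7, 7))
        outlier[0, 6] = 5.0
        outlier += 0.1
        grid[1, 1] = outlier / outlier.sum()
        post = sbr_posterior(grid, params_with((1.0, 1.0)), UNIT_SPACING)
        assert np.unravel_index(post[1, 1].argmax(), (7, 7)) == (3, 3)

    def test_no_neighbors_returns_prior(self, rng):
        grid = random_pdf_grid(rng, (2, 2), (7, 7))
        spec = NeighborhoodSpec.empty((2, 2))
        post = sbr_posterior(grid, params_with((1.0, 1.0)), UNIT_SPACING, spec)
        np.testing.assert_allclose(post, grid, atol=1e-12)

    def test_matches_brute_force(self, rng):
        grid = random_pdf_grid(rng, (3, 3), (9, 9))
        post = sbr_posterior(grid, params_with((1.3, 0.9)), UNIT_SPACING)
        np.testing.assert_allclose(post, sbr_direct(grid, (1.3, 0.9)),
                                   atol=1e-12)

    def test_neighbor_order_permutation_invariant(self, rng):
        # transposing the grid swaps left/right with top/bottom neighbor roles
        grid = random_pdf_grid(rng, (3, 3), (7, 7))
        sig = params_with((1.1, 1.1))
        a = sbr_posterior(grid, sig, UNIT_SPACING)
        b = sbr_posterior(grid.transpose(1, 0, 2, 3).copy(), sig, UNIT_SPACING)
        np.testing.assert_allclose(a, b.transpose(1, 0, 2, 3), atol=1e-12)


class TestSTBR:
    def test_stbr1_matches_brute_force(self, rng):
        grids = [random_pdf_grid(rng, (3, 3), (7, 7)) for _ in range(3)]
        post = stbr1_posterior(*grids, params_with((1.2, 0.7), (0.9, 1.4)),
                               UNIT_SPACING)
        np.testing.assert_allclose(
            post, stbr1_direct(*grids, (1.2, 0.7), (0.9, 1.4)), atol=1e-12)

    def test_stbr2_matches_brute_force(self, rng):
        grids = [random_pdf_grid(rng, (3, 3), (9, 9)) for _ in range(3)]
        post = stbr2_posterior(*grids, params_with((1.0, 1.5), (0.8, 0.8)),
                               UNIT_SPACING)
        np.testing.assert_allclose(
            post, stbr2_direct(*grids, (1.0, 1.5), (0.8, 0.8)), atol=1e-12)

    def test_temporal_outlier_corrected(self, rng):
        peaked = np.zeros((7, 7))
        peaked[2, 2] = 5.0
        peaked += 0.1
        peaked /= peaked.sum()
        outlier = np.zeros((7, 7))
        outlier[6, 6] = 5.0
        outlier += 0.1
        outlier /= outlier.sum()
        past = np.tile(peaked, (1, 1, 1, 1))
        future = np.tile(peaked, (1, 1, 1, 1))
        present = np.tile(outlier, (1, 1, 1, 1))
        post = stbr1_posterior(past, present, future,
                               params_with((1.0, 1.0), (1.0, 1.0)),
                               UNIT_SPACING)
        assert np.unravel_index(post[0, 0].argmax(), (7, 7)) == (2, 2)

    def test_stbr1_missing_neighbors_falls_back_to_sbr(self, rng):
        grid = random_pdf_grid(rng, (3, 3), (7, 7))
        p = params_with((1.0, 1.0), (0.5, 0.5))
        post = stbr1_posterior(None, grid, None, p, UNIT_SPACING)
        np.testing.assert_allclose(
            post, sbr_posterior(grid, p, UNIT_SPACING, n_iterations=1),
            atol=1e-12)

    def test_stbr2_flat_temporal_limit_reduces_to_sbr(self, rng):
        grids = [random_pdf_grid(rng, (3, 3), (9, 9)) for _ in range(3)]
        p_inf = params_with((1.0, 1.0), (np.inf, np.inf))
        post = stbr2_posterior(*grids, p_inf, UNIT_SPACING)
        sbr = sbr_posterior(grids[1], p_inf, UNIT_SPACING)
        np.testing.assert_allclose(post, sbr, atol=1e-9)

    def test_stbr1_flat_temporal_limit_keeps_stage1(self, rng):
        grids = [random_pdf_grid(rng, (2, 2), (7, 7)) for _ in range(3)]
        p_inf = params_with((1.0, 1.0), (np.inf, np.inf))
        post = stbr1_posterior(*grids, p_inf, UNIT_SPACING)
        stage1 = sbr_posterior(grids[1], p_inf, UNIT_SPACING, n_iterations=1)
        np.testing.assert_allclose(post, stage1, atol=1e-9)


class TestLagReferences:
    def test_constant_reference_changes_nothing(self, rng):
        grid = random_pdf_grid(rng, (3, 3), (9, 9))
        ref = (np.full((3, 3), 7, dtype=int), np.full((3, 3), -2, dtype=int))
        a = sbr_posterior(grid, params_with((1.0, 1.0)), UNIT_SPACING)
        b = sbr_posterior(grid, params_with((1.0, 1.0)), UNIT_SPACING,
                          lag_ref=ref)
        np.testing.assert_allclose(a, b, atol=1e-14)

    def test_reference_shift_aligns_neighbors(self, rng):
        # two blocks with identical physics but lag origins offset by 1:
        # block 1's surface is block 0's shifted by -1 axial lag.  With the
        # references supplied, the posterior argmaxes must agree physically.
        base = np.zeros((9, 9))
        base[5, 4] = 4.0
        base += 0.05
        pdf0 = base / base.sum()
        pdf1 = np.roll(pdf0, -1, axis=0)  # same total lag, origin +1
        grid = np.stack([pdf0, pdf1])[:, None]
        ref = (np.array([[0], [1]]), np.array([[0], [0]]))
        post = sbr_posterior(grid, params_with((1.0, 1.0)), UNIT_SPACING,
                             lag_ref=ref)
        a0 = np.unravel_index(post[0, 0].argmax(), (9, 9))
        a1 = np.unravel_index(post[1, 0].argmax(), (9, 9))
        assert a0[0] + 0 == a1[0] + 1  # total lag equal
        assert a0[1] == a1[1]


class TestMapDisplacement:
    def test_delta_posterior_exact(self):
        post = np.zeros((7, 7))
        post[5, 2] = 1.0
        a, l, fl = map_displacement(post, lag_offset=(-3, -3))
        assert (a, l) == (2.0, -1.0)

    def test_posterior_equal_prior_matches_raw_peak(self, rng):
        from echostrain._interp import subsample_peak
        smi = rng.uniform(-0.5, 0.9, (9, 9))
        smi[4, 5] = 0.95
        pdf = smi_to_pdf(smi)
        spec = NeighborhoodSpec.empty((1, 1))
        post = sbr_posterior(pdf[None, None], params_with((1.0, 1.0)),
                             UNIT_SPACING, spec)[0, 0]
        a1 = map_displacement(post, (-4, -4))
        a2 = subsample_peak(post, (-4, -4))
        assert a1 == a2

    def test_smooth_posterior_matches_dense_argmax(self):
        from echostrain._interp import sinc_interp_2d
        a = np.arange(-4, 5)
        A, L = np.meshgrid(a, a, indexing="ij")
        r = np.sqrt((A - 0.6) ** 2 + (L + 1.2) ** 2)
        surf = np.where(r < 4, 0.5 * (1 + np.cos(np.pi * r / 4)), 0.0)
        pdf = surf / surf.sum()
        est = map_displacement(pdf, (-4, -4))
        # dense-grid oracle on the same interpolant
        (ia, il) = np.unravel_index(pdf.argmax(), pdf.shape)
        xs = np.linspace(ia - 1, ia + 1, 2001)
        ys = np.linspace(il - 1, il + 1, 2001)
        f = sinc_interp_2d(pdf, xs, ys, 4)
        k = np.unravel_index(f.argmax(), f.shape)
        assert abs(est[0] - (xs[k[0]] - 4)) <= 0.02
        assert abs(est[1] - (ys[k[1]] - 4)) <= 0.02


def test_every_posterior_is_valid_pdf(rng):
    """Posterior validity invariant across methods, specs and sigmas."""
    for shape, lags in (((3, 3), (9, 9)), ((2, 4), (7, 5))):
        grids = [random_pdf_grid(rng, shape, lags) for _ in range(3)]
        for sig in ((0.4, 0.4), (1.5, 2.5)):
            p = params_with(sig, (0.7, 0.7))
            assert_valid_pdf(sbr_posterior(grids[1], p, UNIT_SPACING))
            assert_valid_pdf(stbr1_posterior(*grids, p, UNIT_SPACING))
            assert_valid_pdf(stbr2_posterior(*grids, p, UNIT_SPACING))
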