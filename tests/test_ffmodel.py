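import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from v2pool import ffmodel as ff
from v2pool import synthetic
from v2pool.oimaps import ORIENTATIONS, vector_sum_po_single


@pytest.fixture(scope="module")
def raster():
    return ff.make_raster((0.0, 0.0), 2.0, 0.01)


class TestGaborFilter:
    def test_unit_l2_norm(self, raster):
        for th, g in [(0.0, 1.0), (30.0, 0.5), (120.0, 2.0)]:
            f = ff.gabor_filter(ff.GaborParams(theta_c=th, gamma_c=g), raster)
            assert np.linalg.norm(f) == pytest.approx(1.0, abs=1e-10)

    def test_even_odd_symmetry(self, raster):
        even = ff.gabor_filter(ff.GaborParams(phi=0.0), raster)
        odd = ff.gabor_filter(ff.GaborParams(phi=np.pi / 2), raster)
        np.testing.assert_allclose(even, even[::-1, :], atol=1e-12)
        np.testing.assert_allclose(odd, -odd[::-1, :], atol=1e-12)

    def test_rotation_equivariance(self, raster):
        theta = 35.0
        rotated_params = ff.gabor_filter(ff.GaborParams(theta_c=theta), raster)
        th = np.deg2rad(theta)
        xr = -raster.y * np.sin(th) + raster.x * np.cos(th)
        yr = raster.y * np.cos(th) + raster.x * np.sin(th)
        rotated_grid = ff.gabor_filter(
            ff.GaborParams(theta_c=0.0), ff.Raster(x=xr, y=yr, step=raster.step))
        np.testing.assert_allclose(rotated_params, rotated_grid, atol=1e-12)

    def test_coarse_raster_rejected(self):
        coarse = ff.make_raster((0, 0), 2.0, 0.3)
        with pytest.raises(ValueError, match="coarse"):
            ff.gabor_filter(ff.GaborParams(), coarse)


class TestSimpleResponse:
    def test_self_projection(self, raster):
        f = ff.gabor_filter(ff.GaborParams(), raster)
        assert ff.simple_response(f, f) == pytest.approx(1.0)

    def test_rectification(self, raster):
        f = ff.gabor_filter(ff.GaborParams(), raster)
        assert ff.simple_response(f, -f) == 0.0

    def test_orthogonal_grating_near_zero(self, raster):
        f = ff.gabor_filter(ff.GaborParams(theta_c=0.0), raster)
        pref = ff.simple_response(f, ff.grating_image(raster, 0.0))
        orth = ff.simple_response(f, ff.grating_image(raster, 90.0))
        assert orth < 1e-3
        assert orth < 1e-3 * pref

    def test_raster_mismatch(self, raster):
        f = ff.gabor_filter(ff.GaborParams(), raster)
        with pytest.raises(ValueError):
            ff.simple_response(f, np.zeros((5, 5)))


class TestComplexResponse:
    def test_contrast_inversion_invariance(self, raster, rng):
        cell = ff.V1Cell(ff.GaborParams(theta_c=60.0))
        img = rng.standard_normal(raster.shape)
        assert ff.complex_response(cell, img, raster) \
            == pytest.approx(ff.complex_response(cell, -img, raster), abs=1e-12)

    def test_zero_image(self, raster):
        cell = ff.V1Cell(ff.GaborParams())
        assert ff.complex_response(cell, np.zeros(raster.shape), raster) == 0.0

    def test_phase_modulation_bounded_by_sqrt2(self):
        cell = ff.V1Cell(ff.GaborParams(theta_c=22.5))
        r = ff._local_raster(cell)  # covers the envelope fully
        resp = [ff.complex_response(cell,
                                    ff.grating_image(r, 22.5, phase=p), r)
                for p in np.linspace(0, 2 * np.pi, 32, endpoint=False)]
        assert min(resp) > 0
        assert max(resp) / min(resp) <= np.sqrt(2) + 1e-6

    def test_simple_mode_rejected(self, raster):
        cell = ff.V1Cell(ff.GaborParams(), mode="simple_even")
        with pytest.raises(ValueError):
            ff.complex_response(cell, np.zeros(raster.shape), raster)


class TestGratingTuning:
    def test_matches_bruteforce_phase_sampling(self):
        cell = ff.V1Cell(ff.GaborParams(theta_c=45.0, gamma_c=1.3))
        fast = ff.grating_tuning(cell, n_phases=8)
        r = ff._local_raster(cell)
        phases = 2 * np.pi * np.arange(8) / 8
        slow = np.array([
            np.mean([ff.complex_response(cell,
                                         ff.grating_image(r, ori, phase=p), r)
                     for p in phases])
            for ori in ORIENTATIONS])
        np.testing.assert_allclose(fast, slow, rtol=1e-10)

    @pytest.mark.parametrize("theta", [0.0, 36.0, 90.0, 157.5])
    def test_po_recovery(self, theta):
        cell = ff.V1Cell(ff.GaborParams(theta_c=theta))
        tun = ff.grating_tuning(cell)
        po = vector_sum_po_single(tun)
        d = abs(po - theta) % 180
        assert min(d, 180 - d) < 1.0


class TestAspectRatio:
    def test_bank_size(self):
        assert len(ff.ASPECT_RATIO_BANK) == 40
        assert ff.ASPECT_RATIO_BANK[0] == pytest.approx(0.1)
        assert ff.ASPECT_RATIO_BANK[-1] == pytest.approx(4.0)

    def test_self_consistency(self):
        cell = ff.V1Cell(ff.GaborParams(gamma_c=1.5))
        measured = ff.grating_tuning(cell)
        gamma, sse, flagged = ff.estimate_aspect_ratio(measured)
        assert not flagged
        assert gamma == pytest.approx(1.5)
        assert sse < 1e-12

    def test_flat_tuning_flagged(self):
        gamma, _, flagged = ff.estimate_aspect_ratio(np.full(8, 2.0))
        assert flagged and gamma == 1.0


class TestWeights:
    def test_identical_curves(self):
        t = synthetic.cosine_tuning(45.0)
        assert ff.compute_weights(t, t).w[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_pos(self):
        w = ff.compute_weights(synthetic.cosine_tuning(0.0),
                               synthetic.cosine_tuning(90.0)).w[0, 0]
        assert w == pytest.approx(-1.0, abs=1e-12)

    def test_45_deg_apart(self):
        w = ff.compute_weights(synthetic.cosine_tuning(0.0),
                               synthetic.cosine_tuning(45.0)).w[0, 0]
        assert w == pytest.approx(0.0, abs=1e-12)

    def test_constant_curve_excluded(self):
        wm = ff.compute_weights(np.vstack([np.full(8, 3.0),
                                           synthetic.cosine_tuning(10.0)]),
                                synthetic.cosine_tuning(10.0))
        assert wm.excluded_cells == [0]
        assert wm.w[0, 0] == 0.0

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounds_on_random_inputs(self, seed):
        r = np.random.default_rng(seed)
        w = ff.compute_weights(r.normal(size=(5, 8)), r.normal(size=(4, 8))).w
        assert np.all(w >= -1.0) and np.all(w <= 1.0)


class TestV2Response:
    def test_single_input(self):
        assert ff.v2_response(np.array([1.0]), np.array([7.3])) == 7.3

    def test_zero_weights(self, rng):
        assert ff.v2_response(np.zeros(6), rng.random(6)) == 0.0

    def test_linearity(self, rng):
        w1, w2, r = rng.normal(size=6), rng.normal(size=6), rng.random(6)
        assert ff.v2_response(w1 + 2.5 * w2, r) == pytest.approx(
            ff.v2_response(w1, r) + 2.5 * ff.v2_response(w2, r))

    def test_two_orthogonal_cells_flatten(self):
        # co-centred cells with orthogonal POs: summed tuning has a strictly
        # smaller range than either cell alone
        t0 = ff.grating_tuning(ff.V1Cell(ff.GaborParams(theta_c=0.0)))
        t90 = ff.grating_tuning(ff.V1Cell(ff.GaborParams(theta_c=90.0)))
        pair, _ = synthetic.simulate_v2_pixel(np.stack([t0, t90]), np.ones(2))
        assert np.ptp(pair) < np.ptp(t0)
        assert np.ptp(pair) < np.ptp(t90)


class TestRenderRF:
    def test_single_cell(self, raster):
        cell = ff.V1Cell(ff.GaborParams(theta_c=30.0))
        rf = ff.render_v2_rf([cell], np.array([1.0]), raster, parity="even")
        np.testing.assert_allclose(
            rf, ff.gabor_filter(ff.GaborParams(theta_c=30.0, phi=0.0), raster))

    def test_sign_flip_negates(self, raster):
        cells = [ff.V1Cell(ff.GaborParams(xc=x, theta_c=90.0))
                 for x in (-0.4, 0.0, 0.4)]
        w = np.array([0.8, 1.0, 0.6])
        a = ff.render_v2_rf(cells, w, raster, "odd")
        b = ff.render_v2_rf(cells, -w, raster, "odd")
        np.testing.assert_allclose(a, -b)

    def test_collinear_cells_elongate(self, raster):
        # cells stacked along their common orientation axis (vertical)
        single = ff.V1Cell(ff.GaborParams(theta_c=0.0))
        rf1 = ff.render_v2_rf([single], np.array([1.0]), raster, "even")
        cells = [ff.V1Cell(ff.GaborParams(xc=x, theta_c=0.0))
                 for x in (-0.5, 0.0, 0.5)]
        rf3 = ff.render_v2_rf(cells, np.ones(3), raster, "even")

        def major_second_moment(rf):
            p = rf ** 2
            p /= p.sum()
            mx = (p * raster.x).sum()
            return (p * (raster.x - mx) ** 2).sum()

        assert major_second_moment(rf3) > major_second_moment(rf1)

    def test_bad_parity(self, raster):
        with pytest.raises(ValueError):
            ff.render_v2_rf([], np.array([]), raster, "diagonal")


@pytest.fixture(scope="module")
def loo_setup(v1_population_16):
    cells, tunings = v1_population_16
    pos = np.array([c.params.theta_c for c in cells])
    targets = np.linspace(5, 175, 10)
    v2 = np.stack([synthetic.simulate_v2_pixel(
        tunings, synthetic.like_to_like_weights(pos, t))[0]
        for t in targets])
    return tunings, v2


class TestLOOCrossValidation:
    def test_fold_structure(self, loo_setup):
        tunings, v2 = loo_setup
        cv = ff.loo_cross_validate(tunings, v2, v1_grating_responses=tunings)
        assert cv.predicted.shape == v2.shape
        assert cv.relative_error.shape == v2.shape

    def test_noiseless_self_consistency(self, loo_setup):
        tunings, v2 = loo_setup
        cv = ff.loo_cross_validate(tunings, v2, v1_grating_responses=tunings)
        assert cv.mean_relative_error < 0.05
        assert np.median(cv.po_abs_error) < 1.0

    def test_degenerate_range_rejected(self, loo_setup):
        tunings, _ = loo_setup
        with pytest.raises(ValueError, match="degenerate"):
            ff.loo_cross_validate(tunings, np.full((2, 8), 5.0),
                                  v1_grating_responses=tunings)

    def test_weight_recovery_noiseless_exact(self):
        # alias-free raised-cosine tunings on a uniform PO grid: harmonic
        # orthogonality makes the recovered weight profile exactly
        # proportional to the generative like-to-like profile
        pos = np.arange(16) * 180.0 / 16
        tunings = np.stack([synthetic.cosine_tuning(p) for p in pos])
        w_gen = synthetic.like_to_like_weights(pos, 70.0)
        v2, gt = synthetic.simulate_v2_pixel(tunings, w_gen)
        w_rec = ff.compute_weights(tunings, v2).w[:, 0]
        r = np.corrcoef(w_rec, gt.true_weights)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_weight_recovery_gabor_population(self, v1_population_16):
        # Gabor tunings alias high harmonics into the 8-point sampling, so
        # recovery is near- but not machine-exact
        cells, tunings = v1_population_16
        pos = np.array([c.params.theta_c for c in cells])
        w_gen = synthetic.like_to_like_weights(pos, 70.0)
        v2, gt = synthetic.simulate_v2_pixel(tunings, w_gen)
        w_rec = ff.compute_weights(tunings, v2).w[:, 0]
        assert np.corrcoef(w_rec, gt.true_weights)[0, 1] > 0.999
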