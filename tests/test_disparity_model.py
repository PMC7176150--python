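"""V1 binocular energy, MT pooling, decoding, and the model variants."""

import math

import numpy as np
import pytest
from scipy import ndimage

from fovdisp import model as md
from fovdisp import stimulus as st
from fovdisp.model import _PlainImage
from fovdisp.retino_cortical import CorticalImage, make_mapping


V1 = md.V1PopulationSpec()
MT = md.MTPopulationSpec()


@pytest.fixture(scope="module")
def texture_pair():
    """Plain (uniform-grid) image pair with a known 0.76-px vertical shift."""
    rng = np.random.default_rng(8)
    base = ndimage.gaussian_filter(rng.standard_normal((100, 128)), 1.0)
    rows = np.arange(80, dtype=float) + 10.0
    cols = np.arange(128, dtype=float)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    shift = 0.76
    left = ndimage.map_coordinates(base, [rr - shift / 2, cc], order=3)
    right = ndimage.map_coordinates(base, [rr + shift / 2, cc], order=3)
    return _PlainImage(left), _PlainImage(right), shift


class TestGabor:
    def test_zero_dc(self):
        g = md.gabor_kernel(md.GaborSpec(theta=0.3, sigma=5.12, fs=0.13))
        assert abs(g.sum()) < 1e-12
        assert np.sum(np.abs(g) ** 2) == pytest.approx(1.0)

    def test_quadrature_pair(self):
        g = md.gabor_kernel(md.GaborSpec(theta=0.0, sigma=4.0, fs=0.15))
        # even real part, odd imaginary part along the carrier axis
        assert np.allclose(g.real, g.real[::-1, :], atol=1e-12)
        assert np.allclose(g.imag, -g.imag[::-1, :], atol=1e-9)

    def test_orientation_tuning(self):
        """Response magnitude to a sinusoid at fs peaks at the matched
        orientation across the 12-filter bank."""
        n = 64
        xi = np.arange(n)[:, None] * np.ones((1, n))
        eta = np.arange(n)[None, :] * np.ones((n, 1))
        target = V1.thetas[3]
        img = np.sin(2 * np.pi * V1.fs * (np.cos(target) * xi
                                          + np.sin(target) * eta))
        mags = []
        for theta in V1.thetas:
            g = md.gabor_kernel(md.GaborSpec(theta=theta, sigma=V1.sigma,
                                             fs=V1.fs))
            from scipy.signal import fftconvolve
            resp = fftconvolve(img, g, mode="valid")
            mags.append(np.abs(resp).max())
        # theta and theta+pi are conjugate filters: equal magnitude
        assert np.argmax(mags) in (3, 3 + V1.n_orientations // 2)

    def test_bandwidth_sigma_relation(self):
        """The published filter scale (5.12 px at fs = 0.13) corresponds
        to a ~0.70-octave bandwidth under the one-SD spectral cutoff."""
        b = md.gabor_bandwidth_from_sigma(0.13, 5.12)
        assert b == pytest.approx(0.70, abs=0.01)
        assert md.gabor_sigma_from_bandwidth(0.13, b) == pytest.approx(
            5.12, rel=1e-9)

    def test_small_support_warns(self):
        with pytest.warns(UserWarning, match="support"):
            md.gabor_kernel(md.GaborSpec(theta=0.0, sigma=5.0, fs=0.1),
                            support=11)

    def test_constant_image_zero_response(self):
        g = md.gabor_kernel(md.GaborSpec(theta=1.0, sigma=3.0, fs=0.2))
        img = np.full((41, 41), 0.7)
        from scipy.signal import fftconvolve
        resp = fftconvolve(img, g, mode="valid")
        assert np.abs(resp).max() < 1e-10


class TestSimpleAndComplexCells:
    def test_identical_eyes_zero_phase_doubles_monocular(self):
        rng = np.random.default_rng(0)
        img = ndimage.gaussian_filter(rng.standard_normal((60, 70)), 1.0)
        eye = _PlainImage(img)
        resp, resp_q = md.simple_cells(eye, eye, V1)
        k0 = V1.n_channels // 2  # the delta_psi = 0 channel
        mono = md._conv_bank(img, md._monocular_kernels(V1))
        assert np.allclose(resp[k0], 2.0 * mono.real, atol=1e-10)
        assert np.allclose(resp_q[k0], 2.0 * mono.imag, atol=1e-10)

    def test_mapping_mismatch_rejected(self):
        m1 = make_mapping(64, 64, 16, 2.0)
        m2 = make_mapping(64, 64, 20, 2.0)
        a = CorticalImage(np.zeros((16, m1.S)), m1)
        b = CorticalImage(np.zeros((20, m2.S)), m2)
        with pytest.raises(ValueError):
            md.simple_cells(a, b, V1)

    def test_energy_arithmetic(self):
        assert md.complex_energy(np.array([3.0]),
                                 np.array([4.0]))[0] == 25.0

    def test_energy_shape_mismatch(self):
        with pytest.raises(ValueError):
            md.complex_energy(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_zero_contrast_zero_energy(self):
        eye = _PlainImage(np.full((50, 60), 0.5))
        resp, resp_q = md.simple_cells(eye, eye, V1)
        assert np.abs(md.complex_energy(resp, resp_q)).max() < 1e-18

    def test_energy_phase_invariance(self):
        """Adding a common absolute phase to both eyes' sinusoid leaves
        the binocular energy unchanged (quadrature-pair property)."""
        n = 80
        xi = np.arange(n)[:, None] * np.ones((1, n))
        energies = []
        for phase in (0.0, 1.1):
            img = 0.5 + 0.3 * np.sin(2 * np.pi * V1.fs * xi + phase)
            eye = _PlainImage(img)
            r, rq = md.simple_cells(eye, eye, V1)
            energies.append(md.complex_energy(r, rq)[:, :, 30:-30, 30:-30])
        # invariance is exact for ideal quadrature pairs; discrete,
        # DC-corrected kernels leave a small residual ripple
        ref = energies[0].max()
        assert np.max(np.abs(energies[0] - energies[1])) < 0.02 * ref

    def test_eye_swap_negates_preferred_disparity(self, texture_pair):
        """Swapping the eyes mirrors the disparity tuning: the channel
        responding maximally flips sign."""
        left, right, shift = texture_pair
        inner = (slice(None), slice(None), slice(20, -20), slice(20, -20))

        def peak_channel(a, b):
            r, rq = md.simple_cells(a, b, V1)
            e = md.complex_energy(r, rq)[inner]
            # orientation 0 (vertical carrier direction = xi) sees the shift
            profile = e[:, 0].mean(axis=(1, 2))
            return V1.disparities[int(np.argmax(profile))]

        assert peak_channel(left, right) == pytest.approx(shift)
        assert peak_channel(right, left) == pytest.approx(-shift)

    def test_interocular_phase_selects_channel(self):
        """A full-field cortical sinusoid with a known interocular phase
        offset drives most the channel predicted by the analytic
        binocular-energy profile 1 + cos(delta_psi + offset).

        A positive spatial shift d of the left image corresponds to an
        image-phase offset of -2*pi*fs*d, so the channel tuned to
        delta_psi responds maximally at image-phase offset -delta_psi;
        the spatial-domain convention is pinned by the eye-swap and
        decoder-recovery tests.
        """
        n = 96
        xi = np.arange(n)[:, None] * np.ones((1, n))
        carrier = 2 * np.pi * V1.fs * xi
        for offset in (0.35, -0.9):
            left = _PlainImage(0.5 + 0.3 * np.sin(carrier + offset / 2))
            right = _PlainImage(0.5 + 0.3 * np.sin(carrier - offset / 2))
            r, rq = md.simple_cells(left, right, V1)
            e = md.complex_energy(r, rq)[:, 0, 40:-40, 40:-40].mean(
                axis=(1, 2))
            oracle = 1.0 + np.cos(V1.delta_psis + offset)
            assert np.argmax(e) == np.argmax(oracle)


class TestNormalization:
    def test_equal_orientations_give_uniform_shares(self):
        e = np.ones((V1.n_channels, V1.n_orientations, 4, 5))
        out = md.normalize_v1(e, V1)
        assert np.allclose(out, 1.0 / V1.n_orientations, atol=1e-5)

    def test_contrast_invariance(self, texture_pair):
        left, right, _ = texture_pair
        outs = []
        for c in (1.0, 10.0):
            l2 = _PlainImage(left.values * c)
            r2 = _PlainImage(right.values * c)
            r_, rq = md.simple_cells(l2, r2, V1)
            outs.append(md.normalize_v1(md.complex_energy(r_, rq), V1))
        sl = (slice(None), slice(None), slice(20, -20), slice(20, -20))
        a, b = outs[0][sl], outs[1][sl]
        assert np.max(np.abs(a - b) / (np.abs(a) + 1e-9)) < 0.01

    def test_zero_texture_zero_output(self):
        e = np.zeros((V1.n_channels, V1.n_orientations, 3, 3))
        out = md.normalize_v1(e, V1)
        assert np.all(out == 0.0)

    def test_nonnegative_with_noise(self, texture_pair):
        left, right, _ = texture_pair
        r, rq = md.simple_cells(left, right, V1)
        out = md.normalize_v1(md.complex_energy(r, rq), V1,
                              rng=np.random.default_rng(0))
        assert np.all(out >= 0.0)


class TestMT:
    def test_unit_gain_at_zero_lambda(self, texture_pair):
        left, right, _ = texture_pair
        r, rq = md.simple_cells(left, right, V1)
        e_v1 = md.normalize_v1(md.complex_energy(r, rq), V1)
        flat = md.mt_response(e_v1, V1, md.MTPopulationSpec(lambda_gain=0.0))
        assert np.allclose(flat, 1.0, atol=1e-12)

    def test_no_noise_without_texture(self):
        e_v1 = np.zeros((V1.n_channels, V1.n_orientations, 20, 30))
        e_mt = md.mt_response(e_v1, V1, MT, rng=np.random.default_rng(1))
        assert np.allclose(e_mt, 1.0, atol=1e-12)

    def test_uniform_shift_peaks_at_matching_direction(self, texture_pair):
        """A pure xi-shift drives the phi = 0 population hardest, on the
        channel side matching the shift's sign.

        The cosine-weighted orientation pooling makes the MT tuning over
        preferred disparity sigmoidal rather than bell-shaped, so the
        population peak identifies direction and sign; the magnitude is
        read out by the (calibrated) linear decoder, tested below.
        """
        left, right, shift = texture_pair
        r, rq = md.simple_cells(left, right, V1)
        e_v1 = md.normalize_v1(md.complex_energy(r, rq), V1)
        e_mt = md.mt_response(e_v1, V1, MT)
        inner = (slice(20, -20), slice(20, -20))
        prof = e_mt[:, :, inner[0], inner[1]].mean(axis=(2, 3))  # (K, P)
        k_best, p_best = np.unravel_index(np.argmax(prof), prof.shape)
        assert p_best == 0  # phi = 0 population carries the xi-shift
        assert np.sign(V1.disparities[k_best]) == np.sign(shift)
        # the phi = 0 tuning is monotone toward the shift direction
        assert np.all(np.diff(prof[:, 0]) > 0)


@pytest.fixture(scope="module")
def observer():
    return md.make_observer(pixels_per_degree=6.0, noisy=False)


class TestAnnularPooling:

    def test_masks_partition_grid(self, observer):
        masks = md.annular_masks(observer.mapping, 6.0)
        total = sum(m.astype(int) for m in masks)
        assert np.all(total == 1)

    def test_overlapping_masks_rejected(self, observer):
        masks = md.annular_masks(observer.mapping, 6.0)
        bad = [masks[0] | masks[1], masks[1], masks[2]]
        with pytest.raises(ValueError, match="disjoint"):
            md.pool_annuli([np.ones((3,) + m.shape) for m in bad], bad)

    def test_fullfield_recombination_is_exact(self, observer):
        masks = md.annular_masks(observer.mapping, 6.0)
        rng = np.random.default_rng(2)
        e_mt = rng.random((5, 2) + masks[0].shape)
        combined = md.pool_annuli([e_mt, e_mt, e_mt], masks)
        assert np.array_equal(combined, e_mt)

    def test_energy_localized_to_stimulated_annulus(self, observer):
        """A 3-9 deg stimulus leaves (pre-normalization) binocular energy
        outside the mid cortical band, beyond a filter-width guard, at the
        numerical floor."""
        m = observer.mapping
        spec = st.StimulusSpec(corrugation_frequency=0.18,
                               peak_to_trough_disparity=4.0,
                               annulus_inner=3.0, annulus_outer=9.0,
                               field_radius=21.0, pixels_per_degree=6.0,
                               rng_seed=5)
        pair = st.make_stimulus(spec)
        from fovdisp.retino_cortical import to_cortical
        left = to_cortical(pair.left, m)
        right = to_cortical(pair.right, m)
        r, rq = md.simple_cells(left, right, V1)
        energy = md.complex_energy(r, rq).mean(axis=(0, 1))
        masks = md.annular_masks(m, 6.0)
        guard = int(math.ceil(3 * V1.sigma)) + 1
        mid_rows = np.where(masks[1][:, 0])[0]
        lo, hi = mid_rows.min() - guard, mid_rows.max() + guard
        outside = np.ones(m.R, dtype=bool)
        outside[max(lo, 0):hi + 1] = False
        inside_mean = energy[masks[1]].mean()
        if outside.any():
            assert energy[outside].mean() < 5e-3 * inside_mean


class TestDecode:
    def test_even_profile_decodes_to_zero(self):
        e = np.ones((V1.n_channels, 2, 6, 7))
        dxi, deta = md.decode(e, V1)
        assert np.allclose(dxi, 0.0) and np.allclose(deta, 0.0)

    def test_linearity(self, texture_pair):
        left, right, _ = texture_pair
        r, rq = md.simple_cells(left, right, V1)
        e_mt = md.mt_response(
            md.normalize_v1(md.complex_energy(r, rq), V1), V1, MT)
        d1 = md.decode(e_mt, V1)
        d3 = md.decode(3.0 * e_mt, V1)
        assert np.allclose(d3[0], 3.0 * d1[0], rtol=1e-12)

    def test_calibrated_recovery_within_channel_spacing(self):
        """Uniform cortical shifts inside the tuning range are recovered
        within one channel spacing at >= 80% of textured nodes."""
        gain = md.decoder_gain(V1, MT)
        rng = np.random.default_rng(41)
        for shift in (-1.2, 0.5, 1.52):
            base = ndimage.gaussian_filter(
                rng.standard_normal((100, 120)), 1.0)
            rows = np.arange(80, dtype=float) + 10.0
            cols = np.arange(120, dtype=float)
            rr, cc = np.meshgrid(rows, cols, indexing="ij")
            left = ndimage.map_coordinates(base, [rr - shift / 2, cc],
                                           order=3)
            right = ndimage.map_coordinates(base, [rr + shift / 2, cc],
                                            order=3)
            r, rq = md.simple_cells(_PlainImage(left), _PlainImage(right),
                                    V1)
            e_mt = md.mt_response(
                md.normalize_v1(md.complex_energy(r, rq), V1), V1, MT)
            dxi, deta = md.decode(e_mt, V1, gain=gain)
            err = np.hypot(dxi - shift, deta)[15:-15, 15:-15]
            assert (err < V1.channel_spacing).mean() >= 0.8


class TestTiltDecision:
    def test_ideal_corrugation_maps(self):
        for tilt in (45.0, 135.0):
            spec = st.StimulusSpec(corrugation_frequency=0.18,
                                   peak_to_trough_disparity=8.0, tilt=tilt,
                                   annulus_inner=3.0, annulus_outer=9.0,
                                   field_radius=21.0, pixels_per_degree=6.0)
            dmap = st.corrugation_map(spec)
            rng = np.random.default_rng(0)
            assert md.tilt_decision(dmap, rng) == tilt

    def test_zero_map_is_chance(self):
        rng = np.random.default_rng(0)
        picks = [md.tilt_decision(np.zeros((32, 32)), rng)
                 for _ in range(400)]
        frac45 = np.mean([p == 45.0 for p in picks])
        assert 0.42 < frac45 < 0.58

    def test_nonfinite_rejected(self):
        rng = np.random.default_rng(0)
        bad = np.zeros((8, 8))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError):
            md.tilt_decision(bad, rng)


class TestVariantsAndGeometry:
    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError):
            md.make_observer(variant="pyramid", pixels_per_degree=6.0)

    def test_variant_aliases(self):
        obs = md.make_observer(variant="noLP/2S", pixels_per_degree=6.0)
        assert obs.variant == "noLP2S" and obs.n_scales == 2

    def test_rf_scale_moves_fs_and_range_together(self):
        obs = md.make_observer(pixels_per_degree=6.0, rf_scale=2.0)
        assert obs.v1.sigma == pytest.approx(2 * 5.12)
        assert obs.v1.fs == pytest.approx(0.13 / 2)
        assert obs.v1.disparity_range == pytest.approx(2 * 1.52)

    def test_disparity_range_reference_values(self):
        """With the published full-scale geometry the tuning range spans
        +/-0.43 arcmin at the foveal edge; the peripheral end evaluates
        to ~24 arcmin."""
        from fovdisp.retino_cortical import (mapping_from_geometry,
                                             solve_field_radius)
        rho_max = solve_field_radius(318, 9.0, 6.4)
        m = mapping_from_geometry(rho_max, 9.0, 318)
        fov, per = md.disparity_range_arcmin(m, 1.52)
        assert round(fov, 2) == 0.43
        assert 20.0 < per < 28.0

    def test_nolp_uniform_disparity_no_eccentricity_falloff(self):
        """The uniform-sampling variant decodes the same disparity
        magnitude at all eccentricities."""
        obs = md.make_observer(variant="noLP", pixels_per_degree=6.0,
                               noisy=False)
        spec = st.StimulusSpec(corrugation_frequency=0.1,
                               peak_to_trough_disparity=0.0,
                               annulus_inner=0.0, annulus_outer=21.0,
                               field_radius=21.0, pixels_per_degree=6.0,
                               rng_seed=9)
        noise = st.pink_noise(spec.size, 9)
        d_arcmin = 25.0
        pair = st.render_stereo(noise, np.full_like(noise, d_arcmin), spec)
        resp = obs.respond(pair, np.random.default_rng(0))
        n = resp.retinal_dx.shape[0]
        x = np.arange(n) - (n - 1) / 2
        # the uniform-variant map is at downsampled resolution
        rho_deg = np.hypot(x[None, :], x[:, None]) * obs.downsample / 6.0
        meds = [np.median(resp.retinal_dx[(rho_deg > lo) & (rho_deg < hi)])
                for lo, hi in ((1, 5), (5, 11), (11, 18))]
        assert all(m > 0 for m in meds)
        spread = (max(meds) - min(meds)) / np.mean(meds)
        assert abs(spread) < 0.5

    @pytest.mark.parametrize("variant", ["LP2S", "noLP2S"])
    def test_two_scale_variants_run_end_to_end(self, variant):
        """The cortical-pyramid variants produce a finite decoded field
        and a valid decision."""
        obs = md.make_observer(variant=variant, pixels_per_degree=3.0,
                               noisy=False)
        spec = st.StimulusSpec(corrugation_frequency=0.18,
                               peak_to_trough_disparity=8.0,
                               annulus_inner=3.0, annulus_outer=9.0,
                               field_radius=21.0, pixels_per_degree=3.0,
                               rng_seed=2)
        resp = obs.respond(st.make_stimulus(spec),
                           np.random.default_rng(0))
        assert np.all(np.isfinite(resp.retinal_dx))
        assert resp.decision in (45.0, 135.0)

    def test_respond_deterministic_given_rng_state(self):
        obs = md.make_observer(pixels_per_degree=6.0)
        spec = st.StimulusSpec(corrugation_frequency=0.18,
                               peak_to_trough_disparity=6.0,
                               annulus_inner=3.0, annulus_outer=9.0,
                               field_radius=21.0, pixels_per_degree=6.0,
                               rng_seed=3)
        pair = st.make_stimulus(spec)
        a = obs.respond(pair, np.random.default_rng(7))
        b = obs.respond(pair, np.random.default_rng(7))
        assert np.array_equal(a.retinal_dx, b.retinal_dx)
        assert a.decision == b.decision
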