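import numpy as np
import pytest

from phyllotaxis3d import (
    Compartment,
    ImperfectionModel,
    PhantomSpec,
    SequenceParams,
    Tissue,
    TrajectoryConfig,
    analytic_ball_transform,
    bssfp_contrast_weights,
    build_spoke_set,
    corrupt_spokes,
    estimate_tissue,
    gaussian_coil_profiles,
    simulate_acquisition,
    simulate_phase_cycled_series,
)
from phyllotaxis3d.bssfp import BssfpProfile


def supersampled_raster(comp, matrix, factor=3):
    """Partial-volume-aware rasterization: box-average a finer binary grid."""
    m2 = matrix * factor
    # subvoxel centers of coarse voxel i lie at i - matrix//2 + (j+0.5)/f - 0.5
    x = (np.arange(m2) + 0.5) / factor - 0.5 - matrix // 2
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    cx, cy, cz = comp.center
    fine = (((X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2)
            <= comp.radius ** 2).astype(float)
    fine = fine.reshape(matrix, factor, matrix, factor, matrix, factor)
    return comp.amplitude * fine.mean(axis=(1, 3, 5))


class TestBallTransform:
    def test_dc_equals_volume(self):
        comp = Compartment(center=(0, 0, 0), radius=1.0, amplitude=1.0)
        val = analytic_ball_transform(comp, np.zeros((1, 3)))[0]
        assert val == pytest.approx(4 * np.pi / 3, rel=1e-12)

    def test_hermitian_symmetry(self):
        comp = Compartment(center=(2.0, -1.0, 0.5), radius=5.0, amplitude=1.0)
        rng = np.random.default_rng(0)
        k = rng.uniform(-0.5, 0.5, (50, 3))
        assert np.allclose(analytic_ball_transform(comp, -k),
                           np.conj(analytic_ball_transform(comp, k)))

    def test_small_argument_continuity(self):
        comp = Compartment(center=(0, 0, 0), radius=3.0)
        k = np.array([[1e-6, 0, 0], [2e-5, 0, 0], [1e-3, 0, 0]])
        vals = analytic_ball_transform(comp, k).real
        assert np.all(np.diff(vals) < 0)
        assert vals[0] == pytest.approx(comp.volume, rel=1e-6)

    def test_agrees_with_rasterized_dft(self):
        comp = Compartment(center=(3.0, -2.0, 1.0), radius=9.0)
        M = 64
        vol = supersampled_raster(comp, M)
        F = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))
        K1 = np.fft.fftshift(np.fft.fftfreq(M))
        KX, KY, KZ = np.meshgrid(K1, K1, K1, indexing="ij")
        kk = np.stack([KX, KY, KZ], -1)
        ana = analytic_ball_transform(comp, kk.reshape(-1, 3)).reshape(M, M, M)
        mask = np.sqrt(KX ** 2 + KY ** 2 + KZ ** 2) <= 0.25
        rel = np.linalg.norm(F[mask] - ana[mask]) / np.linalg.norm(ana[mask])
        assert rel < 0.02


class TestCorruption:
    def test_identity_model(self, small_p2p_spokes):
        eff, phase = corrupt_spokes(small_p2p_spokes, ImperfectionModel())
        assert np.array_equal(eff, small_p2p_spokes.sample_positions())
        assert np.all(phase == 0)

    def test_phase_odd_in_direction(self, small_p2p_spokes):
        rng = np.random.default_rng(2)
        c = tuple(rng.standard_normal(3))
        model = ImperfectionModel(phase_coeffs=c)
        _, phase = corrupt_spokes(small_p2p_spokes, model)
        d = small_p2p_spokes.directions
        expected = d @ np.asarray(c)
        assert np.allclose(phase, expected)
        # exact antipodes would get exactly opposite phases by linearity
        assert np.allclose(d @ np.asarray(c) + (-d) @ np.asarray(c), 0.0)

    def test_isotropic_delay_is_pure_readout_shift(self, small_p2p_spokes):
        t = 0.7
        model = ImperfectionModel(delays=(t, t, t))
        eff, _ = corrupt_spokes(small_p2p_spokes, model)
        nominal = small_p2p_spokes.sample_positions()
        dk = small_p2p_spokes.config.delta_k
        shift = nominal - eff  # (S, M, 3)
        d = small_p2p_spokes.directions
        along = np.einsum("smx,sx->sm", shift, d)
        perp = shift - along[:, :, None] * d[:, None, :]
        assert np.allclose(along, t * dk)
        assert np.max(np.abs(perp)) < 1e-15


class TestSimulation:
    def test_identity_stores_equal_coords(self, clean_small_kspace):
        assert np.array_equal(clean_small_kspace.nominal_coords,
                              clean_small_kspace.effective_coords)

    def test_clean_center_phase_zero(self, clean_small_kspace):
        center = clean_small_kspace.samples[:, clean_small_kspace.center_index, 0]
        assert np.max(np.abs(np.angle(center))) < 1e-10

    def test_determinism(self, small_ball, small_p2p_spokes):
        model = ImperfectionModel(noise_sigma=0.02)
        a = simulate_acquisition(small_ball, small_p2p_spokes, model, seed=42)
        b = simulate_acquisition(small_ball, small_p2p_spokes, model, seed=42)
        assert np.array_equal(a.samples, b.samples)
        c = simulate_acquisition(small_ball, small_p2p_spokes, model, seed=43)
        assert not np.array_equal(a.samples, c.samples)

    def test_noise_variance_scaling(self, small_ball, small_p2p_spokes,
                                    clean_small_kspace):
        sigma = 0.05
        model = ImperfectionModel(noise_sigma=sigma)
        noisy = simulate_acquisition(small_ball, small_p2p_spokes, model, seed=3)
        diff = noisy.samples - clean_small_kspace.samples
        assert diff.size >= 1e4
        measured = np.mean(np.abs(diff) ** 2)
        expected = (sigma * small_ball.dc_magnitude) ** 2
        assert measured == pytest.approx(expected, rel=0.05)

    def test_multicoil_matches_analytic_sampling(self, small_ball):
        """Forward-gridded sensitivity-weighted phantom vs grid-free sampling."""
        cfg = TrajectoryConfig(n_spokes=200, n_interleaves=4,
                               design="pole_to_pole", samples_per_spoke=65)
        ss = build_spoke_set(cfg)
        flat = gaussian_coil_profiles(1, 48)
        flat = np.ones_like(flat)  # uniform sensitivity isolates the transform
        multi = simulate_acquisition(small_ball, ss, coil_profiles=flat)
        single = simulate_acquisition(small_ball, ss)
        r = np.linalg.norm(multi.nominal_coords, axis=-1)
        mask = r <= 0.35  # away from the raster grid's Nyquist edge
        a = multi.samples[:, :, 0][mask]
        b = single.samples[:, :, 0][mask]
        assert np.linalg.norm(a - b) / np.linalg.norm(b) < 0.02


class TestValidation:
    def test_tissue_all_or_none(self):
        with pytest.raises(ValueError):
            PhantomSpec((
                Compartment(center=(0, 0, 0), radius=2.0),
                Compartment(center=(4, 0, 0), radius=2.0,
                            tissue=Tissue(1000, 100)),
            ))

    def test_radius_positive(self):
        with pytest.raises(ValueError):
            Compartment(center=(0, 0, 0), radius=0.0)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            ImperfectionModel(noise_sigma=-0.1)
        with pytest.raises(ValueError):
            ImperfectionModel(phase_coeffs=(np.inf, 0, 0))


class TestBssfpContrast:
    SEQ = SequenceParams(tr_ms=5.0, te_ms=2.5, flip_deg=20.0,
                         rf_phase_increments_deg=tuple(np.arange(0.0, 341.0, 20.0)))

    def test_zero_proton_density_gives_zero(self):
        ph = PhantomSpec((Compartment(center=(0, 0, 0), radius=3.0,
                                      tissue=Tissue(1000, 100, proton_density=0.0)),))
        out = bssfp_contrast_weights(ph, self.SEQ, 180.0)
        assert out.compartments[0].amplitude == 0

    def test_identical_tissue_identical_amplitude(self):
        t = Tissue(800, 80)
        ph = PhantomSpec((Compartment(center=(0, 0, 0), radius=3.0, tissue=t),
                          Compartment(center=(6, 0, 0), radius=3.0, tissue=t)))
        out = bssfp_contrast_weights(ph, self.SEQ, 60.0)
        assert out.compartments[0].amplitude == out.compartments[1].amplitude

    def test_amplitudes_trace_model_ellipse(self):
        t = Tissue(1000, 100, off_resonance_hz=12.0)
        ph = PhantomSpec((Compartment(center=(0, 0, 0), radius=3.0, tissue=t),))
        amps = [bssfp_contrast_weights(ph, self.SEQ, inc).compartments[0].amplitude
                for inc in self.SEQ.rf_phase_increments_deg]
        profile = BssfpProfile(signal=np.asarray(amps),
                               increments_deg=np.asarray(self.SEQ.rf_phase_increments_deg))
        est = estimate_tissue(profile, self.SEQ)
        assert est.residual < 1e-10

    def test_series_matches_per_increment_simulation(self, small_p2p_spokes):
        t = Tissue(1000, 100)
        ph = PhantomSpec((Compartment(center=(0, 0, 0), radius=5.0, tissue=t),))
        seq = SequenceParams(tr_ms=5.0, te_ms=2.5, flip_deg=20.0,
                             rf_phase_increments_deg=(0.0, 90.0, 180.0, 270.0, 300.0, 330.0))
        series = simulate_phase_cycled_series(ph, small_p2p_spokes, seq)
        one = simulate_acquisition(ph, small_p2p_spokes, seq=seq,
                                   phase_increment_deg=90.0)
        assert np.allclose(series[1].samples, one.samples)

    def test_tissue_mode_requires_sequence(self, small_p2p_spokes):
        ph = PhantomSpec((Compartment(center=(0, 0, 0), radius=3.0,
                                      tissue=Tissue(1000, 100)),))
        with pytest.raises(ValueError):
            simulate_acquisition(ph, small_p2p_spokes)
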