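"""Two-pool MT model, lineshapes, fitting, and AREX isolation."""

import math

import numpy as np
import pytest

from stxseg.core_data import b1_to_omega1, ppm_to_angular
from stxseg.phantom import make_phantom, simulate_study
from stxseg.preprocess import drift_correct, steady_state_de_signal
from stxseg.qmt import (
    AREXSpectrum,
    ExchangePool,
    QMTParams,
    absorption_lineshape,
    arex,
    cluster_arex_spectra,
    emr_reference,
    fit_cluster_qmt,
    fit_two_pool,
    mtr_arex,
    observed_r1a,
    ode_steady_state_z,
    pairwise_contrast_offsets,
    steady_state_z,
    super_lorentzian_quad,
    two_pool_z,
)

TUMOUR = QMTParams(2200.0, 53.0, 25.0, 1.2 / 25.0, 8.2)
NECROSIS = QMTParams(2600.0, 80.0, 25.0, 1.1 / 25.0, 7.8)


class TestLineshape:
    @pytest.mark.parametrize("kind", ["lorentzian", "super_lorentzian"])
    def test_even_in_offset(self, kind):
        dw = np.array([1e4, 3e4, 2e5])
        g_pos = absorption_lineshape(dw, 8e-6, kind)
        g_neg = absorption_lineshape(-dw, 8e-6, kind)
        np.testing.assert_allclose(g_pos, g_neg, rtol=1e-12)

    def test_lorentzian_on_resonance(self):
        t2b = 1e-4
        assert absorption_lineshape(0.0, t2b, "lorentzian") == \
            pytest.approx(t2b / math.pi, rel=1e-12)

    def test_super_lorentzian_matches_quadrature_oracle(self):
        # T2B = 8 us at ~48 ppm (7 T): dw = 2*pi*14300 rad/s
        t2b = 8e-6
        dw = 2 * math.pi * 14300.0
        got = absorption_lineshape(dw, t2b, "super_lorentzian")
        oracle = t2b * super_lorentzian_quad(dw * t2b)
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_cutoff_patch_continuous_and_finite(self):
        dw = np.linspace(0, 4e4, 200)
        g = absorption_lineshape(dw, 8e-6, "super_lorentzian")
        assert np.all(np.isfinite(g)) and np.all(g > 0)
        assert np.abs(np.diff(g) / g[:-1]).max() < 0.2  # no jump at the seam


class TestTwoPoolModel:
    def test_no_mt_pool_reduces_to_direct_saturation(self):
        p = QMTParams(2000.0, 100.0, 25.0, 0.0, 8.2)
        offs = np.array([0.0, 1.0, 5.0, 50.0])
        z = two_pool_z(p, 0.5, offs)
        expected = steady_state_de_signal(
            ppm_to_angular(offs, 7.0), 2.0, 0.1, float(b1_to_omega1(0.5)))
        np.testing.assert_allclose(z, expected, rtol=1e-12)

    def test_far_offset_low_b1_near_unity(self):
        assert two_pool_z(TUMOUR, 0.5, 300.0) >= 0.99

    def test_closed_form_matches_ode_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = QMTParams(rng.uniform(1500, 3000), rng.uniform(25, 130),
                          rng.uniform(5, 60), rng.uniform(0.005, 0.2),
                          rng.uniform(5, 100),
                          lineshape=str(rng.choice(["super_lorentzian",
                                                    "lorentzian"])))
            b1 = rng.uniform(0.1, 6.0)
            off = rng.uniform(3.0, 300.0)
            assert abs(two_pool_z(p, b1, off)
                       - ode_steady_state_z(p, b1, off)) <= 1e-3

    def test_observed_r1a_matches_slow_eigenvalue(self):
        """The observed-rate constraint inverts the slow recovery eigenvalue
        of the exchange-coupled pair."""
        r1_obs, r, m0b, r1b = 0.45, 30.0, 0.06, 1.0
        r1a = observed_r1a(r1_obs, r, m0b, r1b)
        A = np.array([[-(r1a + r * m0b), r * m0b],
                      [r, -(r1b + r)]])
        slow = -np.max(np.linalg.eigvals(A).real)
        assert slow == pytest.approx(r1_obs, rel=1e-10)

    def test_multipool_reduces_to_two_pool(self):
        pool = ExchangePool(0.05, 25.0, 8.2e-6, 0.0, "super_lorentzian", 1.0)
        p = QMTParams(2200.0, 53.0, 25.0, 0.05, 8.2)
        offs = np.array([5.0, 20.0, 100.0])
        dw = ppm_to_angular(offs, 7.0)
        r1a = observed_r1a(1000.0 / 2200.0, 25.0, 0.05)
        z_multi = steady_state_z(dw, float(b1_to_omega1(2.0)), r1a, 0.053,
                                 [pool])
        z_two = two_pool_z(p, 2.0, offs)
        np.testing.assert_allclose(z_multi, z_two, rtol=1e-12)


class TestFitting:
    def _spectra(self, p, noise=0.0, rng=None):
        wassr = np.linspace(-0.5, 0.5, 21)
        hi = np.logspace(np.log10(300), np.log10(3), 11)
        out = []
        for b1, offs in ((0.1, wassr), (3.0, hi), (6.0, hi)):
            if b1 <= 0.2:
                # the WASSR block probes the direct effect only
                z = steady_state_de_signal(
                    ppm_to_angular(offs, 7.0), p.t1_obs_ms / 1000.0,
                    p.t2a_ms / 1000.0, float(b1_to_omega1(b1)))
            else:
                z = np.asarray(two_pool_z(p, b1, offs))
            if noise:
                z = z + rng.normal(0, noise, z.shape)
            out.append((b1, offs, z))
        return out

    def test_noise_free_recovery(self):
        p = QMTParams(2200.0, 53.0, 60.0, 1.2 / 60.0, 8.2)
        fit = fit_two_pool(self._spectra(p), p.t1_obs_ms, n_voxels=50)
        assert fit.rm0b == pytest.approx(p.rm0b, rel=0.05)
        assert fit.t2b_us == pytest.approx(p.t2b_us, rel=0.05)
        assert fit.t2a_ms == pytest.approx(p.t2a_ms, rel=0.10)

    def test_small_cluster_rejected(self):
        p = TUMOUR
        with pytest.raises(ValueError, match="7"):
            fit_two_pool(self._spectra(p), p.t1_obs_ms, n_voxels=6)

    def test_lorentzian_cluster_recovery(self):
        p = QMTParams(2800.0, 130.0, 25.0, 0.9 / 25.0, 100.0,
                      lineshape="lorentzian")
        fit = fit_two_pool(self._spectra(p), p.t1_obs_ms,
                           lineshape="lorentzian", n_voxels=20)
        assert fit.rm0b == pytest.approx(p.rm0b, rel=0.05)


class TestContrastExtrapolation:
    def test_identical_params_give_zero(self):
        off, diff = pairwise_contrast_offsets(TUMOUR, TUMOUR, 6.0)
        assert diff == 0.0 and math.isnan(off)

    def test_symmetric_in_arguments(self):
        a = pairwise_contrast_offsets(TUMOUR, NECROSIS, 6.0)
        b = pairwise_contrast_offsets(NECROSIS, TUMOUR, 6.0)
        assert a == b

    def test_tumour_necrosis_argmax_in_mt_band(self):
        off, diff = pairwise_contrast_offsets(TUMOUR, NECROSIS, 6.0)
        assert 37.0 <= off < 290.0  # interior of the grid, MT-weighted band
        assert diff > 0.01

    def test_argmax_offset_rises_with_b1(self):
        off3, _ = pairwise_contrast_offsets(TUMOUR, NECROSIS, 3.0)
        off6, _ = pairwise_contrast_offsets(TUMOUR, NECROSIS, 6.0)
        assert off6 > off3


class TestArex:
    def test_mtr_identities(self):
        assert mtr_arex(0.5, 0.8) == pytest.approx(0.75)
        assert mtr_arex(0.7, 0.7) == 0.0
        assert math.isnan(mtr_arex(-0.1, 0.5))

    def test_arex_scaling(self):
        assert arex(0.75, 2200.0) == pytest.approx(0.75 / 2.2)
        assert arex(0.75, 1100.0) == pytest.approx(2 * arex(0.75, 2200.0))
        assert arex(0.0, 2200.0) == 0.0

    def test_emr_equals_direct_saturation_without_mt(self):
        p = QMTParams(2000.0, 80.0, 25.0, 0.0, 8.2)
        offs = np.linspace(-5, 5, 21)
        z = emr_reference(p, 2.0, offs)
        expected = steady_state_de_signal(
            ppm_to_angular(offs, 7.0), 2.0, 0.08, float(b1_to_omega1(2.0)))
        np.testing.assert_allclose(z, expected, rtol=1e-12)

    def test_amide_pool_depresses_z_near_3p5ppm(self):
        offs = np.linspace(2.5, 4.5, 21)
        dw = ppm_to_angular(offs, 7.0)
        w1 = float(b1_to_omega1(2.0))
        mt = ExchangePool(0.05, 25.0, 8.2e-6, 0.0, "super_lorentzian")
        amide = ExchangePool(0.001, 50.0, 0.01, 3.5)
        r1a = observed_r1a(0.45, 25.0, 0.05)
        z_emr = steady_state_z(dw, w1, r1a, 0.053, [mt])
        z_lab = steady_state_z(dw, w1, r1a, 0.053, [mt, amide])
        assert np.all(z_lab < z_emr)

    def test_arex_peak_at_amide_offset_and_monotone(self):
        offs = np.linspace(1.0, 6.0, 51)
        dw = ppm_to_angular(offs, 7.0)
        w1 = float(b1_to_omega1(2.0))
        mt = ExchangePool(0.05, 25.0, 8.2e-6, 0.0, "super_lorentzian")
        r1a = observed_r1a(0.45, 25.0, 0.05)
        z_emr = steady_state_z(dw, w1, r1a, 0.053, [mt])
        amps = []
        for frac in (5e-4, 1e-3, 2e-3):
            amide = ExchangePool(frac, 50.0, 0.01, 3.5)
            z_lab = steady_state_z(dw, w1, r1a, 0.053, [mt, amide])
            sp = AREXSpectrum(offs, z_lab, z_emr, 2.0, 2200.0)
            peak = offs[int(np.argmax(sp.arex_per_s))]
            assert peak == pytest.approx(3.5, abs=offs[1] - offs[0])
            amps.append(sp.at_offset(3.5))
        assert amps[0] < amps[1] < amps[2]


@pytest.fixture(scope="module")
def fitted_phantom():
    truth = make_phantom(shape=(32, 32), seed=31)
    ds = drift_correct(simulate_study(truth))
    params = fit_cluster_qmt(ds, truth.label_map, truth.maps["t1_obs_ms"])
    return truth, ds, params


class TestClusterAnalysis:

    def test_small_clusters_excluded(self, fitted_phantom):
        truth, _ds, params = fitted_phantom
        for label, p in params.items():
            assert p.n_voxels >= 7
            assert p.n_voxels == int((truth.label_map == label).sum())

    def test_emr_matches_mt_only_voxels(self):
        """For a phantom without solute pools, the fitted reference
        reproduces the measured low-B1 spectrum."""
        from stxseg.phantom import TissueParams, default_tissue_params

        stripped = {l: TissueParams(tp.name, tp.t1_obs_ms, tp.t2a_ms,
                                    tp.r_exchange_per_s, tp.m0b, tp.t2b_us,
                                    lineshape=tp.lineshape, cest_pools=())
                    for l, tp in default_tissue_params().items()}
        # homogeneous classes: drop blood/edema, whose intentional 15%
        # parameter spread makes cluster-mean Z differ from Z(mean params)
        truth = make_phantom(shape=(28, 28), seed=32, jitter_sd=0.0,
                             fluid_amplitude=0.0, tissue_params=stripped,
                             class_fractions={"blood_edema": 0.0})
        ds = drift_correct(simulate_study(truth, apply_b0=False,
                                          apply_drift=False,
                                          apply_noise=False))
        params = fit_cluster_qmt(ds, truth.label_map,
                                 truth.maps["t1_obs_ms"])
        spectra = cluster_arex_spectra(ds, truth.label_map, params,
                                       (0.5, 2.0))
        for (label, b1), sp in spectra.items():
            keep = np.abs(sp.offsets_ppm) > 1.6  # outside lineshape patch
            assert np.abs(sp.z_lab - sp.z_emr)[keep].max() < 2e-3

    def test_tumour_arex_exceeds_necrosis_at_amide(self, fitted_phantom):
        truth, ds, params = fitted_phantom
        spectra = cluster_arex_spectra(ds, truth.label_map, params, (2.0,))
        tum = spectra[(1, 2.0)].at_offset(3.5)
        nec = spectra[(2, 2.0)].at_offset(3.5)
        assert tum > nec
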