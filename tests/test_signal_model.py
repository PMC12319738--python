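"""Forward-model unit and property tests against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from axomyelin.signal_model import (
    GAMMA_PROTON,
    AcquisitionProtocol,
    ShellTable,
    TissueParams,
    bvalue_from_gradients,
    cylinder_perp_attenuation_gpd,
    default_exvivo_protocol,
    effective_perp_diffusivity,
    gpd_neg_log_attenuation,
    gradient_from_bvalue,
    model_signal,
    powder_average,
    smt_axisymmetric,
    spherical_mean_snr_gain,
)
from axomyelin.synthetic import preset_tissue_params

DELTA, BIGDELTA = 11.0, 15.0


class TestBValue:
    def test_maximum_gradient_gives_top_shell(self):
        b = bvalue_from_gradients(GAMMA_PROTON, DELTA, BIGDELTA, 660.0)
        assert round(b) == 43

    def test_zero_gradient(self):
        assert bvalue_from_gradients(GAMMA_PROTON, DELTA, BIGDELTA, 0.0) == 0.0

    def test_quadratic_in_gradient(self):
        b_full = bvalue_from_gradients(GAMMA_PROTON, DELTA, BIGDELTA, 660.0)
        b_half = bvalue_from_gradients(GAMMA_PROTON, DELTA, BIGDELTA, 330.0)
        assert b_half == pytest.approx(b_full / 4.0, rel=1e-12)

    def test_gradient_roundtrip(self):
        for b in (1.0, 11.1, 43.0):
            G = gradient_from_bvalue(GAMMA_PROTON, DELTA, BIGDELTA, b)
            assert bvalue_from_gradients(GAMMA_PROTON, DELTA, BIGDELTA, G) \
                == pytest.approx(b, rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1.0, 15.0), (15.0, 11.0), (11.0, 11.0)])
    def test_invalid_timings_rejected(self, bad):
        d, D = bad
        with pytest.raises(ValueError):
            bvalue_from_gradients(GAMMA_PROTON, d, D, 100.0)


class TestCylinderGPD:
    def test_vanishing_radius_no_attenuation(self):
        a = cylinder_perp_attenuation_gpd(0.01, DELTA, BIGDELTA, 660.0, 0.45)
        assert a == pytest.approx(1.0, abs=1e-6)

    def test_zero_gradient_no_attenuation(self):
        assert cylinder_perp_attenuation_gpd(3.0, DELTA, BIGDELTA, 0.0, 0.45) == 1.0

    def test_series_truncation_oracle(self):
        """Default truncation agrees with a >= 50-root evaluation to 1e-8."""
        G43 = gradient_from_bvalue(GAMMA_PROTON, DELTA, BIGDELTA, 43.0)
        a_def = cylinder_perp_attenuation_gpd(3.0, DELTA, BIGDELTA, G43, 0.45)
        a50 = cylinder_perp_attenuation_gpd(3.0, DELTA, BIGDELTA, G43, 0.45,
                                            n_roots=50)
        assert a_def == pytest.approx(a50, abs=1e-8)

    def test_series_stable_under_5x_roots_over_diameter_range(self):
        d = np.linspace(0.1, 10.0, 40)
        G43 = gradient_from_bvalue(GAMMA_PROTON, DELTA, BIGDELTA, 43.0)
        a = cylinder_perp_attenuation_gpd(d, DELTA, BIGDELTA, G43, 0.45)
        a5 = cylinder_perp_attenuation_gpd(d, DELTA, BIGDELTA, G43, 0.45, 70)
        assert np.max(np.abs(a - a5)) < 1e-8

    def test_monotone_in_diameter_and_gradient(self):
        d = np.linspace(0.5, 10.0, 30)
        a = cylinder_perp_attenuation_gpd(d, DELTA, BIGDELTA, 400.0, 0.45)
        assert np.all(np.diff(a) <= 0)
        G = np.linspace(0.0, 660.0, 30)
        aG = cylinder_perp_attenuation_gpd(4.0, DELTA, BIGDELTA, G, 0.45)
        assert np.all(np.diff(aG) <= 0)

    def test_convergence_check_flags_short_series(self):
        G43 = gradient_from_bvalue(GAMMA_PROTON, DELTA, BIGDELTA, 43.0)
        with pytest.raises(RuntimeError):
            cylinder_perp_attenuation_gpd(8.0, DELTA, BIGDELTA, G43, 0.45,
                                          n_roots=1, check_convergence=True,
                                          conv_tol=1e-12)
        # and passes at the default root count
        cylinder_perp_attenuation_gpd(8.0, DELTA, BIGDELTA, G43, 0.45,
                                      n_roots=10, check_convergence=True,
                                      conv_tol=1e-8)


class TestEffectivePerpDiffusivity:
    def test_vanishing_diameter(self):
        assert effective_perp_diffusivity(0.01, DELTA, BIGDELTA, 0.45) \
            == pytest.approx(0.0, abs=1e-8)

    def test_monotone_in_diameter(self):
        d = np.linspace(1.0, 10.0, 50)
        dpe = effective_perp_diffusivity(d, DELTA, BIGDELTA, 0.45)
        assert np.all(np.diff(dpe) > 0)

    def test_independent_of_reference_gradient(self):
        """-ln A / b is the same at any G (GPD log-attenuation ~ G^2)."""
        for G in (100.0, 500.0):
            b = bvalue_from_gradients(GAMMA_PROTON, DELTA, BIGDELTA, G)
            neg_log = gpd_neg_log_attenuation(4.0, DELTA, BIGDELTA, G, 0.45)
            dpe = effective_perp_diffusivity(4.0, DELTA, BIGDELTA, 0.45)
            assert neg_log / b == pytest.approx(dpe, rel=1e-10)

    def test_reproduces_attenuation(self):
        G = 400.0
        b = bvalue_from_gradients(GAMMA_PROTON, DELTA, BIGDELTA, G)
        dpe = effective_perp_diffusivity(4.0, DELTA, BIGDELTA, 0.45)
        a = cylinder_perp_attenuation_gpd(4.0, DELTA, BIGDELTA, G, 0.45)
        assert dpe * b == pytest.approx(-np.log(a), abs=1e-10)


def _sphere_quadrature_smt(b, d_par, d_perp):
    """Independent oracle: direct quadrature of the directional signal."""
    val, _ = quad(
        lambda t: np.exp(-b * (d_perp + (d_par - d_perp) * t**2)), 0.0, 1.0,
        epsabs=1e-12, epsrel=1e-12)
    return val


class TestSphericalMean:
    def test_isotropic_limit(self):
        assert smt_axisymmetric(5.0, 0.3, 0.3) == pytest.approx(
            np.exp(-5.0 * 0.3), rel=1e-10)

    def test_b_zero(self):
        assert smt_axisymmetric(0.0, 0.6, 0.1) == 1.0

    def test_quadrature_oracle(self):
        got = smt_axisymmetric(10.0, 0.6, 0.1)
        want = _sphere_quadrature_smt(10.0, 0.6, 0.1)
        assert got == pytest.approx(want, abs=1e-8)

    def test_quadrature_oracle_small_anisotropy_branch(self):
        # exercises the Taylor branch b(D_par - D_perp) < 1e-6
        got = smt_axisymmetric(1e-4, 0.3 + 1e-3, 0.3)
        want = _sphere_quadrature_smt(1e-4, 0.3 + 1e-3, 0.3)
        assert got == pytest.approx(want, abs=1e-10)

    def test_rejects_dperp_above_dpar(self):
        with pytest.raises(ValueError):
            smt_axisymmetric(1.0, 0.1, 0.2)


class TestModelSignal:
    def test_pure_dot_is_flat(self, protocol):
        theta = TissueParams(f_ia=0.0, f_dot=1.0, d_a=2.0, d_par_ia=0.45,
                             ec_perp_frac=0.5)
        s = model_signal(theta, protocol)
        assert np.allclose(s.means, 1.0)

    def test_stick_limit(self, protocol):
        theta = TissueParams(f_ia=1.0, f_dot=0.0, d_a=1e-3, d_par_ia=0.45,
                             ec_perp_frac=0.5)
        s = model_signal(theta, protocol)
        stick = smt_axisymmetric(protocol.b_values, 0.45, 0.0)
        assert np.allclose(s.means, stick, atol=1e-7)

    def test_high_b_asymptote_is_dot_fraction(self):
        proto = AcquisitionProtocol.from_shell_table(
            [1e6], [32], delta=DELTA, Delta=BIGDELTA)
        theta = preset_tissue_params("macaque", 4.0)
        s = model_signal(theta, proto)
        assert s.means[0] == pytest.approx(theta.f_dot, abs=1e-6)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        f_ia=st.floats(0.0, 1.0),
        dot_frac=st.floats(0.0, 1.0),
        d_a=st.floats(0.2, 10.0),
        d_par=st.floats(0.05, 0.9),
        ec=st.floats(0.0, 1.0),
    )
    def test_normalized_and_monotone_for_any_valid_state(
            self, f_ia, dot_frac, d_a, d_par, ec):
        """S(0)=1 and S non-increasing across the 8 shells for any valid θ."""
        theta = TissueParams(f_ia=f_ia, f_dot=(1.0 - f_ia) * dot_frac,
                             d_a=d_a, d_par_ia=d_par, ec_perp_frac=ec)
        proto = default_exvivo_protocol()
        s = model_signal(theta, proto)
        total = theta.f_ia + theta.f_ec + theta.f_dot
        assert total == pytest.approx(1.0, abs=1e-12)  # S(0) = 1 by closure
        assert np.all(np.diff(s.means) <= 1e-12)
        assert np.all(s.means <= 1.0 + 1e-12)

    def test_orientation_integration_oracle(self, protocol):
        """Closed form equals averaging the directional cylinder signal over
        10,000 near-uniform orientations (spherical Fibonacci set)."""
        theta = preset_tissue_params("macaque", 4.0)
        i = np.arange(10_000) + 0.5
        phi = np.arccos(1.0 - 2.0 * i / 10_000)
        lon = np.pi * (1.0 + np.sqrt(5.0)) * i
        cos2 = np.cos(phi) ** 2
        sin_psi = np.sqrt(np.clip(1.0 - cos2, 0.0, 1.0))
        got = model_signal(theta, protocol).means
        d_perp_ec = theta.ec_perp_frac * theta.d_par_ia
        for k, shell in enumerate(protocol.shells):
            a = cylinder_perp_attenuation_gpd(
                theta.d_a, shell.delta, shell.Delta,
                shell.gradient_strength * sin_psi, theta.d_par_ia)
            s_ia = (np.exp(-shell.b_value * theta.d_par_ia * cos2) * a).mean()
            s_ec = np.exp(-shell.b_value * (
                d_perp_ec + (theta.d_par_ia - d_perp_ec) * cos2)).mean()
            want = theta.f_ia * s_ia + theta.f_ec * s_ec + theta.f_dot
            assert got[k] == pytest.approx(want, abs=1e-4)


class TestProtocol:
    def test_default_shell_table(self, protocol):
        assert list(protocol.b_values) == [1.0, 2.5, 5.0, 7.5, 11.1, 18.1,
                                           25.0, 43.0]
        assert list(protocol.n_directions) == [12, 12, 12, 12, 32, 32, 32, 32]
        assert protocol.n_b0 == 8
        # top shell lands at the scanner's maximum gradient strength
        assert protocol.shells[-1].gradient_strength == pytest.approx(660.0,
                                                                      rel=0.01)

    def test_inconsistent_b_and_gradient_rejected(self):
        from axomyelin.signal_model import Shell
        with pytest.raises(ValueError, match="inconsistent"):
            AcquisitionProtocol(shells=(Shell(43.0, 32, 100.0, DELTA,
                                              BIGDELTA),))

    def test_duplicate_shells_rejected(self):
        with pytest.raises(ValueError):
            AcquisitionProtocol.from_shell_table([5.0, 5.0], [12, 12],
                                                 DELTA, BIGDELTA)


class TestShellTable:
    def test_grouping_with_tolerance(self):
        bvals = [0.0, 0.01, 1.0, 1.02, 0.98, 5.0, 5.1, 43.0]
        table = ShellTable.from_bvals(bvals)
        assert table.n_shells == 3
        assert list(table.assignment[:2]) == [-1, -1]
        assert table.assignment[2] == table.assignment[3] == table.assignment[4]
        assert table.assignment[5] == table.assignment[6]

    def test_low_b_counts_as_b0(self):
        table = ShellTable.from_bvals([0.04, 1.0])
        assert table.assignment[0] == -1


class TestPowderAverage:
    def test_constant_volumes(self):
        bvals = [0.0, 1.0, 1.0, 5.0, 5.0]
        table = ShellTable.from_bvals(bvals)
        dwi = np.zeros((2, 2, 1, 5))
        dwi[..., 0] = 2.0
        dwi[..., 1:3] = 1.0
        dwi[..., 3:] = 0.5
        sm = powder_average(dwi, table)
        assert np.allclose(sm.means[..., 0], 0.5)
        assert np.allclose(sm.means[..., 1], 0.25)

    def test_roundtrip_of_model_signal(self, protocol):
        """DWIs whose directional signals equal the spherical mean reproduce
        the forward model after averaging and normalization, to 1e-10."""
        theta = preset_tissue_params("macaque", 3.0)
        clean = model_signal(theta, protocol).means
        bvals, vols = [], []
        for k, shell in enumerate(protocol.shells):
            bvals.append(0.0)
            vols.append(np.ones((2, 2, 1)))
            for _ in range(shell.n_directions):
                bvals.append(shell.b_value)
                vols.append(np.full((2, 2, 1), clean[k]))
        table = ShellTable.from_bvals(bvals)
        sm = powder_average(np.stack(vols, axis=-1), table)
        assert np.allclose(sm.means, clean[None, None, None, :], atol=1e-10)

    def test_noise_reduction_scales_with_sqrt_directions(self):
        """Monte-Carlo: SD of the shell mean ~ 1/(snr sqrt(N))."""
        rng = np.random.default_rng(0)
        snr, n_dir, n_vox = 50.0, 32, 4000
        bvals = [0.0] + [10.0] * n_dir
        table = ShellTable.from_bvals(bvals)
        dwi = np.ones((n_vox, 1, 1, n_dir + 1))
        dwi[..., 1:] = 0.5 + rng.normal(0, 1 / snr, size=(n_vox, 1, 1, n_dir))
        sm = powder_average(dwi, table)
        sd = sm.means[..., 0].std()
        assert sd == pytest.approx(1 / (snr * np.sqrt(n_dir)), rel=0.1)
        assert spherical_mean_snr_gain(n_dir) == pytest.approx(np.sqrt(n_dir))

    def test_nonpositive_b0_flagged(self):
        table = ShellTable.from_bvals([0.0, 5.0])
        dwi = np.ones((2, 1, 1, 2))
        dwi[0, 0, 0, 0] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            sm = powder_average(dwi, table)
        assert not sm.valid[0, 0, 0]
        assert np.isnan(sm.means[0, 0, 0, 0])

    def test_shape_mismatch_rejected(self):
        table = ShellTable.from_bvals([0.0, 5.0])
        with pytest.raises(ValueError):
            powder_average(np.ones((2, 2, 1, 3)), table)


class TestTissueParams:
    @pytest.mark.parametrize("kw", [
        dict(f_ia=1.2, f_dot=0.0),
        dict(f_ia=0.7, f_dot=0.5),
        dict(f_ia=0.5, f_dot=0.1, d_a=-1.0),
        dict(f_ia=0.5, f_dot=0.1, ec_perp_frac=1.5),
    ])
    def test_invariants_enforced(self, kw):
        full = dict(f_ia=0.5, f_dot=0.1, d_a=3.0, d_par_ia=0.45,
                    ec_perp_frac=0.4)
        full.update(kw)
        with pytest.raises(ValueError):
            TissueParams(**full)

    def test_fraction_closure(self):
        t = preset_tissue_params("human", 4.0)
        assert t.f_ia + t.f_ec + t.f_dot == pytest.approx(1.0)
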