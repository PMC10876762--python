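"""Bloch and small-tip-angle simulators against closed-form oracles."""

import numpy as np
import pytest

import fastptx as fp
from fastptx.sim import GAMMA


def _single_voxel_maps(b1=1000.0 + 0j, b0=0.0, resolution=0.001):
    return fp.FieldMapSet(
        b1=np.full((1, 1, 1, 1), b1, complex),
        b0=np.full((1, 1, 1), b0),
        mask=np.ones((1, 1, 1), bool),
        resolution=resolution,
    )


class TestBloch:
    def test_on_resonance_rotation_closed_form(self):
        """1 uT constant field for 100 us tips by gamma*B1*tau exactly."""
        maps = _single_voxel_maps(b1=1000.0 + 0j)  # nT/V
        pulse = fp.PulseWaveform(rf=np.ones((1, 10), complex),
                                 grad=np.zeros((3, 10)), raster=1e-5)
        res = fp.bloch_simulate(pulse, maps)
        expected = np.degrees(GAMMA * 1e-6 * 100e-6)  # 1.5328 deg
        assert res.fa[0] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1.5328, abs=5e-4)

    def test_zero_pulse_leaves_magnetization_unchanged(self):
        maps = _single_voxel_maps()
        pulse = fp.PulseWaveform(rf=np.zeros((1, 7), complex),
                                 grad=np.zeros((3, 7)), raster=1e-5)
        init = np.array([[0.3, -0.4, np.sqrt(1 - 0.25)]])
        res = fp.bloch_simulate(pulse, maps, initial=init)
        assert np.allclose([res.mxy.real[0], res.mxy.imag[0], res.mz[0]],
                           init[0], atol=1e-14)

    def test_norm_conservation_without_relaxation(self, maps8, rng):
        """|m| = 1 to 1e-9 after an arbitrary strong pulse."""
        rf = 80.0 * (rng.normal(size=(8, 40)) + 1j * rng.normal(size=(8, 40)))
        grad = 5e-3 * rng.normal(size=(3, 40))
        res = fp.bloch_simulate(fp.PulseWaveform(rf=rf, grad=grad, raster=1e-5), maps8)
        norm = np.abs(res.mxy) ** 2 + res.mz**2
        assert np.abs(norm - 1.0).max() < 1e-9

    def test_gradient_precession_phase(self):
        """Gx = 10 mT/m at x = 10 mm for 100 us precesses by gamma*G*x*tau.

        Positive B_z precesses M_xy clockwise under dM/dt = gamma M x B, so
        the accrued phase is negative.
        """
        maps = fp.FieldMapSet(
            b1=np.zeros((1, 3, 1, 1), complex),
            b0=np.zeros((3, 1, 1)),
            mask=np.array([False, False, True]).reshape(3, 1, 1),
            resolution=0.01,  # masked voxel at x = +10 mm
        )
        pulse = fp.PulseWaveform(
            rf=np.zeros((1, 10), complex),
            grad=np.vstack([np.full(10, 1e-2), np.zeros((2, 10))]),
            raster=1e-5,
        )
        res = fp.bloch_simulate(pulse, maps, initial=np.array([[1.0, 0.0, 0.0]]))
        expected = GAMMA * 1e-2 * 0.01 * 100e-6  # 2.67522 rad
        assert expected == pytest.approx(2.67522, abs=1e-5)
        assert np.radians(res.phase[0]) == pytest.approx(-expected, rel=1e-9)

    def test_positive_b0_precesses_clockwise(self):
        maps = _single_voxel_maps(b1=0.0 + 0j, b0=100.0)
        pulse = fp.PulseWaveform(rf=np.zeros((1, 10), complex),
                                 grad=np.zeros((3, 10)), raster=1e-5)
        res = fp.bloch_simulate(pulse, maps, initial=np.array([[1.0, 0.0, 0.0]]))
        assert np.radians(res.phase[0]) == pytest.approx(-2 * np.pi * 100 * 1e-4)

    def test_relaxation_decay_and_regrowth(self):
        maps = _single_voxel_maps(b1=0.0 + 0j)
        tau = 50e-5
        pulse = fp.PulseWaveform(rf=np.zeros((1, 50), complex),
                                 grad=np.zeros((3, 50)), raster=1e-5)
        relax = fp.RelaxationSpec(t1=1.0, t2=0.05)
        res = fp.bloch_simulate(pulse, maps, relax=relax,
                                initial=np.array([[1.0, 0.0, 0.0]]))
        assert np.abs(res.mxy[0]) == pytest.approx(np.exp(-tau / 0.05), rel=1e-12)
        assert res.mz[0] == pytest.approx(1.0 - np.exp(-tau / 1.0), rel=1e-9)

    def test_zero_length_pulse_rejected(self, maps8):
        with pytest.raises(ValueError):
            fp.bloch_simulate(
                fp.PulseWaveform(rf=np.zeros((8, 0), complex),
                                 grad=np.zeros((3, 0)), raster=1e-5),
                maps8,
            )

    def test_channel_mismatch_rejected(self, maps8):
        with pytest.raises(ValueError, match="channels"):
            fp.bloch_simulate(
                fp.PulseWaveform(rf=np.zeros((4, 5), complex),
                                 grad=np.zeros((3, 5)), raster=1e-5),
                maps8,
            )


class TestSta:
    def test_system_matrix_limit_case(self):
        """Zero gradients, zero B0: every element reduces to i gamma b1 dt."""
        maps = _single_voxel_maps(b1=500.0 + 200.0j)
        a = fp.sta_system_matrix(maps, np.zeros((3, 4)), 1e-5)
        expected = 1j * GAMMA * 1e-5 * (500.0 + 200.0j) * 1e-9
        assert np.allclose(a, expected)

    def test_b0_phase_at_minus_5ms(self):
        """Single voxel at r=0, b0=100 Hz, t - T = -5 ms: phase is -pi."""
        maps = _single_voxel_maps(b1=1000.0 + 0j, b0=100.0)
        nt = 500  # 5 ms at 10 us; first sample has t - T = -4.99 ms... use 501
        a = fp.sta_system_matrix(maps, np.zeros((3, nt + 1)), 1e-5)
        # column of the first sample: t_0 - T = -5 ms
        ph = np.angle(a[0, 0] / (1j * GAMMA * 1e-5 * 1e-6))
        assert ph == pytest.approx(-np.pi) or ph == pytest.approx(np.pi)

    def test_k_of_last_sample_is_zero(self, maps8, rng):
        """k(T) = 0: the last column's phase carries no gradient contribution."""
        grad = 5e-3 * rng.normal(size=(3, 20))
        a_g = fp.sta_system_matrix(maps8, grad, 1e-5)
        a_0 = fp.sta_system_matrix(maps8, np.zeros((3, 20)), 1e-5)
        nt = 20
        for c in range(maps8.n_channels):
            col = c * nt + (nt - 1)
            assert np.allclose(a_g[:, col], a_0[:, col])

    def test_matrix_and_factored_paths_agree(self, maps8, cp10_8):
        a = fp.sta_system_matrix(maps8, cp10_8.grad, cp10_8.raster)
        mxy_mat = a @ cp10_8.rf.reshape(-1)
        res = fp.sta_simulate(cp10_8, maps8)
        assert np.allclose(mxy_mat, res.mxy, rtol=1e-12, atol=1e-15)

    def test_linearity_is_exact(self, maps8, cp10_8):
        base = fp.sta_simulate(cp10_8, maps8)
        doubled = fp.sta_simulate(cp10_8.scaled(2.0), maps8)
        assert np.array_equal(doubled.mxy, 2.0 * base.mxy)
        zero = fp.sta_simulate(cp10_8.scaled(0.0), maps8)
        assert np.all(zero.mxy == 0.0)

    def test_small_angle_agreement_with_bloch(self, maps8, cp10_8):
        """At a 10 deg target the two forward models agree within 2% NRMSE."""
        sta = fp.sta_simulate(cp10_8, maps8)
        blo = fp.bloch_simulate(cp10_8, maps8)
        cross = np.sqrt(np.mean((sta.fa - blo.fa) ** 2)) / np.mean(blo.fa) * 100
        assert cross < 2.0


class TestDerivedMaps:
    @pytest.mark.parametrize(
        "mxy, mz, fa_expect, phase_expect",
        [
            (np.sin(np.radians(10.0)), np.cos(np.radians(10.0)), 10.0, 0.0),
            (0.0, 1.0, 0.0, 0.0),  # phase undefined -> 0 by convention
            (0.0, -1.0, 180.0, 0.0),
            (1j * np.sin(np.radians(30.0)), np.cos(np.radians(30.0)), 30.0, 90.0),
        ],
    )
    def test_fa_phase_from_state(self, mxy, mz, fa_expect, phase_expect):
        fa, phase = fp.fa_phase_from_state(np.array([mxy]), np.array([mz]))
        assert fa[0] == pytest.approx(fa_expect, abs=1e-9)
        assert phase[0] == pytest.approx(phase_expect, abs=1e-9)

    def test_nrmse_examples(self):
        target = np.full(10, 10.0)
        assert fp.nrmse(target, target) == 0.0
        assert fp.nrmse(np.full(10, 5.0), target) == pytest.approx(50.0)
        fa = target.copy()
        fa[:5] += 1.0
        fa[5:] -= 1.0
        assert fp.nrmse(fa, target) == pytest.approx(10.0)

    def test_nrmse_zero_target_rejected(self):
        with pytest.raises(ValueError):
            fp.nrmse(np.ones(4), np.zeros(4))


class TestDifferentiability:
    def test_bloch_and_sta_gradients_match_finite_differences(self, maps2_tiny):
        """Autodiff through both forward models vs central differences."""
        from fastptx import autodiff as ad
        from fastptx.sim import bloch_core, sta_core

        rng = np.random.default_rng(0)
        nt = 6
        rf_re = 30.0 * rng.normal(size=(2, nt))
        rf_im = 30.0 * rng.normal(size=(2, nt))
        grad = 3e-3 * rng.normal(size=(3, nt))

        def scalar_bloch(rf_re, rf_im, grad):
            mx, my, mz = bloch_core(rf_re, rf_im, grad, maps2_tiny, 1e-5)
            return ad.asum(mx * mx + my * my) + ad.asum(mz)

        def scalar_sta(rf_re, rf_im, grad):
            re, im = sta_core(rf_re, rf_im, grad, maps2_tiny, 1e-5)
            return ad.asum(re * re + im * im)

        for fn in (scalar_bloch, scalar_sta):
            args = [ad.tensor(rf_re), ad.tensor(rf_im), ad.tensor(grad)]
            out = fn(*args)
            out.backward()
            for idx, (name, base, scale) in enumerate(
                [("rf_re", rf_re, 1.0), ("rf_im", rf_im, 1.0), ("grad", grad, 1e-4)]
            ):
                num = np.zeros_like(base)
                h = 1e-4 * scale
                flat = base.ravel()
                nf = num.ravel()
                for i in range(flat.size):
                    orig = flat[i]
                    vals = []
                    for sgn in (+1, -1):
                        flat[i] = orig + sgn * h
                        vals.append(float(fn(rf_re, rf_im, grad)))
                    flat[i] = orig
                    nf[i] = (vals[0] - vals[1]) / (2 * h)
                got = args[idx].grad
                denom = np.abs(num).max() + 1e-12
                assert np.abs(got - num).max() / denom < 1e-3, name
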