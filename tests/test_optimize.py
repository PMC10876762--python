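"""The AdamW-driven joint design loop and the design recipes."""

import numpy as np
import pytest

import fastptx as fp


def _problem(maps, **kw):
    defaults = dict(target_fa=10.0, duration=120e-6, raster=1e-5,
                    limits=fp.Limits(), model="sta", initial_pulse="random")
    defaults.update(kw)
    return fp.DesignProblem(maps=maps, **defaults)


class TestOptimizeContract:
    def test_parameter_count_of_the_reference_geometry(self, maps8):
        """520 us / 10 us raster, 16 channels, RF + 3 gradient axes: 1820."""
        maps16 = fp.synth_fieldmaps(
            fp.PhantomSpec(n_channels=16, grid_shape=(6, 6, 6),
                           resolution=0.03, seed=5)
        )
        problem = _problem(maps16, duration=520e-6)
        assert fp.n_parameters(problem) == 52 * 16 * 2 + 52 * 3 == 1820
        assert fp.n_parameters(_problem(maps8, optimize_grad=False)) == 8 * 12 * 2

    def test_running_best_cost_is_non_increasing(self, maps8):
        cfg = fp.OptimizerConfig(n_iterations=40, restart_period=15, seed=0)
        pulse, history = fp.optimize(_problem(maps8), cfg)
        totals = [b.total for b in history]
        running = np.minimum.accumulate(totals)
        assert np.all(np.diff(running) <= 0.0)
        # the returned pulse attains the best total seen
        fa = fp.sta_simulate(pulse, maps8).fa
        bd = fp.cost_terms(pulse, fa, 10.0, None, fp.Limits())
        assert bd.total == pytest.approx(min(totals), rel=1e-12)

    def test_fixed_seed_is_bit_identical(self, maps8):
        cfg = fp.OptimizerConfig(n_iterations=10, seed=3)
        p1, h1 = fp.optimize(_problem(maps8), cfg)
        p2, h2 = fp.optimize(_problem(maps8), cfg)
        assert np.array_equal(p1.rf, p2.rf)
        assert np.array_equal(p1.grad, p2.grad)
        assert [b.total for b in h1] == [b.total for b in h2]

    def test_multi_subject_cost_is_mean_of_single_subject_costs(self):
        subjects = [
            fp.synth_fieldmaps(fp.PhantomSpec(n_channels=4, grid_shape=(8, 8, 8),
                                              resolution=0.025, seed=s))
            for s in (0, 1, 2)
        ]
        seed_pulse = fp.cp_mode_pulse(4, 20.0, 120e-6, 1e-5)
        cfg = fp.OptimizerConfig(n_iterations=1, seed=0)
        _, hist_up = fp.optimize(_problem(subjects, initial_pulse=seed_pulse), cfg)
        singles = []
        for m in subjects:
            _, h = fp.optimize(_problem(m, initial_pulse=seed_pulse), cfg)
            singles.append(h[0].total)
        assert hist_up[0].total == pytest.approx(np.mean(singles), rel=1e-12)

    def test_single_voxel_reaches_closed_form_flip_angle(self):
        """One voxel, one channel: the optimizer finds the 10 deg solution."""
        maps = fp.FieldMapSet(
            b1=np.full((1, 1, 1, 1), 800.0 + 0j),
            b0=np.zeros((1, 1, 1)),
            mask=np.ones((1, 1, 1), bool),
            resolution=0.002,
        )
        problem = _problem(maps, duration=100e-6, optimize_grad=False,
                           model="bloch")
        cfg = fp.OptimizerConfig(n_iterations=1500, seed=1)
        pulse, _ = fp.optimize(problem, cfg)
        fa = fp.bloch_simulate(pulse, maps).fa[0]
        assert abs(fa - 10.0) < 0.1

    def test_non_finite_cost_aborts_with_term_name(self, maps8):
        absurd = fp.PulseWaveform(rf=np.full((8, 12), 1e200, complex),
                                  grad=np.zeros((3, 12)), raster=1e-5)
        problem = _problem(maps8, initial_pulse=absurd)
        with pytest.raises(RuntimeError, match=r"cost term \w+ became non-finite"):
            fp.optimize(problem, fp.OptimizerConfig(n_iterations=2, seed=0))

    def test_geometry_validation(self, maps8):
        with pytest.raises(ValueError):
            _problem(maps8, duration=105e-6)  # not a raster multiple
        with pytest.raises(ValueError):
            _problem(maps8, optimize_rf=False, optimize_grad=False)


class TestScaleToMeanFa:
    def test_sta_scaling_is_exact(self, maps8, cp10_8):
        scaled = fp.scale_pulse_to_mean_fa(cp10_8, maps8, 7.0, model="sta")
        assert fp.sta_simulate(scaled, maps8).fa.mean() == pytest.approx(7.0)

    def test_bloch_scalar_close_to_sta_at_small_fa(self, maps8, cp10_8):
        s_sta = fp.scale_pulse_to_mean_fa(cp10_8, maps8, 5.0, model="sta")
        s_blo = fp.scale_pulse_to_mean_fa(cp10_8, maps8, 5.0, model="bloch")
        ratio = np.abs(s_blo.rf).max() / np.abs(s_sta.rf).max()
        assert abs(ratio - 1.0) < 0.01
        assert fp.bloch_simulate(s_blo, maps8).fa.mean() == pytest.approx(5.0, abs=1e-3)

    def test_zero_target_gives_zero_pulse(self, maps8, cp10_8):
        z = fp.scale_pulse_to_mean_fa(cp10_8, maps8, 0.0)
        assert np.all(z.rf == 0.0)


class TestRecipes:
    def test_small_fa_design_improves_on_cp(self, maps8, vops8, cp10_8):
        pulse = fp.design_small_fa(maps8, 10.0, 520e-6, 1e-5, iters_sta=300,
                                   iters_bloch=0, vops=vops8, seed=0)
        n_design = fp.nrmse(fp.bloch_simulate(pulse, maps8).fa, 10.0)
        n_cp = fp.nrmse(fp.bloch_simulate(cp10_8, maps8).fa, 10.0)
        assert n_design < n_cp

    def test_bloch_refinement_runs_and_does_not_regress(self, maps8):
        sta_only = fp.design_small_fa(maps8, 10.0, 120e-6, 1e-5, iters_sta=80,
                                      iters_bloch=0, seed=0)
        refined = fp.design_small_fa(maps8, 10.0, 120e-6, 1e-5, iters_sta=80,
                                     iters_bloch=40, seed=0)
        n0 = fp.nrmse(fp.bloch_simulate(sta_only, maps8).fa, 10.0)
        n1 = fp.nrmse(fp.bloch_simulate(refined, maps8).fa, 10.0)
        assert n1 <= n0 * 1.02  # the Bloch phase must not damage the design

    def test_voltage_rescaling_after_design(self, maps8):
        """Scaling the 10 deg design to 9 deg multiplies voltages by 0.9."""
        pulse = fp.design_small_fa(maps8, 10.0, 120e-6, 1e-5, iters_sta=30,
                                   iters_bloch=0, seed=0)
        down = pulse.scaled(0.9)
        assert np.allclose(down.rf, 0.9 * pulse.rf)
        fa10 = fp.sta_simulate(pulse, maps8).fa
        fa9 = fp.sta_simulate(down, maps8).fa
        assert np.allclose(fa9, 0.9 * fa10)

    def test_large_fa_recipe(self):
        maps = fp.synth_fieldmaps(
            fp.PhantomSpec(n_channels=8, grid_shape=(8, 8, 8),
                           resolution=0.025, seed=1)
        )
        limits = fp.Limits()
        refined = fp.design_large_fa(maps, 90.0, 1.5e-3, 1e-5, limits=limits,
                                     iters_sta=150, iters_bloch=60, seed=0)
        naive = fp.design_small_fa(
            maps, 9.0, 1.5e-3, 1e-5, iters_sta=150, iters_bloch=0,
            limits=limits.scaled(0.1), seed=0,
        ).scaled(10.0)
        # the scaled intermediate obeys the full voltage limit by construction
        assert np.abs(naive.rf).max() <= limits.u_limit
        # RF-only refinement leaves the gradients bitwise unchanged
        assert np.array_equal(refined.grad, naive.grad)
        n_naive = fp.nrmse(fp.bloch_simulate(naive, maps).fa, 90.0)
        n_ref = fp.nrmse(fp.bloch_simulate(refined, maps).fa, 90.0)
        assert n_ref < n_naive

    def test_slab_design(self, maps8):
        from fastptx.optimize import build_slab_seed, slab_target_pattern

        thickness, fa = 0.08, 10.0
        target = slab_target_pattern(maps8, thickness, (0, 0, 1), fa)
        in_slab = np.abs(maps8.coords[..., 2]) <= thickness / 2
        assert np.all(target[in_slab] == fa)
        assert np.all(target[~in_slab] == 0.0)

        seed_pulse = build_slab_seed(maps8, thickness, fa=fa)
        # the sinc envelope (TBW 8) changes sign 6 times between its 8 zeros
        env = seed_pulse.rf[0, np.abs(seed_pulse.rf[0]) > 0]
        mag_phase = env * np.exp(-1j * np.angle(env[np.abs(env).argmax()]))
        signs = np.sign(mag_phase.real)
        assert int(np.sum(np.abs(np.diff(signs)) > 0)) == 6
        assert len(env) == 120  # 1.2 ms of RF at 10 us raster

        opt = fp.design_slab(maps8, thickness, fa=fa, n_iterations=120, seed=0)
        t_masked = target[maps8.mask]
        rmse_seed = np.sqrt(np.mean(
            (fp.bloch_simulate(seed_pulse, maps8).fa - t_masked) ** 2))
        rmse_opt = np.sqrt(np.mean(
            (fp.bloch_simulate(opt, maps8).fa - t_masked) ** 2))
        assert rmse_opt < rmse_seed


class TestRobustness:
    def test_zero_spread_reproduces_baseline(self, maps8, cp10_8):
        base = fp.nrmse(fp.bloch_simulate(cp10_8, maps8).fa, 10.0)
        vals = fp.robustness_eval(cp10_8, maps8, 10.0, n_reps=4,
                                  mag_sd=0.0, phase_sd_deg=0.0, seed=0)
        assert all(v == pytest.approx(base, rel=1e-12) for v in vals)

    def test_seeded_determinism_and_moderate_spread(self, maps8, cp10_8):
        a = fp.robustness_eval(cp10_8, maps8, 10.0, n_reps=10, seed=4)
        b = fp.robustness_eval(cp10_8, maps8, 10.0, n_reps=10, seed=4)
        assert a == b
        base = fp.nrmse(fp.bloch_simulate(cp10_8, maps8).fa, 10.0)
        # 5% / 5 deg channel errors move the NRMSE by a few points at most
        assert max(abs(v - base) for v in a) < 10.0
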