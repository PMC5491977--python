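"""Tests of the coupled-column integrator and the equilibrium solver."""

import numpy as np
import pytest

from callosim import (
    ColumnState,
    CouplingSpec,
    ModulatingInputSpec,
    NoiseSpec,
    SimulationSpec,
    StimulusSpec,
    coupled_input,
    fixed_point,
    integrate,
    integrate_batch,
)

QUIET = StimulusSpec(
    noise_p=NoiseSpec(mean=40.0, sd=0.0),
    noise_f=NoiseSpec(mean=3.0, sd=0.0, target="fast"),
)


def short_sim(seed=0, duration=2.0, warmup=0.5, dt=1e-4):
    return SimulationSpec(
        duration_s=duration, dt_s=dt, warmup_s=warmup, master_seed=seed
    )


class TestCoupledInput:
    def test_uncoupled_limit_passes_noise_through(self):
        assert coupled_input(3.0, 0.0, 4.0) == 3.0

    def test_fast_target_arithmetic(self):
        # K = 10 split 30/70: u_f = 3 + 0.7 * 10 * 4
        spec = CouplingSpec(K=10.0)
        assert coupled_input(3.0, spec.Kf, 4.0) == pytest.approx(31.0)

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError):
            coupled_input(3.0, -1.0, 4.0)

    def test_split_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CouplingSpec(K=10.0, split_p=0.5, split_f=0.6)


class TestIntegrate:
    def test_same_seed_is_bit_identical(self):
        a = integrate("LB", sim=short_sim(seed=5))
        b = integrate("LB", sim=short_sim(seed=5))
        assert np.array_equal(a.v_out, b.v_out)
        assert np.array_equal(a.zp, b.zp)

    def test_batch_member_equals_solo_run(self):
        solo = integrate(("LB", "LB"), CouplingSpec(K=10.0), sim=short_sim(seed=11))
        batch = integrate_batch(
            ("LB", "LB"),
            CouplingSpec(K=10.0),
            StimulusSpec(),
            short_sim(seed=11),
            seeds=[11, 12],
        )
        assert np.array_equal(solo.v_out, batch[0].v_out)

    def test_output_potential_consistent_with_states(self):
        tr = integrate("LB", sim=short_sim(seed=3), keep_states=True)
        conn = tr.columns[0].conn
        # STATE_FIELDS order: yp xp ye xe ys xs yf xf yl xl
        vp = (
            conn.Cpe * tr.states[..., 2]
            - conn.Cps * tr.states[..., 4]
            - conn.Cpf * tr.states[..., 6]
        )
        assert np.array_equal(vp, tr.v_out)

    def test_rates_stay_inside_sigmoid_range(self):
        tr = integrate(("LB", "LB"), CouplingSpec(K=20.0), sim=short_sim(seed=9))
        for rate in (tr.zp, tr.ze, tr.zs, tr.zf):
            assert np.all((rate > 0.0) & (rate < 5.0))

    def test_single_column_must_be_uncoupled(self):
        with pytest.raises(ValueError):
            integrate("LB", CouplingSpec(K=5.0), sim=short_sim())

    def test_fs_out_must_divide_step_rate(self):
        with pytest.raises(ValueError):
            SimulationSpec(dt_s=3e-4)

    def test_nonfinite_initial_state_reports_blowup(self):
        bad = ColumnState(yp=np.nan)
        with pytest.raises(FloatingPointError, match="blow-up"):
            integrate("LB", sim=short_sim(), initial_state=bad)


class TestDelay:
    def test_delayed_rate_enters_fast_input_after_exactly_t(self):
        """With the delay set to a whole number of output samples, the
        fast-target input of one column equals the mean drive plus
        K_f times the other column's pyramidal rate T seconds earlier,
        sample for sample."""
        coupling = CouplingSpec(K=10.0, delay_s=0.02)  # 2 output samples
        stim = StimulusSpec(
            noise_p=QUIET.noise_p,
            noise_f=QUIET.noise_f,
            modulation=ModulatingInputSpec(
                baseline_s=0.3, rise_s=0.2, plateau_s=0.3, fall_s=0.2, rest_s=1.0
            ),
        )
        tr = integrate(
            ("LB", "LB"), coupling, stim, short_sim(duration=2.0, warmup=0.0),
            keep_inputs=True,
        )
        lag = 2
        zp_left = tr.zp[:, 0]
        u_f_right = tr.inputs_f[:, 1]
        expect = 3.0 + coupling.Kf * zp_left[:-lag]
        assert np.array_equal(u_f_right[lag:], expect)

    def test_before_one_delay_the_history_is_zero(self):
        coupling = CouplingSpec(K=10.0, delay_s=0.02)
        tr = integrate(
            ("LB", "LB"), coupling, QUIET, short_sim(duration=1.0, warmup=0.0),
            keep_inputs=True,
        )
        assert np.all(tr.inputs_f[:2] == 3.0)


class TestNoiseFreeDynamics:
    def test_run_from_equilibrium_stays_there(self):
        fp = fixed_point("LB")[-1]
        tr = integrate(
            "LB", stimuli=QUIET, sim=short_sim(duration=2.0, warmup=0.0),
            initial_state=fp.states[0],
        )
        assert np.abs(tr.zp - fp.rates[0].zp).max() < 1e-6

    def test_zero_start_converges_to_equilibrium(self):
        fp = fixed_point("LB")[-1]
        tr = integrate("LB", stimuli=QUIET, sim=short_sim(duration=4.0, warmup=0.0))
        tail = tr.zp[tr.time > 3.0]
        assert np.abs(tail - fp.rates[0].zp).max() < 1e-3

    def test_halving_dt_barely_moves_the_mean_rate(self):
        means = []
        for dt in (1e-4, 5e-5):
            tr = integrate(
                "LB", stimuli=QUIET, sim=short_sim(duration=3.0, warmup=1.0, dt=dt)
            )
            means.append(tr.zp.mean())
        assert abs(means[0] - means[1]) < 1e-3


class TestFixedPoint:
    def test_uncoupled_matches_reference_rates(self):
        rates = fixed_point("LB")[-1].rates[0]
        # frozen from an independent solve of the algebraic system
        assert rates.zp == pytest.approx(4.32845, abs=1e-4)
        assert rates.ze == pytest.approx(5.0, abs=1e-6)
        assert rates.zs == pytest.approx(4.59947, abs=1e-4)
        assert rates.zf == pytest.approx(0.47221, abs=1e-4)

    def test_weakly_coupled_pair_has_symmetric_equilibrium(self):
        fps = fixed_point(("LB", "LB"), CouplingSpec(K=5.0))
        diffs = [
            abs(float(np.atleast_1d(fp.rates[0].zp)[0]) - float(np.atleast_1d(fp.rates[1].zp)[0]))
            for fp in fps
        ]
        assert min(diffs) < 1e-6

    def test_strongly_coupled_pair_has_asymmetric_equilibria(self):
        fps = fixed_point(("LB", "LB"), CouplingSpec(K=70.0), n_starts=60)
        diffs = [
            abs(float(np.atleast_1d(fp.rates[0].zp)[0]) - float(np.atleast_1d(fp.rates[1].zp)[0]))
            for fp in fps
        ]
        assert max(diffs) > 3.0
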