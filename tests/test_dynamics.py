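import numpy as np
import pytest
from scipy.integrate import solve_ivp

from vnccpg.circuit import expand_genotype
from vnccpg.dynamics import (
    BACKWARD,
    FORWARD,
    ClampStimulus,
    InputProtocol,
    IntegrationError,
    NeuronParams,
    SimulationConfig,
    bistability_threshold,
    classify_bistability,
    find_equilibria,
    run_clamp_protocol,
    sigmoid,
    simulate,
    _matrices,
)
from vnccpg.synthetic import sample_genotype

PASSIVE = NeuronParams(theta=-1.8, tau=0.03, w_self=0.6)
ACTIVE = NeuronParams(theta=-3.4, tau=0.05, w_self=5.1)


def _reference_solution(instance, protocol, t_eval):
    """Adaptive-step oracle for the same vector field."""
    W, G, gsum = _matrices(instance)
    avb, ava = instance.external_drive()
    u_b, u_a = protocol.drives(1)
    I = instance.tonic + u_b * avb + u_a * ava

    def rhs(t, y):
        return (-y + W @ sigmoid(y + instance.theta) + G @ y - gsum * y + I) \
            / instance.tau

    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), np.zeros(instance.n_cells),
                    t_eval=t_eval, method="LSODA", rtol=1e-10, atol=1e-12,
                    max_step=0.5)
    return sol.y.T


class TestSimulate:
    def test_quiescent_circuit_stays_at_rest(self, constant_instance):
        trace = simulate(constant_instance, FORWARD, duration=5.0)
        np.testing.assert_array_equal(trace.y, 0.0)
        expected = sigmoid(constant_instance.theta)
        np.testing.assert_allclose(
            trace.outputs, np.broadcast_to(expected, trace.outputs.shape))

    def test_outputs_bounded_in_unit_interval(self):
        # sigma maps to (0, 1); saturation may round to the closed endpoints
        # in floating point, but can never escape [0, 1]
        for seed in range(5):
            inst = expand_genotype(sample_genotype(seed))
            trace = simulate(inst, BACKWARD, duration=26.0)
            assert trace.outputs.min() >= 0.0
            assert trace.outputs.max() <= 1.0
            assert np.isfinite(trace.y).all()

    def test_agrees_with_adaptive_oracle_on_evaluation_window(self):
        # compare where the assay reads the trace (post-reset-transient)
        for seed in range(5):
            inst = expand_genotype(sample_genotype(seed))
            trace = simulate(inst, FORWARD, duration=26.0)
            sub = slice(None, None, 40)
            ref = _reference_solution(inst, FORWARD, trace.time[sub])
            err = np.abs(ref - trace.y[sub])
            assert err[trace.time[sub] >= 6.0].max() < 1e-2

    def test_first_order_convergence(self):
        inst = expand_genotype(sample_genotype(3))
        errs = []
        for dt in (0.0025, 0.00125):
            tr = simulate(inst, FORWARD, SimulationConfig(dt=dt), duration=26.0)
            ref = _reference_solution(inst, FORWARD, tr.time[:: int(0.1 / dt)])
            errs.append(np.abs(ref - tr.y[:: int(0.1 / dt)]).max())
        ratio = errs[0] / errs[1]
        assert 1.5 < ratio < 2.5  # halving dt roughly halves the error

    def test_record_from_matches_full_recording(self, random_instance):
        full = simulate(random_instance, FORWARD, duration=10.0)
        tail = simulate(random_instance, FORWARD, duration=10.0, record_from=6.0)
        i0 = np.searchsorted(full.time, tail.time[0])
        np.testing.assert_allclose(full.y[i0:], tail.y, rtol=0, atol=1e-12)

    def test_divergence_reported_with_step(self):
        inst = expand_genotype(np.zeros(34))
        inst.tonic[:] = 0.0
        inst.self_weight[:] = 0.0
        # unstable positive feedback through a huge hand-set self weight
        inst.self_weight[0] = 1e9
        inst.theta[0] = 10.0
        with pytest.raises(IntegrationError, match="step"):
            simulate(inst, FORWARD, duration=5.0)

    def test_custom_drive_requires_unit_interval(self, constant_instance):
        protocol = InputProtocol("custom", u_avb=np.array([0.5, 2.0]),
                                 u_ava=np.array([0.0, 0.0]))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            simulate(constant_instance, protocol, duration=0.005)


class TestClampProtocols:
    def test_passive_step_returns_to_rest(self):
        # graded rise under a current step, full relaxation after offset
        stim = ClampStimulus(times=(0.0, 1.0, 6.0), amplitudes=(0.0, 4.0, 0.0),
                             kind="steps")
        trace = run_clamp_protocol(PASSIVE, stim, duration=12.0)
        out = trace.outputs[:, 0]
        rest = out[int(0.9 / trace.dt)]
        during = out[int(5.9 / trace.dt)]
        after = out[-1]
        assert during > rest + 0.05
        assert abs(after - rest) < 1e-4

    def test_active_step_latches_plateau(self):
        # the printed active parameters are monostable at zero input but
        # bistable within a band of holding currents; a depolarising step on
        # such a holding current latches a long-lived plateau, and the cell
        # settles at a different steady state from where it started
        hold = 0.85
        assert not classify_bistability(ACTIVE, 0.0)
        assert classify_bistability(ACTIVE, hold)
        stim = ClampStimulus(times=(0.0, 4.0, 9.0),
                             amplitudes=(hold, 4.0, hold), kind="steps")
        trace = run_clamp_protocol(ACTIVE, stim, duration=17.0)
        out = trace.outputs[:, 0]
        rest = out[int(3.9 / trace.dt)]
        after = out[-1]
        assert after > rest + 0.3
        lo, hi = sorted(y for y, s in find_equilibria(ACTIVE, hold) if s)
        assert abs(trace.y[int(3.9 / trace.dt), 0] - lo) < 1e-3
        assert abs(trace.y[-1, 0] - hi) < 1e-3

    def test_passive_ramp_is_graded(self):
        stim = ClampStimulus(times=(0.0, 10.0), amplitudes=(0.0, 5.0),
                             kind="ramp")
        trace = run_clamp_protocol(PASSIVE, stim, duration=10.0)
        dout = np.diff(trace.outputs[:, 0])
        # monotone, non-regenerative rise: no step-to-step acceleration burst
        assert dout.min() >= -1e-9
        assert dout.max() < 5 * trace.dt

    def test_active_ramp_becomes_regenerative(self):
        stim = ClampStimulus(times=(0.0, 10.0), amplitudes=(0.0, 5.0),
                             kind="ramp")
        trace = run_clamp_protocol(ACTIVE, stim, duration=10.0)
        dy = np.diff(trace.y[:, 0])
        # the regenerative jump is far faster than the initial linear phase
        assert dy.max() > 20 * np.median(dy[dy > 0])
        assert trace.outputs[-1, 0] > 0.9  # plateau

    def test_zero_stimulus_rests_at_fixed_point(self):
        stim = ClampStimulus(times=(0.0,), amplitudes=(0.0,))
        trace = run_clamp_protocol(PASSIVE, stim, duration=5.0)
        (y_star, stable), = find_equilibria(PASSIVE)
        assert stable
        assert abs(trace.y[-1, 0] - y_star) < 1e-6


class TestEquilibria:
    def test_passive_neuron_has_unique_stable_point(self):
        eq = find_equilibria(PASSIVE)
        assert len(eq) == 1
        assert eq[0][1] is True

    def test_bistable_band_for_strong_self_connection(self):
        eq = find_equilibria(NeuronParams(theta=-2.55, tau=1.0, w_self=5.1))
        stables = [s for _, s in eq]
        assert stables.count(True) == 2
        assert stables.count(False) == 1

    def test_stable_and_unstable_points_alternate(self):
        eq = find_equilibria(NeuronParams(theta=-10.0, tau=1.0, w_self=20.0))
        flags = [s for _, s in eq]
        assert flags == [True, False, True]

    def test_matches_brute_force_scan_on_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            p = NeuronParams(theta=float(rng.uniform(-20, 20)), tau=1.0,
                             w_self=float(rng.uniform(-20, 20)))
            eq = find_equilibria(p)
            # dense sign-change scan as the independent oracle
            y = np.arange(-30.0, 30.0, 1e-3)
            h = p.w_self * sigmoid(y + p.theta) - y
            oracle = int(np.sum(np.sign(h[:-1]) * np.sign(h[1:]) < 0))
            assert len(eq) == oracle

    def test_classify_bistability(self):
        assert not classify_bistability(NeuronParams(0.0, 1.0, 0.0))
        assert classify_bistability(NeuronParams(-10.0, 1.0, 20.0))
        # below the saddle-node threshold no bias admits bistability
        for theta in np.linspace(-20, 20, 41):
            assert not classify_bistability(NeuronParams(theta, 1.0, 3.9))

    def test_threshold_is_four(self):
        thr = bistability_threshold(tol=1e-4)
        assert abs(thr - 4.0) < 1e-3
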