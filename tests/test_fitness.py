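import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logit

from vnccpg.dynamics import Trace
from vnccpg.fitness import (
    BACKWARD_SETS,
    FORWARD_SETS,
    FitnessConstants,
    bump_norm,
    dominance_score,
    evaluate_assay,
    oscillation_score,
    phase_score,
)

C = FitnessConstants()
T, A = C.T, C.A


def make_trace(outputs_by_cell: dict, dt: float = 0.0025) -> Trace:
    """Trace whose sigmoidal outputs equal the given arrays (theta = 0)."""
    cells = list(outputs_by_cell)
    O = np.column_stack([np.asarray(outputs_by_cell[c], float) for c in cells])
    y = logit(np.clip(O, 1e-12, 1 - 1e-12))
    time = np.arange(O.shape[0]) * dt
    return Trace(time=time, y=y, cells=cells, theta=np.zeros(len(cells)))


def triangle(n_cycles: float, peak_to_peak: float, base: float = 0.35,
             dt: float = 0.0025, phase: float = 0.0) -> np.ndarray:
    t = np.arange(0, T, dt)
    saw = (t * n_cycles / T + phase) % 1.0
    tri = 2 * np.abs(saw - 0.5)
    return base + peak_to_peak * tri


class TestOscillationScore:
    def test_constant_trace_scores_zero(self):
        tr = make_trace({c: np.full(8001, 0.5) for c in FORWARD_SETS.dominant})
        f1, s = oscillation_score(tr, FORWARD_SETS.dominant, C)
        assert f1 == 0.0
        assert all(v == 0.0 for v in s.values())

    @pytest.mark.parametrize("cycles,expected", [(5, 1.0), (2.5, 0.5)])
    def test_triangle_wave_closed_form(self, cycles, expected):
        # total variation of a triangle with peak-to-peak A over k cycles is
        # 2*A*k, so S = 2*(2*A*k)/(A*T) = 4k/T
        wave = triangle(cycles, A)
        tr = make_trace({c: wave for c in FORWARD_SETS.dominant})
        f1, s = oscillation_score(tr, FORWARD_SETS.dominant, C)
        assert s["DB"] == pytest.approx(expected, abs=1e-3)
        assert f1 == pytest.approx(expected ** 3, rel=1e-2)

    def test_capped_at_one_per_neuron(self):
        wave = triangle(40, 0.5)
        tr = make_trace({c: wave for c in FORWARD_SETS.dominant})
        f1, s = oscillation_score(tr, FORWARD_SETS.dominant, C)
        assert all(v == 1.0 for v in s.values())
        assert f1 == 1.0

    def test_invariant_to_constant_offset_and_reflection(self):
        wave = triangle(3, 0.2, base=0.3)
        for variant in (wave + 0.1, 1.0 - wave):
            t1 = make_trace({c: wave for c in FORWARD_SETS.dominant})
            t2 = make_trace({c: variant for c in FORWARD_SETS.dominant})
            f1a, _ = oscillation_score(t1, FORWARD_SETS.dominant, C)
            f1b, _ = oscillation_score(t2, FORWARD_SETS.dominant, C)
            assert f1a == pytest.approx(f1b, rel=1e-9)

    def test_signed_variant_telescopes_to_nothing(self):
        # the literal (unsigned-bars-free) reading of the integral collapses
        # on periodic windows, which is why the default uses |dO/dt|
        wave = triangle(5, A)
        tr = make_trace({c: wave for c in FORWARD_SETS.dominant})
        f1, _ = oscillation_score(tr, FORWARD_SETS.dominant, C, signed=True)
        assert f1 < 0.01

    def test_empty_window_rejected(self):
        tr = make_trace({c: np.array([0.5]) for c in FORWARD_SETS.dominant})
        with pytest.raises(ValueError, match="empty"):
            oscillation_score(tr, FORWARD_SETS.dominant, C)


class TestPhaseScore:
    def test_exact_antiphase_scores_one(self):
        wave = triangle(4, 0.3)
        anti = triangle(4, 0.3, phase=0.5)
        tr = make_trace({"DB": wave, "VBa": anti, "VBp": anti})
        f2, factors = phase_score(tr, FORWARD_SETS.pairs, C)
        assert f2 == pytest.approx(1.0, abs=2e-3)

    def test_in_phase_scores_zero(self):
        wave = triangle(4, 0.3)
        tr = make_trace({"DB": wave, "VBa": wave, "VBp": wave})
        f2, factors = phase_score(tr, FORWARD_SETS.pairs, C)
        assert f2 == pytest.approx(0.0, abs=2e-3)

    def test_flat_against_monotone_scores_half(self):
        n = 8001
        flat = np.full(n, 0.4)
        rising = np.linspace(0.2, 0.8, n)
        tr = make_trace({"DB": rising, "VBa": flat, "VBp": flat})
        f2, factors = phase_score(tr, FORWARD_SETS.pairs, C)
        assert factors["VBa|DB"] == pytest.approx(0.5, abs=1e-3)

    def test_symmetric_in_the_pair(self):
        rng = np.random.default_rng(4)
        a = np.cumsum(rng.normal(size=2001)) * 1e-3 + 0.5
        b = np.cumsum(rng.normal(size=2001)) * 1e-3 + 0.5
        t1 = make_trace({"DB": a, "VBa": b, "VBp": b})
        t2 = make_trace({"DB": b, "VBa": a, "VBp": a})
        f_ab = phase_score(t1, (("VBa", "DB"),), C)[0]
        f_ba = phase_score(t2, (("VBa", "DB"),), C)[0]
        assert f_ab == pytest.approx(f_ba, rel=1e-12)


class TestBumpNorm:
    def test_zero_argument_gives_floor(self):
        for x0 in (0.1, 0.3, 0.7, 1.0, 5.0):
            assert bump_norm(0.0, x0) == pytest.approx(0.1)

    def test_maximum_at_reference(self):
        assert bump_norm(0.3, 0.3) == pytest.approx(1.0)
        assert bump_norm(0.7, 0.7) == pytest.approx(1.0)

    @given(st.floats(0.01, 5.0), st.floats(0.01, 5.0))
    @settings(max_examples=100, deadline=None)
    def test_unimodal_shape(self, x, x0):
        eps = 1e-6
        f = bump_norm(x, x0)
        assert 0.1 <= f <= 1.0 + 1e-12
        if x + eps < x0:
            assert bump_norm(x + eps, x0) > f
        elif x - eps > x0:
            # strictly decreasing past the peak until the exponential tail
            # underflows against the 0.1 floor
            if x / x0 < 30:
                assert bump_norm(x - eps, x0) > f
            else:
                assert bump_norm(x - eps, x0) >= f

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            bump_norm(0.5, 0.0)
        with pytest.raises(ValueError):
            bump_norm(-0.1, 0.3)


class TestDominanceScore:
    def test_ideal_configuration_scores_one(self):
        # dominant oscillating in [0.7, 1.0], nondominant flat at 0.3:
        # every argument sits exactly at its reference
        dom = triangle(4, A, base=1 - A)
        flat = np.full(dom.shape, A)
        tr = make_trace({**{c: dom for c in FORWARD_SETS.dominant},
                         **{c: flat for c in FORWARD_SETS.nondominant}})
        f3, detail = dominance_score(tr, FORWARD_SETS.dominant,
                                     FORWARD_SETS.nondominant, C)
        assert f3 == pytest.approx(1.0, abs=1e-6)
        assert detail["m_Y"]["DB"] == pytest.approx(0.7)
        assert detail["A_Y"]["DB"] == pytest.approx(0.3)

    def test_constant_outputs_hit_amplitude_floor(self):
        flat = np.full(801, 0.5)
        tr = make_trace({c: flat for c in
                         FORWARD_SETS.dominant + FORWARD_SETS.nondominant})
        f3, detail = dominance_score(tr, FORWARD_SETS.dominant,
                                     FORWARD_SETS.nondominant, C)
        for v in detail["A_Y"].values():
            assert v == 0.0
        # each zero amplitude contributes the 0.1 floor
        assert f3 == pytest.approx(
            bump_norm(0.5, 1 - A) ** 3 * bump_norm(0.5, A) ** 4 * 0.1 ** 3)

    def test_factor_counts_by_direction(self):
        # forward: 3 minima + 4 maxima + 3 amplitudes; backward: 4 + 3 + 4
        assert (len(FORWARD_SETS.dominant), len(FORWARD_SETS.nondominant)) \
            == (3, 4)
        assert (len(BACKWARD_SETS.dominant), len(BACKWARD_SETS.nondominant)) \
            == (4, 3)


class TestAssay:
    def test_zero_weight_instance_scores_zero(self, constant_instance):
        assert evaluate_assay(constant_instance).total == 0.0

    def test_reference_fixture_clears_dashed_line(self, reference):
        assert evaluate_assay(reference).total >= 0.2

    def test_components_lie_in_unit_interval(self, reference, random_instance):
        for inst in (reference, random_instance):
            b = evaluate_assay(inst)
            for d in (b.forward, b.backward):
                assert 0.0 <= d.f1 <= 1.0
                assert 0.0 <= d.f2 <= 1.0 + 1e-12
                assert 0.0 < d.f3 <= 1.0 + 1e-12

    def test_invariant_under_anterior_posterior_relabel(self, reference):
        swapped = reference.copy()

        def flip(c):
            return c[:2] + {"a": "p", "p": "a"}.get(c[2:], c[2:])

        swapped.cells = [flip(c) for c in swapped.cells]
        swapped.chemical_synapses = [(flip(p), flip(q), w)
                                     for p, q, w in swapped.chemical_synapses]
        swapped.gap_junctions = [(flip(a), flip(b), g)
                                 for a, b, g in swapped.gap_junctions]
        b0 = evaluate_assay(reference)
        b1 = evaluate_assay(swapped)
        assert b1.total == pytest.approx(b0.total, rel=1e-9)
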