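import numpy as np
import pytest

from vnccpg.ablation import (
    ablate_cells,
    dependency_profile,
    find_core_oscillators,
    remove_connection,
    substitute_connection_tonic,
)
from vnccpg.dynamics import FORWARD, NeuronParams, find_equilibria, simulate
from vnccpg.ensemble import measure_phase_lag, UndefinedLagError
from vnccpg.fitness import direction_trace, evaluate_assay
from vnccpg.synthetic import make_constant_instance


class TestAblateCells:
    def test_unknown_cell_rejected(self, reference):
        with pytest.raises(KeyError):
            ablate_cells(reference, ["XX"])

    def test_removing_everything_rejected(self, reference):
        with pytest.raises(ValueError, match="every cell"):
            ablate_cells(reference, ["AS", "DA", "DB", "VA", "VB", "VD"])

    def test_class_name_expands_to_both_cells(self, reference):
        out = ablate_cells(reference, ["VA"])
        assert "VAa" not in out.cells and "VAp" not in out.cells
        assert len(out.cells) == 9
        assert all("VA" not in (p[:2], q[:2])
                   for p, q, _ in out.chemical_synapses)

    def test_unconnected_cell_removal_leaves_rest_unchanged(self):
        # in the all-midpoint instance DB has zero-weight synapses and no gap
        # junctions, so deleting it cannot move the survivors
        inst = make_constant_instance()
        out = ablate_cells(inst, ["DB"])
        t_full = simulate(inst, FORWARD, duration=5.0)
        t_cut = simulate(out, FORWARD, duration=5.0)
        keep = [inst.index(c) for c in out.cells]
        np.testing.assert_array_equal(t_full.y[:, keep], t_cut.y)

    def test_compensation_adds_tonic_current(self, reference):
        out = ablate_cells(reference, ["VB"], compensation={"DB": 1.5})
        assert out.tonic[out.index("DB")] == reference.tonic[
            reference.index("DB")] + 1.5

    def test_single_subthreshold_cell_cannot_oscillate(self, reference):
        # one isolated neuron with self-weight < 4 has a unique stable
        # equilibrium, hence no oscillation for any ablation pattern
        weak = reference.copy()
        weak.self_weight[weak.index("DB")] = 3.0
        alone = ablate_cells(weak, ["AS", "DA", "VA", "VB", "VD"])
        trace = simulate(alone, FORWARD, duration=300.0, record_from=280.0)
        assert trace.outputs.max() - trace.outputs.min() < 1e-9
        eq = find_equilibria(NeuronParams(float(alone.theta[0]), 1.0,
                                          float(alone.self_weight[0])),
                             float(alone.tonic[0] + alone.w_avb))
        assert sum(s for _, s in eq) == 1


class TestConnectionSurgery:
    def test_removal_and_reinsertion_restores_trace_bit_exactly(self, reference):
        base = simulate(reference, FORWARD, duration=10.0)
        stripped, w = remove_connection(reference, "ASa", "VDa")
        stripped.chemical_synapses.append(("ASa", "VDa", w))
        again = simulate(stripped, FORWARD, duration=10.0)
        np.testing.assert_array_equal(base.y, again.y)

    def test_unknown_connection_rejected(self, reference):
        with pytest.raises(KeyError):
            remove_connection(reference, "DB", "VBa")

    def test_sweep_spans_attainable_range(self, reference):
        w = dict(((p, q), w) for p, q, w in reference.chemical_synapses)[
            ("ASa", "VDa")]
        res = substitute_connection_tonic(reference, "ASa", "VDa",
                                          n_values=11)
        assert res.values[0] == pytest.approx(min(0.0, w))
        assert res.values[-1] == pytest.approx(max(0.0, w))

    def test_zero_weight_connection_is_inert_under_substitution(self, reference):
        nulled = reference.copy()
        nulled.chemical_synapses = [
            (p, q, 0.0 if (p, q) == ("VBa", "VAa") else w)
            for p, q, w in nulled.chemical_synapses]
        base = evaluate_assay(nulled).total
        res = substitute_connection_tonic(nulled, "VBa", "VAa", n_values=3)
        bf, vf = res.best_forward
        bb, vb = res.best_backward
        assert bf * bb == pytest.approx(base, rel=1e-9)
        assert vf == vb == 0.0


class TestReferenceCircuitDissection:
    def test_dorsal_trio_is_a_minimal_core_oscillator(self, reference):
        cores = find_core_oscillators(reference, sweep_n=15)
        assert ("AS", "DA", "DB") in cores
        # minimality: no returned subset strictly contains another
        sets = [set(s) for s in cores]
        assert not any(a < b for a in sets for b in sets)

    def test_non_oscillator_has_no_core(self):
        assert find_core_oscillators(make_constant_instance()) == []

    def test_vd_vb_class_connection_is_phasic_required(self, reference):
        # the only route into the VB cells: replacing both instances of the
        # class connection with a shared constant silences them
        base = evaluate_assay(reference).total
        res = substitute_connection_tonic(reference, "VD", "VB", n_values=60)
        bf, _ = res.best_forward
        bb, _ = res.best_backward
        assert bf * bb < 0.2 * base

    def test_substituting_as_vd_destroys_antiphase(self, reference):
        # dorsoventral coordination travels through AS->VD; replacing both
        # instances with their best constants leaves VD flat or in-phase
        stripped, w1 = remove_connection(reference, "ASa", "VDa")
        stripped, w2 = remove_connection(stripped, "ASp", "VDp")
        best = -1.0
        lags = None
        for c in np.linspace(min(0, w1), max(0, w1), 25):
            trial = stripped.copy()
            trial.tonic[trial.index("VDa")] += c
            trial.tonic[trial.index("VDp")] += c
            b = evaluate_assay(trial)
            if b.total > best:
                best = b.total
                trace = direction_trace(trial, "forward")
                lags = []
                for v, d in (("VBa", "DB"), ("VBp", "DB")):
                    try:
                        lags.append(measure_phase_lag(trace.output(v),
                                                      trace.output(d)))
                    except UndefinedLagError:
                        lags.append(None)
        # antiphase gone: no pair keeps a lag near half a period
        assert not any(l is not None and abs(l - 0.5) <= 0.125 for l in lags)

    def test_dependency_profile_covers_all_connections(self, reference):
        report = dependency_profile(reference, n_chemical=25, n_electrical=25)
        kinds = [p.electrical for p in report.profiles]
        assert kinds.count(False) == 20
        assert kinds.count(True) == 6
        for p in report.profiles:
            assert p.best_forward_fitness <= 1.0
            assert p.best_backward_fitness <= 1.0

    def test_profile_stable_under_sweep_refinement(self, reference):
        # doubling the sweep resolution leaves the classification unchanged
        r1 = dependency_profile(reference, n_chemical=20, n_electrical=20)
        r2 = dependency_profile(reference, n_chemical=40, n_electrical=40)
        c1 = {(p.pre, p.post): p.classification for p in r1.profiles}
        c2 = {(p.pre, p.post): p.classification for p in r2.profiles}
        assert c1 == c2
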