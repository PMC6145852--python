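"""Circuit dissection: cell ablation, tonic substitution of connections,
core-oscillator subset search, and per-connection dependency profiling.

Replacing a connection's time-varying synaptic term with a swept constant
current separates two roles a presynaptic partner can play: keeping the
postsynaptic cell in its operating range (a tonic substitute then restores
performance) versus transmitting a phasic signal (no constant can).  Sweep
sizes follow the study (1000 constants for chemical synapses, 2000 for
electrical); the sweep *ranges* are a declared design choice: a chemical
term w*sigma(.) can only ever deliver currents in [min(0, w), max(0, w)],
and an electrical term is swept over its empirically observed range during
the unablated assay, extended by 50% on each side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .circuit import CircuitInstance
from .dynamics import IntegrationError, SimulationConfig
from .ensemble import CriteriaThresholds, detect_oscillation
from .fitness import FitnessConstants, direction_trace, evaluate_direction

__all__ = [
    "AblationSpec",
    "SubstitutionResult",
    "ConnectionProfile",
    "AblationReport",
    "ablate_cells",
    "remove_connection",
    "substitute_connection_tonic",
    "find_core_oscillators",
    "dependency_profile",
]

CLASS_NAMES = ("AS", "DA", "DB", "VA", "VB", "VD")


@dataclass(frozen=True)
class AblationSpec:
    """Cells (or whole classes) to remove plus optional tonic compensation."""

    removed: tuple[str, ...] = ()
    compensation: dict = field(default_factory=dict)  # cell -> constant current


def _expand_cell_names(instance: CircuitInstance, names: Iterable[str]) -> list[str]:
    out: list[str] = []
    for name in names:
        if name in instance.cells:
            out.append(name)
        elif name in CLASS_NAMES:
            members = [c for c in instance.cells if c[:2] == name]
            if not members:
                raise KeyError(f"class {name!r} has no cells in this instance")
            out.extend(members)
        else:
            raise KeyError(f"unknown cell or class {name!r}")
    return out


def ablate_cells(
    instance: CircuitInstance,
    cells: Iterable[str],
    compensation: dict | None = None,
) -> CircuitInstance:
    """Remove cells (or whole classes) and every incident connection.

    `compensation` adds constant currents to named surviving cells, standing
    in for the mean drive the removed partners used to provide.
    """
    removed = set(_expand_cell_names(instance, cells))
    survivors = [c for c in instance.cells if c not in removed]
    if not survivors:
        raise ValueError("ablation would remove every cell in the circuit")
    keep = np.array([c not in removed for c in instance.cells])
    out = CircuitInstance(
        cells=survivors,
        tau=instance.tau[keep],
        theta=instance.theta[keep],
        self_weight=instance.self_weight[keep],
        chemical_synapses=[(p, q, w) for p, q, w in instance.chemical_synapses
                           if p not in removed and q not in removed],
        gap_junctions=[(a, b, g) for a, b, g in instance.gap_junctions
                       if a not in removed and b not in removed],
        w_avb=instance.w_avb,
        w_ava=instance.w_ava,
        tonic=instance.tonic[keep].copy(),
    )
    for cell, current in (compensation or {}).items():
        if not np.isfinite(current):
            raise ValueError(f"non-finite compensation for {cell!r}")
        out.tonic[out.index(cell)] += current
    return out


def _matches(cell: str, name: str) -> bool:
    """Exact cell match, or class match when `name` is a bare class name."""
    return cell == name or (name in CLASS_NAMES and cell[:2] == name)


def _matching_connections(
    instance: CircuitInstance, pre: str, post: str, electrical: bool
) -> list[tuple[str, str, float]]:
    if electrical:
        hits = [(a, b, g) for a, b, g in instance.gap_junctions
                if (_matches(a, pre) and _matches(b, post))
                or (_matches(a, post) and _matches(b, pre))]
    else:
        hits = [(p, q, w) for p, q, w in instance.chemical_synapses
                if _matches(p, pre) and _matches(q, post)]
    if not hits:
        kind = "gap junction" if electrical else "chemical synapse"
        raise KeyError(f"{kind} {pre}{'<->' if electrical else '->'}{post} "
                       f"not found")
    return hits


def remove_connection(
    instance: CircuitInstance,
    pre: str,
    post: str,
    electrical: bool = False,
) -> tuple[CircuitInstance, float]:
    """Drop matching connections; returns (modified instance, class weight).

    `pre`/`post` may be cell names (one instance) or bare class names (all
    instances of the class connection, which share one weight under the
    symmetry constraint).
    """
    hits = _matching_connections(instance, pre, post, electrical)
    out = instance.copy()
    if electrical:
        keep = [gj for gj in out.gap_junctions if gj not in hits]
        out.gap_junctions = keep
    else:
        out.chemical_synapses = [s for s in out.chemical_synapses
                                 if s not in hits]
    return out, hits[0][2]


def _gap_current_range(
    instance: CircuitInstance,
    a: str,
    b: str,
    g: float,
    config: SimulationConfig,
) -> tuple[float, float]:
    """Empirical range of the gap current g*(y_b - y_a) into cell `a` during
    the unablated assay (both directions), extended +-50%."""
    lo, hi = np.inf, -np.inf
    for direction in ("forward", "backward"):
        trace = direction_trace(instance, direction, config)
        diff = g * (trace.y[:, instance.index(b)] - trace.y[:, instance.index(a)])
        lo = min(lo, float(diff.min()))
        hi = max(hi, float(diff.max()))
    span = hi - lo
    pad = 0.5 * span if span > 0 else max(abs(lo), 1e-3)
    return lo - pad, hi + pad


@dataclass
class SubstitutionResult:
    pre: str
    post: str
    electrical: bool
    values: np.ndarray
    forward_fitness: np.ndarray
    backward_fitness: np.ndarray

    @property
    def best_forward(self) -> tuple[float, float]:
        i = int(np.argmax(self.forward_fitness))
        return float(self.forward_fitness[i]), float(self.values[i])

    @property
    def best_backward(self) -> tuple[float, float]:
        i = int(np.argmax(self.backward_fitness))
        return float(self.backward_fitness[i]), float(self.values[i])


def substitute_connection_tonic(
    instance: CircuitInstance,
    pre: str,
    post: str,
    electrical: bool = False,
    n_values: int = 1000,
    config: SimulationConfig | None = None,
    constants: FitnessConstants = FitnessConstants(),
) -> SubstitutionResult:
    """Sweep constant replacements for a connection's synaptic term.

    `pre`/`post` may be cell names (one synapse instance) or bare class
    names, in which case every instance of the class connection is replaced
    by the same shared constant — the class-level view of the published
    ablation columns.

    Chemical: the term w*sigma(y_pre+theta_pre) into `post` is replaced by a
    constant over its attainable range [min(0, w), max(0, w)].  Electrical:
    the gap current into `pre`'s side is replaced by +c and the reciprocal
    current into the partner by -c, with c swept over the empirical range of
    the unablated current +-50%.  Best fitness is taken independently for
    the forward and backward segments.
    """
    config = config or SimulationConfig()
    hits = _matching_connections(instance, pre, post, electrical)
    stripped, weight = remove_connection(instance, pre, post, electrical)
    if electrical:
        lo, hi = np.inf, -np.inf
        for a, b, g in hits:
            l, h = _gap_current_range(instance, a, b, g, config)
            lo, hi = min(lo, l), max(hi, h)
    else:
        lo, hi = min(0.0, weight), max(0.0, weight)
    values = np.linspace(lo, hi, n_values)

    fwd = np.empty(n_values)
    bwd = np.empty(n_values)
    base_tonic = stripped.tonic.copy()
    for k, c in enumerate(values):
        stripped.tonic = base_tonic.copy()
        if electrical:
            for a, b, _ in hits:
                stripped.tonic[stripped.index(a)] += c
                stripped.tonic[stripped.index(b)] -= c
        else:
            for _, q, _ in hits:
                stripped.tonic[stripped.index(q)] += c
        try:
            fwd[k] = evaluate_direction(stripped, "forward", config, constants).total
            bwd[k] = evaluate_direction(stripped, "backward", config, constants).total
        except IntegrationError:
            fwd[k] = 0.0
            bwd[k] = 0.0
    stripped.tonic = base_tonic
    return SubstitutionResult(pre=pre, post=post, electrical=electrical,
                              values=values, forward_fitness=fwd,
                              backward_fitness=bwd)


# ---------------------------------------------------------------------------
# Core-oscillator subset search
# ---------------------------------------------------------------------------

def _severed_input_ranges(
    instance: CircuitInstance,
    survivors: set[str],
) -> dict[str, tuple[float, float]]:
    """Attainable range of the summed lost chemical input per surviving cell."""
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    for p, q, w in instance.chemical_synapses:
        if q in survivors and p not in survivors:
            lo[q] = lo.get(q, 0.0) + min(0.0, w)
            hi[q] = hi.get(q, 0.0) + max(0.0, w)
    return {c: (lo[c], hi[c]) for c in lo}


def _subset_oscillation_score(
    sub: CircuitInstance,
    config: SimulationConfig,
    thresholds: CriteriaThresholds,
) -> tuple[bool, float]:
    """(sustains oscillation in both drive conditions, min-over-direction
    best sustained amplitude)."""
    worst = np.inf
    ok = True
    for direction in ("forward", "backward"):
        try:
            trace = direction_trace(sub, direction, config)
        except IntegrationError:
            return False, 0.0
        best_amp = 0.0
        any_osc = False
        for c in sub.cells:
            flag, amp = detect_oscillation(trace.output(c), thresholds)
            if flag:
                any_osc = True
                best_amp = max(best_amp, amp)
        ok = ok and any_osc
        worst = min(worst, best_amp)
    return ok, (0.0 if not np.isfinite(worst) else worst)


def _compensate_greedy(
    instance: CircuitInstance,
    sub: CircuitInstance,
    config: SimulationConfig,
    thresholds: CriteriaThresholds,
    sweep_n: int,
) -> CircuitInstance:
    """Greedy per-cell tonic compensation for severed inputs.

    Cells are visited in canonical order; for each, the summed lost chemical
    drive is replaced by the constant (from `sweep_n` candidates over its
    attainable range) that maximises the subset's sustained oscillation
    amplitude so far.
    """
    ranges = _severed_input_ranges(instance, set(sub.cells))
    current = sub
    for cell in sub.cells:
        if cell not in ranges:
            continue
        lo, hi = ranges[cell]
        if hi - lo < 1e-12:
            continue
        best_score = -1.0
        best = current
        for c in np.linspace(lo, hi, sweep_n):
            trial = current.copy()
            trial.tonic[trial.index(cell)] += c
            ok, amp = _subset_oscillation_score(trial, config, thresholds)
            score = amp + (1.0 if ok else 0.0)
            if score > best_score:
                best_score = score
                best = trial
        current = best
    return current


def find_core_oscillators(
    instance: CircuitInstance,
    config: SimulationConfig | None = None,
    thresholds: CriteriaThresholds | None = None,
    sweep_n: int = 21,
) -> list[tuple[str, ...]]:
    """Inclusion-minimal neuron-class subsets that still oscillate.

    Every nonempty class subset is ablated down to, severed inputs are
    compensated greedily with swept tonic currents, and the subset passes if
    at least one surviving cell sustains an oscillation under both the
    forward and backward drive conditions.  Returns minimal passing subsets
    (largest first within equal size not guaranteed; sorted by size, name).
    """
    config = config or SimulationConfig()
    thresholds = thresholds or CriteriaThresholds()

    present = tuple(c for c in CLASS_NAMES
                    if any(cell[:2] == c for cell in instance.cells))
    full_ok, _ = _subset_oscillation_score(instance, config, thresholds)
    if not full_ok:
        return []

    passing: list[tuple[str, ...]] = []
    for mask in range(1, 2 ** len(present)):
        subset = tuple(c for i, c in enumerate(present) if mask >> i & 1)
        if len(subset) == len(present):
            passing.append(subset)
            continue
        to_remove = [c for c in present if c not in subset]
        sub = ablate_cells(instance, to_remove)
        sub = _compensate_greedy(instance, sub, config, thresholds, sweep_n)
        ok, _ = _subset_oscillation_score(sub, config, thresholds)
        if ok:
            passing.append(subset)

    passing_sets = [set(s) for s in passing]
    minimal = [
        s for s, ss in zip(passing, passing_sets)
        if not any(other < ss for other in passing_sets)
    ]
    return sorted(minimal, key=lambda s: (len(s), s))


# ---------------------------------------------------------------------------
# Dependency profiling
# ---------------------------------------------------------------------------

@dataclass
class ConnectionProfile:
    pre: str
    post: str
    electrical: bool
    best_forward_fitness: float
    best_forward_value: float
    best_backward_fitness: float
    best_backward_value: float
    normalized_best: float  # best fwd*bwd product over unablated total
    classification: str     # 'inert' | 'tonic-replaceable' | 'phasic-required'


@dataclass
class AblationReport:
    unablated_forward: float
    unablated_backward: float
    profiles: list[ConnectionProfile]

    @property
    def unablated_total(self) -> float:
        return self.unablated_forward * self.unablated_backward

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{
            "pre": p.pre, "post": p.post,
            "kind": "electrical" if p.electrical else "chemical",
            "best_forward_fitness": p.best_forward_fitness,
            "best_forward_value": p.best_forward_value,
            "best_backward_fitness": p.best_backward_fitness,
            "best_backward_value": p.best_backward_value,
            "normalized_best": p.normalized_best,
            "classification": p.classification,
        } for p in self.profiles])


def dependency_profile(
    instance: CircuitInstance,
    config: SimulationConfig | None = None,
    constants: FitnessConstants = FitnessConstants(),
    n_chemical: int = 1000,
    n_electrical: int = 2000,
    fitness_floor: float = 0.2,
    inert_tolerance: float = 0.01,
) -> AblationReport:
    """Tonic-substitution profile of every connection instance.

    Each connection is classified by the best normalised fitness its sweep
    achieves: within `inert_tolerance` of the unablated value -> inert; at
    least `fitness_floor` (20% of the unablated fitness, the study's dashed
    line) -> tonic-replaceable; below -> phasic-required.
    """
    config = config or SimulationConfig()
    fwd0 = evaluate_direction(instance, "forward", config, constants).total
    bwd0 = evaluate_direction(instance, "backward", config, constants).total
    total0 = fwd0 * bwd0
    if total0 <= 0:
        raise ValueError("dependency profile requires a fit, oscillating instance")

    profiles: list[ConnectionProfile] = []
    targets = [(p, q, False) for p, q, _ in instance.chemical_synapses]
    targets += [(a, b, True) for a, b, _ in instance.gap_junctions]
    for pre, post, electrical in targets:
        res = substitute_connection_tonic(
            instance, pre, post, electrical=electrical,
            n_values=n_electrical if electrical else n_chemical,
            config=config, constants=constants)
        bf, vf = res.best_forward
        bb, vb = res.best_backward
        norm = (bf * bb) / total0
        if norm >= 1.0 - inert_tolerance:
            cls = "inert"
        elif norm >= fitness_floor:
            cls = "tonic-replaceable"
        else:
            cls = "phasic-required"
        profiles.append(ConnectionProfile(
            pre=pre, post=post, electrical=electrical,
            best_forward_fitness=bf, best_forward_value=vf,
            best_backward_fitness=bb, best_backward_value=vb,
            normalized_best=norm, classification=cls))
    return AblationReport(unablated_forward=fwd0, unablated_backward=bwd0,
                          profiles=profiles)
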