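"""Three-criterion locomotion fitness and the forward/backward assay.

A candidate circuit is scored in a two-segment assay.  Starting from reset,
the forward condition (AVB drive on) runs for a transient (6 time units)
followed by an evaluation window of T = 20 units; the state is then reset
and the backward condition (AVA drive on) is assayed identically.  Each
direction is scored by three multiplicative components:

* F1 (oscillation): per dominant neuron, S = 2/(A*T) * integral |dO/dt| dt,
  capped at 1; F1 is the product over the dominant set.  A = 0.3 is the
  target peak-to-peak amplitude (about a third of the output range), so a
  sustained oscillation of amplitude A scores exactly 1.
* F2 (antiphase): per dorsoventral pair, 1 - 1/(2T) * integral
  |sgn(dO_V) + sgn(dO_D)| dt — 1 for exact antiphase, 0 for in-phase.
* F3 (dominance): bump-shaped factors rewarding a dominant-class minimum
  near 1-A, a nondominant maximum near A, and dominant amplitudes near A.

Per-direction fitness is F1*F2*F3 and the assay total is the product of the
two directional values.  The integrands are written here with absolute
values: over a near-periodic window the signed integrals telescope to ~0,
which contradicts the intended semantics (total variation; antiphase
maximal), so |.| is the default and the signed variant is available via
``signed=True`` for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circuit import CircuitInstance
from .dynamics import BACKWARD, FORWARD, SimulationConfig, Trace, simulate

__all__ = [
    "DominanceSets",
    "FORWARD_SETS",
    "BACKWARD_SETS",
    "FitnessConstants",
    "DirectionFitness",
    "FitnessBreakdown",
    "bump_norm",
    "oscillation_score",
    "phase_score",
    "dominance_score",
    "evaluate_direction",
    "evaluate_assay",
    "stability_refilter",
    "RefilterResult",
]


@dataclass(frozen=True)
class DominanceSets:
    """Dominant / nondominant cells and dorsoventral pairs for one direction."""

    dominant: tuple[str, ...]
    nondominant: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...]  # (ventral, dorsal)


FORWARD_SETS = DominanceSets(
    dominant=("DB", "VBa", "VBp"),
    nondominant=("DAa", "DAp", "VAa", "VAp"),
    pairs=(("VBa", "DB"), ("VBp", "DB")),
)
BACKWARD_SETS = DominanceSets(
    dominant=("DAa", "DAp", "VAa", "VAp"),
    nondominant=("DB", "VBa", "VBp"),
    pairs=(("VAa", "DAa"), ("VAp", "DAp")),
)

DIRECTION_SETS = {"forward": FORWARD_SETS, "backward": BACKWARD_SETS}
DIRECTION_PROTOCOLS = {"forward": FORWARD, "backward": BACKWARD}


@dataclass(frozen=True)
class FitnessConstants:
    """A: optimal oscillation amplitude; T: evaluation-window length."""

    A: float = 0.3
    T: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.A < 1:
            raise ValueError("A must lie in (0, 1)")
        if self.T <= 0:
            raise ValueError("T must be positive")


def bump_norm(x: float, x0: float) -> float:
    """Smooth normalisation f(x, x0) = 0.1 + 0.9 (x/x0) e^(1 - x/x0).

    Nonzero everywhere, maximal (= 1) at x = x0, and 0.1 at x = 0.
    """
    if x0 <= 0:
        raise ValueError("reference point x0 must be positive")
    if x < 0:
        raise ValueError("argument x must be nonnegative")
    u = x / x0
    return 0.1 + 0.9 * u * math.exp(1.0 - u)


def _window_outputs(trace: Trace, cells: tuple[str, ...]) -> np.ndarray:
    if trace.time.size < 2:
        raise ValueError("evaluation window is empty")
    O = trace.outputs
    idx = [trace.cells.index(c) for c in cells]
    return O[:, idx]


def oscillation_score(
    trace: Trace,
    dominant: tuple[str, ...],
    constants: FitnessConstants = FitnessConstants(),
    signed: bool = False,
) -> tuple[float, dict[str, float]]:
    """F1 and per-neuron S over the dominant set (trace = post-transient window)."""
    O = _window_outputs(trace, dominant)
    dO = np.diff(O, axis=0)
    if not signed:
        dO = np.abs(dO)
    S = 2.0 / (constants.A * constants.T) * dO.sum(axis=0)
    S = np.minimum(S, 1.0)
    per_neuron = {c: float(s) for c, s in zip(dominant, S)}
    return float(np.prod(S)), per_neuron


def phase_score(
    trace: Trace,
    pairs: tuple[tuple[str, str], ...],
    constants: FitnessConstants = FitnessConstants(),
    signed: bool = False,
) -> tuple[float, dict[str, float]]:
    """F2: product over dorsoventral pairs of the antiphase factor.

    Per pair: 1 - 1/(2T) * integral |sgn(dO_V) + sgn(dO_D)| dt, with
    sgn(0) = 0 so flat segments exert half pressure.
    """
    dt = trace.dt
    factors: dict[str, float] = {}
    total = 1.0
    for ventral, dorsal in pairs:
        dv = np.sign(np.diff(trace.output(ventral)))
        dd = np.sign(np.diff(trace.output(dorsal)))
        integrand = dv + dd
        if not signed:
            integrand = np.abs(integrand)
        val = 1.0 - integrand.sum() * dt / (2.0 * constants.T)
        factors[f"{ventral}|{dorsal}"] = float(val)
        total *= val
    return float(total), factors


def dominance_score(
    trace: Trace,
    dominant: tuple[str, ...],
    nondominant: tuple[str, ...],
    constants: FitnessConstants = FitnessConstants(),
) -> tuple[float, dict[str, dict[str, float]]]:
    """F3 with the per-cell extrema it is built from.

    m_Y (dominant minima) are normalised against 1-A, M_X (nondominant
    maxima) against A, and A_Y (dominant peak-to-peak amplitudes) against A.
    """
    A = constants.A
    OY = _window_outputs(trace, dominant)
    OX = _window_outputs(trace, nondominant)
    m_Y = {c: float(v) for c, v in zip(dominant, OY.min(axis=0))}
    M_X = {c: float(v) for c, v in zip(nondominant, OX.max(axis=0))}
    A_Y = {c: float(v) for c, v in zip(dominant, OY.max(axis=0) - OY.min(axis=0))}
    f3 = 1.0
    for v in m_Y.values():
        f3 *= bump_norm(v, 1.0 - A)
    for v in M_X.values():
        f3 *= bump_norm(v, A)
    for v in A_Y.values():
        f3 *= bump_norm(v, A)
    return float(f3), {"m_Y": m_Y, "M_X": M_X, "A_Y": A_Y}


@dataclass
class DirectionFitness:
    """Per-direction components and their product."""

    f1: float
    f2: float
    f3: float
    s_y: dict[str, float]
    phase_factors: dict[str, float]
    extrema: dict[str, dict[str, float]]

    @property
    def total(self) -> float:
        return self.f1 * self.f2 * self.f3


@dataclass
class FitnessBreakdown:
    """Both directions plus the assay total (product across directions)."""

    forward: DirectionFitness
    backward: DirectionFitness

    @property
    def total(self) -> float:
        return self.forward.total * self.backward.total

    def to_dict(self) -> dict:
        out = {}
        for name in ("forward", "backward"):
            d: DirectionFitness = getattr(self, name)
            out[name] = {
                "F1": d.f1, "F2": d.f2, "F3": d.f3, "F": d.total,
                "S_Y": d.s_y, "phase_factors": d.phase_factors,
                "extrema": d.extrema,
            }
        out["total"] = self.total
        return out


def direction_trace(
    instance: CircuitInstance,
    direction: str,
    config: SimulationConfig | None = None,
    horizon: float | None = None,
) -> Trace:
    """Post-transient evaluation-window trace for one assay segment.

    The circuit starts from reset; with a long `horizon` only the final
    evaluation window is recorded (used by the stability re-filter).
    """
    config = config or SimulationConfig()
    protocol = DIRECTION_PROTOCOLS[direction]
    if horizon is None:
        horizon = config.transient + config.eval_window
    record_from = horizon - config.eval_window
    return simulate(instance, protocol, config, duration=horizon,
                    record_from=record_from)


def evaluate_direction(
    instance: CircuitInstance,
    direction: str,
    config: SimulationConfig | None = None,
    constants: FitnessConstants = FitnessConstants(),
    horizon: float | None = None,
    signed: bool = False,
) -> DirectionFitness:
    sets = DIRECTION_SETS[direction]
    trace = direction_trace(instance, direction, config, horizon)
    f1, s_y = oscillation_score(trace, sets.dominant, constants, signed)
    f2, pf = phase_score(trace, sets.pairs, constants, signed)
    f3, extrema = dominance_score(trace, sets.dominant, sets.nondominant, constants)
    return DirectionFitness(f1=f1, f2=f2, f3=f3, s_y=s_y,
                            phase_factors=pf, extrema=extrema)


def evaluate_assay(
    instance: CircuitInstance,
    config: SimulationConfig | None = None,
    constants: FitnessConstants = FitnessConstants(),
    signed: bool = False,
) -> FitnessBreakdown:
    """Full forward-then-backward assay (state reset between segments)."""
    return FitnessBreakdown(
        forward=evaluate_direction(instance, "forward", config, constants,
                                   signed=signed),
        backward=evaluate_direction(instance, "backward", config, constants,
                                    signed=signed),
    )


@dataclass
class RefilterResult:
    passed: bool
    long_breakdown: FitnessBreakdown
    report: object  # ensemble.CriteriaReport


def stability_refilter(
    instance: CircuitInstance,
    config: SimulationConfig | None = None,
    constants: FitnessConstants = FitnessConstants(),
    thresholds=None,
) -> RefilterResult:
    """Long-horizon re-evaluation that rejects damped oscillators.

    Each direction is simulated for the long horizon (3000 units) and the
    fitness components are recomputed on the final evaluation window; the
    solution passes iff the three-criterion classification still holds there.
    """
    from . import ensemble  # runtime import; ensemble builds on this module

    config = config or SimulationConfig()
    breakdown = FitnessBreakdown(
        forward=evaluate_direction(instance, "forward", config, constants,
                                   horizon=config.long_horizon),
        backward=evaluate_direction(instance, "backward", config, constants,
                                    horizon=config.long_horizon),
    )
    report = ensemble.classify_criteria(instance, config, thresholds,
                                        horizon="long")
    return RefilterResult(passed=report.overall, long_breakdown=breakdown,
                          report=report)
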