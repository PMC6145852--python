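"""Solution classification against the three locomotion criteria and
ensemble-level summaries (criterion fractions, dorsal-core sign patterns,
per-class bistability census).

The binary criteria mirror the fitness components but are thresholded:

* oscillation — every dominant-set neuron sustains a peak-to-peak output
  amplitude above a threshold over the final evaluation window, without
  damping (last-quarter amplitude at least half the first-quarter one);
* phase — each dorsoventral pair oscillates within a tolerance of half a
  period out of phase (lag 0.5 +- 0.125 of a period by default);
* dominance — the dominant class's mean output exceeds the nondominant
  class's in both directions.

The exact thresholds behind the published ensemble fractions are not
reported, so they are configuration, not constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .circuit import CircuitInstance
from .dynamics import NeuronParams, SimulationConfig, Trace, classify_bistability
from .fitness import DIRECTION_SETS, direction_trace

__all__ = [
    "CriteriaThresholds",
    "CriteriaReport",
    "SignPattern",
    "UndefinedLagError",
    "detect_oscillation",
    "measure_phase_lag",
    "dominance_difference",
    "classify_criteria",
    "classify_sign_pattern",
    "operating_input",
    "bistable_at_operating_point",
    "summarize_ensemble",
    "DORSAL_CORE_CONNECTIONS",
    "SIGN_PATTERN_LABELS",
]


class UndefinedLagError(ValueError):
    """Phase lag requested for a non-oscillating trace."""


@dataclass(frozen=True)
class CriteriaThresholds:
    min_amplitude: float = 0.05          # peak-to-peak output units
    damping_ratio: float = 0.5           # last-quarter vs first-quarter amplitude
    antiphase_tolerance: float = 0.125   # fraction of a period around 0.5


def detect_oscillation(
    output: np.ndarray, thresholds: CriteriaThresholds = CriteriaThresholds()
) -> tuple[bool, float]:
    """Sustained-oscillation test on one cell's output over the final window.

    Returns (flag, peak-to-peak amplitude).  Damped transients are rejected
    by comparing the amplitude of the last quarter-window with the first.
    """
    output = np.asarray(output, dtype=float)
    amplitude = float(output.max() - output.min())
    if amplitude < thresholds.min_amplitude:
        return False, amplitude
    q = len(output) // 4
    first = output[:q].max() - output[:q].min()
    last = output[-q:].max() - output[-q:].min()
    sustained = last >= thresholds.damping_ratio * first
    return bool(sustained), amplitude


def _dominant_period_steps(x: np.ndarray) -> float:
    """Period (in samples) of the strongest nonzero Fourier component."""
    x = x - x.mean()
    spectrum = np.abs(np.fft.rfft(x))
    if len(spectrum) < 2:
        raise UndefinedLagError("trace too short for a period estimate")
    k = int(np.argmax(spectrum[1:])) + 1
    return len(x) / k


def measure_phase_lag(trace_v: np.ndarray, trace_d: np.ndarray) -> float:
    """Lag of the ventral trace behind the dorsal one, as a fraction of the
    period in [0, 1), from the argmax of the circular cross-correlation.

    The period is the dominant Fourier component of the dorsal trace; both
    traces are cropped to an integer number of periods so the circular
    correlation is well posed.
    """
    v = np.asarray(trace_v, dtype=float)
    d = np.asarray(trace_d, dtype=float)
    if v.shape != d.shape:
        raise ValueError("traces must share a time grid")
    if (v.max() - v.min()) < 1e-9 or (d.max() - d.min()) < 1e-9:
        raise UndefinedLagError("constant trace has no phase")
    period = _dominant_period_steps(d)
    n_periods = int(len(d) / period)
    if n_periods < 1:
        raise UndefinedLagError("window shorter than one oscillation period")
    n = int(round(n_periods * period))
    v = v[:n] - v[:n].mean()
    d = d[:n] - d[:n].mean()
    # circular cross-correlation c[s] = sum_t v[(t+s) mod n] d[t]
    c = np.fft.irfft(np.fft.rfft(v) * np.conj(np.fft.rfft(d)), n)
    p = n / n_periods  # effective period after cropping, in samples
    span = int(round(p))
    shift = int(np.argmax(c[:span]))
    return float((shift / p) % 1.0)


def dominance_difference(trace: Trace, direction: str) -> float:
    """Mean dominant-set output minus mean nondominant-set output."""
    sets = DIRECTION_SETS[direction]
    O = trace.outputs
    dom = np.mean([O[:, trace.cells.index(c)].mean() for c in sets.dominant])
    non = np.mean([O[:, trace.cells.index(c)].mean() for c in sets.nondominant])
    return float(dom - non)


@dataclass
class DirectionCriteria:
    oscillation_flags: dict[str, bool]
    amplitudes: dict[str, float]
    phase_lags: dict[str, float | None]
    dominance_diff: float

    @property
    def oscillation(self) -> bool:
        return all(self.oscillation_flags.values())


@dataclass
class CriteriaReport:
    forward: DirectionCriteria
    backward: DirectionCriteria
    oscillation: bool
    phase: bool
    dominance: bool
    filtered: bool  # True when classified on the long horizon

    @property
    def overall(self) -> bool:
        return self.oscillation and self.phase and self.dominance

    def to_dict(self) -> dict:
        return {
            "oscillation": self.oscillation,
            "phase": self.phase,
            "dominance": self.dominance,
            "overall": self.overall,
            "filtered": self.filtered,
            "forward": {
                "oscillation_flags": self.forward.oscillation_flags,
                "amplitudes": self.forward.amplitudes,
                "phase_lags": self.forward.phase_lags,
                "dominance_difference": self.forward.dominance_diff,
            },
            "backward": {
                "oscillation_flags": self.backward.oscillation_flags,
                "amplitudes": self.backward.amplitudes,
                "phase_lags": self.backward.phase_lags,
                "dominance_difference": self.backward.dominance_diff,
            },
        }


def _classify_direction(
    trace: Trace, direction: str, thresholds: CriteriaThresholds
) -> DirectionCriteria:
    sets = DIRECTION_SETS[direction]
    flags, amps, lags = {}, {}, {}
    for c in sets.dominant:
        flag, amp = detect_oscillation(trace.output(c), thresholds)
        flags[c] = flag
        amps[c] = amp
    for ventral, dorsal in sets.pairs:
        key = f"{ventral}|{dorsal}"
        try:
            lags[key] = measure_phase_lag(trace.output(ventral),
                                          trace.output(dorsal))
        except UndefinedLagError:
            lags[key] = None
    return DirectionCriteria(
        oscillation_flags=flags,
        amplitudes=amps,
        phase_lags=lags,
        dominance_diff=dominance_difference(trace, direction),
    )


def classify_criteria(
    instance: CircuitInstance,
    config: SimulationConfig | None = None,
    thresholds: CriteriaThresholds | None = None,
    horizon: str = "long",
) -> CriteriaReport:
    """Three-criterion classification from fresh simulations.

    horizon='long' evaluates the final window of the 3000-unit run (the
    post-search filtered view); horizon='short' uses the standard assay and
    marks the report unfiltered.
    """
    config = config or SimulationConfig()
    thresholds = thresholds or CriteriaThresholds()
    if horizon not in ("long", "short"):
        raise ValueError("horizon must be 'long' or 'short'")
    h = config.long_horizon if horizon == "long" else None

    per_dir = {}
    for direction in ("forward", "backward"):
        trace = direction_trace(instance, direction, config, horizon=h)
        per_dir[direction] = _classify_direction(trace, direction, thresholds)

    tol = thresholds.antiphase_tolerance

    def _phase_ok(dc: DirectionCriteria) -> bool:
        return all(
            lag is not None and abs(lag - 0.5) <= tol
            for lag in dc.phase_lags.values()
        )

    return CriteriaReport(
        forward=per_dir["forward"],
        backward=per_dir["backward"],
        oscillation=per_dir["forward"].oscillation and per_dir["backward"].oscillation,
        phase=_phase_ok(per_dir["forward"]) and _phase_ok(per_dir["backward"]),
        dominance=(per_dir["forward"].dominance_diff > 0
                   and per_dir["backward"].dominance_diff > 0),
        filtered=(horizon == "long"),
    )


# ---------------------------------------------------------------------------
# Dorsal-core sign patterns
# ---------------------------------------------------------------------------

# ordered dorsal-core connections whose signs define the pattern
DORSAL_CORE_CONNECTIONS: tuple[tuple[str, str], ...] = (
    ("AS", "DA"), ("DA", "DB"), ("DB", "AS"),
)

# Patterns I-III carry exactly one inhibitory synapse (placement varies),
# pattern IV is all-inhibitory.  II = (+,+,-) is anchored by the best-circuit
# narrative (DB inhibits AS); the I/III assignment follows the placement of
# the single inhibitory synapse (I: AS->DA, III: DA->DB).
SIGN_PATTERN_LABELS: dict[tuple[int, int, int], str] = {
    (-1, 1, 1): "I",
    (1, 1, -1): "II",
    (1, -1, 1): "III",
    (-1, -1, -1): "IV",
}


@dataclass(frozen=True)
class SignPattern:
    signs: tuple[int, int, int]
    label: str


def classify_sign_pattern(instance: CircuitInstance) -> SignPattern:
    """Sign triple of (AS->DA, DA->DB, DB->AS) and its pattern label.

    Any zero weight, or a sign combination outside the four named patterns,
    maps to 'other'.  Class-level signs are read from the anterior instance
    (anterior-posterior symmetry makes the choice immaterial for decoded
    genotypes).
    """
    signs = []
    for pre_cls, post_cls in DORSAL_CORE_CONNECTIONS:
        w = None
        for pre, post, weight in instance.chemical_synapses:
            if pre.startswith(pre_cls) and post.startswith(post_cls):
                w = weight
                break
        if w is None:
            raise KeyError(f"dorsal-core connection {pre_cls}->{post_cls} "
                           f"absent from instance")
        signs.append(int(np.sign(w)))
    triple = tuple(signs)
    return SignPattern(signs=triple, label=SIGN_PATTERN_LABELS.get(triple, "other"))


# ---------------------------------------------------------------------------
# Bistability at the operating point
# ---------------------------------------------------------------------------

def operating_input(instance: CircuitInstance, trace: Trace,
                    cell: str, external: float) -> float:
    """Time-averaged total non-self input into `cell` over the trace window.

    A cell embedded in the circuit never sees zero input: its operating
    point is set by the mean synaptic drive, gap-junction currents and
    command input.  Bistability censuses evaluate the isolated-neuron
    reduction at this input — a cell like AS, inhibited by DB across the
    oscillation cycle, is bistable exactly where it operates even when its
    zero-input dynamics are monostable.
    """
    i = instance.index(cell)
    W = instance.weight_matrix()
    G = instance.gap_matrix()
    O = trace.outputs
    syn = sum(W[i, j] * O[:, j].mean()
              for j in range(instance.n_cells) if j != i)
    gap = sum(G[i, j] * (trace.y[:, j] - trace.y[:, i]).mean()
              for j in range(instance.n_cells))
    return float(syn + gap + external)


def bistable_at_operating_point(
    instance: CircuitInstance,
    cell: str,
    config: SimulationConfig | None = None,
) -> bool:
    """True iff the cell's isolated reduction is bistable at the mean input
    it receives during either assay direction."""
    config = config or SimulationConfig()
    i = instance.index(cell)
    params = NeuronParams(theta=float(instance.theta[i]), tau=1.0,
                          w_self=float(instance.self_weight[i]))
    avb, ava = instance.external_drive()
    for direction, ext in (("forward", avb[i]), ("backward", ava[i])):
        trace = direction_trace(instance, direction, config)
        if classify_bistability(params, operating_input(instance, trace,
                                                        cell, float(ext))):
            return True
    return False


# ---------------------------------------------------------------------------
# Ensemble summaries
# ---------------------------------------------------------------------------

def _bootstrap_fraction(flags: np.ndarray, rng: np.random.Generator,
                        n_boot: int = 1000) -> tuple[float, float, float]:
    n = len(flags)
    frac = float(flags.mean())
    if n == 1:
        return frac, frac, frac
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = flags[idx].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return frac, float(lo), float(hi)


def summarize_ensemble(
    items: Sequence[tuple[CircuitInstance, CriteriaReport]],
    seed: int = 0,
    n_boot: int = 1000,
) -> dict:
    """Criterion fractions (with bootstrap CIs), sign-pattern census, and
    per-class bistability rates over a set of classified solutions."""
    if len(items) == 0:
        raise ValueError("empty ensemble")
    rng = np.random.default_rng(seed)
    reports = [r for _, r in items]
    instances = [i for i, _ in items]
    n = len(items)

    fractions = {}
    for name in ("oscillation", "phase", "dominance", "overall"):
        flags = np.array([float(getattr(r, name)) for r in reports])
        frac, lo, hi = _bootstrap_fraction(flags, rng, n_boot)
        fractions[name] = {"fraction": frac, "ci95": [lo, hi], "n": n}

    census: dict[str, int] = {}
    for inst in instances:
        label = classify_sign_pattern(inst).label
        census[label] = census.get(label, 0) + 1

    classes = sorted({c[:2] for inst in instances for c in inst.cells})
    bistab: dict[str, float] = {}
    for cls in classes:
        flags = []
        for inst in instances:
            rep = next(c for c in inst.cells if c.startswith(cls))
            flags.append(bistable_at_operating_point(inst, rep))
        bistab[cls] = float(np.mean(flags))

    return {
        "n": n,
        "criterion_fractions": fractions,
        "sign_pattern_census": census,
        "bistability_rates": bistab,
    }
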