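"""Synthetic inputs: command-interneuron traces, random genotypes, fixtures.

Everything the pipeline consumes is generated here, with no external data.
The command-trace generator emulates the qualitative statistics of
calcium-imaging recordings of the AVA/AVB command interneurons in freely
moving worms: normalised amplitudes in [0, 1] and alternating multi-cycle
dominance bouts (AVB high while AVA is low during forward bouts, and the
reverse during backward bouts) with smooth crossfades.  It reproduces those
statistics, not any particular recorded waveform; the downstream claim being
exercised is dominance *tracking*, not waveform fidelity.

Bout-duration statistics of the original recordings are not published;
the defaults below are order-of-magnitude choices (bouts lasting several
oscillation cycles of a typical evolved circuit) exposed in
`CommandTraceParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import (
    GENOTYPE_LENGTH,
    CircuitInstance,
    expand_genotype,
)

__all__ = [
    "CommandTraceParams",
    "generate_command_traces",
    "sample_genotype",
    "make_reference_oscillator",
    "make_damped_oscillator",
    "make_constant_instance",
    "REFERENCE_GENOTYPE",
    "DAMPED_GENOTYPE",
]


@dataclass(frozen=True)
class CommandTraceParams:
    """Knobs of the synthetic AVA/AVB trace generator (dimensionless time)."""

    duration: float = 300.0
    dt: float = 0.0025
    mean_bout: float = 40.0    # mean bout length per dominance state
    min_bout: float = 10.0     # hard floor on bout length
    crossfade_tau: float = 1.5 # first-order smoothing time constant
    high_level: float = 0.9    # mean plateau of the dominant command
    low_level: float = 0.05    # mean level of the suppressed command
    noise_level: float = 0.02  # std of the smoothed additive noise

    def __post_init__(self) -> None:
        if self.min_bout <= 0 or self.mean_bout < self.min_bout:
            raise ValueError("need 0 < min_bout <= mean_bout")
        if not 0 <= self.low_level < self.high_level <= 1:
            raise ValueError("need 0 <= low_level < high_level <= 1")
        if self.noise_level < 0:
            raise ValueError("noise_level must be nonnegative")


def generate_command_traces(
    params: CommandTraceParams | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(time, u_AVB, u_AVA) with alternating anti-correlated dominance bouts.

    Bout lengths are min_bout plus an exponential excess; the square
    dominance schedule is low-pass filtered (crossfade) and carries smoothed
    additive noise, then is clipped to [0, 1].  Seeded and reproducible.
    """
    params = params or CommandTraceParams()
    rng = np.random.default_rng(seed)
    n = int(round(params.duration / params.dt))
    time = np.arange(n) * params.dt

    # alternating dominance schedule; first bout direction is random
    forward_first = bool(rng.integers(0, 2))
    edges = [0.0]
    while edges[-1] < params.duration:
        excess = rng.exponential(params.mean_bout - params.min_bout)
        edges.append(edges[-1] + params.min_bout + excess)
    schedule = np.zeros(n, dtype=bool)  # True = forward (AVB-dominant)
    state = forward_first
    for a, b in zip(edges, edges[1:]):
        i, j = int(a / params.dt), min(int(b / params.dt), n)
        schedule[i:j] = state
        state = not state
    square_b = np.where(schedule, params.high_level, params.low_level)
    square_a = np.where(schedule, params.low_level, params.high_level)

    alpha = params.dt / params.crossfade_tau

    def smooth(x: np.ndarray) -> np.ndarray:
        # first-order low-pass y[i] = a*x[i] + (1-a)*y[i-1], started at x[0]
        from scipy.signal import lfilter

        y, _ = lfilter([alpha], [1.0, alpha - 1.0], x,
                       zi=[(1.0 - alpha) * x[0]])
        return y

    u_b = smooth(square_b)
    u_a = smooth(square_a)
    if params.noise_level > 0:
        def coloured_noise() -> np.ndarray:
            raw = smooth(rng.normal(0.0, 1.0, n))
            std = raw.std()
            return raw * (params.noise_level / std) if std > 0 else raw
        u_b = u_b + coloured_noise()
        u_a = u_a + coloured_noise()
    return time, np.clip(u_b, 0.0, 1.0), np.clip(u_a, 0.0, 1.0)


def sample_genotype(seed_or_rng=0) -> np.ndarray:
    """Uniform random genotype on [-1, 1]^34, seeded."""
    rng = (seed_or_rng if isinstance(seed_or_rng, np.random.Generator)
           else np.random.default_rng(seed_or_rng))
    return rng.uniform(-1.0, 1.0, GENOTYPE_LENGTH)


# ---------------------------------------------------------------------------
# Frozen fixtures.  REFERENCE_GENOTYPE was obtained once from a seeded
# evolutionary search, selected for the canonical solution motif (dorsal-core
# sign pattern II with bistable intrinsically active AS and VD, AS->VD
# inhibitory), then frozen here.  Regenerate only deliberately via
# scripts in the repository, never implicitly.
# ---------------------------------------------------------------------------

# Product of a seeded evolutionary search constrained to the canonical
# solution motif (dorsal-core signs +,+,- with AS->VD inhibitory; AS and VD
# pinned to self-weight 6 with bias 0; remaining self-weights capped below
# the bistability threshold), then frozen.  Layout: per class (bias, tau,
# self-weight) for AS, DA, DB, VA, VB, VD; ten chemical weights in fixture
# order; four gap conductances; (w_AVB, w_AVA).
REFERENCE_GENOTYPE: np.ndarray = np.array([
    0, -0.9479784827029807, 0.3, -0.1232831302638582,
    0.828150788635436, -0.7058428004418866, -0.8471021297646568, 0.4406219688239936,
    -0.6333749057943039, 0.06888495307081022, -0.1912818492264972, -0.8343430064639967,
    -0.1884974371276074, 0.5046703480629104, -0.9796973901082255, 0,
    -0.9769018879464308, 0.3, 0.5259107821996736, -0.854155893274102,
    0.5448004327938625, -0.01583652218206311, -0.6048885358763005, -0.3733494439664771,
    0.03610032059178092, 0.4567572385425314, 0.9545104637316926, -0.04934051838933184,
    -0.8945787613876512, -0.7146736991115756, -0.8639594302619313, 0.8942409560012783,
    0.7931976826124889, 0.5468505409649622,
])

# Constructed analytically: a three-stage negative-feedback ring through the
# dorsal core (AS->DA->DB->AS, weights +-7, biases placing the fixed point at
# half activation, taus 0.5).  The per-stage gain 7/4 keeps the loop below
# its oscillatory instability at gain 2, so the reset transient rings
# visibly through the short assay window and decays to the focus long before
# the 3000-unit re-filter horizon.  Everything outside the ring is silent.
DAMPED_GENOTYPE: np.ndarray = np.array([
    0.175, -0.5384615385, 0.0,    # AS: theta=3.5, tau=0.5, w_self=0
    -0.175, -0.5384615385, 0.0,   # DA: theta=-3.5
    -0.175, -0.5384615385, 0.0,   # DB: theta=-3.5
    0.0, -0.5384615385, 0.0,      # VA
    0.0, -0.5384615385, 0.0,      # VB
    0.0, -0.5384615385, 0.0,      # VD
    0.35, 0.0, 0.35, 0.0, -0.35, 0.0, 0.0, 0.0, 0.0, 0.0,  # ring +-7
    -1.0, -1.0, -1.0, -1.0,       # no gap junctions
    0.0, 0.0,                     # no command drive
])


def make_reference_oscillator() -> CircuitInstance:
    """Criteria-passing reference circuit (dorsal-core pattern II).

    Behaviour flags verified by the test suite: passes all three criteria in
    both directions after the long-horizon re-filter; AS (self-weight 6) is
    bistable at its operating input while DA and DB (self-weights below 4)
    never are; AS->DA and DA->DB are excitatory, DB->AS inhibitory; the
    inhibitory AS->VD synapse routes the dorsal rhythm to the ventral side,
    from where VD->VB and the VD routes to VA propagate it; {AS, DA, DB} is
    the minimal oscillating class subset.
    """
    return expand_genotype(REFERENCE_GENOTYPE)


def make_damped_oscillator() -> CircuitInstance:
    """Fixture whose oscillation decays (stable focus): rings visibly
    through the short assay window but fails the long-horizon re-filter."""
    return expand_genotype(DAMPED_GENOTYPE)


def make_constant_instance() -> CircuitInstance:
    """All-midpoint instance (zero chemical weights, zero drive): outputs
    constant at sigma(theta), fitness identically zero."""
    return expand_genotype(np.zeros(GENOTYPE_LENGTH))
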