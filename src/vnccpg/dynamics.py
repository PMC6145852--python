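"""Continuous-time network dynamics, single-neuron protocols, and bistability.

Each cell follows the continuous-time recurrent neural network equation

    tau_i dy_i/dt = -y_i + sum_j w_ji sigma(y_j + theta_j)
                    + sum_k g_ki (y_k - y_i) + I_i

with sigma(x) = 1/(1+exp(-x)) the synaptic output nonlinearity, w_ji signed
chemical weights (the diagonal holds self-connections), g_ki >= 0
nonrectifying gap-junction conductances, and I_i the external drive from the
command interneurons (plus any tonic currents injected by ablation
compensation).  Time and voltage are dimensionless.

Integration is forward Euler at a fixed step (default 0.0025), compiled with
numba.  An isolated neuron reduces to y' = (-y + w sigma(y+theta) + I)/tau,
whose fixed points satisfy y = w sigma(y+theta) + I; a self-connection w > 4
is necessary for two stable fixed points to coexist (saddle-node condition
w sigma' = 1 with max sigma' = 1/4), which is what makes plateau potentials
and intrinsically active bistable cells possible in this model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from numba import njit
from scipy.optimize import brentq

from .circuit import CircuitInstance

__all__ = [
    "SimulationConfig",
    "InputProtocol",
    "NeuronParams",
    "Trace",
    "IntegrationError",
    "sigmoid",
    "simulate",
    "run_clamp_protocol",
    "find_equilibria",
    "classify_bistability",
    "bistability_threshold",
    "ClampStimulus",
]

DIVERGENCE_LIMIT = 1e6


class IntegrationError(RuntimeError):
    """Raised when the state diverges (first offending step in the message)."""


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and assay-window settings (dimensionless time units)."""

    dt: float = 0.0025
    transient: float = 6.0
    eval_window: float = 20.0
    long_horizon: float = 3000.0
    initial_state: float = 0.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("transient", "eval_window", "long_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def steps(self, duration: float) -> int:
        return int(round(duration / self.dt))


@dataclass(frozen=True)
class InputProtocol:
    """Command-interneuron drive.

    forward: u_AVB = 1, u_AVA = 0; backward: the reverse; custom: per-step
    arrays in [0, 1].  The realised current is w_AVB*u_AVB into B-class cells
    plus w_AVA*u_AVA into A-class cells; AS and VD receive none.
    """

    mode: str = "forward"
    u_avb: np.ndarray | float | None = None
    u_ava: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("forward", "backward", "custom"):
            raise ValueError(f"unknown protocol mode {self.mode!r}")
        if self.mode == "custom" and (self.u_avb is None or self.u_ava is None):
            raise ValueError("custom protocol requires u_avb and u_ava")

    def drives(self, n_steps: int) -> tuple[np.ndarray | float, np.ndarray | float]:
        if self.mode == "forward":
            return 1.0, 0.0
        if self.mode == "backward":
            return 0.0, 1.0
        u_b = self.u_avb if np.isscalar(self.u_avb) else np.asarray(self.u_avb, float)
        u_a = self.u_ava if np.isscalar(self.u_ava) else np.asarray(self.u_ava, float)
        for u in (u_b, u_a):
            arr = np.atleast_1d(u)
            if arr.min() < 0 or arr.max() > 1:
                raise ValueError("drive values must lie in [0, 1]")
            if not np.isscalar(u) and len(arr) < n_steps:
                raise ValueError("custom drive shorter than the simulation")
        return u_b, u_a


FORWARD = InputProtocol("forward")
BACKWARD = InputProtocol("backward")


class NeuronParams(NamedTuple):
    """Physiology of one neuron class: bias, time constant, self-weight."""

    theta: float
    tau: float
    w_self: float


@dataclass
class Trace:
    """Time-indexed membrane states and sigmoidal outputs."""

    time: np.ndarray
    y: np.ndarray  # (T, n)
    cells: list[str]
    theta: np.ndarray
    inputs: np.ndarray | None = None  # (T,) stimulus, for clamp protocols
    _outputs: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def outputs(self) -> np.ndarray:
        if self._outputs is None:
            self._outputs = sigmoid(self.y + self.theta)
        return self._outputs

    def output(self, cell: str) -> np.ndarray:
        return self.outputs[:, self.cells.index(cell)]

    def window(self, t_from: float, t_to: float | None = None) -> "Trace":
        mask = self.time >= t_from - 1e-12
        if t_to is not None:
            mask &= self.time <= t_to + 1e-12
        return Trace(self.time[mask], self.y[mask], self.cells, self.theta,
                     None if self.inputs is None else self.inputs[mask])

    def to_frame(self):
        """Tidy (time, cell, y, output) DataFrame."""
        import pandas as pd

        O = self.outputs
        frames = []
        for j, c in enumerate(self.cells):
            frames.append(pd.DataFrame({
                "time": self.time, "cell": c, "y": self.y[:, j], "output": O[:, j],
            }))
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Euler kernels (numba).  `gsum` is the row sum of G so the gap-junction term
# is G @ y - gsum * y.  Kernels return -1 on success, else the first step at
# which the state left [-DIVERGENCE_LIMIT, DIVERGENCE_LIMIT].
# ---------------------------------------------------------------------------

@njit(cache=True)
def _step(y, tau, theta, W, G, gsum, I, dt, act, dy):
    n = y.shape[0]
    for i in range(n):
        act[i] = 1.0 / (1.0 + math.exp(-(y[i] + theta[i])))
    for i in range(n):
        s = -y[i] + I[i]
        for j in range(n):
            s += W[i, j] * act[j] + G[i, j] * y[j]
        s -= gsum[i] * y[i]
        dy[i] = dt * s / tau[i]
    for i in range(n):
        y[i] += dy[i]


@njit(cache=True)
def _run(y, tau, theta, W, G, gsum, I, dt, n_steps):
    n = y.shape[0]
    act = np.empty(n)
    dy = np.empty(n)
    for s in range(n_steps):
        _step(y, tau, theta, W, G, gsum, I, dt, act, dy)
        for i in range(n):
            if not (-1e6 <= y[i] <= 1e6):
                return s
    return -1


@njit(cache=True)
def _run_record(y, tau, theta, W, G, gsum, I, dt, n_steps, out):
    n = y.shape[0]
    act = np.empty(n)
    dy = np.empty(n)
    for i in range(n):
        out[0, i] = y[i]
    for s in range(n_steps):
        _step(y, tau, theta, W, G, gsum, I, dt, act, dy)
        for i in range(n):
            if not (-1e6 <= y[i] <= 1e6):
                return s
            out[s + 1, i] = y[i]
    return -1


@njit(cache=True)
def _run_record_drive(y, tau, theta, W, G, gsum, I_t, dt, n_steps, out):
    n = y.shape[0]
    act = np.empty(n)
    dy = np.empty(n)
    for i in range(n):
        out[0, i] = y[i]
    for s in range(n_steps):
        _step(y, tau, theta, W, G, gsum, I_t[s], dt, act, dy)
        for i in range(n):
            if not (-1e6 <= y[i] <= 1e6):
                return s
            out[s + 1, i] = y[i]
    return -1


def _matrices(instance: CircuitInstance):
    W = instance.weight_matrix()
    G = instance.gap_matrix()
    return W, G, G.sum(axis=1)


def simulate(
    instance: CircuitInstance,
    protocol: InputProtocol,
    config: SimulationConfig | None = None,
    duration: float | None = None,
    record_from: float = 0.0,
    y0: np.ndarray | None = None,
) -> Trace:
    """Forward-Euler trajectory of the full circuit under a drive protocol.

    `record_from` discards the trajectory before that time (the state is
    still integrated through it), which keeps long-horizon runs cheap.
    """
    config = config or SimulationConfig()
    if duration is None:
        duration = config.transient + config.eval_window
    n_steps = config.steps(duration)
    n_skip = config.steps(record_from)
    if n_skip > n_steps:
        raise ValueError("record_from exceeds the simulation duration")

    if y0 is None:
        y = np.full(instance.n_cells, float(config.initial_state))
    else:
        y = np.array(y0, dtype=float)
    W, G, gsum = _matrices(instance)
    avb, ava = instance.external_drive()
    u_b, u_a = protocol.drives(n_steps)

    constant = np.isscalar(u_b) and np.isscalar(u_a)
    dt = config.dt

    if constant:
        I = instance.tonic + u_b * avb + u_a * ava
        if n_skip:
            status = _run(y, instance.tau, instance.theta, W, G, gsum, I, dt, n_skip)
            _check(status, 0, dt)
        out = np.empty((n_steps - n_skip + 1, instance.n_cells))
        status = _run_record(y, instance.tau, instance.theta, W, G, gsum, I, dt,
                             n_steps - n_skip, out)
        _check(status, n_skip, dt)
    else:
        u_b_arr = np.broadcast_to(np.atleast_1d(u_b), (n_steps,)) \
            if np.isscalar(u_b) else np.asarray(u_b, float)[:n_steps]
        u_a_arr = np.broadcast_to(np.atleast_1d(u_a), (n_steps,)) \
            if np.isscalar(u_a) else np.asarray(u_a, float)[:n_steps]
        I_t = (instance.tonic[None, :]
               + np.outer(u_b_arr, avb) + np.outer(u_a_arr, ava))
        if n_skip:
            status = _run_record_drive(y, instance.tau, instance.theta, W, G, gsum,
                                       I_t[:n_skip], dt, n_skip,
                                       np.empty((n_skip + 1, instance.n_cells)))
            _check(status, 0, dt)
        out = np.empty((n_steps - n_skip + 1, instance.n_cells))
        status = _run_record_drive(y, instance.tau, instance.theta, W, G, gsum,
                                   I_t[n_skip:], dt, n_steps - n_skip, out)
        _check(status, n_skip, dt)

    time = (n_skip + np.arange(out.shape[0])) * dt
    return Trace(time=time, y=out, cells=list(instance.cells), theta=instance.theta)


def _check(status: int, offset_steps: int, dt: float) -> None:
    if status >= 0:
        step = offset_steps + status
        raise IntegrationError(
            f"state diverged (|y| > {DIVERGENCE_LIMIT:g}) at step {step} "
            f"(t = {step * dt:g})"
        )


# ---------------------------------------------------------------------------
# Single-neuron electrophysiology protocols
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClampStimulus:
    """Piecewise-linear injected current: value interpolated between knots.

    kind='steps' holds each amplitude constant until the next knot;
    kind='ramp' interpolates linearly between knots.
    """

    times: tuple[float, ...]
    amplitudes: tuple[float, ...]
    kind: str = "steps"

    def __post_init__(self) -> None:
        if self.kind not in ("steps", "ramp"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if len(self.times) != len(self.amplitudes) or len(self.times) < 1:
            raise ValueError("times and amplitudes must be equal-length, nonempty")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")

    def sample(self, time: np.ndarray) -> np.ndarray:
        t = np.asarray(self.times)
        a = np.asarray(self.amplitudes)
        if self.kind == "ramp":
            return np.interp(time, t, a)
        idx = np.clip(np.searchsorted(t, time, side="right") - 1, -1, len(a) - 1)
        vals = np.where(idx >= 0, a[np.clip(idx, 0, None)], 0.0)
        return vals


def run_clamp_protocol(
    params: NeuronParams,
    stimulus: ClampStimulus,
    duration: float | None = None,
    config: SimulationConfig | None = None,
) -> Trace:
    """Isolated-neuron current-injection protocol (input and output aligned)."""
    config = config or SimulationConfig()
    if duration is None:
        duration = stimulus.times[-1] + 1.0
    n_steps = config.steps(duration)
    time = np.arange(n_steps + 1) * config.dt
    I_t = stimulus.sample(time[:-1])[:, None]

    y = np.full(1, float(config.initial_state))
    W = np.array([[params.w_self]])
    G = np.zeros((1, 1))
    out = np.empty((n_steps + 1, 1))
    status = _run_record_drive(
        y, np.array([params.tau]), np.array([params.theta]),
        W, G, np.zeros(1), I_t, config.dt, n_steps, out)
    _check(status, 0, config.dt)
    inputs = np.concatenate([I_t[:, 0], I_t[-1:, 0]])
    return Trace(time=time, y=out, cells=["neuron"],
                 theta=np.array([params.theta]), inputs=inputs)


# ---------------------------------------------------------------------------
# Equilibria of the isolated neuron and the bistability boundary
# ---------------------------------------------------------------------------

def find_equilibria(
    params: NeuronParams,
    constant_input: float = 0.0,
    grid_points: int = 2001,
) -> list[tuple[float, bool]]:
    """All fixed points y* = w sigma(y*+theta) + I with stability flags.

    Roots are bracketed by a sign-change scan over the attainable interval
    [I + min(0, w), I + max(0, w)] (padded) and polished with Brent's method.
    Stability is the sign of the linearisation -1 + w sigma'(y*+theta).
    """
    theta, _, w = params.theta, params.tau, params.w_self
    I = constant_input

    def h(y):
        return w / (1.0 + math.exp(-(y + theta))) + I - y

    lo = I + min(0.0, w) - 1e-6
    hi = I + max(0.0, w) + 1e-6
    if hi - lo < 1e-9:
        lo, hi = I - 1.0, I + 1.0
    grid = np.linspace(lo, hi, grid_points)
    vals = w * sigmoid(grid + theta) + I - grid

    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(brentq(h, grid[i], grid[i + 1], xtol=1e-12)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))

    # dedupe near-coincident roots from grid-boundary hits
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-8:
            uniq.append(r)

    out = []
    for r in uniq:
        s = 1.0 / (1.0 + math.exp(-(r + theta)))
        stable = (-1.0 + w * s * (1.0 - s)) < 0
        out.append((r, bool(stable)))
    return out


def classify_bistability(
    params: NeuronParams, constant_input: float = 0.0
) -> bool:
    """True iff the isolated neuron has >= 2 stable fixed points at this input."""
    eq = find_equilibria(params, constant_input)
    return sum(1 for _, stable in eq if stable) >= 2


def _any_theta_bistable(w: float, thetas: np.ndarray) -> bool:
    # the bistable bias band (when it exists) is centred on theta = -w/2,
    # so the symmetric bias is always included in the scan
    for theta in np.concatenate([thetas, [-w / 2.0]]):
        if classify_bistability(NeuronParams(theta=float(theta), tau=1.0, w_self=w)):
            return True
    return False


def bistability_threshold(
    w_lo: float = 1.0,
    w_hi: float = 10.0,
    tol: float = 1e-4,
    theta_grid: np.ndarray | None = None,
) -> float:
    """Infimum self-weight admitting two stable equilibria, by bisection on w.

    For each candidate w the bias theta is scanned over a grid augmented with
    the symmetric value -w/2 (the centre of the bistable band, which becomes
    vanishingly narrow just above threshold).
    """
    thetas = theta_grid if theta_grid is not None else np.linspace(-20.0, 20.0, 81)
    if _any_theta_bistable(w_lo, thetas):
        raise ValueError("lower bracket already bistable; decrease w_lo")
    if not _any_theta_bistable(w_hi, thetas):
        raise ValueError("upper bracket not bistable; increase w_hi")
    lo, hi = w_lo, w_hi
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _any_theta_bistable(mid, thetas):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)
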