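# Methods

## The circuit model

The package models one repeating motorneuron unit of the *C. elegans*
ventral nerve cord as a continuous-time recurrent neural network.  Six
classes participate — AS, DA, DB (dorsal) and VA, VB, VD (ventral); the DD
class is omitted because, once the anterior–posterior symmetry constraint is
imposed, it retains no outgoing connection inside the unit and cannot
contribute to pattern generation.  Every class except DB contributes an
anterior and a posterior cell (suffix `a`/`p`); DB contributes a single
cell, for 11 cells in total.

Each cell obeys

    tau_i dy_i/dt = -y_i + sum_j w_ji * sigma(y_j + theta_j)
                    + sum_k g_ki (y_k - y_i) + I_i,
    sigma(x) = 1 / (1 + exp(-x)),

with y_i the membrane potential relative to rest, theta_i a bias setting the
cell's intrinsic activation, w_ji signed chemical weights (w_ii is the
self-connection), g_ki >= 0 nonrectifying gap-junction conductances, and I_i
the external drive.  Time and voltage are dimensionless; no physical-unit
conversion is attempted.

Connections are parameterised at the class level and expanded to cells under
the symmetry constraint (anterior to anterior, posterior to posterior; DB
stands in for both).  The class-level edge list ships as an editable
plain-text fixture (`src/vnccpg/data/unit_architecture.txt`).  Nine of the
ten chemical class connections are fixed by the study narrative; the tenth
(VB→VA here) is derived from the circuit diagram rather than the text and is
flagged as such in the fixture file, where it can be swapped without
touching code.  Expansion yields exactly 20 chemical synapse instances and 6
gap-junction instances; the two same-class electrical connections (VD—VD,
VB—VB) are intersegmental and instantiate once, coupling the unit's own a-
and p-cells, because a single simulated unit has no neighbour to couple to.

The 34 free parameters (6 x 3 class physiology, 10 chemical weights, 4
electrical conductances, 2 command-input weights) form a genotype normalised
to [-1, 1] with per-entry linear decoding onto the physiological ranges:
tau in [0.05, 2], biases / self-weights / chemical weights / input weights
in [-20, 20], gap conductances in [0, 2.5].  Chemical polarity is the sign
of the weight — excitatory and inhibitory synapses are one parameter, not
two.

## Integration and single-neuron behaviour

Trajectories use forward Euler at dt = 0.0025, compiled with numba; a
divergence guard aborts if |y| exceeds 1e6 (bounded weights make true
trajectories bounded, so blow-up indicates a configuration error).  The
state resets to y = 0 between assay segments (the reset value is not
specified by the source study; it is configurable).

Accuracy, measured against an adaptive-step reference (`solve_ivp`, LSODA,
rtol 1e-10): convergence is cleanly first order, and on the evaluation
window the fitness actually reads (t >= 6 after reset) the maximum state
error across random circuits is below 1e-2.  Across the *full* 26-unit
segment including the reset transient the typical maximum error is ~2e-2:
cells with tau = 0.05 traverse tens of voltage units within the first ~0.3
time units, and a first-order method at dt/tau = 0.05 pays its largest local
errors there.  Conclusions about the post-transient dynamics (oscillation,
phase, dominance) are unaffected.

An isolated neuron reduces to y' = (-y + w*sigma(y+theta) + I)/tau.  Its
fixed points are found by a dense sign-change bracket over the attainable
interval [I + min(0, w), I + max(0, w)] polished with Brent's method;
stability is the sign of -1 + w*sigma'(y*).  Two stable fixed points require
w > 4 (saddle-node condition w*sigma' = 1 with max sigma' = 1/4).  The
numerical boundary locator bisects on w with the bias scanned over a grid
augmented with the symmetric value theta = -w/2: the bistable bias band is
centred there and becomes vanishingly narrow just above threshold, so a
plain grid would overestimate the boundary.  The locator recovers w = 4 to
1e-3.

A characterisation worth recording: the printed "active" parameter set
(theta = -3.4, tau = 0.05, w = 5.1) is monostable at zero input; its
bistable band is I in roughly (0.67, 1.03).  Plateau potentials therefore
latch under a depolarising step only when a holding current inside that band
is maintained — which is how the clamp-protocol tests exercise it.  The
"passive" set (theta = -1.8, tau = 0.03, w = 0.6) is globally monostable, so
steps produce graded responses with full return to rest.

## Fitness

Each candidate runs a two-segment assay: forward (AVB drive = 1 into DB,
VBa, VBp) and, after reset, backward (AVA drive = 1 into DAa, DAp, VAa,
VAp); each segment discards a 6-unit transient and evaluates T = 20 units.
Three multiplicative components score each direction (A = 0.3, the target
peak-to-peak output amplitude):

* F1, oscillation: per dominant neuron S = 2/(A*T) * integral |dO/dt| dt,
  capped at 1; F1 is the product over the dominant set ({DB, VBa, VBp}
  forward; the four A-cells backward).
* F2, antiphase: per dorsoventral pair (VB cells against DB forward, VA
  against DA backward), 1 - 1/(2T) * integral |sgn(dO_V)+sgn(dO_D)| dt, with
  sgn(0) = 0.
* F3, dominance: smooth bump factors f(x, x0) = 0.1 + 0.9*(x/x0)*e^(1-x/x0)
  rewarding dominant minima near 1-A, nondominant maxima near A, and
  dominant amplitudes near A.

The printed component definitions carry no absolute-value bars, but the
signed integrals telescope to ~0 on periodic windows, contradicting their
described meaning (total variation; antiphase maximal); the implementation
therefore applies |.| by default and exposes `signed=True` so the literal
reading can be re-run for sensitivity analysis.  Derivatives are first
differences on the Euler grid and integrals rectangle sums on the same grid,
consistent with the integration step.  Assay fitness is the product of the
two per-direction components; component-level values are always reported so
any other grouping can be recomputed.

Damped oscillators can score well on a 20-unit window, so the ensemble
analyses re-simulate each best-of-run circuit for 3000 units per direction
and re-apply the three-criterion classification to the final window; only
survivors count as solutions.

## Criteria thresholds

The binary classification behind ensemble fractions is threshold-dependent
and the source study does not print its cutoffs, so these are configuration
(defaults in parentheses): a neuron "oscillates" when its peak-to-peak
output over the final window exceeds 0.05 and the last quarter-window
retains at least half the amplitude of the first (rejecting damping); a pair
is "antiphase" when the circular-cross-correlation lag lies within 0.125 of
half a period; dominance requires a positive mean-output difference in the
direction-appropriate sense.  Published ensemble fractions should therefore
be compared qualitatively.

Phase lags are measured by estimating the period from the dominant Fourier
component of the dorsal trace, cropping both traces to an integer number of
periods, and taking the argmax of the circular cross-correlation, normalised
to [0, 1).

Bistability censuses evaluate the isolated-neuron reduction at the cell's
*operating input* — its time-averaged synaptic, gap-junction and command
drive during the assay — not at zero input.  The distinction matters: in
this architecture AS receives only inhibition (DB→AS), so a cell bistable at
zero input could be switched off but never back on, and no functioning
dorsal-core circuit can carry one.  A working AS instead has a bistable
input band (self-weight > 4) that the oscillation sweeps across, and its
mean drive sits inside that band — bistable where it operates, monostable
and intrinsically active at rest.  `classify_bistability` keeps zero input
as its default for the bare single-neuron API;
`bistable_at_operating_point` implements the census definition.

## Evolutionary search

The source study reports only a genetic algorithm with populations of 1000,
1000 generations, and 1000 independent runs (~1e9 circuit evaluations) —
cluster scale.  Operators are therefore explicit configuration: tournament
selection (size 3), elitism of the top individual, optional uniform
crossover (probability 0.5), per-gene Gaussian mutation (probability 0.5,
sigma 0.2 on the gene scale) with reflection at the [-1, 1] bounds and a
per-generation sigma decay (default 0.99; coarse search early, refinement
late).  A convex-surrogate sanity check
(single-peak surface over the genotype cube) converges to ~1e-5 of the
optimum within 200 generations, confirming the optimizer independently of
the biology.

Desk-scale profiles are first class.  The profile used by the reproduction
script (population 128, 110 generations, 6 runs) is set by single-CPU
throughput; success fractions at this budget are noisier and typically lower
than the published ensemble's, and the package treats the quantitative
fraction as optimizer-dependent (the original operators being unreported).
Every run is seeded; (seed, config) fully determines all draws, and batches
derive distinct per-run seeds from one base seed.

## Synthetic command traces

Calcium-imaging traces of the AVA/AVB command interneurons are not deposited,
so the generator emulates their qualitative statistics only: normalised
amplitudes in [0, 1], alternating AVB-high/AVA-high dominance bouts
(exponential bout lengths with a hard floor, defaults 40 and 10 time units —
several oscillation cycles of a typical evolved circuit), first-order
crossfades (tau 1.5) and low-pass-filtered additive noise, clipped to [0, 1].
What passing tests show is that evolved circuits *track dominance switches*
under such drive; nothing is claimed about waveform-level agreement with any
recording.

## Ablation machinery

Tonic substitution replaces one connection's time-varying synaptic term with
a swept constant into the postsynaptic cell (for gap junctions, +c into one
side and -c into the other, preserving the antisymmetry of the ohmic
current).  Sweep sizes follow the study (1000 constants for chemical, 2000
for electrical); the ranges are this package's choice: a chemical term
w*sigma(.) can only deliver currents in [min(0, w), max(0, w)], and gap
currents are swept over their empirically observed unablated range extended
by 50%.  Best fitness is taken independently for the forward and backward
segments.  Substitution works per synapse instance or, when bare class names
are given, replaces every instance of a class connection with one shared
constant — the class-level view behind statements like "no other path to VB
exists" (per-instance substitution of VD→VB can leak signal through the
VB—VB gap junction that couples the unit's two VB cells).  Classification: "inert" when some constant restores fitness to
within 1% of the unablated value, "tonic-replaceable" above 20% of it (the
study's dashed-line floor), otherwise "phasic-required"; all thresholds
configurable.

The core-oscillator search enumerates all 63 neuron-class subsets, ablates
the complement, compensates each surviving cell's severed chemical input
greedily with a swept tonic constant (candidates over the summed attainable
range of the lost terms), and requires at least one surviving cell to
sustain an oscillation under both drive conditions.  Inclusion-minimal
passing subsets are returned.  Greedy per-cell compensation does not
guarantee the monotonicity a joint search would; the returned minimal sets
should be read as "oscillates under the compensation policy stated here".

## Fixtures

`make_reference_oscillator()` returns a frozen instance found once by a
seeded evolutionary search constrained to the canonical solution motif —
dorsal-core sign pattern II (AS→DA and DA→DB excitatory, DB→AS inhibitory),
AS and VD pinned to self-weight 6 with the other self-weights capped below
the bistability threshold, inhibitory AS→VD routing to the ventral side —
and verified by the test suite to pass all three criteria after the
long-horizon re-filter.  Its AS is bistable at its operating input while the
A- and B-class cells never are; its VD carries the same bistable-capable
self-weight but happens to operate just outside its band, consistent with
the published observation that VD bistability is dispensable.  `make_damped_oscillator()` is constructed
analytically: a three-stage negative-feedback ring (AS→DA→DB→AS) with loop
gain just below its oscillatory instability, giving a stable focus whose
ringing survives a 26-unit assay but vanishes long before 3000 units.
Fixtures are frozen constants in `synthetic.py`, regenerated only
deliberately.

## Known limitations

* The model has no body, muscles, or stretch-receptor feedback; "forward"
  and "backward" refer to neural activity signatures, not locomotion.
* A single unit is simulated; intersegmental gap junctions close within the
  unit rather than coupling neighbours, and multi-unit chains are out of
  scope.
* Ensemble fractions depend on unreported GA operators and classification
  thresholds and are reproduced qualitatively, not numerically.
* Greedy tonic compensation understates what an exhaustive joint
  compensation search could rescue.
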