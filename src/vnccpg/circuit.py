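"""Repeating neural unit of the ventral nerve cord: architecture and genotype.

The model circuit is a single anterior-posterior symmetric repeating unit of
six motorneuron classes (AS, DA, DB, VA, VB, VD; DD omitted).  Every class
except DB contributes an anterior ('a') and posterior ('p') cell, DB a single
cell, giving 11 cells.  Connections are specified at the *class* level and
expanded to cell-level instances under the symmetry constraint: anterior maps
to anterior, posterior to posterior, and connections touching DB fan both
halves into/out of the sole DB cell.  Electrical connections between a class
and itself (VD|-|VD, VB|-|VB) are intersegmental and instantiate once,
coupling the unit's own a- and p-cells.

The free parameters form a genotype of 34 entries normalised to [-1, 1]:
per-class bias, time constant and self-weight (18), one signed weight per
chemical class connection (10), one conductance per electrical class
connection (4), and the two command-interneuron input weights (AVB -> B-class,
AVA -> A-class).  Decoding is linear per entry onto the physiological ranges.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "NEURON_CLASSES",
    "CLASS_CARDINALITY",
    "A_CLASS_CELLS",
    "B_CLASS_CELLS",
    "CellId",
    "ClassConnection",
    "CircuitArchitecture",
    "ParameterRanges",
    "CircuitInstance",
    "build_default_architecture",
    "load_architecture",
    "expand_genotype",
    "encode_instance",
    "count_free_parameters",
    "GENOTYPE_LENGTH",
]

NEURON_CLASSES: tuple[str, ...] = ("AS", "DA", "DB", "VA", "VB", "VD")
CLASS_CARDINALITY: dict[str, int] = {
    "AS": 2, "DA": 2, "DB": 1, "VA": 2, "VB": 2, "VD": 2,
}

# Cells driven by the command interneurons: AVB excites the B-class,
# AVA the A-class.  AS and VD receive no external drive.
B_CLASS_CELLS: tuple[str, ...] = ("DB", "VBa", "VBp")
A_CLASS_CELLS: tuple[str, ...] = ("DAa", "DAp", "VAa", "VAp")

GENOTYPE_LENGTH = 34
_N_PHYSIOLOGY_PER_CLASS = 3  # bias, tau, self-weight
_N_INPUT_WEIGHTS = 2


@dataclass(frozen=True)
class CellId:
    """A single motorneuron cell within the unit."""

    neuron_class: str
    position: str  # 'anterior' | 'posterior' | 'sole'

    def __post_init__(self) -> None:
        if self.neuron_class not in NEURON_CLASSES:
            raise ValueError(f"unknown neuron class {self.neuron_class!r}")
        sole = CLASS_CARDINALITY[self.neuron_class] == 1
        if sole != (self.position == "sole"):
            raise ValueError(
                f"{self.neuron_class} position must be "
                f"{'sole' if sole else 'anterior/posterior'}, got {self.position!r}"
            )

    @property
    def name(self) -> str:
        suffix = {"anterior": "a", "posterior": "p", "sole": ""}[self.position]
        return self.neuron_class + suffix


@dataclass(frozen=True)
class ClassConnection:
    """A class-level connection; electrical ones are unordered pairs."""

    pre: str
    post: str
    kind: str  # 'chemical' | 'electrical'

    def __post_init__(self) -> None:
        if self.kind not in ("chemical", "electrical"):
            raise ValueError(f"unknown connection kind {self.kind!r}")
        for c in (self.pre, self.post):
            if c not in NEURON_CLASSES:
                raise ValueError(f"unknown neuron class {c!r}")
        if self.kind == "electrical" and self.pre > self.post:
            # normalise unordered pair
            a, b = self.post, self.pre
            object.__setattr__(self, "pre", a)
            object.__setattr__(self, "post", b)

    @property
    def is_intersegmental(self) -> bool:
        return self.kind == "electrical" and self.pre == self.post

    def __str__(self) -> str:
        arrow = "->" if self.kind == "chemical" else "<->"
        return f"{self.pre}{arrow}{self.post}"


def _cells_of(cls: str) -> list[CellId]:
    if CLASS_CARDINALITY[cls] == 1:
        return [CellId(cls, "sole")]
    return [CellId(cls, "anterior"), CellId(cls, "posterior")]


@dataclass(frozen=True)
class CircuitArchitecture:
    """Class-level wiring diagram plus its expansion rule to cells."""

    classes: tuple[str, ...] = NEURON_CLASSES
    connections: tuple[ClassConnection, ...] = ()

    @property
    def chemical(self) -> tuple[ClassConnection, ...]:
        return tuple(c for c in self.connections if c.kind == "chemical")

    @property
    def electrical(self) -> tuple[ClassConnection, ...]:
        return tuple(c for c in self.connections if c.kind == "electrical")

    def cells(self) -> list[CellId]:
        out: list[CellId] = []
        for cls in self.classes:
            out.extend(_cells_of(cls))
        return out

    def cell_names(self) -> list[str]:
        return [c.name for c in self.cells()]

    def expand_connection(self, conn: ClassConnection) -> list[tuple[str, str]]:
        """Cell-level instances of a class connection (names, pre first).

        Anterior partners pair with anterior, posterior with posterior; the
        sole DB cell stands in for both.  Intersegmental electrical
        connections (same class on both ends) instantiate once, linking the
        a- and p-cells of that class.
        """
        if conn.is_intersegmental:
            return [(conn.pre + "a", conn.post + "p")]
        pre_cells = _cells_of(conn.pre)
        post_cells = _cells_of(conn.post)
        if len(pre_cells) == 1:
            pairs = [(pre_cells[0], q) for q in post_cells]
        elif len(post_cells) == 1:
            pairs = [(p, post_cells[0]) for p in pre_cells]
        else:
            pairs = list(zip(pre_cells, post_cells))
        return [(p.name, q.name) for p, q in pairs]

    def expand_all(self) -> tuple[list[tuple[str, str, ClassConnection]],
                                  list[tuple[str, str, ClassConnection]]]:
        """(chemical, electrical) instance lists as (pre, post, class_conn)."""
        chem, elec = [], []
        for conn in self.connections:
            target = chem if conn.kind == "chemical" else elec
            for pre, post in self.expand_connection(conn):
                target.append((pre, post, conn))
        return chem, elec


@dataclass(frozen=True)
class ParameterRanges:
    """Physiological ranges; genotype entries map linearly onto these."""

    tau: tuple[float, float] = (0.05, 2.0)
    bias: tuple[float, float] = (-20.0, 20.0)
    self_weight: tuple[float, float] = (-20.0, 20.0)
    chemical_weight: tuple[float, float] = (-20.0, 20.0)
    electrical_weight: tuple[float, float] = (0.0, 2.5)
    interneuron_input: tuple[float, float] = (-20.0, 20.0)

    def __post_init__(self) -> None:
        for name in ("tau", "bias", "self_weight", "chemical_weight",
                     "electrical_weight", "interneuron_input"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"empty range for {name}: [{lo}, {hi}]")
        if self.electrical_weight[0] < 0:
            raise ValueError("electrical weights must be nonnegative")


def _decode(value: float, rng: tuple[float, float]) -> float:
    lo, hi = rng
    return lo + (value + 1.0) * 0.5 * (hi - lo)


def _encode(value: float, rng: tuple[float, float]) -> float:
    lo, hi = rng
    return 2.0 * (value - lo) / (hi - lo) - 1.0


@dataclass
class CircuitInstance:
    """Fully instantiated phenotype: per-cell physiology and per-synapse weights.

    `chemical_synapses` and `gap_junctions` are the authoritative connection
    lists; `weight_matrix`/`gap_matrix` assemble them (plus self-weights on
    the diagonal) for simulation.  `tonic` holds extra constant currents used
    by ablation compensation; it is zero for freshly decoded genotypes.
    """

    cells: list[str]
    tau: np.ndarray
    theta: np.ndarray
    self_weight: np.ndarray
    chemical_synapses: list[tuple[str, str, float]]
    gap_junctions: list[tuple[str, str, float]]
    w_avb: float
    w_ava: float
    tonic: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.cells)
        self.tau = np.asarray(self.tau, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.self_weight = np.asarray(self.self_weight, dtype=float)
        if self.tonic is None:
            self.tonic = np.zeros(n)
        else:
            self.tonic = np.asarray(self.tonic, dtype=float)
        for arr, name in ((self.tau, "tau"), (self.theta, "theta"),
                          (self.self_weight, "self_weight"), (self.tonic, "tonic")):
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per cell")
        for a, b, g in self.gap_junctions:
            if g < 0:
                raise ValueError(f"negative gap-junction conductance {a}<->{b}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def index(self, cell: str) -> int:
        try:
            return self.cells.index(cell)
        except ValueError:
            raise KeyError(f"cell {cell!r} not in instance") from None

    def weight_matrix(self) -> np.ndarray:
        """Chemical weights W[post, pre], self-weights on the diagonal."""
        n = self.n_cells
        W = np.zeros((n, n))
        W[np.diag_indices(n)] = self.self_weight
        for pre, post, w in self.chemical_synapses:
            W[self.index(post), self.index(pre)] += w
        return W

    def gap_matrix(self) -> np.ndarray:
        """Symmetric nonrectifying conductances G[i, k]."""
        n = self.n_cells
        G = np.zeros((n, n))
        for a, b, g in self.gap_junctions:
            i, k = self.index(a), self.index(b)
            G[i, k] += g
            G[k, i] += g
        return G

    def external_drive(self) -> tuple[np.ndarray, np.ndarray]:
        """(AVB mask * w_avb, AVA mask * w_ava) per-cell drive vectors."""
        avb = np.zeros(self.n_cells)
        ava = np.zeros(self.n_cells)
        for c in B_CLASS_CELLS:
            if c in self.cells:
                avb[self.index(c)] = self.w_avb
        for c in A_CLASS_CELLS:
            if c in self.cells:
                ava[self.index(c)] = self.w_ava
        return avb, ava

    def copy(self) -> "CircuitInstance":
        return CircuitInstance(
            cells=list(self.cells),
            tau=self.tau.copy(),
            theta=self.theta.copy(),
            self_weight=self.self_weight.copy(),
            chemical_synapses=list(self.chemical_synapses),
            gap_junctions=list(self.gap_junctions),
            w_avb=self.w_avb,
            w_ava=self.w_ava,
            tonic=self.tonic.copy(),
        )


def load_architecture(path_or_lines) -> CircuitArchitecture:
    """Parse a plain-text edge list (one 'PRE POST KIND' per line, # comments)."""
    if isinstance(path_or_lines, (list, tuple)):
        lines: Iterable[str] = path_or_lines
    else:
        with open(path_or_lines) as fh:
            lines = fh.readlines()
    conns: list[ClassConnection] = []
    for ln, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"line {ln}: expected 'PRE POST KIND', got {raw!r}")
        conns.append(ClassConnection(parts[0], parts[1], parts[2]))
    return CircuitArchitecture(connections=tuple(conns))


def build_default_architecture() -> CircuitArchitecture:
    """The shipped repeating-unit wiring (10 chemical + 4 electrical)."""
    ref = importlib.resources.files("vnccpg").joinpath("data/unit_architecture.txt")
    return load_architecture(ref.read_text().splitlines())


def count_free_parameters(arch: CircuitArchitecture) -> dict[str, int]:
    """Free-parameter census under the symmetry constraint."""
    physiology = _N_PHYSIOLOGY_PER_CLASS * len(arch.classes)
    chemical = len(arch.chemical)
    electrical = len(arch.electrical)
    inputs = _N_INPUT_WEIGHTS
    return {
        "physiology": physiology,
        "chemical": chemical,
        "electrical": electrical,
        "inputs": inputs,
        "total": physiology + chemical + electrical + inputs,
    }


def _genotype_layout(arch: CircuitArchitecture) -> int:
    return count_free_parameters(arch)["total"]


def expand_genotype(
    genotype: Sequence[float],
    ranges: ParameterRanges | None = None,
    arch: CircuitArchitecture | None = None,
) -> CircuitInstance:
    """Decode a normalised genotype into a cell-level circuit instance.

    Layout: for each class in architecture order, (bias, tau, self-weight);
    then one weight per chemical class connection in file order; one
    conductance per electrical class connection; finally (w_AVB, w_AVA).
    """
    ranges = ranges or ParameterRanges()
    arch = arch or build_default_architecture()
    g = np.asarray(genotype, dtype=float)
    expected = _genotype_layout(arch)
    if g.shape != (expected,):
        raise ValueError(f"genotype must have length {expected}, got {g.shape}")
    if np.any(g < -1.0) or np.any(g > 1.0):
        bad = int(np.argmax((g < -1.0) | (g > 1.0)))
        raise ValueError(f"genotype entry {bad} = {g[bad]} outside [-1, 1]")

    cells = arch.cell_names()
    cls_of = {c.name: c.neuron_class for c in arch.cells()}

    idx = 0
    theta_c, tau_c, self_c = {}, {}, {}
    for cls in arch.classes:
        theta_c[cls] = _decode(g[idx], ranges.bias)
        tau_c[cls] = _decode(g[idx + 1], ranges.tau)
        self_c[cls] = _decode(g[idx + 2], ranges.self_weight)
        idx += 3

    chem_weights = {}
    for conn in arch.chemical:
        chem_weights[conn] = _decode(g[idx], ranges.chemical_weight)
        idx += 1
    elec_weights = {}
    for conn in arch.electrical:
        elec_weights[conn] = _decode(g[idx], ranges.electrical_weight)
        idx += 1
    w_avb = _decode(g[idx], ranges.interneuron_input)
    w_ava = _decode(g[idx + 1], ranges.interneuron_input)

    chem_inst, elec_inst = arch.expand_all()
    chemical = [(pre, post, chem_weights[conn]) for pre, post, conn in chem_inst]
    gaps = [(a, b, elec_weights[conn]) for a, b, conn in elec_inst]

    return CircuitInstance(
        cells=cells,
        tau=np.array([tau_c[cls_of[c]] for c in cells]),
        theta=np.array([theta_c[cls_of[c]] for c in cells]),
        self_weight=np.array([self_c[cls_of[c]] for c in cells]),
        chemical_synapses=chemical,
        gap_junctions=gaps,
        w_avb=w_avb,
        w_ava=w_ava,
    )


def encode_instance(
    instance: CircuitInstance,
    ranges: ParameterRanges | None = None,
    arch: CircuitArchitecture | None = None,
) -> np.ndarray:
    """Inverse of :func:`expand_genotype` (round-trip to floating tolerance).

    Class-level values are read from the anterior (or sole) representative
    cell / instance of each class connection.
    """
    ranges = ranges or ParameterRanges()
    arch = arch or build_default_architecture()
    rep = {cls: _cells_of(cls)[0].name for cls in arch.classes}
    g: list[float] = []
    for cls in arch.classes:
        i = instance.index(rep[cls])
        g.append(_encode(instance.theta[i], ranges.bias))
        g.append(_encode(instance.tau[i], ranges.tau))
        g.append(_encode(instance.self_weight[i], ranges.self_weight))
    chem_lookup = {(pre, post): w for pre, post, w in instance.chemical_synapses}
    for conn in arch.chemical:
        pre, post = arch.expand_connection(conn)[0]
        g.append(_encode(chem_lookup[(pre, post)], ranges.chemical_weight))
    gap_lookup = {}
    for a, b, w in instance.gap_junctions:
        gap_lookup[(a, b)] = w
        gap_lookup[(b, a)] = w
    for conn in arch.electrical:
        a, b = arch.expand_connection(conn)[0]
        g.append(_encode(gap_lookup[(a, b)], ranges.electrical_weight))
    g.append(_encode(instance.w_avb, ranges.interneuron_input))
    g.append(_encode(instance.w_ava, ranges.interneuron_input))
    return np.asarray(g)
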