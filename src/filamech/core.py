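"""Shared mechanical primitives for coarse-grained filament models.

Units used throughout the package: forces in pN, lengths in nm, times in s,
energies in pN nm (1 pN nm = 1 zJ; kBT at room temperature = 4.114 pN nm).
Rates are in 1/s and stiffnesses in pN/nm.

This module holds the pieces both filament simulators build on: Bell
(slip-bond) kinetics, fixed-step Monte Carlo transition probabilities, and
quasi-static force balance on serial/parallel spring-and-bond networks.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

#: Thermal energy at 25 degrees C, pN nm.
KBT_ROOM = 4.114

#: Per-step transition probabilities above this are refined by substepping.
MAX_STEP_PROBABILITY = 0.1


class ParameterError(ValueError):
    """A physical parameter is outside its admissible domain."""


class RuptureError(RuntimeError):
    """The network lost force-bearing connectivity (filament rupture)."""


class BondState(enum.Enum):
    CLOSED = "closed"
    OPEN = "open"


class Branch(enum.Enum):
    STRETCH = "stretch"
    RELAX = "relax"


@dataclass
class MechanicalParams:
    """Global mechanical/kinetic parameters of a simulation.

    kBT defaults to room temperature; dt is the Monte Carlo base time step,
    refined automatically whenever a per-step transition probability would
    exceed :data:`MAX_STEP_PROBABILITY`.
    """

    kBT: float = KBT_ROOM           # pN nm
    pulling_speed: float = 500.0    # nm/s
    dt: float = 1e-3                # s

    def __post_init__(self) -> None:
        if self.kBT <= 0:
            raise ParameterError(f"kBT must be positive, got {self.kBT}")
        if self.dt <= 0:
            raise ParameterError(f"dt must be positive, got {self.dt}")
        if self.pulling_speed <= 0:
            raise ParameterError(
                f"pulling_speed must be positive, got {self.pulling_speed}"
            )


@dataclass
class BondElement:
    """A lateral interaction that is either load-bearing (CLOSED) or not (OPEN).

    An OPEN element transmits no lateral force.  Opening is force-activated
    with Bell kinetics (``k0_open``, ``x_open``); rebinding occurs at
    ``rebind_rate`` once open.
    """

    state: BondState = BondState.CLOSED
    k0_open: float = 0.0      # 1/s at zero force
    x_open: float = 0.0       # nm
    rebind_rate: float = 0.0  # 1/s
    rest_length: float = 0.0  # nm
    stiffness: float = 1.0    # pN/nm

    def __post_init__(self) -> None:
        if min(self.k0_open, self.x_open, self.rebind_rate) < 0:
            raise ParameterError("bond rates and distances must be non-negative")
        if self.stiffness <= 0:
            raise ParameterError("bond stiffness must be positive")


@dataclass
class ForceExtensionRecord:
    """One stretch or relax branch of a cycle: sampled time, distance, force."""

    t: np.ndarray             # s, strictly increasing
    d: np.ndarray             # nm, end-to-end distance
    F: np.ndarray             # pN
    branch: Branch
    cycle_index: int = 1

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        if not (len(self.t) == len(self.d) == len(self.F)):
            raise ParameterError("t, d, F must have equal length")
        if len(self.t) < 2:
            raise ParameterError("a record needs at least two samples")
        if np.any(np.diff(self.t) <= 0):
            raise ParameterError("t must be strictly increasing")
        if self.cycle_index < 1:
            raise ParameterError("cycle_index must be >= 1")
        dd = np.diff(self.d)
        if self.branch is Branch.STRETCH and np.any(dd < -1e-9):
            raise ParameterError("STRETCH branch must have non-decreasing d")
        if self.branch is Branch.RELAX and np.any(dd > 1e-9):
            raise ParameterError("RELAX branch must have non-increasing d")


def bell_rate(F, k0, x, kBT=KBT_ROOM):
    """Force-activated transition rate k0 * exp(F x / kBT) (Bell kinetics).

    The standard slip-bond law: an applied tension F tilts the energy
    landscape along the reaction coordinate by F*x, lowering the barrier.
    Monotone non-decreasing in F.  Accepts scalars or arrays.
    """
    F = np.asarray(F, dtype=float)
    if np.any(F < 0):
        raise ParameterError("tension F must be non-negative")
    if np.any(np.asarray(k0) < 0) or np.any(np.asarray(x) < 0):
        raise ParameterError("k0 and x must be non-negative")
    if kBT <= 0:
        raise ParameterError("kBT must be positive")
    out = k0 * np.exp(F * x / kBT)
    return float(out) if out.ndim == 0 else out


def step_probability(rate, dt):
    """Probability that a Poisson transition with the given rate fires within dt.

    Returns 1 - exp(-rate*dt), the exact single-event probability, which
    satisfies the semigroup property over consecutive substeps.
    """
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ParameterError("rate must be non-negative")
    if dt <= 0:
        raise ParameterError("dt must be positive")
    out = -np.expm1(-rate * dt)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Spring/bond network force balance
# ---------------------------------------------------------------------------

@dataclass
class FilamentLattice:
    """Discrete serial x parallel spring network with breakable lateral bonds.

    ``n_serial`` axial segments by ``n_parallel`` protofilament chains.
    Longitudinal springs connect consecutive nodes along each chain
    (stiffness ``long_k[i, j]``, rest offset ``long_offset[i, j]``; a zero
    stiffness marks a broken segment).  Lateral bonds couple neighbouring
    chains at interior node rows: ``lateral[r][j]`` is the BondElement
    between nodes (row r, chain j) and (row r, chain j+1); OPEN bonds
    transmit nothing.  Node axial displacements are measured from the
    zero-extension configuration; both boundary rows move rigidly.
    """

    n_serial: int
    n_parallel: int
    long_k: np.ndarray = field(default=None)
    long_offset: np.ndarray = field(default=None)
    lateral: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_serial < 1 or self.n_parallel < 1:
            raise ParameterError("lattice dimensions must be >= 1")
        if self.long_k is None:
            self.long_k = np.ones((self.n_serial, self.n_parallel))
        self.long_k = np.asarray(self.long_k, dtype=float)
        if self.long_offset is None:
            self.long_offset = np.zeros((self.n_serial, self.n_parallel))
        self.long_offset = np.asarray(self.long_offset, dtype=float)
        if self.long_k.shape != (self.n_serial, self.n_parallel):
            raise ParameterError("long_k has wrong shape")
        if self.long_offset.shape != (self.n_serial, self.n_parallel):
            raise ParameterError("long_offset has wrong shape")
        if np.any(self.long_k < 0):
            raise ParameterError("spring stiffnesses must be non-negative")

    def _boundary_component(self):
        """Set of node ids connected to the boundaries (union-find).

        Raises :class:`RuptureError` when the two boundaries are not in the
        same component (no force-bearing path).  Nodes outside the returned
        set belong to floating fragments that transmit no force.
        """
        n_rows = self.n_serial + 1
        npar = self.n_parallel
        parent = list(range(n_rows * npar))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

        for i in range(self.n_serial):
            for j in range(npar):
                if self.long_k[i, j] > 0:
                    union(i * npar + j, (i + 1) * npar + j)
        for r, row in enumerate(self.lateral):
            for j, bond in enumerate(row):
                if bond is not None and bond.state is BondState.CLOSED:
                    union(r * npar + j, r * npar + j + 1)
        # left boundary row nodes are rigidly tied together; same for right
        for j in range(1, npar):
            union(j, 0)
            union(self.n_serial * npar + j, self.n_serial * npar)
        if find(0) != find(self.n_serial * npar):
            raise RuptureError("network disconnected: no force-bearing path")
        root = find(0)
        return {n for n in range(n_rows * npar) if find(n) == root}


def network_force(lattice: FilamentLattice, end_distance: float) -> float:
    """Quasi-static tension of the spring network at an imposed extension.

    ``end_distance`` is the imposed end-to-end extension beyond the
    zero-offset rest configuration (d = 0 at zero filament extension).
    Interior node displacements are solved from force balance; the returned
    force is the total axial load on the right boundary.  Raises
    :class:`RuptureError` if no force-bearing path connects the boundaries.
    """
    if end_distance < 0:
        raise ParameterError("end_distance must be non-negative")
    active = lattice._boundary_component()
    ns, npar = lattice.n_serial, lattice.n_parallel
    n_int = (ns - 1) * npar  # interior nodes: rows 1..ns-1

    def idx(i, j):  # interior row i (1-based) -> unknown index
        return (i - 1) * npar + j

    if n_int == 0:
        # single segment: chains directly between the boundaries
        f = float(np.sum(lattice.long_k[0] * (end_distance - lattice.long_offset[0])))
        return f

    rows, cols, vals = [], [], []
    b = np.zeros(n_int)

    def add(a, c, v):
        rows.append(a)
        cols.append(c)
        vals.append(v)

    # longitudinal springs (floating fragments are excluded: they relax
    # to zero force and transmit nothing to the boundaries)
    for i in range(ns):
        for j in range(npar):
            k = lattice.long_k[i, j]
            if k == 0 or i * npar + j not in active:
                continue
            o = lattice.long_offset[i, j]
            lo, hi = i, i + 1  # node rows
            lo_int = 1 <= lo <= ns - 1
            hi_int = 1 <= hi <= ns - 1
            # spring force on node pair; boundary values u=0 (row 0), u=D (row ns)
            if lo_int:
                a = idx(lo, j)
                add(a, a, k)
                if hi_int:
                    add(a, idx(hi, j), -k)
                else:
                    b[a] += k * end_distance
                b[a] -= k * o
            if hi_int:
                a = idx(hi, j)
                add(a, a, k)
                if lo_int:
                    add(a, idx(lo, j), -k)
                b[a] += k * o
    # lateral bonds (interior rows only contribute unknowns; boundary-row
    # lateral bonds connect rigidly-moving nodes and carry constant load)
    for r, row in enumerate(lattice.lateral):
        if not (1 <= r <= ns - 1):
            continue
        for j, bond in enumerate(row):
            if bond is None or bond.state is not BondState.CLOSED:
                continue
            if r * npar + j not in active:
                continue
            k, o = bond.stiffness, bond.rest_length
            a, c = idx(r, j), idx(r, j + 1)
            add(a, a, k)
            add(a, c, -k)
            b[a] -= k * o
            add(c, c, k)
            add(c, a, -k)
            b[c] += k * o

    K = sp.csr_matrix((vals, (rows, cols)), shape=(n_int, n_int))
    # chains may be fully broken (all-zero rows): pin those nodes
    diag = K.diagonal()
    free = diag == 0
    if np.any(free):
        K = K + sp.diags(free.astype(float))
    u = spla.spsolve(K.tocsc(), b)

    # total load on the right boundary = sum of last-segment spring forces
    F = 0.0
    for j in range(npar):
        k = lattice.long_k[ns - 1, j]
        if k == 0 or (ns - 1) * npar + j not in active:
            continue
        u_prev = u[idx(ns - 1, j)] if ns >= 2 else 0.0
        F += k * (end_distance - u_prev - lattice.long_offset[ns - 1, j])
    return float(F)
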