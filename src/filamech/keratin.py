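"""Monte Carlo model of keratin filament cycling by subunit sliding.

The filament is a lattice of ``n_serial`` axial repeats by ``n_parallel``
protofilaments (keratin: 16 monomers = 8 dimer chains per cross-section).
Longitudinal dimer backbones are springs; each axial interface of each
protofilament carries one lateral bond that can rupture under force (Bell
kinetics).  A ruptured subunit slides by one lattice period and rebinds:
with probability ``p_neighbor`` (default 10%) at the shifted periodic site
of a *neighbouring* dimer — a permanent slip that elongates the
protofilament by one period — and otherwise back to its original partner,
so the slide is transient and is recovered once the filament goes slack.
New bonds have the same properties as the old ones, so the filament
stiffness never changes: the filament elongates at constant stiffness, the
metal-like plasticity signature.

Mean-field reduction (see docs/methods.md): tension is shared equally
among parallel paths, each slide changes the filament rest length by
``period / n_parallel``, and every bond tracks its own local stretch which
resets to zero when it rebinds.  The reset makes the sliding flow
reload-limited: a freshly rebound bond must be re-strained by further
pulling before it can rupture again, so the creep rate stays a bounded
fraction of the pulling speed at any force and high-force triggers remain
attainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    Branch,
    MechanicalParams,
    ParameterError,
    RuptureError,
    bell_rate,
    MAX_STEP_PROBABILITY,
)

#: hard cap on kinetic substeps per base step before declaring dt infeasible
_MAX_SUBSTEPS = 1000


@dataclass
class KeratinModel:
    """Keratin lattice geometry, elasticity and sliding kinetics.

    All numeric defaults are calibration parameters (the coarse-grained
    literature does not fix them); they are calibrated once so that the
    default simulator reproduces the measured elongation and dissipation
    bands, and recorded with provenance tags in ``defaults.yaml``.
    """

    n_serial: int = 20
    n_parallel: int = 8          # 16 monomers -> 8 dimer chains
    period: float = 55.0         # axial repeat / slide distance per rupture, nm (calibrated)
    spring_k: float = 1.8        # longitudinal spring per dimer segment, pN/nm
    stiff_k: float = 8.0         # backbone stiffness above the stiffening onset
    stiff_onset: float = 24.0    # per-segment elastic stretch where backbone stiffens, nm
    k0_open: float = 1e-4        # zero-force opening rate, 1/s (calibrated)
    x_open: float = 1.2          # Bell distance, nm (calibrated)
    p_neighbor: float = 0.10     # fraction of slides that rebind to a neighbour
    k_recover: float = 25.0      # 1/s, transient slides return once slack
    slack_force: float = 5.0     # pN, below this the filament counts as slack

    def __post_init__(self) -> None:
        if self.n_serial < 2 or self.n_parallel < 2:
            raise ParameterError("lattice must be at least 2 x 2")
        if self.period <= 0 or self.spring_k <= 0 or self.stiff_k <= 0:
            raise ParameterError("period and stiffnesses must be positive")
        if not 0.0 <= self.p_neighbor <= 1.0:
            raise ParameterError("p_neighbor must be a probability")
        if min(self.k0_open, self.x_open, self.k_recover) < 0:
            raise ParameterError("rates and distances must be non-negative")

    @property
    def L0(self) -> float:
        """Rest length of the pristine filament, nm."""
        return self.n_serial * self.period

    def segment_force(self, e):
        """Backbone elastic law per segment: linear, stiffening above onset."""
        e = np.asarray(e, dtype=float)
        f = np.where(
            e <= self.stiff_onset,
            self.spring_k * e,
            self.spring_k * self.stiff_onset + self.stiff_k * (e - self.stiff_onset),
        )
        f = np.clip(f, 0.0, None)
        return float(f) if f.ndim == 0 else f


class KeratinSim:
    """Stepper for one keratin filament trajectory (quasi-static force balance)."""

    def __init__(self, model: KeratinModel, mech: MechanicalParams, rng):
        self.model = model
        self.mech = mech
        self.rng = rng
        self.L0 = model.L0
        self.t = 0.0
        self.d = self.L0                 # start at rest, F = 0
        # per-bond local stretch since last (re)bind, nm; shape (n_serial, n_parallel)
        self.s = np.zeros((model.n_serial, model.n_parallel))
        self.slip = np.zeros(model.n_parallel, dtype=int)   # permanent, per chain
        self.n_transient = 0             # outstanding same-site slides
        self.current_cycle = 1
        self.events: list[tuple] = []    # (t, cycle, branch, kind, chain, F)
        self._elastic = 0.0              # cached elastic extension, nm

    # -- mechanics ---------------------------------------------------------

    @property
    def rest_length(self) -> float:
        m = self.model
        plastic = (self.slip.sum() + self.n_transient) * m.period / m.n_parallel
        return self.L0 + plastic

    def force(self) -> float:
        m = self.model
        elastic = max(self.d - self.rest_length, 0.0)
        return m.n_parallel * m.segment_force(elastic / m.n_serial)

    # -- kinetics ----------------------------------------------------------

    def _sync(self) -> float:
        """Re-balance after d or rest length changed.

        The change of total elastic extension is distributed uniformly over
        the per-bond stretches; returns the current force.
        """
        m = self.model
        elastic = max(self.d - self.rest_length, 0.0)
        ds = (elastic - self._elastic) / m.n_serial
        if ds != 0.0:
            self.s = np.clip(self.s + ds, 0.0, None)
            self._elastic = elastic
        return m.n_parallel * m.segment_force(elastic / m.n_serial)

    def _slide(self, flat_index: int, branch: Branch, F: float) -> None:
        m = self.model
        j = flat_index % m.n_parallel
        if self.rng.random() < m.p_neighbor:
            self.slip[j] += 1
            kind = "slip_permanent"
        else:
            self.n_transient += 1
            kind = "slip_transient"
        self.s.flat[flat_index] = 0.0
        self.events.append((self.t, self.current_cycle, branch.value, kind, j, F))

    def step(self, direction: int, branch: Branch) -> float:
        """Advance one base time step dt; returns the force afterwards."""
        m, mech = self.model, self.mech
        dt = mech.dt
        self.t += dt
        self.d += direction * mech.pulling_speed * dt
        F = self._sync()

        remaining = dt
        n_sub = 0
        while remaining > 0.0:
            n_sub += 1
            if n_sub > _MAX_SUBSTEPS:
                raise ParameterError(
                    "kinetics too fast for the configured dt (substep cap exceeded)"
                )
            rates = bell_rate(self.model.segment_force(self.s),
                              m.k0_open, m.x_open, mech.kBT)
            r_max = float(rates.max()) if rates.size else 0.0
            slack = F < m.slack_force
            if slack and self.n_transient > 0:
                r_max = max(r_max, m.k_recover)
            dt_sub = remaining if r_max <= 0 else min(
                remaining, MAX_STEP_PROBABILITY / r_max
            )

            # bond ruptures -> slide and rebind, processed in random order
            p = -np.expm1(-rates * dt_sub)
            fired = np.flatnonzero(self.rng.random(p.shape) < p)
            if fired.size:
                per_section = np.bincount(fired // m.n_parallel,
                                          minlength=m.n_serial)
                self.rng.shuffle(fired)
                for b in fired:
                    self._slide(int(b), branch, F)
                    F = self._sync()
                if np.any(per_section >= m.n_parallel):
                    raise RuptureError(
                        "simultaneous rupture of a full cross-section"
                    )
            # recovery of transient slides while slack
            if slack and self.n_transient > 0:
                p_rec = -np.expm1(-m.k_recover * dt_sub)
                n_back = self.rng.binomial(self.n_transient, p_rec)
                if n_back:
                    self.n_transient -= int(n_back)
                    self.events.append(
                        (self.t, self.current_cycle, branch.value,
                         "recover_transient", -1, F)
                    )
                    F = self._sync()
            remaining -= dt_sub
        return F


def simulate_keratin(protocol, mech: MechanicalParams | None = None,
                     model: KeratinModel | None = None, seed: int = 0,
                     record_every: int = 1):
    """Run a keratin filament through a full loading protocol.

    Returns ``(records, events, completed)``; deterministic given ``seed``
    (a counter-based Philox stream keyed by the seed drives all kinetics).
    """
    from .protocols import run_protocol

    mech = mech or MechanicalParams()
    model = model or KeratinModel()
    rng = np.random.Generator(np.random.Philox(seed))
    sim = KeratinSim(model, mech, rng)
    return run_protocol(protocol, sim, record_every=record_every)
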