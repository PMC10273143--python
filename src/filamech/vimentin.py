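"""Monte Carlo model of vimentin filament cycling by alpha-helix unfolding.

Vimentin cross-sections hold 32 monomers, modelled as ``n_parallel = 16``
dimer-level elements per cross-section, with ``n_serial`` cross-sections in
series.  Lateral connections inside a cross-section are strong and never
break (the double-network-gel picture): all elements of a cross-section
share the same extension, cross-sections share the same force.

Each element is a two-state-plus-coil unit:

* ``ALPHA``   — folded alpha helix: short rest length, stiff spring.
* ``UNFOLDED``— force-unfolded helix: long rest length; reached from ALPHA
  by Bell kinetics under the element's own tension, irreversibly within a
  trajectory (no refolding to ALPHA).
* ``COIL``    — soft random-coil state adopted by unfolded helices once the
  local tension drops on relaxation.  A coil cycles between a compact and
  an extended configuration with its own weaker force-activated kinetics,
  so repeated cycles keep a smaller but persistent hysteresis while the
  rest length is recovered: the filament softens but keeps its length.

Force balance is the closed-form series-of-parallel-groups reduction: with
group stiffness ``K_i = sum_j k_ij`` and effective group rest length
``R_i = sum_j k_ij l_ij / K_i``, the tension at imposed end-to-end
distance d is ``F = (d - sum_i R_i) / sum_i 1/K_i`` (clamped at zero when
slack).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Branch,
    MechanicalParams,
    ParameterError,
    RuptureError,
    bell_rate,
    MAX_STEP_PROBABILITY,
)

_MAX_SUBSTEPS = 1000

# state codes
ALPHA, UNFOLDED, COIL_COMPACT, COIL_EXTENDED = 0, 1, 2, 3


@dataclass
class VimentinModel:
    """Vimentin lattice geometry, state properties and kinetics.

    State rest lengths and stiffnesses are calibration parameters; the
    defaults are calibrated so the first stretch shows the measured
    elastic/plateau/stiffening shape (plateau onset near strain 0.15 at
    about 250 pN) and the measured dissipation, and are recorded with
    provenance tags in ``defaults.yaml``.
    """

    n_serial: int = 40
    n_parallel: int = 16         # 32 monomers -> 16 dimer-level elements
    len_alpha: float = 43.0      # nm
    len_unfolded: float = 73.0   # nm (unfolded helices are longest)
    len_coil: float = 47.0       # nm (length-recovering: close to alpha)
    coil_extension: float = 18.0 # nm added in the extended coil configuration
    k_alpha: float = 2.4         # pN/nm
    k_unfolded: float = 1.2      # pN/nm
    k_coil: float = 1.1          # pN/nm (coil is softer than alpha)
    k0_unfold: float = 2.4e-8    # 1/s (calibrated)
    x_unfold: float = 3.5        # nm (calibrated)
    k0_coil_ext: float = 7e-6    # 1/s (calibrated, weaker threshold)
    x_coil_ext: float = 3.0      # nm
    refold_force: float = 5.0    # pN; UNFOLDED -> COIL below this on relax
    coil_retract_force: float = 5.0  # pN; COIL_EXTENDED -> compact below this
    hf_destabilize: bool = False # optional second-cycle rupture rule
    destabilize_fraction: float = 0.9
    destabilize_rupture_force: float = 250.0  # pN, rupture threshold once destabilized

    def __post_init__(self) -> None:
        if self.n_serial < 2 or self.n_parallel < 2:
            raise ParameterError("lattice must be at least 2 x 2")
        if not self.len_unfolded > self.len_alpha:
            raise ParameterError("UNFOLDED rest length must exceed ALPHA")
        if not self.k_coil < self.k_alpha:
            raise ParameterError("COIL must be softer than ALPHA")
        if min(self.k0_unfold, self.x_unfold, self.k0_coil_ext,
               self.x_coil_ext) < 0:
            raise ParameterError("rates and distances must be non-negative")

    @property
    def L0(self) -> float:
        return self.n_serial * self.len_alpha

    def state_rest(self) -> np.ndarray:
        return np.array([self.len_alpha, self.len_unfolded, self.len_coil,
                         self.len_coil + self.coil_extension])

    def state_k(self) -> np.ndarray:
        return np.array([self.k_alpha, self.k_unfolded, self.k_coil,
                         self.k_coil])


class VimentinSim:
    """Stepper for one vimentin filament trajectory."""

    def __init__(self, model: VimentinModel, mech: MechanicalParams, rng):
        self.model = model
        self.mech = mech
        self.rng = rng
        self.L0 = model.L0
        self.t = 0.0
        self.d = self.L0
        self.states = np.zeros((model.n_serial, model.n_parallel), dtype=np.int8)
        self._rest = model.state_rest()
        self._k = model.state_k()
        self.current_cycle = 1
        self.events: list[tuple] = []
        self._doomed = False      # set by the optional destabilization rule
        self.section_length_log: list[np.ndarray] | None = None

    # -- mechanics ---------------------------------------------------------

    def _balance(self):
        """Force and per-section lengths at the imposed distance."""
        k = self._k[self.states]           # (ns, np)
        l = self._rest[self.states]
        K = k.sum(axis=1)                  # group stiffness
        R = (k * l).sum(axis=1) / K        # effective group rest length
        compliance = (1.0 / K).sum()
        F = (self.d - R.sum()) / compliance
        if F <= 0.0:                       # slack filament
            return 0.0, R
        return float(F), R + F / K

    def force(self) -> float:
        return self._balance()[0]

    def element_tensions(self):
        """Per-element tension (clamped at zero) given the current balance."""
        F, sec_len = self._balance()
        k = self._k[self.states]
        l = self._rest[self.states]
        f = k * (sec_len[:, None] - l)
        return np.clip(f, 0.0, None), F

    @property
    def rest_length(self) -> float:
        k = self._k[self.states]
        l = self._rest[self.states]
        return float(((k * l).sum(axis=1) / k.sum(axis=1)).sum())

    # -- kinetics ----------------------------------------------------------

    def _transition(self, flat_index: int, new_state: int, branch: Branch,
                    F: float, kind: str) -> None:
        self.states.flat[flat_index] = new_state
        i, j = divmod(flat_index, self.model.n_parallel)
        self.events.append((self.t, self.current_cycle, branch.value, kind, j, F))

    def step(self, direction: int, branch: Branch) -> float:
        m, mech = self.model, self.mech
        dt = mech.dt
        self.t += dt
        self.d += direction * mech.pulling_speed * dt

        if self._doomed and branch is Branch.STRETCH:
            if self.force() > m.destabilize_rupture_force:
                raise RuptureError("destabilized filament ruptured on reloading")

        remaining = dt
        n_sub = 0
        while remaining > 0.0:
            n_sub += 1
            if n_sub > _MAX_SUBSTEPS:
                raise ParameterError(
                    "kinetics too fast for the configured dt (substep cap exceeded)"
                )
            f, F = self.element_tensions()
            rates = np.zeros_like(f)
            alpha = self.states == ALPHA
            coil_c = self.states == COIL_COMPACT
            rates[alpha] = bell_rate(f[alpha], m.k0_unfold, m.x_unfold, mech.kBT)
            rates[coil_c] = bell_rate(f[coil_c], m.k0_coil_ext, m.x_coil_ext,
                                      mech.kBT)
            r_max = float(rates.max()) if rates.size else 0.0
            dt_sub = remaining if r_max <= 0 else min(
                remaining, MAX_STEP_PROBABILITY / r_max
            )

            p = -np.expm1(-rates * dt_sub)
            fired = np.flatnonzero(self.rng.random(p.shape) < p)
            if fired.size:
                self.rng.shuffle(fired)
                for b in fired:
                    s = int(self.states.flat[b])
                    if s == ALPHA:
                        self._transition(int(b), UNFOLDED, branch, F, "unfold")
                    elif s == COIL_COMPACT:
                        self._transition(int(b), COIL_EXTENDED, branch, F,
                                         "coil_extend")
                    F = self.force()

            # deterministic low-tension coil retraction.  An extended coil
            # snaps back only when it would also be relaxed in the compact
            # configuration (hypothetical compact tension below threshold),
            # so extension is not undone while the section is still long.
            F, sec_len = self._balance()
            f_compact = self._k[COIL_COMPACT] * (sec_len[:, None]
                                                 - self._rest[COIL_COMPACT])
            retract = (self.states == COIL_EXTENDED) & (f_compact
                                                        < m.coil_retract_force)
            if np.any(retract):
                self.states[retract] = COIL_COMPACT
                self.events.append((self.t, self.current_cycle, branch.value,
                                    "coil_retract", int(retract.sum()), F))
            remaining -= dt_sub

        F = self.force()
        if self.section_length_log is not None:
            self.section_length_log.append(self._balance()[1].copy())
        return F

    def on_cycle_end(self, branch: Branch = Branch.RELAX) -> None:
        """Between-cycles relaxation of the fully slack filament.

        Unfolded helices turn into random coils, and extended coils snap
        back to the compact configuration, once the load is fully removed
        at the end of a relax branch; the filament rest length returns to
        within one element length of the original (times the converted
        fraction), so repeated cycles conserve filament length.
        """
        m = self.model
        if m.hf_destabilize and not self._doomed:
            # structural changes during the cycle destabilize the filament:
            # if nearly all helices left the folded state, the next
            # high-force reloading ruptures it
            if (self.states != ALPHA).mean() > m.destabilize_fraction:
                self._doomed = True
        refold = self.states == UNFOLDED
        if np.any(refold):
            self.states[refold] = COIL_COMPACT
            self.events.append((self.t, self.current_cycle, branch.value,
                                "unfolded_to_coil", int(refold.sum()), 0.0))
        retract = self.states == COIL_EXTENDED
        if np.any(retract):
            self.states[retract] = COIL_COMPACT
            self.events.append((self.t, self.current_cycle, branch.value,
                                "coil_retract", int(retract.sum()), 0.0))


def simulate_vimentin(protocol, mech: MechanicalParams | None = None,
                      model: VimentinModel | None = None, seed: int = 0,
                      record_every: int = 1, log_section_lengths: bool = False):
    """Run a vimentin filament through a full loading protocol.

    Returns ``(records, events, completed)``; deterministic given ``seed``.
    With ``log_section_lengths`` the per-step cross-section lengths are
    collected on the simulator (``sim.section_length_log``) for diagnostic
    use; the log is returned as a fourth element in that case.
    """
    from .protocols import run_protocol

    mech = mech or MechanicalParams()
    model = model or VimentinModel()
    rng = np.random.Generator(np.random.Philox(seed))
    sim = VimentinSim(model, mech, rng)
    if log_section_lengths:
        sim.section_length_log = []
    out = run_protocol(protocol, sim, record_every=record_every)
    if log_section_lengths:
        return (*out, sim.section_length_log)
    return out
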