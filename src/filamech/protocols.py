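"""Loading programs for stretch-relax cycling and their calibration triggers.

Two protocol modes mirror the measurements:

* ``CONST_DMAX`` — the first stretch runs until the trigger force is
  reached; the distance at which that happens is fixed as ``d_max`` for all
  following cycles, so the peak force may decrease from cycle to cycle.
* ``CONST_FMAX`` — every stretch runs until the trigger force is first
  attained, so the peak distance may grow from cycle to cycle.

Two force regimes: LF (trigger 250 pN, the typical onset force of the
vimentin plateau) and HF (up to 900 pN).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Branch, ForceExtensionRecord, ParameterError, RuptureError


class ProtocolError(RuntimeError):
    """A loading program could not be executed (e.g. trigger never reached)."""


class Mode(enum.Enum):
    CONST_DMAX = "const_dmax"
    CONST_FMAX = "const_fmax"


class Regime(enum.Enum):
    LF = "lf"
    HF = "hf"


_DEFAULT_TRIGGER = {Regime.LF: 250.0, Regime.HF: 900.0}


@dataclass
class ProtocolSpec:
    """A loading program: mode, force regime, cycle count and triggers."""

    mode: Mode = Mode.CONST_DMAX
    regime: Regime = Regime.LF
    n_cycles: int = 8
    F_trigger: Optional[float] = None   # pN; defaults to 250 (LF) / 900 (HF)
    d_max_nm: Optional[float] = None    # explicit distance trigger (overrides force)
    dmax_rule: str = "force"            # "force" | "plateau_onset" (cycle-1 stop)
    onset_margin: float = 0.08          # strain past the detected onset (plateau_onset)
    relax_to: Optional[float] = None    # nm; default: the starting distance
    max_strain: float = 4.0             # safety bound on d / L0 - 1

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if self.F_trigger is None:
            self.F_trigger = _DEFAULT_TRIGGER[self.regime]
        if self.F_trigger <= 0:
            raise ParameterError("F_trigger must be positive")
        if self.dmax_rule not in ("force", "plateau_onset"):
            raise ParameterError("dmax_rule must be 'force' or 'plateau_onset'")


def first_upward_crossing(x: np.ndarray, y: np.ndarray, y_ref: float) -> float:
    """x-position of the first upward crossing of ``y_ref``, interpolated.

    Noisy traces may cross several times; the first crossing from below is
    used, which is the operational meaning of "the distance at which a
    force is reached".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y[0] >= y_ref:
        raise ProtocolError(f"trace starts at or above the reference ({y_ref})")
    below = y[:-1] < y_ref
    above = y[1:] >= y_ref
    idx = np.flatnonzero(below & above)
    if idx.size == 0:
        raise ProtocolError(f"trace never reaches the reference value {y_ref}")
    i = int(idx[0])
    frac = (y_ref - y[i]) / (y[i + 1] - y[i])
    return float(x[i] + frac * (x[i + 1] - x[i]))


def calibrate_dmax_keratin(first_stretch: ForceExtensionRecord,
                           F_trigger: float = 250.0) -> float:
    """Distance at which the trigger force is first reached on cycle 1.

    Keratin filaments show no force plateau, so the maximum distance is
    fixed where the initial stretch first attains ``F_trigger``.
    """
    return first_upward_crossing(first_stretch.d, first_stretch.F, F_trigger)


def calibrate_dmax_vimentin(first_stretch: ForceExtensionRecord,
                            L0: Optional[float] = None,
                            slope_drop: float = 0.5,
                            window: float = 0.05) -> float:
    """Distance at the onset of the force plateau of a vimentin stretch.

    Operational definition: sliding a fitting window of ``window`` strain
    along the curve, the onset is the first window whose local slope falls
    below ``slope_drop`` times the initial elastic slope.  Raises
    :class:`ProtocolError` when no such drop exists (no plateau).
    """
    from .analysis import reference_length  # local import to avoid a cycle

    if L0 is None:
        L0 = reference_length(first_stretch)
    eps = (first_stretch.d - L0) / L0
    F = first_stretch.F
    start = float(eps[0])
    centers = np.arange(start + window / 2, float(eps[-1]) - window / 2,
                        window / 4)
    slopes, cs = [], []
    for c in centers:
        m = (eps >= c - window / 2) & (eps <= c + window / 2)
        if m.sum() < 3:
            continue
        slopes.append(np.polyfit(eps[m], F[m], 1)[0])
        cs.append(c)
    if len(slopes) < 2:
        raise ProtocolError("stretch too short for plateau detection")
    slopes = np.asarray(slopes)
    cs = np.asarray(cs)
    ref = slopes[0]
    hit = np.flatnonzero(slopes < slope_drop * ref)
    if hit.size == 0:
        raise ProtocolError("no plateau onset detected (slope never drops)")
    onset_strain = float(cs[hit[0]])
    return L0 * (1.0 + onset_strain)


def run_protocol(spec: ProtocolSpec, sim, record_every: int = 1):
    """Drive a filament stepper through stretch-relax cycles.

    ``sim`` must expose ``t``, ``d``, ``L0``, ``current_cycle``, ``events``
    and ``step(direction, branch) -> force``.  Returns
    ``(records, events, completed)``: one STRETCH and one RELAX
    :class:`ForceExtensionRecord` per cycle; on mid-protocol rupture the
    partial records collected so far are returned with ``completed=False``.
    """
    records: list[ForceExtensionRecord] = []
    d_start = sim.d
    relax_to = spec.relax_to if spec.relax_to is not None else d_start
    d_cap = sim.L0 * (1.0 + spec.max_strain)
    d_max: Optional[float] = spec.d_max_nm
    completed = True

    try:
        for cycle in range(1, spec.n_cycles + 1):
            sim.current_cycle = cycle
            # --- stretch ---
            ts, ds, Fs = [sim.t], [sim.d], [sim.force()]
            n = 0
            onset_check = (spec.dmax_rule == "plateau_onset" and cycle == 1
                           and d_max is None)
            while True:
                F = sim.step(+1, Branch.STRETCH)
                n += 1
                if n % record_every == 0:
                    ts.append(sim.t), ds.append(sim.d), Fs.append(F)
                if d_max is not None:
                    if sim.d >= d_max:
                        break
                    if spec.mode is Mode.CONST_FMAX and F >= spec.F_trigger:
                        break
                elif F >= spec.F_trigger and not onset_check:
                    break
                elif onset_check and n % 25 == 0 and F > 0.3 * spec.F_trigger:
                    # stop the first stretch at the beginning of the force
                    # plateau, detected online by the slope-drop criterion
                    partial = ForceExtensionRecord(
                        np.array(ts), np.array(ds), np.array(Fs),
                        Branch.STRETCH, cycle)
                    try:
                        calibrate_dmax_vimentin(partial)
                        # probe a little way into the plateau before turning
                        d_max = sim.d + spec.onset_margin * sim.L0
                        onset_check = False
                    except RuntimeError:
                        pass  # onset not (yet) detectable
                if sim.d > d_cap:
                    raise ProtocolError(
                        "trigger not reached before the strain safety bound"
                    )
            if ts[-1] != sim.t:
                ts.append(sim.t), ds.append(sim.d), Fs.append(F)
            if cycle == 1 and spec.mode is Mode.CONST_DMAX and d_max is None:
                d_max = sim.d
            if spec.mode is Mode.CONST_FMAX:
                d_max = None if spec.d_max_nm is None else d_max
            records.append(ForceExtensionRecord(
                np.array(ts), np.array(ds), np.array(Fs),
                Branch.STRETCH, cycle))
            # --- relax ---
            ts, ds, Fs = [sim.t], [sim.d], [sim.force()]
            n = 0
            while sim.d > relax_to:
                F = sim.step(-1, Branch.RELAX)
                n += 1
                if n % record_every == 0:
                    ts.append(sim.t), ds.append(sim.d), Fs.append(F)
            if ts[-1] != sim.t:
                ts.append(sim.t), ds.append(sim.d), Fs.append(F)
            records.append(ForceExtensionRecord(
                np.array(ts), np.array(ds), np.array(Fs),
                Branch.RELAX, cycle))
            hook = getattr(sim, "on_cycle_end", None)
            if hook is not None:
                hook()
    except RuptureError:
        completed = False

    return records, list(sim.events), completed
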