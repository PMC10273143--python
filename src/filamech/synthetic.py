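"""Synthetic optical-tweezers stretch-relax traces with known ground truth.

Generates force-distance-time cycles that emulate the statistical structure
of single-filament pulling experiments — monotone commanded distance ramps,
additive Gaussian force noise, a low-force region so the 5 pN reference
length is defined — over three noiseless templates:

* ``LINEAR``        — F = kappa (eps - eps_e), the pure elastic fixture;
* ``KERATIN_LIKE``  — near-linear rise with stiffening above strain 0.7;
* ``VIMENTIN_LIKE`` — elastic rise, force plateau between strains 0.15 and
  0.8, stiffening beyond.

Every injected parameter (true stiffness, per-cycle effective lengths,
plateau bounds, noise level) is recorded in a truth manifest so the
analysis pipeline can be validated end-to-end without any simulator.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import Branch, ForceExtensionRecord, ParameterError


class Template(enum.Enum):
    LINEAR = "linear"
    KERATIN_LIKE = "keratin_like"
    VIMENTIN_LIKE = "vimentin_like"


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a synthetic filament."""

    template: Template = Template.LINEAR
    kappa_true: float = 500.0           # pN per unit strain
    eps_e_schedule: tuple = (0.0,)      # true effective length per cycle
    L0_true: float = 860.0              # nm
    eps_start: float = -0.02            # commanded strain at cycle start
    eps_max: float = 0.55               # commanded strain at the turnaround
    plateau_bounds: tuple = (0.15, 0.8) # VIMENTIN_LIKE only
    plateau_slope_frac: float = 0.05    # plateau slope as a fraction of kappa
    stiffen_onset: float = 0.7          # KERATIN_LIKE stiffening strain
    stiffen_factor: float = 3.0
    noise_sd: float = 2.0               # pN, additive white Gaussian on force
    relax_fraction: float = 0.5         # relax-branch force scale (1 = elastic)
    sample_rate: float = 1000.0         # 1/s
    pulling_speed: float = 500.0        # nm/s
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.template, str):
            self.template = Template(self.template)
        if self.noise_sd < 0 or self.kappa_true <= 0 or self.L0_true <= 0:
            raise ParameterError("noise_sd >= 0 and kappa, L0 > 0 required")
        lo, hi = self.plateau_bounds
        if self.template is Template.VIMENTIN_LIKE and not lo < hi:
            raise ParameterError("plateau bounds inverted")
        if self.eps_max <= self.eps_start:
            raise ParameterError("eps_max must exceed eps_start")
        sched = np.asarray(self.eps_e_schedule, dtype=float)
        if np.any(np.diff(sched) < 0):
            raise ParameterError("eps_e_schedule must be non-decreasing")

    def force_template(self, eps, cycle_index: int = 1):
        """Noiseless stretch-branch force at the given strain values."""
        sched = self.eps_e_schedule
        eps_e = sched[min(cycle_index, len(sched)) - 1]
        x = np.asarray(eps, dtype=float) - eps_e
        k = self.kappa_true
        if self.template is Template.LINEAR:
            F = k * x
        elif self.template is Template.KERATIN_LIKE:
            on = self.stiffen_onset
            F = np.where(x <= on, k * x,
                         k * on + self.stiffen_factor * k * (x - on))
        else:
            lo, hi = self.plateau_bounds
            kp = self.plateau_slope_frac * k
            F = np.where(
                x <= lo, k * x,
                np.where(x <= hi, k * lo + kp * (x - lo),
                         k * lo + kp * (hi - lo)
                         + self.stiffen_factor * k * (x - hi)))
        return np.clip(F, 0.0, None)


def generate_cycle(truth: SyntheticTruth, cycle_index: int = 1, rng=None):
    """One stretch-relax cycle: a pair of ForceExtensionRecords.

    Deterministic for a given (truth.seed, cycle_index); the underlying
    noiseless curve passes exactly through the template shifted by the
    cycle's true effective length.
    """
    if rng is None:
        rng = np.random.Generator(np.random.Philox(key=truth.seed,
                                                   counter=cycle_index))
    L0 = truth.L0_true
    d_lo = L0 * (1 + truth.eps_start)
    d_hi = L0 * (1 + truth.eps_max)
    n = max(int(round((d_hi - d_lo) / truth.pulling_speed
                      * truth.sample_rate)), 2)
    t0 = (cycle_index - 1) * 2 * n / truth.sample_rate
    t = t0 + np.arange(n) / truth.sample_rate
    d = np.linspace(d_lo, d_hi, n)
    eps = (d - L0) / L0
    F_clean = truth.force_template(eps, cycle_index)
    F = F_clean + rng.normal(0.0, truth.noise_sd, n) if truth.noise_sd else \
        F_clean.copy()
    stretch = ForceExtensionRecord(t, d, F, Branch.STRETCH, cycle_index)

    t_r = t[-1] + (np.arange(1, n + 1)) / truth.sample_rate
    d_r = d[::-1]
    F_clean_r = truth.force_template((d_r - L0) / L0, cycle_index) \
        * truth.relax_fraction
    F_r = F_clean_r + rng.normal(0.0, truth.noise_sd, n) if truth.noise_sd \
        else F_clean_r
    relax = ForceExtensionRecord(t_r, d_r, F_r, Branch.RELAX, cycle_index)
    return stretch, relax


def generate_filament(truth: SyntheticTruth, n_cycles: int | None = None):
    """All cycles of one synthetic filament (list of records)."""
    if n_cycles is None:
        n_cycles = len(truth.eps_e_schedule)
    records = []
    for c in range(1, n_cycles + 1):
        records.extend(generate_cycle(truth, c))
    return records


def generate_cohort(truths, seed: int = 0, n_cycles: int | None = None,
                    outdir: str | Path | None = None,
                    n_filaments: int | None = None):
    """A cohort of synthetic filaments plus a truth manifest.

    ``truths`` is a list of :class:`SyntheticTruth` (one per filament), or a
    single truth combined with ``n_filaments`` replicates.  Per-filament
    seeds are derived from the master seed so two runs with the same master
    seed produce identical traces.  With ``outdir`` the traces are written
    as CSV files next to a ``truth_manifest.json``.
    """
    from . import io as fio

    if isinstance(truths, SyntheticTruth):
        truths = [truths] * (n_filaments if n_filaments is not None else 1)
    cohort, manifest = [], []
    for fid, base in enumerate(truths):
        truth = SyntheticTruth(**{**vars(base),
                                  "template": base.template.value,
                                  "seed": int(seed * 100003 + fid)})
        records = generate_filament(truth, n_cycles)
        cohort.append(records)
        entry = {k: (v.value if isinstance(v, Template) else
                     list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(truth).items()}
        entry["filament"] = fid
        manifest.append(entry)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for fid, records in enumerate(cohort):
            fio.write_trace_csv(records, outdir / f"filament_{fid:03d}.csv")
        (outdir / "truth_manifest.json").write_text(
            json.dumps(manifest, indent=1))
    return cohort, manifest
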