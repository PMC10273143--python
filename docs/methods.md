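# Methods

## Scope and units

`filamech` models single keratin and vimentin intermediate filaments under
quasi-static cyclic stretching and reproduces the complete force-strain
cycle analysis used on optical-tweezers data. Forces are in pN, lengths in
nm, times in s, energies in pN·nm; kBT = 4.114 pN·nm (room temperature,
the experiments do not state a temperature). Inertia, solvent drag, bead
and trap dynamics, and thermal force fluctuations at fixed internal state
are all neglected: pulling is slow compared with elastic relaxation, so the
filament is in force balance at every Monte Carlo step.

## Shared kinetics

All force-activated transitions use Bell (slip-bond) kinetics,
k(f) = k₀·exp(f·x/kBT), the standard single-barrier law for bond rupture
and domain unfolding. Time is advanced in fixed steps dt = 1 ms; a
transition with rate k fires within a step with probability 1 − exp(−k·dt).
Whenever the largest instantaneous rate would give a per-step probability
above 0.1, the step is subdivided adaptively until every per-substep
probability is below 0.1 (this is checked against an event-driven
exponential-waiting-time oracle in the tests). Simultaneously fired
transitions are resolved sequentially in random order, re-evaluating the
force balance after each event. Each replicate filament is driven by its
own counter-based (Philox) random stream keyed by the seed, so runs are
bit-reproducible.

## Keratin: sliding at constant stiffness

The filament is a lattice of `n_serial = 20` axial repeats by
`n_parallel = 8` protofilament chains (16 monomers = 8 dimers per
cross-section). The longitudinal dimer backbone is elastic: per-segment
force f(e) = k·e for an elastic stretch e below 24 nm, and stiffer
(8 pN/nm) beyond — the high-strain stiffening seen above strain ≈ 0.7.
Under the mean-field reduction, tension is shared equally among the
parallel chains, so the filament force is
F = n_parallel · f((d − R)/n_serial), with d the end-to-end distance and R
the current rest length. The fitted stiffness κ_f is therefore an
invariant of the model by construction: sliding never changes the springs.

Each of the 160 axial interfaces carries one lateral bond. A bond's
rupture rate depends on its *own* local tension, which is reset to zero
when the bond (re)binds and then grows with further elastic deformation
(uniformly distributed across the 20 repeats). This reload-limited
formulation is the package's key mechanistic choice: a freshly rebound
bond must be re-strained before it can rupture again, so the sliding flow
is a bounded fraction of the pulling speed at *any* force. A formulation
in which every bond always carries F/n_parallel has a hard force ceiling —
the creep flow grows exponentially with force and can always absorb the
imposed pulling — and can never reach the 900 pN high-force trigger.

On rupture the subunit slides one period δ = 55 nm (about one unit-length
filament repeat; the slide distance is not observable in the data and is a
calibration parameter) and rebinds instantly:

* with probability `p_neighbor = 0.10` at the shifted periodic site of a
  neighbouring dimer — a **permanent slip**; the chain's rest length grows
  by δ, the filament's by δ/n_parallel;
* otherwise back to its original partner — a **transient slide** with the
  same immediate mechanical effect, but reverted (rate 25 s⁻¹) once the
  filament is slack (< 5 pN), restoring the original registry between
  cycles.

Both event types dissipate the elastic energy released by the local
relaxation, which is why the first cycle dissipates more than half of the
input energy while the permanent elongation per cycle stays small; the
10 : 90 split between permanent and transient rebinding ties the
elongation band (ε_e ≈ 0.1–0.2 after eight 250 pN cycles, 0.6–0.8 after
eight 900 pN cycles) to the dissipated fraction. A simultaneous rupture of
all bonds in one cross-section within a single substep is treated as
filament rupture and truncates the trajectory.

## Vimentin: unfolding at constant length

The filament is `n_serial = 40` rigid cross-sections in series, each
holding `n_parallel = 16` dimer-level elements in parallel (32 monomers).
Elements in a cross-section share extension; cross-sections share force;
the force balance is closed-form:
F = (d − Σᵢ Rᵢ) / Σᵢ 1/Kᵢ with Kᵢ = Σⱼ kᵢⱼ and
Rᵢ = Σⱼ kᵢⱼ·lᵢⱼ / Kᵢ, clamped at zero when slack. Forty sections (rather
than the sketch-level twenty) keep single-section unfolding avalanches
from dropping the force into the 100–150 pN fit window; each avalanche
then costs ≈ 15–30 pN, giving the experimentally flat-looking sawtooth
plateau.

Element states: **α** (rest 43 nm, 2.4 pN/nm) unfolds irreversibly under
its own tension (Bell, k₀ = 2.4·10⁻⁸ s⁻¹, x = 3.5 nm, calibrated so the
plateau rides at ≈ 250 pN starting at strain ≈ 0.15); **unfolded** (rest
73 nm, 1.2 pN/nm) sets the plateau extent (strains ≈ 0.15–0.85) and the
recoverable elastic energy of the relax branch; **coil** (rest 47 nm,
1.1 pN/nm) is the soft persistent state unfolded helices adopt once the
load is removed. A coil cycles between compact and extended (+18 nm)
configurations with its own weaker Bell kinetics (threshold ≈ 190 pN at
the filament level), so repeated cycles keep a smaller but persistent
hysteresis while the rest length recovers: the filament softens but keeps
its length. Extension is not undone while the section is still long — an
extended coil retracts only when its *hypothetical compact* tension falls
below 5 pN.

The unfolded→coil conversion happens when a relax branch completes and the
filament is fully slack (every local tension ≈ 0). A per-element 5 pN
threshold applied mid-relax was rejected: converting a long slack element
to a short coil at fixed distance re-tensions the filament and produces
force spikes on the relax branch that the measured curves do not show; the
end-of-relax rule places the conversion between cycles, where the
underlying cycling experiments locate it.

An optional destabilization rule (off by default) marks the filament
doomed when more than 90% of all elements have left the α state by the end
of a cycle; it then ruptures on the next reloading above 250 pN —
mirroring the observation that high-force vimentin always breaks in the
second cycle.

## Loading protocols

* `CONST_DMAX`: the first stretch runs to the trigger force (250 pN LF,
  900 pN HF); the distance reached is fixed for all later cycles, so the
  peak force decays as the filament elongates.
* `CONST_FMAX`: every stretch runs to the trigger force, so the peak
  distance grows.
* `dmax_rule = "plateau_onset"` (vimentin): the simulated plateau rides at
  or slightly below 250 pN, so a force trigger would run through the whole
  plateau; instead the first stretch stops at the detected plateau onset
  plus a 0.08-strain margin — the measured vimentin protocol stretches "to
  the beginning of the plateau", i.e. slightly into it, which is also what
  produces the observed softening and per-cycle hysteresis.
* Plateau onset detector: sliding 0.05-strain window fits; the onset is
  the first window whose slope drops below 50% of the initial elastic
  slope (both fractions configurable).
* Relaxation returns to the starting distance at the pulling speed
  (500 nm/s); there is no inter-cycle pause — dwell times are not
  reported for the experiments.

## Cycle analysis

The analysis chain is independent of the simulators and consumes plain
force-distance-time traces. Reference length L₀ = distance at the first
upward 5 pN crossing of the first stretch (linear interpolation); all
strains of that filament use this L₀. Window fits use the stretch branch.
κ_f and ε_e come from ordinary least squares on samples with
F ∈ [100, 150] pN (slope and x-intercept); κ_ε from a fixed strain window
[0.1, 0.3], optionally on the corrected strain ε_c = ε − ε_e. Energies use
the trapezoid rule on the common distance support of the two branches
(non-overlapping tails excluded); E_rel = (E_in − E_return)/E_in and the
absolute dissipated energy is reported per initial length in kBT/µm.
Percentiles use linear interpolation between order statistics (type 7).
A cycle that fails a fit precondition yields missing values, never an
abort.

Two measurement details are robustified against noise, in ways that are
exactly inert on noiseless traces: (i) the 5 pN crossing is detected on a
Savitzky–Golay (order 1) locally line-fitted force whose window is a fixed
fraction (2%) of the trace, because the reference force is of the same
order as trap noise and a raw first crossing fires on the first upward
noise excursion; (ii) membership of the 100–150 pN fit window is decided
on a lightly smoothed force (11-sample running mean), because selecting on
the raw noisy force preferentially admits down-fluctuated points at the
top edge and up-fluctuated points at the bottom edge and attenuates the
fitted slope by ≈ 10% at 5 pN noise. With these choices the ε_e estimator
is unbiased to < 0.005 strain and κ_f to < 2% at 5 pN Gaussian noise
(verified over 1000 synthetic cycles).

## Synthetic traces

The generator emulates the statistical structure of the stretch-relax
measurements — commanded monotone distance ramps, additive white Gaussian
force noise (default SD 2 pN; trap force-detection noise dominates and the
distance is the commanded coordinate), a guaranteed 5 pN crossing — over
three C0 piecewise-linear/power templates: linear, keratin-like (near
linear, stiffening above strain 0.7) and vimentin-like (plateau between
strains 0.15 and 0.8). Every injected parameter is recorded in a truth
manifest. What passing generator-based tests shows is that the *analysis
chain* recovers known inputs; it does not validate the filament models
against real data, and the generator deliberately omits drift,
low-frequency bead noise, attachment-geometry artefacts and rupture
events.

## Problem sizes and calibration

Default cohorts use 20 replicate filaments per condition and 8 cycles
(15 where the analysis window extends to the 15th cycle); the
cross-model elongation cohorts use the four keratin loading programs
(LF/HF × constant-d_max/constant-F_max) plus a vimentin fixed-distance
grid spanning ε_max 0.45–1.0, 15 cycles each. These sizes put the median
estimates comfortably inside the reported bands while keeping a full
acceptance run at a few CPU-minutes.

All free coarse-grained constants (spring stiffnesses, Bell parameters,
state lengths, the slide period) are calibration parameters: they were
fixed once so that the default simulators land inside the measured bands
for first-cycle shape (250 pN near strain 0.55 for keratin; plateau onset
near 0.15 at ≈ 250 pN for vimentin), elongation, stiffness and
dissipation, and they are recorded with provenance tags in
`defaults.yaml`. The keratin slide period was re-centred once (60 → 55 nm)
after a larger replicate study showed the elongation median sitting high
in its band.

## Known limitations

* The keratin model dissipates in proportion to its creep every cycle, so
  its repeated-cycle relative dissipation stays at ≈ 0.5–0.7 instead of
  decaying towards ≈ 0.3 as measured; consequently the repeated-cycle
  vimentin/keratin dissipation ratio comes out near 0.7–1.0 rather than
  the measured ≈ 2. Capturing the measured decay would need a
  work-hardening mechanism (early cycles consuming "easy" slip sites)
  that the break–slide–rebind picture with identical-property rebinding
  does not contain.
* Mean-field load sharing ignores stress heterogeneity along and across
  the filament; rupture statistics of weakly-coupled protofilaments are
  not reproduced, and the keratin cross-section rupture rule is a contract
  placeholder rather than a calibrated failure model.
* The vimentin model has no β-sheet transition and no explicit tetramer
  compaction; above the plateau it is simply elastic in the unfolded
  state, so very high-strain (> 1.2) behaviour is extrapolation.
* Filament lengths are fixed (1.1 µm keratin, 1.7 µm vimentin);
  experimental filaments span a range of lengths, which the strain
  normalisation removes only to first order.
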