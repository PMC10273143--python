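# filamech

Coarse-grained mechanics of single keratin and vimentin intermediate
filaments under cyclic stretching.

Keratin and vimentin are the intermediate filaments of epithelial and
mesenchymal cells; the switch between them during the
epithelial-to-mesenchymal transition changes cell mechanics. Optical
tweezers stretch-relax experiments on single filaments show that the two
respond in opposite ways: **keratin filaments elongate plastically but keep
their stiffness** (metal-like slip plasticity), while **vimentin filaments
keep their length but soften** (Mullins-like damage of a double-network
material) — and both dissipate a large fraction of the input energy, of
order 10⁴ kBT/µm, through entirely different mechanisms.

`filamech` implements:

* a **keratin model**: a lattice of `n_serial × n_parallel` dimer chains
  whose lateral bonds rupture under force with Bell kinetics
  k(f) = k₀·exp(f·x/kBT); a ruptured subunit slides by one lattice period δ
  and rebinds — with probability p ≈ 0.1 at a *neighbouring* site (a
  permanent slip that elongates the filament by δ/n_parallel), otherwise
  back to its original partner (a transient slide, recovered when the
  filament goes slack). Because new bonds have the same properties as old
  ones, the stiffness never changes while the rest length creeps.
* a **vimentin model**: serial cross-sections of parallel two-state
  elements; α-helices unfold irreversibly under their own tension
  (producing the force plateau between strains ≈ 0.15 and 0.8 at ≈ 250 pN),
  convert to a *softer random-coil state* once the filament is unloaded,
  and the coils then cycle in length on later stretches — persistent
  softening with length recovery.
* the **loading programs** of the experiments: constant-d_max and
  constant-F_max cycling in the low-force (250 pN) and high-force (900 pN)
  regimes, plus a plateau-onset trigger for vimentin;
* the full **cycle analysis**: reference length L₀ at 5 pN, strain
  ε = ΔL/L₀, the 100–150 pN window fit giving the stretching stiffness κ_f
  and the effective length ε_e (x-intercept), strain-window stiffness κ_ε
  with the corrected strain ε_c = ε − ε_e, hysteresis energies (relative,
  and absolute per length in kBT/µm), Δε_e, cohort medians/quartiles,
  Freedman–Diaconis bin widths and the ε_e-vs-ε_max regression;
* a **synthetic trace generator** with known ground truth (linear,
  keratin-like and vimentin-like templates plus Gaussian force noise) for
  end-to-end validation of the analysis chain.

## Worked example

```python
from filamech import ProtocolSpec, Regime, simulate_keratin, analyze_filament

records, events, ok = simulate_keratin(ProtocolSpec(regime=Regime.LF), seed=1)
metrics = analyze_filament(records)
print(metrics[["cycle", "eps_max", "eps_e", "kappa_f", "E_rel"]].round(3))
```

prints (one keratin filament, eight constant-d_max cycles to a 250 pN
first-cycle trigger):

```
 cycle  eps_max  eps_e  kappa_f  E_rel
     1     0.55 -0.006  797.000  0.612
     2     0.55  0.003  690.883  0.639
     3     0.55  0.043  797.000  0.608
     4     0.55  0.050  797.000  0.616
     5     0.55  0.072  690.112  0.537
     6     0.55  0.112  797.000  0.499
     7     0.55  0.118  797.000  0.572
     8     0.55  0.137  797.000  0.468
```

The filament is stretched to strain 0.55 each cycle; its effective length
ε_e (the x-intercept of the 100–150 pN window fit, i.e. the plastic
elongation in strain units) creeps from ≈ 0 to 0.14 — 26 permanent slip
events in this run — while the stiffness κ_f (pN per unit strain) stays at
its first-cycle value, and each cycle dissipates half or more of the input
energy. A vimentin filament run the same way shows the opposite: ε_e stays
near zero, κ_f drops after the first cycle and then saturates.

The same pipeline is available from the shell:

```sh
filamech simulate --model keratin --regime lf --cycles 8 --replicates 5 \
    --seed 1 --out runs/keratin
filamech analyze --traces runs/keratin --out runs/keratin_metrics
filamech report  --metrics runs/keratin_metrics/metrics.csv --out runs/report
filamech synth   --template vimentin_like --n 10 --out runs/fixtures
```

All model defaults live in `src/filamech/defaults.yaml`, each tagged as
experiment-stated, calibrated, or plumbing; a run manifest (seed, config
hash, versions) is written next to every output.

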