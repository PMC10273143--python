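"""Shared fixtures: simulated cohorts reused across acceptance tests.

The cohorts are the study conditions: default model parameters, the four
loading programs, and at least 20 replicate filaments where a median over
replicates is asserted.  They are session-scoped because the Monte Carlo
runs dominate the suite's runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

from filamech import (
    KeratinModel,
    MechanicalParams,
    Mode,
    ProtocolSpec,
    Regime,
    VimentinModel,
    analyze_cohort,
    simulate_keratin,
    simulate_vimentin,
)

N_REPLICATES = 20


@pytest.fixture(scope="session")
def mech():
    return MechanicalParams()


@pytest.fixture(scope="session")
def keratin_lf_cohort(mech):
    """Keratin, constant-dmax LF (250 pN trigger), 15 cycles, 20 seeds."""
    spec = ProtocolSpec(mode=Mode.CONST_DMAX, regime=Regime.LF, n_cycles=15)
    runs = [simulate_keratin(spec, mech, seed=s, record_every=2)[0]
            for s in range(1, N_REPLICATES + 1)]
    return runs, analyze_cohort(runs)


@pytest.fixture(scope="session")
def keratin_hf_cohort(mech):
    """Keratin, constant-dmax HF (900 pN trigger), 8 cycles, 20 seeds."""
    spec = ProtocolSpec(mode=Mode.CONST_DMAX, regime=Regime.HF, n_cycles=8)
    runs = [simulate_keratin(spec, mech, seed=100 + s, record_every=2)[0]
            for s in range(1, N_REPLICATES + 1)]
    return runs, analyze_cohort(runs)


@pytest.fixture(scope="session")
def keratin_cf_cohort(mech):
    """Keratin, constant-Fmax LF, 8 cycles, 10 seeds (matched comparison)."""
    spec = ProtocolSpec(mode=Mode.CONST_FMAX, regime=Regime.LF, n_cycles=8)
    runs = [simulate_keratin(spec, mech, seed=200 + s, record_every=2)[0]
            for s in range(1, 11)]
    return runs, analyze_cohort(runs)


@pytest.fixture(scope="session")
def vimentin_lf_cohort(mech):
    """Vimentin, constant-dmax at the plateau onset, 15 cycles, 20 seeds."""
    spec = ProtocolSpec(mode=Mode.CONST_DMAX, regime=Regime.LF, n_cycles=15,
                        dmax_rule="plateau_onset")
    runs = [simulate_vimentin(spec, mech, seed=300 + s, record_every=2)[0]
            for s in range(1, N_REPLICATES + 1)]
    return runs, analyze_cohort(runs)


@pytest.fixture(scope="session")
def vimentin_deep_cycle(mech):
    """Vimentin, one stretch-relax cycle to strain 0.8, 20 seeds."""
    model = VimentinModel()
    spec = ProtocolSpec(n_cycles=1, d_max_nm=model.L0 * 1.8)
    runs = [simulate_vimentin(spec, mech, model, seed=400 + s,
                              record_every=2)[0]
            for s in range(1, N_REPLICATES + 1)]
    return runs, analyze_cohort(runs)


@pytest.fixture(scope="session")
def cross_model_cohort(mech):
    """The elongation-vs-maxstrain cohorts: the four keratin loading
    programs (LF/HF x constant-dmax/constant-Fmax) and a vimentin
    fixed-distance grid spanning eps_max 0.45-1.0, 15 cycles each."""
    ker, vim = [], []
    programs = [(250.0, Mode.CONST_DMAX), (900.0, Mode.CONST_DMAX),
                (250.0, Mode.CONST_FMAX), (900.0, Mode.CONST_FMAX)]
    for i, (trig, mode) in enumerate(programs):
        spec = ProtocolSpec(mode=mode, F_trigger=trig, n_cycles=15)
        ker.append(simulate_keratin(spec, mech, seed=500 + i,
                                    record_every=2)[0])
    vmodel = VimentinModel()
    for i, em in enumerate(np.linspace(0.45, 1.0, 4)):
        spec = ProtocolSpec(n_cycles=15, d_max_nm=vmodel.L0 * (1 + em))
        vim.append(simulate_vimentin(spec, mech, vmodel, seed=600 + i,
                                     record_every=2)[0])
    return analyze_cohort(ker), analyze_cohort(vim)
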