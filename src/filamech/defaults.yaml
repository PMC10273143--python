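# Default run configuration and model parameters.
#
# Provenance tags:
#   stated     — value printed in the measurement literature this package models
#   calibrated — free coarse-grained parameter, fixed once so the default
#                simulators reproduce the measured elongation / stiffness /
#                dissipation bands; do not tune per run
#   invented   — plumbing choice with no physical counterpart
#
# These values mirror the dataclass defaults in keratin.py / vimentin.py /
# core.py / protocols.py (a unit test keeps them in sync).

mechanics:
  kBT: 4.114            # pN nm, room temperature               [stated]
  pulling_speed: 500.0  # nm/s                                  [calibrated]
  dt: 0.001             # s, base Monte Carlo step              [invented]

keratin:
  n_serial: 20          # axial repeats                         [calibrated]
  n_parallel: 8         # 16 monomers -> 8 dimer chains         [stated]
  period: 55.0          # nm, axial repeat = slide distance     [calibrated]
  spring_k: 1.8         # pN/nm, longitudinal dimer spring      [calibrated]
  stiff_k: 8.0          # pN/nm, backbone above stiffening      [calibrated]
  stiff_onset: 24.0     # nm/segment elastic stretch            [calibrated]
  k0_open: 1.0e-4       # 1/s, zero-force bond opening          [calibrated]
  x_open: 1.2           # nm, Bell distance                     [calibrated]
  p_neighbor: 0.10      # rebind-to-neighbour fraction          [stated]
  k_recover: 25.0       # 1/s, transient slide return when slack [calibrated]
  slack_force: 5.0      # pN                                    [stated]

vimentin:
  n_serial: 40          # cross-sections                        [calibrated]
  n_parallel: 16        # 32 monomers -> 16 dimer elements      [stated]
  len_alpha: 43.0       # nm                                    [calibrated]
  len_unfolded: 73.0    # nm                                    [calibrated]
  len_coil: 47.0        # nm                                    [calibrated]
  coil_extension: 18.0  # nm                                    [calibrated]
  k_alpha: 2.4          # pN/nm                                 [calibrated]
  k_unfolded: 1.2       # pN/nm                                 [calibrated]
  k_coil: 1.1           # pN/nm                                 [calibrated]
  k0_unfold: 2.4e-8     # 1/s                                   [calibrated]
  x_unfold: 3.5         # nm                                    [calibrated]
  k0_coil_ext: 7.0e-6   # 1/s                                   [calibrated]
  x_coil_ext: 3.0       # nm                                    [calibrated]
  refold_force: 5.0     # pN                                    [calibrated]
  coil_retract_force: 5.0  # pN                                 [calibrated]
  hf_destabilize: false # optional second-cycle rupture rule    [invented]
  destabilize_fraction: 0.9                                   # [invented]
  destabilize_rupture_force: 250.0  # pN                        [invented]

protocol:
  mode: const_dmax      # const_dmax | const_fmax               [stated]
  regime: lf            # lf (250 pN) | hf (900 pN)             [stated]
  n_cycles: 8           #                                       [stated]
  dmax_rule: force      # force | plateau_onset                 [invented]
  onset_margin: 0.08    # strain past detected onset            [calibrated]

analysis:
  F_ref: 5.0            # pN, reference-length crossing         [stated]
  F_lo: 100.0           # pN, stiffness/elongation fit window   [stated]
  F_hi: 150.0           # pN                                    [stated]
  eps_lo: 0.1           # strain-window fit                     [stated]
  eps_hi: 0.3           #                                       [stated]
  eps_threshold: 0.4    # elongation-vs-maxstrain fit cutoff    [stated]
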