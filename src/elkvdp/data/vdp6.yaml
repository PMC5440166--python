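# Canonical 6-state VDP gating scheme for zELK-type KCNH channels.
# Rates in s^-1 at 0 mV (k0) with exponential voltage dependence k1 (mV^-1).
# The mode-reverse rates eps_r and mode_closed_rev are package defaults chosen
# so recovery from potentiation at -100 mV relaxes with tau ~ 136 ms; the
# mode_closed_fwd rate is fixed by detailed balance:
#   k = (gamma/delta) * (eps/eps_r) * (kappa/omicron) * mode_closed_rev
scheme:
  name: vdp6
  conductance: 1.0
  e_rev: 0.0
  states:
    - {name: C1}
    - {name: C2}
    - {name: O1, conducting: true}
    - {name: C1p, mode: potentiated}
    - {name: C2p, mode: potentiated}
    - {name: O2, conducting: true, mode: potentiated}
  transitions:
    - {from: C1,  to: C2,  k0: 80.0,   k1: 0.025,  label: alpha_n}
    - {from: C2,  to: C1,  k0: 600.0,  k1: -0.025, label: beta_n}
    - {from: C2,  to: O1,  k0: 60.0,   label: gamma}
    - {from: O1,  to: C2,  k0: 200.0,  label: delta}
    - {from: C1p, to: C2p, k0: 80.0,   k1: 0.025,  label: alpha_p}
    - {from: C2p, to: C1p, k0: 600.0,  k1: -0.025, label: beta_p}
    - {from: C2p, to: O2,  k0: 5000.0, label: omicron}
    - {from: O2,  to: C2p, k0: 70.0,   label: kappa}
    - {from: O1,  to: O2,  k0: 35.0,   label: eps}
    - {from: O2,  to: O1,  k0: 2.0,    label: eps_r}
    - {from: C1,  to: C1p, k0: 0.5292, label: mode_closed_fwd}
    - {from: C1p, to: C1,  k0: 7.2,    label: mode_closed_rev}

protocols:
  # Step family for current-voltage relations and activation kinetics.
  iv:
    dt: 1.0e-4
    epochs:
      - {voltage: -100, duration: 0.05}
      - {voltage: 0,    duration: 0.5}    # variable test voltage
      - {voltage: -100, duration: 0.15}
    variable_epoch: 1
    variable_field: voltage
    variable_values: [-120, -100, -80, -60, -40, -20, 0, 20, 40, 60, 80, 100, 120]
  # Tail-current G-V family without a depolarising prepulse.
  gv_naive:
    dt: 1.0e-4
    epochs:
      - {voltage: -100, duration: 0.05}
      - {voltage: 0,    duration: 0.1}    # variable test voltage
      - {voltage: -100, duration: 0.15}
    variable_epoch: 1
    variable_field: voltage
    variable_values: [-120, -100, -80, -60, -40, -20, 0, 20, 40, 60, 80, 100, 120]
  # Same family preceded by a 500 ms +60 mV potentiating prepulse.
  gv_prepulse:
    dt: 1.0e-4
    epochs:
      - {voltage: -100, duration: 0.05}
      - {voltage: 60,   duration: 0.5}
      - {voltage: -100, duration: 0.01}
      - {voltage: 0,    duration: 0.1}    # variable test voltage
      - {voltage: -100, duration: 0.15}
    variable_epoch: 3
    variable_field: voltage
    variable_values: [-120, -100, -80, -60, -40, -20, 0, 20, 40, 60, 80, 100, 120]
  # +60 mV pulses of increasing duration; tails report potentiation build-up.
  duration:
    dt: 1.0e-4
    epochs:
      - {voltage: -100, duration: 0.05}
      - {voltage: 60,   duration: 0.1}    # variable test duration
      - {voltage: -100, duration: 0.15}
    variable_epoch: 1
    variable_field: duration
    variable_values: [0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0]
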