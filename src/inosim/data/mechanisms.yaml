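# Positive-inotropy mechanism scans and the in vitro sarcomere-shortening
# effects (fraction of control) observed at each compound's EC50 in adult
# human primary cardiomyocytes, with the maximum fraction seen in vitro.
mechanisms:
  extracellular_ca_increase: {params: [cao], range: [1, 3], direction: increase}
  ical_activation: {params: [sCaL], range: [1, 3], direction: increase}
  ryr_activation: {params: [sJrel], range: [1, 3], direction: increase}
  serca_activation: {params: [sJup], range: [1, 3], direction: increase}
  ncx_inactivation: {params: [sNCX], range: [0.1, 1], direction: decrease}
  beta_adrenergic: {params: [sCaL, sKs], range: [1, 3], direction: increase}
  ca_sensitivity_decrease: {params: [ca50_scale], range: [0.1, 1], direction: decrease}
  nak_inactivation: {params: [sNaK], range: [0.1, 1], direction: decrease}
  myosin_activation: {params: [kuw_scale], range: [1, 5], direction: increase}
compounds:
  - {compound: CaCl2, mechanism: extracellular_ca_increase, ec50_fraction: 1.20, max_invitro_fraction: 2.20}
  - {compound: Levosimendan, mechanism: ca_sensitivity_decrease, ec50_fraction: 1.15, max_invitro_fraction: 1.31}
  - {compound: Bay-K 8644, mechanism: ical_activation, ec50_fraction: 1.38, max_invitro_fraction: 1.80}
  - {compound: SEA-0400, mechanism: ncx_inactivation, ec50_fraction: 1.36, max_invitro_fraction: 1.68}
  - {compound: Digoxin, mechanism: nak_inactivation, ec50_fraction: 1.77, max_invitro_fraction: 2.50}
  - {compound: Ouabain, mechanism: nak_inactivation, ec50_fraction: 1.73, max_invitro_fraction: 2.37}
  - {compound: EMD-57003, mechanism: myosin_activation, ec50_fraction: 2.37, max_invitro_fraction: 3.68}
  - {compound: Omecamtiv mecarbil, mechanism: myosin_activation, ec50_fraction: 1.81, max_invitro_fraction: 2.63}
  - {compound: Caffeine, mechanism: ryr_activation, ec50_fraction: 1.88, max_invitro_fraction: 2.61}
  - {compound: N-106, mechanism: serca_activation, ec50_fraction: 1.24, max_invitro_fraction: 1.48}
  - {compound: Dobutamine, mechanism: beta_adrenergic, ec50_fraction: 1.71, max_invitro_fraction: 2.26}
  - {compound: Isoproterenol, mechanism: beta_adrenergic, ec50_fraction: 2.58, max_invitro_fraction: 4.34}
  - {compound: Epinephrine, mechanism: beta_adrenergic, ec50_fraction: 1.93, max_invitro_fraction: 2.80}
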