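seed: 7
analysis:
  bin_width_pA: 0.1
  max_channels: 4
  sampling_rate_hz: 10000.0
  filter_hz: 2000.0
conditions:
- name: mg_10mM
  voltage_mV: -80.0
  duration_s: 8.0
  noise_sd_pA: 0.5
  gating:
    n_channels: 1
    po: 0.36
    unitary_conductance_pS: 95.5
    reversal_mV: 0.0
    close_rate_s: 50.0
- name: mg_2mM
  voltage_mV: -80.0
  duration_s: 8.0
  noise_sd_pA: 0.5
  gating:
    n_channels: 1
    po: 0.012
    unitary_conductance_pS: 95.5
    reversal_mV: 0.0
    close_rate_s: 50.0
electrochem:
  cytoplasmic:
    label: cytoplasmic 20 mM HNO3, pH 7
    temperature_K: 295.15
    pH: 7.0
    species:
    - name: NO3
      charge: -1
      mM: 20
    - name: Cl
      charge: -1
      mM: 8.0
    - name: Ca
      charge: 2
      mM: 2.0
    - name: Mg
      charge: 2
      mM: 2.0
    - name: BTP
      charge: 1
      mM: 16
  vacuolar:
    label: vacuolar 200 mM HNO3, pH 5
    temperature_K: 295.15
    pH: 5.0
    species:
    - name: NO3
      charge: -1
      mM: 200
    - name: Cl
      charge: -1
      mM: 8.0
    - name: Ca
      charge: 2
      mM: 2.0
    - name: Mg
      charge: 2
      mM: 2.0
    - name: BTP
      charge: 1
      mM: 101
  nernst_ions:
  - NO3
  junction_potential: true
chelation:
- label: 100 uM free Ca bath
  cacl2_mM: 2.08
  mgcl2_mM: 2.0
- label: 10 mM free Mg bath
  cacl2_mM: 0.0
  mgcl2_mM: 10.44
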