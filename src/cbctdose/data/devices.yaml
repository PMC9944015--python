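# Device registry: the two CBCT units of the audited imaging center.
# DAP correction factors are the QC-established values: 0.76 for the
# 3D Accuitomo 170, 1.0 for the Newtom VGI EVO (recorded DAP accurate).
# Newtom nominal DAPs are cohort means (the unit applies TCM).
schema_version: 1
devices:
  - device_id: accuitomo170
    display_name: 3D Accuitomo 170
    tcm: false
    dap_correction_factor: 0.76
    protocols:
      - {mode: Standard, fov: 4x4, tube_voltage_kv: 90, total_exposure_mas: 87.5, nominal_recorded_dap_dgycm2: 4.02}
      - {mode: Standard, fov: 6x6, tube_voltage_kv: 90, total_exposure_mas: 87.5, nominal_recorded_dap_dgycm2: 8.23}
      - {mode: Standard, fov: 10x5, tube_voltage_kv: 90, total_exposure_mas: 87.5, nominal_recorded_dap_dgycm2: 10.0}
      - {mode: Standard, fov: 8x8, tube_voltage_kv: 90, total_exposure_mas: 87.5, nominal_recorded_dap_dgycm2: 13.1}
      - {mode: Standard, fov: 10x10, tube_voltage_kv: 90, total_exposure_mas: 87.5, nominal_recorded_dap_dgycm2: 18.2}
      - {mode: Standard, fov: 14x10, tube_voltage_kv: 90, total_exposure_mas: 87.5, nominal_recorded_dap_dgycm2: 21.7}
      - {mode: Standard, fov: 17x12, tube_voltage_kv: 90, total_exposure_mas: 87.5, nominal_recorded_dap_dgycm2: 25.6}
      - {mode: High-Fidelity, fov: 14x10, tube_voltage_kv: 90, total_exposure_mas: 154, nominal_recorded_dap_dgycm2: 38.1}
      - {mode: High-Fidelity, fov: 17x12, tube_voltage_kv: 90, total_exposure_mas: 154, nominal_recorded_dap_dgycm2: 45.0}
  - device_id: newtom_vgi_evo
    display_name: Newtom VGI EVO
    tcm: true
    dap_correction_factor: 1.0
    protocols:
      - {mode: Regular scan, fov: 5x5, tube_voltage_kv: 110, total_exposure_mas: [13, 33], nominal_recorded_dap_dgycm2: 1.23}
      - {mode: Regular scan, fov: 8x5, tube_voltage_kv: 110, total_exposure_mas: [13, 33], nominal_recorded_dap_dgycm2: 1.83}
      - {mode: Regular scan, fov: 10x5, tube_voltage_kv: 110, total_exposure_mas: [13, 33], nominal_recorded_dap_dgycm2: 2.12}
      - {mode: Regular scan, fov: 8x8, tube_voltage_kv: 110, total_exposure_mas: [13, 33], nominal_recorded_dap_dgycm2: 2.23}
      - {mode: Regular scan, fov: 12x8, tube_voltage_kv: 110, total_exposure_mas: [13, 33], nominal_recorded_dap_dgycm2: 3.22}
      - {mode: Regular scan, fov: 10x10, tube_voltage_kv: 110, total_exposure_mas: [13, 33], nominal_recorded_dap_dgycm2: 3.31}
      - {mode: Regular scan, fov: 15x12, tube_voltage_kv: 110, total_exposure_mas: [13, 33], nominal_recorded_dap_dgycm2: 4.74}
      - {mode: Regular scan, fov: 16x16, tube_voltage_kv: 110, total_exposure_mas: [13, 33], nominal_recorded_dap_dgycm2: 6.16}
      - {mode: Regular scan, fov: 24x19, tube_voltage_kv: 110, total_exposure_mas: [13, 33], nominal_recorded_dap_dgycm2: 9.54}
      - {mode: High-Resolution, fov: 5x5, tube_voltage_kv: 110, total_exposure_mas: [30, 99], nominal_recorded_dap_dgycm2: 4.20}
      - {mode: High-Resolution, fov: 8x5, tube_voltage_kv: 110, total_exposure_mas: [30, 99], nominal_recorded_dap_dgycm2: 6.77}
      - {mode: High-Resolution, fov: 10x5, tube_voltage_kv: 110, total_exposure_mas: [30, 99], nominal_recorded_dap_dgycm2: 7.82}
      - {mode: High-Resolution, fov: 8x8, tube_voltage_kv: 110, total_exposure_mas: [30, 99], nominal_recorded_dap_dgycm2: 8.29}
      - {mode: High-Resolution, fov: 12x8, tube_voltage_kv: 110, total_exposure_mas: [30, 99], nominal_recorded_dap_dgycm2: 11.3}
      - {mode: High-Resolution, fov: 10x10, tube_voltage_kv: 110, total_exposure_mas: [30, 99], nominal_recorded_dap_dgycm2: 12.5}
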