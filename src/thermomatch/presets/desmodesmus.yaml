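# Resource scenario: Desmodesmus sp. oxygen-evolution assays.
species_name: Desmodesmus sp.
kind: resource
assay_temperatures_C: [14.0, 18.0, 22.0, 26.0, 30.0, 34.0, 38.0, 42.0]
replicates_per_block: 3
n_blocks: 2
oxygen_assay_density_cells_per_mL: 2.0e5
initial_density_cells_per_mL: 1.3e6
rate_presets:
  net_photosynthesis:
    model: tpc
    Ea_eV: 0.66
    Eh_eV: 1.66
    Topt_C: 27.40
    MRP: 7.2e-8
    units: mg_O2_per_L_per_min_per_cell
  respiration:
    model: tpc
    Ea_eV: 0.50
    Eh_eV: 20.0
    Topt_C: 39.34
    MRP: 3.0e-9
    units: mg_O2_per_L_per_min_per_cell
noise:
  slope_noise_sd: null
  density_cv: 0.05
  control_drift_sd: 5.0e-4
  control_density_drift_per_h: 0.0
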