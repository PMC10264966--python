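# Resource scenario: Chlamydomonas reinhardtii oxygen-evolution assays.
# TPC summaries are published point estimates; MRP is in mg O2 L^-1 min^-1
# per cell (the familiar ng-scale values divided by 1e6).
species_name: Chlamydomonas reinhardtii
kind: resource
assay_temperatures_C: [14.0, 18.0, 22.0, 26.0, 30.0, 34.0, 38.0, 42.0]
replicates_per_block: 3
n_blocks: 2
oxygen_assay_density_cells_per_mL: 2.0e4
initial_density_cells_per_mL: 4.5e5
rate_presets:
  net_photosynthesis:
    model: tpc
    Ea_eV: 1.44
    Eh_eV: 5.27
    Topt_C: 31.66
    MRP: 1.29e-6
    units: mg_O2_per_L_per_min_per_cell
  respiration:
    model: tpc
    Ea_eV: 0.57
    Eh_eV: 13.73
    Topt_C: 38.99
    MRP: 3.84e-7
    units: mg_O2_per_L_per_min_per_cell
noise:
  slope_noise_sd: null        # null -> 10% of the organism signal at Topt
  density_cv: 0.05
  control_drift_sd: 5.0e-4    # mg O2 L^-1 min^-1, common slope per block
  control_density_drift_per_h: 0.0
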