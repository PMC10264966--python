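# Consumer-resource pair: Daphnia pulex grazing Desmodesmus sp.
# Ingestion shows no thermal dependence for this pair, so the line is
# zero-slope, pinned at the published crossover temperature.
species_name: Daphnia pulex on Desmodesmus sp.
kind: pair
resource_preset: desmodesmus
assay_temperatures_C: [14.0, 18.0, 22.0, 26.0, 30.0, 32.0, 34.0, 36.0]
replicates_per_block: 3
n_blocks: 2
n_consumers_per_vial: 5
dead_consumer_rate: 0.0
assimilation_efficiency: 0.10
per_cell_energy_J: 4.0e-7
initial_density_cells_per_mL: 1.3e6
ingestion_duration_min: 150.0
rate_presets:
  respiration:
    model: tpc
    Ea_eV: 1.08
    Eh_eV: 1.99
    Topt_C: 29.40
    MRP: 2.00
    units: J_per_L_per_h_per_daphnid
  ingestion:
    model: linear
    slope: 0.0
    tc_anchor_C: 22.5
    zero_slope: true
    units: J_per_L_per_h_per_daphnid
is_line:
  slope_per_C: 0.0004
  anchor_T_C: 25.0
  anchor_IS: 0.012
  noise_sd: 0.005
noise:
  slope_noise_sd: null
  density_cv: 0.05
  control_drift_sd: 5.0e-4
  control_density_drift_per_h: 0.0
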