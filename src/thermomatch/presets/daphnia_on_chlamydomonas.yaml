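# Consumer-resource pair: Daphnia pulex grazing Chlamydomonas reinhardtii.
# Consumer respiration is the published TPC in energetic units; the
# ingestion line is anchored so that the ingestion/respiration balance
# crosses 1 at the published crossover temperature (its intercept is not
# printed anywhere). per_cell_energy_J is a documented placeholder constant:
# every anchored or ratio-based quantity is invariant to it.
species_name: Daphnia pulex on Chlamydomonas reinhardtii
kind: pair
resource_preset: chlamydomonas
assay_temperatures_C: [14.0, 18.0, 22.0, 26.0, 30.0, 32.0, 34.0, 36.0]
replicates_per_block: 3
n_blocks: 2
n_consumers_per_vial: 5
dead_consumer_rate: 0.0
assimilation_efficiency: 0.14
per_cell_energy_J: 1.0e-6
initial_density_cells_per_mL: 4.5e5
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
    slope: -0.075            # J L^-1 h^-1 per daphnid per degC
    tc_anchor_C: 20.7
    zero_slope: false
    units: J_per_L_per_h_per_daphnid
is_line:
  slope_per_C: -0.0007
  anchor_T_C: 25.0
  anchor_IS: 0.018           # h^-1 daphnid^-1 at the anchor temperature
  noise_sd: 0.005
noise:
  slope_noise_sd: null
  density_cv: 0.05
  control_drift_sd: 5.0e-4
  control_density_drift_per_h: 0.0
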