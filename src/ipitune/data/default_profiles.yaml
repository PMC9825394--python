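# Default simulation profiles for the IPI-tuning analysis.
#
# CALIBRATED, NOT MEASURED: parameter means are the published species-average
# estimates of the AMMC-B1 tuning function, and the coefficients of variation
# are computed from the published per-individual estimates. Fluorescence-trace
# constants (baseline, bleach slope, noise, gain) and the behavioural hazard
# rates were never reported and are free parameters chosen to produce
# realistic GCaMP6f recordings and copulation-assay outcomes; they are not
# ground truth.

species_profiles:
  melanogaster:
    param_means: {a: 0.2017, tau_b: 83.9797, c: 1.8644, tau_d: 3.8980}
    param_cv: {a: 0.00266, tau_b: 0.00892, c: 0.12780, tau_d: 0.03068}
    trace_noise_sd: 0.5          # a.u.
    bleach_slope_range: [-0.5, -0.1]   # a.u. per second
    baseline_f0: 100.0           # a.u.
    response_gain: 400.0         # a.u. per unit normalized response
  simulans:
    param_means: {a: 0.2084, tau_b: 85.8339, c: 3.5893, tau_d: 4.0434}
    param_cv: {a: 0.00188, tau_b: 0.00720, c: 0.03531, tau_d: 0.01283}
    trace_noise_sd: 0.5
    bleach_slope_range: [-0.5, -0.1]
    baseline_f0: 100.0
    response_gain: 400.0

behavior_profile:
  observation_limit_min: 35.0
  n_pairs_per_cell: 45
  # Constant copulation hazards per minute, keyed by species and stimulus IPI.
  # melanogaster base rates peak at the conspecific 35-ms song; simulans rates
  # are base * 0.6 (overall slower copulation) * the interaction ratios
  # (1.44, 1.0, 2.30, 1.01, 0.93) at (15, 35, 55, 75, 95) ms, so that the
  # 35-ms-referenced species-by-IPI hazard ratios equal the published values.
  hazard_per_min:
    melanogaster: {15: 0.020, 35: 0.060, 55: 0.050, 75: 0.045, 95: 0.040}
    simulans: {15: 0.01728, 35: 0.036, 55: 0.069, 75: 0.02727, 95: 0.02232}

stimulus:
  ipis_ms: [15, 25, 35, 45, 55, 65, 75, 85, 95, 105]
  n_pulses: 20
  frame_rate_hz: 10.0
  n_trials: 3
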