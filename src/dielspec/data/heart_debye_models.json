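{
  "description": "Three-pole Debye model parameters for six parts of the ovine heart, fitted to the mean of repeated open-ended coaxial probe measurements on four heart samples (A1-A4). A1/A3 models are valid over 500 MHz-20 GHz, A2/A4 over 500 MHz-8.5 GHz. Relaxation times are stored in seconds.",
  "tau_unit": "s",
  "models": [
    {"heart_id": "A1", "part": "appendage_interior", "eps_inf": 6.86, "sigma_s": 0.741,
     "poles": [{"delta_eps": 7.23, "tau_s": 3.4e-10}, {"delta_eps": 4.79, "tau_s": 4.01e-11}, {"delta_eps": 43.27, "tau_s": 8.05e-12}]},
    {"heart_id": "A2", "part": "appendage_interior", "eps_inf": 13.02, "sigma_s": 0.263,
     "poles": [{"delta_eps": 137.91, "tau_s": 2.15e-9}, {"delta_eps": 4.32, "tau_s": 1.01e-10}, {"delta_eps": 37.74, "tau_s": 1.01e-11}]},
    {"heart_id": "A3", "part": "appendage_interior", "eps_inf": 7.12, "sigma_s": 0.426,
     "poles": [{"delta_eps": 88.09, "tau_s": 1.77e-9}, {"delta_eps": 4.84, "tau_s": 7.89e-11}, {"delta_eps": 46.33, "tau_s": 8.38e-12}]},
    {"heart_id": "A4", "part": "appendage_interior", "eps_inf": 12.71, "sigma_s": 0.210,
     "poles": [{"delta_eps": 244.73, "tau_s": 3.03e-9}, {"delta_eps": 4.59, "tau_s": 8.59e-11}, {"delta_eps": 42.98, "tau_s": 9.64e-12}]},
    {"heart_id": "A1", "part": "appendage_exterior", "eps_inf": 7.00, "sigma_s": 0.373,
     "poles": [{"delta_eps": 72.86, "tau_s": 1.39e-9}, {"delta_eps": 4.95, "tau_s": 6.10e-11}, {"delta_eps": 39.72, "tau_s": 8.20e-12}]},
    {"heart_id": "A2", "part": "appendage_exterior", "eps_inf": 11.60, "sigma_s": 0.323,
     "poles": [{"delta_eps": 96.24, "tau_s": 2.02e-9}, {"delta_eps": 4.30, "tau_s": 8.44e-11}, {"delta_eps": 31.89, "tau_s": 9.96e-12}]},
    {"heart_id": "A3", "part": "appendage_exterior", "eps_inf": 7.48, "sigma_s": 0.690,
     "poles": [{"delta_eps": 11.34, "tau_s": 4.2e-10}, {"delta_eps": 4.78, "tau_s": 4.17e-11}, {"delta_eps": 40.64, "tau_s": 8.16e-12}]},
    {"heart_id": "A4", "part": "appendage_exterior", "eps_inf": 14.40, "sigma_s": 0.704,
     "poles": [{"delta_eps": 19.93, "tau_s": 9.7e-10}, {"delta_eps": 3.97, "tau_s": 8.51e-11}, {"delta_eps": 36.31, "tau_s": 1.07e-11}]},
    {"heart_id": "A1", "part": "endocardium", "eps_inf": 7.53, "sigma_s": 0.124,
     "poles": [{"delta_eps": 311.85, "tau_s": 3.41e-9}, {"delta_eps": 4.70, "tau_s": 6.24e-11}, {"delta_eps": 48.61, "tau_s": 8.41e-12}]},
    {"heart_id": "A2", "part": "endocardium", "eps_inf": 13.38, "sigma_s": 0.626,
     "poles": [{"delta_eps": 44.30, "tau_s": 1.31e-9}, {"delta_eps": 3.51, "tau_s": 9.77e-11}, {"delta_eps": 43.37, "tau_s": 1.00e-11}]},
    {"heart_id": "A3", "part": "endocardium", "eps_inf": 7.36, "sigma_s": 0.734,
     "poles": [{"delta_eps": 17.80, "tau_s": 7.4e-10}, {"delta_eps": 4.36, "tau_s": 6.57e-11}, {"delta_eps": 47.12, "tau_s": 8.20e-12}]},
    {"heart_id": "A4", "part": "endocardium", "eps_inf": 14.22, "sigma_s": 0.433,
     "poles": [{"delta_eps": 170.62, "tau_s": 3.31e-9}, {"delta_eps": 3.97, "tau_s": 1.06e-10}, {"delta_eps": 41.88, "tau_s": 1.02e-11}]},
    {"heart_id": "A1", "part": "epicardium", "eps_inf": 7.70, "sigma_s": 0.439,
     "poles": [{"delta_eps": 63.45, "tau_s": 1.40e-9}, {"delta_eps": 5.13, "tau_s": 6.42e-11}, {"delta_eps": 40.64, "tau_s": 8.21e-12}]},
    {"heart_id": "A2", "part": "epicardium", "eps_inf": 12.71, "sigma_s": 0.154,
     "poles": [{"delta_eps": 254.62, "tau_s": 3.34e-9}, {"delta_eps": 4.40, "tau_s": 8.30e-11}, {"delta_eps": 36.84, "tau_s": 9.62e-12}]},
    {"heart_id": "A3", "part": "epicardium", "eps_inf": 6.74, "sigma_s": 0.550,
     "poles": [{"delta_eps": 14.43, "tau_s": 5.4e-10}, {"delta_eps": 4.49, "tau_s": 4.97e-11}, {"delta_eps": 34.95, "tau_s": 8.06e-12}]},
    {"heart_id": "A4", "part": "epicardium", "eps_inf": 14.75, "sigma_s": 0.141,
     "poles": [{"delta_eps": 207.25, "tau_s": 2.64e-9}, {"delta_eps": 4.27, "tau_s": 7.95e-11}, {"delta_eps": 33.65, "tau_s": 1.11e-11}]},
    {"heart_id": "A1", "part": "myocardium", "eps_inf": 8.34, "sigma_s": 0.538,
     "poles": [{"delta_eps": 25.33, "tau_s": 8.6e-10}, {"delta_eps": 4.73, "tau_s": 6.90e-11}, {"delta_eps": 41.52, "tau_s": 8.54e-12}]},
    {"heart_id": "A2", "part": "myocardium", "eps_inf": 10.49, "sigma_s": 0.035,
     "poles": [{"delta_eps": 396.00, "tau_s": 5.37e-9}, {"delta_eps": 4.81, "tau_s": 1.03e-10}, {"delta_eps": 35.23, "tau_s": 9.50e-12}]},
    {"heart_id": "A3", "part": "myocardium", "eps_inf": 8.12, "sigma_s": 0.533,
     "poles": [{"delta_eps": 26.58, "tau_s": 9.2e-10}, {"delta_eps": 5.21, "tau_s": 7.61e-11}, {"delta_eps": 43.11, "tau_s": 8.56e-12}]},
    {"heart_id": "A4", "part": "myocardium", "eps_inf": 12.75, "sigma_s": 0.286,
     "poles": [{"delta_eps": 112.78, "tau_s": 2.15e-9}, {"delta_eps": 5.02, "tau_s": 9.42e-11}, {"delta_eps": 34.14, "tau_s": 1.08e-11}]},
    {"heart_id": "A1", "part": "great_vessels_luminal", "eps_inf": 8.76, "sigma_s": 0.369,
     "poles": [{"delta_eps": 88.96, "tau_s": 1.65e-9}, {"delta_eps": 5.00, "tau_s": 5.70e-11}, {"delta_eps": 40.53, "tau_s": 8.39e-12}]},
    {"heart_id": "A2", "part": "great_vessels_luminal", "eps_inf": 12.75, "sigma_s": 0.012,
     "poles": [{"delta_eps": 376.15, "tau_s": 3.97e-9}, {"delta_eps": 4.68, "tau_s": 7.33e-11}, {"delta_eps": 37.08, "tau_s": 9.68e-12}]},
    {"heart_id": "A3", "part": "great_vessels_luminal", "eps_inf": 8.02, "sigma_s": 0.674,
     "poles": [{"delta_eps": 14.78, "tau_s": 6.0e-10}, {"delta_eps": 5.28, "tau_s": 5.42e-11}, {"delta_eps": 41.48, "tau_s": 8.15e-12}]},
    {"heart_id": "A4", "part": "great_vessels_luminal", "eps_inf": 14.70, "sigma_s": 0.319,
     "poles": [{"delta_eps": 152.86, "tau_s": 2.50e-9}, {"delta_eps": 4.75, "tau_s": 7.34e-11}, {"delta_eps": 34.59, "tau_s": 9.99e-12}]}
  ]
}
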