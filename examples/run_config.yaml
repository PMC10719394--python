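# Full-suite pipeline configuration; every key is optional and shown at its
# default except output_dir/seed.  Run with:  eutroscen run --config examples/run_config.yaml
output_dir: run_output
seed: 1
# outfalls_csv: my_outfalls.csv     # default: built-in synthetic outfall suite
synth_overrides: {}                 # any SynthConfig field, e.g. {nx: 60, ny: 45, months: 12}
# scenario_labels: [CTRL, ANTH]     # default: full 8-scenario suite
theta_omega: 1.4                    # calcifier Omega_Ar threshold
considerable_threshold: 10.0        # mmol m-2 d-1
band_km: 15.0                       # inshore band width
npp_window: [0.0, 100.0]            # m
resp_window: [0.0, 200.0]           # m
isobath_m: 200.0
habitat_metrics: [aerobic]          # add calcifier for the Omega_Ar metric
write_netcdf: false
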