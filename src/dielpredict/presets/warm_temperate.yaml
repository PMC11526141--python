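# Warm temperate harbour: wide seasonal range, moderate diel signal
# present roughly half the time.
site_id: warm_temperate
days: 120
mean_T: 18.0
seasonal_amp_T: 14.0
diel_amp_T: 2.0
p_day: 0.55
ar1_phi: 0.8
noise_sd: 0.7
coupling_kappa: 5.0
lag_tau: 0.0
mean_DO: 85.0
diel_amp_DO: 20.0
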