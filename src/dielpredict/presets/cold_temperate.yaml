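# Cold temperate fjord: narrow, cool regime with a weaker diel cycle
# significant about half of the days.
site_id: cold_temperate
days: 120
mean_T: 10.0
seasonal_amp_T: 5.0
diel_amp_T: 1.2
p_day: 0.5
ar1_phi: 0.8
noise_sd: 0.5
coupling_kappa: 4.0
lag_tau: 3600.0
mean_DO: 100.0
diel_amp_DO: 12.0
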