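# Tropical coastal lagoon: hot, strongly and regularly fluctuating,
# highly predictable diel cycles in both temperature and oxygen.
site_id: tropical
days: 120
mean_T: 30.0
seasonal_amp_T: 4.0
diel_amp_T: 3.0
p_day: 0.9
ar1_phi: 0.8
noise_sd: 0.6
coupling_kappa: 8.0
lag_tau: 3600.0
mean_DO: 110.0
diel_amp_DO: 35.0
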