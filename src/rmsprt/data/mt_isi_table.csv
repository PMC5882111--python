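coherence,n_neurons,pref_mean,pref_sd,omega_null_mean,omega_null_sd,omegad_n2_null_mean,omegad_n2_null_sd,omegad_n4_null_mean,omegad_n4_null_sd
3.2,206,54.1,33.1,59.4,34.5,59.0,34.4,58.5,34.3
6.4,211,52.0,32.2,62.9,35.3,60.6,34.7,59.8,34.4
12.8,213,46.1,30.5,65.5,36.1,60.3,34.6,58.3,34.0
25.6,208,37.7,28.0,70.2,37.2,62.0,34.9,59.9,34.3
51.2,189,29.9,26.0,83.5,40.6,75.5,38.5,71.8,37.4
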