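# Control regime: polarized PCP and myosin enrichment, convergence flow,
# V-biased junction shrinkage and intercalation, rosettes present.
n_cells: 100
n_frames: 31
dt_s: 20.0
enrichment_V: 2.0
enrichment_T: 1.0
myosin_enrichment_V: 1.8
myosin_enrichment_T: 1.0
intensity_length_coupling: 0.2
convergence_rate_per_s: 0.00015
t1_rate_per_cell_per_hr: 0.25
shrink_bias: 0.9
n_rosettes: 2
pulse_coupling_rho: 0.7
pulse_lag_frames: 0
noise_sd: 0.1
reorientation: ml
frap_mobile_fraction: 0.6
frap_tau_s: 25.0
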