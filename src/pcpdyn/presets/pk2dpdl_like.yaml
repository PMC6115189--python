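# Prickle-deletion-construct-like regime: PCP enrichment at V-junctions
# reduced to near baseline, myosin V enrichment lost, no convergence flow,
# unpolarized shrinkage, reduced intercalation, no reorientation.
n_cells: 100
n_frames: 31
dt_s: 20.0
enrichment_V: 1.1
enrichment_T: 1.0
myosin_enrichment_V: 1.05
myosin_enrichment_T: 1.0
intensity_length_coupling: 0.05
convergence_rate_per_s: 0.0
t1_rate_per_cell_per_hr: 0.08
shrink_bias: 0.5
n_rosettes: 0
pulse_coupling_rho: 0.3
pulse_lag_frames: 0
noise_sd: 0.1
reorientation: none
frap_mobile_fraction: 0.8
frap_tau_s: 25.0
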