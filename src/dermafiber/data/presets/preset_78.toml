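# Donor-age preset: targets from the packaged cohort table, generator
# settings chosen a priori (length_mean_um is only the calibration start).

[targets]
age = 78
fiber_count = 1070
mean_diameter_um = 3.36
volume_fraction_pct = 2.32
n_clusters = 51
vertical_proportion_pct = 9.63

[generator]
seed = 1078
length_mean_um = 12.6
length_sd_um = 4.41
diameter_sd_um = 0.25
waviness = 0.04
break_gap_um = 1.2
height_um = 150.0
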