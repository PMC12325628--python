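# Donor-age preset: targets from the packaged cohort table, generator
# settings chosen a priori (length_mean_um is only the calibration start).

[targets]
age = 38
fiber_count = 2437
mean_diameter_um = 3.86
volume_fraction_pct = 4.23
n_clusters = 5
vertical_proportion_pct = 25.44

[generator]
seed = 1038
length_mean_um = 7.6
length_sd_um = 2.66
diameter_sd_um = 0.25
waviness = 0.04
break_gap_um = 1.2
height_um = 150.0
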