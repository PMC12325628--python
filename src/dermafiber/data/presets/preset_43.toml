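# Donor-age preset: targets from the packaged cohort table, generator
# settings chosen a priori (length_mean_um is only the calibration start).

[targets]
age = 43
fiber_count = 2183
mean_diameter_um = 3.68
volume_fraction_pct = 5.26
n_clusters = 11
vertical_proportion_pct = 18.51

[generator]
seed = 1043
length_mean_um = 11.7
length_sd_um = 4.09
diameter_sd_um = 0.25
waviness = 0.04
break_gap_um = 1.2
height_um = 150.0
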