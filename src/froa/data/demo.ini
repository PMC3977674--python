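# Demo pipeline configuration: a small two-group synthetic experiment.
# Scanpath duration parameters follow the reported dwell-time means of the
# two task groups; Monte-Carlo iterations are reduced for a fast demo run
# (the package default is 1000).

[run]
seed = 12345

[geometry]
frame_px = 800
frame_deg = 18.0

[stimuli]
families = dumbbell,elbow
jitter_lo = 0.95
jitter_hi = 1.15

[design]
n_participants_per_group = 4
n_trials = 6
n_fixations = 8

[group.basic]
roi_preference = 0.8
target_model = concave
duration_mean = 198.15
duration_shape = 18.4

[group.subordinate]
roi_preference = 0.8
target_model = concave
duration_mean = 195.99
duration_shape = 18.7

[shape_models]
smoothing_sigma = 15
kappa_min = 0.005
r_min = 2
r_max = 20
kappa_sat = 0.05
prominence = 0.01
band_px = 8

[froa]
region_radius_deg = 1.0
n_iterations = 200
null_density = uniform_object
sidedness = one-sided

[stats]
pooled = true
bonferroni = false
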