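# Synthetic four-level study: wall thickness increases across samples and the
# simulated storage half-life increases linearly with it.  Run with:
#   lyothick run examples/demo.toml -o demo_out

[output]
directory = "demo_out"

[thickness]
bin_um = 0.5
weighting = "voxel_volume"

[segmentation]
median_window = 3
threshold = "otsu"

[viability]
windows = [[0, 28], [28, 56]]

[[samples]]
id = "wall2"
storage = "canister"
phantom = { geometry = "parallel_plates", wall_um = 1.28, spacing_um = 3.84, voxel_um = 0.64, shape = [48, 24, 24] }
render = { noise_sd = 18.0, blur_sigma_voxels = 0.5, seed = 2 }
decay = { half_life_days = 6.2, c0 = 1e9 }

[[samples]]
id = "wall3"
storage = "canister"
phantom = { geometry = "parallel_plates", wall_um = 1.92, spacing_um = 3.84, voxel_um = 0.64, shape = [48, 24, 24] }
render = { noise_sd = 18.0, blur_sigma_voxels = 0.5, seed = 3 }
decay = { half_life_days = 7.8, c0 = 1e9 }

[[samples]]
id = "wall5"
storage = "canister"
phantom = { geometry = "parallel_plates", wall_um = 3.2, spacing_um = 3.84, voxel_um = 0.64, shape = [52, 24, 24] }
render = { noise_sd = 18.0, blur_sigma_voxels = 0.5, seed = 5 }
decay = { half_life_days = 11.0, c0 = 1e9 }

[[samples]]
id = "wall7"
storage = "canister"
phantom = { geometry = "parallel_plates", wall_um = 4.48, spacing_um = 3.84, voxel_um = 0.64, shape = [60, 24, 24] }
render = { noise_sd = 18.0, blur_sigma_voxels = 0.5, seed = 7 }
decay = { half_life_days = 14.2, c0 = 1e9 }
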