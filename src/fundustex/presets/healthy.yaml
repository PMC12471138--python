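# Synthetic cohort emulating the healthy group: dense, wide, branching
# vasculature with no chromatic shift.
group_name: healthy
n_images: 15
image_size: [256, 256]
vessel_density: 0.12
root_count: 6
branch_prob: 0.015
width_mean: 3.4
width_sd: 0.4
tortuosity: 0.15
background_rgb_mean: [170.0, 90.0, 45.0]
background_rgb_sd: [8.0, 8.0, 6.0]
green_shift: 0.0
blue_shift: 0.0
noise_sd: 4.0
seed: 0
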