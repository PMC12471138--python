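# Synthetic cohort emulating a pathological group: sparser, thinner,
# less branching vasculature plus negative green/blue chromatic shifts.
group_name: pathological
n_images: 15
image_size: [256, 256]
vessel_density: 0.07
root_count: 4
branch_prob: 0.008
width_mean: 2.6
width_sd: 0.3
tortuosity: 0.10
background_rgb_mean: [170.0, 90.0, 45.0]
background_rgb_sd: [8.0, 8.0, 6.0]
green_shift: -10.0
blue_shift: -8.0
noise_sd: 4.0
seed: 1
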