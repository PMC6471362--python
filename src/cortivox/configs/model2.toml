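# Validation Model II - healthy cortical bone, 3 x 1.5 x 0.75 mm prism
master_seed = 1
voxel_size_um = 5.0
scale_factor = 1.0

[parameters]
OnDr = [120, 240]
OnDn = 18.5
thetaOn = [0, 6.5]
CLT = [1, 4]
HCDR = [60, 85]
VCDR = [45, 50]
DBVC = [150, 400]
thetaVC = 13

[macroshape]
prism_dims = [3.0, 1.5, 0.75]
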