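# Validation Model III - osteoporotic cortical bone (inputs deliberately
# outside the healthy admissible ranges), 3 x 1.5 x 0.75 mm prism
master_seed = 1
voxel_size_um = 5.0
scale_factor = 1.0

[parameters]
OnDr = [180, 250]
OnDn = 9.5
thetaOn = [0, 3]
CLT = [0, 3]
HCDR = [95, 150]
VCDR = [70, 80]
DBVC = [165, 400]
thetaVC = 15

[macroshape]
prism_dims = [3.0, 1.5, 0.75]
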