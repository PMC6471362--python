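# Validation Model I - healthy cortical bone, 3 x 1.5 x 0.75 mm prism
master_seed = 1
voxel_size_um = 5.0
scale_factor = 1.0

[parameters]
OnDr = [100, 250]      # osteon diameter range, um
OnDn = 22              # osteon density, osteons/mm^2
thetaOn = [0, 10]      # osteon inclination from Z, degrees
CLT = [0, 5]           # cement line thickness, um
HCDR = [50, 90]        # Haversian canal diameter, um
VCDR = [40, 50]        # Volkmann canal diameter, um
DBVC = [150, 500]      # interconnection-point spacing along the axis, um
thetaVC = 15           # max Volkmann inclination from the XY plane, degrees

[macroshape]
prism_dims = [3.0, 1.5, 0.75]  # mm
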